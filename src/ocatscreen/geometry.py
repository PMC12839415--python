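"""Screen geometry and pixel/millimetre/degree conversions.

The OCAT tablet presents stimuli on a 14-inch 1920x1080 screen viewed at
60 cm.  Pixels are assumed square, so a single millimetres-per-pixel factor
is derived from the physical diagonal.  Visual angles use the exact
arctangent form, which is consistent with the small-angle approximation for
the distances that occur on this screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

MM_PER_INCH = 25.4


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical description of the recording setup.

    Defaults match the tablet used for the OCAT: 1920x1080 px, 14-inch
    diagonal, 600 mm viewing distance.
    """

    width_px: int = 1920
    height_px: int = 1080
    diagonal_in: float = 14.0
    viewing_distance_mm: float = 600.0

    def __post_init__(self) -> None:
        if min(self.width_px, self.height_px) <= 0:
            raise ValueError("screen dimensions must be positive")
        if self.diagonal_in <= 0 or self.viewing_distance_mm <= 0:
            raise ValueError("diagonal and viewing distance must be positive")

    @property
    def diagonal_px(self) -> float:
        return math.hypot(self.width_px, self.height_px)

    @property
    def mm_per_px(self) -> float:
        return self.diagonal_in * MM_PER_INCH / self.diagonal_px


DEFAULT_GEOMETRY = ScreenGeometry()


def px_to_mm(d_px, geometry: ScreenGeometry = DEFAULT_GEOMETRY):
    """Convert an on-screen distance in pixels to millimetres."""
    return d_px * geometry.mm_per_px


def mm_to_px(d_mm, geometry: ScreenGeometry = DEFAULT_GEOMETRY):
    return d_mm / geometry.mm_per_px


def mm_to_deg(d_mm, geometry: ScreenGeometry = DEFAULT_GEOMETRY):
    import numpy as np

    return np.degrees(np.arctan(np.asarray(d_mm, dtype=float) / geometry.viewing_distance_mm))


def px_to_deg(d_px, geometry: ScreenGeometry = DEFAULT_GEOMETRY):
    """Convert an on-screen distance in pixels to degrees of visual angle."""
    return mm_to_deg(px_to_mm(d_px, geometry), geometry)


def deg_to_px(d_deg, geometry: ScreenGeometry = DEFAULT_GEOMETRY):
    import numpy as np

    d_mm = np.tan(np.radians(np.asarray(d_deg, dtype=float))) * geometry.viewing_distance_mm
    return mm_to_px(d_mm, geometry)
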