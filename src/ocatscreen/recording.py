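"""Raw gaze recording container and its on-disk CSV dialect.

A :class:`GazeRecording` holds one participant's gaze/pupil time series
sampled at a nominal rate (120 Hz for the OCAT tablet) together with the
stimulus-onset and click event log.  On disk a recording is two CSV files:
``<id>.csv`` with columns ``t_ms, x_px, y_px, pupil_mm, valid`` and a sidecar
``<id>_events.csv`` with columns ``kind, t_ms, seq_idx, pos_idx, target_x_px,
target_y_px`` where ``kind`` is ``onset`` or ``click``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import DEFAULT_GEOMETRY, ScreenGeometry

SAMPLE_COLUMNS = ["t_ms", "x_px", "y_px", "pupil_mm", "valid"]
EVENT_COLUMNS = ["kind", "t_ms", "seq_idx", "pos_idx", "target_x_px", "target_y_px"]


@dataclass
class GazeRecording:
    """Per-participant raw gaze time series plus stimulus/click events.

    ``samples`` columns: t_ms, x_px, y_px, pupil_mm, valid (bool); after QC a
    ``raw_valid`` column preserves the acquisition-time validity flags.
    ``events`` columns: kind ('onset'|'click'), t_ms, seq_idx, pos_idx,
    target_x_px, target_y_px (targets only meaningful for onsets).
    """

    participant_id: str
    samples: pd.DataFrame
    events: pd.DataFrame
    sampling_rate_hz: float = 120.0
    geometry: ScreenGeometry = field(default_factory=lambda: DEFAULT_GEOMETRY)

    def __post_init__(self) -> None:
        if len(self.samples) == 0:
            raise ValueError("recording must contain at least one sample")
        t = self.samples["t_ms"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    # -- derived views -------------------------------------------------

    @property
    def duration_ms(self) -> float:
        t = self.samples["t_ms"].to_numpy()
        return float(t[-1] - t[0])

    @property
    def raw_valid(self) -> np.ndarray:
        """Acquisition-time validity flags (pre-interpolation)."""
        col = "raw_valid" if "raw_valid" in self.samples.columns else "valid"
        return self.samples[col].to_numpy(dtype=bool)

    @property
    def onsets(self) -> pd.DataFrame:
        return self.events[self.events["kind"] == "onset"].reset_index(drop=True)

    @property
    def clicks(self) -> pd.DataFrame:
        return self.events[self.events["kind"] == "click"].reset_index(drop=True)

    def copy(self) -> "GazeRecording":
        return GazeRecording(
            participant_id=self.participant_id,
            samples=self.samples.copy(),
            events=self.events.copy(),
            sampling_rate_hz=self.sampling_rate_hz,
            geometry=self.geometry,
        )

    # -- I/O -----------------------------------------------------------

    def write(self, directory: str | Path) -> tuple[Path, Path]:
        """Write the recording as ``<id>.csv`` + ``<id>_events.csv``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        sample_path = directory / f"{self.participant_id}.csv"
        event_path = directory / f"{self.participant_id}_events.csv"
        out = self.samples.copy()
        out["valid"] = out["valid"].astype(int)
        if "raw_valid" in out.columns:
            out["raw_valid"] = out["raw_valid"].astype(int)
        out.to_csv(sample_path, index=False)
        self.events.to_csv(event_path, index=False)
        return sample_path, event_path


def read_recording(
    sample_path: str | Path,
    event_path: str | Path | None = None,
    sampling_rate_hz: float = 120.0,
    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
) -> GazeRecording:
    """Read a recording from its CSV pair (events path inferred if omitted)."""
    sample_path = Path(sample_path)
    if event_path is None:
        event_path = sample_path.with_name(sample_path.stem + "_events.csv")
    samples = pd.read_csv(sample_path)
    samples["valid"] = samples["valid"].astype(bool)
    if "raw_valid" in samples.columns:
        samples["raw_valid"] = samples["raw_valid"].astype(bool)
    events = pd.read_csv(event_path)
    return GazeRecording(
        participant_id=sample_path.stem,
        samples=samples,
        events=events,
        sampling_rate_hz=sampling_rate_hz,
        geometry=geometry,
    )
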