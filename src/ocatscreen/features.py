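"""Canonical OCAT feature dictionary.

The screening analysis uses 31 named features per participant: 6 time-related
features and 25 eye-movement-related features (18 fixation, 3 saccade, 2 blink,
2 pupillary), plus participant age.  Feature names carry a ``(Log-)`` prefix
where the analysis log-transforms the value before modelling; extraction
always produces the raw (untransformed) value under that name.
"""

from __future__ import annotations

TIME_FEATURES: list[str] = [
    "Total Test Time (s)",
    "Mean Time for Number 1 (low cognitive workload) (s)",
    "Mean Time for Number 2 (medium cognitive workload) (s)",
    "Mean Time for Number 3 (high cognitive workload) (s)",
    "(Log-) Mean Latency Time (ms)",
    "(Log-) Standard Deviation of Latency Time (ms)",
]

FIXATION_FEATURES: list[str] = [
    name
    for k in (1, 2, 3)
    for name in (
        f"Mean Fixation Time for Number {k} (ms)",
        f"(Log-) Standard Deviation of Fixation Time for Number {k} (ms)",
        f"Mean Fixation Size for Number {k} (mm)",
        f"(Log-) Standard Deviation of Fixation Size for Number {k} (mm)",
        f"Mean Fixation Area for Number {k} (mm^2)",
        f"(Log-) Standard Deviation of Fixation Area for Number {k} (mm^2)",
    )
]

SACCADE_FEATURES: list[str] = [
    "Median Diagonal Saccadic Velocity (deg/s)",
    "Median Horizontal Saccadic Velocity (deg/s)",
    "Median Vertical Saccadic Velocity (deg/s)",
]

BLINK_FEATURES: list[str] = [
    "Blink Rate (number of blinks per minute)",
    "Median Blink Duration (ms)",
]

PUPIL_FEATURES: list[str] = [
    "Standard Deviation of Pupil Size (mm)",
    "Coefficient of Variation of Pupil Size",
]

EYE_FEATURES: list[str] = FIXATION_FEATURES + SACCADE_FEATURES + BLINK_FEATURES + PUPIL_FEATURES

ALL_FEATURES: list[str] = TIME_FEATURES + EYE_FEATURES

AGE_FEATURE = "Age (years)"
LABEL_COLUMN = "group"
ID_COLUMN = "id"

#: Features whose name marks them for logarithmic transformation.
LOG_MARKED: list[str] = [f for f in ALL_FEATURES if f.startswith("(Log-)")]

#: Feature-set modes used in the modelling stage.  Age is part of every mode.
FEATURE_SET_MODES: dict[str, list[str]] = {
    "combined": ALL_FEATURES,
    "time_only": TIME_FEATURES,
    "eye_only": EYE_FEATURES,
}


def feature_set(mode: str, include_age: bool = True) -> list[str]:
    """Return the feature names for one of the three modelling modes."""
    try:
        names = list(FEATURE_SET_MODES[mode])
    except KeyError:
        raise ValueError(f"unknown feature-set mode {mode!r}; expected one of {sorted(FEATURE_SET_MODES)}") from None
    if include_age:
        names.append(AGE_FEATURE)
    return names


assert len(TIME_FEATURES) == 6
assert len(EYE_FEATURES) == 25
assert len(ALL_FEATURES) == 31
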