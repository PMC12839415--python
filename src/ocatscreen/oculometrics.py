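"""Fixation/saccade classification and the OCAT feature dictionary.

Fixations are detected with the dispersion-threshold (I-DT) algorithm:
a window of at least the minimum duration whose spatial dispersion -- the
maximum pairwise distance between its samples, expressed in degrees of
visual angle -- stays below threshold is grown until the threshold is
violated, then emitted as a fixation.  Intervals between consecutive
fixations whose displacement exceeds the threshold are saccades.  Invalid
runs (blinks, signal loss) split the recording; events are never joined
across them.

From the classified events plus the stimulus/click log, the module computes
the 31 per-participant features (6 time-related, 25 eye-movement-related)
used by the screening models, with these definitions for the quantities the
protocol names but does not define:

* fixation *size*: maximum pairwise sample distance within the fixation (mm);
* fixation *area*: convex-hull area of the fixation samples (mm^2);
* saccadic *plane*: direction-angle bins of +/-22.5 degrees around the
  horizontal (0/180) and vertical (90/270) axes; everything else diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from . import features as F
from .geometry import DEFAULT_GEOMETRY, ScreenGeometry, deg_to_px, px_to_deg, px_to_mm
from .qc import BLINK_MAX_MS, BLINK_MIN_MS, detect_blinks
from .recording import GazeRecording


class MissingFeatureWarning(UserWarning):
    """A feature could not be computed (no qualifying events)."""


class InvalidRecordingError(ValueError):
    """The recording violates a precondition of feature extraction."""


@dataclass
class OcularEvent:
    kind: str  # 'fixation' | 'saccade'
    t_start_ms: float
    t_end_ms: float
    centroid_px: tuple[float, float]
    dispersion_px: float  # max pairwise sample distance
    points_px: np.ndarray | None = None  # samples of a fixation
    # saccade attributes
    amplitude_deg: float = np.nan
    median_velocity_deg_s: float = np.nan
    direction_deg: float = np.nan  # 0 = rightward, 90 = up
    plane: str | None = None
    start_px: tuple[float, float] | None = None
    end_px: tuple[float, float] | None = None
    # stimulus attribution
    seq_idx: int | None = None
    pos_idx: int | None = None

    @property
    def duration_ms(self) -> float:
        return self.t_end_ms - self.t_start_ms


def direction_plane(angle_deg: float) -> str:
    """Assign a direction angle to the horizontal/vertical/diagonal plane
    using +/-22.5 degree bins around the cardinal axes."""
    fold = angle_deg % 180.0
    if fold <= 22.5 or fold >= 157.5:
        return "horizontal"
    if 67.5 <= fold <= 112.5:
        return "vertical"
    return "diagonal"


def _max_pairwise(x: np.ndarray, y: np.ndarray) -> float:
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    return float(np.sqrt(dx * dx + dy * dy).max())


def _idt_segment(t, x, y, thresh_px, min_dur_ms):
    """I-DT on one contiguous valid segment; yields (i, j) inclusive windows."""
    n = len(t)
    out = []
    i = 0
    while i < n:
        j = int(np.searchsorted(t, t[i] + min_dur_ms, side="left"))
        if j >= n:
            break
        # dispersion of the initial window, tracked incrementally afterwards
        disp = _max_pairwise(x[i : j + 1], y[i : j + 1])
        if disp <= thresh_px:
            k = j + 1
            while k < n:
                cand = max(disp, float(np.hypot(x[i:k] - x[k], y[i:k] - y[k]).max()))
                if cand > thresh_px:
                    break
                disp = cand
                k += 1
            out.append((i, k - 1, disp))
            i = k
        else:
            i += 1
    return out


def idt_classify(
    samples: pd.DataFrame,
    dispersion_thresh_deg: float = 1.0,
    min_duration_ms: float = 100.0,
    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
    saccade_onset_deg_s: float = 60.0,
) -> list[OcularEvent]:
    """Classify cleaned, time-ordered samples into fixations and saccades.

    ``samples`` needs columns ``t_ms, x_px, y_px, valid``.  Returns events in
    time order.  Traces too short for a single minimum-duration window yield
    an empty list.

    Saccade timing is delimited *within* each inter-fixation interval by a
    velocity criterion: from the interval's velocity peak, the movement
    bounds extend while velocity stays above ``saccade_onset_deg_s``.
    Dispersion grouping only localizes the interval; stationary padding at
    its edges (e.g. a dwell too short to qualify as a fixation) is not part
    of the movement.  If the peak never exceeds the criterion the full
    interval is used.
    """
    if dispersion_thresh_deg <= 0 or min_duration_ms <= 0:
        raise ValueError("thresholds must be positive")
    thresh_px = float(deg_to_px(dispersion_thresh_deg, geometry))
    t_all = samples["t_ms"].to_numpy(dtype=float)
    x_all = samples["x_px"].to_numpy(dtype=float)
    y_all = samples["y_px"].to_numpy(dtype=float)
    valid = samples["valid"].to_numpy(dtype=bool)

    events: list[OcularEvent] = []
    n = len(valid)
    seg_start = 0
    while seg_start < n:
        if not valid[seg_start]:
            seg_start += 1
            continue
        seg_end = seg_start
        while seg_end < n and valid[seg_end]:
            seg_end += 1
        t = t_all[seg_start:seg_end]
        x = x_all[seg_start:seg_end]
        y = y_all[seg_start:seg_end]

        fixations = _idt_segment(t, x, y, thresh_px, min_duration_ms)
        seg_events: list[OcularEvent] = []
        for (i, j, disp) in fixations:
            pts = np.column_stack([x[i : j + 1], y[i : j + 1]])
            seg_events.append(
                OcularEvent(
                    kind="fixation",
                    t_start_ms=float(t[i]),
                    t_end_ms=float(t[j]),
                    centroid_px=(float(x[i : j + 1].mean()), float(y[i : j + 1].mean())),
                    dispersion_px=disp,
                    points_px=pts,
                )
            )
        # saccades between consecutive fixations with sufficient displacement
        for a_idx in range(len(fixations) - 1):
            _, ja, _ = fixations[a_idx]
            ib, _, _ = fixations[a_idx + 1]
            if ib - ja < 2:
                # adjacent fixations with no intervening movement samples:
                # an instantaneous centre shift, not a saccade
                continue
            p0 = np.array([x[ja], y[ja]])
            p1 = np.array([x[ib], y[ib]])
            ca = seg_events[a_idx].centroid_px
            cb = seg_events[a_idx + 1].centroid_px
            displacement_px = float(np.hypot(cb[0] - ca[0], cb[1] - ca[1]))
            if px_to_deg(displacement_px, geometry) <= dispersion_thresh_deg:
                continue
            sl = slice(ja, ib + 1)
            vel = np.hypot(np.diff(x[sl]), np.diff(y[sl])) / (np.diff(t[sl]) / 1000.0)
            vel_deg = np.asarray(px_to_deg(vel, geometry))
            peak = int(np.argmax(vel_deg))
            if vel_deg[peak] > saccade_onset_deg_s:
                # walk outward from the velocity peak to the movement bounds
                lo = peak
                while lo > 0 and vel_deg[lo - 1] > saccade_onset_deg_s:
                    lo -= 1
                hi = peak
                while hi < len(vel_deg) - 1 and vel_deg[hi + 1] > saccade_onset_deg_s:
                    hi += 1
                first = ja + lo
                last = ja + hi + 1
                vel_deg = vel_deg[lo : hi + 1]
            else:
                first, last = ja, ib
            dx, dy = p1[0] - p0[0], p1[1] - p0[1]
            angle = float(np.degrees(np.arctan2(-dy, dx)) % 360.0)
            events_sacc = OcularEvent(
                kind="saccade",
                t_start_ms=float(t[first]),
                t_end_ms=float(t[last]),
                centroid_px=(float((p0[0] + p1[0]) / 2), float((p0[1] + p1[1]) / 2)),
                dispersion_px=float(np.hypot(dx, dy)),
                amplitude_deg=float(px_to_deg(np.hypot(dx, dy), geometry)),
                median_velocity_deg_s=float(np.median(vel_deg)) if len(vel_deg) else np.nan,
                direction_deg=angle,
                plane=direction_plane(angle),
                start_px=(float(p0[0]), float(p0[1])),
                end_px=(float(p1[0]), float(p1[1])),
            )
            seg_events.append(events_sacc)
        events.extend(seg_events)
        seg_start = seg_end
    events.sort(key=lambda e: (e.t_start_ms, e.kind))
    return events


def attribute_events(events: list[OcularEvent], onsets: pd.DataFrame, end_ms: float) -> None:
    """Attach (seq_idx, pos_idx) to each event by the stimulus interval that
    contains the event's temporal midpoint."""
    if len(onsets) == 0:
        return
    times = onsets["t_ms"].to_numpy(dtype=float)
    for ev in events:
        mid = 0.5 * (ev.t_start_ms + ev.t_end_ms)
        k = int(np.searchsorted(times, mid, side="right")) - 1
        if k < 0 or mid > end_ms:
            continue
        ev.seq_idx = int(onsets["seq_idx"].iloc[k])
        ev.pos_idx = int(onsets["pos_idx"].iloc[k])


# ---------------------------------------------------------------------------
# Feature computations
# ---------------------------------------------------------------------------


def _circdiff_deg(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def saccadic_latency(
    events: list[OcularEvent],
    stimulus_onsets: pd.DataFrame,
    direction_gate_deg: float = 45.0,
    min_amplitude_deg: float = 2.0,
    max_latency_ms: float = 800.0,
) -> np.ndarray:
    """Per-stimulus saccadic latency (ms).

    For each onset, the latency is the start time (relative to onset) of the
    first saccade beginning in [onset, next onset) whose direction lies
    within ``direction_gate_deg`` of the direction from the saccade's start
    point to the new target.  Saccades smaller than ``min_amplitude_deg``
    are ignored: they are fixational micro-shifts, not target-directed
    movements.  Latencies above ``max_latency_ms`` are treated as artifacts
    (e.g. the true saccade was lost in a blink and a much later movement
    matched) and excluded.  Stimuli with no qualifying saccade yield NaN.
    """
    onsets = stimulus_onsets.sort_values("t_ms").reset_index(drop=True)
    times = onsets["t_ms"].to_numpy(dtype=float)
    bounds = np.append(times[1:], np.inf)
    saccades = [e for e in events
                if e.kind == "saccade" and e.amplitude_deg >= min_amplitude_deg]
    out = np.full(len(onsets), np.nan)
    for k in range(len(onsets)):
        tx, ty = onsets["target_x_px"].iloc[k], onsets["target_y_px"].iloc[k]
        for ev in saccades:
            if not (times[k] <= ev.t_start_ms < bounds[k]):
                continue
            sx, sy = ev.start_px
            to_target = float(np.degrees(np.arctan2(-(ty - sy), tx - sx)) % 360.0)
            if _circdiff_deg(ev.direction_deg, to_target) <= direction_gate_deg:
                lat = ev.t_start_ms - times[k]
                if lat <= max_latency_ms:
                    out[k] = lat
                break
    return out


def _sd(values: np.ndarray) -> float:
    """Population SD; a single observation has zero spread by convention."""
    if len(values) == 0:
        return np.nan
    return float(np.std(values))


def time_features(recording: GazeRecording, latencies: np.ndarray) -> dict[str, float]:
    """The six time-related features (seconds / milliseconds)."""
    onsets = recording.onsets.sort_values(["seq_idx", "pos_idx"])
    clicks = recording.clicks.sort_values(["seq_idx", "pos_idx"])
    if len(onsets) == 0:
        raise InvalidRecordingError("recording has no stimulus onsets")
    merged = onsets.merge(clicks, on=["seq_idx", "pos_idx"], suffixes=("_on", "_click"))
    if len(merged) != len(onsets):
        raise InvalidRecordingError("every stimulus requires exactly one click")
    merged["rt_ms"] = merged["t_ms_click"] - merged["t_ms_on"]
    total_s = (clicks["t_ms"].max() - onsets["t_ms"].min()) / 1000.0
    per_pos = merged.groupby("pos_idx")["rt_ms"].mean() / 1000.0

    lat = latencies[np.isfinite(latencies)]
    if len(lat) == 0:
        warnings.warn("no qualifying saccade for any stimulus; latency features missing",
                      MissingFeatureWarning, stacklevel=2)
        lat_mean = lat_sd = np.nan
    else:
        lat_mean, lat_sd = float(np.mean(lat)), _sd(lat)
    return {
        F.TIME_FEATURES[0]: float(total_s),
        F.TIME_FEATURES[1]: float(per_pos.get(1, np.nan)),
        F.TIME_FEATURES[2]: float(per_pos.get(2, np.nan)),
        F.TIME_FEATURES[3]: float(per_pos.get(3, np.nan)),
        F.TIME_FEATURES[4]: lat_mean,
        F.TIME_FEATURES[5]: lat_sd,
    }


def _hull_area_px2(points: np.ndarray) -> float:
    if points is None or len(points) < 3:
        return 0.0
    try:
        return float(ConvexHull(points).volume)  # 2-D: volume is the area
    except QhullError:
        return 0.0  # collinear samples enclose no area


def fixation_features(
    events: list[OcularEvent], geometry: ScreenGeometry = DEFAULT_GEOMETRY
) -> dict[str, float]:
    """Mean and SD of fixation time (ms), size (mm) and area (mm^2), pooled
    over all fixations attributed to each workload position."""
    out: dict[str, float] = {}
    mm = geometry.mm_per_px
    for k in (1, 2, 3):
        fx = [e for e in events if e.kind == "fixation" and e.pos_idx == k]
        names = [f for f in F.FIXATION_FEATURES if f"Number {k}" in f]
        if not fx:
            warnings.warn(f"no fixations attributed to position {k}", MissingFeatureWarning,
                          stacklevel=2)
            out.update({name: np.nan for name in names})
            continue
        times = np.array([e.duration_ms for e in fx])
        sizes = np.array([e.dispersion_px * mm for e in fx])
        areas = np.array([_hull_area_px2(e.points_px) * mm * mm for e in fx])
        vals = [np.mean(times), _sd(times), np.mean(sizes), _sd(sizes), np.mean(areas), _sd(areas)]
        out.update(dict(zip(names, map(float, vals))))
    return out


def saccade_velocity_features(events: list[OcularEvent]) -> dict[str, float]:
    """Per-plane median of the saccades' median velocities (deg/s)."""
    out = {}
    for plane, name in (
        ("diagonal", F.SACCADE_FEATURES[0]),
        ("horizontal", F.SACCADE_FEATURES[1]),
        ("vertical", F.SACCADE_FEATURES[2]),
    ):
        v = [e.median_velocity_deg_s for e in events if e.kind == "saccade" and e.plane == plane]
        if not v:
            warnings.warn(f"no saccades in the {plane} plane", MissingFeatureWarning, stacklevel=2)
            out[name] = np.nan
        else:
            out[name] = float(np.median(v))
    return out


def blink_features(blinks, duration_s: float) -> dict[str, float]:
    """Blink rate (events/min) and median blink duration (ms)."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rate = 60.0 * len(blinks) / duration_s
    if not blinks:
        warnings.warn("no blinks detected; median duration missing", MissingFeatureWarning,
                      stacklevel=2)
        med = np.nan
    else:
        med = float(np.median([b.duration_ms for b in blinks]))
    return {F.BLINK_FEATURES[0]: float(rate), F.BLINK_FEATURES[1]: med}


def pupil_features(recording: GazeRecording) -> dict[str, float]:
    """SD (mm) and coefficient of variation of pupil size over valid samples."""
    pupil = recording.samples.loc[recording.samples["valid"], "pupil_mm"].to_numpy(dtype=float)
    pupil = pupil[np.isfinite(pupil)]
    if len(pupil) < 2:
        raise InvalidRecordingError("need at least 2 valid pupil samples")
    sd = float(np.std(pupil))
    mean = float(np.mean(pupil))
    return {F.PUPIL_FEATURES[0]: sd, F.PUPIL_FEATURES[1]: sd / mean}


@dataclass(frozen=True)
class ExtractConfig:
    dispersion_thresh_deg: float = 1.0
    min_fixation_ms: float = 100.0
    blink_min_ms: float = BLINK_MIN_MS
    blink_max_ms: float = BLINK_MAX_MS
    latency_gate_deg: float = 45.0
    latency_min_amplitude_deg: float = 2.0
    latency_max_ms: float = 800.0


def extract_features(
    recording: GazeRecording,
    age: float,
    geometry: ScreenGeometry | None = None,
    config: ExtractConfig = ExtractConfig(),
) -> pd.Series:
    """Assemble the full 31-feature vector plus age for one QC'd recording.

    Returns a Series indexed by the canonical feature names; components that
    cannot be computed are NaN (with a :class:`MissingFeatureWarning`).
    """
    geometry = geometry or recording.geometry
    events = idt_classify(recording.samples, config.dispersion_thresh_deg,
                          config.min_fixation_ms, geometry)
    onsets = recording.onsets
    end_ms = float(recording.clicks["t_ms"].max()) if len(recording.clicks) else recording.duration_ms
    attribute_events(events, onsets, end_ms)
    latencies = saccadic_latency(events, onsets, config.latency_gate_deg,
                                 config.latency_min_amplitude_deg,
                                 config.latency_max_ms)
    blinks = detect_blinks(recording, config.blink_min_ms, config.blink_max_ms)

    values: dict[str, float] = {}
    values.update(time_features(recording, latencies))
    values.update(fixation_features(events, geometry))
    values.update(saccade_velocity_features(events))
    values.update(blink_features(blinks, recording.duration_ms / 1000.0))
    values.update(pupil_features(recording))
    values[F.AGE_FEATURE] = float(age)
    return pd.Series(values, index=F.ALL_FEATURES + [F.AGE_FEATURE], dtype=float)


def events_table(events: list[OcularEvent]) -> pd.DataFrame:
    """Event-level export for debugging."""
    return pd.DataFrame(
        [
            {
                "kind": e.kind,
                "t_start_ms": e.t_start_ms,
                "t_end_ms": e.t_end_ms,
                "plane": e.plane,
                "median_velocity_deg_s": e.median_velocity_deg_s,
                "dispersion_px": e.dispersion_px,
                "seq_idx": e.seq_idx,
                "pos_idx": e.pos_idx,
            }
            for e in events
        ]
    )
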