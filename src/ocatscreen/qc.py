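"""Quality control and artifact correction of raw gaze recordings.

Stages, in the order the pipeline applies them:

1. tracking-ratio exclusion -- participants whose fraction of valid samples
   falls below 80% are dropped (an acquisition-quality gate computed on the
   raw validity flags, before any interpolation);
2. spike correction -- samples implying physiologically implausible
   inter-sample angular velocity are invalidated and short invalid gaps are
   re-filled by linear interpolation between the nearest valid neighbours;
3. optional light median filtering (window 3) of the gaze coordinates;
4. blink detection -- maximal runs of invalid samples whose duration lies in
   a physiological band are blinks; longer runs are treated as signal loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import px_to_deg
from .recording import GazeRecording

#: Default maximum gap re-filled by interpolation.  Kept below the blink
#: minimum (75 ms) so interpolation can never fabricate gaze through a blink.
DEFAULT_MAX_GAP_MS = 50.0
DEFAULT_V_MAX_DEG_S = 1000.0
BLINK_MIN_MS = 75.0
BLINK_MAX_MS = 500.0


@dataclass(frozen=True)
class BlinkEvent:
    t_start_ms: float
    t_end_ms: float

    @property
    def duration_ms(self) -> float:
        return self.t_end_ms - self.t_start_ms


@dataclass
class QCReport:
    participant_id: str
    tracking_ratio: float
    included: bool
    n_spikes: int = 0
    n_interpolated: int = 0


def compute_tracking_ratio(recording: GazeRecording) -> float:
    """Fraction of samples with a valid eye detection (raw flags)."""
    raw = recording.raw_valid
    if len(raw) == 0:
        raise ValueError("empty recording")
    return float(raw.sum()) / len(raw)


def apply_exclusion(
    recordings: list[GazeRecording], threshold: float = 0.80
) -> tuple[list[GazeRecording], list[GazeRecording], list[QCReport]]:
    """Partition recordings into (kept, excluded) by tracking ratio >= threshold."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    kept, excluded, reports = [], [], []
    for rec in recordings:
        ratio = compute_tracking_ratio(rec)
        ok = ratio >= threshold
        (kept if ok else excluded).append(rec)
        reports.append(QCReport(rec.participant_id, ratio, ok))
    return kept, excluded, reports


def _valid_chain_spikes(t: np.ndarray, x: np.ndarray, y: np.ndarray,
                        valid: np.ndarray, v_max: float, geometry) -> np.ndarray:
    """Indices of spike samples along the chain of valid samples.

    Interior chain samples are spikes when the angular velocity both into and
    out of them exceeds ``v_max`` (out-and-back excursions); chain endpoints
    are spikes when their single defined velocity -- recomputed after interior
    removal -- exceeds it.
    """
    idx = np.flatnonzero(valid)
    if len(idx) < 2:
        return np.array([], dtype=int)

    def velocities(ii: np.ndarray) -> np.ndarray:
        d = np.hypot(np.diff(x[ii]), np.diff(y[ii]))
        dt_s = np.diff(t[ii]) / 1000.0
        return px_to_deg(d, geometry) / dt_s

    v = velocities(idx)
    fast = v > v_max
    interior = fast[:-1] & fast[1:]  # both sides of chain sample k
    spikes = list(idx[1:-1][interior])

    remaining = np.array([i for i in idx if i not in set(spikes)])
    if len(remaining) >= 2:
        v2 = velocities(remaining)
        if v2[0] > v_max:
            spikes.append(remaining[0])
        if v2[-1] > v_max:
            spikes.append(remaining[-1])
    return np.array(sorted(spikes), dtype=int)


def despike(
    recording: GazeRecording,
    v_max_deg_s: float = DEFAULT_V_MAX_DEG_S,
    max_gap_ms: float = DEFAULT_MAX_GAP_MS,
) -> tuple[GazeRecording, int, int]:
    """Invalidate implausibly fast samples and re-fill short invalid gaps.

    Gaps no longer than ``max_gap_ms`` (whether from spikes or dropouts) are
    linearly interpolated between the nearest valid neighbours; gaps at the
    recording boundary are filled one-sidedly with the nearest valid value.
    Longer gaps (blinks, signal loss) remain invalid.  Timestamps are never
    altered.  Returns ``(corrected, n_spikes, n_interpolated)``; the
    corrected recording keeps the original flags in a ``raw_valid`` column.
    """
    if v_max_deg_s <= 0:
        raise ValueError("v_max_deg_s must be positive")
    rec = recording.copy()
    df = rec.samples
    if "raw_valid" not in df.columns:
        df["raw_valid"] = df["valid"].copy()
    t = df["t_ms"].to_numpy(dtype=float)
    x = df["x_px"].to_numpy(dtype=float)
    y = df["y_px"].to_numpy(dtype=float)
    pupil = df["pupil_mm"].to_numpy(dtype=float)
    valid = df["valid"].to_numpy(dtype=bool).copy()

    spikes = _valid_chain_spikes(t, x, y, valid, v_max_deg_s, rec.geometry)
    valid[spikes] = False

    # interpolate invalid runs of duration <= max_gap_ms
    n = len(valid)
    nominal_dt = 1000.0 / rec.sampling_rate_hz
    n_interp = 0
    i = 0
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        run_ms = (j - i) * nominal_dt
        if run_ms <= max_gap_ms:
            left = i - 1 if i > 0 else None
            right = j if j < n else None
            for arr in (x, y, pupil):
                if left is not None and right is not None:
                    arr[i:j] = np.interp(t[i:j], [t[left], t[right]], [arr[left], arr[right]])
                elif left is not None:
                    arr[i:j] = arr[left]
                elif right is not None:
                    arr[i:j] = arr[right]
                else:
                    run_ms = np.inf  # no valid neighbour anywhere
                    break
            if np.isfinite(run_ms):
                valid[i:j] = True
                n_interp += j - i
        i = j

    df["x_px"] = x
    df["y_px"] = y
    df["pupil_mm"] = pupil
    df["valid"] = valid
    return rec, int(len(spikes)), int(n_interp)


def median_filter_gaze(recording: GazeRecording, window: int = 3) -> GazeRecording:
    """Light median filter on the gaze coordinates of valid samples.

    The recording procedure names filtering without fixing a type; a
    window-3 running median is the default and can simply be skipped.
    """
    if window % 2 != 1 or window < 3:
        raise ValueError("window must be odd and >= 3")
    rec = recording.copy()
    df = rec.samples
    valid = df["valid"].to_numpy(dtype=bool)
    for col in ("x_px", "y_px"):
        v = df[col].to_numpy(dtype=float)
        sub = pd.Series(v[valid])
        df.loc[valid, col] = sub.rolling(window, center=True, min_periods=1).median().to_numpy()
    return rec


def detect_blinks(
    recording: GazeRecording,
    min_ms: float = BLINK_MIN_MS,
    max_ms: float = BLINK_MAX_MS,
) -> list[BlinkEvent]:
    """Blinks: maximal runs of (raw-)invalid samples with duration in
    ``[min_ms, max_ms]``.  Run duration is the run length times the nominal
    sample interval."""
    if not (0 < min_ms < max_ms):
        raise ValueError("need 0 < min_ms < max_ms")
    raw = recording.raw_valid
    t = recording.samples["t_ms"].to_numpy(dtype=float)
    dt = 1000.0 / recording.sampling_rate_hz
    blinks: list[BlinkEvent] = []
    n = len(raw)
    i = 0
    while i < n:
        if raw[i]:
            i += 1
            continue
        j = i
        while j < n and not raw[j]:
            j += 1
        dur = (j - i) * dt
        if min_ms <= dur <= max_ms:
            blinks.append(BlinkEvent(t_start_ms=t[i], t_end_ms=t[i] + dur))
        i = j
    return blinks


def preprocess(
    recording: GazeRecording,
    v_max_deg_s: float = DEFAULT_V_MAX_DEG_S,
    max_gap_ms: float = DEFAULT_MAX_GAP_MS,
    median_window: int | None = 3,
) -> tuple[GazeRecording, QCReport]:
    """Despike + optional median filter; returns the cleaned recording and a
    QC report (tracking ratio computed on raw validity)."""
    ratio = compute_tracking_ratio(recording)
    rec, n_spikes, n_interp = despike(recording, v_max_deg_s, max_gap_ms)
    if median_window:
        rec = median_filter_gaze(rec, median_window)
    report = QCReport(recording.participant_id, ratio, ratio >= 0.80, n_spikes, n_interp)
    return rec, report


def qc_report_table(reports: list[QCReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": r.participant_id,
                "tracking_ratio": r.tracking_ratio,
                "included": r.included,
                "n_spikes": r.n_spikes,
                "n_interpolated": r.n_interpolated,
            }
            for r in reports
        ]
    )
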