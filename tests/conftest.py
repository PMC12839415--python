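import numpy as np
import pandas as pd
import pytest

from ocatscreen.geometry import DEFAULT_GEOMETRY
from ocatscreen.recording import EVENT_COLUMNS, GazeRecording

FS = 120.0
DT = 1000.0 / FS


def make_recording(
    x,
    y,
    valid=None,
    pupil=None,
    events=None,
    participant_id="T000",
    fs=FS,
):
    """Build a GazeRecording from raw coordinate arrays (test helper)."""
    n = len(x)
    t = np.arange(n) * (1000.0 / fs)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    if pupil is None:
        pupil = np.full(n, 3.5)
    samples = pd.DataFrame(
        {"t_ms": t, "x_px": np.asarray(x, float), "y_px": np.asarray(y, float),
         "pupil_mm": np.asarray(pupil, float), "valid": np.asarray(valid, bool)}
    )
    if events is None:
        events = pd.DataFrame(columns=EVENT_COLUMNS)
    return GazeRecording(participant_id=participant_id, samples=samples, events=events,
                         sampling_rate_hz=fs, geometry=DEFAULT_GEOMETRY)


def stationary_trace(n, x0, y0, jitter=0.0, rng=None):
    rng = rng or np.random.default_rng(0)
    return x0 + jitter * rng.standard_normal(n), y0 + jitter * rng.standard_normal(n)


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-effect cohort with extracted features, shared across
    tests that only need 'some realistic' data."""
    from ocatscreen.pipeline import simulate_feature_table
    from ocatscreen.simulate import CohortSpec

    spec = CohortSpec(n_cn=28, n_pmci=12, seed=17)
    features, qc_table, metadata = simulate_feature_table(spec)
    return {"spec": spec, "features": features, "qc": qc_table, "metadata": metadata}
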