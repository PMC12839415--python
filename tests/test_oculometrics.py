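"""Event classification and feature extraction tests, including the
brute-force window-scan oracle for I-DT."""

import numpy as np
import pandas as pd
import pytest

import ocatscreen.features as F
from ocatscreen.geometry import deg_to_px
from ocatscreen.oculometrics import (
    ExtractConfig,
    InvalidRecordingError,
    MissingFeatureWarning,
    OcularEvent,
    blink_features,
    extract_features,
    fixation_features,
    idt_classify,
    pupil_features,
    saccade_velocity_features,
    saccadic_latency,
    time_features,
)
from ocatscreen.qc import BlinkEvent, preprocess
from ocatscreen.recording import EVENT_COLUMNS
from ocatscreen.simulate import CohortSpec, generate_task_script, sample_participant, simulate_gaze

from .conftest import DT, make_recording
from .reference import average_precision_reference, idt_reference

DEG_PX = float(deg_to_px(1.0))  # ~65 px per degree at this geometry


class TestIDT:
    def test_stationary_second_is_one_fixation(self):
        n = 120
        rec = make_recording(np.full(n, 400.0), np.full(n, 300.0))
        events = idt_classify(rec.samples)
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == "fixation"
        assert ev.t_start_ms == 0.0
        assert ev.t_end_ms == pytest.approx((n - 1) * DT)

    def test_two_clusters_give_two_fixations_one_saccade(self):
        # two stationary 500 ms clusters 10 degrees apart, brief transition
        x = np.concatenate([
            np.full(60, 400.0),
            np.linspace(400, 400 + 10 * DEG_PX, 5),
            np.full(60, 400 + 10 * DEG_PX),
        ])
        y = np.full(len(x), 300.0)
        events = idt_classify(make_recording(x, y).samples)
        kinds = [e.kind for e in events]
        assert kinds == ["fixation", "saccade", "fixation"]
        sacc = events[1]
        assert sacc.plane == "horizontal"
        assert sacc.amplitude_deg == pytest.approx(10.0, abs=0.5)

    def test_short_trace_yields_nothing(self):
        rec = make_recording(np.full(6, 400.0), np.full(6, 300.0))  # 50 ms
        assert idt_classify(rec.samples, min_duration_ms=100.0) == []

    def test_fixations_disjoint_and_above_min_duration(self):
        rng = np.random.default_rng(5)
        prof = sample_participant("CN", CohortSpec(seed=1), rng)
        script = generate_task_script(3, rng=rng)
        rec = simulate_gaze(prof, script)
        fx = [e for e in idt_classify(rec.samples) if e.kind == "fixation"]
        assert fx
        for a, b in zip(fx[:-1], fx[1:]):
            assert a.t_end_ms < b.t_start_ms
        assert all(e.duration_ms >= 100.0 for e in fx)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_window_scan(self, seed):
        # random-walk traces with validity gaps, <= 2000 samples
        rng = np.random.default_rng(seed)
        n = 1200
        steps = rng.normal(0, 6, size=(n, 2))
        jumps = rng.random(n) < 0.01
        steps[jumps] += rng.normal(0, 200, size=(jumps.sum(), 2))
        pos = 600 + np.cumsum(steps, axis=0)
        valid = rng.random(n) > 0.03
        rec = make_recording(pos[:, 0], pos[:, 1], valid=valid)
        events = idt_classify(rec.samples)
        fx = [(e.t_start_ms, e.t_end_ms, e.dispersion_px) for e in events if e.kind == "fixation"]
        sc = [(e.t_start_ms, e.t_end_ms) for e in events if e.kind == "saccade"]
        t = rec.samples["t_ms"].to_numpy()
        ref_fx, ref_sc = idt_reference(t, pos[:, 0], pos[:, 1], valid)
        assert len(fx) == len(ref_fx)
        for got, want in zip(fx, ref_fx):
            assert got[0] == want[0] and got[1] == want[1]
            assert got[2] == pytest.approx(want[2], abs=1e-9)
        assert sc == [(a, b) for a, b in ref_sc]


def _make_saccade(t_start, direction_deg, amplitude_deg=8.0, velocity=250.0, start=(500.0, 500.0)):
    rad = np.radians(direction_deg)
    amp_px = amplitude_deg * DEG_PX
    end = (start[0] + amp_px * np.cos(rad), start[1] - amp_px * np.sin(rad))
    return OcularEvent(
        kind="saccade", t_start_ms=t_start, t_end_ms=t_start + 40.0,
        centroid_px=start, dispersion_px=amp_px, amplitude_deg=amplitude_deg,
        median_velocity_deg_s=velocity, direction_deg=direction_deg % 360.0,
        plane=None, start_px=start, end_px=end,
    )


def _onsets(rows):
    return pd.DataFrame(rows, columns=["t_ms", "target_x_px", "target_y_px", "seq_idx", "pos_idx"])


class TestSaccadicLatency:
    def test_constructed_latency_of_180ms(self):
        onsets = _onsets([(1000.0, 500.0 + 8 * DEG_PX, 500.0, 0, 1)])
        events = [_make_saccade(1180.0, direction_deg=0.0)]
        lat = saccadic_latency(events, onsets)
        assert lat[0] == pytest.approx(180.0)

    def test_no_saccade_before_next_onset_is_missing(self):
        onsets = _onsets([(1000.0, 900.0, 500.0, 0, 1), (2000.0, 200.0, 500.0, 0, 2)])
        events = [_make_saccade(2100.0, direction_deg=180.0)]  # belongs to 2nd stimulus
        lat = saccadic_latency(events, onsets)
        assert np.isnan(lat[0])
        assert lat[1] == pytest.approx(100.0)

    def test_direction_gate_rejects_opposite_saccade(self):
        onsets = _onsets([(1000.0, 500.0 + 8 * DEG_PX, 500.0, 0, 1)])
        events = [_make_saccade(1150.0, direction_deg=180.0)]  # away from target
        assert np.isnan(saccadic_latency(events, onsets)[0])

    def test_micro_saccades_ignored(self):
        onsets = _onsets([(1000.0, 500.0 + 8 * DEG_PX, 500.0, 0, 1)])
        events = [
            _make_saccade(1100.0, direction_deg=0.0, amplitude_deg=1.2),  # refixation shift
            _make_saccade(1210.0, direction_deg=0.0, amplitude_deg=8.0),
        ]
        assert saccadic_latency(events, onsets)[0] == pytest.approx(210.0)

    def test_implausibly_late_match_discarded(self):
        onsets = _onsets([(1000.0, 500.0 + 8 * DEG_PX, 500.0, 0, 1)])
        events = [_make_saccade(2600.0, direction_deg=0.0)]
        assert np.isnan(saccadic_latency(events, onsets)[0])


@pytest.fixture(scope="module")
def sim_recording():
    rng = np.random.default_rng(8)
    prof = sample_participant("CN", CohortSpec(seed=2), rng)
    script = generate_task_script(3, rng=rng)
    return simulate_gaze(prof, script)


class TestTimeFeatures:
    def test_bookkeeping_identity(self, sim_recording):
        # with onsets coinciding with the previous click, per-position mean
        # times scale up to exactly the total stimulus-response time
        tf = time_features(sim_recording, np.array([200.0]))
        total = tf[F.TIME_FEATURES[0]]
        per_pos_sum = sum(tf[F.TIME_FEATURES[k]] for k in (1, 2, 3))
        assert per_pos_sum * 3 == pytest.approx(total, rel=1e-9)

    def test_single_sequence_means_equal_raw_times(self):
        events = pd.DataFrame(
            [
                ("onset", 0.0, 0, 1, 100.0, 100.0),
                ("click", 1500.0, 0, 1, np.nan, np.nan),
                ("onset", 1500.0, 0, 2, 200.0, 100.0),
                ("click", 3600.0, 0, 2, np.nan, np.nan),
                ("onset", 3600.0, 0, 3, 300.0, 100.0),
                ("click", 6900.0, 0, 3, np.nan, np.nan),
            ],
            columns=EVENT_COLUMNS,
        )
        rec = make_recording(np.full(900, 100.0), np.full(900, 100.0), events=events)
        tf = time_features(rec, np.array([150.0, 170.0]))
        assert tf[F.TIME_FEATURES[0]] == pytest.approx(6.9)
        assert tf[F.TIME_FEATURES[1]] == pytest.approx(1.5)
        assert tf[F.TIME_FEATURES[2]] == pytest.approx(2.1)
        assert tf[F.TIME_FEATURES[3]] == pytest.approx(3.3)
        assert tf[F.TIME_FEATURES[4]] == pytest.approx(160.0)
        assert tf[F.TIME_FEATURES[5]] == pytest.approx(10.0)

    def test_workload_multipliers_order_mean_times(self):
        # positions 1 -> 3 slow down in expectation under the default 1.0/1.2/1.5
        rng = np.random.default_rng(3)
        spec = CohortSpec(seed=3)
        means = np.zeros(3)
        for s in range(6):
            prof = sample_participant("CN", spec, rng)
            script = generate_task_script(4, rng=rng)
            tf = time_features(simulate_gaze(prof, script), np.array([200.0]))
            means += [tf[F.TIME_FEATURES[k]] for k in (1, 2, 3)]
        assert means[0] < means[1] < means[2]

    def test_missing_click_is_an_error(self):
        events = pd.DataFrame(
            [("onset", 0.0, 0, 1, 100.0, 100.0)], columns=EVENT_COLUMNS)
        rec = make_recording(np.full(200, 100.0), np.full(200, 100.0), events=events)
        with pytest.raises(InvalidRecordingError):
            time_features(rec, np.array([np.nan]))


def _fixation(pos_idx, duration=300.0, points=None, t0=0.0):
    if points is None:
        points = np.array([[100.0, 100.0], [104.0, 100.0], [100.0, 104.0]])
    x, y = points[:, 0], points[:, 1]
    disp = max(
        float(np.hypot(xi - xj, yi - yj))
        for i, (xi, yi) in enumerate(points)
        for (xj, yj) in points[i + 1:]
    ) if len(points) > 1 else 0.0
    return OcularEvent(
        kind="fixation", t_start_ms=t0, t_end_ms=t0 + duration,
        centroid_px=(float(x.mean()), float(y.mean())), dispersion_px=disp,
        points_px=points, pos_idx=pos_idx, seq_idx=0,
    )


class TestFixationFeatures:
    def test_single_fixation_has_zero_spread(self):
        with pytest.warns(MissingFeatureWarning):
            out = fixation_features([_fixation(1)])
        for stat in ("Time", "Size", "Area"):
            assert out[f"(Log-) Standard Deviation of Fixation {stat} for Number 1" +
                       (" (ms)" if stat == "Time" else " (mm)" if stat == "Size" else " (mm^2)")] == 0.0
        assert np.isnan(out["Mean Fixation Time for Number 2 (ms)"])

    def test_collinear_samples_have_area_zero_size_positive(self):
        pts = np.array([[100.0, 100.0], [110.0, 100.0], [120.0, 100.0]])
        with pytest.warns(MissingFeatureWarning):
            out = fixation_features([_fixation(1, points=pts)])
        assert out["Mean Fixation Area for Number 1 (mm^2)"] == 0.0
        assert out["Mean Fixation Size for Number 1 (mm)"] > 0.0

    def test_statistics_pool_over_attributed_fixations(self):
        evs = [_fixation(1, duration=200.0), _fixation(1, duration=400.0),
               _fixation(2, duration=300.0)]
        with pytest.warns(MissingFeatureWarning):  # position 3 empty
            out = fixation_features(evs)
        assert out["Mean Fixation Time for Number 1 (ms)"] == pytest.approx(300.0)
        assert out["(Log-) Standard Deviation of Fixation Time for Number 1 (ms)"] == pytest.approx(100.0)
        assert out["Mean Fixation Time for Number 2 (ms)"] == pytest.approx(300.0)


class TestSaccadeVelocity:
    def test_single_plane_constructed(self):
        events = [_make_saccade(100.0 * i, 0.0, velocity=200.0) for i in range(3)]
        for e in events:
            e.plane = "horizontal"
        with pytest.warns(MissingFeatureWarning):
            out = saccade_velocity_features(events)
        assert out[F.SACCADE_FEATURES[1]] == pytest.approx(200.0)
        assert np.isnan(out[F.SACCADE_FEATURES[0]])
        assert np.isnan(out[F.SACCADE_FEATURES[2]])

    def test_symmetric_planes_have_equal_medians(self):
        events = []
        for plane, direction in (("horizontal", 0.0), ("vertical", 90.0), ("diagonal", 45.0)):
            for i, v in enumerate((150.0, 210.0, 260.0)):
                e = _make_saccade(100.0 * i, direction, velocity=v)
                e.plane = plane
                events.append(e)
        out = saccade_velocity_features(events)
        assert len({round(v, 9) for v in out.values()}) == 1

    def test_median_matches_brute_force_on_seven(self):
        vels = [310.0, 150.0, 260.0, 190.0, 220.0, 400.0, 180.0]
        events = []
        for i, v in enumerate(vels):
            e = _make_saccade(50.0 * i, 40.0, velocity=v)
            e.plane = "diagonal"
            events.append(e)
        with pytest.warns(MissingFeatureWarning):
            out = saccade_velocity_features(events)
        assert out[F.SACCADE_FEATURES[0]] == sorted(vels)[3]


class TestBlinkAndPupil:
    def test_five_blinks_in_30s_is_10_per_minute(self):
        blinks = [BlinkEvent(1000.0 * i, 1000.0 * i + 120.0) for i in range(5)]
        out = blink_features(blinks, 30.0)
        assert out[F.BLINK_FEATURES[0]] == pytest.approx(10.0)

    def test_median_duration(self):
        blinks = [BlinkEvent(0, 80.0), BlinkEvent(1000, 1100.0), BlinkEvent(2000, 2120.0)]
        out = blink_features(blinks, 60.0)
        assert out[F.BLINK_FEATURES[1]] == pytest.approx(100.0)

    def test_zero_blinks(self):
        with pytest.warns(MissingFeatureWarning):
            out = blink_features([], 60.0)
        assert out[F.BLINK_FEATURES[0]] == 0.0
        assert np.isnan(out[F.BLINK_FEATURES[1]])

    def test_constant_pupil_has_zero_sd_and_cv(self):
        rec = make_recording(np.full(50, 100.0), np.full(50, 100.0), pupil=np.full(50, 4.0))
        out = pupil_features(rec)
        assert out[F.PUPIL_FEATURES[0]] == 0.0
        assert out[F.PUPIL_FEATURES[1]] == 0.0

    def test_scaling_pupil_scales_sd_not_cv(self):
        rng = np.random.default_rng(0)
        pupil = 3.5 + rng.normal(0, 0.1, 500)
        rec1 = make_recording(np.full(500, 1.0), np.full(500, 1.0), pupil=pupil)
        rec2 = make_recording(np.full(500, 1.0), np.full(500, 1.0), pupil=2.0 * pupil)
        o1, o2 = pupil_features(rec1), pupil_features(rec2)
        assert o2[F.PUPIL_FEATURES[0]] == pytest.approx(2 * o1[F.PUPIL_FEATURES[0]])
        assert o2[F.PUPIL_FEATURES[1]] == pytest.approx(o1[F.PUPIL_FEATURES[1]])

    def test_gaussian_noise_sd_recovered(self):
        rng = np.random.default_rng(1)
        pupil = 3.5 + rng.normal(0, 0.1, 7200)
        rec = make_recording(np.full(7200, 1.0), np.full(7200, 1.0), pupil=pupil)
        assert pupil_features(rec)[F.PUPIL_FEATURES[0]] == pytest.approx(0.1, abs=0.005)

    def test_too_few_pupil_samples(self):
        rec = make_recording([1.0, 1.0], [1.0, 1.0], valid=[True, False])
        with pytest.raises(InvalidRecordingError):
            pupil_features(rec)


@pytest.fixture(scope="module")
def clean_recording():
    rng = np.random.default_rng(4)
    prof = sample_participant("CN", CohortSpec(seed=4), rng)
    script = generate_task_script(3, rng=rng)
    rec = simulate_gaze(prof, script)
    clean, _ = preprocess(rec)
    return clean


class TestExtractFeatures:
    def test_exactly_31_features_plus_age(self, clean_recording):
        vec = extract_features(clean_recording, age=70.0)
        assert list(vec.index) == F.ALL_FEATURES + [F.AGE_FEATURE]
        assert len(F.ALL_FEATURES) == 31
        assert vec[F.AGE_FEATURE] == 70.0

    def test_deterministic(self, clean_recording):
        v1 = extract_features(clean_recording, age=70.0)
        v2 = extract_features(clean_recording, age=70.0)
        pd.testing.assert_series_equal(v1, v2)

    def test_time_features_positive(self, clean_recording):
        vec = extract_features(clean_recording, age=70.0)
        assert (vec[F.TIME_FEATURES] > 0).all()


def test_auprc_reference_self_check():
    # perfect ranking scores 1.0 under the brute-force enumeration
    assert average_precision_reference([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == pytest.approx(1.0)
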