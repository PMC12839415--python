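"""Preprocessing tests: skewness rule, log transform, stratified split,
SMOTE balancing, leakage-safe standardization."""

import numpy as np
import pandas as pd
import pytest

import ocatscreen.features as F
from ocatscreen.prep import (
    SYNTHETIC_COLUMN,
    TransformError,
    destandardize,
    log_transform,
    prepare,
    skewness,
    smote,
    standardize_apply,
    standardize_fit,
    stratified_split,
)


def _table(n_cn, n_pmci, n_features=4, seed=0, shift=0.0):
    """Labelled feature table with Gaussian features (PMCI shifted)."""
    rng = np.random.default_rng(seed)
    cols = [f"f{i}" for i in range(n_features)]
    X = rng.normal(0, 1, (n_cn + n_pmci, n_features))
    X[n_cn:] += shift
    df = pd.DataFrame(X, columns=cols)
    df[F.LABEL_COLUMN] = ["CN"] * n_cn + ["PMCI"] * n_pmci
    df[F.ID_COLUMN] = [f"P{i:03d}" for i in range(len(df))]
    return df, cols


class TestSkewness:
    def test_symmetric_sample_is_zero(self):
        assert skewness([-1.0, 0.0, 1.0]) == pytest.approx(0.0, abs=1e-12)

    def test_exponential_sample_near_two(self):
        rng = np.random.default_rng(0)
        assert skewness(rng.exponential(1.0, 100000)) == pytest.approx(2.0, abs=0.1)

    def test_constant_sample_is_zero_by_policy(self):
        assert skewness([3.0, 3.0, 3.0, 3.0]) == 0.0

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            skewness([1.0, 2.0])


class TestLogTransform:
    def test_all_ones_become_zeros(self):
        df = pd.DataFrame({F.LOG_MARKED[0]: np.ones(5)})
        out, applied = log_transform(df, feature_columns=[F.LOG_MARKED[0]])
        assert applied == [F.LOG_MARKED[0]]
        assert (out[F.LOG_MARKED[0]] == 0.0).all()

    def test_marked_policy_targets_log_designated_features(self):
        df = pd.DataFrame({
            F.LOG_MARKED[0]: [1.0, 2.0, 3.0],
            F.TIME_FEATURES[0]: [1.0, 2.0, 3.0],
        })
        out, applied = log_transform(df)
        assert applied == [F.LOG_MARKED[0]]
        assert (out[F.TIME_FEATURES[0]] == df[F.TIME_FEATURES[0]]).all()

    def test_skewness_policy_spares_mild_features(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"mild": rng.normal(10, 1, 2000)})  # |skew| ~ 0
        out, applied = log_transform(df, policy="skewness", feature_columns=["mild"])
        assert applied == []

    def test_lognormal_feature_normalized_by_skewness_policy(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"ln": rng.lognormal(0.0, 1.0, 5000)})
        out, applied = log_transform(df, policy="skewness", feature_columns=["ln"])
        assert applied == ["ln"]
        assert abs(skewness(out["ln"])) < 1.0

    def test_negative_values_raise_naming_the_feature(self):
        df = pd.DataFrame({F.LOG_MARKED[0]: [1.0, -2.0]})
        with pytest.raises(TransformError, match="Latency"):
            log_transform(df, feature_columns=[F.LOG_MARKED[0]])


class TestStratifiedSplit:
    def test_166_40_at_20_percent_gives_33_8(self):
        df, _ = _table(166, 40)
        train, test = stratified_split(df, 0.2, seed=0)
        assert test[F.LABEL_COLUMN].value_counts().to_dict() == {"CN": 33, "PMCI": 8}
        assert train[F.LABEL_COLUMN].value_counts().to_dict() == {"CN": 133, "PMCI": 32}

    def test_explicit_count_override(self):
        df, _ = _table(166, 40)
        train, test = stratified_split(df, seed=0, test_counts={"CN": 31, "PMCI": 11})
        assert test[F.LABEL_COLUMN].value_counts().to_dict() == {"CN": 31, "PMCI": 11}
        assert train[F.LABEL_COLUMN].value_counts().to_dict() == {"CN": 135, "PMCI": 29}

    def test_partition_disjoint_by_id(self):
        df, _ = _table(50, 20)
        train, test = stratified_split(df, 0.2, seed=1)
        assert set(train[F.ID_COLUMN]).isdisjoint(test[F.ID_COLUMN])
        assert len(train) + len(test) == len(df)

    def test_zero_test_fraction_rejected(self):
        df, _ = _table(20, 10)
        with pytest.raises(ValueError):
            stratified_split(df, 0.0, seed=0)

    def test_deterministic_membership(self):
        df, _ = _table(60, 15)
        _, t1 = stratified_split(df, 0.2, seed=7)
        _, t2 = stratified_split(df, 0.2, seed=7)
        assert list(t1[F.ID_COLUMN]) == list(t2[F.ID_COLUMN])

    def test_tiny_class_rejected(self):
        df, _ = _table(30, 1)
        with pytest.raises(ValueError):
            stratified_split(df, 0.2, seed=0)


class TestSmote:
    def test_table3_counts_balance_to_table4(self):
        df, cols = _table(135, 29, seed=3)
        out = smote(df, cols, seed=0)
        counts = out[F.LABEL_COLUMN].value_counts().to_dict()
        assert counts == {"CN": 135, "PMCI": 135}
        assert out[SYNTHETIC_COLUMN].sum() == 135 - 29
        assert (out.loc[out[SYNTHETIC_COLUMN], F.LABEL_COLUMN] == "PMCI").all()

    def test_already_balanced_returned_unchanged(self):
        df, cols = _table(40, 40, seed=4)
        out = smote(df, cols, seed=0)
        assert len(out) == len(df)
        assert not out[SYNTHETIC_COLUMN].any()

    def test_synthetic_points_lie_on_minority_segments(self):
        df, cols = _table(60, 12, seed=5)
        out = smote(df, cols, seed=1)
        originals = df.loc[df[F.LABEL_COLUMN] == "PMCI", cols].to_numpy()
        synth = out.loc[out[SYNTHETIC_COLUMN], cols].to_numpy()
        for s in synth:
            on_segment = False
            for i in range(len(originals)):
                for j in range(len(originals)):
                    if i == j:
                        continue
                    a, b = originals[i], originals[j]
                    ab = b - a
                    denom = float(ab @ ab)
                    if denom == 0:
                        continue
                    t = float((s - a) @ ab) / denom
                    if -1e-9 <= t <= 1 + 1e-9 and np.linalg.norm(s - (a + t * ab)) < 1e-9:
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_small_minority_reduces_k_with_warning(self):
        df, cols = _table(20, 4, seed=6)
        with pytest.warns(UserWarning, match="reducing k"):
            out = smote(df, cols, k_neighbors=5, seed=0)
        assert out[F.LABEL_COLUMN].value_counts().to_dict() == {"CN": 20, "PMCI": 20}

    def test_single_minority_sample_rejected(self):
        df, cols = _table(10, 1, seed=7)
        with pytest.raises(ValueError):
            smote(df, cols, seed=0)


class TestStandardize:
    def test_training_columns_become_zero_mean_unit_sd(self):
        df, cols = _table(80, 20, seed=8)
        state = standardize_fit(df, cols)
        out = standardize_apply(state, df)
        assert np.allclose(out[cols].mean(), 0.0, atol=1e-9)
        assert np.allclose(out[cols].std(ddof=0), 1.0, atol=1e-9)

    def test_train_state_applied_to_test_differs_from_refit(self):
        train, cols = _table(80, 20, seed=9)
        test, _ = _table(20, 5, seed=10)
        test[cols] = test[cols] + 2.0  # global shift the train scaler must not absorb
        state = standardize_fit(train, cols)
        via_train = standardize_apply(state, test)
        via_refit = standardize_apply(standardize_fit(test, cols), test)
        assert not np.allclose(via_train[cols], via_refit[cols])
        # shifted test data should not be re-centred by the train scaler
        assert via_train[cols].mean().mean() > 0.5

    def test_round_trip(self):
        df, cols = _table(50, 10, seed=11)
        state = standardize_fit(df, cols)
        back = destandardize(state, standardize_apply(state, df))
        assert np.allclose(back[cols], df[cols], atol=1e-9)

    def test_zero_variance_feature_warns_and_keeps_sd_one(self):
        df, cols = _table(30, 10, seed=12)
        df["f0"] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            state = standardize_fit(df, cols)
        assert state.sds["f0"] == 1.0


class TestPrepare:
    def test_test_partition_untouched_by_balancing(self):
        df, cols = _table(83, 20, seed=13, shift=1.0)
        ds_bal = prepare(df, cols, balanced=True, seed=3)
        ds_orig = prepare(df, cols, balanced=False, seed=3)
        pd.testing.assert_frame_equal(ds_bal.test, ds_orig.test)
        assert ds_bal.class_counts("test") == ds_orig.class_counts("test")

    def test_smote_adds_exactly_the_deficit(self):
        df, cols = _table(83, 20, seed=14)
        ds = prepare(df, cols, balanced=True, seed=0)
        counts = ds.class_counts("train")
        assert counts["CN"] == counts["PMCI"]
        added = ds.train_balanced[SYNTHETIC_COLUMN].sum()
        assert added == counts["CN"] - (20 - ds.test[F.LABEL_COLUMN].eq("PMCI").sum())

    def test_transform_state_is_pure_function_of_training(self):
        df, cols = _table(83, 20, seed=15)
        ds1 = prepare(df, cols, balanced=True, seed=5)
        # perturbing the test rows must not change the fitted state
        df2 = df.copy()
        test_ids = set(ds1.test[F.ID_COLUMN])
        mask = df2[F.ID_COLUMN].isin(test_ids)
        df2.loc[mask, cols] = df2.loc[mask, cols] + 100.0
        ds2 = prepare(df2, cols, balanced=True, seed=5)
        pd.testing.assert_series_equal(ds1.state.means, ds2.state.means)
        pd.testing.assert_series_equal(ds1.state.sds, ds2.state.sds)
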