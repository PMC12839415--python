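"""Tabular preprocessing ahead of modelling.

Order of operations follows the screening protocol: logarithmic transform of
the designated skewed features, stratified 80/20 split, SMOTE balancing of
the training partition only, then z-score standardization fitted on the
(balanced) training data and applied unchanged to the test data.  A
train-fitted median imputation step fills the occasional missing feature
(e.g. a plane with no saccades) before balancing, since the downstream
models cannot accept missing values.

All transform state is a pure function of the training split; the test
partition is never consulted while fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from . import features as F

MINORITY = "PMCI"
MAJORITY = "CN"
SYNTHETIC_COLUMN = "is_synthetic"


class TransformError(ValueError):
    pass


def skewness(values) -> float:
    """Adjusted Fisher-Pearson (bias-corrected) sample skewness.

    A constant sample has zero skewness by convention.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 3:
        raise ValueError("skewness requires at least 3 finite values")
    if np.ptp(v) == 0:
        return 0.0
    return float(stats.skew(v, bias=False))


def log_transform(
    table: pd.DataFrame,
    policy: str = "marked",
    feature_columns: list[str] | None = None,
    skew_reference: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Natural-log transform of skewed features.

    ``policy='marked'`` (default) transforms exactly the features whose
    canonical name carries the ``(Log-)`` designation.  ``policy='skewness'``
    transforms any feature whose sample skewness falls outside (-1, 1),
    computed on ``skew_reference`` (e.g. the training partition) when given,
    otherwise on ``table`` itself.

    Zero values receive a small positive offset (1e-6 of the feature's
    median) before the log; negative values raise a :class:`TransformError`
    naming the feature.
    """
    out = table.copy()
    if feature_columns is None:
        feature_columns = [c for c in table.columns if c in set(F.ALL_FEATURES + [F.AGE_FEATURE])]
    if policy == "marked":
        chosen = [c for c in feature_columns if c in set(F.LOG_MARKED)]
    elif policy == "skewness":
        ref = skew_reference if skew_reference is not None else table
        chosen = [c for c in feature_columns
                  if abs(skewness(ref[c].dropna())) > 1.0]
    else:
        raise ValueError(f"unknown log policy {policy!r}")

    for col in chosen:
        v = out[col].to_numpy(dtype=float)
        finite = np.isfinite(v)
        if np.any(v[finite] < 0):
            raise TransformError(f"feature {col!r} has negative values; cannot log-transform")
        med = float(np.median(v[finite])) if finite.any() else 0.0
        eps = max(1e-6 * med, 1e-12)
        zero = finite & (v == 0)
        v = v.copy()
        v[zero] = eps
        v[finite & (v > 0)] = np.log(v[finite & (v > 0)])
        out[col] = v
    return out, chosen


@dataclass
class TransformState:
    """Train-fitted preprocessing state (imputation medians, scaler)."""

    feature_columns: list[str]
    impute_medians: pd.Series
    means: pd.Series
    sds: pd.Series
    log_features: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_columns,
                "impute_median": self.impute_medians.values,
                "mean": self.means.values,
                "sd": self.sds.values,
                "log": [c in set(self.log_features) for c in self.feature_columns],
            }
        )


@dataclass
class SplitDataset:
    """Stratified train/test partition with balanced and standardized views."""

    train: pd.DataFrame  # original training rows (after log/impute)
    test: pd.DataFrame
    train_balanced: pd.DataFrame | None = None  # after SMOTE, None if not balanced
    train_model: pd.DataFrame | None = None  # standardized table fed to models
    test_model: pd.DataFrame | None = None
    state: TransformState | None = None
    feature_columns: list[str] = field(default_factory=list)

    def class_counts(self, which: str = "train") -> dict[str, int]:
        table = {"train": self.train_balanced if self.train_balanced is not None else self.train,
                 "test": self.test}[which]
        return table[F.LABEL_COLUMN].value_counts().to_dict()


def stratified_split(
    table: pd.DataFrame,
    test_fraction: float = 0.2,
    seed: int = 0,
    test_counts: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified random split preserving the class distribution.

    Per-class test counts are the rounded class shares reconciled to the
    rounded global test size by largest remainder; ``test_counts`` overrides
    them explicitly (e.g. to force a printed split).  Deterministic given
    ``seed``.
    """
    labels = table[F.LABEL_COLUMN]
    classes = labels.value_counts()
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if (classes < 2).any():
        raise ValueError("each class needs at least 2 members to split")
    if test_counts is None:
        if not (0 < test_fraction < 1):
            raise ValueError("test_fraction must be in (0, 1)")
        total_test = int(round(len(table) * test_fraction))
        ideal = classes * test_fraction
        base = np.floor(ideal).astype(int)
        short = total_test - int(base.sum())
        order = (ideal - base).sort_values(ascending=False).index
        test_counts = base.to_dict()
        for cls in list(order)[:short]:
            test_counts[cls] += 1
    if sum(test_counts.values()) == 0:
        raise ValueError("test split would be empty")

    rng = np.random.default_rng(seed)
    test_idx: list = []
    for cls, n_test in test_counts.items():
        members = table.index[labels == cls].to_numpy()
        if n_test > len(members):
            raise ValueError(f"cannot place {n_test} test members of class {cls}")
        test_idx.extend(rng.choice(members, size=n_test, replace=False))
    test_mask = table.index.isin(test_idx)
    return table.loc[~test_mask].copy(), table.loc[test_mask].copy()


def smote(
    train_table: pd.DataFrame,
    feature_columns: list[str],
    k_neighbors: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic minority oversampling: raise the minority class to the
    majority count by interpolating between minority samples and their
    k nearest minority neighbours (Euclidean, on the feature columns).

    Synthetic rows are flagged in an ``is_synthetic`` column; majority and
    original minority rows pass through untouched.  The test partition is
    never involved.
    """
    out = train_table.copy()
    if SYNTHETIC_COLUMN not in out.columns:
        out[SYNTHETIC_COLUMN] = False
    counts = out[F.LABEL_COLUMN].value_counts()
    if len(counts) < 2:
        raise ValueError("both classes must be present for balancing")
    minority = counts.idxmin()
    n_needed = int(counts.max() - counts.min())
    if n_needed == 0:
        return out
    minority_rows = out[out[F.LABEL_COLUMN] == minority]
    n_min = len(minority_rows)
    if n_min < 2:
        raise ValueError("need at least 2 minority samples for SMOTE")
    if n_min <= k_neighbors:
        warnings.warn(
            f"minority count {n_min} <= k={k_neighbors}; reducing k to {n_min - 1}",
            UserWarning, stacklevel=2)
        k_neighbors = n_min - 1

    X = minority_rows[feature_columns].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise TransformError("SMOTE requires finite feature values; impute first")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    _, neigh = nn.kneighbors(X)  # first column is the sample itself

    rng = np.random.default_rng(seed)
    base_idx = rng.integers(0, n_min, size=n_needed)
    pick = rng.integers(1, k_neighbors + 1, size=n_needed)
    u = rng.uniform(0.0, 1.0, size=n_needed)
    partner = neigh[base_idx, pick]
    synth = X[base_idx] + u[:, None] * (X[partner] - X[base_idx])

    new_rows = pd.DataFrame(synth, columns=feature_columns)
    new_rows[F.LABEL_COLUMN] = minority
    new_rows[SYNTHETIC_COLUMN] = True
    if F.ID_COLUMN in out.columns:
        new_rows[F.ID_COLUMN] = [f"SYN{i:03d}" for i in range(n_needed)]
    return pd.concat([out, new_rows], ignore_index=True)


def impute_fit(train_table: pd.DataFrame, feature_columns: list[str]) -> pd.Series:
    return train_table[feature_columns].median()


def impute_apply(table: pd.DataFrame, medians: pd.Series) -> pd.DataFrame:
    out = table.copy()
    out[medians.index] = out[medians.index].fillna(medians)
    return out


def standardize_fit(
    train_table: pd.DataFrame,
    feature_columns: list[str],
    log_features: list[str] | None = None,
    impute_medians: pd.Series | None = None,
) -> TransformState:
    """Fit per-feature z-score parameters on the training table only.

    Zero-variance features keep SD 1 (with a warning) so they standardize to
    a constant zero rather than dividing by zero.
    """
    X = train_table[feature_columns]
    means = X.mean()
    sds = X.std(ddof=0)
    zero = sds == 0
    if zero.any():
        warnings.warn(f"zero-variance features {list(sds.index[zero])}; SD set to 1",
                      UserWarning, stacklevel=2)
        sds = sds.mask(zero, 1.0)
    if impute_medians is None:
        impute_medians = X.median()
    return TransformState(
        feature_columns=list(feature_columns),
        impute_medians=impute_medians,
        means=means,
        sds=sds,
        log_features=list(log_features or []),
    )


def standardize_apply(state: TransformState, table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    cols = state.feature_columns
    out[cols] = (out[cols] - state.means) / state.sds
    return out


def destandardize(state: TransformState, table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    cols = state.feature_columns
    out[cols] = out[cols] * state.sds + state.means
    return out


def prepare(
    features: pd.DataFrame,
    feature_columns: list[str],
    balanced: bool = True,
    test_fraction: float = 0.2,
    seed: int = 0,
    test_counts: dict[str, int] | None = None,
    log_policy: str = "marked",
    k_neighbors: int = 5,
) -> SplitDataset:
    """Full preprocessing chain: log -> split -> (impute) -> SMOTE ->
    standardize.  Returns the split with standardized model-ready views."""
    logged, log_cols = log_transform(features, policy=log_policy,
                                     feature_columns=feature_columns)
    train, test = stratified_split(logged, test_fraction, seed, test_counts)

    medians = impute_fit(train, feature_columns)
    train = impute_apply(train, medians)
    test_imp = impute_apply(test, medians)

    train_bal = smote(train, feature_columns, k_neighbors, seed) if balanced else None
    fit_on = train_bal if train_bal is not None else train
    state = standardize_fit(fit_on, feature_columns, log_cols, medians)
    return SplitDataset(
        train=train,
        test=test,
        train_balanced=train_bal,
        train_model=standardize_apply(state, fit_on),
        test_model=standardize_apply(state, test_imp),
        state=state,
        feature_columns=list(feature_columns),
    )
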