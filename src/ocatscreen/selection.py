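"""Two-step feature selection.

Step 1 groups mutually correlated features (|Pearson r| > 0.8, connected
components of the correlation graph) and keeps, within each multi-feature
group, the single feature with the highest Random-Forest impurity importance
(one forest fitted on all features, 500 trees, fixed seed).  Step 2 scores
each surviving feature with a univariate depth-limited decision tree
(stratified cross-validated ROC-AUC by default) and drops features scoring
no better than chance (AUC <= 0.5).

Selection is a pure function of the training split and the seeds; all
dropped features carry a recorded reason.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from . import features as F


class SelectionError(ValueError):
    pass


@dataclass
class SelectionReport:
    groups: list[list[str]]
    retained_per_group: dict[str, str]  # group key (first member) -> retained feature
    auc_scores: dict[str, float]
    selected: list[str]
    dropped: dict[str, str]  # feature -> reason
    r_threshold: float = 0.8
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "groups": self.groups,
                    "retained_per_group": self.retained_per_group,
                    "auc_scores": self.auc_scores,
                    "selected": self.selected,
                    "dropped": self.dropped,
                    "r_threshold": self.r_threshold,
                    "seed": self.seed,
                },
                fh,
                indent=2,
            )


def correlation_groups(
    train_features: pd.DataFrame,
    r_threshold: float = 0.8,
    feature_columns: list[str] | None = None,
) -> list[list[str]]:
    """Connected components of the graph with an edge where |r| > threshold.

    Constant features correlate with nothing (r defined as 0, with a
    warning) and end up as singletons.  Groups and their members keep the
    canonical column order.
    """
    cols = feature_columns or list(train_features.columns)
    if len(train_features) < 2:
        raise ValueError("need at least 2 rows to correlate")
    X = train_features[cols]
    constant = X.std(ddof=0) == 0
    if constant.any():
        warnings.warn(f"constant features treated as uncorrelated: {list(X.columns[constant])}",
                      UserWarning, stacklevel=2)
    corr = X.corr().fillna(0.0).abs()
    # union-find over the |r| > threshold graph
    parent = list(range(len(cols)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if corr.iloc[i, j] > r_threshold:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    comps: dict[int, list[str]] = {}
    for i, col in enumerate(cols):
        comps.setdefault(find(i), []).append(col)
    return [comps[k] for k in sorted(comps)]


def rf_group_select(
    groups: list[list[str]],
    train_features: pd.DataFrame,
    train_labels: pd.Series,
    n_estimators: int = 500,
    seed: int = 0,
) -> tuple[list[str], dict[str, str]]:
    """Keep one feature per correlated group by Random-Forest importance.

    A single forest is fitted on all features; within each multi-feature
    group the feature with the highest impurity importance survives (ties
    break toward the canonical feature order).  Singleton groups pass
    through.  Returns (retained features, retained-by-group mapping).
    """
    if train_labels.nunique() < 2:
        raise SelectionError("training labels contain a single class")
    cols = [c for g in groups for c in g]
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    rf.fit(train_features[cols].to_numpy(), train_labels.to_numpy())
    importance = dict(zip(cols, rf.feature_importances_))
    retained: list[str] = []
    by_group: dict[str, str] = {}
    for group in groups:
        best = max(group, key=lambda c: (importance[c], -group.index(c)))
        retained.append(best)
        by_group[group[0]] = best
    return retained, by_group


def univariate_auc_filter(
    train_features: pd.DataFrame,
    train_labels: pd.Series,
    features: list[str],
    mode: str = "cv",
    cv_folds: int = 5,
    max_depth: int = 3,
    seed: int = 0,
) -> tuple[list[str], dict[str, float]]:
    """Score each feature with a single-feature decision tree and keep those
    with ROC-AUC > 0.5.

    ``mode='cv'`` (default) averages AUC over stratified cross-validation
    folds of the training data; ``mode='resubstitution'`` scores on the
    training data itself.
    """
    y = (train_labels == "PMCI").to_numpy(dtype=int) if train_labels.dtype == object else train_labels.to_numpy()
    aucs: dict[str, float] = {}
    for col in features:
        x = train_features[col].to_numpy(dtype=float).reshape(-1, 1)
        if mode == "resubstitution":
            tree = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
            tree.fit(x, y)
            aucs[col] = float(roc_auc_score(y, tree.predict_proba(x)[:, 1]))
        elif mode == "cv":
            skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
            fold_aucs = []
            for tr, te in skf.split(x, y):
                tree = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
                tree.fit(x[tr], y[tr])
                proba = tree.predict_proba(x[te])
                score = proba[:, 1] if proba.shape[1] == 2 else np.zeros(len(te))
                if len(np.unique(y[te])) < 2:
                    continue
                fold_aucs.append(roc_auc_score(y[te], score))
            aucs[col] = float(np.mean(fold_aucs)) if fold_aucs else 0.5
        else:
            raise ValueError(f"unknown mode {mode!r}")
    selected = [c for c in features if aucs[c] > 0.5]
    return selected, aucs


def select_features(
    train_table: pd.DataFrame,
    feature_columns: list[str],
    r_threshold: float = 0.8,
    auc_mode: str = "cv",
    seed: int = 0,
) -> SelectionReport:
    """Run the full two-step selection on a training table.

    If the AUC filter would drop everything (possible on null data), the
    single best-scoring feature is kept so that a model can still be fitted;
    the report records the fallback.
    """
    labels = train_table[F.LABEL_COLUMN]
    groups = correlation_groups(train_table, r_threshold, feature_columns)
    retained, by_group = rf_group_select(groups, train_table, labels, seed=seed)
    selected, aucs = univariate_auc_filter(train_table, labels, retained,
                                           mode=auc_mode, seed=seed)
    dropped: dict[str, str] = {}
    retained_set = set(retained)
    for group in groups:
        for col in group:
            if col not in retained_set:
                dropped[col] = "correlated-redundant"
    for col in retained:
        if col not in selected:
            dropped[col] = "auc<=0.5"
    if not selected:
        best = max(retained, key=lambda c: (aucs[c], -retained.index(c)))
        selected = [best]
        dropped[best] = "kept-as-fallback (filter emptied the set)"
        warnings.warn("AUC filter removed every feature; keeping the best-scoring one",
                      UserWarning, stacklevel=2)
    return SelectionReport(
        groups=groups,
        retained_per_group=by_group,
        auc_scores=aucs,
        selected=selected,
        dropped=dropped,
        r_threshold=r_threshold,
        seed=seed,
    )
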