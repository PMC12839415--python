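"""End-to-end orchestration: simulate -> QC -> extract -> prep -> select ->
model -> report.

A run is driven by a :class:`RunConfig` (constructible from YAML) and writes
every stage artifact into a run directory together with a manifest recording
the package version, seeds, stage hashes and filter counts, so that reruns
with the same configuration are byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import features as F
from .evaluate import DEFAULT_THRESHOLDS, ModelReport, evaluate_model, train_knn, train_lr
from .oculometrics import ExtractConfig, MissingFeatureWarning, extract_features
from .prep import SplitDataset, prepare
from .qc import apply_exclusion, preprocess, qc_report_table
from .selection import SelectionReport, select_features
from .simulate import CohortSpec, generate_cohort, null_cohort_spec


class StageError(RuntimeError):
    """A pipeline stage failed; partial artifacts are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of a full pipeline run on a synthetic cohort."""

    n_cn: int = 166
    n_pmci: int = 40
    n_sequences: int = 3
    seed: int = 0
    null_effects: bool = False
    modes: tuple[str, ...] = ("combined", "time_only", "eye_only")
    balancing: tuple[str, ...] = ("smote", "original")
    models: tuple[str, ...] = ("LR", "KNN")
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    test_fraction: float = 0.2
    test_counts: dict | None = None
    bootstrap_B: int = 1000
    write_recordings: bool = False

    def cohort_spec(self) -> CohortSpec:
        if self.null_effects:
            return null_cohort_spec(self.n_cn, self.n_pmci, seed=self.seed,
                                    n_sequences=self.n_sequences)
        return CohortSpec(n_cn=self.n_cn, n_pmci=self.n_pmci, seed=self.seed,
                          n_sequences=self.n_sequences)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["modes"] = list(self.modes)
        d["balancing"] = list(self.balancing)
        d["models"] = list(self.models)
        d["thresholds"] = list(self.thresholds)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("modes", "balancing", "models", "thresholds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# Stage helpers (also used directly by tests and the acceptance script)
# ---------------------------------------------------------------------------


def simulate_feature_table(
    spec: CohortSpec,
    extract_config: ExtractConfig = ExtractConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort, run QC, and extract the per-participant features.

    Returns ``(features, qc_table, metadata)``; ``features`` has one row per
    included participant with columns id, group, the 31 features and age.
    """
    recordings, metadata = generate_cohort(spec)
    kept, _, reports = apply_exclusion(recordings)
    meta = metadata.set_index("id")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", MissingFeatureWarning)
        for rec in kept:
            clean, qc = preprocess(rec)
            for r in reports:
                if r.participant_id == rec.participant_id:
                    r.n_spikes, r.n_interpolated = qc.n_spikes, qc.n_interpolated
            vec = extract_features(clean, age=meta.loc[rec.participant_id, "age"],
                                   config=extract_config)
            row = {F.ID_COLUMN: rec.participant_id,
                   F.LABEL_COLUMN: meta.loc[rec.participant_id, "group"]}
            row.update(vec.to_dict())
            rows.append(row)
    features = pd.DataFrame(rows)
    return features, qc_report_table(reports), metadata


@dataclass
class ComboResult:
    mode: str
    balancing: str
    split: SplitDataset
    selection: SelectionReport
    reports: list[ModelReport]


def run_models(
    features: pd.DataFrame,
    mode: str,
    balancing: str = "smote",
    seed: int = 0,
    models: tuple[str, ...] = ("LR", "KNN"),
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    B: int = 1000,
    test_fraction: float = 0.2,
    test_counts: dict | None = None,
) -> ComboResult:
    """Preprocess, select and model one feature-set/balancing combination."""
    cols = F.feature_set(mode)
    ds = prepare(features, cols, balanced=(balancing == "smote"),
                 test_fraction=test_fraction, seed=seed, test_counts=test_counts)
    sel = select_features(ds.train_model, cols, seed=seed)
    train_X = ds.train_model[sel.selected]
    train_y = ds.train_model[F.LABEL_COLUMN]
    test_X = ds.test_model[sel.selected]
    test_y = ds.test_model[F.LABEL_COLUMN]

    reports: list[ModelReport] = []
    base_cfg = {"mode": mode, "balancing": balancing, "features": sel.selected, "seed": seed}
    for model_name in models:
        if model_name == "LR":
            lr = train_lr(train_X, train_y)
            for dt in thresholds:
                reports.append(
                    evaluate_model(lr, test_X, test_y, "LR", dt=dt, B=B, seed=seed,
                                   config=base_cfg)
                )
        elif model_name == "KNN":
            knn, best_k = train_knn(train_X, train_y, seed=seed)
            reports.append(
                evaluate_model(knn, test_X, test_y, "KNN", dt=None, B=B, seed=seed,
                               config=dict(base_cfg, best_k=best_k))
            )
        else:
            raise ValueError(f"unknown model {model_name!r}")
    return ComboResult(mode, balancing, ds, sel, reports)


# ---------------------------------------------------------------------------
# Full run with artifacts
# ---------------------------------------------------------------------------


def _log(outdir: Path, message: str) -> None:
    with open(outdir / "log.txt", "a") as fh:
        fh.write(message + "\n")


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full workflow and write every stage artifact.

    Raises :class:`StageError` naming the failing stage; artifacts written
    before the failure are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "log.txt").write_text("")
    summary: dict = {"config": config.to_dict(), "version": __version__}

    stage = "simulate+qc+extract"
    try:
        spec = config.cohort_spec()
        features, qc_table, metadata = simulate_feature_table(spec)
        if config.write_recordings:
            recordings, _ = generate_cohort(spec)
            for rec in recordings:
                rec.write(outdir / "recordings")
        metadata.to_csv(outdir / "metadata.csv", index=False)
        qc_table.to_csv(outdir / "qc_report.csv", index=False)
        features.to_csv(outdir / "features.csv", index=False)
        n_excluded = int((~qc_table["included"]).sum())
        _log(outdir, f"simulate: {len(metadata)} participants (seed={config.seed})")
        _log(outdir, f"qc: excluded {n_excluded} below tracking ratio 0.80")
        _log(outdir, f"extract: {len(features)} feature vectors x {len(F.ALL_FEATURES)} features + age")
        summary["n_participants"] = len(metadata)
        summary["n_excluded"] = n_excluded
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage, exc) from exc

    (outdir / "selection").mkdir(exist_ok=True)
    (outdir / "models").mkdir(exist_ok=True)
    (outdir / "pr_curves").mkdir(exist_ok=True)
    summary["combos"] = []
    for mode in config.modes:
        for balancing in config.balancing:
            stage = f"model[{mode},{balancing}]"
            try:
                combo = run_models(
                    features, mode, balancing, seed=config.seed, models=config.models,
                    thresholds=config.thresholds, B=config.bootstrap_B,
                    test_fraction=config.test_fraction, test_counts=config.test_counts,
                )
                combo.selection.to_json(outdir / "selection" / f"{mode}_{balancing}.json")
                (outdir / "selection" / f"{mode}_{balancing}_selected.txt").write_text(
                    "\n".join(combo.selection.selected) + "\n")
                entries = [r.to_dict() for r in combo.reports]
                with open(outdir / "models" / f"{mode}_{balancing}.json", "w") as fh:
                    json.dump(entries, fh, indent=2)
                for r in combo.reports:
                    tag = f"{mode}_{balancing}_{r.model}" + (
                        f"_dt{r.config['dt']}" if r.config.get("dt") is not None else "")
                    r.pr_points.to_csv(outdir / "pr_curves" / f"{tag}.csv", index=False)
                _log(outdir, f"{stage}: selected {len(combo.selection.selected)} features; "
                             f"{len(combo.reports)} model evaluations")
                summary["combos"].append({
                    "mode": mode, "balancing": balancing,
                    "selected": combo.selection.selected,
                    "models": [r.model for r in combo.reports],
                })
            except Exception as exc:  # noqa: BLE001 - stage boundary
                raise StageError(stage, exc) from exc

    stage = "manifest"
    try:
        manifest = {
            "version": __version__,
            "config": config.to_dict(),
            "stage_hashes": _hash_tree(outdir),
            "summary": {k: v for k, v in summary.items() if k != "config"},
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc
    summary["manifest"] = manifest
    return summary


def _hash_tree(outdir: Path) -> dict[str, str]:
    hashes = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name not in ("manifest.json", "log.txt", "report.md"):
            if path.suffix == ".png":
                continue
            hashes[str(path.relative_to(outdir))] = hashlib.sha256(path.read_bytes()).hexdigest()
    return hashes


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

_MODE_TITLES = {
    "combined": "Combined time and eye-movement features",
    "eye_only": "Eye-movement features alone",
    "time_only": "Time-related features alone",
}
_METRIC_TITLES = [
    ("recall", "Recall/Sensitivity"),
    ("precision", "Precision"),
    ("specificity", "Specificity"),
    ("f1", "F1-Score"),
    ("accuracy", "Accuracy"),
    ("auprc", "AUPRC"),
]


def _fmt(mean: float, lo: float, hi: float) -> str:
    return f"{mean:.2f} [{lo:.2f}–{hi:.2f}]"


def render_report(outdir: str | Path, make_plots: bool = True) -> str:
    """Render per-feature-set metric tables (and PR plots) from a completed
    run directory; missing artifacts are listed and skipped."""
    outdir = Path(outdir)
    lines = ["# OCAT screening model report", ""]
    missing = []
    for mode, title in _MODE_TITLES.items():
        tables = sorted((outdir / "models").glob(f"{mode}_*.json")) if (outdir / "models").exists() else []
        if not tables:
            missing.append(f"models for mode {mode}")
            continue
        lines.append(f"## {title}")
        lines.append("")
        header = "| Model | Hyper-parameter | " + " | ".join(t for _, t in _METRIC_TITLES) + " |"
        lines.append(header)
        lines.append("|" + "---|" * (2 + len(_METRIC_TITLES)))
        for path in tables:
            balancing = path.stem.split("_")[-1]
            entries = json.loads(path.read_text())
            for entry in entries:
                m = entry["metrics"]
                if entry["model"] == "LR":
                    hyper = f"DT = {entry['config']['dt']}"
                else:
                    hyper = f"Best k = {entry['config'].get('best_k', '?')}"
                label = f"{entry['model']}–{'SMOTE' if balancing == 'smote' else 'Original'}"
                cells = [_fmt(m[k]["mean"], m[k]["ci_lower"], m[k]["ci_upper"])
                         for k, _ in _METRIC_TITLES]
                lines.append(f"| {label} | {hyper} | " + " | ".join(cells) + " |")
        lines.append("")
        if make_plots:
            _plot_pr(outdir, mode)
    if missing:
        lines.append("## Missing artifacts")
        lines.extend(f"- {m}" for m in missing)
    text = "\n".join(lines) + "\n"
    (outdir / "report.md").write_text(text)
    return text


def _plot_pr(outdir: Path, mode: str) -> None:
    curves = sorted((outdir / "pr_curves").glob(f"{mode}_*.csv"))
    if not curves:
        return
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for path in curves:
        df = pd.read_csv(path)
        label = path.stem[len(mode) + 1:]
        ax.plot(df["recall"], df["precision"], label=label, drawstyle="steps-post")
    ax.set_xlabel("Recall")
    ax.set_ylabel("Precision")
    ax.set_title(_MODE_TITLES.get(mode, mode))
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(outdir / f"pr_{mode}.png", dpi=120)
    plt.close(fig)
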