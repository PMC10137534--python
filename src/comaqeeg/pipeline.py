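"""End-to-end orchestration: cohort -> features -> stats -> balance -> models.

A pipeline run is a pure function of its configuration (all randomness
flows from the configured seeds) and produces a run directory containing
the feature table (CSV, one row per instance: 4 metadata + 160 feature
columns), the statistical screen (JSON + significance grid CSV), the
band-energy group summary, the balancing audit, per-model metric reports
for both the unbalanced and balanced variants, pooled ROC scores, and a
top-level report keyed by the configuration hash.

Two balancing modes are provided: ``global`` oversamples the whole
table once before cross-validation (synthetic instances can then leak into
test folds — a warning is logged) and ``leak-free`` oversamples inside
each training fold only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .balancing import SmoteConfig, balance_dataset
from .bands import CANONICAL_BANDS
from .edf import read_recording, write_recording
from .evaluation import MODEL_FAMILIES, MetricsReport, ModelSpec, run_kfold_cv, run_leave_one_patient_out
from .features import WelchConfig, extract_recording_features, feature_column_names, vectors_to_frame
from .preprocess import apply_lowpass, apply_notch
from .recording import Recording
from .stats import energy_group_summary, ks_normality, screen_features, significance_table
from .synthetic import SyntheticCohortConfig, default_profiles, iter_cohort

logger = logging.getLogger(__name__)

MODES = ("global", "leak-free")


@dataclass
class PipelineConfig:
    """Everything a run needs; see module docstring for the artifacts."""

    out_dir: Path = Path("runs/latest")
    seed: int = 0
    input_dir: Path | None = None  # EDF cohort + manifest.csv; None -> synthesize
    cohort: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    notch_hz: float = 50.0
    notch_q: float = 30.0
    lowpass_hz: float = 30.0
    welch: WelchConfig = field(default_factory=WelchConfig)
    alpha: float = 0.05
    smote: SmoteConfig = field(default_factory=SmoteConfig)
    mode: str = "global"
    models: tuple[str, ...] = MODEL_FAMILIES
    cv_k: int = 20
    lopo: bool = False

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.cv_k < 2:
            raise ValueError("cv_k must be >= 2")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        unknown = set(self.models) - set(MODEL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown model families: {sorted(unknown)}")
        if max(b.f_hi for b in CANONICAL_BANDS) > self.lowpass_hz:
            raise ValueError("band upper edges must lie within the lowpass passband")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "cohort" in kwargs:
            c = dict(kwargs["cohort"])
            if "patients_per_level" in c:
                c["patients_per_level"] = {int(k): int(v) for k, v in c["patients_per_level"].items()}
            kwargs["cohort"] = SyntheticCohortConfig(**c)
        if "welch" in kwargs:
            kwargs["welch"] = WelchConfig(**kwargs["welch"])
        if "smote" in kwargs:
            s = dict(kwargs["smote"])
            if isinstance(s.get("plan"), dict):
                s["plan"] = {int(k): float(v) for k, v in s["plan"].items()}
            kwargs["smote"] = SmoteConfig(**s)
        if "models" in kwargs:
            kwargs["models"] = tuple(kwargs["models"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, Path):
                return str(o)
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_cohort(config: PipelineConfig):
    """EDF cohort from disk (manifest.csv: patient_id, gcs, file) or synthetic.

    The synthetic path returns a lazy iterator (recordings are large);
    the disk path returns a list.
    """
    if config.input_dir is None:
        return iter_cohort(config.cohort, default_profiles())
    input_dir = Path(config.input_dir)
    manifest = pd.read_csv(input_dir / "manifest.csv")
    recordings = []
    for row in manifest.itertuples():
        rec = read_recording(input_dir / row.file)
        rec.patient_id = str(row.patient_id)
        rec.gcs = int(row.gcs)
        recordings.append(rec)
    return recordings


def write_cohort(recordings: list[Recording], out_dir) -> pd.DataFrame:
    """Write one EDF per patient plus the manifest; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"{rec.patient_id}.edf"
        write_recording(rec, out_dir / fname)
        rows.append({"patient_id": rec.patient_id, "gcs": rec.gcs, "file": fname})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def extract_features(recordings, config: PipelineConfig) -> pd.DataFrame:
    """Denoise, segment, and extract the 160-feature table for a cohort."""
    vectors = []
    for rec in recordings:
        denoised = apply_lowpass(
            apply_notch(rec, config.notch_hz, config.notch_q), config.lowpass_hz
        )
        vectors.extend(
            extract_recording_features(
                denoised, config.cohort.schedule, CANONICAL_BANDS, config.welch
            )
        )
    return vectors_to_frame(vectors)


def report_to_dict(report: MetricsReport) -> dict:
    return {
        "overall_accuracy": report.overall_accuracy,
        "macro": report.macro,
        "weighted": report.weighted,
        "per_class": report.per_class.reset_index(names="class").to_dict("records"),
        "per_class_auc": {str(k): v for k, v in (report.per_class_auc or {}).items()},
        "beta": report.beta,
    }


def _roc_points(pooled_scores: pd.DataFrame) -> pd.DataFrame:
    """One-vs-rest ROC curve points per (model, variant, class)."""
    from sklearn.metrics import roc_curve

    score_cols = [c for c in pooled_scores.columns if c.startswith("score_")]
    rows = []
    for (model, variant), chunk in pooled_scores.groupby(["model", "variant"]):
        for col in score_cols:
            cls = col.removeprefix("score_")
            positive = chunk["y_true"].astype(str) == cls
            scores = chunk[col].to_numpy()
            ok = np.isfinite(scores)
            if not positive[ok].any() or positive[ok].all():
                continue
            fpr, tpr, _ = roc_curve(positive[ok], scores[ok])
            for f, t in zip(fpr, tpr):
                rows.append(
                    {"model": model, "variant": variant, "class": cls, "fpr": f, "tpr": t}
                )
    return pd.DataFrame(rows, columns=["model", "variant", "class", "fpr", "tpr"])


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write the run directory; returns its path."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    feature_cols = feature_column_names()

    def stage(name):
        logger.info("pipeline stage: %s", name)

    stage("cohort + features")
    table = extract_features(load_cohort(config), config)
    table.to_csv(run_dir / "features.csv", index=False)

    stage("stats")
    # normality gate: motivates the nonparametric screen
    normal_fraction = {}
    for col in feature_cols:
        try:
            normal_fraction[col] = ks_normality(table[col].to_numpy()) > config.alpha
        except ValueError:
            normal_fraction[col] = False
    results = screen_features(table, feature_cols)
    grid = significance_table(results, alpha=config.alpha)
    grid["p"].to_csv(run_dir / "significance_grid.csv")
    energy_group_summary(table).to_csv(run_dir / "energy_summary.csv")
    stats_json = {
        "normality_pass_fraction": float(np.mean(list(normal_fraction.values()))),
        "kruskal_wallis": {
            r.feature_id: {
                "H": r.H,
                "p": r.p,
                "pairwise": {f"{a}-{b}": v for (a, b), v in r.pairwise.items()},
            }
            for r in results
        },
    }
    (run_dir / "stats.json").write_text(json.dumps(stats_json, indent=1))

    stage("balance")
    X = table[feature_cols].to_numpy(dtype=np.float64)
    y = table["gcs"].to_numpy(dtype=int)
    X_bal, y_bal, audit = balance_dataset(X, y, config.smote)
    audit["mode"] = config.mode
    (run_dir / "balance_audit.json").write_text(json.dumps(audit, indent=1, default=str))
    balanced = pd.DataFrame(X_bal, columns=feature_cols)
    balanced.insert(0, "gcs", y_bal)
    balanced.to_csv(run_dir / "balanced.csv", index=False)
    if config.mode == "global":
        logger.warning(
            "global mode balances before cross-validation; synthetic "
            "instances may leak into test folds (use leak-free to avoid)"
        )

    stage("classify")
    metrics: dict = {}
    roc_frames = []
    for family in config.models:
        spec = ModelSpec(family=family, seed=config.seed)
        pooled_u, report_u = run_kfold_cv(X, y, spec, k=config.cv_k, seed=config.seed)
        variants = {"unbalanced": (pooled_u, report_u)}
        if config.mode == "global":
            variants["balanced"] = run_kfold_cv(
                X_bal, y_bal, spec, k=config.cv_k, seed=config.seed
            )
        else:
            variants["balanced"] = run_kfold_cv(
                X, y, spec, k=config.cv_k, seed=config.seed, balance_in_fold=config.smote
            )
        metrics[family] = {}
        for variant, (pooled, report) in variants.items():
            metrics[family][variant] = report_to_dict(report)
            pooled = pooled.copy()
            pooled.insert(0, "variant", variant)
            pooled.insert(0, "model", family)
            roc_frames.append(pooled)
        if config.lopo:
            lopo = run_leave_one_patient_out(table, feature_cols, spec)
            metrics[family]["leave_one_patient_out"] = {
                "accuracy": float((lopo.y_true == lopo.y_pred).mean()),
                "per_patient": lopo.drop(columns=["votes"]).to_dict("records"),
            }
    (run_dir / "metrics.json").write_text(json.dumps(metrics, indent=1))
    pooled_scores = pd.concat(roc_frames, ignore_index=True)
    pooled_scores.to_csv(run_dir / "roc_scores.csv", index=False)
    _roc_points(pooled_scores).to_csv(run_dir / "roc_points.csv", index=False)

    stage("report")
    summary = {
        "config_hash": config.config_hash(),
        "n_patients": int(table["patient_id"].nunique()),
        "n_instances": int(len(table)),
        "instances_per_level": table.groupby("gcs").size().to_dict(),
        "balanced_per_level": pd.Series(y_bal).value_counts().sort_index().to_dict(),
        "overall_accuracy": {
            family: {v: metrics[family][v]["overall_accuracy"] for v in ("unbalanced", "balanced")}
            for family in config.models
        },
    }
    (run_dir / "report.json").write_text(json.dumps(summary, indent=1, default=str))
    return run_dir
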