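"""Classifier benchmarking with one-vs-rest, imbalance-aware metrics.

Four classifier families are benchmarked: Random Forest (100 trees), 1-NN
with Euclidean distance, an ensemble of 30 bagged decision trees, and a
cubic-kernel SVM.  Evaluation pools held-out predictions over stratified
k-fold cross-validation (default k = 20) into a single 6x6 confusion
matrix, from which per-class one-vs-rest counts give sensitivity,
specificity, precision, F-score (beta = 1), and G-mean; a grouped
leave-one-patient-out protocol predicts each patient's label by majority
vote over that patient's held-out segments.

The one-vs-rest accounting and the metric formulas are implemented here;
classifier internals are delegated to scikit-learn estimators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

MODEL_FAMILIES = ("random_forest", "knn", "bagged_trees", "svm_cubic")


@dataclass(frozen=True)
class ModelSpec:
    """One classifier configuration.

    Defaults follow the benchmarked settings: 100 trees for the random
    forest, K = 1 Euclidean for kNN, 30 decision-tree learners for bagging,
    and a cubic polynomial kernel with automatic scale for the SVM.
    Distance- and margin-based families (knn, svm) receive z-scored
    features (training-fold statistics); tree ensembles take raw features.
    """

    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {MODEL_FAMILIES}")

    def build(self) -> Pipeline:
        hp = dict(self.hyperparameters)
        scale = False
        if self.family == "random_forest":
            est = RandomForestClassifier(
                n_estimators=hp.pop("n_estimators", 100), random_state=self.seed, **hp
            )
        elif self.family == "knn":
            est = KNeighborsClassifier(
                n_neighbors=hp.pop("n_neighbors", 1), metric=hp.pop("metric", "euclidean"), **hp
            )
            scale = True
        elif self.family == "bagged_trees":
            est = BaggingClassifier(
                estimator=DecisionTreeClassifier(random_state=self.seed),
                n_estimators=hp.pop("n_estimators", 30),
                random_state=self.seed,
                **hp,
            )
        else:  # svm_cubic
            est = SVC(
                kernel="poly",
                degree=hp.pop("degree", 3),
                gamma=hp.pop("gamma", "scale"),
                coef0=hp.pop("coef0", 1.0),
                random_state=self.seed,
                **hp,
            )
            scale = True
        steps = [("impute", SimpleImputer(strategy="median"))]
        if scale:
            steps.append(("scale", StandardScaler()))
        steps.append(("model", est))
        return Pipeline(steps)


@dataclass
class ConfusionCounts:
    """A labelled actual x predicted count matrix."""

    matrix: np.ndarray
    classes: tuple

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        k = len(self.classes)
        if self.matrix.shape != (k, k):
            raise ValueError("confusion matrix must be square over the class list")
        if np.any(self.matrix < 0):
            raise ValueError("confusion counts must be >= 0")

    @classmethod
    def from_predictions(cls, y_true, y_pred, classes=None) -> "ConfusionCounts":
        labels = tuple(classes) if classes is not None else tuple(sorted(set(y_true)))
        index = {c: i for i, c in enumerate(labels)}
        m = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for t, p in zip(y_true, y_pred):
            m[index[t], index[p]] += 1
        return cls(m, labels)


def one_vs_rest_counts(confusion: ConfusionCounts, cls) -> tuple[int, int, int, int]:
    """(TP, FN, FP, TN) for one class of a multiclass confusion matrix.

    TP is the diagonal cell, FN the rest of the class's row, FP the rest
    of its column, TN everything else.
    """
    if cls not in confusion.classes:
        raise ValueError(f"unknown class {cls!r}")
    i = confusion.classes.index(cls)
    m = confusion.matrix
    tp = int(m[i, i])
    fn = int(m[i].sum() - tp)
    fp = int(m[:, i].sum() - tp)
    tn = int(m.sum() - tp - fn - fp)
    return tp, fn, fp, tn


@dataclass
class MetricsReport:
    """Per-class and averaged one-vs-rest metrics of one evaluation."""

    per_class: pd.DataFrame
    macro: dict[str, float]
    weighted: dict[str, float]
    overall_accuracy: float
    beta: float = 1.0
    per_class_auc: dict | None = None


def _safe_div(num: float, den: float, what: str, cls) -> float:
    if den == 0:
        logger.warning("metric %s undefined for class %r (zero denominator)", what, cls)
        return float("nan")
    return num / den


def compute_metrics(confusion: ConfusionCounts, beta: float = 1.0) -> MetricsReport:
    """Sensitivity, specificity, precision, F-score, G-mean per class.

    Each metric follows its one-vs-rest definition; F-score uses the
    stated beta (beta = 1 reduces to the harmonic mean of precision and
    sensitivity) and G-mean is sqrt(sensitivity x specificity).  Zero
    denominators yield NaN with a log entry, never a silent 0.  Overall
    accuracy is trace / total.
    """
    rows = {}
    total = int(confusion.matrix.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    for cls in confusion.classes:
        tp, fn, fp, tn = one_vs_rest_counts(confusion, cls)
        sens = _safe_div(tp, tp + fn, "sensitivity", cls)
        spec = _safe_div(tn, tn + fp, "specificity", cls)
        prec = _safe_div(tp, tp + fp, "precision", cls)
        f_den = beta**2 * sens + prec
        fscore = (1 + beta**2) * sens * prec / f_den if f_den > 0 else float("nan")
        gmean = float(np.sqrt(sens * spec))
        rows[cls] = {
            "support": tp + fn,
            "sensitivity": sens,
            "specificity": spec,
            "precision": prec,
            "f_score": fscore,
            "g_mean": gmean,
        }
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    metric_cols = ["sensitivity", "specificity", "precision", "f_score", "g_mean"]
    macro = {m: float(per_class[m].mean()) for m in metric_cols}
    w = per_class["support"] / per_class["support"].sum()
    weighted = {m: float((per_class[m] * w).sum()) for m in metric_cols}
    return MetricsReport(
        per_class=per_class,
        macro=macro,
        weighted=weighted,
        overall_accuracy=float(np.trace(confusion.matrix) / total),
        beta=beta,
    )


def _check_stratifiable(y: np.ndarray, k: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    for cls, n in zip(classes, counts):
        if n < k:
            raise ValueError(
                f"class {cls!r} has only {n} instances; cannot stratify into {k} folds"
            )


def run_kfold_cv(
    matrix: np.ndarray,
    labels: np.ndarray,
    spec: ModelSpec,
    k: int = 20,
    seed: int = 0,
    beta: float = 1.0,
    balance_in_fold=None,
) -> tuple[pd.DataFrame, MetricsReport]:
    """Stratified k-fold CV with predictions pooled across held-out folds.

    Returns (pooled prediction table, metrics report from the pooled
    confusion).  ``balance_in_fold`` optionally supplies a SmoteConfig used
    to oversample each *training* fold only (the leakage-free balancing
    mode); the held-out fold is never touched.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X = np.asarray(matrix, dtype=np.float64)
    y = np.asarray(labels)
    _check_stratifiable(y, k)
    classes = tuple(sorted(np.unique(y).tolist()))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    scores = np.full((len(y), len(classes)), np.nan)
    for train_idx, test_idx in skf.split(X, y):
        X_tr, y_tr = X[train_idx], y[train_idx]
        if balance_in_fold is not None:
            from .balancing import balance_dataset

            X_tr, y_tr, _ = balance_dataset(X_tr, y_tr, balance_in_fold)
        model = spec.build()
        model.fit(X_tr, y_tr)
        y_pred[test_idx] = model.predict(X[test_idx])
        s = _class_scores(model, X[test_idx], classes)
        if s is not None:
            scores[test_idx] = s
    pooled = pd.DataFrame({"y_true": y, "y_pred": y_pred})
    for i, cls in enumerate(classes):
        pooled[f"score_{cls}"] = scores[:, i]
    confusion = ConfusionCounts.from_predictions(y, y_pred, classes)
    report = compute_metrics(confusion, beta=beta)
    report.per_class_auc = roc_auc_ovr(scores, y, classes)
    return pooled, report


def _class_scores(model, X, classes) -> np.ndarray | None:
    """Per-class scores aligned with ``classes`` (probability or decision)."""
    fitted_classes = list(model.classes_)
    if hasattr(model, "predict_proba"):
        raw = model.predict_proba(X)
    elif hasattr(model, "decision_function"):
        raw = model.decision_function(X)
        if raw.ndim == 1:
            raw = np.column_stack([-raw, raw])
    else:  # pragma: no cover
        return None
    out = np.full((X.shape[0], len(classes)), np.nan)
    for j, cls in enumerate(classes):
        if cls in fitted_classes:
            out[:, j] = raw[:, fitted_classes.index(cls)]
    return out


def run_leave_one_patient_out(
    frame: pd.DataFrame,
    feature_columns: list[str],
    spec: ModelSpec,
    label_column: str = "gcs",
    patient_column: str = "patient_id",
) -> pd.DataFrame:
    """Grouped CV: all segments of one patient are held out per fold.

    The patient-level prediction is the majority vote over that patient's
    segment predictions (ties broken toward the smallest label).  Returns
    one row per patient: true label, voted label, and the vote counts.
    """
    patients = frame[patient_column].unique()
    if len(patients) < 2:
        raise ValueError("leave-one-patient-out needs >= 2 patients")
    X = frame[feature_columns].to_numpy(dtype=np.float64)
    y = frame[label_column].to_numpy()
    groups = frame[patient_column].to_numpy()
    rows = []
    for patient in patients:
        test = groups == patient
        model = spec.build()
        model.fit(X[~test], y[~test])
        seg_pred = model.predict(X[test])
        values, counts = np.unique(seg_pred, return_counts=True)
        voted = values[np.lexsort((values, -counts))][0]
        rows.append(
            {
                patient_column: patient,
                "y_true": y[test][0],
                "y_pred": voted,
                "n_segments": int(test.sum()),
                "votes": dict(zip(values.tolist(), counts.tolist())),
            }
        )
    return pd.DataFrame(rows)


def roc_auc_ovr(class_scores: np.ndarray, labels, classes) -> dict:
    """Per-class one-vs-rest AUC by threshold sweep and trapezoid rule.

    A class absent from the labels (or with all-NaN scores) gets NaN with
    a log entry instead of an exception.
    """
    y = np.asarray(labels)
    scores = np.asarray(class_scores, dtype=np.float64)
    out: dict = {}
    for j, cls in enumerate(classes):
        positive = y == cls
        s = scores[:, j]
        ok = np.isfinite(s)
        if not positive.any() or positive.all() or not ok.any():
            logger.warning("AUC undefined for class %r", cls)
            out[cls] = float("nan")
            continue
        fpr, tpr, _ = roc_curve(positive[ok], s[ok])
        out[cls] = float(np.trapezoid(tpr, fpr))
    return out
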