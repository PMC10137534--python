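"""SMOTE oversampling and the per-class balancing plan.

Synthetic minority instances are linear interpolations toward K nearest
same-class neighbors:  x_new = x_i + (x_knn - x_i) * w  with w uniform in
[0, 1] and x_knn drawn uniformly from the K Euclidean nearest neighbors of
x_i (the query point itself excluded).  The number of synthetic instances
for a class oversampled by ``percent`` is floor(size * percent / 100),
which reproduces the study's consistent plan rows exactly (74 @ 8% -> 79,
36 @ 120% -> 79, 18 @ 340% -> 79).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SmoteConfig:
    """Balancing settings.

    plan maps class label -> increase percentage; the string "auto" raises
    every minority class to the largest class's size.  standardize z-scores
    features before the neighbor search only (synthetic instances are still
    generated in the raw feature space); off by default since the study
    does not mention scaling before SMOTE.
    """

    K: int = 5
    plan: dict | str = "auto"
    seed: int = 0
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if isinstance(self.plan, dict) and any(p < 0 for p in self.plan.values()):
            raise ValueError("plan percentages must be >= 0")


def smote_oversample(
    instances: np.ndarray,
    percent: float,
    K: int = 5,
    seed=0,
    n_synthetic: int | None = None,
    neighbor_space: np.ndarray | None = None,
) -> np.ndarray:
    """Synthetic instances for one class.

    Emits floor(n * percent / 100) synthetic vectors (or ``n_synthetic``
    when given explicitly).  Parents are cycled through the class in order;
    for each synthetic vector a neighbor among the parent's K nearest
    (Euclidean, self excluded) is chosen uniformly and the interpolation
    weight drawn uniformly from [0, 1].  ``seed`` may be an int, Generator,
    or any object exposing ``random()`` and ``integers(n)`` (the latter is
    handy for forcing the interpolation endpoints in tests).
    ``neighbor_space`` optionally supplies transformed coordinates for the
    neighbor search while interpolation stays in the raw space.
    """
    X = np.asarray(instances, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("instances must be a 2-D array")
    n = X.shape[0]
    if n <= K:
        raise ValueError(
            f"class size {n} must exceed K={K}; reduce K or supply more instances"
        )
    if percent < 0:
        raise ValueError("percent must be >= 0")
    if not np.all(np.isfinite(X)):
        raise ValueError("instances must be finite (impute NaNs before SMOTE)")
    rng = seed if hasattr(seed, "random") and hasattr(seed, "integers") else np.random.default_rng(seed)
    n_syn = int(n * percent // 100) if n_synthetic is None else int(n_synthetic)
    if n_syn == 0:
        return np.empty((0, X.shape[1]))

    space = X if neighbor_space is None else np.asarray(neighbor_space, dtype=np.float64)
    nn = NearestNeighbors(n_neighbors=K + 1).fit(space)
    _, idx = nn.kneighbors(space)
    # drop the query point itself; with duplicate rows it may not be listed
    # first, so filter by index rather than position
    neighbor_idx = np.empty((n, K), dtype=int)
    for i in range(n):
        others = idx[i][idx[i] != i]
        if others.size < K:  # duplicates of i beyond the first K+1 returned
            others = np.concatenate([others, [j for j in range(n) if j != i]])
        neighbor_idx[i] = others[:K]

    out = np.empty((n_syn, X.shape[1]))
    for j in range(n_syn):
        i = j % n
        knn = neighbor_idx[i][int(rng.integers(K))]
        w = float(rng.random())
        out[j] = X[i] + (X[knn] - X[i]) * w
    return out


def _impute_class_median(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Replace NaNs column-wise by the class median; returns (imputed, count)."""
    X = X.copy()
    n_imputed = 0
    for col in range(X.shape[1]):
        mask = ~np.isfinite(X[:, col])
        if mask.any():
            finite = X[~mask, col]
            fill = float(np.median(finite)) if finite.size else 0.0
            X[mask, col] = fill
            n_imputed += int(mask.sum())
    return X, n_imputed


def balance_dataset(
    feature_matrix: np.ndarray,
    labels: np.ndarray,
    config: SmoteConfig = SmoteConfig(),
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Oversample every planned class; originals first, synthetic appended.

    Returns (balanced matrix, balanced labels, audit log).  The audit log
    records per-class before/after counts, the applied percentage, and the
    number of NaN cells imputed (per-class median) before neighbor search.
    Class counts never decrease (oversampling-only contract).
    """
    X = np.asarray(feature_matrix, dtype=np.float64)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("feature_matrix and labels disagree in length")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("balance_dataset needs >= 2 classes")
    count_of = dict(zip(classes.tolist(), counts.tolist()))

    if isinstance(config.plan, dict):
        missing = [c for c in config.plan if c not in count_of]
        if missing:
            raise ValueError(f"plan references absent class(es): {missing}")

    rng = np.random.default_rng(config.seed)
    synthetic_chunks: list[np.ndarray] = []
    synthetic_labels: list[np.ndarray] = []
    audit: dict = {"classes": {}, "mode": "auto" if config.plan == "auto" else "plan"}
    n_max = int(counts.max())

    for cls in classes.tolist():
        n_cls = count_of[cls]
        Xc = X[y == cls]
        Xc_imp, n_imputed = _impute_class_median(Xc)
        if config.plan == "auto":
            n_syn = n_max - n_cls
            percent = 100.0 * n_syn / n_cls
        else:
            percent = float(config.plan.get(cls, 0.0))
            n_syn = int(n_cls * percent // 100)
        if n_syn > 0:
            space = None
            if config.standardize:
                sd = Xc_imp.std(axis=0)
                sd[sd == 0] = 1.0
                space = (Xc_imp - Xc_imp.mean(axis=0)) / sd
            syn = smote_oversample(
                Xc_imp, percent, K=config.K, seed=rng,
                n_synthetic=n_syn, neighbor_space=space,
            )
            synthetic_chunks.append(syn)
            synthetic_labels.append(np.full(n_syn, cls, dtype=y.dtype))
        audit["classes"][cls] = {
            "before": int(n_cls),
            "percent": round(percent, 4),
            "synthetic": int(n_syn),
            "after": int(n_cls + n_syn),
            "imputed_cells": n_imputed,
        }

    if synthetic_chunks:
        X_bal = np.vstack([X] + synthetic_chunks)
        y_bal = np.concatenate([y] + synthetic_labels)
    else:
        X_bal, y_bal = X.copy(), y.copy()
    audit["total_before"] = int(len(y))
    audit["total_after"] = int(len(y_bal))
    return X_bal, y_bal, audit


def plan_arithmetic(
    counts: dict, percents: dict, printed_after: dict | None = None
) -> pd.DataFrame:
    """Audit a balancing plan's arithmetic under the floor rule.

    For each class: after = before + floor(before * percent / 100).  When
    ``printed_after`` supplies externally stated post-balancing counts, any
    class whose stated count disagrees with the floor rule is flagged
    (``consistent`` False) and the stated count is kept in the totals row,
    so stated table totals are reproduced as plain table arithmetic.
    The totals row carries the summed counts and the overall percentage
    increase.
    """
    rows = []
    for cls in sorted(counts):
        before = int(counts[cls])
        percent = float(percents.get(cls, 0.0) or 0.0)
        computed = before + int(before * percent // 100)
        stated = int(printed_after[cls]) if printed_after and cls in printed_after else None
        consistent = stated is None or stated == computed
        if not consistent:
            logger.warning(
                "class %r: stated post-balance count %d != floor-rule count %d",
                cls, stated, computed,
            )
        rows.append(
            {
                "class": cls,
                "before": before,
                "percent": percent,
                "after_floor_rule": computed,
                "after_stated": stated if stated is not None else computed,
                "consistent": consistent,
            }
        )
    table = pd.DataFrame(rows).set_index("class")
    total_before = int(table["before"].sum())
    total_after = int(table["after_stated"].sum())
    table.loc["total"] = {
        "before": total_before,
        "percent": round(100.0 * (total_after - total_before) / total_before, 2),
        "after_floor_rule": int(table["after_floor_rule"].sum()),
        "after_stated": total_after,
        "consistent": bool(table["consistent"].all()),
    }
    return table
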