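"""Nonparametric group screening of the 160 features across GCS levels.

The screen mirrors common practice for skewed biomedical features: a
Kolmogorov-Smirnov normality gate (with estimated mean/sd, so the usual
Lilliefors caveat applies: the tabulated p-values are anti-conservative),
a Kruskal-Wallis test across the six GCS groups per feature, and Dunn's
pairwise post-hoc z-tests with Bonferroni adjustment over the
C(6,2) = 15 pairs of one feature (not across the 160-feature family).

Instances are pooled per segment (up to 9 per patient) as independent
observations, mirroring the study design; note this pseudo-replicates
patients and overlapping T10 windows — see the per-patient aggregation
option in :func:`screen_features`.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FEATURE_NAMES


@dataclass
class GroupComparisonResult:
    """Kruskal-Wallis + Dunn post-hoc outcome for one feature."""

    feature_id: str
    H: float
    p: float
    pairwise: dict[tuple[int, int], float]
    group_labels: tuple[int, ...]


def _clean_groups(groups) -> list[np.ndarray]:
    cleaned = []
    for g in groups:
        a = np.asarray(g, dtype=np.float64)
        cleaned.append(a[np.isfinite(a)])
    return cleaned


def ks_normality(values) -> float:
    """One-sample KS p-value against a normal with estimated mean and sd."""
    a = np.asarray(values, dtype=np.float64)
    a = a[np.isfinite(a)]
    if a.size < 3:
        raise ValueError(f"ks_normality needs >= 3 finite values, got {a.size}")
    sd = a.std(ddof=1)
    if sd == 0:
        raise ValueError("ks_normality: zero-variance (constant) input")
    return float(sps.kstest(a, "norm", args=(a.mean(), sd)).pvalue)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    NaNs are dropped per group.  All-identical data returns (0, 1) by
    convention (no rank variation means no evidence of group differences).
    """
    cleaned = _clean_groups(groups)
    if len(cleaned) < 2 or any(g.size == 0 for g in cleaned):
        raise ValueError("kruskal_wallis needs >= 2 nonempty groups")
    pooled = np.concatenate(cleaned)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*cleaned)
    return float(h), float(p)


def dunn_bonferroni(groups) -> dict[tuple[int, int], float]:
    """Dunn's pairwise post-hoc z-tests with Bonferroni adjustment.

    Groups are rank-compared on the pooled sample with tie correction;
    each raw two-sided p is multiplied by the number of pairs and clipped
    at 1.  Keys are 0-based group index pairs (i, j), i < j.
    """
    cleaned = _clean_groups(groups)
    if len(cleaned) < 2 or any(g.size == 0 for g in cleaned):
        raise ValueError("dunn_bonferroni needs >= 2 nonempty groups")
    k = len(cleaned)
    pooled = np.concatenate(cleaned)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in cleaned:
        mean_ranks.append(ranks[start : start + g.size].mean())
        start += g.size
    # tie correction: sum over tied groups of (t^3 - t)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts.astype(np.float64) ** 3 - counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    m = k * (k - 1) // 2
    out: dict[tuple[int, int], float] = {}
    for i, j in combinations(range(k), 2):
        denom = var_base * (1.0 / cleaned[i].size + 1.0 / cleaned[j].size)
        if denom <= 0:  # every pooled value identical
            out[(i, j)] = 1.0
            continue
        z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(denom)
        p_raw = 2.0 * sps.norm.sf(abs(z))
        out[(i, j)] = float(min(1.0, m * p_raw))
    return out


def screen_features(
    frame: pd.DataFrame,
    feature_columns: list[str],
    group_column: str = "gcs",
    per_patient: bool = False,
) -> list[GroupComparisonResult]:
    """Kruskal-Wallis + Dunn screen of each feature column across groups.

    With ``per_patient`` the instances of each patient are first averaged
    (guarding against pseudo-replication); off by default to mirror the
    pooled-instance study design.
    """
    if per_patient:
        frame = frame.groupby(["patient_id", group_column], as_index=False)[
            feature_columns
        ].mean()
    levels = tuple(sorted(frame[group_column].unique()))
    results = []
    for col in feature_columns:
        groups = [frame.loc[frame[group_column] == lv, col].to_numpy() for lv in levels]
        h, p = kruskal_wallis(groups)
        pairwise_idx = dunn_bonferroni(groups)
        pairwise = {(levels[i], levels[j]): v for (i, j), v in pairwise_idx.items()}
        results.append(GroupComparisonResult(col, h, p, pairwise, levels))
    return results


def significance_table(
    results: list[GroupComparisonResult], alpha: float = 0.05
) -> dict[str, pd.DataFrame]:
    """Feature x (channel, band) grid of KW p-values with p > alpha flagged.

    Expects feature ids of the form "channel|band|feature".  Returns
    ``{"p": ..., "flagged": ...}`` with features as rows and a
    (channel, band) MultiIndex on the columns.
    """
    if not results:
        raise ValueError("significance_table: no results")
    rows: dict[str, dict[tuple[str, str], float]] = {f: {} for f in FEATURE_NAMES}
    for r in results:
        channel, band, feat = r.feature_id.split("|")
        rows.setdefault(feat, {})[(channel, band)] = r.p
    p = pd.DataFrame.from_dict(rows, orient="index")
    p = p.reindex([f for f in FEATURE_NAMES if f in p.index])
    p.columns = pd.MultiIndex.from_tuples(p.columns, names=["channel", "band"])
    p = p.sort_index(axis=1)
    return {"p": p, "flagged": p > alpha}


def energy_group_summary(
    frame: pd.DataFrame, group_column: str = "gcs"
) -> pd.DataFrame:
    """Per-group mean +/- standard error of every Energy feature.

    The tabular analogue of a band-energy-by-GCS summary: rows are
    (channel, band), columns a (statistic, group) MultiIndex with the mean
    and the standard error of the mean.
    """
    energy_cols = [c for c in frame.columns if c.endswith("|Energy")]
    records = {}
    for col in energy_cols:
        channel, band, _ = col.split("|")
        by = frame.groupby(group_column)[col]
        records[(channel, band)] = {
            **{("mean", g): v for g, v in by.mean().items()},
            **{("sem", g): v for g, v in by.sem().items()},
        }
    out = pd.DataFrame.from_dict(records, orient="index")
    out.index = pd.MultiIndex.from_tuples(out.index, names=["channel", "band"])
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["stat", group_column])
    return out.sort_index(axis=1)
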