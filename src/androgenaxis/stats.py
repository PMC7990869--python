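"""Nonparametric cohort statistics: normality screening, Kruskal-Wallis with
Dunn's post-hoc, Spearman correlations, and median/IQR summaries.

Hormone distributions in clinical cohorts are rarely normal, so group
comparisons are rank-based throughout: the Kruskal-Wallis H test across
gonadal-status classes, followed by Dunn's pairwise test when H is
significant, and Spearman's rank correlation for associations.  Scipy
provides the Kruskal-Wallis, Spearman and D'Agostino-Pearson machinery;
Dunn's test (pooled-rank pairwise z with tie correction) is implemented
here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "GroupComparisonResult",
    "CorrelationResult",
    "DunnPair",
    "median_iqr",
    "dagostino_pearson",
    "kruskal_wallis",
    "dunn_posthoc",
    "spearman",
    "correlation_panel",
    "compare_groups",
    "ALPHA",
]

ALPHA = 0.05  # significance threshold: p <= alpha is significant


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, Q1, Q3) with quartiles by linear interpolation.

    Missing values (NaN/None) are dropped first; an empty remainder is an
    error.
    """
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("median_iqr requires at least one value")
    med, q1, q3 = np.percentile(arr, [50, 25, 75], method="linear")
    return float(med), float(q1), float(q3)


def dagostino_pearson(values: Sequence[float]) -> tuple[float, float]:
    """D'Agostino-Pearson omnibus normality test (K2, p).

    Combines skewness and kurtosis z-scores into a chi-square(2) statistic.
    Requires n >= 20; below that the kurtosis approximation is invalid.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 20:
        raise ValueError("the omnibus normality test requires n >= 20; "
                         f"got n={arr.size}")
    if np.ptp(arr) == 0:
        raise ValueError("normality test undefined for a constant sample")
    k2, p = sps.normaltest(arr)
    return float(k2), float(p)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square(k-1)."""
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis requires at least two groups")
    clean = []
    for g in groups:
        arr = np.asarray(list(g), dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size == 0:
            raise ValueError("Kruskal-Wallis groups must be non-empty")
        clean.append(arr)
    if np.ptp(np.concatenate(clean)) == 0:
        # all observations identical: no separation by construction
        return 0.0, 1.0
    h, p = sps.kruskal(*clean)
    return float(h), float(p)


@dataclass(frozen=True)
class DunnPair:
    group_i: int
    group_j: int
    z: float
    p_unadjusted: float
    p_adjusted: float


def dunn_posthoc(groups: Sequence[Sequence[float]],
                 adjust: str = "bonferroni") -> list[DunnPair]:
    """Dunn's pairwise post-hoc test on pooled ranks with tie correction.

    For groups i, j with mean pooled ranks ``Rbar_i``, ``Rbar_j``,

        z_ij = (Rbar_i - Rbar_j) /
               sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j)),

    where ``T = sum(t^3 - t) / (12 (N-1))`` corrects for tied values.
    Two-sided p from the standard normal; ``p_adjusted`` applies Bonferroni
    over the k(k-1)/2 comparisons (capped at 1).  Intended to follow a
    significant Kruskal-Wallis result.
    """
    if len(groups) < 2:
        raise ValueError("Dunn's test requires at least two groups")
    if adjust not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    clean = [np.asarray(list(g), dtype=float) for g in groups]
    clean = [g[~np.isnan(g)] for g in clean]
    if any(g.size == 0 for g in clean):
        raise ValueError("Dunn's test groups must be non-empty")
    pooled = np.concatenate(clean)
    n_tot = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction over the pooled sample
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term

    sizes = [g.size for g in clean]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [float(np.mean(ranks[bounds[i]:bounds[i + 1]]))
                  for i in range(len(clean))]

    m = len(clean) * (len(clean) - 1) // 2
    out = []
    for i in range(len(clean)):
        for j in range(i + 1, len(clean)):
            se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            if se == 0:
                z, p = 0.0, 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / se
                p = 2.0 * sps.norm.sf(abs(z))
            p_adj = min(1.0, p * m) if adjust == "bonferroni" else p
            out.append(DunnPair(i, j, float(z), float(p), float(p_adj)))
    return out


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    rho: Optional[float]   # None when undefined (zero variance)
    p_value: Optional[float]
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value is not None and self.p_value <= ALPHA


def spearman(x: Sequence[float], y: Sequence[float],
             names: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Spearman rank correlation with pairwise deletion of missing values.

    Rho is Pearson's r on average ranks; the p-value uses the
    t-approximation with n-2 degrees of freedom.  Zero variance in either
    vector leaves rho undefined (flagged as ``None``) rather than raising.
    """
    xa = np.asarray([np.nan if v is None else v for v in x], dtype=float)
    ya = np.asarray([np.nan if v is None else v for v in y], dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must be paired (equal length)")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    n = int(xa.size)
    if n < 3:
        raise ValueError(f"Spearman correlation requires n >= 3 pairs; got {n}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        logger.warning("zero variance in %s/%s: rho undefined",
                       names[0], names[1])
        return CorrelationResult(names[0], names[1], None, None, n)
    rho, p = sps.spearmanr(xa, ya)
    return CorrelationResult(names[0], names[1], float(rho), float(p), n)


def correlation_panel(data, targets: Sequence[str],
                      covariates: Sequence[str]) -> list[CorrelationResult]:
    """All target-covariate Spearman correlations from a records table.

    ``data`` is a pandas DataFrame (one row per patient).  Pairs where one
    member is the other are skipped; each pair uses pairwise-complete
    observations, with the n actually used reported.
    """
    out = []
    for t in targets:
        for c in covariates:
            if t == c:
                continue
            out.append(spearman(data[t].to_numpy(), data[c].to_numpy(),
                                names=(t, c)))
    return out


@dataclass(frozen=True)
class GroupComparisonResult:
    """Per-class median (Q1-Q3) summaries with the Kruskal-Wallis test and,
    when significant, Dunn's pairwise follow-up."""

    variable: str
    group_labels: tuple
    group_summaries: tuple   # (median, q1, q3) per group
    group_ns: tuple
    h_statistic: float
    p_value: float
    dunn_pairs: Optional[tuple] = None  # only when p <= alpha


def compare_groups(groups: dict, variable: str,
                   alpha: float = ALPHA) -> GroupComparisonResult:
    """Median/IQR per class plus Kruskal-Wallis; Dunn's test when significant.

    ``groups`` maps class label -> value sequence; missing values are
    dropped per class (count logged).
    """
    labels, cleaned = [], []
    for label, vals in groups.items():
        arr = np.asarray([np.nan if v is None else v for v in vals],
                         dtype=float)
        kept = arr[~np.isnan(arr)]
        if arr.size != kept.size:
            logger.info("%s/%s: dropped %d missing value(s)",
                        variable, label, arr.size - kept.size)
        if kept.size == 0:
            raise ValueError(f"group {label!r} is empty for {variable!r}")
        labels.append(label)
        cleaned.append(kept)
    h, p = kruskal_wallis(cleaned)
    dunn = tuple(dunn_posthoc(cleaned)) if p <= alpha else None
    return GroupComparisonResult(
        variable=variable,
        group_labels=tuple(labels),
        group_summaries=tuple(median_iqr(g) for g in cleaned),
        group_ns=tuple(int(g.size) for g in cleaned),
        h_statistic=h,
        p_value=p,
        dunn_pairs=dunn,
    )
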