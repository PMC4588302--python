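"""Inferential statistics applied to the classifier's predictions.

Fisher's exact test on 2×2 transfer-contingency tables, Pearson correlation
between predictive probabilities and covariates with single-pass
Cook-distance outlier screening, and the Wilcoxon signed-rank test for
paired thickness comparisons.  No multiplicity correction is applied across
modalities; each contrast is reported at its nominal level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.outliers_influence import OLSInfluence

__all__ = [
    "ContingencyTable",
    "ScreenedCorrelation",
    "fisher_exact_2x2",
    "pearson_corr",
    "cooks_distances",
    "cooks_screen",
    "wilcoxon_signed_rank",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 table of true groups (rows) against predicted classes (columns)."""

    counts: np.ndarray
    row_labels: tuple[str, str]
    col_labels: tuple[str, str]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (2, 2):
            raise ValueError("counts must be a 2×2 table")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            counts = counts.astype(float)
            if np.any(counts < 0) or np.any(counts != np.round(counts)):
                raise ValueError("counts must be nonnegative integers")
        object.__setattr__(self, "counts", counts.astype(int))

    @property
    def row_percentages(self) -> np.ndarray:
        """Per-row percentages at one decimal place (rows sum to ~100)."""
        totals = self.counts.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            raise ValueError("row with zero total")
        return np.round(100.0 * self.counts / totals, 1)


@dataclass(frozen=True)
class ScreenedCorrelation:
    """Correlation before and after Cook-distance outlier exclusion."""

    rho_all: float
    p_all: float
    excluded_indices: tuple[int, ...]
    rho_screened: float
    p_screened: float
    cook_threshold: float
    n_all: int
    n_screened: int


def fisher_exact_2x2(table: ContingencyTable | np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2×2 table.

    Uses the probability-mass rule: the p-value sums the hypergeometric
    probabilities of every table with the observed margins whose
    probability does not exceed that of the observed table (within a small
    relative slack for floating-point ties).
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    counts = np.asarray(counts, dtype=int)
    if counts.shape != (2, 2) or np.any(counts < 0):
        raise ValueError("need a 2×2 table of nonnegative integers")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("Fisher test undefined for a zero margin")
    return float(sps.fisher_exact(counts, alternative="two-sided")[1])


def pearson_corr(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation and its two-sided p from the
    t transform with n − 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r = sps.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def cooks_distances(x, y) -> np.ndarray:
    """Cook distances of each point under the simple linear regression of y
    on x (intercept + slope): D_i = r_i^2 h_ii / (p (1 − h_ii)) with p = 2
    and r_i the internally studentized residual."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need equal-length vectors with n >= 4")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return np.asarray(OLSInfluence(fit).cooks_distance[0], dtype=float)


def cooks_screen(x, y, threshold: float = 0.5) -> ScreenedCorrelation:
    """Correlate y with x, then once more after removing high-influence
    points.

    Cook distances are computed on the full-data simple regression; points
    with D_i > threshold are excluded in a single pass (no iteration) and
    the Pearson correlation is recomputed on the remainder.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho_all, p_all = pearson_corr(x, y)
    d = cooks_distances(x, y)
    excluded = tuple(int(i) for i in np.flatnonzero(d > threshold))
    keep = np.setdiff1d(np.arange(x.size), excluded)
    if keep.size < 3:
        raise ValueError("too few points remain after Cook screening")
    if excluded:
        rho_s, p_s = pearson_corr(x[keep], y[keep])
    else:
        rho_s, p_s = rho_all, p_all
    return ScreenedCorrelation(
        rho_all=rho_all,
        p_all=p_all,
        excluded_indices=excluded,
        rho_screened=rho_s,
        p_screened=p_s,
        cook_threshold=float(threshold),
        n_all=int(x.size),
        n_screened=int(keep.size),
    )


def wilcoxon_signed_rank(a, b) -> float:
    """Two-sided Wilcoxon signed-rank p for paired samples.

    Zero differences are dropped (Wilcoxon's original rule) and tied ranks
    averaged.  The exact null distribution is used for up to 25 informative
    pairs; beyond that the normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D vectors")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    has_ties = np.unique(np.abs(d)).size < d.size
    if d.size <= 25 and not has_ties:
        method = "exact"
    else:
        method = "approx"
    res = sps.wilcoxon(
        d, zero_method="wilcox", correction=True, method=method,
        alternative="two-sided",
    )
    return float(res.pvalue)
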