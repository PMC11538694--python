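"""Group-level statistics over coupling tables.

The battery used on session-level endpoints (interbrain r, directed GPDC
summaries, TBR): Friedman tests across repeated conditions/days,
Mann-Whitney U for two-sample contrasts, Holm-Sidak step-down adjustment
for families of comparisons, ordinary least-squares regression of coupling
on cumulative social exposure, and a logistic growth fit that locates the
plateau day of coupling over extended interaction schedules.  Standard
tests delegate to scipy/statsmodels; the Friedman statistic is computed
in-house (mid-rank ties, valid for two columns as well).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    name: str
    statistic: float
    p: float
    n: int
    sided: str = "two-sided"
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p-value {self.p} outside [0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p - 1e-12:
            raise ValueError("adjusted p must be >= raw p")


def friedman(table: np.ndarray) -> TestResult:
    """Friedman rank test on a complete block design (subjects x conditions).

    Rows are blocks (subjects/dyads), columns the repeated conditions
    (e.g. days).  Ties are mid-ranked with the standard tie correction; the
    p-value uses the chi-square approximation with k-1 degrees of freedom.
    Incomplete blocks (NaN) are an error -- no imputation.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValueError("table must be 2-D (subjects x conditions)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    if np.isnan(x).any():
        raise ValueError("incomplete blocks (NaN present); no imputation is performed")
    ranks = stats.rankdata(x, axis=1)  # mid-ranks within each block
    col_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    # tie correction
    tie_term = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        tie_term += np.sum(counts**3 - counts)
    denom = 1.0 - tie_term / (n * k * (k**2 - 1))
    if denom <= 0:
        stat, p = 0.0, 1.0
    else:
        stat = stat / denom
        p = float(stats.chi2.sf(stat, k - 1))
    return TestResult(name="friedman", statistic=float(stat), p=p, n=n)


def mann_whitney(x, y, sided: str = "two-sided") -> TestResult:
    """Mann-Whitney U: exact p when both groups have <= 8 untied values,
    otherwise the tie-corrected normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    exact = max(x.size, y.size) <= 8 and not ties
    method = "exact" if exact else "asymptotic"
    logger.debug("mann_whitney: n=(%d, %d) method=%s", x.size, y.size, method)
    res = stats.mannwhitneyu(x, y, alternative=sided, method=method)
    return TestResult(
        name="mann-whitney-u",
        statistic=float(res.statistic),
        p=float(min(res.pvalue, 1.0)),
        n=int(x.size + y.size),
        sided=sided,
    )


def holm_sidak(p_values) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values (order-preserving, >= raw)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="holm-sidak")[1]


@dataclass
class ExposureFit:
    beta: float  # slope per unit exposure
    sem: float  # standard error of the slope
    p: float  # two-sided t test of slope = 0
    intercept: float
    n: int


def exposure_regression(values, exposure) -> ExposureFit:
    """OLS regression of a coupling endpoint on cumulative social exposure
    (e.g. interaction days)."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(exposure, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("values and exposure must be 1-D and matched")
    if y.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("exposure is constant; slope undefined")
    res = stats.linregress(x, y)
    return ExposureFit(
        beta=float(res.slope),
        sem=float(res.stderr),
        p=float(res.pvalue),
        intercept=float(res.intercept),
        n=y.size,
    )


@dataclass
class GrowthFit:
    """Logistic growth y = L / (1 + exp(-k (t - t0)))."""

    L: float
    k: float
    t0: float
    plateau_day: float | None  # first t with fitted y >= 0.95 L
    converged: bool
    sse: float = float("nan")

    def predict(self, t) -> np.ndarray:
        return self.L / (1.0 + np.exp(-self.k * (np.asarray(t, dtype=float) - self.t0)))


def logistic_growth_fit(days, values) -> GrowthFit:
    """Least-squares logistic growth fit with multi-start initialization.

    Degenerate data (constant values) or non-convergence from every start
    returns a flagged (converged=False) result with no plateau day.
    """
    t = np.asarray(days, dtype=float)
    y = np.asarray(values, dtype=float)
    if np.unique(t).size < 5:
        raise ValueError("need at least 5 distinct days")
    if np.ptp(y) == 0:
        return GrowthFit(L=float(y[0]), k=0.0, t0=float(t.mean()), plateau_day=None, converged=False)

    def model(tt, L, k, t0):
        return L / (1.0 + np.exp(-k * (tt - t0)))

    best = None
    l0 = max(y.max(), 1e-6)
    for k0 in (0.3, 0.7, 1.2, 2.0):
        for t0 in np.quantile(t, (0.25, 0.5, 0.75)):
            try:
                popt, _ = optimize.curve_fit(
                    model,
                    t,
                    y,
                    p0=(l0, k0, t0),
                    bounds=((1e-9, 1e-6, t.min() - 20), (np.inf, np.inf, t.max() + 20)),
                    maxfev=5000,
                )
            except (RuntimeError, ValueError):
                continue
            sse = float(np.sum((model(t, *popt) - y) ** 2))
            if best is None or sse < best[1]:
                best = (popt, sse)
    if best is None:
        return GrowthFit(L=float("nan"), k=float("nan"), t0=float("nan"), plateau_day=None, converged=False)
    (L, k, t0), sse = best
    plateau = t0 + np.log(19.0) / k  # y(t) = 0.95 L
    return GrowthFit(L=float(L), k=float(k), t0=float(t0), plateau_day=float(plateau), converged=True, sse=sse)
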