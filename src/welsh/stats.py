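"""Validation statistics for questionnaire-vs-field-test agreement studies.

This module collects every statistic the validation pipeline needs behind a
small, typed surface: Wilson score intervals for binomial proportions,
Spearman rank correlation (average ranks for ties, two-sided p via the
t approximation on n-2 degrees of freedom), the Fisher r-to-z two-sample
comparison of correlations, Benjamini-Hochberg FDR adjustment, Pearson
chi-square independence tests, Welch two-sample t tests, ordinary
least-squares calibration lines, and Fisher-z sample-size planning for a
target correlation.

Standard computations are delegated to scipy/statsmodels; the Fisher-z
comparison and sample-size formula, which have no library equivalent, are
implemented directly:

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))
    n = ceil( ((z_{1-alpha/2} + z_{power}) / atanh(r))^2 + 3 )
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint


class StatError(ValueError):
    """Invalid input to a statistical routine."""


@dataclass(frozen=True)
class ProportionCI:
    """Binomial proportion with a Wilson score confidence interval."""

    k: int
    n: int
    level: float
    low: float
    high: float

    @property
    def proportion(self) -> float:
        return self.k / self.n


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation with raw and (optionally) adjusted p values."""

    rho: float
    n: int
    p_raw: float
    p_adj: Optional[float] = None

    def with_adjusted(self, p_adj: float) -> "CorrelationResult":
        return replace(self, p_adj=float(p_adj))


@dataclass(frozen=True)
class ZComparison:
    """Fisher r-to-z comparison of two independent correlations."""

    r1: float
    n1: int
    r2: float
    n2: int
    z_stat: float
    p: float
    p_adj: Optional[float] = None

    def with_adjusted(self, p_adj: float) -> "ZComparison":
        return replace(self, p_adj=float(p_adj))


@dataclass(frozen=True)
class FitLine:
    """Ordinary least-squares calibration line (response per unit predictor)."""

    slope: float
    intercept: float
    n: int


def wilson_ci(k: int, n: int, level: float = 0.95) -> ProportionCI:
    """Wilson score interval for ``k`` successes in ``n`` trials.

    The Wilson interval inverts the normal-approximation score test and,
    unlike the Wald interval, always contains the sample proportion and has
    sensible behaviour at k = 0 and k = n (lower bound exactly 0, upper
    exactly 1).  No continuity correction is applied.
    """
    if n < 1:
        raise StatError("undefined interval: n must be >= 1")
    if not 0 <= k <= n:
        raise StatError(f"k={k} outside [0, n={n}]")
    if not 0 < level < 1:
        raise StatError("confidence level must be in (0, 1)")
    low, high = proportion_confint(k, n, alpha=1 - level, method="wilson")
    # the Wilson bounds are exactly 0 at k=0 and 1 at k=n; snap floating noise
    low = 0.0 if k == 0 else float(np.clip(low, 0, 1))
    high = 1.0 if k == n else float(np.clip(high, 0, 1))
    return ProportionCI(k, n, level, low, high)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with tie-aware average ranks.

    Equivalent to the Pearson correlation of mid-ranks; the two-sided p
    value uses the t approximation with n-2 degrees of freedom, standard
    for the sample sizes of a field validation study.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatError("x and y must be equal-length 1-d samples")
    n = x.size
    if n < 4:
        raise StatError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatError("correlation undefined for a constant sample")
    res = sps.spearmanr(x, y)
    return CorrelationResult(rho=float(res.statistic), n=n, p_raw=float(res.pvalue))


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> ZComparison:
    """Compare two independent correlations on the Fisher z scale.

    atanh(r) is approximately normal with variance 1/(n-3), so the
    standardized difference is referred to a standard normal (two-sided).
    Antisymmetric in the two groups: swapping them negates z.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if not abs(r) < 1:
            raise StatError(f"|r|={abs(r)} must be < 1 for the z transform")
        if n <= 3:
            raise StatError("each group needs n > 3")
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (math.atanh(r1) - math.atanh(r2)) / se
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return ZComparison(r1, n1, r2, n2, z_stat=z, p=min(p, 1.0))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up FDR adjustment, order-preserving.

    Sort ascending, set q_i = p_(i) * m / i, enforce monotonicity from the
    largest down, cap at 1, and return in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise StatError("p values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return [float(q) for q in adj]


def chi_square_independence(table: Sequence[Sequence[int]]) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a contingency table.

    Returns ``(statistic, df, p)``; expected counts come from the margins
    and no continuity correction is applied.
    """
    obs = np.asarray(table)
    if obs.ndim != 2:
        raise StatError("table must be two-dimensional")
    if np.any(obs < 0) or not np.issubdtype(obs.dtype, np.integer):
        raise StatError("table must contain non-negative integer counts")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise StatError("every row and column margin must be positive")
    res = sps.chi2_contingency(obs, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def two_sample_t(
    x: Sequence[float], y: Sequence[float], equal_var: bool = False
) -> tuple[float, float, float]:
    """Two-sample t test, Welch form by default.

    Returns ``(t, df, p)`` with Welch-Satterthwaite degrees of freedom
    (or pooled df when ``equal_var=True``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise StatError("each sample needs at least 2 observations")
    if np.var(x) == 0 and np.var(y) == 0:
        raise StatError("degenerate samples: both variances are zero")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def fit_line(x: Sequence[float], y: Sequence[float]) -> FitLine:
    """Ordinary least-squares line ``y = slope * x + intercept``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise StatError("need equal-length 1-d samples with n >= 2")
    if np.ptp(x) == 0:
        raise StatError("undefined fit: predictor has zero variance")
    res = sps.linregress(x, y)
    return FitLine(slope=float(res.slope), intercept=float(res.intercept), n=x.size)


def sample_size_for_correlation(r: float, alpha: float = 0.05, power: float = 0.80) -> int:
    """Minimal n to detect correlation ``r`` at two-sided ``alpha`` with ``power``.

    Uses the Fisher-z normal approximation:
    ``n = ceil(((z_{1-alpha/2} + z_{power}) / atanh(r))**2 + 3)``.
    """
    if not 0 < r < 1:
        raise StatError("target correlation must be in (0, 1)")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise StatError("alpha and power must be in (0, 1)")
    z_a = float(sps.norm.ppf(1 - alpha / 2))
    z_b = float(sps.norm.ppf(power))
    return math.ceil(((z_a + z_b) / math.atanh(r)) ** 2 + 3)
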