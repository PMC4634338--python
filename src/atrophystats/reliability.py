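"""Reliability statistics for atrophy measurement techniques.

Three aspects of a technique's plausibility and consistency are
quantified here:

* **short-interval change** — mean standardized change over scan pairs
  where true change should be negligible (same-day duplicate scans and
  the two-week repeat), with a one-sample t-test against zero;
* **symmetry** — agreement between a forward change measure A->B and
  the negated backward measure B->A of the same pair;
* **transitivity** — agreement between the direct change A->C and the
  chained sum A->B plus B->C.

All change values are standardized to a ``100*ln`` scale, which
approximates percent change while being multiplicatively symmetric.
Symmetry/transitivity differences are summarized by the median with an
exact binomial order-statistic 95% confidence interval, because ratios
with small denominators produce heavy-tailed outliers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: Relative threshold below which a ratio denominator is treated as zero.
DENOM_TOL = 1e-12


@dataclass(frozen=True)
class ShortIntervalSummary:
    """Mean short-interval change with t-test against zero."""

    group: str
    structure: str
    interval: str  # "same_day" | "two_week"
    mean_change: float
    ci95: tuple[float, float]
    t_stat: float
    p_value: float
    n: int


@dataclass(frozen=True)
class ConsistencySummary:
    """Median symmetry or transitivity difference with binomial 95% CI."""

    group: str
    structure: str
    metric: str  # "symmetry" | "transitivity"
    median: float
    ci95: tuple[float, float]
    n: int
    n_undefined: int = 0


def c_indirect(v_baseline: float, v_repeat: float):
    """Standardized indirect change: 100*ln(V_r / V_b).

    Both volumes must be positive.  Antisymmetric in its arguments.
    """
    v_b = np.asarray(v_baseline, dtype=float)
    v_r = np.asarray(v_repeat, dtype=float)
    if np.any(v_b <= 0) or np.any(v_r <= 0):
        raise ValueError("volumes must be positive")
    return 100.0 * np.log(v_r / v_b)


def c_direct(v_baseline: float, delta_v: float):
    """Standardized direct change: 100*ln((V_b + dV) / V_b)."""
    v_b = np.asarray(v_baseline, dtype=float)
    dv = np.asarray(delta_v, dtype=float)
    if np.any(v_b <= 0):
        raise ValueError("baseline volume must be positive")
    if np.any(v_b + dv <= 0):
        raise ValueError("V_b + dV must be positive (implausible change)")
    return 100.0 * np.log((v_b + dv) / v_b)


def c_direct_percent(delta_v_percent: float):
    """Standardized direct change from a percent change: 100*ln(1 + dV%/100)."""
    dvp = np.asarray(delta_v_percent, dtype=float)
    if np.any(dvp <= -100.0):
        raise ValueError("percent change must exceed -100")
    return 100.0 * np.log1p(dvp / 100.0)


def short_interval_test(
    changes, group: str = "", structure: str = "", interval: str = "same_day"
) -> ShortIntervalSummary:
    """One-sample two-tailed t-test that mean standardized change is zero."""
    x = np.asarray(changes, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two changes for a t-test")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    n = x.size
    if sd == 0.0:
        # Degenerate: all values identical; CI collapses to the mean.
        t_stat = math.inf if mean != 0 else 0.0
        p = 0.0 if mean != 0 else 1.0
        ci = (mean, mean)
    else:
        res = stats.ttest_1samp(x, 0.0)
        t_stat, p = float(res.statistic), float(res.pvalue)
        half = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
        ci = (mean - half, mean + half)
    return ShortIntervalSummary(group, structure, interval, mean, ci, t_stat, p, n)


def _ratio_difference(numerator, denominator):
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    scale = np.maximum(np.abs(num), np.abs(den))
    undefined = np.abs(den) <= DENOM_TOL * np.maximum(scale, 1.0)
    out = np.full(np.broadcast(num, den).shape, np.nan)
    ok = ~undefined
    out[ok] = 100.0 * num[ok] / den[ok]
    if np.ndim(numerator) == 0 and np.ndim(denominator) == 0:
        if undefined:
            raise ZeroDivisionError("ratio denominator is (numerically) zero")
        return float(out)
    return out


def symmetry_difference(forward, neg_backward):
    """Symmetry difference d_sym in percent.

    ``forward`` is the direct change baseline->repeat; ``neg_backward``
    the *negated* backward change repeat->baseline (so both should agree
    for a symmetric technique).  Returns
    100*(fwd - neg_bwd) / (0.5*(fwd + neg_bwd)); element-wise NaN (or a
    ZeroDivisionError for scalars) where the signed average vanishes.
    """
    fwd = np.asarray(forward, dtype=float)
    nbw = np.asarray(neg_backward, dtype=float)
    return _ratio_difference(fwd - nbw, 0.5 * (fwd + nbw))


def transitivity_difference(c_b_r12, c_b_r6, c_r6_r12):
    """Transitivity difference d_trans in percent.

    Compares the direct change over a long interval with the sum of the
    two chained changes covering it:
    100*(c_b_r12 - (c_b_r6 + c_r6_r12)) /
    (0.5*(c_b_r12 + c_b_r6 + c_r6_r12)).
    """
    a = np.asarray(c_b_r12, dtype=float)
    b = np.asarray(c_b_r6, dtype=float)
    c = np.asarray(c_r6_r12, dtype=float)
    return _ratio_difference(a - (b + c), 0.5 * (a + b + c))


def median_ci_exact(values, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial order-statistic confidence interval for the median.

    Uses the distribution-free interval (x_(l), x_(u)) with l, u chosen
    from the Binomial(n, 1/2) distribution so the coverage is at least
    ``level``.  For n == 1 the interval degenerates to the single value.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("no values")
    if n == 1:
        logger.warning("median CI from a single value is degenerate")
        return (x[0], x[0])
    alpha = 1.0 - level
    # Largest l with P(X < l) <= alpha/2, X ~ Bin(n, 0.5); u symmetric.
    lo = int(stats.binom.ppf(alpha / 2.0, n, 0.5))
    if stats.binom.cdf(lo, n, 0.5) > alpha / 2.0:
        lo = max(lo - 1, 0)
    hi = n - 1 - lo
    return (float(x[lo]), float(x[hi]))


def median_with_ci(
    values, group: str = "", structure: str = "", metric: str = "symmetry"
) -> ConsistencySummary:
    """Sample median with exact binomial 95% CI; NaNs counted as undefined."""
    x = np.asarray(values, dtype=float)
    undefined = int(np.sum(~np.isfinite(x)))
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no defined values to summarize")
    med = float(np.median(x))
    ci = median_ci_exact(x)
    return ConsistencySummary(group, structure, metric, med, ci, int(x.size), undefined)
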