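"""Statistical protocol for descriptor samples.

Normality is screened two ways before any mean comparison: the Shapiro-Wilk
test (well-powered for the small samples, n < 50, that per-cluster descriptor
tables produce) and the coefficient of determination of a normal probability
plot built on Filliben's order-statistic probability estimates.  Normality is
considered supported only when the Shapiro-Wilk p-value exceeds 0.05 AND the
probability-plot R^2 exceeds 0.9.  Model pairs are then compared with
Welch's unequal-variance t-test, with degrees of freedom from the
Welch-Satterthwaite approximation and two-sided p-values at the 0.05 level.

The Shapiro-Wilk statistic

    W = (sum_i a_i x_(i))^2 / sum_i (x_i - xbar)^2

is computed with Royston's AS R94 approximation of the coefficients a_i and
of the null distribution of W, the standard computational route for
3 <= n <= 5000 (exact for n = 3, where a_1 = sqrt(1/2)).  No multiple-testing
correction is applied by default (per-pair 0.05 thresholds); a Holm step-down
helper is provided for callers who want one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "Sample",
    "NormalityResult",
    "WelchResult",
    "BoxSummary",
    "DegenerateSampleError",
    "shapiro_wilk",
    "filliben_quantiles",
    "probability_plot_r2",
    "normality_screen",
    "welch_t",
    "summarize_distribution",
    "holm_bonferroni",
]

ALPHA = 0.05
R2_THRESHOLD = 0.9


class DegenerateSampleError(ValueError):
    """Sample has no usable variance for the requested test."""


@dataclass(frozen=True)
class Sample:
    """Labeled sample of per-frame descriptor values."""

    values: np.ndarray
    model: str = ""
    size: int = 0
    space: str = ""
    measure: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sample values must be finite")


def _values(x) -> np.ndarray:
    if isinstance(x, Sample):
        return x.values
    v = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("sample values must be finite")
    return v


@dataclass(frozen=True)
class NormalityResult:
    W: float
    p_value: float
    r_squared: float | None = None
    verdict: str | None = None


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p_value: float
    significant: bool


@dataclass(frozen=True)
class BoxSummary:
    mean: float
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def _poly(coeffs, x: float) -> float:
    """coeffs[0] + coeffs[1] x + coeffs[2] x^2 + ..."""
    return float(sum(c * x**i for i, c in enumerate(coeffs)))


def _royston_coefficients(n: int) -> np.ndarray:
    """Shapiro-Wilk coefficients a_1..a_n per Royston's AS R94."""
    if n == 3:
        s = np.sqrt(0.5)
        return np.array([-s, 0.0, s])
    m = _sps.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    ssq = float(np.sum(m * m))
    rsn = 1.0 / np.sqrt(n)
    c = m / np.sqrt(ssq)
    a_n = c[-1] + _poly([0.0, 0.221157, -0.147981, -2.071190, 4.434685, -2.706056], rsn)
    a = np.empty(n)
    if n > 5:
        a_n1 = c[-2] + _poly([0.0, 0.042981, -0.293762, -1.752461, 5.682633, -3.582633], rsn)
        phi = (ssq - 2 * m[-1] ** 2 - 2 * m[-2] ** 2) / (1 - 2 * a_n**2 - 2 * a_n1**2)
        a[-1], a[-2] = a_n, a_n1
        a[0], a[1] = -a_n, -a_n1
        a[2 : n - 2] = m[2 : n - 2] / np.sqrt(phi)
    else:
        phi = (ssq - 2 * m[-1] ** 2) / (1 - 2 * a_n**2)
        a[-1] = a_n
        a[0] = -a_n
        a[1 : n - 1] = m[1 : n - 1] / np.sqrt(phi)
    return a


def _royston_pvalue(W: float, n: int) -> float:
    if n == 3:
        p = 6.0 / np.pi * (np.arcsin(np.sqrt(W)) - np.arcsin(np.sqrt(0.75)))
        return float(min(max(p, 0.0), 1.0))
    if n <= 11:
        gamma = _poly([-2.273, 0.459], n)
        w_t = -np.log(gamma - np.log1p(-W))
        mu = _poly([0.5440, -0.39978, 0.025054, -0.0006714], n)
        sigma = np.exp(_poly([1.3822, -0.77857, 0.062767, -0.0020322], n))
    else:
        ln_n = np.log(n)
        w_t = np.log1p(-W)
        mu = _poly([-1.5861, -0.31082, -0.083751, 0.0038915], ln_n)
        sigma = np.exp(_poly([-0.4803, -0.082676, 0.0030302], ln_n))
    return float(_sps.norm.sf((w_t - mu) / sigma))


def shapiro_wilk(sample) -> NormalityResult:
    """Shapiro-Wilk W and p-value (Royston AS R94), for 3 <= n <= 5000."""
    x = np.sort(_values(sample))
    n = x.size
    if not 3 <= n <= 5000:
        raise ValueError(f"Shapiro-Wilk supports 3 <= n <= 5000, got n={n}")
    sse = float(np.sum((x - x.mean()) ** 2))
    if sse <= 0:
        raise DegenerateSampleError("sample has zero variance")
    a = _royston_coefficients(n)
    W = float(np.dot(a, x) ** 2 / sse)
    W = min(W, 1.0)
    return NormalityResult(W=W, p_value=_royston_pvalue(W, n))


def filliben_quantiles(n: int) -> np.ndarray:
    """Filliben order-statistic probability estimates p_1..p_n (ascending).

    p_1 = 1 - 0.5^(1/n), p_n = 0.5^(1/n), interior (i - 0.3175)/(n + 0.365).
    Strictly increasing and symmetric: p_i + p_{n+1-i} = 1.
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    p = (np.arange(1, n + 1) - 0.3175) / (n + 0.365)
    p[0] = 1.0 - 0.5 ** (1.0 / n)
    p[-1] = 0.5 ** (1.0 / n)
    return p


def probability_plot_r2(sample) -> float:
    """R^2 of the ordered sample against normal quantiles at Filliben
    probabilities; 1 means a perfectly linear (hence normal-consistent) plot."""
    x = np.sort(_values(sample))
    if x.size < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("sample has zero variance")
    q = _sps.norm.ppf(filliben_quantiles(x.size))
    r = np.corrcoef(q, x)[0, 1]
    return float(r * r)


def normality_screen(sample) -> NormalityResult:
    """Combined screen: normality is supported iff the Shapiro-Wilk p-value
    exceeds 0.05 and the probability-plot R^2 exceeds 0.9."""
    sw = shapiro_wilk(sample)
    r2 = probability_plot_r2(sample)
    verdict = "normal-supported" if (sw.p_value > ALPHA and r2 > R2_THRESHOLD) else "rejected"
    return NormalityResult(W=sw.W, p_value=sw.p_value, r_squared=r2, verdict=verdict)


def welch_t(sample_a, sample_b) -> WelchResult:
    """Welch's unequal-variance t-test, two-sided.

    t = (xbar_1 - xbar_2) / sqrt(s1^2/n1 + s2^2/n2), with degrees of freedom
    from the Welch-Satterthwaite approximation.  Identical samples give
    t = 0, p = 1; two zero-variance samples are degenerate.
    """
    a, b = _values(sample_a), _values(sample_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need n >= 2")
    va = a.var(ddof=1) / a.size
    vb = b.var(ddof=1) / b.size
    if va + vb == 0:
        raise DegenerateSampleError("both samples have zero variance")
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    p = 2.0 * _sps.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p_value=float(p), significant=bool(p < ALPHA))


def summarize_distribution(sample) -> BoxSummary:
    """Box-plot summary: quartiles by linear interpolation between closest
    ranks, whiskers at the most extreme values within 1.5*IQR of the box,
    and everything beyond flagged as an outlier."""
    x = np.sort(_values(sample))
    if x.size < 1:
        raise ValueError("need at least 1 value")
    q1, med, q3 = np.percentile(x, [25, 50, 75], method="linear")
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = tuple(float(v) for v in x[(x < lo_fence) | (x > hi_fence)])
    return BoxSummary(
        mean=float(x.mean()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
    )


def holm_bonferroni(p_values, alpha: float = ALPHA) -> np.ndarray:
    """Holm step-down rejection flags (optional; off by default elsewhere)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject
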