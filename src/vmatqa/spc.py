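"""Statistical process control and process capability for QA pass-rate series.

The quality characteristic is the percent gamma pass rate of successive QA
measurements (one value per plan, in acquisition order).  Individuals (x)
and moving-range (mR) charts give the tolerance limit:

    mR_bar = mean |x_i - x_{i-1}|          (i = 2..n)
    CL     = x_bar
    LCL    = x_bar - 2.66 * mR_bar

computed on the first in-control ``baseline_n`` points (20 by default);
since the pass rate cannot exceed 100%, only the lower limit is clinically
meaningful.  Action limits come from process capability analysis:

    dA  = beta * sqrt((x_bar - T)^2 + sigma^2),   LAL = T - dA/2,  UAL = 100

with process target T = 100%, beta = 4, and sigma the sample standard
deviation.  The capability index against the action limits is

    C_pk = min(C_pl, C_pu)
    C_pl = (x_bar - LAL) / (6 (1 - P_x) s),  C_pu = (UAL - x_bar) / (6 P_x s)

where P_x is the probability of x <= x_bar, estimated by default as the
empirical proportion (a normal-theory value of 0.5 is selectable).  For a
pass-rate series the lower side governs, so C_pk = C_pl.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import stats

__all__ = [
    "QaSeries",
    "ControlChart",
    "ActionLimits",
    "CapabilityResult",
    "CohortComparison",
    "moving_range",
    "control_limits",
    "action_limits",
    "lal_from_delta_a",
    "cpk",
    "remove_out_of_control",
    "compare_cohorts",
    "iqr",
    "flag_rate",
    "round_half_away",
]

SPC_CONSTANT = 2.66  # individuals-chart factor converting mR_bar to 3-sigma


@dataclass
class QaSeries:
    """Ordered percent-gamma pass rates of one QA cohort."""

    values: np.ndarray
    labels: dict = field(default_factory=dict)  # detector, procedure, criteria...

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("a QA series must be one-dimensional")
        if np.any((self.values < 0) | (self.values > 100)):
            raise ValueError("percent gamma values must lie in [0, 100]")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class ControlChart:
    """Individuals-chart summary: CL, mR_bar, LCL and flagged points."""

    cl: float
    mr_bar: float
    lcl: float
    baseline_n: int
    flagged: np.ndarray  # indices with x_i < LCL (baseline and beyond)
    moving_ranges: np.ndarray


@dataclass
class ActionLimits:
    delta_a: float
    lal: float
    ual: float = 100.0
    target: float = 100.0
    beta: float = 4.0
    sigma: float = 0.0


@dataclass
class CapabilityResult:
    cpk: float
    cpl: float
    cpu: float
    x_bar: float
    s: float
    p_x: float
    lal: float
    ual: float
    n_used: int
    px_method: str = "empirical"


@dataclass
class CohortComparison:
    test: str  # "paired_t" or "wilcoxon"
    statistic: float
    p_value: float
    significant: bool
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    iqr_a: float
    iqr_b: float
    normal_a: bool
    normal_b: bool
    alpha: float = 0.05


def _series(x) -> np.ndarray:
    if isinstance(x, QaSeries):
        return x.values
    return np.asarray(x, dtype=float)


# ---------------------------------------------------------------------------
# control charts
# ---------------------------------------------------------------------------

def moving_range(series) -> float:
    """Average moving range: mean of |x_i - x_{i-1}| (divisor n - 1)."""
    x = _series(series)
    if x.size < 2:
        raise ValueError("moving range needs at least two points")
    return float(np.abs(np.diff(x)).mean())


def control_limits(series, baseline_n: int = 20) -> ControlChart:
    """CL and LCL from the first ``baseline_n`` points; flag x_i < LCL.

    Points of the whole series (baseline and after) are flagged against the
    baseline limits, matching how an individuals chart monitors new cases.
    """
    x = _series(series)
    if baseline_n < 2:
        raise ValueError("baseline must contain at least two points")
    if baseline_n > x.size:
        raise ValueError("baseline size exceeds the series length")
    base = x[:baseline_n]
    mr_bar = moving_range(base)
    cl = float(base.mean())
    lcl = cl - SPC_CONSTANT * mr_bar
    flagged = np.nonzero(x < lcl)[0]
    return ControlChart(
        cl=cl,
        mr_bar=mr_bar,
        lcl=lcl,
        baseline_n=baseline_n,
        flagged=flagged,
        moving_ranges=np.abs(np.diff(x)),
    )


# ---------------------------------------------------------------------------
# action limits and capability
# ---------------------------------------------------------------------------

def action_limits(series, beta: float = 4.0, target: float = 100.0) -> ActionLimits:
    """Action-limit span dA = beta * sqrt((x_bar - T)^2 + sigma^2), LAL = T - dA/2.

    sigma is the sample standard deviation (ddof = 1) of the series.
    """
    x = _series(series)
    if x.size < 2:
        raise ValueError("action limits need at least two points")
    sigma = float(x.std(ddof=1))
    delta_a = beta * float(np.sqrt((x.mean() - target) ** 2 + sigma**2))
    return ActionLimits(
        delta_a=delta_a,
        lal=lal_from_delta_a(delta_a, target),
        ual=100.0,
        target=target,
        beta=beta,
        sigma=sigma,
    )


def lal_from_delta_a(delta_a: float, target: float = 100.0) -> float:
    """Lower action limit from the action-limit span: LAL = T - dA/2."""
    return target - delta_a / 2.0


def cpk(
    series,
    lal: float,
    ual: float = 100.0,
    px_method: str = "empirical",
) -> CapabilityResult:
    """Process capability C_pk = min(C_pl, C_pu) against the action limits.

    P_x is the probability of x <= x_bar: the empirical proportion by
    default, or 0.5 under the normal-theory assumption
    (``px_method="normal"``).
    """
    x = _series(series)
    if x.size < 2:
        raise ValueError("capability needs at least two points")
    x_bar = float(x.mean())
    s = float(x.std(ddof=1))
    if s == 0:
        raise ValueError("capability undefined: zero sample standard deviation")
    if px_method == "empirical":
        p_x = float(np.mean(x <= x_bar))
    elif px_method == "normal":
        p_x = 0.5
    else:
        raise ValueError(f"unknown P_x method: {px_method!r}")
    # degenerate P_x (all points on one side) would zero a denominator
    p_x = min(max(p_x, 1.0 / (2 * x.size)), 1.0 - 1.0 / (2 * x.size))
    cpl = (x_bar - lal) / (6.0 * (1.0 - p_x) * s)
    cpu = (ual - x_bar) / (6.0 * p_x * s)
    return CapabilityResult(
        cpk=min(cpl, cpu),
        cpl=cpl,
        cpu=cpu,
        x_bar=x_bar,
        s=s,
        p_x=p_x,
        lal=lal,
        ual=ual,
        n_used=x.size,
        px_method=px_method,
    )


def remove_out_of_control(series, lcl: float):
    """Drop points below the tolerance limit (single pass, no iteration)."""
    x = _series(series)
    return x[x >= lcl]


# ---------------------------------------------------------------------------
# cohort comparison
# ---------------------------------------------------------------------------

def iqr(values, method: str = "linear") -> float:
    """Inter-quartile range Q3 - Q1.

    "linear": quartiles by linear interpolation of order statistics
    (numpy's default, Hyndman-Fan type 7).  "tukey": median-of-halves
    quartiles (gives 4.0 for 1..8 where type 7 gives 3.5).
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size < 2:
        raise ValueError("IQR needs at least two points")
    if method == "linear":
        q1, q3 = np.percentile(x, [25, 75])
    elif method == "tukey":
        half = x.size // 2
        lower = x[:half]
        upper = x[half:] if x.size % 2 == 0 else x[half + 1:]
        q1, q3 = np.median(lower), np.median(upper)
    else:
        raise ValueError(f"unknown quartile method: {method!r}")
    return float(q3 - q1)


def compare_cohorts(a, b, alpha: float = 0.05, quartile_method: str = "linear") -> CohortComparison:
    """Paired comparison of two QA cohorts.

    Normality of each cohort is checked with the Shapiro-Wilk test and a
    Kolmogorov-Smirnov test against the fitted normal; if both cohorts look
    normal a paired t-test is used, otherwise the Wilcoxon signed-rank
    test.  Two-tailed, significance at ``alpha``.
    """
    xa, xb = _series(a), _series(b)
    if xa.size != xb.size:
        raise ValueError("paired cohorts must have equal length")
    if xa.size < 3:
        raise ValueError("cohort comparison needs at least three pairs")

    def _normal(x: np.ndarray) -> bool:
        if np.ptp(x) == 0:
            return False
        p_sw = stats.shapiro(x).pvalue
        p_ks = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).pvalue
        return bool(p_sw > alpha and p_ks > alpha)

    na, nb = _normal(xa), _normal(xb)
    diff = xa - xb
    if np.ptp(diff) == 0 and diff[0] == 0:
        # identical cohorts: zero differences, nothing to detect
        test, statistic, p = ("paired_t", 0.0, 1.0)
    elif na and nb:
        res = stats.ttest_rel(xa, xb)
        test, statistic, p = "paired_t", float(res.statistic), float(res.pvalue)
    else:
        res = stats.wilcoxon(xa, xb, zero_method="wilcox")
        test, statistic, p = "wilcoxon", float(res.statistic), float(res.pvalue)

    return CohortComparison(
        test=test,
        statistic=statistic,
        p_value=p,
        significant=bool(p < alpha),
        mean_a=float(xa.mean()),
        mean_b=float(xb.mean()),
        median_a=float(np.median(xa)),
        median_b=float(np.median(xb)),
        iqr_a=iqr(xa, quartile_method),
        iqr_b=iqr(xb, quartile_method),
        normal_a=na,
        normal_b=nb,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# report helpers
# ---------------------------------------------------------------------------

def flag_rate(n_flagged: int, n_total: int) -> float:
    """Percent of cases below the tolerance limit."""
    if n_total <= 0:
        raise ValueError("total case count must be positive")
    return 100.0 * n_flagged / n_total


def round_half_away(value: float, ndigits: int = 2) -> float:
    """Round half away from zero (table-style rounding), e.g. 88.765 -> 88.77."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
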