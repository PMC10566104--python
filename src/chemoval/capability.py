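"""Six-sigma process capability: descriptive statistics, X-bar/R (or
individuals/moving-range) control charts, and Cp/Cpk vs Pp/Ppk indices.

Conventions follow the standard "sixpack" report: the short-term
(within-subgroup) sigma is estimated as R-bar/d2 from subgroup ranges and
feeds Cp/Cpk, while the overall sample standard deviation feeds Pp/Ppk.
A process is called capable when Cpk >= 1.33 (the 4-sigma criterion); a
negative Cpk means the process mean has crossed a specification limit.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

# Shewhart chart constants, subgroup sizes 2..10 (d2, A2, D3, D4).
_CHART_CONSTANTS = {
    2: (1.128, 1.880, 0.0, 3.267),
    3: (1.693, 1.023, 0.0, 2.574),
    4: (2.059, 0.729, 0.0, 2.282),
    5: (2.326, 0.577, 0.0, 2.114),
    6: (2.534, 0.483, 0.0, 2.004),
    7: (2.704, 0.419, 0.076, 1.924),
    8: (2.847, 0.373, 0.136, 1.864),
    9: (2.970, 0.337, 0.184, 1.816),
    10: (3.078, 0.308, 0.223, 1.777),
}
#: d2 for a moving range of 2 (individuals chart)
_D2_MR = 1.128


class DegenerateProcessWarning(UserWarning):
    """All subgroup ranges are zero; the within-sigma estimate is 0."""


@dataclass
class CapabilitySeries:
    """Subgrouped process measurements with specification limits.

    ``subgroup_size`` = 1 means individual determinations (moving-range
    chart).  ``lsl`` may be None for a one-sided (upper-limit) specification,
    e.g. an impurity limited as "not more than" a ceiling.
    """

    values: np.ndarray
    subgroup_size: int = 1
    lsl: float | None = None
    usl: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 2:
            raise ValueError("need a 1-D series of at least 2 values")
        if self.subgroup_size < 1:
            raise ValueError("subgroup_size must be >= 1")
        if len(self.values) % self.subgroup_size:
            raise ValueError("series length must be a multiple of subgroup_size")
        if self.lsl is None and self.usl is None:
            raise ValueError("at least one specification limit is required")
        if self.lsl is not None and self.usl is not None and not self.lsl < self.usl:
            raise ValueError("require lsl < usl")

    @property
    def subgroups(self) -> np.ndarray:
        return self.values.reshape(-1, self.subgroup_size)


@dataclass(frozen=True)
class DescriptiveStats:
    count: int
    total: float
    mean: float
    se: float
    median: float
    mode: float
    sd: float
    variance: float
    kurtosis: float
    skewness: float
    value_range: float
    minimum: float
    maximum: float

    def to_dict(self) -> dict:
        return {
            "Count": self.count, "Sum": self.total, "Mean": self.mean,
            "Standard Error": self.se, "Median": self.median, "Mode": self.mode,
            "Standard Deviation": self.sd, "Variance": self.variance,
            "Kurtosis": self.kurtosis, "Skewness": self.skewness,
            "Range": self.value_range, "Minimum": self.minimum,
            "Maximum": self.maximum,
        }


def descriptive_stats(values, decimals: int | None = None) -> DescriptiveStats:
    """Spreadsheet-style descriptive summary of a measurement series.

    Sample (n-1) SD/variance, SE = SD/sqrt(n), adjusted Fisher-Pearson
    skewness, excess kurtosis (both bias-corrected).  The mode of continuous
    data is the most frequent value after rounding to ``decimals`` (default:
    the largest number of decimals present in the data, so already-rounded
    assay values are used as printed); ties go to the smallest value.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need a 1-D series of at least 2 values")
    if decimals is None:
        decimals = _inferred_decimals(v)
    rounded = np.round(v, decimals)
    counts = Counter(rounded.tolist())
    top = max(counts.values())
    mode = min(val for val, c in counts.items() if c == top)
    sd = float(v.std(ddof=1))
    n = len(v)
    return DescriptiveStats(
        count=n, total=float(v.sum()), mean=float(v.mean()),
        se=sd / np.sqrt(n), median=float(np.median(v)), mode=float(mode),
        sd=sd, variance=sd ** 2,
        kurtosis=float(stats.kurtosis(v, fisher=True, bias=False)),
        skewness=float(stats.skew(v, bias=False)),
        value_range=float(np.ptp(v)), minimum=float(v.min()),
        maximum=float(v.max()))


def _inferred_decimals(v: np.ndarray, cap: int = 6) -> int:
    for d in range(cap + 1):
        if np.allclose(v, np.round(v, d), rtol=0.0, atol=1e-12):
            return d
    return cap


@dataclass(frozen=True)
class CapabilityIndices:
    cp: float | None
    cpk: float


def cp_cpk(mean: float, sigma: float, lsl: float | None = None,
           usl: float | None = None) -> CapabilityIndices:
    """Capability indices for a given sigma.

    Cp = (USL-LSL)/6sigma (None for one-sided specs); Cpk is the worse of
    (mean-LSL)/3sigma and (USL-mean)/3sigma, using whichever limits exist.
    Cpk may be negative when the mean lies beyond a limit, and Cpk <= Cp
    always, with equality only when the mean sits at the limits' midpoint.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if lsl is None and usl is None:
        raise ValueError("at least one specification limit is required")
    sides = []
    if lsl is not None:
        sides.append((mean - lsl) / (3.0 * sigma))
    if usl is not None:
        sides.append((usl - mean) / (3.0 * sigma))
    cp = (usl - lsl) / (6.0 * sigma) if lsl is not None and usl is not None else None
    return CapabilityIndices(cp=cp, cpk=min(sides))


@dataclass(frozen=True)
class ControlChart:
    center: float
    ucl: float
    lcl: float
    r_bar: float
    r_ucl: float
    r_lcl: float
    sigma_within: float
    xbar_flags: tuple
    r_flags: tuple
    degenerate: bool


def xbar_r(series: CapabilitySeries) -> ControlChart:
    """X-bar/R chart (subgroup size 2-10) or individuals/moving-range chart
    (subgroup size 1), with 3-sigma limits from the tabulated constants.

    Flags are the indices of subgroup means (or individuals) and ranges
    beyond their control limits.  A zero average range yields sigma_within 0
    with a :class:`DegenerateProcessWarning`, never a division error.
    """
    k = series.subgroup_size
    if k == 1:
        x = series.values
        mr = np.abs(np.diff(x))
        r_bar = float(mr.mean())
        sigma_w = r_bar / _D2_MR
        center = float(x.mean())
        ucl, lcl = center + 3.0 * sigma_w, center - 3.0 * sigma_w
        r_ucl, r_lcl = 3.267 * r_bar, 0.0
        xflags = tuple(np.nonzero((x > ucl) | (x < lcl))[0]) if r_bar > 0 else ()
        rflags = tuple(np.nonzero(mr > r_ucl)[0]) if r_bar > 0 else ()
    elif k in _CHART_CONSTANTS:
        d2, a2, d3, d4 = _CHART_CONSTANTS[k]
        sub = series.subgroups
        means, ranges = sub.mean(axis=1), np.ptp(sub, axis=1)
        r_bar = float(ranges.mean())
        sigma_w = r_bar / d2
        center = float(means.mean())
        ucl, lcl = center + a2 * r_bar, center - a2 * r_bar
        r_ucl, r_lcl = d4 * r_bar, d3 * r_bar
        xflags = tuple(np.nonzero((means > ucl) | (means < lcl))[0]) if r_bar > 0 else ()
        rflags = tuple(np.nonzero((ranges > r_ucl) | (ranges < r_lcl))[0]) if r_bar > 0 else ()
    else:
        raise ValueError(f"unsupported subgroup size {k}: use 1 (moving range) or 2-10")
    degenerate = r_bar == 0.0
    if degenerate:
        warnings.warn("all subgroup ranges are zero; sigma_within is 0 and "
                      "control limits are degenerate", DegenerateProcessWarning,
                      stacklevel=2)
    return ControlChart(center=center, ucl=ucl, lcl=lcl, r_bar=r_bar,
                        r_ucl=r_ucl, r_lcl=r_lcl, sigma_within=sigma_w,
                        xbar_flags=xflags, r_flags=rflags, degenerate=degenerate)


@dataclass(frozen=True)
class CapabilityResult:
    mean: float
    sigma_within: float
    sigma_overall: float
    cp: float | None
    cpk: float | None
    pp: float | None
    ppk: float
    chart: ControlChart
    descriptive: DescriptiveStats
    verdict: str


def sixpack(series: CapabilitySeries) -> CapabilityResult:
    """Combined capability report: descriptives, control chart, short-term
    Cp/Cpk (sigma = R-bar/d2) and long-term Pp/Ppk (overall sample SD)."""
    desc = descriptive_stats(series.values)
    chart = xbar_r(series)
    sigma_o = desc.sd
    if chart.sigma_within > 0:
        within = cp_cpk(desc.mean, chart.sigma_within, series.lsl, series.usl)
        cp, cpk = within.cp, within.cpk
    else:
        cp = cpk = None
    overall = cp_cpk(desc.mean, sigma_o, series.lsl, series.usl)
    headline = cpk if cpk is not None else overall.cpk
    if headline < 0:
        verdict = "process mean has exceeded the specified limit"
    elif headline >= 1.33:
        verdict = "capable"
    elif headline >= 1.0:
        verdict = "marginally capable (meets the specification limit)"
    else:
        verdict = "not capable (does not match the specification limit)"
    return CapabilityResult(
        mean=desc.mean, sigma_within=chart.sigma_within, sigma_overall=sigma_o,
        cp=cp, cpk=cpk, pp=overall.cp, ppk=overall.cpk, chart=chart,
        descriptive=desc, verdict=verdict)
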