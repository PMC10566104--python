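"""Accelerated-stability trending and the significant-change rule.

An accelerated study stores the product at elevated temperature/humidity and
assays it at fixed intervals (typically 0, 1, 3, 6 months).  A decrease of
more than 5% from the initial assay at any point is a *significant change*
and triggers intermediate-condition studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .validation import mean_rsd


@dataclass
class StabilitySeries:
    """Assay values of one analyte in one product over storage months.

    ``limits`` is (lo, hi) in % label claim; either side may be None for a
    one-sided limit (e.g. an impurity capped from above only).
    """

    product: str
    analyte: str
    months: np.ndarray
    assays: np.ndarray
    limits: tuple = (None, None)

    def __post_init__(self) -> None:
        self.months = np.asarray(self.months, dtype=float)
        self.assays = np.asarray(self.assays, dtype=float)
        if self.months.shape != self.assays.shape or self.months.ndim != 1:
            raise ValueError("months and assays must be equal-length vectors")
        if np.any(np.diff(self.months) < 0):
            raise ValueError("months must be non-decreasing")
        if len(self.months) == 0 or self.months[0] != 0:
            raise ValueError("series must start at month 0 (the initial assay)")


@dataclass(frozen=True)
class StabilitySummary:
    mean: float
    rsd: float
    pct_change: np.ndarray
    significant_change: bool
    within_limits: np.ndarray
    verdict: str


def stability_summary(series: StabilitySeries, threshold_pct: float = 5.0,
                      mode: str = "relative") -> StabilitySummary:
    """Trend summary with the >5% significant-change rule.

    ``pct_change`` is 100*(assay_t - assay_0)/assay_0 per point.  With the
    default ``mode="relative"`` a significant change is a decrease of more
    than ``threshold_pct`` percent of the initial value; ``mode="absolute"``
    instead compares the drop in percentage points of label claim.
    The rule is monotone: lowering any later assay can only turn it on.
    """
    if len(series.assays) < 2:
        raise ValueError("need at least the initial assay and one later point")
    a0 = series.assays[0]
    pct_change = 100.0 * (series.assays - a0) / a0
    if mode == "relative":
        significant = bool(np.any(pct_change < -threshold_pct))
    elif mode == "absolute":
        significant = bool(np.any(series.assays - a0 < -threshold_pct))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    lo, hi = series.limits
    ok = np.ones(len(series.assays), dtype=bool)
    if lo is not None:
        ok &= series.assays >= lo
    if hi is not None:
        ok &= series.assays <= hi
    m, rsd = mean_rsd(series.assays)
    if significant:
        verdict = (f"significant change (>{threshold_pct}% decrease from initial): "
                   "perform intermediate-condition stability studies")
    else:
        verdict = "no significant change through the study"
    return StabilitySummary(mean=m, rsd=rsd, pct_change=pct_change,
                            significant_change=significant, within_limits=ok,
                            verdict=verdict)
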