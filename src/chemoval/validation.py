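"""ICH-style analytical method validation statistics.

Linearity (least-squares calibration with LOD/LOQ from the intercept
dispersion), accuracy/recovery summaries, assay of a formulation against an
external standard, and RSD-based precision tables.  All dispersion statistics
use the sample (n-1) standard deviation, and RSD = 100*SD/mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted straight-line calibration: signal = slope*conc + intercept.

    ``sigma_intercept`` is the regression standard error of the intercept;
    LOD = 3.3*sigma/|slope| and LOQ = 10*sigma/|slope|, so LOQ/LOD = 10/3.3
    whenever both derive from the same sigma.  ``signal_lo``/``signal_hi``
    bracket the fitted signals for extrapolation warnings downstream.
    """

    slope: float
    intercept: float
    r: float
    sigma_intercept: float
    lod: float
    loq: float
    range_lo: float
    range_hi: float
    n: int
    signal_lo: float | None = None
    signal_hi: float | None = None

    def predict_concentration(self, signal):
        return (np.asarray(signal, dtype=float) - self.intercept) / self.slope

    def predict_signal(self, conc):
        return self.slope * np.asarray(conc, dtype=float) + self.intercept


def fit_calibration(concs, signals, sigma_mode: str = "intercept_se") -> CalibrationCurve:
    """Ordinary least squares calibration line with sensitivity limits.

    ``sigma_mode`` selects the dispersion used in LOD/LOQ: the standard error
    of the intercept (default) or the residual standard deviation of the
    regression ("residual_sd").
    """
    x = np.asarray(concs, dtype=float)
    y = np.asarray(signals, dtype=float)
    if len(x) < 3:
        raise ValueError("calibration needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("calibration concentrations are constant")
    res = stats.linregress(x, y)
    if sigma_mode == "intercept_se":
        sigma = float(res.intercept_stderr)
    elif sigma_mode == "residual_sd":
        resid = y - (res.slope * x + res.intercept)
        dof = max(len(x) - 2, 1)
        sigma = float(np.sqrt(np.sum(resid ** 2) / dof))
    else:
        raise ValueError(f"unknown sigma_mode {sigma_mode!r}")
    slope = float(res.slope)
    if slope == 0:
        raise ValueError("zero slope: signal does not respond to concentration")
    lod = 3.3 * sigma / abs(slope)
    return CalibrationCurve(
        slope=slope, intercept=float(res.intercept), r=float(res.rvalue),
        sigma_intercept=float(res.intercept_stderr), lod=lod, loq=10.0 / 3.3 * lod,
        range_lo=float(x.min()), range_hi=float(x.max()), n=len(x),
        signal_lo=float(y.min()), signal_hi=float(y.max()))


@dataclass(frozen=True)
class RecoveryRecord:
    """One spiked-recovery determination."""

    nominal: float
    measured: float

    @property
    def recovery_pct(self) -> float:
        return 100.0 * self.measured / self.nominal


def _as_recovery_pcts(records) -> np.ndarray:
    pcts = [r.recovery_pct if isinstance(r, RecoveryRecord) else float(r)
            for r in records]
    return np.asarray(pcts, dtype=float)


def mean_rsd(values) -> tuple[float, float]:
    """Mean and percent relative standard deviation (sample SD, n-1)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    m = float(v.mean())
    sd = float(v.std(ddof=1))
    return m, 100.0 * sd / m


def recovery_summary(records) -> tuple[float, float]:
    """Mean recovery (%) and its RSD over a set of determinations.

    ``records`` may be :class:`RecoveryRecord` objects or raw recovery
    percentages.
    """
    return mean_rsd(_as_recovery_pcts(records))


def dilution_concentration(amount_mg: float, first_volume_ml: float,
                           *steps: tuple[float, float]) -> float:
    """Concentration (µg/mL) after a dilution chain.

    ``amount_mg`` is dissolved in ``first_volume_ml``; each subsequent step
    takes ``aliquot_ml`` into ``flask_ml``.  E.g. 290 mg → 500 mL → (5, 100)
    gives 29 µg/mL of the weighed material.
    """
    if amount_mg <= 0 or first_volume_ml <= 0:
        raise ValueError("amount and volumes must be positive")
    conc = amount_mg * 1000.0 / first_volume_ml
    for aliquot_ml, flask_ml in steps:
        if aliquot_ml <= 0 or flask_ml <= 0:
            raise ValueError("dilution volumes must be positive")
        conc *= aliquot_ml / flask_ml
    return conc


def assay_percent(response_test: float, response_std: float,
                  conc_std: float, conc_test: float,
                  potency: float = 1.0) -> float:
    """Percent of label claim by external-standard comparison:
    (response_test/response_std) * (conc_std/conc_test) * potency * 100."""
    if response_std <= 0:
        raise ValueError("standard response must be positive")
    if response_test < 0 or conc_std <= 0 or conc_test <= 0:
        raise ValueError("responses and concentrations must be positive")
    return response_test / response_std * conc_std / conc_test * potency * 100.0


@dataclass(frozen=True)
class PrecisionEntry:
    rsd: float
    passed: bool


def precision_table(groups: dict, rsd_limit: float = 2.0) -> dict:
    """Per-condition RSD with a pass flag against ``rsd_limit`` (%).

    ``groups`` maps a condition label (day, analyst, column, ...) to its
    replicate determinations.
    """
    out = {}
    for condition, values in groups.items():
        _, rsd = mean_rsd(values)
        out[condition] = PrecisionEntry(rsd=rsd, passed=rsd <= rsd_limit)
    return out
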