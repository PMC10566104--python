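"""Ratio-spectra chemometrics for overlapped two-component UV mixtures.

Two classical algorithms are implemented, both resting on Beer's-law
additivity Abs(mix) = alpha_X*C_X + alpha_Y*C_Y with no interaction term:

* **Ratio subtraction (RS)** — divide the mixture spectrum by a pure
  divisor spectrum (component Y at a known concentration d).  In a window
  where only Y absorbs, the ratio is the constant C_Y/d; subtracting that
  plateau constant and multiplying back by the divisor restores the
  zero-order spectrum of X, which is then read at a single wavelength
  against a calibration line.

* **Mean centering of ratio spectra (MCR)** — mean-center the ratio
  spectrum over an analysis window.  The divisor component contributes a
  constant C_Y/d to the ratio, and mean centering annihilates constants, so
  the centered amplitude at the read wavelength is linear in C_X and exactly
  invariant to C_Y.  No plateau window is needed, only a window where the
  divisor is safely nonzero.

Wavelengths where the divisor is numerically near zero are masked rather
than divided; masking, not smoothing, is the only preprocessing applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: divisor absorbances below this (AU) are masked instead of divided
DIVISOR_EPS = 1e-4


class NoOverlapError(ValueError):
    """The two spectra share no wavelength range."""


class NotAPlateauWarning(UserWarning):
    """The window used for the plateau constant is not flat."""


class ExtrapolationWarning(UserWarning):
    """A read amplitude fell outside the calibrated signal range."""


@dataclass
class Spectrum:
    """A zero-order UV spectrum on a strictly increasing wavelength grid.

    ``concentration`` (µg/mL) is metadata for standards; ``meta`` carries
    generator ground truth or file provenance and travels through I/O.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    label: str = ""
    concentration: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.shape != self.absorbance.shape or self.wavelengths.ndim != 1:
            raise ValueError("wavelengths and absorbance must be equal-length 1-D vectors")
        if len(self.wavelengths) >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")

    def value_at(self, wavelength: float) -> float:
        """Linearly interpolated absorbance; exact on grid points."""
        lam = float(wavelength)
        if not (self.wavelengths[0] <= lam <= self.wavelengths[-1]):
            raise ValueError(f"wavelength {lam} nm outside the grid "
                             f"[{self.wavelengths[0]}, {self.wavelengths[-1]}]")
        return float(np.interp(lam, self.wavelengths, self.absorbance))

    def interp_to(self, grid: np.ndarray) -> np.ndarray:
        """Absorbance resampled onto ``grid`` by linear interpolation
        (identity when the grids already coincide)."""
        return np.interp(grid, self.wavelengths, self.absorbance)

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.wavelengths, self.absorbance * factor,
                        label=self.label, concentration=self.concentration,
                        meta=dict(self.meta))


@dataclass
class RatioSpectrum(Spectrum):
    """A mixture spectrum divided by a pure-component divisor spectrum.

    ``mask`` is True at wavelengths excluded from analysis (near-zero or
    uncovered divisor); masked entries of ``absorbance`` hold 0.
    """

    divisor_label: str = ""
    divisor_concentration: float = float("nan")
    mask: np.ndarray = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.mask is None:
            self.mask = np.zeros(len(self.wavelengths), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.wavelengths.shape:
            raise ValueError("mask length must equal the grid length")


@dataclass(frozen=True)
class PlateauWindow:
    """Wavelength window [lo, hi] nm where only the divisor component absorbs."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("plateau window requires lo < hi")

    def contains(self, wavelengths: np.ndarray) -> np.ndarray:
        return (wavelengths >= self.lo) & (wavelengths <= self.hi)


def ratio_spectrum(mixture: Spectrum, divisor: Spectrum,
                   eps: float = DIVISOR_EPS) -> RatioSpectrum:
    """Pointwise quotient mixture/divisor on the mixture's grid.

    The divisor is linearly interpolated onto the mixture grid.  Points where
    |divisor| < ``eps`` or where the divisor grid gives no coverage are masked
    instead of divided.
    """
    lo = max(mixture.wavelengths[0], divisor.wavelengths[0])
    hi = min(mixture.wavelengths[-1], divisor.wavelengths[-1])
    if lo >= hi:
        raise NoOverlapError(
            f"mixture [{mixture.wavelengths[0]}, {mixture.wavelengths[-1]}] nm and "
            f"divisor [{divisor.wavelengths[0]}, {divisor.wavelengths[-1]}] nm share no range")
    grid = mixture.wavelengths
    div = divisor.interp_to(grid)
    mask = (np.abs(div) < eps) | (grid < lo) | (grid > hi)
    ratio = np.zeros_like(div)
    np.divide(mixture.absorbance, div, out=ratio, where=~mask)
    return RatioSpectrum(
        wavelengths=grid, absorbance=ratio,
        label=f"{mixture.label}/{divisor.label}" if mixture.label else "",
        concentration=mixture.concentration, meta=dict(mixture.meta),
        divisor_label=divisor.label,
        divisor_concentration=(divisor.concentration
                               if divisor.concentration is not None else float("nan")),
        mask=mask)


def plateau_constant(ratio: RatioSpectrum, window: PlateauWindow,
                     flat_tol: float = 0.02) -> tuple[float, float]:
    """Mean ratio value over the plateau window, with a flatness check.

    Returns ``(constant, flatness)`` where flatness is the coefficient of
    variation over the unmasked window points.  A CV above ``flat_tol``
    triggers :class:`NotAPlateauWarning` — the window likely contains the
    non-divisor component, and the constant would be biased.
    """
    sel = window.contains(ratio.wavelengths) & ~ratio.mask
    if sel.sum() < 3:
        raise ValueError(
            f"plateau window {window.lo}-{window.hi} nm holds fewer than 3 usable points")
    vals = ratio.absorbance[sel]
    const = float(np.mean(vals))
    flatness = float(np.std(vals, ddof=1) / abs(const)) if const != 0 else float("inf")
    # a near-zero constant (non-divisor component absent) makes the CV blow up
    # although subtracting ~0 is harmless; only warn about material constants
    if flatness > flat_tol and abs(const) > 1e-6:
        warnings.warn(
            f"window {window.lo}-{window.hi} nm is not flat (CV {flatness:.3f} "
            f"> {flat_tol}); the plateau constant may be biased",
            NotAPlateauWarning, stacklevel=2)
    return const, flatness


def ratio_subtract_restore(ratio: RatioSpectrum, constant: float,
                           divisor: Spectrum) -> Spectrum:
    """(ratio - constant) * divisor: the restored zero-order spectrum of the
    non-divisor component.  Masked points are filled by linear interpolation
    of neighbouring restored values and flagged in ``meta['filled']``."""
    if not np.isfinite(constant):
        raise ValueError("plateau constant must be finite")
    grid = ratio.wavelengths
    div = divisor.interp_to(grid)
    restored = (ratio.absorbance - constant) * div
    if ratio.mask.any():
        good = ~ratio.mask
        restored = np.where(good, restored,
                            np.interp(grid, grid[good], restored[good]))
    return Spectrum(grid, restored,
                    label=f"restored({ratio.label})" if ratio.label else "restored",
                    meta={**ratio.meta, "filled": ratio.mask.copy()})


def rs_process(mixture: Spectrum, divisor: Spectrum, window: PlateauWindow,
               eps: float = DIVISOR_EPS, flat_tol: float = 0.02) -> Spectrum:
    """Full RS transform of one spectrum: ratio, plateau constant, restore."""
    r = ratio_spectrum(mixture, divisor, eps=eps)
    const, _ = plateau_constant(r, window, flat_tol=flat_tol)
    return ratio_subtract_restore(r, const, divisor)


def rs_quantify(mixtures, divisor: Spectrum, window: PlateauWindow,
                read_wavelength: float, calibration) -> np.ndarray:
    """Ratio-subtraction assay of a batch of mixtures.

    Each mixture is RS-processed and the restored amplitude at
    ``read_wavelength`` is converted through the calibration line
    ((amplitude - intercept)/slope).  The calibration must have been fitted
    on restored amplitudes of pure standards at the same wavelength.
    """
    amps = np.array([rs_process(m, divisor, window).value_at(read_wavelength)
                     for m in mixtures])
    _warn_if_extrapolating(amps, calibration)
    return (amps - calibration.intercept) / calibration.slope


def mean_center(v) -> np.ndarray:
    """Subtract the arithmetic mean; the output sums to zero.

    The linchpin of MCR: constants map to the zero vector, and
    mean_center(n*v) = n*mean_center(v).
    """
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1 or len(arr) < 2:
        raise ValueError("mean_center needs a 1-D vector of length >= 2")
    return arr - arr.mean()


def mcr_amplitude(mixture: Spectrum, divisor: Spectrum, analysis_range: PlateauWindow,
                  read_wavelength: float, eps: float = DIVISOR_EPS) -> float:
    """Mean-centered ratio amplitude of one spectrum at the read wavelength.

    The ratio spectrum is restricted to the unmasked points of
    ``analysis_range``; mean centering is performed over exactly that vector,
    as the window choice changes the mean and hence the amplitudes (the same
    window must be used for standards and unknowns).
    """
    r = ratio_spectrum(mixture, divisor, eps=eps)
    sel = analysis_range.contains(r.wavelengths) & ~r.mask
    if sel.sum() < 2:
        raise ValueError("analysis range holds fewer than 2 usable points")
    lam = r.wavelengths[sel]
    if not (lam[0] <= read_wavelength <= lam[-1]):
        raise ValueError(f"read wavelength {read_wavelength} nm outside the "
                         f"usable analysis range [{lam[0]}, {lam[-1]}] nm")
    centered = mean_center(r.absorbance[sel])
    return float(np.interp(read_wavelength, lam, centered))


def mcr_quantify(mixtures, divisor: Spectrum, analysis_range: PlateauWindow,
                 read_wavelength: float, calibration) -> np.ndarray:
    """Mean-centering-of-ratio-spectra assay of a batch of mixtures."""
    amps = np.array([mcr_amplitude(m, divisor, analysis_range, read_wavelength)
                     for m in mixtures])
    _warn_if_extrapolating(amps, calibration)
    return (amps - calibration.intercept) / calibration.slope


def _warn_if_extrapolating(amps: np.ndarray, calibration) -> None:
    lo, hi = getattr(calibration, "signal_lo", None), getattr(calibration, "signal_hi", None)
    if lo is None or hi is None:
        return
    if np.any(amps < lo) or np.any(amps > hi):
        warnings.warn("read amplitude outside the calibrated signal range; "
                      "concentration is extrapolated", ExtrapolationWarning,
                      stacklevel=3)
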