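"""Synthetic data generators with embedded ground truth.

Everything the pipeline consumes can be generated here: Beer's-law additive
two-component UV spectra with single-component plateau regions, quadratic
chromatographic truth surfaces over (temperature, %ACN, pH), Gaussian-peak
chromatograms, and hierarchically normal batch-assay series.  Generators are
seed-deterministic and write their truth into ``meta`` so parameter-recovery
tests can close the loop.

The component band shapes are sums of Gaussians chosen for analytic
tractability, not digitized real spectra: component X peaks near 257 nm with
a secondary band near 295 nm so it absorbs alone in the 275-320 nm tail,
while component Y peaks near 251 nm with a secondary band near 215 nm so it
absorbs alone in 210-225 nm.  Band widths are narrow enough that each
component's absorptivity in the other's exclusive window stays below
~1e-9 AU/(µg/mL), so plateau constants are unbiased at working
concentrations.  The two overlap strongly around 245-265 nm,
which is exactly the structural situation the ratio-spectra methods resolve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .capability import CapabilitySeries
from .doe import DesignTable, QuadraticSurfaceModel
from .spectra import PlateauWindow, Spectrum

#: default absorbance noise, AU (instrument-level photometric noise)
DEFAULT_ABS_NOISE = 0.002
#: default wavelength grid, nm
DEFAULT_GRID = (200.0, 340.0, 0.2)
#: window where only component X absorbs (plateau for an X divisor)
X_ONLY_WINDOW = PlateauWindow(275.0, 320.0)
#: window where only component Y absorbs (plateau for a Y divisor)
Y_ONLY_WINDOW = PlateauWindow(210.0, 225.0)


class GeneratorConfigError(ValueError):
    """The requested component library violates a structural assumption."""


@dataclass(frozen=True)
class ComponentSpectrumSpec:
    """Sum-of-Gaussians unit-absorptivity spectrum for one component.

    ``bands`` is a list of (center_nm, sigma_nm, peak_height) triples; the
    height is the absorbance contributed per µg/mL at the band center.
    """

    label: str
    bands: tuple

    def __post_init__(self) -> None:
        for center, width, height in self.bands:
            if width <= 0:
                raise ValueError(f"{self.label}: band width must be > 0")
            if height < 0:
                raise ValueError(f"{self.label}: band height must be >= 0")

    def absorptivity(self, wavelengths: np.ndarray) -> np.ndarray:
        lam = np.asarray(wavelengths, dtype=float)
        out = np.zeros_like(lam)
        for center, width, height in self.bands:
            out += height * np.exp(-0.5 * ((lam - center) / width) ** 2)
        return out


# Default library: strongly overlapped around 250-260 nm, exclusive windows
# at the edges.  Band widths keep cross-window leakage below ~1e-8 AU/(µg/mL).
DEFAULT_X_SPEC = ComponentSpectrumSpec(
    label="X", bands=((257.0, 5.0, 0.060), (305.0, 13.0, 0.020)))
DEFAULT_Y_SPEC = ComponentSpectrumSpec(
    label="Y", bands=((251.0, 4.5, 0.045), (215.0, 6.0, 0.050)))


def make_component_library(specs=None, grid=DEFAULT_GRID, seed=None,
                           exclusive_windows=None, leak_tol: float = 1e-6):
    """Build the two unit-absorptivity spectra and check their structure.

    ``exclusive_windows`` maps each component label to the window where it
    must absorb alone; the other component's absorptivity there must stay
    below ``leak_tol`` (AU per µg/mL) or a :class:`GeneratorConfigError` is
    raised, since the ratio-subtraction plateau step depends on it.
    The library is deterministic; ``seed`` is accepted for API uniformity.
    """
    if specs is None:
        specs = (DEFAULT_X_SPEC, DEFAULT_Y_SPEC)
    if len(specs) != 2:
        raise ValueError("the library holds exactly two components")
    lo, hi, step = grid
    lam = np.arange(lo, hi + step / 2, step)
    spectra = tuple(
        Spectrum(lam, s.absorptivity(lam), label=s.label, concentration=1.0,
                 meta={"unit_absorptivity": True})
        for s in specs)
    if exclusive_windows is None:
        exclusive_windows = {specs[0].label: X_ONLY_WINDOW,
                             specs[1].label: Y_ONLY_WINDOW}
    for own, other in (spectra, spectra[::-1]):
        win = exclusive_windows.get(own.label)
        if win is None:
            continue
        sel = win.contains(lam)
        if not sel.any():
            raise GeneratorConfigError(
                f"window {win.lo}-{win.hi} nm lies outside the grid")
        if float(other.absorbance[sel].max()) > leak_tol:
            raise GeneratorConfigError(
                f"component {other.label} absorbs in the {own.label}-only window "
                f"{win.lo}-{win.hi} nm (max {other.absorbance[sel].max():.2e} "
                f"> {leak_tol:.0e}); no single-component region")
    return spectra


def make_mixtures(library, concentration_pairs, noise_sd: float = 0.0,
                  seed=None) -> list:
    """Beer's-law additive mixtures of the two library components.

    Each (c_x, c_y) pair yields alpha_X*c_x + alpha_Y*c_y plus i.i.d.
    Gaussian noise of SD ``noise_sd`` (AU).  Ground-truth concentrations ride
    along in ``meta['truth']``.
    """
    alpha_x, alpha_y = library
    rng = np.random.default_rng(seed)
    out = []
    for cx, cy in concentration_pairs:
        if cx < 0 or cy < 0:
            raise ValueError("concentrations must be >= 0")
        ab = alpha_x.absorbance * cx + alpha_y.absorbance * cy
        if noise_sd > 0:
            ab = ab + rng.normal(0.0, noise_sd, size=ab.shape)
        out.append(Spectrum(
            alpha_x.wavelengths, ab,
            label=f"mix({alpha_x.label}={cx},{alpha_y.label}={cy})",
            meta={"truth": {alpha_x.label: float(cx), alpha_y.label: float(cy)},
                  "noise_sd": float(noise_sd)}))
    return out


def pure_standard(library, component: str, concentration: float) -> Spectrum:
    """A noise-free single-component spectrum at a given concentration."""
    for comp in library:
        if comp.label == component:
            s = comp.scaled(concentration)
            s.label = component
            s.concentration = float(concentration)
            return s
    raise KeyError(f"no component {component!r} in the library")


@dataclass(frozen=True)
class TruthSurface:
    """Known quadratic response surfaces used to simulate design responses."""

    models: tuple
    noise_sd: dict = field(default_factory=dict)


# Fitted-surface coefficients used as the default generating truth: the
# resolution and retention-time surfaces of the shipped 17-run design, with
# noise SDs matched to their residual mean squares (sqrt(0.1206), sqrt(0.0291)).
DEFAULT_TRUTH = TruthSurface(
    models=(
        QuadraticSurfaceModel("Rs", 3.22, (-0.5200, -0.2438, -1.17),
                              (0.6625, 0.4225, 0.7100),
                              (-0.4475, -0.5250, -0.3700)),
        QuadraticSurfaceModel("Rt", 2.51, (-0.1453, -0.8749, 0.2031),
                              (0.0507, -0.0063, -0.2310),
                              (0.0213, 0.0230, 0.2650)),
    ),
    noise_sd={"Rs": 0.347, "Rt": 0.171},
)


def make_design_data(truth: TruthSurface, design: DesignTable,
                     seed=None) -> DesignTable:
    """Fill a design's responses from known truth surfaces plus normal noise."""
    rng = np.random.default_rng(seed)
    responses = {}
    for model in truth.models:
        y = model.predict(design.coded)
        sd = truth.noise_sd.get(model.response_name, 0.0)
        if sd > 0:
            y = y + rng.normal(0.0, sd, size=y.shape)
        responses[model.response_name] = y
    return design.with_responses(**responses)


@dataclass(frozen=True)
class ChromatogramSpec:
    """Gaussian peaks on a uniform time grid.

    ``peaks``: (retention_min, sigma_min, height) triples; ``rate_hz`` is the
    detector sampling rate; the trace runs from 0 to ``duration_min``.
    """

    peaks: tuple
    rate_hz: float = 20.0
    duration_min: float = 5.0

    def __post_init__(self) -> None:
        for rt, sig, h in self.peaks:
            if rt <= 0 or sig <= 0:
                raise ValueError("retention and sigma must be > 0")


@dataclass
class Chromatogram:
    time_min: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)


def make_chromatogram(spec: ChromatogramSpec, noise_sd: float = 0.0,
                      seed=None) -> Chromatogram:
    """Render a chromatographic trace from the peak spec (+ optional noise)."""
    n = int(spec.duration_min * 60.0 * spec.rate_hz) + 1
    t = np.linspace(0.0, spec.duration_min, n)
    y = np.zeros_like(t)
    for rt, sig, h in spec.peaks:
        y += h * np.exp(-0.5 * ((t - rt) / sig) ** 2)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=y.shape)
    return Chromatogram(t, y, meta={"peaks": [tuple(p) for p in spec.peaks]})


@dataclass(frozen=True)
class PeakMetrics:
    retention_min: float
    sigma_min: float
    plates: float
    tailing: float


def peak_metrics(trace: Chromatogram, min_height_frac: float = 0.05):
    """Pharmacopoeial system-suitability metrics measured from the trace.

    Peaks are located by local maxima; sigma comes from the half-height width
    (w_half = 2.3548*sigma), the tangent width is w = 4*sigma, plate count
    N = 16*(t/w)^2 = (t/sigma)^2, and the tailing factor is W05/(2f) with W05
    the full width and f the front half-width, both at 5% height.  Returns
    ``(metrics, resolutions)`` where resolutions holds Rs = 2*dt/(w1+w2) for
    each consecutive peak pair (empty for a single peak).
    """
    t, y = trace.time_min, trace.intensity
    idx, _ = sps.find_peaks(y, height=min_height_frac * y.max())
    if len(idx) == 0:
        raise ValueError("no peaks found in the trace")
    half_w, _, _, _ = sps.peak_widths(y, idx, rel_height=0.5)
    w05, _, left05, right05 = sps.peak_widths(y, idx, rel_height=0.95)
    dt = t[1] - t[0]
    metrics = []
    for i, p in enumerate(idx):
        sigma = half_w[i] * dt / 2.3548200450309493  # w_half = 2*sqrt(2 ln 2)*sigma
        rt = float(t[p])
        front = (p - left05[i]) * dt
        tail = (w05[i] * dt) / (2.0 * front) if front > 0 else float("nan")
        metrics.append(PeakMetrics(retention_min=rt, sigma_min=float(sigma),
                                   plates=float((rt / sigma) ** 2),
                                   tailing=float(tail)))
    resolutions = []
    for a, b in zip(metrics, metrics[1:]):
        w1, w2 = 4.0 * a.sigma_min, 4.0 * b.sigma_min
        resolutions.append(2.0 * (b.retention_min - a.retention_min) / (w1 + w2))
    return metrics, resolutions


def make_batches(mean: float, sigma_within: float, sigma_between: float,
                 n_subgroups: int, subgroup_size: int = 1, seed=None,
                 lsl: float | None = None, usl: float | None = None) -> CapabilitySeries:
    """Hierarchical normal batch-assay series with embedded truth.

    Each subgroup draws a level shift ~ N(0, sigma_between^2) shared by its
    ``subgroup_size`` determinations, which add N(0, sigma_within^2) noise.
    """
    if sigma_within < 0 or sigma_between < 0:
        raise ValueError("sigmas must be >= 0")
    rng = np.random.default_rng(seed)
    shifts = rng.normal(0.0, sigma_between, size=n_subgroups)
    values = (mean + shifts[:, None]
              + rng.normal(0.0, sigma_within, size=(n_subgroups, subgroup_size)))
    return CapabilitySeries(
        values=values.ravel(), subgroup_size=subgroup_size, lsl=lsl, usl=usl,
        meta={"truth": {"mean": mean, "sigma_within": sigma_within,
                        "sigma_between": sigma_between}})
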