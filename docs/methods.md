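# Methods

This note documents the statistical models, algorithmic conventions, and
design choices behind `chemoval`, and what the synthetic-data generators do
and do not emulate.

## Response-surface modeling (`chemoval.doe`)

**Design.** Only the 3-factor Box-Behnken design is supported: the 12 edge
midpoints (±1, ±1, 0)-type plus replicated center points. Center replicates
supply pure error; at least one is required. Standard order is fixed
(edge blocks (A,B), (A,C), (B,C), then centers); run order may be shuffled
with an explicit seed.

**Coding.** Factor levels map piecewise-linearly onto −1/0/+1, so an
asymmetric center is allowed and the map stays monotone. All model
coefficients are reported in coded units, which makes effect sizes
comparable across factors; levels outside [low, high] are extrapolated with
a warning rather than rejected, since optimization polish can probe slightly
outside the fitted region.

**Fitting.** The full second-order polynomial
{1, A, B, C, AB, AC, BC, A², B², C²} is fitted by ordinary least squares
(`numpy.linalg.lstsq`). A rank check precedes the solve; a deficient basis
raises an error naming the collinear terms instead of silently returning a
minimum-norm solution. Fitting data simulated from a known quadratic with
zero noise recovers every coefficient to better than 1e-8 (tested).

**ANOVA.** Term sums of squares are partial (drop-one-term, Type III):
SS(term) = SSE(model without the term) − SSE(full model). On an exact BBD
the linear columns have Σx² = 8 and the interaction columns Σx² = 4, so the
partial SS reduce to 8b² and 4b² respectively — a cross-check the test suite
applies against the drop-one refits. F statistics divide by the residual
mean square; p-values are upper-tail F probabilities stored at full
precision (presentation-layer formatting such as "< 0.0001" is not baked
in). Pure error pools the within-group SS of replicate (identical-coded)
runs. Two degenerate cases are handled explicitly rather than propagated as
NaN: zero residual df (saturated fit) flags the table and reports F/p as
absent, and zero pure error (identical replicates, common when responses are
transcribed at 2–3 decimals) reports the lack-of-fit F as absent.

**Desirability.** Per-response Derringer–Suich ramps with weight 1 by
default (linear ramps), combined by an unweighted geometric mean. The
optimizer is deterministic: exhaustive search on a fixed grid over the coded
cube (ties broken by first point in lexicographic grid order) followed by a
coordinate-descent polish with a halving step schedule starting at the grid
spacing and stopping below 1e-6. Polish can only improve the objective
(tested). Goals that are infeasible everywhere produce a `feasible=False`
result, not an exception, because an empty operating window is a legitimate
screening outcome.

## Ratio-spectra resolution (`chemoval.spectra`)

Both algorithms assume Beer's-law additivity with no component interaction.
Dividing a mixture by a pure divisor spectrum (component Y at concentration
d) gives

    ratio(λ) = α_X(λ)·C_X / (α_Y(λ)·d) + C_Y/d.

*Ratio subtraction* estimates the constant C_Y/d as the arithmetic mean of
the ratio over a plateau window where only Y absorbs, subtracts it, and
multiplies back by the divisor to restore X's zero-order spectrum. The
plateau's coefficient of variation is reported as a flatness diagnostic; a
CV above 2 % triggers a warning (the window likely contains the other
component), except when the constant itself is below 1e-6 AU, where the CV
is numerically meaningless and subtracting ~0 is harmless.

*Mean centering of ratio spectra* subtracts the mean of the ratio over an
analysis window; because mean centering annihilates constants, the C_Y/d
term vanishes and the centered amplitude at any read wavelength is exactly
linear in C_X and invariant to C_Y. The same window must be used for
standards and unknowns, since the window determines the subtracted mean.
The divisor-invariance property holds to ~1e-15 on noise-free synthetic data
(tested at 1e-8).

Numerical choices: wavelengths where |divisor| < 1e-4 AU are masked rather
than divided (restored spectra fill masked points by linear interpolation
and flag them); grids are harmonized by linear interpolation onto the
mixture grid, exact when the grids already coincide; no smoothing or
derivative preprocessing is applied anywhere. Divisor concentrations, read
wavelengths, and windows are always explicit arguments/config — plateau
constants are computed quantities, never inputs.

## Validation statistics (`chemoval.validation`)

Calibration is ordinary least squares (`scipy.stats.linregress`); r is the
Pearson correlation. The dispersion σ in LOD = 3.3 σ/S and LOQ = 10 σ/S is
the regression standard error of the intercept by default — the common
"standard deviation of the intercept" reading — with the residual-SD
alternative selectable, since lab SOPs differ. LOQ/LOD = 10/3.3 identically
whenever both use the same σ. All RSDs use the sample (n−1) standard
deviation; this convention reproduces printed summary rows from printed
individual determinations (e.g. RSD 1.76 from a four-point stability
series). Assay of a formulation uses the external-standard ratio
(response_test/response_std)·(C_std/C_test)·potency·100, with a dilution
helper for weight→volume→aliquot chains.

## Process capability (`chemoval.capability`)

The sixpack convention separates short- and long-term variation: Cp/Cpk use
the within-subgroup sigma R̄/d₂ from the control chart; Pp/Ppk use the
overall sample SD. Both are reported because single-number "Cpk" claims are
ambiguous when batches are single determinations. The default subgroup size
is 1 (individuals/moving-range chart, d₂ = 1.128) because batch assays are
typically one determination per batch; sizes 2–10 use the tabulated
Shewhart constants. Flags are 3σ breaches only — Western Electric run rules
are out of scope. One-sided specifications (e.g. an impurity limited from
above) give Cpk from the available side and no Cp. The mode in the
descriptive block is the most frequent value after rounding to the data's
inferred printed precision (ties to the smallest value), which makes a mode
meaningful for assay data recorded at fixed decimals. Verdicts: Cpk ≥ 1.33
"capable", ≥ 1.0 marginal, < 0 "mean has exceeded the specified limit".

## Stability trending (`chemoval.stability`)

Per-point change is 100·(assay_t − assay_0)/assay_0. "More than 5 %" is
interpreted as a strict relative decrease from the month-0 value (the
absolute-percentage-point reading is available via `mode="absolute"`); the
rule is monotone in later assays (property-tested). Specification-limit
compliance is reported per point alongside the rule. The rule is intended
for assay analytes; impurity-style one-sided limits are reported for
compliance only.

## Synthetic data (`chemoval.synth`)

The generators emulate the *structure* real data must have for the methods
to apply, not any particular instrument's output:

* **Spectra** are sums of Gaussians on a 200–340 nm grid (0.2 nm step).
  Component X peaks at 257 nm (σ 5 nm) with a secondary band at 305 nm
  (σ 13 nm); Y peaks at 251 nm (σ 4.5 nm) with a secondary band at 215 nm
  (σ 6 nm). This yields strong overlap at 245–262 nm plus exclusive windows
  (X alone in 275–320 nm, Y alone in 210–225 nm) with cross-window leakage
  below ~1e-9 AU/(µg/mL), so plateau constants are unbiased at working
  concentrations; the library constructor verifies this and rejects
  configurations without single-component regions. Default photometric
  noise is 0.002 AU (typical UV photometric repeatability). Real spectra
  have correlated baseline drift, stray-light nonlinearity at high
  absorbance, and non-Gaussian band shapes — none are modeled, so passing
  recovery tests demonstrate algorithmic correctness under the methods' own
  assumptions, not robustness to instrument artifacts.
* **Design responses** are generated from known 10-coefficient quadratic
  surfaces; the default truth uses the fitted surfaces of the bundled study
  with noise SDs matched to their residual mean squares (0.347 for Rs,
  0.171 min for Rt), so simulated replicates have realistic
  signal-to-noise. Monte-Carlo coefficient spread matches the analytic OLS
  covariance σ²(XᵀX)⁻¹ (tested at 500 replicates).
* **Chromatograms** are pure Gaussian peaks; metrics (plate count
  N = 16(t/w)², tangent width w = 4σ from the half-height width, tailing
  from 5 %-height front/back widths, Rs = 2Δt/(w₁+w₂)) are measured from the
  trace by height crossings and verified against closed forms. Exponentially
  modified (tailing) peaks are not modeled.
* **Batch series** are hierarchical normal draws (between-subgroup shift +
  within-subgroup noise) with truth embedded, sized by default like a
  100-batch quarterly trend (mean 99.04, σ 0.58, limits 90–105 %).

All generators are seed-deterministic (identical seed ⇒ bit-identical
output) via `numpy.random.default_rng`.

## Problem sizes in the test suite

Simulation-based tests use sizes chosen to make sampling error a small
fraction of the asserted tolerance while keeping the default suite fast:
500 replicates for Monte-Carlo SE checks, 10⁴ values for capability
recovery, 10⁵ points for the control-chart false-alarm rate. The whole
suite runs in a few seconds.

## Known limitations

* Only 3-factor BBDs; no central-composite, D-optimal, or mixture designs.
* Two-component mixtures only; no derivative spectrophotometry or
  multivariate (PLS/PCR) calibration.
* Capability assumes normality; no transforms for non-normal data.
* No shelf-life regression (ICH-Q1E-style extrapolation) in the stability
  module.
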