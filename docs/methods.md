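# Methods

## Spectral quantities

Spectra are series of (wavelength nm, value) pairs, either transmittance
fractions `T ∈ [0, 1]` (sample vs blank-medium reference) or absorption
percentages `Abs = 100·(1 − T)`. Absorption percent — not absorbance/OD
`−log₁₀T` — is the working quantity: compact spectrometers without
photomultipliers are unreliable at high OD, and absorption surfaces are the
easier shape to describe. Only the 330–860 nm band is used (outside it the
reference-divided signal is noise-dominated). Deuterium-lamp emission
artifacts are removed by masking narrow windows and linearly interpolating
across them; the defaults (484–488 nm, 654–658 nm) cover the Balmer H-β and
H-α lines of a deuterium/halogen source. The masks are configuration, not
physics: linear interpolation is used because the masks are a few nm wide
and the underlying cell spectra vary slowly there. Reference-subtracted
absorption can dip slightly below zero; values in [−1, 0) percentage points
are clipped to zero (with a logged count), anything lower is rejected.

Badly shaped spectra (bubbles, mispositioned cuvettes) are filtered by a
documented heuristic: a free two-Gaussian fit must reach R² ≥ 0.9. Well
formed cell spectra in this band are fitted by two Gaussians at R² ≈ 0.98+,
so the threshold is permissive; it is configurable, and a threshold of 0
disables shape filtering.

## The species shape model

`Abs(λ, C) = Σᵢ aᵢ(C)·exp(−((λ − bᵢ(C))/cᵢ(C))²)` with sub-function
families: constant `k`; Beer–Lambert amplitude `100(1 − 10^(−p₁C))`
(dimensionally an absorption percent; `p₁` in mL/cells); power `p₁C^p₂`
(empirical — no light–matter mechanism is claimed for it); log-linear
`p₁ + p₂·log₁₀C`. Two components are the default: component 1 carries the
concentration dependence, component 2 is a constant near-infrared baseline.
The component count is a model property, not a hard-coded constant.

The shipped CEM model (range 10⁵–10⁶ cells/mL) uses a Beer–Lambert
amplitude, constant center, power width, plus a constant baseline Gaussian
centered beyond the window (936.1 nm). The shipped *Candida albicans*
model (0.5–4 × 10⁶ cells/mL) uses log-linear amplitudes and a log-linear
Gaussian-1 center; at its printed parameters that center is far off-axis
(negative nm) over the calibrated range, making component 1 a broad sloping
background — the parameters are used as printed, not "corrected".
Log-linear coefficients are meaningless as C → 0, so the CA model carries a
validity floor (default 10⁴ cells/mL) below which the species contributes
zero absorption; this lets mixtures degrade gracefully to fewer species.
"Center-range concentration" means the midpoint of the calibrated range
(5.5 × 10⁵ for CEM); the divisor of percent-scaled dispersions is
configurable.

Mixtures: transmittances of independent absorbers multiply, so
`Abs_mix = 100(1 − Π(1 − Absᵢ/100))`. Inputs must lie in [0, 100]
(tolerance 10⁻⁶); model-evaluated spectra are clamped to [0, 100] before
mixing, with a warning beyond ±0.5.

## Calibration

1. **Free Gaussian fits.** Each spectrum is fitted by trust-region least
   squares with bounds (amplitudes [0, 200] %, centers within 3 window
   spans of the window, widths [0.1, 6×span] nm). Starting point: component
   1 at the absorption-weighted centroid, width span/4, amplitude max(y);
   baseline at the upper window edge, width span/3, amplitude 10% of max.
   Because the baseline center lies beyond the window it is weakly
   constrained and a single start occasionally lands in a degenerate local
   minimum (collapsed width), so two further deterministic starts (width
   span/2 and span/8, baseline amplitude = the value at the window edge)
   are tried and the lowest-SSE solution kept. Degenerate fits (width
   < 1 nm, amplitude ratio < 10⁻³, or two coincident components) are
   flagged, not silently accepted.
2. **Structure discovery (iterated constant-fixing).** All spectra are
   fitted freely; components are relabeled so the amplitude most correlated
   with concentration is component 1. Per free coefficient a spread
   statistic is computed across spectra: coefficient of variation
   (std/|mean|) for amplitudes and widths, std divided by the window span
   for centers (their offset is arbitrary, a CV would be meaningless). The
   smallest spread below the threshold (default 0.05) is fixed at its mean
   — one coefficient per iteration, preserving an auditable trail — and the
   set is refitted with the pinned value until nothing qualifies (cap 8
   iterations). Coefficients can be force-pinned to reproduce manual
   structure choices. Requires ≥ 5 spectra spanning ≥ 3× in concentration.
3. **Sub-function family selection.** Every family is least-squares fitted
   to each free coefficient's (C, value) rows. Families with more
   parameters than the constant must beat it in a partial F-test at
   α = 0.05 to be eligible; among eligible families the highest R² wins,
   exact ties going to fewest parameters then declaration order. The gate
   exists because a 2-parameter family always attains nominally higher R²
   than a constant (R² = 0 by construction), even on pure noise — on
   constant data with 1% noise the expected spurious R² of a 2-parameter
   fit at n = 8 is ≈ 0.3, so no fixed R² margin separates signal from
   noise, while the F-test does.
4. **Global surface minimization.** All scalar parameters (including the
   constants) are polished jointly by Nelder–Mead on the summed squared
   error between the model surface and every calibration spectrum,
   `Σ_λ Σ_C (model − data)²`, uniformly weighted. Parameters are scaled by
   their starting magnitudes (they span 10⁻⁷ to 10³). Convergence:
   relative simplex size < 10⁻⁶ and relative objective change < 10⁻⁹ (with
   a 10⁻¹⁰ absolute floor — from a near-exact start the objective is ~10⁻²²
   and a purely relative criterion would burn the whole budget), cap 10⁴
   evaluations, one restart. The result never exceeds the starting
   objective; hitting the cap flags the result not-converged.

Calibration is fully deterministic given data and configuration.

## Inversion

Single species: SSE over concentration is scanned on 200 log-spaced points
over [C_min/2, 2·C_max] (the calibrated range padded — extrapolation is
allowed but surfaces as an `at_bound` status rather than silently), then
refined by golden-section search to 10⁻⁶ relative. Mixtures: a coarse
15-points-per-axis log grid over the product of species ranges (extended
down to floor/2 for floored species) followed by Nelder–Mead refinement in
log₁₀-concentration space from the best 3 grid points; spectrally similar
species produce shallow valleys, and multiple starts guard against them.
Near-ties (ΔSSE < 10⁻⁹) resolve to the smallest total concentration. A
species is reported `below_floor` when its estimate is under its validity
floor or it contributes no absorption at the estimate; a flat residual
surface (grid SSE range < 10⁻⁶ of its maximum) is `not_converged`. R² is
reported against the windowed spectrum mean.

## Accuracy machinery

*Bias* is the least-squares intercept of calculated-vs-counter
concentrations on the line Y = X + Bias, i.e. mean(calc − counter);
positive means overestimation. *Dispersion* is the RMS residual about that
line. Cross-validation enumerates every k-subset of the experimental sets
(lexicographic), recalibrates on the union of the model sets — structure
fixed to a template, parameters refit; the simplex starts from the
template's parameters by default, or from per-spectrum fits — and scores
the held-out sets. Growth series are fitted in log space (linear regression
of ln C on t; closed form, deterministic), doubling time ln 2/k flagged
non-finite for k ≤ 0; the dispersion about the exponential uses the same
time window as the fit. Crosstalk planes are ordinary least squares of each
species' calculated concentration on all species' true concentrations;
crosstalk-free unmixing gives own-slope 1, cross-slope 0.

## Synthetic data

The generator emulates the three documented noise sources of the real
measurement chain:

* **Cuvette variability** — disposable cuvettes spread the measured
  absorption; across 100 cuvettes the 600 nm absorption is normally
  distributed with ≈ ±2.5% FWHM. Modeled as a multiplicative factor
  g ~ N(1, 0.025/2.355) per cuvette, applied to the whole spectrum by
  default (the cuvette is part of the optical path); a flag restricts it to
  concentration-dependent components. Multiplicative (relative) rather
  than additive was chosen because cuvette optics scale transmitted
  intensity.
* **Detector noise** — i.i.d. N(0, 0.2) percentage points per wavelength
  (no wavelength correlation is modeled).
* **Counter dispersion** — the reference counter reads a 10 µL aliquot and
  scatters ≈10% (CV) around the truth. It perturbs the *label* only, never
  the spectrum, modeling the sampling-representativeness error of the
  reference method. Ground truth is stored separately so recovery tests
  have an exact oracle.

Calibration sets default to 8 concentrations log-spaced over the species
range (the weekly dilution-series design). Growth series are piecewise
exponentials sampled on a dense monitoring schedule (hourly 0–4 h,
half-hourly 4–11 h, two-hourly 21–30 h with the 30 h endpoint, 25 points);
a single cuvette hosts the whole series, so the cuvette factor is forced
to 1. Mixture grids are reconstructed compositionally — per-species
spectra combined through the mixture law — mirroring how co-culture
spectra are proved out without actual co-cultures.

What the generator does **not** emulate: wavelength-correlated baseline
drift, lamp aging, scattering nonlinearity at high density, biological
lag/stationary phases, and week-scale bias drift between experimental
campaigns. Passing tests therefore demonstrate the correctness and noise
robustness of the algorithms under the documented noise structure, not
instrument-grade validation on real cultures.

## Problem sizes and numerical choices

Synthetic spectra in tests and in `scripts/acceptance.py` use a 2 nm grid
step over 330–860 nm (266 points) rather than the instrument's 0.22 nm: the
fitted quantities are broad (widths ≥ 170 nm) and grid density beyond ~2 nm
changes estimates by < 0.5% (asserted by the subsampling-invariance test),
while cutting runtime by an order of magnitude. Cross-validation runs use
a 2000-evaluation simplex cap with 10⁻⁴/10⁻⁶ relative tolerances — ample
for parameters started at a template and dominated by label noise. The
noise-realism replicate count (10 seeds × 56 combinations) matches the
design of the dispersion-band check.

## Known limitations

* Structure discovery assumes the free Gaussian fits identify components
  consistently across spectra; wildly heterogeneous sets can defeat the
  correlation-based relabeling.
* Mixture inversion of spectrally similar species is ill-conditioned by
  nature; the multi-start search mitigates but cannot remove crosstalk.
* No uncertainty quantification on calibrated parameters or estimated
  concentrations (point estimates with diagnostics only).
* Supported formats are plain-text exports; proprietary vendor binaries
  and instrument control are out of scope, as are dark/reference
  acquisition (assumed applied upstream).
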