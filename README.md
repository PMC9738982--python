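# speccult

Cell-concentration determination from white-light absorption spectra via
Gaussian spectral-shape models.

## The problem

Closed-loop cell-culture monitoring (e.g. T-cell expansion for advanced
therapy medicinal products) needs concentration measurements without
sampling the bioreactor. A white-light source, a cuvette and a compact
spectrometer provide an absorption spectrum, expressed in percent,

    Abs(λ, C) = 100 · (1 − T(λ, C)),

with `T` the transmittance against a blank-medium reference. A single
wavelength (Beer–Lambert turbidimetry) gives one number and can track one
species; the *shape* of the whole spectrum carries enough information to
unmix several species growing together. `speccult` implements the
shape-based workflow: model calibration, concentration inversion,
co-culture unmixing, and the accuracy machinery around them.

## The model

A species' spectrum is a sum of Gaussian components whose coefficients are
functions of concentration ("sub-functions"):

    Abs_species(λ, C) = Σᵢ aᵢ(C) · exp(−((λ − bᵢ(C)) / cᵢ(C))²)

Typically two components suffice: a concentration-sensitive Gaussian (a
Beer–Lambert amplitude `100·(1 − 10^(−p₁C))`, a power-law width `p₁·C^p₂`,
or log-linear coefficients `p₁ + p₂·log₁₀C`) plus a constant near-infrared
baseline Gaussian. Mixtures follow from optical-density additivity
(transmittances multiply):

    Abs_mix = 100 · (1 − Πᵢ (1 − Absᵢ/100)).

Calibration discovers which coefficients are constant (iterated
constant-fixing over per-spectrum free Gaussian fits), picks sub-function
families for the rest, and polishes all parameters with a derivative-free
simplex fit of the full (λ × C) surface. Inversion matches a measured
spectrum to the model by least squares over concentration(s). Two
calibrated models ship as JSON fixtures: `cem_table2.json` (CEM
T lymphoblasts, 10⁵–10⁶ cells/mL) and `ca_table3.json` (*Candida albicans*
yeasts, 0.5–4 × 10⁶ cells/mL).

## Worked example

```python
import numpy as np
import speccult as sc

cem = sc.load_builtin_model("cem_table2")
lam = np.arange(330, 860.1, 2.0)

# a synthetic calibration set at the documented noise levels
sset = sc.generate_calibration_set(
    cem, sc.default_cem_concentrations(8), grid=(330, 860, 2.0),
    noise=sc.NoiseConfig(seed=7),
)
wl, X = sset.to_matrix()
y = sset.counter_concentrations()

reg = sc.SpectralShapeRegressor(name="CEM").fit(X, y, wavelengths=wl)
print({k: (v if v == "free" else "constant") for k, v in reg.structure_.items()})
print(np.round(reg.predict(X[:3]) / 1e5, 2), np.round(y[:3] / 1e5, 2))

dc = sc.concentration_equivalent_of_absorption_change(cem, 600.0, 5.5e5, 2.5)
print(f"{dc:.3g}")
```

prints

```
{'a1': 'free', 'b1': 'constant', 'c1': 'free', 'a2': 'constant', 'b2': 'constant', 'c2': 'constant'}
[1.04 1.38 1.87] [1.11 1.4  1.95]
3.86e+04
```

The structure line says calibration found both Gaussian centers, the
baseline amplitude and the baseline width constant, leaving the first
Gaussian's amplitude and width concentration-dependent. The second line
compares inverted concentrations (×10⁵ cells/mL) with the noisy counter
labels. The last number is the model's sensitivity: a 2.5-percentage-point
absorption spread at 600 nm (typical cuvette-to-cuvette variability) is
worth ≈3.9 × 10⁴ cells/mL at the center of the calibrated range.

Mixture unmixing works the same way with several models:

```python
ca = sc.load_builtin_model("ca_table3")
mix = sc.MixtureConcentrationRegressor([cem, ca]).fit(wavelengths=lam)
spectrum = sc.MixtureModel((cem, ca)).evaluate(lam, (4e5, 2e6))
print(mix.predict(spectrum[None, :]))   # -> [[4.0e5  2.0e6]]
```

A `speccult` CLI wraps the same functionality (`speccult preprocess`,
`eval`, `mix`, `calibrate`, `invert`, `simulate`, `crossval`, `growth`,
`crosstalk`); run `speccult --help`.

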