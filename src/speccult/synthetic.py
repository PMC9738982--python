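"""Synthetic spectra generation.

Generates calibration sets, growth-monitoring series and mixture grids with
the statistical structure of real cuvette spectroscopy:

* cuvette-to-cuvette variability -- disposable plastic cuvettes scatter the
  measured absorption; across cuvettes the absorption at 600 nm is normally
  distributed with a full width at half maximum of about +-2.5% (relative),
  i.e. a multiplicative factor with sd 0.025/2.355 ~ 0.0106;
* per-wavelength detector noise (i.i.d. Gaussian, absorption percentage
  points);
* counter reading dispersion -- the reference cell counter uses a 10 uL
  aliquot, so its reading scatters by ~10% (CV) around the true
  concentration.  Counter noise perturbs the *label*, never the spectrum.

Ground truth is always stored separately (``extra["true_concentration"]``)
so recovery tests have an exact oracle.  A fixed seed and configuration
yield bitwise-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .models import SpeciesModel, mix_absorption_spectra
from .spectra import ABSORPTION, Spectrum, SpectrumSet

__all__ = [
    "NoiseConfig",
    "generate_calibration_set",
    "generate_growth_series",
    "generate_mixture_grid",
    "monitoring_schedule",
    "piecewise_exponential_concentration",
    "default_cem_concentrations",
    "default_ca_concentrations",
]

#: FWHM of a normal distribution is 2*sqrt(2 ln 2) ~ 2.355 standard deviations.
_FWHM_PER_SD = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class NoiseConfig:
    """Noise model for synthetic spectra.

    ``cuvette_sd`` is the relative sd of the multiplicative cuvette factor
    (default 0.025/2.355, i.e. a 2.5% FWHM at 600 nm); ``detector_sd`` is
    the per-wavelength additive noise in absorption percentage points;
    ``counter_cv`` the relative sd of the reported counter concentration.
    ``scale_baseline`` controls whether the cuvette factor also scales the
    concentration-independent (baseline) components; the default scales the
    whole optical path.
    """

    cuvette_sd: float = 0.025 / _FWHM_PER_SD
    detector_sd: float = 0.2
    counter_cv: float = 0.10
    seed: int = 0
    scale_baseline: bool = True

    def __post_init__(self) -> None:
        for name in ("cuvette_sd", "detector_sd", "counter_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def zero_noise(self) -> "NoiseConfig":
        return replace(self, cuvette_sd=0.0, detector_sd=0.0, counter_cv=0.0)


def default_cem_concentrations(n: int = 8) -> np.ndarray:
    """``n`` concentrations log-distributed over 1e5..1e6 cells/mL."""
    return np.geomspace(1e5, 1e6, n)


def default_ca_concentrations(n: int = 7) -> np.ndarray:
    """``n`` concentrations log-distributed over 0.5e6..4e6 cells/mL."""
    return np.geomspace(0.5e6, 4e6, n)


def _grid_from_spec(grid) -> np.ndarray:
    lo, hi, step = grid
    if step <= 0:
        raise ValueError("grid step must be > 0")
    return np.arange(float(lo), float(hi) + step / 2.0, float(step))


def _noisy_spectrum(
    model: SpeciesModel,
    lam: np.ndarray,
    c_true: float,
    g: float,
    detector: np.ndarray,
    scale_baseline: bool,
) -> np.ndarray:
    if scale_baseline:
        vals = g * model.evaluate(lam, c_true, check_range=False)
    else:
        vals = np.zeros_like(lam)
        for comp in model.components:
            part = comp.evaluate(lam, c_true)
            vals += g * part if comp.is_concentration_dependent else part
    return np.clip(vals + detector, 0.0, 100.0)


def generate_calibration_set(
    m: SpeciesModel,
    concentrations,
    grid=(330.0, 860.0, 0.22),
    noise: NoiseConfig | None = None,
    set_id: str | None = None,
) -> SpectrumSet:
    """Generate one calibration set of noisy spectra.

    Per spectrum (in a fixed draw order for seed determinism): one cuvette
    factor ``g ~ N(1, cuvette_sd)``, one detector-noise vector, one counter
    reading ``C_true * (1 + N(0, counter_cv))``.  Values are clipped to
    [0, 100].
    """
    conc = np.asarray(list(concentrations), dtype=float)
    if conc.size == 0:
        raise ValueError("empty concentration list")
    lam = _grid_from_spec(grid)
    noise = noise or NoiseConfig()
    rng = noise.rng()
    spectra = []
    for j, c_true in enumerate(conc):
        g = 1.0 + rng.normal(0.0, noise.cuvette_sd) if noise.cuvette_sd else 1.0
        detector = (
            rng.normal(0.0, noise.detector_sd, size=lam.size)
            if noise.detector_sd
            else np.zeros(lam.size)
        )
        counter = c_true * (1.0 + (rng.normal(0.0, noise.counter_cv)
                                   if noise.counter_cv else 0.0))
        vals = _noisy_spectrum(m, lam, float(c_true), g, detector,
                               noise.scale_baseline)
        spectra.append(
            Spectrum(
                lam.copy(),
                vals,
                ABSORPTION,
                species=m.name,
                counter_concentration=float(counter),
                set_id=set_id,
                cuvette_id=f"{set_id or 'set'}-{j}",
                extra={"true_concentration": float(c_true)},
            )
        )
    return SpectrumSet(spectra)


def piecewise_exponential_concentration(c0: float, schedule, t) -> np.ndarray:
    """Piecewise-exponential ``C(t)`` with per-segment doubling times.

    ``schedule`` is a list of ``(t_start, t_end, doubling_time_h)`` segments
    that must be contiguous and start at the earliest sample time; the
    concentration is continuous across segment boundaries.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    segs = sorted((float(a), float(b), float(td)) for a, b, td in schedule)
    if not segs:
        raise ValueError("empty schedule")
    for (a0, b0, _), (a1, _, _) in zip(segs, segs[1:]):
        if a1 < b0 - 1e-12:
            raise ValueError("schedule segments overlap")
        if a1 > b0 + 1e-12:
            raise ValueError("schedule segments must be contiguous")
    for _, _, td in segs:
        if td <= 0:
            raise ValueError("doubling times must be > 0")
    if np.any(t < segs[0][0] - 1e-12) or np.any(t > segs[-1][1] + 1e-12):
        raise ValueError("sample times fall outside the schedule")
    out = np.empty(t.size)
    c_seg = float(c0)
    for a, b, td in segs:
        inside = (t >= a - 1e-12) & (t <= b + 1e-12)
        out[inside] = c_seg * 2.0 ** ((t[inside] - a) / td)
        c_seg = c_seg * 2.0 ** ((b - a) / td)
    return out


def monitoring_schedule() -> np.ndarray:
    """Dense cultivation-monitoring sample times (hours): hourly over 0-4 h,
    half-hourly over 4-11 h, two-hourly over 21-30 h (endpoints included);
    25 time points in total."""
    block1 = np.arange(0.0, 4.0 + 1e-9, 1.0)
    block2 = np.arange(4.5, 11.0 + 1e-9, 0.5)
    block3 = np.append(np.arange(21.0, 30.0 - 1e-9, 2.0), 30.0)
    return np.concatenate([block1, block2, block3])


def generate_growth_series(
    m: SpeciesModel,
    c0: float,
    schedule,
    sample_times,
    grid=(330.0, 860.0, 0.22),
    noise: NoiseConfig | None = None,
) -> SpectrumSet:
    """Generate a growth-monitoring series measured in a single cuvette.

    A single cuvette means no cuvette-to-cuvette variability: the cuvette
    factor is forced to 1 regardless of ``noise.cuvette_sd``.  Detector
    noise still applies.  Ground-truth concentrations are stored per time
    point.
    """
    if c0 <= 0:
        raise ValueError("C0 must be > 0")
    t = np.asarray(list(sample_times), dtype=float)
    lam = _grid_from_spec(grid)
    noise = replace(noise or NoiseConfig(), cuvette_sd=0.0)
    rng = noise.rng()
    c_true = piecewise_exponential_concentration(c0, schedule, t)
    spectra = []
    for j, (ti, ci) in enumerate(zip(t, c_true)):
        detector = (
            rng.normal(0.0, noise.detector_sd, size=lam.size)
            if noise.detector_sd
            else np.zeros(lam.size)
        )
        vals = _noisy_spectrum(m, lam, float(ci), 1.0, detector, True)
        spectra.append(
            Spectrum(
                lam.copy(),
                vals,
                ABSORPTION,
                species=m.name,
                time_h=float(ti),
                cuvette_id="growth-cuvette",
                extra={"true_concentration": float(ci)},
            )
        )
    return SpectrumSet(spectra)


def generate_mixture_grid(
    models,
    concentration_lists,
    grid=(330.0, 860.0, 0.22),
    noise: NoiseConfig | None = None,
):
    """Reconstructed mixture spectra over the product of concentration lists.

    Mirrors the reconstructed co-culture protocol: per-species spectra are
    generated (with per-species cuvette/detector/counter noise) and combined
    with the OD-additivity mixture law rather than co-cultured.  Returns a
    list of ``(true_concentrations, counter_concentrations, Spectrum)``
    with one entry per grid combination, enumerated in row-major order.
    """
    import itertools

    if len(models) != len(concentration_lists):
        raise ValueError("one concentration list per species model")
    lam = _grid_from_spec(grid)
    noise = noise or NoiseConfig()
    # One independently noisy single-species spectrum per (species, level).
    per_species_sets = [
        generate_calibration_set(m, concs, grid=grid,
                                 noise=replace(noise, seed=noise.seed + k),
                                 set_id=f"mix-{m.name}")
        for k, (m, concs) in enumerate(zip(models, concentration_lists))
    ]
    out = []
    for idx in itertools.product(*[range(len(c)) for c in concentration_lists]):
        members = [per_species_sets[k][i] for k, i in enumerate(idx)]
        mixed = mix_absorption_spectra([s.values for s in members])
        true = tuple(s.extra["true_concentration"] for s in members)
        counter = tuple(s.counter_concentration for s in members)
        out.append(
            (
                true,
                counter,
                Spectrum(
                    lam.copy(),
                    mixed,
                    ABSORPTION,
                    species="+".join(m.name for m in models),
                    extra={"true_concentrations": true},
                ),
            )
        )
    return out
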