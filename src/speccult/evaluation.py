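"""Accuracy machinery: bias/dispersion descriptors, cross-validation,
growth-curve analysis and crosstalk mean planes.

The accuracy of spectral concentration measurement is summarized against a
reference cell counter by two descriptors: the *bias*, the least-squares
intercept of the calculated-vs-counter line ``Y = X + Bias`` (positive =
overestimation), and the *dispersion*, the RMS residual about that line --
a shifted form of the standard deviation.  Cross-validation recalibrates
the model on every k-subset of the experimental sets and scores it on the
held-out sets.  Growth monitoring fits an exponential to a calculated
concentration time series and reports the doubling time; crosstalk in
mixture unmixing is quantified by mean planes regressing each species'
calculated concentration on all species' true concentrations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .models import SpeciesModel
from .spectra import SpectrumSet, resample_to_common_grid

__all__ = [
    "AccuracyReport",
    "CrossValReport",
    "GrowthFit",
    "CrosstalkPlane",
    "CalibrationConfig",
    "InversionConfig",
    "compute_bias",
    "compute_dispersion",
    "accuracy_report",
    "cross_validate",
    "fit_growth_curve",
    "fit_crosstalk_planes",
]


@dataclass
class AccuracyReport:
    """Bias and dispersion of calculated vs counter concentrations."""

    bias: float
    dispersion: float
    n: int
    percent_at_center: float | None = None


@dataclass
class CrossValReport:
    """Per-combination accuracy over all model/test set splits."""

    combinations: list[tuple[tuple[int, ...], tuple[int, ...], AccuracyReport]]
    average_bias: float
    average_dispersion: float
    average_percent_at_center: float | None = None
    failed: list[tuple[tuple[int, ...], str]] = field(default_factory=list)


@dataclass
class GrowthFit:
    """Exponential growth fit ``C(t) = C0 * exp(k t)`` over a time window."""

    c0: float
    rate_per_h: float
    doubling_time_h: float  # inf (flagged) when the rate is <= 0
    disp_vs_fit: float
    window: tuple[float, float]
    n: int

    @property
    def doubling_time_finite(self) -> bool:
        return math.isfinite(self.doubling_time_h)


@dataclass
class CrosstalkPlane:
    """Mean plane of one species' calculated concentration vs true grid."""

    species: str
    p0: float
    slopes: tuple[float, ...]  # one slope per true-concentration axis
    residual_rms: float


def compute_bias(calc, counter) -> float:
    """Least-squares intercept of ``Y = X + Bias``, i.e. mean(calc - counter)."""
    calc = np.asarray(calc, dtype=float)
    counter = np.asarray(counter, dtype=float)
    if calc.shape != counter.shape:
        raise ValueError("calc and counter must have equal lengths")
    if calc.size < 1:
        raise ValueError("need at least one sample")
    return float(np.mean(calc - counter))


def compute_dispersion(calc, counter, bias: float) -> float:
    """RMS residual of calculated concentrations about ``Y = X + Bias``:
    ``sqrt(mean((calc_i - (counter_i + bias))**2))``."""
    calc = np.asarray(calc, dtype=float)
    counter = np.asarray(counter, dtype=float)
    if calc.shape != counter.shape:
        raise ValueError("calc and counter must have equal lengths")
    if calc.size < 1:
        raise ValueError("need at least one sample")
    return float(np.sqrt(np.mean((calc - (counter + bias)) ** 2)))


def accuracy_report(calc, counter, center: float | None = None) -> AccuracyReport:
    """Bias + dispersion summary; ``center`` scales dispersion to percent."""
    bias = compute_bias(calc, counter)
    disp = compute_dispersion(calc, counter, bias)
    pct = 100.0 * disp / center if center else None
    return AccuracyReport(bias=bias, dispersion=disp, n=len(np.atleast_1d(calc)),
                          percent_at_center=pct)


# ---- cross-validation -----------------------------------------------------

@dataclass
class CalibrationConfig:
    """Calibration settings used by :func:`cross_validate`.

    ``template`` fixes the model structure (one shape equation whose
    parameters are refit per model-set combination); ``start``
    is ``"template"`` (start the surface minimization at the template's
    parameters) or ``"auto"`` (derive starts from per-spectrum fits).
    """

    template: SpeciesModel
    start: str = "template"
    n_components: int = 2
    max_fun_evals: int = 10000
    xtol_rel: float = 1e-6
    ftol_rel: float = 1e-9
    name: str = "species"


@dataclass
class InversionConfig:
    n_grid: int = 200
    rel_tol: float = 1e-6


def cross_validate(
    sets: list[SpectrumSet],
    k_model: int,
    calibration_config: CalibrationConfig,
    inversion_config: InversionConfig | None = None,
    center: float | None = None,
) -> CrossValReport:
    """Leave-sets-out cross-validation of the calibration/inversion pipeline.

    For every ``k_model``-subset of sets (lexicographic order by set
    index): calibrate on the union of the model sets, invert every test-set
    spectrum, and summarize bias/dispersion against counter concentrations.
    A failed calibration flags its combination and the run continues.
    """
    from .estimators import SpectralShapeRegressor
    from .inversion import estimate_concentration

    n_sets = len(sets)
    if n_sets < k_model + 1:
        raise ValueError("need at least k_model + 1 sets")
    inversion_config = inversion_config or InversionConfig()
    cfg = calibration_config
    if center is None and cfg.template is not None:
        center = cfg.template.center_concentration

    combos = []
    failed = []
    for model_ids in itertools.combinations(range(n_sets), k_model):
        test_ids = tuple(i for i in range(n_sets) if i not in model_ids)
        union = SpectrumSet(
            [s for i in model_ids for s in sets[i].spectra]
        )
        union = resample_to_common_grid(union)
        try:
            lam, x = union.to_matrix()
            reg = SpectralShapeRegressor(
                n_components=cfg.n_components,
                template=cfg.template,
                start=cfg.start,
                max_fun_evals=cfg.max_fun_evals,
                xtol_rel=cfg.xtol_rel,
                ftol_rel=cfg.ftol_rel,
                name=cfg.name,
            )
            reg.fit(x, union.counter_concentrations(), wavelengths=lam)
        except (ValueError, RuntimeError) as exc:
            failed.append((model_ids, str(exc)))
            continue
        calc, counter = [], []
        for i in test_ids:
            for s in sets[i]:
                est = estimate_concentration(
                    s, reg.model_,
                    n_grid=inversion_config.n_grid,
                    rel_tol=inversion_config.rel_tol,
                )
                calc.append(est.concentration)
                counter.append(s.counter_concentration)
        combos.append(
            (model_ids, test_ids, accuracy_report(calc, counter, center=center))
        )
    if not combos:
        raise RuntimeError("every cross-validation combination failed")
    avg_bias = float(np.mean([r.bias for _, _, r in combos]))
    avg_disp = float(np.mean([r.dispersion for _, _, r in combos]))
    avg_pct = 100.0 * avg_disp / center if center else None
    return CrossValReport(
        combinations=combos,
        average_bias=avg_bias,
        average_dispersion=avg_disp,
        average_percent_at_center=avg_pct,
        failed=failed,
    )


# ---- growth analysis ------------------------------------------------------

def fit_growth_curve(times_h, concentrations, window: tuple[float, float] | None = None) -> GrowthFit:
    """Exponential growth fit of a concentration time series.

    The fit is linear regression of ``ln C`` on ``t`` (closed form,
    deterministic); doubling time is ``ln 2 / k``, flagged non-finite when
    the rate is not positive.  The dispersion is the RMS residual of the
    concentrations about the fitted exponential, over the same window.
    """
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.shape != c.shape:
        raise ValueError("times and concentrations must have equal lengths")
    if window is None:
        window = (float(t.min()), float(t.max()))
    lo, hi = window
    sel = (t >= lo) & (t <= hi)
    if int(sel.sum()) < 3:
        raise ValueError("need at least 3 points inside the time window")
    t, c = t[sel], c[sel]
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive for an exponential fit")
    k, ln_c0 = np.polyfit(t, np.log(c), 1)
    c0 = float(np.exp(ln_c0))
    doubling = math.log(2.0) / k if k > 0 else math.inf
    fit_vals = c0 * np.exp(k * t)
    disp = float(np.sqrt(np.mean((c - fit_vals) ** 2)))
    return GrowthFit(
        c0=c0,
        rate_per_h=float(k),
        doubling_time_h=float(doubling),
        disp_vs_fit=disp,
        window=(lo, hi),
        n=int(t.size),
    )


# ---- crosstalk mean planes ------------------------------------------------

def fit_crosstalk_planes(true_grid, calc, species_names=None) -> list[CrosstalkPlane]:
    """Mean planes ``calc_s = p0 + sum_j p_j * C_true_j`` per species.

    Ordinary least squares per species; the own-species slope should be 1
    and cross slopes 0 for crosstalk-free unmixing.  Requires at least
    ``n_species + 2`` non-collinear samples.
    """
    true_grid = np.atleast_2d(np.asarray(true_grid, dtype=float))
    calc = np.atleast_2d(np.asarray(calc, dtype=float))
    if true_grid.shape != calc.shape:
        raise ValueError("true_grid and calc must have identical shapes")
    n, n_sp = true_grid.shape
    if n < n_sp + 2:
        raise ValueError("need at least n_species + 2 samples")
    design = np.column_stack([np.ones(n), true_grid])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design: true concentrations are collinear")
    if species_names is None:
        species_names = [f"species{i + 1}" for i in range(n_sp)]
    planes = []
    for s in range(n_sp):
        coef, *_ = np.linalg.lstsq(design, calc[:, s], rcond=None)
        resid = calc[:, s] - design @ coef
        planes.append(
            CrosstalkPlane(
                species=str(species_names[s]),
                p0=float(coef[0]),
                slopes=tuple(float(v) for v in coef[1:]),
                residual_rms=float(np.sqrt(np.mean(resid ** 2))),
            )
        )
    return planes
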