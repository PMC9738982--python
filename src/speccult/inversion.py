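"""Concentration estimation from measured spectra (shape-model inversion).

Given one or several calibrated species models, a measured absorption
spectrum is inverted for concentrations by least-squares shape matching:
the model spectrum (or the OD-additivity mixture of model spectra) is
matched to the measurement over the model's wavelength window, and the
concentration(s) minimizing the summed squared residual are reported.

Single-species search is a log-spaced grid scan followed by golden-section
refinement; multi-species search is a coarse log-grid over the product of
species ranges followed by simplex refinement from the best grid points
(several starts guard against the shallow valleys created by spectrally
similar species).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .models import MixtureModel, SpeciesModel, mix_absorption_spectra
from .spectra import ABSORPTION, Spectrum, window_spectrum

__all__ = ["ConcentrationEstimate", "estimate_concentration",
           "estimate_mixture_concentrations"]

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class ConcentrationEstimate:
    """Concentrations recovered from one spectrum, with fit diagnostics.

    ``status`` is ``converged``, ``at_bound`` (the optimum sits on a search
    bound), ``below_floor`` (a species landed under its validity floor) or
    ``not_converged`` (non-identifiable, flat residual surface).
    ``species_status`` carries the per-species flavour of the same flags for
    mixtures.
    """

    concentrations: np.ndarray
    fit_r2: float
    residual_sse: float
    status: str
    solver_evals: int
    species_status: tuple[str, ...] = ()

    @property
    def concentration(self) -> float:
        """Convenience scalar accessor for single-species estimates."""
        if self.concentrations.size != 1:
            raise ValueError("estimate holds several species; use .concentrations")
        return float(self.concentrations[0])


def _windowed_arrays(s: Spectrum, window: tuple[float, float]):
    if s.value_kind != ABSORPTION:
        raise ValueError("inversion expects an absorption_percent spectrum")
    lo, hi = window
    if s.wavelengths_nm[0] > lo - 1e-9 and s.wavelengths_nm[-1] < hi + 1e-9:
        ws = s  # already inside the window
    else:
        ws = window_spectrum(s, lo, hi)
    return ws.wavelengths_nm, ws.values


def _r_squared(y: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -np.inf
    return 1.0 - ss_res / ss_tot


def estimate_concentration(
    s: Spectrum,
    m: SpeciesModel,
    n_grid: int = 200,
    rel_tol: float = 1e-6,
    bounds: tuple[float, float] | None = None,
) -> ConcentrationEstimate:
    """Estimate one species' concentration from an absorption spectrum.

    The residual ``sum_lambda (Abs_model(lambda, C) - s(lambda))**2`` is
    scanned on ``n_grid`` log-spaced concentrations over
    ``[C_min/2, 2*C_max]`` (the calibrated range padded for diagnosable
    extrapolation) and refined by golden-section search to relative
    tolerance ``rel_tol``.
    """
    lam, y = _windowed_arrays(s, m.wavelength_window)
    if bounds is None:
        lo, hi = m.concentration_range
        bounds = (lo / 2.0, 2.0 * hi)
    c_lo, c_hi = bounds
    grid = np.geomspace(c_lo, c_hi, n_grid)
    pred = m.evaluate(lam, grid, check_range=False)
    sse = np.sum((pred - y[None, :]) ** 2, axis=1)
    best = int(np.argmin(sse))
    evals = n_grid

    def f(c: float) -> float:
        return float(np.sum((m.evaluate(lam, c, check_range=False) - y) ** 2))

    if best in (0, n_grid - 1):
        c_star, f_star = float(grid[best]), float(sse[best])
        status = "at_bound"
    else:
        a, b = float(grid[best - 1]), float(grid[best + 1])
        # golden-section search on [a, b]
        x1 = b - _GOLDEN * (b - a)
        x2 = a + _GOLDEN * (b - a)
        f1, f2 = f(x1), f(x2)
        evals += 2
        while (b - a) > rel_tol * max(abs(b), 1e-300):
            if f1 <= f2:
                b, x2, f2 = x2, x1, f1
                x1 = b - _GOLDEN * (b - a)
                f1 = f(x1)
            else:
                a, x1, f1 = x1, x2, f2
                x2 = a + _GOLDEN * (b - a)
                f2 = f(x2)
            evals += 1
        c_star, f_star = (x1, f1) if f1 <= f2 else (x2, f2)
        status = "converged"
    if m.validity_floor is not None and c_star < m.validity_floor:
        status = "below_floor"
    pred_star = m.evaluate(lam, c_star, check_range=False)
    return ConcentrationEstimate(
        concentrations=np.array([c_star]),
        fit_r2=_r_squared(y, pred_star),
        residual_sse=f_star,
        status=status,
        solver_evals=evals,
        species_status=(status,),
    )


def estimate_mixture_concentrations(
    s: Spectrum,
    mm: MixtureModel,
    starts: int = 3,
    n_grid_axis: int = 15,
    rel_tol: float = 1e-6,
    max_evals: int = 4000,
) -> ConcentrationEstimate:
    """Estimate per-species concentrations of a mixture spectrum.

    A coarse log-spaced grid over the product of per-species search ranges
    locates candidate basins; Nelder-Mead refinement (in log10-concentration
    space) is run from the best ``starts`` grid points and the lowest-SSE
    solution wins.  Near-ties (SSE within 1e-9) are broken by the smallest
    total concentration.
    """
    if len(mm.species) < 1:
        raise ValueError("mixture model has no species")
    lam, y = _windowed_arrays(s, mm.wavelength_window)
    n_sp = len(mm.species)

    axes = []
    for sp in mm.species:
        lo, hi = sp.concentration_range
        lo_search = lo / 2.0
        if sp.validity_floor is not None:
            # Let the solver park a floored species in its zero-contribution
            # region, so mixtures degrade gracefully to fewer species.
            lo_search = min(lo_search, sp.validity_floor / 2.0)
        axes.append(np.geomspace(lo_search, 2.0 * hi, n_grid_axis))

    # Per-species spectra on each axis, combined over the product grid.
    per_species = [
        np.clip(sp.evaluate(lam, ax, check_range=False), 0.0, 100.0)
        for sp, ax in zip(mm.species, axes)
    ]
    trans = np.ones((1, lam.size))
    for mat in per_species:
        t = 1.0 - mat / 100.0
        trans = (trans[:, None, :] * t[None, :, :]).reshape(-1, lam.size)
    mix = 100.0 * (1.0 - trans)
    sse = np.sum((mix - y[None, :]) ** 2, axis=1)
    evals = sse.size

    sse_range = float(sse.max() - sse.min())
    if sse_range < 1e-6 * max(float(sse.max()), 1e-300):
        return ConcentrationEstimate(
            concentrations=np.full(n_sp, np.nan),
            fit_r2=-np.inf,
            residual_sse=float(sse.min()),
            status="not_converged",
            solver_evals=evals,
            species_status=("not_converged",) * n_sp,
        )

    shape = (n_grid_axis,) * n_sp
    order = np.argsort(sse)[: max(1, starts)]
    start_points = [
        np.array([axes[d][idx] for d, idx in enumerate(np.unravel_index(k, shape))])
        for k in order
    ]

    log_lo = np.array([np.log10(ax[0]) for ax in axes])
    log_hi = np.array([np.log10(ax[-1]) for ax in axes])

    def objective(log_c: np.ndarray) -> float:
        clipped = np.clip(log_c, log_lo, log_hi)
        over = float(np.sum((log_c - clipped) ** 2))
        c = 10.0 ** clipped
        pred = mix_absorption_spectra(
            [np.clip(sp.evaluate(lam, float(cc), check_range=False), 0.0, 100.0)
             for sp, cc in zip(mm.species, c)]
        )
        return float(np.sum((pred - y) ** 2)) * (1.0 + over) + over

    candidates = []
    budget = max_evals // max(1, len(start_points))
    for p in start_points:
        res = optimize.minimize(
            objective,
            np.log10(p),
            method="Nelder-Mead",
            options={"maxfev": budget, "xatol": rel_tol, "fatol": 1e-12,
                     "adaptive": n_sp > 2},
        )
        evals += res.nfev
        candidates.append((float(res.fun), 10.0 ** np.clip(res.x, log_lo, log_hi)))

    best_sse = min(f for f, _ in candidates)
    tied = [c for f, c in candidates if f <= best_sse + 1e-9]
    conc = min(tied, key=lambda c: float(np.sum(c)))

    statuses = []
    for sp, c, lo, hi in zip(mm.species, conc, 10.0 ** log_lo, 10.0 ** log_hi):
        contribution = float(
            np.max(np.clip(sp.evaluate(lam, float(c), check_range=False), 0.0, 100.0))
        )
        if (sp.validity_floor is not None and c < sp.validity_floor) or \
                contribution <= 1e-9:
            statuses.append("below_floor")
        elif c <= lo * (1 + 1e-9) or c >= hi * (1 - 1e-9):
            statuses.append("at_bound")
        else:
            statuses.append("converged")
    overall = "converged"
    for flag in ("at_bound", "below_floor"):
        if flag in statuses:
            overall = flag
    pred = mix_absorption_spectra(
        [np.clip(sp.evaluate(lam, float(c), check_range=False), 0.0, 100.0)
         for sp, c in zip(mm.species, conc)]
    )
    return ConcentrationEstimate(
        concentrations=np.asarray(conc, dtype=float),
        fit_r2=_r_squared(y, pred),
        residual_sse=float(np.sum((pred - y) ** 2)),
        status=overall,
        solver_evals=evals,
        species_status=tuple(statuses),
    )
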