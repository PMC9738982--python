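"""Calibration of species spectral-shape models.

The calibration workflow mirrors how such models are built in practice:

1. every calibration spectrum is fitted freely with a sum of Gaussians
   (:func:`fit_free_gaussians`);
2. Gaussian coefficients whose across-spectra spread is small are fixed one
   per iteration at their mean, and the remaining spectra refitted, until no
   coefficient qualifies (:func:`iterate_constant_fixing`) -- this discovers
   which coefficients are constants and which carry the concentration
   dependence;
3. each concentration-dependent coefficient is described by the best-fitting
   sub-function family (:func:`fit_subfunction_families`);
4. all scalar parameters are polished jointly by derivative-free simplex
   minimization of the summed squared error between the model surface and
   every calibration spectrum (:func:`minimize_global_surface`).

Steps 1-3 provide the starting point; step 4 provides the final parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .models import (
    SUBFUNCTION_FAMILIES,
    GaussianComponent,
    ModelValidityError,
    SpeciesModel,
    SubFunction,
)
from .spectra import Spectrum, SpectrumSet

__all__ = [
    "CoefficientTable",
    "CalibrationResult",
    "fit_free_gaussians",
    "iterate_constant_fixing",
    "fit_subfunction_families",
    "minimize_global_surface",
    "coefficient_labels",
]

#: Width (nm) below which a fitted Gaussian is flagged as degenerate.
DEGENERATE_WIDTH_NM = 1.0


def coefficient_labels(n_gauss: int) -> list[str]:
    """Coefficient labels ``a1, b1, c1, a2, ...`` (amplitude, center, width)."""
    return [f"{letter}{i + 1}" for i in range(n_gauss) for letter in "abc"]


def _gauss_sum(lam: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Sum of Gaussians; ``coeffs`` shaped (n_gauss, 3) as (a, b, c)."""
    out = np.zeros_like(lam)
    for a, b, c in coeffs:
        out = out + a * np.exp(-(((lam - b) / c) ** 2))
    return out


def _r_squared(y: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -np.inf
    return 1.0 - ss_res / ss_tot


def fit_free_gaussians(
    s,
    n_gauss: int = 2,
    fixed: dict[str, float] | None = None,
    p0: np.ndarray | None = None,
    max_nfev: int = 20000,
):
    """Least-squares fit of a sum of ``n_gauss`` Gaussians to one spectrum.

    Parameters
    ----------
    s : Spectrum or (wavelengths, values) pair
        Absorption-percent spectrum on a windowed grid.
    fixed : dict, optional
        Coefficients to pin, keyed by label (``a1``, ``b1``, ``c1``, ...).
    p0 : ndarray, optional
        Starting coefficients shaped (n_gauss, 3); defaults to a
        deterministic rule (component 1 at the absorption-weighted centroid
        with width = window/4 and amplitude = max value; the last component
        at the upper window edge with width = window/3 and 10% amplitude).

    Returns
    -------
    coeffs : ndarray of shape (n_gauss, 3)
        Fitted (amplitude, center, width) per component.  With no pinned
        coefficients, components are returned sorted by ascending center.
    r2 : float
    flags : dict
        ``degenerate_width`` and ``degenerate_amplitude`` markers.
    """
    if isinstance(s, Spectrum):
        lam, y = s.wavelengths_nm, s.values
    else:
        lam, y = (np.asarray(a, dtype=float) for a in s)
    if n_gauss < 1:
        raise ValueError("n_gauss must be >= 1")
    labels = coefficient_labels(n_gauss)
    fixed = dict(fixed or {})
    unknown = set(fixed) - set(labels)
    if unknown:
        raise ValueError(f"unknown fixed coefficient label(s): {sorted(unknown)}")

    lo, hi = float(lam[0]), float(lam[-1])
    span = hi - lo
    total = float(np.sum(np.abs(y)))
    centroid = float(np.sum(lam * np.abs(y)) / total) if total > 0 else 0.5 * (lo + hi)
    peak = float(np.max(y)) if np.max(y) > 0 else 1.0
    edge = float(max(y[-1], 0.01 * peak))
    if p0 is not None:
        starts = [np.asarray(p0, dtype=float).reshape(n_gauss, 3)]
    else:
        # Deterministic multi-start: a weakly constrained baseline component
        # (center beyond the window) makes single-start fits fall into
        # degenerate local minima for some spectra.
        starts = []
        for w1, a2 in ((span / 4.0, 0.1 * peak), (span / 2.0, edge),
                       (span / 8.0, edge)):
            cand = np.empty((n_gauss, 3))
            cand[0] = (peak, centroid, w1)
            for i in range(1, n_gauss):
                cand[i] = (a2, hi + 0.2 * span * (i - n_gauss + 1), span / 3.0)
            starts.append(cand)

    free_idx = [i for i, lbl in enumerate(labels) if lbl not in fixed]
    full0 = starts[0].ravel().copy()
    for lbl, val in fixed.items():
        full0[labels.index(lbl)] = float(val)
    if not free_idx:
        coeffs = full0.reshape(n_gauss, 3)
        return coeffs, _r_squared(y, _gauss_sum(lam, coeffs)), {}

    lower = np.tile([0.0, lo - 3 * span, DEGENERATE_WIDTH_NM / 10], n_gauss)
    upper = np.tile([200.0, hi + 3 * span, 6 * span], n_gauss)

    best = None
    errors = []
    for cand in starts:
        full = cand.ravel().copy()
        for lbl, val in fixed.items():
            full[labels.index(lbl)] = float(val)

        def residuals(theta: np.ndarray, full=full) -> np.ndarray:
            p = full.copy()
            p[free_idx] = theta
            return _gauss_sum(lam, p.reshape(n_gauss, 3)) - y

        x0 = np.clip(full[free_idx], lower[free_idx], upper[free_idx])
        try:
            res = optimize.least_squares(
                residuals,
                x0,
                bounds=(lower[free_idx], upper[free_idx]),
                method="trf",
                max_nfev=max_nfev,
            )
        except ValueError as exc:
            errors.append(str(exc))
            continue
        if not res.success:
            errors.append(str(res.message))
            continue
        if best is None or res.cost < best[0]:
            solved = full.copy()
            solved[free_idx] = res.x
            best = (res.cost, solved)
    if best is None:
        raise RuntimeError(f"free Gaussian fit did not converge: {errors}")
    coeffs = best[1].reshape(n_gauss, 3)
    if not fixed:
        coeffs = coeffs[np.argsort(coeffs[:, 1])]
    r2 = _r_squared(y, _gauss_sum(lam, coeffs))
    amps = np.abs(coeffs[:, 0])
    flags = {}
    if np.any(coeffs[:, 2] < DEGENERATE_WIDTH_NM):
        flags["degenerate_width"] = True
    if n_gauss > 1 and amps.max() > 0 and amps.min() < 1e-3 * amps.max():
        flags["degenerate_amplitude"] = True
    for i in range(n_gauss):
        for j in range(i + 1, n_gauss):
            # Coincident components split one Gaussian's amplitude
            # arbitrarily; the decomposition is then unidentifiable.
            if (abs(coeffs[i, 1] - coeffs[j, 1]) < DEGENERATE_WIDTH_NM
                    and abs(coeffs[i, 2] - coeffs[j, 2]) < DEGENERATE_WIDTH_NM):
                flags["degenerate_overlap"] = True
    return coeffs, r2, flags


@dataclass
class CoefficientTable:
    """Per-spectrum free-Gaussian coefficients at one fixing iteration."""

    iteration_index: int
    concentrations: np.ndarray  # (n_spectra,)
    coefficients: np.ndarray  # (n_spectra, n_gauss, 3)
    r2: np.ndarray  # (n_spectra,)
    fixed_map: dict[str, float] = field(default_factory=dict)

    def column(self, label: str) -> np.ndarray:
        """Values of one coefficient (by label) across spectra."""
        n_gauss = self.coefficients.shape[1]
        idx = coefficient_labels(n_gauss).index(label)
        return self.coefficients[:, idx // 3, idx % 3]


def _spread_statistic(label: str, values: np.ndarray, window_span: float) -> float:
    """Across-spectra spread used to decide "can be considered constant".

    Amplitudes and widths use the coefficient of variation std/|mean|;
    centers use std divided by the wavelength-window span (their offset is
    arbitrary, so a CV would be meaningless).
    """
    sd = float(np.std(values, ddof=1))
    if label[0] == "b":
        return sd / window_span
    mean = abs(float(np.mean(values)))
    return sd / mean if mean > 0 else np.inf


def iterate_constant_fixing(
    sset: SpectrumSet,
    n_gauss: int = 2,
    cv_threshold: float = 0.05,
    max_iters: int = 8,
    forced_constant: dict[str, float] | None = None,
):
    """Discover which Gaussian coefficients are constants across a set.

    Fits every spectrum freely, then repeatedly fixes the coefficient with
    the smallest across-spectra spread (one per iteration) at its mean, as
    long as that spread is below ``cv_threshold``.  ``forced_constant``
    pre-pins coefficients, reproducing manual choices.

    Returns
    -------
    structure : dict
        Per coefficient label, either ``("constant", value)`` or ``"free"``.
    tables : list of CoefficientTable
        The full audit trail, one table per iteration.
    """
    spectra = list(sset)
    n = len(spectra)
    labels = coefficient_labels(n_gauss)
    if n < len(labels):
        raise ValueError(
            f"need at least {len(labels)} spectra to fit {len(labels)} free "
            f"coefficients, got {n}"
        )
    conc = sset.counter_concentrations()
    if n < 5 or (conc.max() / max(conc.min(), 1e-300)) < 3.0:
        raise ValueError(
            "need >= 5 spectra spanning at least a factor 3 in concentration"
        )
    span = float(
        max(s.wavelengths_nm[-1] for s in spectra)
        - min(s.wavelengths_nm[0] for s in spectra)
    )

    fixed_map: dict[str, float] = dict(forced_constant or {})
    tables: list[CoefficientTable] = []
    prev_coeffs: list[np.ndarray | None] = [None] * n

    for iteration in range(max_iters + 1):
        coeffs = np.empty((n, n_gauss, 3))
        r2 = np.empty(n)
        for i, s in enumerate(spectra):
            coeffs[i], r2[i], _ = fit_free_gaussians(
                s, n_gauss=n_gauss, fixed=fixed_map, p0=prev_coeffs[i]
            )
        if iteration == 0 and n_gauss > 1:
            # Relabel so the component whose amplitude tracks concentration
            # most strongly is component 1 (the rest act as baselines).
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.array(
                    [abs(np.corrcoef(coeffs[:, g, 0], conc)[0, 1])
                     for g in range(n_gauss)]
                )
            order = np.argsort(-np.nan_to_num(corr))
            coeffs = coeffs[:, order, :]
        prev_coeffs = [coeffs[i] for i in range(n)]
        tables.append(
            CoefficientTable(iteration, conc.copy(), coeffs.copy(), r2, dict(fixed_map))
        )
        free = [lbl for lbl in labels if lbl not in fixed_map]
        if not free:
            warnings.warn("all coefficients fixed; spectra carry no concentration "
                          "dependence", stacklevel=2)
            break
        spreads = {
            lbl: _spread_statistic(lbl, tables[-1].column(lbl), span) for lbl in free
        }
        best = min(spreads, key=lambda k: spreads[k])
        if spreads[best] >= cv_threshold or iteration == max_iters:
            break
        fixed_map[best] = float(np.mean(tables[-1].column(best)))

    structure = {
        lbl: ("constant", fixed_map[lbl]) if lbl in fixed_map else "free"
        for lbl in labels
    }
    return structure, tables


def _fit_one_family(family: str, c: np.ndarray, v: np.ndarray):
    """Least-squares fit of one sub-function family; returns (SubFunction, ss_res)."""
    if family == "constant":
        k = float(np.mean(v))
        return SubFunction("constant", (k,)), float(np.sum((v - k) ** 2))
    if family == "log_linear":
        if np.any(c <= 0):
            raise ValueError("log_linear requires C > 0")
        p2, p1 = np.polyfit(np.log10(c), v, 1)
        f = SubFunction("log_linear", (float(p1), float(p2)))
        return f, float(np.sum((v - f(c)) ** 2))
    if family == "power":
        if np.any(v <= 0) or np.any(c <= 0):
            raise ValueError("power fit requires positive data")
        slope, intercept = np.polyfit(np.log10(c), np.log10(v), 1)
        p0 = (10.0 ** intercept, slope)
        popt, _ = optimize.curve_fit(
            lambda cc, p1, p2: p1 * cc ** p2,
            c, v, p0=p0, bounds=([1e-300, -10.0], [np.inf, 10.0]), maxfev=20000,
        )
        f = SubFunction("power", tuple(popt))
        return f, float(np.sum((v - f(c)) ** 2))
    if family == "beer_lambert_amplitude":
        frac = 1.0 - v / 100.0
        ok = (frac > 0) & (frac < 1) & (c > 0)
        if not np.any(ok):
            raise ValueError("beer_lambert_amplitude fit requires values in (0, 100)")
        p0 = float(np.median(-np.log10(frac[ok]) / c[ok]))
        popt, _ = optimize.curve_fit(
            lambda cc, p1: 100.0 * (1.0 - 10.0 ** (-p1 * cc)),
            c, v, p0=max(p0, 1e-300), bounds=(1e-300, np.inf), maxfev=20000,
        )
        f = SubFunction("beer_lambert_amplitude", (float(popt[0]),))
        return f, float(np.sum((v - f(c)) ** 2))
    raise ValueError(f"unknown family {family!r}")


def fit_subfunction_families(
    c,
    values,
    candidates: tuple[str, ...] = SUBFUNCTION_FAMILIES,
    alpha: float = 0.05,
):
    """Select the sub-function family best describing coefficient-vs-C data.

    All candidate families are least-squares fitted.  Families with more
    parameters than the constant must improve on it significantly (partial
    F-test at level ``alpha``) to be eligible -- this keeps parsimony under
    noise, where a richer family always attains a nominally higher R^2.
    Among eligible families the highest R^2 wins; exact ties go to the
    family with fewest parameters, then to family declaration order.

    Returns
    -------
    best : SubFunction
    per_family : dict
        Per family: ``{"r2": float, "subfunction": SubFunction or None,
        "note": str or None, "eligible": bool}``.
    """
    c = np.asarray(c, dtype=float)
    v = np.asarray(values, dtype=float)
    n = c.size
    if n < 3:
        raise ValueError("need at least 3 (C, value) rows")
    ss_tot = float(np.sum((v - np.mean(v)) ** 2))
    ss_const = ss_tot  # the constant fit's residual is the total SS by definition

    per_family: dict[str, dict] = {}
    for fam in candidates:
        entry: dict = {"r2": -np.inf, "subfunction": None, "note": None,
                       "eligible": False}
        try:
            f, ss_res = _fit_one_family(fam, c, v)
        except (ValueError, RuntimeError) as exc:
            entry["note"] = f"skipped: {exc}"
            per_family[fam] = entry
            continue
        if ss_tot == 0.0:
            entry["r2"] = 1.0 if ss_res == 0.0 else -np.inf
        else:
            entry["r2"] = 1.0 - ss_res / ss_tot
        entry["subfunction"] = f
        if f.n_params > 1:
            # Partial F-test of the richer family against the constant.
            df_den = n - f.n_params
            if ss_res == 0.0:
                entry["eligible"] = True
            elif df_den <= 0:
                entry["note"] = "skipped: not enough rows for an F-test"
            else:
                fstat = ((ss_const - ss_res) / (f.n_params - 1)) / (ss_res / df_den)
                pval = float(stats.f.sf(max(fstat, 0.0), f.n_params - 1, df_den))
                entry["eligible"] = pval < alpha
                if not entry["eligible"]:
                    entry["note"] = (
                        f"not significant vs constant (p={pval:.3f} >= {alpha:g})"
                    )
        else:
            entry["eligible"] = True
        per_family[fam] = entry

    eligible = [
        fam for fam in candidates
        if per_family[fam]["eligible"] and per_family[fam]["subfunction"] is not None
    ]
    if not eligible:
        raise RuntimeError("no sub-function family could be fitted")
    best_r2 = max(per_family[fam]["r2"] for fam in eligible)
    tied = [fam for fam in eligible if per_family[fam]["r2"] >= best_r2 - 1e-12]
    tied.sort(key=lambda fam: (per_family[fam]["subfunction"].n_params,
                               SUBFUNCTION_FAMILIES.index(fam)))
    return per_family[tied[0]]["subfunction"], per_family


@dataclass
class CalibrationResult:
    """Outcome of a model calibration.

    ``start_params`` come from the iterated-fitting stage; ``final_params``
    from the global surface minimization, which by construction never
    worsens the summed-squared-error objective.
    """

    model: SpeciesModel
    start_params: np.ndarray
    final_params: np.ndarray
    start_error: float
    final_error: float
    per_spectrum_r2: np.ndarray
    structure: dict | None = None
    iteration_log: list[CoefficientTable] | None = None
    converged: bool = True
    n_evals: int = 0


def _surface_error(lam, conc, y_matrix, model: SpeciesModel) -> float:
    pred = model.evaluate(lam, conc, check_range=False)
    return float(np.sum((pred - y_matrix) ** 2))


def minimize_global_surface(
    sset: SpectrumSet,
    template: SpeciesModel,
    start: np.ndarray | None = None,
    max_evals: int = 10000,
    xtol_rel: float = 1e-6,
    ftol_rel: float = 1e-9,
    n_restarts: int = 1,
) -> CalibrationResult:
    """Jointly refine all model parameters against a calibration surface.

    Minimizes ``sum_lambda sum_C (Abs_model(lambda, C) - spectrum)**2`` with
    a derivative-free Nelder-Mead simplex on parameters scaled by their
    starting magnitudes.  Convergence: relative simplex size below
    ``xtol_rel`` and relative objective change below ``ftol_rel``, or the
    evaluation cap (the result is then flagged not converged).  The returned
    error never exceeds the error at the start vector.
    """
    lam, y = sset.to_matrix()
    conc = sset.counter_concentrations()
    if start is None:
        start = template.parameter_vector()
    start = np.asarray(start, dtype=float)
    if start.size != template.parameter_vector().size:
        raise ValueError("start vector size does not match the template")

    scale = np.where(np.abs(start) > 0, np.abs(start), 1.0)
    penalty = 1e30

    def objective(theta: np.ndarray) -> float:
        try:
            model = template.with_parameter_vector(theta * scale)
            return _surface_error(lam, conc, y, model)
        except (ValueError, ModelValidityError):
            return penalty

    x0 = start / scale
    f0 = objective(x0)
    if not np.isfinite(f0) or f0 >= penalty:
        raise ValueError("objective is not finite at the start vector")

    best_x, best_f = x0, f0
    evals = 0
    converged = True
    for _ in range(max(1, n_restarts + 1)):
        res = optimize.minimize(
            objective,
            best_x,
            method="Nelder-Mead",
            options={
                "maxfev": max(1, max_evals - evals),
                "xatol": xtol_rel,
                "fatol": max(ftol_rel * f0, 1e-10),
                "adaptive": True,
            },
        )
        evals += res.nfev
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
        if evals >= max_evals:
            converged = res.status == 0
            break

    final = best_x * scale
    model = template.with_parameter_vector(final)
    pred = model.evaluate(lam, conc, check_range=False)
    r2 = np.array([_r_squared(y[i], pred[i]) for i in range(y.shape[0])])
    return CalibrationResult(
        model=model,
        start_params=start,
        final_params=final,
        start_error=f0,
        final_error=float(best_f),
        per_spectrum_r2=r2,
        converged=converged,
        n_evals=evals,
    )


def build_template_from_structure(
    name: str,
    structure: dict,
    tables: list[CoefficientTable],
    concentration_range: tuple[float, float],
    wavelength_window: tuple[float, float],
    candidates: tuple[str, ...] = SUBFUNCTION_FAMILIES,
    alpha: float = 0.05,
):
    """Build a start-point SpeciesModel from a discovered structure.

    Constant coefficients become constant sub-functions at their fixed
    values; free coefficients get the best-fitting family over the final
    coefficient table.  Returns ``(model, per_label_family_details)``.
    """
    table = tables[-1]
    n_gauss = table.coefficients.shape[1]
    labels = coefficient_labels(n_gauss)
    subs: dict[str, SubFunction] = {}
    details: dict[str, dict] = {}
    for lbl in labels:
        spec = structure[lbl]
        if spec == "free":
            best, per_family = fit_subfunction_families(
                table.concentrations, table.column(lbl),
                candidates=candidates, alpha=alpha,
            )
            subs[lbl] = best
            details[lbl] = per_family
        else:
            subs[lbl] = SubFunction("constant", (spec[1],))
    comps = tuple(
        GaussianComponent(subs[f"a{i+1}"], subs[f"b{i+1}"], subs[f"c{i+1}"])
        for i in range(n_gauss)
    )
    model = SpeciesModel(
        name=name,
        components=comps,
        concentration_range=concentration_range,
        wavelength_window=wavelength_window,
    )
    return model, details
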