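"""Scikit-learn style estimators wrapping calibration and inversion.

``SpectralShapeRegressor`` is the workhorse: ``fit(X, y)`` calibrates a
Gaussian spectral-shape model from absorption spectra (rows of ``X``) and
their counter concentrations ``y``; ``predict(X)`` inverts spectra for
concentrations.  It composes with sklearn pipelines and model selection.

``MixtureConcentrationRegressor`` holds several calibrated species models
and unmixes spectra into per-species concentrations.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import NotFittedError

from . import calibration as _cal
from . import inversion as _inv
from .models import MixtureModel, SpeciesModel
from .spectra import ABSORPTION, Spectrum, SpectrumSet

__all__ = ["SpectralShapeRegressor", "MixtureConcentrationRegressor"]


def _check_spectra_matrix(X, wavelengths):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise ValueError("X must be a (n_spectra, n_wavelengths) matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if wavelengths is None:
        raise ValueError("wavelengths must be provided (nm grid of X's columns)")
    lam = np.asarray(wavelengths, dtype=float)
    if lam.ndim != 1 or lam.size != X.shape[1]:
        raise ValueError("wavelengths must match the number of columns of X")
    if np.any(np.diff(lam) <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    return X, lam


class SpectralShapeRegressor(RegressorMixin, BaseEstimator):
    """Concentration determination from absorption-spectrum shape.

    Fitting calibrates a species model ``Abs(lambda, C) = sum_i
    a_i(C) exp(-((lambda-b_i(C))/c_i(C))^2)``: per-spectrum free Gaussian
    fits, iterated constant-fixing to discover which coefficients are
    constant, sub-function family selection for the concentration-dependent
    ones, and a global simplex polish of all parameters against the full
    (wavelength x concentration) surface.  Prediction inverts spectra for
    concentration by least-squares shape matching.

    Parameters
    ----------
    n_components : int, default 2
        Number of Gaussian components.
    cv_threshold : float, default 0.05
        Spread threshold under which a coefficient is considered constant
        (coefficient of variation for amplitudes/widths; std over window
        span for centers).
    max_structure_iters : int, default 8
        Cap on constant-fixing iterations.
    subfunction_alpha : float, default 0.05
        Significance level of the parsimony F-gate in family selection.
    template : SpeciesModel or None
        When given, structure discovery is skipped and the template defines
        the model structure (and, with ``start="template"``, the starting
        parameters -- the parameters are still refit to the data).
    start : {"auto", "template"}, default "auto"
        ``auto`` derives starting parameters from per-spectrum fits;
        ``template`` starts the global minimization at the template's
        parameters (requires ``template``).
    forced_constant : dict or None
        Coefficient labels to pin constant a priori (manual structure
        choices), e.g. ``{"b2": 976.9}``.
    max_fun_evals : int, default 10000
        Evaluation cap of the simplex minimization.
    xtol_rel, ftol_rel : float
        Relative simplex-size and objective-change convergence tolerances.
    name : str, default "species"
        Name recorded in the calibrated model.

    Attributes
    ----------
    model_ : SpeciesModel
        The calibrated model.
    calibration_ : CalibrationResult
        Full audit trail (start/final parameters, objective values,
        per-spectrum R^2, iteration log).
    structure_ : dict
        Per-coefficient structure (``("constant", value)`` or ``"free"``).
    wavelengths_ : ndarray
        Wavelength grid of the training spectra (nm).
    """

    def __init__(
        self,
        n_components: int = 2,
        cv_threshold: float = 0.05,
        max_structure_iters: int = 8,
        subfunction_alpha: float = 0.05,
        template: SpeciesModel | None = None,
        start: str = "auto",
        forced_constant: dict | None = None,
        max_fun_evals: int = 10000,
        xtol_rel: float = 1e-6,
        ftol_rel: float = 1e-9,
        name: str = "species",
    ):
        self.n_components = n_components
        self.cv_threshold = cv_threshold
        self.max_structure_iters = max_structure_iters
        self.subfunction_alpha = subfunction_alpha
        self.template = template
        self.start = start
        self.forced_constant = forced_constant
        self.max_fun_evals = max_fun_evals
        self.xtol_rel = xtol_rel
        self.ftol_rel = ftol_rel
        self.name = name

    # ------------------------------------------------------------------
    def fit(self, X, y, wavelengths=None):
        """Calibrate the spectral-shape model.

        Parameters
        ----------
        X : array-like of shape (n_spectra, n_wavelengths)
            Absorption-percent spectra on a common, windowed grid.
        y : array-like of shape (n_spectra,)
            Counter concentrations (cells/mL).
        wavelengths : array-like of shape (n_wavelengths,)
            Wavelength grid in nm.
        """
        X, lam = _check_spectra_matrix(X, wavelengths)
        y = np.asarray(y, dtype=float).ravel()
        if y.size != X.shape[0]:
            raise ValueError("X and y have inconsistent numbers of spectra")
        if np.any(y <= 0):
            raise ValueError("counter concentrations must be positive")

        sset = SpectrumSet(
            [
                Spectrum(lam, X[i], ABSORPTION, counter_concentration=y[i])
                for i in range(X.shape[0])
            ]
        )
        window = (float(lam[0]), float(lam[-1]))
        conc_range = (float(y.min()), float(y.max()))

        if self.start == "template":
            if self.template is None:
                raise ValueError('start="template" requires a template model')
            template = self.template
            structure = None
            tables = None
            start_vec = template.parameter_vector()
        else:
            if self.start != "auto":
                raise ValueError('start must be "auto" or "template"')
            structure, tables = _cal.iterate_constant_fixing(
                sset,
                n_gauss=self.n_components,
                cv_threshold=self.cv_threshold,
                max_iters=self.max_structure_iters,
                forced_constant=self.forced_constant,
            )
            if self.template is not None:
                # Keep the template's families; refit starting values from
                # the per-spectrum coefficient tables.
                template = self._template_with_refit_starts(tables)
            else:
                template, _ = _cal.build_template_from_structure(
                    self.name,
                    structure,
                    tables,
                    concentration_range=conc_range,
                    wavelength_window=window,
                    alpha=self.subfunction_alpha,
                )
            start_vec = template.parameter_vector()

        result = _cal.minimize_global_surface(
            sset,
            template,
            start=start_vec,
            max_evals=self.max_fun_evals,
            xtol_rel=self.xtol_rel,
            ftol_rel=self.ftol_rel,
        )
        result.structure = structure
        result.iteration_log = tables

        model = result.model
        if self.template is not None:
            model = SpeciesModel(
                name=model.name,
                components=model.components,
                concentration_range=self.template.concentration_range,
                wavelength_window=model.wavelength_window,
                validity_floor=self.template.validity_floor,
            )
        else:
            model = SpeciesModel(
                name=self.name,
                components=model.components,
                concentration_range=conc_range,
                wavelength_window=window,
                validity_floor=model.validity_floor,
            )
        self.model_ = model
        self.calibration_ = result
        self.structure_ = structure
        self.wavelengths_ = lam
        self.n_features_in_ = lam.size
        return self

    def _template_with_refit_starts(self, tables):
        """Template families kept; starting params refit from coefficient tables."""
        table = tables[-1]
        labels = _cal.coefficient_labels(self.n_components)
        template = self.template
        if len(template.components) != self.n_components:
            raise ValueError("template component count != n_components")
        from .models import GaussianComponent, SubFunction

        comps = []
        for i, comp in enumerate(template.components):
            subs = []
            for letter, f in zip("abc", (comp.amplitude, comp.center, comp.width)):
                col = table.column(f"{letter}{i + 1}")
                if f.family == "constant":
                    subs.append(SubFunction("constant", (float(np.mean(col)),)))
                else:
                    fitted, _ = _cal._fit_one_family(
                        f.family, table.concentrations, col
                    )
                    subs.append(fitted)
            comps.append(GaussianComponent(*subs))
        return SpeciesModel(
            name=template.name,
            components=tuple(comps),
            concentration_range=template.concentration_range,
            wavelength_window=template.wavelength_window,
            validity_floor=template.validity_floor,
        )

    # ------------------------------------------------------------------
    def predict(self, X):
        """Invert spectra for concentrations (cells/mL)."""
        self._check_is_fitted()
        X, lam = _check_spectra_matrix(X, getattr(self, "wavelengths_", None))
        out = np.empty(X.shape[0])
        for i in range(X.shape[0]):
            est = _inv.estimate_concentration(
                Spectrum(lam, X[i], ABSORPTION), self.model_
            )
            out[i] = est.concentration
        return out

    def predict_estimates(self, X):
        """Like :meth:`predict` but returning full ConcentrationEstimate objects."""
        self._check_is_fitted()
        X, lam = _check_spectra_matrix(X, getattr(self, "wavelengths_", None))
        return [
            _inv.estimate_concentration(Spectrum(lam, X[i], ABSORPTION), self.model_)
            for i in range(X.shape[0])
        ]

    def _check_is_fitted(self):
        if not hasattr(self, "model_"):
            raise NotFittedError(
                "This SpectralShapeRegressor instance is not fitted yet; "
                "call 'fit' first."
            )


class MixtureConcentrationRegressor(BaseEstimator):
    """Unmix spectra of species mixtures into per-species concentrations.

    Parameters
    ----------
    species_models : sequence of SpeciesModel
        Calibrated models sharing one wavelength window.
    starts : int, default 3
        Number of simplex refinement starts per spectrum.
    n_grid_axis : int, default 15
        Coarse-grid resolution per concentration axis.

    Attributes
    ----------
    mixture_ : MixtureModel
    wavelengths_ : ndarray
    """

    def __init__(self, species_models=None, starts: int = 3, n_grid_axis: int = 15):
        self.species_models = species_models
        self.starts = starts
        self.n_grid_axis = n_grid_axis

    def fit(self, X=None, y=None, wavelengths=None):
        """Validate the species models and record the prediction grid."""
        if not self.species_models:
            raise ValueError("species_models must be a non-empty sequence")
        self.mixture_ = MixtureModel(tuple(self.species_models))
        if wavelengths is not None:
            lam = np.asarray(wavelengths, dtype=float)
            if np.any(np.diff(lam) <= 0):
                raise ValueError("wavelengths must be strictly increasing")
            self.wavelengths_ = lam
        elif X is not None:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            lo, hi = self.mixture_.wavelength_window
            self.wavelengths_ = np.linspace(lo, hi, X.shape[1])
        else:
            self.wavelengths_ = None
        return self

    def predict(self, X, wavelengths=None):
        """Per-species concentrations, shape (n_spectra, n_species)."""
        if not hasattr(self, "mixture_"):
            raise NotFittedError(
                "This MixtureConcentrationRegressor instance is not fitted yet; "
                "call 'fit' first."
            )
        lam = wavelengths if wavelengths is not None else self.wavelengths_
        X, lam = _check_spectra_matrix(X, lam)
        out = np.empty((X.shape[0], len(self.mixture_.species)))
        for i in range(X.shape[0]):
            est = _inv.estimate_mixture_concentrations(
                Spectrum(lam, X[i], ABSORPTION),
                self.mixture_,
                starts=self.starts,
                n_grid_axis=self.n_grid_axis,
            )
            out[i] = est.concentrations
        return out
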