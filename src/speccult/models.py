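"""Species spectral-shape models.

A species' white-light absorption spectrum (in percent, i.e. ``100*(1 - T)``
with ``T`` the transmittance) is represented as a sum of Gaussian components
whose coefficients -- amplitude ``a_i`` (%), center ``b_i`` (nm) and width
``c_i`` (nm) -- are themselves scalar functions of the cell concentration
``C`` (cells/mL), here called *sub-functions*:

    Abs(lambda, C) = sum_i a_i(C) * exp(-((lambda - b_i(C)) / c_i(C))**2)

Four sub-function families are supported: a constant, a Beer-Lambert
amplitude ``100*(1 - 10**(-p1*C))``, a power law ``p1*C**p2`` and a
log-linear law ``p1 + p2*log10(C)``.

Mixtures of species follow from the additivity of optical densities:
transmittances multiply, so absorption percentages combine as

    Abs_mix = 100 * (1 - prod_i (1 - Abs_i / 100)).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SUBFUNCTION_FAMILIES",
    "SubFunction",
    "GaussianComponent",
    "SpeciesModel",
    "MixtureModel",
    "ModelValidityError",
    "eval_subfunction",
    "eval_species_model",
    "mix_absorption_spectra",
    "eval_mixture_model",
    "concentration_equivalent_of_absorption_change",
    "load_model",
    "save_model",
    "load_builtin_model",
]

SUBFUNCTION_FAMILIES = ("constant", "beer_lambert_amplitude", "power", "log_linear")

_FAMILY_NPARAMS = {
    "constant": 1,
    "beer_lambert_amplitude": 1,
    "power": 2,
    "log_linear": 2,
}

#: Absorption-percent overshoot tolerated (and clamped) when mixing spectra.
MIX_INPUT_TOLERANCE = 1e-6


class ModelValidityError(ValueError):
    """A model evaluated outside its domain of validity (e.g. width <= 0)."""


@dataclass(frozen=True)
class SubFunction:
    """A scalar function of concentration parameterizing one Gaussian coefficient.

    Parameters
    ----------
    family : str
        One of ``constant``, ``beer_lambert_amplitude``, ``power``,
        ``log_linear``.
    params : tuple of float
        ``constant``: ``(k,)``; ``beer_lambert_amplitude``: ``(p1,)`` with
        ``f(C) = 100*(1 - 10**(-p1*C))``; ``power``: ``(p1, p2)`` with
        ``f(C) = p1*C**p2``; ``log_linear``: ``(p1, p2)`` with
        ``f(C) = p1 + p2*log10(C)``.
    """

    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family not in SUBFUNCTION_FAMILIES:
            raise ValueError(
                f"unknown sub-function family {self.family!r}; "
                f"expected one of {SUBFUNCTION_FAMILIES}"
            )
        params = tuple(float(p) for p in self.params)
        object.__setattr__(self, "params", params)
        expected = _FAMILY_NPARAMS[self.family]
        if len(params) != expected:
            raise ValueError(
                f"family {self.family!r} takes {expected} parameter(s), "
                f"got {len(params)}"
            )
        if self.family == "beer_lambert_amplitude" and params[0] <= 0:
            raise ValueError("beer_lambert_amplitude requires p1 > 0")
        if self.family == "power" and params[0] <= 0:
            raise ValueError("power requires p1 > 0")

    @property
    def n_params(self) -> int:
        return _FAMILY_NPARAMS[self.family]

    def __call__(self, c):
        """Evaluate at concentration(s) ``c`` (cells/mL)."""
        c = np.asarray(c, dtype=float)
        if self.family == "constant":
            return np.broadcast_to(np.float64(self.params[0]), c.shape).copy() if c.shape else np.float64(self.params[0])
        if self.family == "beer_lambert_amplitude":
            return 100.0 * (1.0 - 10.0 ** (-self.params[0] * c))
        if self.family == "power":
            return self.params[0] * c ** self.params[1]
        # log_linear
        if np.any(c <= 0):
            raise ValueError("log_linear sub-function requires C > 0")
        return self.params[0] + self.params[1] * np.log10(c)

    def with_params(self, params: Sequence[float]) -> "SubFunction":
        return SubFunction(self.family, tuple(params))

    def to_dict(self) -> dict:
        return {"family": self.family, "params": list(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "SubFunction":
        return cls(d["family"], tuple(d["params"]))


def eval_subfunction(f: SubFunction, c) -> float:
    """Functional alias for :meth:`SubFunction.__call__`."""
    return f(c)


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian of a species model: amplitude (%), center (nm), width (nm)."""

    amplitude: SubFunction
    center: SubFunction
    width: SubFunction

    def evaluate(self, wavelengths_nm, c):
        """Evaluate the component on a wavelength grid.

        Returns shape ``(len(wavelengths),)`` for scalar ``c`` and
        ``(len(c), len(wavelengths))`` for a vector of concentrations.
        """
        lam = np.asarray(wavelengths_nm, dtype=float)
        scalar = np.isscalar(c) or np.ndim(c) == 0
        c_arr = np.atleast_1d(np.asarray(c, dtype=float))
        amp = np.atleast_1d(self.amplitude(c_arr))
        ctr = np.atleast_1d(self.center(c_arr))
        wid = np.atleast_1d(self.width(c_arr))
        if np.any(~np.isfinite(amp)):
            raise ModelValidityError("evaluated amplitude is not finite")
        # A vanished amplitude makes the component contribute nothing, so
        # its (then meaningless) width is not checked -- e.g. a Beer-Lambert
        # amplitude and a power-law width both collapse to 0 at C = 0.
        if np.any((wid <= 0) & (amp != 0)):
            raise ModelValidityError("evaluated Gaussian width must be > 0")
        safe_wid = np.where(wid > 0, wid, 1.0)
        out = amp[:, None] * np.exp(
            -(((lam[None, :] - ctr[:, None]) / safe_wid[:, None]) ** 2)
        )
        return out[0] if scalar else out

    @property
    def is_concentration_dependent(self) -> bool:
        return any(
            f.family != "constant" for f in (self.amplitude, self.center, self.width)
        )

    def to_dict(self) -> dict:
        return {
            "amplitude": self.amplitude.to_dict(),
            "center": self.center.to_dict(),
            "width": self.width.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianComponent":
        return cls(
            SubFunction.from_dict(d["amplitude"]),
            SubFunction.from_dict(d["center"]),
            SubFunction.from_dict(d["width"]),
        )


@dataclass(frozen=True)
class SpeciesModel:
    """Gaussian-sum spectral-shape model of one species.

    Attributes
    ----------
    name : str
        Species label.
    components : tuple of GaussianComponent
        Ordered components; by convention component 1 is the
        concentration-sensitive Gaussian and the last one acts as a
        near-infrared baseline.
    concentration_range : (float, float)
        Calibrated concentration range in cells/mL; evaluation outside it is
        an extrapolation and triggers a warning.
    wavelength_window : (float, float)
        Wavelength window (nm) over which the model was calibrated.
    validity_floor : float or None
        Concentration below which the species is taken to contribute zero
        absorption.  Used for models (e.g. log-linear amplitudes) that are
        meaningless as C -> 0; ``None`` disables the floor.
    """

    name: str
    components: tuple[GaussianComponent, ...]
    concentration_range: tuple[float, float]
    wavelength_window: tuple[float, float] = (330.0, 860.0)
    validity_floor: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        lo, hi = self.concentration_range
        if not (0 <= lo < hi):
            raise ValueError("concentration_range must satisfy 0 <= C_min < C_max")
        wlo, whi = self.wavelength_window
        if not wlo < whi:
            raise ValueError("wavelength_window must satisfy lo < hi")
        if not self.components:
            raise ValueError("a SpeciesModel needs at least one component")

    # ---- evaluation -----------------------------------------------------
    def evaluate(self, wavelengths_nm, c, check_range: bool = True):
        """Absorption-percent spectrum at concentration(s) ``c``.

        Returns shape ``(L,)`` for scalar ``c``, ``(n_c, L)`` for vector ``c``.
        Concentrations below ``validity_floor`` contribute zero.
        """
        lam = np.asarray(wavelengths_nm, dtype=float)
        scalar = np.isscalar(c) or np.ndim(c) == 0
        c_arr = np.atleast_1d(np.asarray(c, dtype=float))
        if np.any(c_arr < 0):
            raise ValueError("concentration must be >= 0")
        if check_range:
            lo, hi = self.concentration_range
            if np.any((c_arr < lo) | (c_arr > hi)):
                warnings.warn(
                    f"model {self.name!r} evaluated outside its calibrated "
                    f"concentration range [{lo:g}, {hi:g}] (extrapolation)",
                    stacklevel=2,
                )
        out = np.zeros((c_arr.size, lam.size))
        if self.validity_floor is not None:
            active = c_arr >= self.validity_floor
        else:
            active = np.ones(c_arr.size, dtype=bool)
        if np.any(active):
            acc = np.zeros((int(active.sum()), lam.size))
            for comp in self.components:
                acc += comp.evaluate(lam, c_arr[active])
            out[active] = acc
        return out[0] if scalar else out

    def default_grid(self, step_nm: float = 0.22) -> np.ndarray:
        lo, hi = self.wavelength_window
        return np.arange(lo, hi + step_nm / 2, step_nm)

    @property
    def center_concentration(self) -> float:
        """Midpoint of the calibrated concentration range (cells/mL)."""
        lo, hi = self.concentration_range
        return 0.5 * (lo + hi)

    # ---- flat parameter vector (calibration interface) ------------------
    def parameter_vector(self) -> np.ndarray:
        """All scalar parameters, flattened in component order
        (amplitude, center, width per component)."""
        out: list[float] = []
        for comp in self.components:
            for f in (comp.amplitude, comp.center, comp.width):
                out.extend(f.params)
        return np.asarray(out, dtype=float)

    def with_parameter_vector(self, vec: Sequence[float]) -> "SpeciesModel":
        """Rebuild the model with the same structure but new parameters."""
        vec = np.asarray(vec, dtype=float)
        if vec.size != self.parameter_vector().size:
            raise ValueError(
                f"parameter vector has size {vec.size}, expected "
                f"{self.parameter_vector().size}"
            )
        i = 0
        comps = []
        for comp in self.components:
            subs = []
            for f in (comp.amplitude, comp.center, comp.width):
                subs.append(f.with_params(vec[i : i + f.n_params]))
                i += f.n_params
            comps.append(GaussianComponent(*subs))
        return replace(self, components=tuple(comps))

    def parameter_labels(self) -> list[str]:
        """Human-readable labels matching :meth:`parameter_vector` order."""
        labels = []
        for i, comp in enumerate(self.components, start=1):
            for letter, f in zip("abc", (comp.amplitude, comp.center, comp.width)):
                if f.n_params == 1:
                    labels.append(f"{letter}{i}")
                else:
                    labels.extend(f"p{j + 1}{letter}{i}" for j in range(f.n_params))
        return labels

    # ---- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "wavelength_window": list(self.wavelength_window),
            "concentration_range": list(self.concentration_range),
            "components": [c.to_dict() for c in self.components],
        }
        if self.validity_floor is not None:
            d["validity_floor"] = self.validity_floor
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SpeciesModel":
        return cls(
            name=d["name"],
            components=tuple(GaussianComponent.from_dict(c) for c in d["components"]),
            concentration_range=tuple(d["concentration_range"]),
            wavelength_window=tuple(d["wavelength_window"]),
            validity_floor=d.get("validity_floor"),
        )


@dataclass(frozen=True)
class MixtureModel:
    """Several species models sharing one wavelength window."""

    species: tuple[SpeciesModel, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        if not self.species:
            raise ValueError("a MixtureModel needs at least one species")
        windows = {s.wavelength_window for s in self.species}
        if len(windows) != 1:
            raise ValueError(
                f"all species must share one wavelength window, got {windows}"
            )

    @property
    def wavelength_window(self) -> tuple[float, float]:
        return self.species[0].wavelength_window

    def evaluate(self, wavelengths_nm, concentrations, check_range: bool = False):
        """Mixture absorption-percent spectrum (one concentration per species)."""
        return eval_mixture_model(self, wavelengths_nm, concentrations,
                                  check_range=check_range)


def eval_species_model(m: SpeciesModel, wavelengths_nm, c, check_range: bool = True):
    """Functional alias for :meth:`SpeciesModel.evaluate`."""
    return m.evaluate(wavelengths_nm, c, check_range=check_range)


def mix_absorption_spectra(spectra: Iterable[np.ndarray], tolerance: float = MIX_INPUT_TOLERANCE):
    """Combine absorption-percent spectra of independent species.

    Transmittances multiply, hence
    ``Abs_mix = 100*(1 - prod_i (1 - Abs_i/100))`` pointwise.  All inputs
    must share one wavelength grid and lie in [0, 100] (small excursions up
    to ``tolerance`` are clamped).
    """
    arrays = [np.asarray(a, dtype=float) for a in spectra]
    if not arrays:
        raise ValueError("need at least one spectrum to mix")
    shape = arrays[0].shape
    for a in arrays:
        if a.shape != shape:
            raise ValueError("all spectra must share one wavelength grid")
        if np.any(a < -tolerance) or np.any(a > 100.0 + tolerance):
            bad = a[(a < -tolerance) | (a > 100.0 + tolerance)]
            raise ValueError(
                f"absorption values outside [0, 100] beyond tolerance "
                f"(e.g. {bad.flat[0]:.6g}%)"
            )
    trans = np.ones(shape)
    for a in arrays:
        trans *= 1.0 - np.clip(a, 0.0, 100.0) / 100.0
    return 100.0 * (1.0 - trans)


def eval_mixture_model(mm: MixtureModel, wavelengths_nm, concentrations,
                       check_range: bool = False):
    """Evaluate a mixture model at one concentration per species.

    Per-species spectra are clamped to [0, 100] before mixing (a warning is
    emitted on clamping beyond tolerance), since the OD-additivity law only
    guarantees outputs within [0, 100] for inputs within [0, 100].
    """
    conc = np.atleast_1d(np.asarray(concentrations, dtype=float))
    if conc.size != len(mm.species):
        raise ValueError(
            f"got {conc.size} concentrations for {len(mm.species)} species"
        )
    lam = np.asarray(wavelengths_nm, dtype=float)
    parts = []
    for sp, c in zip(mm.species, conc):
        vals = sp.evaluate(lam, float(c), check_range=check_range)
        if np.any(vals < -0.5) or np.any(vals > 100.5):
            warnings.warn(
                f"species {sp.name!r} spectrum clamped to [0, 100] before mixing",
                stacklevel=2,
            )
        parts.append(np.clip(vals, 0.0, 100.0))
    return mix_absorption_spectra(parts)


def concentration_equivalent_of_absorption_change(
    m: SpeciesModel,
    wavelength_nm: float,
    c: float,
    delta_abs: float,
    rel_tol: float = 1e-6,
) -> float:
    """Concentration change equivalent to an absorption change at one wavelength.

    Solves ``Abs(lambda, C') = Abs(lambda, C) + delta_abs`` for ``C'`` by
    bracketed root finding over ``[C_min/2, 2*C_max]`` and returns
    ``C' - C``.  This is the model's sensitivity converter: e.g. a cuvette-
    to-cuvette absorption spread expressed in cells/mL.
    """
    if delta_abs == 0.0:
        return 0.0
    lam = np.asarray([float(wavelength_nm)])
    lo, hi = m.concentration_range
    a, b = lo / 2.0, 2.0 * hi

    def g(cc: float) -> float:
        return float(m.evaluate(lam, cc, check_range=False)[0]) - target

    base = float(m.evaluate(lam, float(c), check_range=False)[0])
    target = base + float(delta_abs)
    ga, gb = g(a), g(b)
    if ga * gb > 0:
        span = sorted((ga + target, gb + target))
        raise ValueError(
            f"target absorption {target:.4g}% not attainable within the search "
            f"bracket; attainable range at {wavelength_nm:g} nm is "
            f"[{span[0]:.4g}%, {span[1]:.4g}%]"
        )
    c_prime = brentq(g, a, b, rtol=rel_tol)
    return float(c_prime - c)


# ---- model files ---------------------------------------------------------

def save_model(m: SpeciesModel, path) -> None:
    """Write a species model to a JSON file (round-trips exactly)."""
    with open(path, "w") as fh:
        json.dump(m.to_dict(), fh, indent=2)
        fh.write("\n")


def load_model(path) -> SpeciesModel:
    """Read a species model from a JSON file."""
    with open(path) as fh:
        return SpeciesModel.from_dict(json.load(fh))


def load_builtin_model(name: str) -> SpeciesModel:
    """Load one of the shipped calibrated models.

    ``cem_table2`` -- CEM T lymphoblasts (Beer-Lambert amplitude + power
    width on Gaussian 1, constant baseline Gaussian).
    ``ca_table3`` -- *Candida albicans* (log-linear amplitudes and center).
    """
    ref = resources.files("speccult.data").joinpath(f"{name}.json")
    with ref.open() as fh:
        return SpeciesModel.from_dict(json.load(fh))
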