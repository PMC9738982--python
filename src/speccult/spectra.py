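"""Spectrum containers, format I/O and preprocessing.

Spectra are series of (wavelength nm, value) pairs where the value is either
a transmittance fraction in [0, 1] or an absorption percentage
``100*(1 - T)`` in [0, 100].  Preprocessing follows the usual white-light
cuvette workflow: window to the informative wavelength band (default
330-860 nm), numerically remove deuterium-lamp emission artifacts, clip
small reference-subtraction negatives, and reject badly shaped spectra with
a free two-Gaussian fit quality heuristic.

Two plain-text formats are supported and round-trip bit-exactly:

* ``two_column_text`` -- one spectrum per file, ``# key=value`` header lines
  followed by whitespace-separated ``wavelength value`` rows;
* ``wide_csv`` -- first column ``wavelength`` (its header may embed
  ``;value_kind=...``), one column per spectrum whose header embeds
  ``id;key=value;...`` metadata.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRANSMITTANCE",
    "ABSORPTION",
    "Spectrum",
    "SpectrumSet",
    "ParseError",
    "read_spectra",
    "write_spectra",
    "convert_value_kind",
    "window_spectrum",
    "remove_lamp_artifacts",
    "clip_small_negatives",
    "quality_filter",
    "resample_to_common_grid",
    "DEFAULT_WINDOW",
    "DEFAULT_ARTIFACT_MASKS",
]

logger = logging.getLogger(__name__)

TRANSMITTANCE = "transmittance_fraction"
ABSORPTION = "absorption_percent"
_VALUE_KINDS = (TRANSMITTANCE, ABSORPTION)

#: Default informative wavelength band (nm).
DEFAULT_WINDOW = (330.0, 860.0)

#: Default deuterium-lamp artifact masks (nm): the H-beta (486.1 nm) and
#: H-alpha (656.3 nm) Balmer emission lines.
DEFAULT_ARTIFACT_MASKS = ((484.0, 488.0), (654.0, 658.0))

# Metadata keys serialized in file headers, in a fixed order.
_META_KEYS = ("species", "concentration", "set", "time", "cuvette", "true")


class ParseError(ValueError):
    """A spectrum file could not be parsed."""


@dataclass(frozen=True)
class Spectrum:
    """One spectrum on a strictly ascending wavelength grid.

    ``counter_concentration`` is the reference concentration from an
    automated cell counter (cells/mL), itself a noisy measurement;
    synthetic spectra additionally carry the exact generating concentration
    in ``extra["true_concentration"]``.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    value_kind: str
    species: str | None = None
    counter_concentration: float | None = None
    time_h: float | None = None
    set_id: str | None = None
    cuvette_id: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", lam)
        object.__setattr__(self, "values", vals)
        if lam.ndim != 1 or vals.ndim != 1:
            raise ValueError("wavelengths and values must be one-dimensional")
        if lam.size != vals.size:
            raise ValueError(
                f"length mismatch: {lam.size} wavelengths, {vals.size} values"
            )
        if lam.size == 0:
            raise ValueError("empty spectrum")
        if np.any(np.diff(lam) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.value_kind not in _VALUE_KINDS:
            raise ValueError(
                f"unknown value_kind {self.value_kind!r}; expected one of "
                f"{_VALUE_KINDS}"
            )

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    def validate_values(self, tolerance: float = 1.0) -> None:
        """Check the value-range invariant for the spectrum's kind.

        Transmittance fractions must lie in [0, 1]; absorption percentages
        in [-tolerance, 100] (the tolerance admits reference-subtracted
        noise dipping below zero).
        """
        v = self.values
        if self.value_kind == TRANSMITTANCE:
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError("transmittance values must lie in [0, 1]")
        else:
            if np.any(v < -tolerance) or np.any(v > 100.0):
                raise ValueError(
                    f"absorption values must lie in [-{tolerance:g}, 100]"
                )


@dataclass
class SpectrumSet:
    """An ordered collection of spectra."""

    spectra: list[Spectrum]

    def __post_init__(self) -> None:
        self.spectra = list(self.spectra)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return SpectrumSet(self.spectra[i])
        return self.spectra[i]

    @property
    def common_grid(self) -> bool:
        """True when all members share a bitwise-identical wavelength grid."""
        if not self.spectra:
            return True
        first = self.spectra[0].wavelengths_nm
        return all(
            s.wavelengths_nm.shape == first.shape
            and np.array_equal(s.wavelengths_nm, first)
            for s in self.spectra
        )

    def to_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(wavelengths, values)`` with values shaped (n_spectra, n_wl)."""
        if not self.spectra:
            raise ValueError("empty SpectrumSet")
        if not self.common_grid:
            raise ValueError(
                "spectra are not on a common grid; resample_to_common_grid first"
            )
        lam = self.spectra[0].wavelengths_nm
        return lam, np.vstack([s.values for s in self.spectra])

    def counter_concentrations(self) -> np.ndarray:
        out = []
        for s in self.spectra:
            if s.counter_concentration is None:
                raise ValueError("a spectrum is missing its counter concentration")
            out.append(s.counter_concentration)
        return np.asarray(out, dtype=float)


# ---- conversions and preprocessing --------------------------------------

def convert_value_kind(s: Spectrum, target: str) -> Spectrum:
    """Convert between transmittance fraction and absorption percent.

    ``Abs = 100*(1 - T)`` and ``T = 1 - Abs/100``; the round trip is exact
    to machine precision.  Converting to the current kind is a no-op with a
    warning.
    """
    if target not in _VALUE_KINDS:
        raise ValueError(f"unknown value_kind {target!r}")
    if target == s.value_kind:
        warnings.warn(
            f"spectrum already has value_kind {target!r}; returning unchanged",
            stacklevel=2,
        )
        return s
    if target == ABSORPTION:
        vals = 100.0 * (1.0 - s.values)
    else:
        vals = 1.0 - s.values / 100.0
    return replace(s, values=vals, value_kind=target)


def window_spectrum(s: Spectrum, lo_nm: float = DEFAULT_WINDOW[0],
                    hi_nm: float = DEFAULT_WINDOW[1]) -> Spectrum:
    """Keep samples with ``lo_nm <= lambda <= hi_nm`` (inclusive)."""
    if not lo_nm < hi_nm:
        raise ValueError("window requires lo < hi")
    keep = (s.wavelengths_nm >= lo_nm) & (s.wavelengths_nm <= hi_nm)
    if not np.any(keep):
        raise ValueError(
            f"window [{lo_nm:g}, {hi_nm:g}] nm contains no samples "
            f"(grid spans [{s.wavelengths_nm[0]:g}, {s.wavelengths_nm[-1]:g}])"
        )
    return replace(s, wavelengths_nm=s.wavelengths_nm[keep], values=s.values[keep])


def remove_lamp_artifacts(
    s: Spectrum, mask_windows: Sequence[tuple[float, float]] = DEFAULT_ARTIFACT_MASKS
) -> Spectrum:
    """Replace samples inside the mask windows by linear interpolation.

    Masks are inclusive; interpolation anchors on the nearest unmasked
    neighbours, so a mask covering either grid end is an error.
    """
    lam = s.wavelengths_nm
    masked = np.zeros(lam.size, dtype=bool)
    for lo, hi in mask_windows:
        masked |= (lam >= lo) & (lam <= hi)
    if not np.any(masked):
        return s
    if masked[0] or masked[-1]:
        raise ValueError("artifact mask covers a grid end; no interpolation anchor")
    vals = s.values.copy()
    vals[masked] = np.interp(lam[masked], lam[~masked], s.values[~masked])
    return replace(s, values=vals)


def clip_small_negatives(s: Spectrum, tolerance: float = 1.0) -> Spectrum:
    """Clip absorption values in ``[-tolerance, 0)`` to zero.

    Reference-subtracted noise can dip slightly below zero; values below
    ``-tolerance`` indicate a real problem and raise instead.
    """
    if s.value_kind != ABSORPTION:
        raise ValueError("clip_small_negatives expects an absorption spectrum")
    if np.any(s.values < -tolerance):
        raise ValueError(
            f"absorption values below -{tolerance:g}% present; spectrum invalid"
        )
    neg = s.values < 0
    if not np.any(neg):
        return s
    logger.info("clipped %d negative absorption values to 0", int(neg.sum()))
    vals = s.values.copy()
    vals[neg] = 0.0
    return replace(s, values=vals)


def quality_filter(
    sset: SpectrumSet, r2_threshold: float = 0.9, tolerance: float = 1.0
) -> tuple[SpectrumSet, SpectrumSet]:
    """Split a set into (kept, rejected) by spectral-shape quality.

    A spectrum is kept when a free two-Gaussian fit attains
    ``R^2 >= r2_threshold`` and its values satisfy the range invariant.
    Rejected spectra carry their reason in ``extra["rejection_reason"]``.
    """
    from .calibration import fit_free_gaussians  # local import avoids a cycle

    kept, rejected = [], []
    for s in sset:
        reason = None
        try:
            s.validate_values(tolerance=tolerance)
        except ValueError as exc:
            reason = f"invariant violation: {exc}"
        if reason is None and r2_threshold > 0:
            try:
                _, r2, _ = fit_free_gaussians(s, n_gauss=2)
            except RuntimeError as exc:
                r2, reason = -np.inf, f"fit failed: {exc}"
            if reason is None and r2 < r2_threshold:
                reason = f"free two-Gaussian fit R2={r2:.4f} < {r2_threshold:g}"
        if reason is None:
            kept.append(s)
        else:
            rejected.append(replace(s, extra={**s.extra, "rejection_reason": reason}))
    return SpectrumSet(kept), SpectrumSet(rejected)


def resample_to_common_grid(sset: SpectrumSet) -> SpectrumSet:
    """Linearly interpolate all spectra onto the first spectrum's grid.

    Grids whose coverage differs by more than 1 nm at either end are
    rejected rather than extrapolated.
    """
    if not sset.spectra:
        return sset
    if sset.common_grid:
        return sset
    ref = sset.spectra[0].wavelengths_nm
    out = [sset.spectra[0]]
    for s in sset.spectra[1:]:
        lam = s.wavelengths_nm
        if abs(lam[0] - ref[0]) > 1.0 or abs(lam[-1] - ref[-1]) > 1.0:
            raise ValueError(
                "grid coverage differs by more than 1 nm; refusing to resample"
            )
        vals = np.interp(ref, lam, s.values)
        out.append(replace(s, wavelengths_nm=ref.copy(), values=vals))
    return SpectrumSet(out)


# ---- metadata (de)serialization ------------------------------------------

def _meta_to_pairs(s: Spectrum) -> list[tuple[str, str]]:
    pairs = []
    if s.species is not None:
        pairs.append(("species", s.species))
    if s.counter_concentration is not None:
        pairs.append(("concentration", repr(float(s.counter_concentration))))
    if s.set_id is not None:
        pairs.append(("set", s.set_id))
    if s.time_h is not None:
        pairs.append(("time", repr(float(s.time_h))))
    if s.cuvette_id is not None:
        pairs.append(("cuvette", s.cuvette_id))
    if "true_concentration" in s.extra:
        pairs.append(("true", repr(float(s.extra["true_concentration"]))))
    return pairs


def _meta_from_dict(d: dict) -> dict:
    out: dict = {"extra": {}}
    if "species" in d:
        out["species"] = str(d["species"])
    if "concentration" in d:
        out["counter_concentration"] = float(d["concentration"])
    if "set" in d:
        out["set_id"] = str(d["set"])
    if "time" in d:
        out["time_h"] = float(d["time"])
    if "cuvette" in d:
        out["cuvette_id"] = str(d["cuvette"])
    if "true" in d:
        out["extra"]["true_concentration"] = float(d["true"])
    return out


# ---- two-column text format ----------------------------------------------

def _write_two_column(s: Spectrum, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# value_kind={s.value_kind}\n")
        for k, v in _meta_to_pairs(s):
            fh.write(f"# {k}={v}\n")
        for lam, val in zip(s.wavelengths_nm, s.values):
            fh.write(f"{float(lam)!r} {float(val)!r}\n")


def _read_two_column(path: Path) -> Spectrum:
    meta: dict = {}
    lams: list[float] = []
    vals: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, _, v = body.partition("=")
                    meta[k.strip()] = v.strip()
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                lams.append(float(parts[0]))
                vals.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            side = json.load(fh)
        for k, v in side.items():
            meta.setdefault(k, v)
    if "value_kind" not in meta:
        raise ValueError(f"{path}: missing required value_kind header/sidecar field")
    kwargs = _meta_from_dict(meta)
    try:
        return Spectrum(np.asarray(lams), np.asarray(vals), meta["value_kind"], **kwargs)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


# ---- wide CSV format ------------------------------------------------------

def _write_wide_csv(sset: SpectrumSet, path: Path) -> None:
    if not sset.spectra:
        raise ValueError("cannot write an empty SpectrumSet")
    if not sset.common_grid:
        raise ValueError("wide CSV requires spectra on a common grid")
    kinds = {s.value_kind for s in sset}
    if len(kinds) != 1:
        raise ValueError("wide CSV requires a single value_kind across spectra")
    (kind,) = kinds
    headers = [f"wavelength;value_kind={kind}"]
    for i, s in enumerate(sset):
        ident = s.cuvette_id or f"s{i}"
        parts = [ident] + [f"{k}={v}" for k, v in _meta_to_pairs(s)]
        headers.append(";".join(parts))
    lam = sset.spectra[0].wavelengths_nm
    with open(path, "w") as fh:
        fh.write(",".join(headers) + "\n")
        cols = [s.values for s in sset]
        for j in range(lam.size):
            row = [repr(float(lam[j]))] + [repr(float(c[j])) for c in cols]
            fh.write(",".join(row) + "\n")


def _read_wide_csv(path: Path) -> SpectrumSet:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from None
    if df.shape[1] < 2:
        raise ParseError(f"{path}: wide CSV needs a wavelength column plus spectra")
    if df.isna().any().any():
        bad = int(np.argwhere(df.isna().values)[0][0]) + 2  # +header +1-based
        raise ParseError(f"{path}: malformed row at line {bad}")

    sidecar = Path(str(path) + ".json")
    side: dict = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            side = json.load(fh)

    def split_header(h: str) -> tuple[str, dict]:
        parts = h.split(";")
        meta = {}
        for p in parts[1:]:
            if "=" in p:
                k, _, v = p.partition("=")
                meta[k.strip()] = v.strip()
        return parts[0].strip(), meta

    wl_name, wl_meta = split_header(df.columns[0])
    value_kind = wl_meta.get("value_kind") or side.get("value_kind")
    if value_kind is None:
        raise ValueError(
            f"{path}: missing required value_kind (header-embedded or sidecar)"
        )
    lam = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(np.diff(lam) <= 0):
        raise ValueError(f"{path}: wavelengths must be strictly increasing")

    spectra = []
    col_side = side.get("columns", {})
    for col in df.columns[1:]:
        ident, meta = split_header(col)
        merged = {**col_side.get(ident, {}), **meta}
        kwargs = _meta_from_dict(merged)
        kwargs.setdefault("cuvette_id", ident)
        spectra.append(
            Spectrum(lam.copy(), df[col].to_numpy(dtype=float), value_kind, **kwargs)
        )
    return SpectrumSet(spectra)


# ---- public I/O -----------------------------------------------------------

def read_spectra(path, format: str) -> SpectrumSet:
    """Read spectra from ``path`` in the given format.

    ``two_column_text`` holds one spectrum per file; ``wide_csv`` holds one
    column per spectrum on a shared wavelength grid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "two_column_text":
        return SpectrumSet([_read_two_column(path)])
    if format == "wide_csv":
        return _read_wide_csv(path)
    raise ValueError(f"unknown format {format!r}")


def write_spectra(sset: SpectrumSet, path, format: str) -> None:
    """Write spectra to ``path``; the result round-trips bit-exactly."""
    path = Path(path)
    if format == "two_column_text":
        if len(sset) != 1:
            raise ValueError("two_column_text holds exactly one spectrum per file")
        _write_two_column(sset[0], path)
    elif format == "wide_csv":
        _write_wide_csv(sset, path)
    else:
        raise ValueError(f"unknown format {format!r}")
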