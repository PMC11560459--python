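"""In-memory containers for spectra and trait tables.

A :class:`SpectraSet` is a dense samples x wavebands reflectance matrix on a
strictly ascending wavelength grid (nm); a :class:`TraitTable` is a
pandas-backed table of named foliar traits with physical units (``%`` for
nitrogen and moisture content, ``ug/g`` for the mineral elements).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataError, InvalidGridError

_TRAIT_HEADER = re.compile(r"^(?P<name>[^\[\]]+)\[(?P<unit>[^\[\]]*)\]$")


@dataclass
class SpectraSet:
    """Reflectance spectra for a set of leaf samples.

    Parameters
    ----------
    sample_ids:
        Unique sample labels, one per spectrum.
    wavelengths:
        Strictly ascending wavelength grid in nm.
    reflectance:
        ``(n_samples, n_wavelengths)`` matrix with values in ``[0, 1]``.
    """

    sample_ids: np.ndarray
    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        if self.wavelengths.ndim != 1 or self.wavelengths.size == 0:
            raise InvalidGridError("wavelength grid must be a non-empty 1-D array")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise InvalidGridError("wavelength grid must be strictly ascending")
        n, p = self.reflectance.shape
        if n != self.sample_ids.size:
            raise DataError(
                f"reflectance has {n} rows but {self.sample_ids.size} sample ids"
            )
        if p != self.wavelengths.size:
            raise DataError(
                f"reflectance has {p} columns but {self.wavelengths.size} wavelengths"
            )
        ids, counts = np.unique(self.sample_ids, return_counts=True)
        if np.any(counts > 1):
            raise DataError(f"duplicated sample ids: {list(ids[counts > 1])}")
        if not np.all(np.isfinite(self.reflectance)):
            raise DataError("reflectance contains non-finite values")
        if self.reflectance.size and (
            self.reflectance.min() < 0.0 or self.reflectance.max() > 1.0
        ):
            raise DataError("reflectance values outside [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.reflectance.shape[1]

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the waveband closest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))

    def to_frame(self) -> pd.DataFrame:
        cols = [_format_wavelength(w) for w in self.wavelengths]
        frame = pd.DataFrame(self.reflectance, columns=cols)
        frame.insert(0, "sample_id", self.sample_ids)
        return frame

    def to_csv(self, path) -> None:
        """Write the spectra CSV dialect (first column ``sample_id``, one
        column per waveband named by its wavelength in nm)."""
        self.to_frame().to_csv(path, index=False)


def _format_wavelength(w: float) -> str:
    return str(int(round(w))) if float(w).is_integer() else repr(float(w))


@dataclass
class TraitTable:
    """Named foliar traits for a set of samples.

    ``data`` is indexed by sample id with one numeric column per trait;
    ``units`` maps each trait name to its unit string. Missing cells (NaN)
    are tolerated and handled per-trait downstream. Non-positive trait
    values are physically implausible for the traits modelled here and
    trigger a warning; strict rejection is applied at file ingestion.
    """

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise DataError("TraitTable.data must be a pandas DataFrame")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DataError(f"duplicated sample ids: {dup}")
        self.data = self.data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.index.name = "sample_id"
        missing_units = [c for c in self.data.columns if c not in self.units]
        self.units = {c: self.units.get(c, "") for c in self.data.columns}
        if missing_units:
            warnings.warn(f"traits without units: {missing_units}", stacklevel=2)
        vals = self.data.to_numpy()
        with np.errstate(invalid="ignore"):
            if np.any(vals <= 0):
                warnings.warn("trait table contains non-positive values", stacklevel=2)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.data.index.to_numpy(dtype=str)

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def trait(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise DataError(f"unknown trait {name!r}; have {self.names}")
        return self.data[name]

    def subset(self, names) -> "TraitTable":
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise DataError(f"unknown traits {missing}; have {self.names}")
        return TraitTable(self.data[list(names)].copy(), dict(self.units))

    def header_labels(self) -> list[str]:
        return [f"{name}[{self.units.get(name, '')}]" for name in self.names]

    def to_csv(self, path) -> None:
        """Write the trait CSV dialect (``sample_id`` column plus one
        ``name[unit]`` column per trait)."""
        out = self.data.copy()
        out.columns = self.header_labels()
        out.to_csv(path, index=True)


def parse_trait_header(label: str) -> tuple[str, str]:
    """Split a ``name[unit]`` trait column header into (name, unit)."""
    m = _TRAIT_HEADER.match(label.strip())
    if not m:
        raise DataError(f"trait column {label!r} is not of the form 'name[unit]'")
    return m.group("name").strip(), m.group("unit").strip()


def align_samples(spectra: SpectraSet, traits: TraitTable):
    """Restrict a spectra set and a trait table to their common samples.

    Samples present in only one of the two inputs are reported through a
    warning and dropped, matching how joint analyses are run when the two
    files were assembled independently.
    """
    spec_ids = list(spectra.sample_ids)
    common = [sid for sid in spec_ids if sid in set(traits.sample_ids)]
    dropped = sorted(
        set(spec_ids).symmetric_difference(traits.sample_ids.tolist())
    )
    if not common:
        raise AlignmentError("spectra and trait table share no sample ids")
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} unmatched samples from joint analysis: "
            f"{dropped[:8]}{'...' if len(dropped) > 8 else ''}",
            stacklevel=2,
        )
    keep = [i for i, sid in enumerate(spec_ids) if sid in set(common)]
    sub_spec = SpectraSet(
        spectra.sample_ids[keep], spectra.wavelengths, spectra.reflectance[keep]
    )
    sub_traits = TraitTable(traits.data.loc[common].copy(), dict(traits.units))
    return sub_spec, sub_traits
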