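"""Spectra/trait ingestion and descriptive analyses.

Covers reading the package CSV dialects, trimming spectra to the modeling
range (default 450-2400 nm, closed interval), replicate averaging, wet-basis
moisture content, descriptive trait statistics (Table-1 style: min, max,
mean, median, sample SD, CV%), per-wavelength Pearson correlation spectra
with exact t-test p-values, and the trait cross-correlation matrix with a
significance mask at a stated alpha (default 0.01).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SpectraSet, TraitTable, parse_trait_header
from .errors import AlignmentError, DataError, DomainError, InvalidGridError

__all__ = [
    "read_spectra",
    "read_traits",
    "trim_spectra",
    "average_replicates",
    "moisture_content",
    "trait_stats",
    "CorrelationSpectrum",
    "correlation_spectrum",
    "TraitCorrelation",
    "trait_correlation_matrix",
]


def read_spectra(path, bounds: str = "clamp") -> SpectraSet:
    """Read the spectra CSV dialect into a :class:`SpectraSet`.

    ``bounds`` controls out-of-range reflectance values: ``"clamp"`` warns
    and clips into [0, 1]; ``"error"`` rejects the file.
    """
    if bounds not in ("clamp", "error"):
        raise DataError(f"bounds policy must be 'clamp' or 'error', got {bounds!r}")
    frame = pd.read_csv(path, float_precision="round_trip")
    if frame.shape[1] < 2 or frame.columns[0] != "sample_id":
        raise DataError("spectra CSV must start with a 'sample_id' column")
    try:
        wavelengths = np.array([float(c) for c in frame.columns[1:]])
    except ValueError as exc:
        raise DataError(f"non-numeric wavelength column header: {exc}") from exc
    if np.any(np.diff(wavelengths) <= 0):
        raise DataError("wavelength columns are not strictly ascending")
    ids = frame["sample_id"].astype(str)
    if ids.duplicated().any():
        raise DataError(
            f"duplicated sample_id rows: {ids[ids.duplicated()].tolist()}"
        )
    body = frame.iloc[:, 1:]
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & body.notna()
    if bad.to_numpy().any():
        row, col = np.argwhere(bad.to_numpy())[0]
        raise DataError(
            f"non-numeric reflectance at sample {ids.iloc[row]!r}, "
            f"column {body.columns[col]!r}"
        )
    if numeric.isna().to_numpy().any():
        raise DataError("missing reflectance values")
    values = numeric.to_numpy(dtype=float)
    if values.size and (values.min() < 0.0 or values.max() > 1.0):
        if bounds == "error":
            raise DataError("reflectance values outside [0, 1]")
        warnings.warn("reflectance outside [0, 1]; clamping", stacklevel=2)
        values = np.clip(values, 0.0, 1.0)
    return SpectraSet(ids.to_numpy(), wavelengths, values)


def read_traits(path) -> TraitTable:
    """Read the trait CSV dialect (``name[unit]`` headers) into a table.

    Values must be strictly positive where present; missing cells are kept
    as NaN and handled per-trait downstream.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    if frame.shape[1] < 2 or frame.columns[0] != "sample_id":
        raise DataError("trait CSV must start with a 'sample_id' column")
    ids = frame["sample_id"].astype(str)
    if ids.duplicated().any():
        raise DataError(
            f"duplicated sample_id rows: {ids[ids.duplicated()].tolist()}"
        )
    names, units = [], {}
    for label in frame.columns[1:]:
        name, unit = parse_trait_header(label)
        if name in units:
            raise DataError(f"duplicated trait column {name!r}")
        names.append(name)
        units[name] = unit
    body = frame.iloc[:, 1:]
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & body.notna()
    if bad.to_numpy().any():
        row, col = np.argwhere(bad.to_numpy())[0]
        raise DataError(
            f"non-numeric trait value at sample {ids.iloc[row]!r}, "
            f"column {body.columns[col]!r}"
        )
    values = numeric.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(values <= 0):
            row, col = np.argwhere(values <= 0)[0]
            raise DataError(
                f"non-positive trait value at sample {ids.iloc[row]!r}, "
                f"column {body.columns[col]!r}"
            )
    data = pd.DataFrame(values, index=pd.Index(ids, name="sample_id"), columns=names)
    return TraitTable(data, units)


def trim_spectra(spectra: SpectraSet, lo: float = 450.0, hi: float = 2400.0) -> SpectraSet:
    """Restrict a spectra set to wavebands in the closed interval [lo, hi].

    Defaults to the 450-2400 nm modeling range, which drops the noisy ends
    of a full 350-2500 nm instrument sweep.
    """
    if lo > hi:
        raise InvalidGridError(f"lo={lo} exceeds hi={hi}")
    mask = (spectra.wavelengths >= lo) & (spectra.wavelengths <= hi)
    if not mask.any():
        raise InvalidGridError(
            f"no wavebands inside [{lo}, {hi}] nm "
            f"(grid spans {spectra.wavelengths[0]}-{spectra.wavelengths[-1]} nm)"
        )
    return SpectraSet(
        spectra.sample_ids, spectra.wavelengths[mask], spectra.reflectance[:, mask]
    )


def average_replicates(replicates: list[SpectraSet]) -> SpectraSet:
    """Average repeated readings of the same samples, waveband by waveband.

    All replicates must share the sample ids (in order) and wavelength grid.
    A single replicate passes through with a warning.
    """
    if not replicates:
        raise DataError("no replicates given")
    first = replicates[0]
    if len(replicates) == 1:
        warnings.warn("single replicate; averaging is a pass-through", stacklevel=2)
        return SpectraSet(first.sample_ids, first.wavelengths, first.reflectance.copy())
    for rep in replicates[1:]:
        if rep.wavelengths.shape != first.wavelengths.shape or not np.array_equal(
            rep.wavelengths, first.wavelengths
        ):
            raise AlignmentError("replicates do not share a wavelength grid")
        if not np.array_equal(rep.sample_ids, first.sample_ids):
            raise AlignmentError("replicates do not share sample ids")
    mean = np.mean([rep.reflectance for rep in replicates], axis=0)
    return SpectraSet(first.sample_ids, first.wavelengths, mean)


def moisture_content(ww, dw):
    """Wet-basis moisture content in percent: ``(ww - dw) / ww * 100``.

    ``ww`` and ``dw`` are wet and dry sample weights in grams (scalars or
    arrays); requires ``0 < dw <= ww``.
    """
    ww = np.asarray(ww, dtype=float)
    dw = np.asarray(dw, dtype=float)
    if np.any(ww <= 0) or np.any(dw <= 0):
        raise DomainError("weights must be positive")
    if np.any(dw > ww):
        raise DomainError("dry weight exceeds wet weight")
    out = (ww - dw) / ww * 100.0
    return float(out) if out.ndim == 0 else out


def trait_stats(traits: TraitTable) -> pd.DataFrame:
    """Descriptive statistics per trait: min/max/mean/median/sd/cv_percent.

    SD is the sample (n-1) standard deviation and CV = SD/mean x 100.
    Missing cells are dropped per trait; each trait needs >= 2 values.
    """
    rows = {}
    for name in traits.names:
        vals = traits.data[name].dropna().to_numpy()
        if vals.size < 2:
            raise DataError(f"trait {name!r} has fewer than 2 values")
        mean = float(np.mean(vals))
        if mean == 0.0:
            raise DomainError(f"trait {name!r} has zero mean; CV undefined")
        sd = float(np.std(vals, ddof=1))
        rows[name] = {
            "min": float(np.min(vals)),
            "max": float(np.max(vals)),
            "mean": mean,
            "median": float(np.median(vals)),
            "sd": sd,
            "cv_percent": sd / mean * 100.0,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "trait"
    return out


@dataclass
class CorrelationSpectrum:
    """Per-waveband Pearson correlation of one trait with reflectance."""

    wavelengths: np.ndarray
    r: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    alpha: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavelength": self.wavelengths,
                "r": self.r,
                "p": self.p,
                "significant": self.significant,
            }
        )


def _pearson_with_p(X: np.ndarray, y: np.ndarray):
    """Vectorized Pearson r of each column of X with y, plus two-sided
    p-values from the exact t transform with n-2 degrees of freedom."""
    n = y.size
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = float(np.sqrt((yc**2).sum()))
    if sy == 0.0:
        raise DomainError("trait has zero variance; correlation undefined")
    denom = sx * sy
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, Xc.T @ yc / np.where(denom > 0, denom, 1.0), 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return r, p


def correlation_spectrum(
    spectra: SpectraSet, trait, alpha: float = 0.01
) -> CorrelationSpectrum:
    """Pearson correlation of a trait with reflectance at every waveband.

    ``trait`` may be a pandas Series indexed by sample id (aligned to the
    spectra, missing samples dropped) or an array matching the spectra row
    order. The significance mask is ``p < alpha`` (default 0.01) with no
    multiple-testing correction across wavebands.
    """
    if not 0.0 < alpha < 1.0:
        raise DomainError("alpha must be in (0, 1)")
    if isinstance(trait, pd.Series):
        aligned = trait.reindex(spectra.sample_ids)
        keep = aligned.notna().to_numpy()
        y = aligned.to_numpy(dtype=float)[keep]
        X = spectra.reflectance[keep]
    else:
        y = np.asarray(trait, dtype=float)
        if y.shape[0] != spectra.n_samples:
            raise AlignmentError(
                f"trait has {y.shape[0]} values for {spectra.n_samples} spectra"
            )
        keep = np.isfinite(y)
        y, X = y[keep], spectra.reflectance[keep]
    if y.size < 3:
        raise DataError("need at least 3 matched samples for a correlation")
    r, p = _pearson_with_p(X, y)
    return CorrelationSpectrum(
        wavelengths=spectra.wavelengths.copy(),
        r=r,
        p=p,
        significant=p < alpha,
        alpha=alpha,
        n=int(y.size),
    )


@dataclass
class TraitCorrelation:
    """Trait x trait Pearson correlation matrix with significance mask."""

    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    alpha: float
    counts: dict[str, int]

    @property
    def n_pairs(self) -> int:
        k = len(self.r)
        return k * (k - 1) // 2


def trait_correlation_matrix(traits: TraitTable, alpha: float = 0.01) -> TraitCorrelation:
    """Pairwise Pearson correlations among traits with a p < alpha mask.

    Pairs are computed on their jointly observed samples (missing cells
    dropped per pair). The returned ``counts`` classify the unique
    off-diagonal pairs as positive/negative (significant) or
    non-significant; the three counts sum to ``k(k-1)/2``.
    """
    if not 0.0 < alpha < 1.0:
        raise DomainError("alpha must be in (0, 1)")
    names = traits.names
    k = len(names)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pair = traits.data[[names[i], names[j]]].dropna()
            if len(pair) < 3:
                raise DataError(
                    f"traits {names[i]!r}/{names[j]!r} share fewer than 3 samples"
                )
            rij, pij = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    sig = (p < alpha) & ~np.eye(k, dtype=bool)
    iu = np.triu_indices(k, 1)
    pos = int(np.sum(sig[iu] & (r[iu] > 0)))
    neg = int(np.sum(sig[iu] & (r[iu] < 0)))
    ns = int(iu[0].size - pos - neg)
    as_df = lambda m: pd.DataFrame(m, index=names, columns=names)  # noqa: E731
    return TraitCorrelation(
        r=as_df(r),
        p=as_df(p),
        significant=as_df(sig),
        alpha=alpha,
        counts={"positive": pos, "negative": neg, "non_significant": ns},
    )
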