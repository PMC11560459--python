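"""Synthetic leaf spectra and trait tables with known latent structure.

The generator plants a low-rank chemical signal inside realistic green-leaf
reflectance curves so that every downstream stage (trait statistics,
correlation spectra, SIMPLS fitting, component selection) can be exercised
against a ground truth:

* a smooth base spectrum with the canonical features of healthy green
  foliage (green-region maximum near 550 nm, chlorophyll-driven red
  absorption, a steep red edge into the NIR plateau, and shortwave-infrared
  water-band depressions),
* ``latent_rank`` independent standard-normal chemical factors, each
  modulating a Gaussian absorption feature (depth x exp(-(l-c)^2 / 2w^2)),
* traits that are exact affine functions of the latent factors plus
  Gaussian noise scaled relative to each trait's noiseless SD, and
* additive spectral measurement noise, with final clipping to the physical
  reflectance range [0, 1].
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import SpectraSet, TraitTable
from .errors import ConfigError, DataError, InvalidGridError

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "base_leaf_spectrum",
    "generate_dataset",
    "write_fixture",
    "planted_rank_config",
]

# Default trait block: names/units, affine offsets and loadings chosen to give
# wheat-like foliar values with CVs spanning roughly 5-30%, mixed-sign
# cross-correlations, and three single-factor traits for planted-signal tests.
_DEFAULT_TRAITS = ("N[%]", "Ca[ug/g]", "Mg[ug/g]", "Fe[ug/g]", "MC[%]")
_DEFAULT_OFFSETS = (3.5, 6200.0, 2400.0, 93.0, 68.6)
_DEFAULT_LOADINGS = (
    (-0.55, 0.0, 0.0),
    (0.0, 1450.0, 0.0),
    (350.0, 450.0, 120.0),
    (12.0, -14.0, 6.0),
    (0.0, 0.0, -3.6),
)


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic leaf dataset.

    ``feature_centers``/``feature_widths``/``feature_depths`` have one entry
    per latent factor and place the Gaussian absorption features (nm, nm,
    reflectance units). ``trait_loading_matrix`` is traits x latent factors;
    ``trait_offsets`` completes the affine map to trait units.
    ``trait_noise_sd`` is expressed as a fraction of each trait's noiseless
    SD; ``spectral_noise_sd`` is in reflectance units.
    """

    n_samples: int = 360
    wavelength_start_nm: float = 350.0
    wavelength_end_nm: float = 2500.0
    step_nm: float = 1.0
    latent_rank: int = 3
    n_traits: int = 5
    feature_centers: tuple[float, ...] = (560.0, 1200.0, 2100.0)
    feature_widths: tuple[float, ...] = (45.0, 80.0, 90.0)
    feature_depths: tuple[float, ...] = (0.035, 0.05, 0.05)
    trait_names: tuple[str, ...] = _DEFAULT_TRAITS
    trait_offsets: tuple[float, ...] = _DEFAULT_OFFSETS
    trait_loading_matrix: tuple[tuple[float, ...], ...] = _DEFAULT_LOADINGS
    trait_noise_sd: float = 0.05
    spectral_noise_sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_rank < 1:
            raise ConfigError("latent_rank must be >= 1")
        if self.n_samples <= self.latent_rank:
            raise ConfigError("n_samples must exceed latent_rank")
        if self.step_nm <= 0 or self.wavelength_end_nm <= self.wavelength_start_nm:
            raise ConfigError("invalid wavelength range / step")
        for c in self.feature_centers:
            if not self.wavelength_start_nm <= c <= self.wavelength_end_nm:
                raise ConfigError(
                    f"feature center {c} nm outside the wavelength range"
                )
        for name, seq in (
            ("feature_centers", self.feature_centers),
            ("feature_widths", self.feature_widths),
            ("feature_depths", self.feature_depths),
        ):
            if len(seq) != self.latent_rank:
                raise ConfigError(f"{name} must have latent_rank entries")
        if any(w <= 0 for w in self.feature_widths):
            raise ConfigError("feature widths must be positive")
        if self.trait_noise_sd < 0 or self.spectral_noise_sd < 0:
            raise ConfigError("noise SDs must be non-negative")
        L = np.asarray(self.trait_loading_matrix, dtype=float)
        if L.ndim != 2 or L.shape != (self.n_traits, self.latent_rank):
            raise ConfigError(
                "trait_loading_matrix must be n_traits x latent_rank "
                f"(expected {(self.n_traits, self.latent_rank)}, got {L.shape})"
            )
        if len(self.trait_names) != self.n_traits:
            raise ConfigError("trait_names must have n_traits entries")
        if len(self.trait_offsets) != self.n_traits:
            raise ConfigError("trait_offsets must have n_traits entries")

    @property
    def loading_matrix(self) -> np.ndarray:
        return np.asarray(self.trait_loading_matrix, dtype=float)

    @property
    def wavelength_grid(self) -> np.ndarray:
        n = int(round((self.wavelength_end_nm - self.wavelength_start_nm) / self.step_nm))
        return self.wavelength_start_nm + self.step_nm * np.arange(n + 1)

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "wavelength_start_nm": self.wavelength_start_nm,
            "wavelength_end_nm": self.wavelength_end_nm,
            "step_nm": self.step_nm,
            "latent_rank": self.latent_rank,
            "n_traits": self.n_traits,
            "feature_centers": list(self.feature_centers),
            "feature_widths": list(self.feature_widths),
            "feature_depths": list(self.feature_depths),
            "trait_names": list(self.trait_names),
            "trait_offsets": list(self.trait_offsets),
            "trait_loading_matrix": [list(r) for r in self.trait_loading_matrix],
            "trait_noise_sd": self.trait_noise_sd,
            "spectral_noise_sd": self.spectral_noise_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "seed" not in d:
            raise ConfigError("synthetic config requires an explicit seed")
        for key in ("feature_centers", "feature_widths", "feature_depths",
                    "trait_names", "trait_offsets"):
            if key in d:
                d[key] = tuple(d[key])
        if "trait_loading_matrix" in d:
            d["trait_loading_matrix"] = tuple(tuple(r) for r in d["trait_loading_matrix"])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown synthetic config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class GroundTruth:
    """Noiseless quantities underlying a generated dataset.

    ``noiseless_traits`` equals ``trait_offsets + latent_scores @ L.T``
    exactly, and ``noiseless_spectra`` is the pre-noise, pre-clipping
    spectra matrix (base spectrum minus the planted absorption features).
    """

    latent_scores: np.ndarray
    noiseless_traits: np.ndarray
    noiseless_spectra: np.ndarray


def planted_rank_config(
    latent_rank: int,
    n_samples: int = 300,
    seed: int = 0,
    trait_noise_sd: float = 0.05,
    spectral_noise_sd: float = 0.002,
    step_nm: float = 10.0,
) -> SyntheticConfig:
    """Config with one trait loading equally on ``latent_rank`` factors.

    The absorption features are spread across 800-2200 nm on the NIR/SWIR
    plateau. Depths are geometrically spaced (ratio 1.45, deepest feature
    at the shortest center where the base reflectance is highest, so the
    [0,1] clip stays inert): with *equal* depths and equal trait loadings
    the response would collapse onto a single informative spectral
    direction (a one-dimensional Krylov space) and one component would
    suffice, whereas well-separated factor variances make the response
    genuinely ``latent_rank``-dimensional for a PLS fit.
    """
    centers = tuple(np.linspace(800.0, 2200.0, latent_rank)) if latent_rank > 1 else (1100.0,)
    depths = tuple(0.03 * 1.45 ** np.arange(latent_rank)[::-1])
    return SyntheticConfig(
        n_samples=n_samples,
        wavelength_start_nm=350.0,
        wavelength_end_nm=2500.0,
        step_nm=step_nm,
        latent_rank=latent_rank,
        n_traits=1,
        feature_centers=centers,
        feature_widths=(60.0,) * latent_rank,
        feature_depths=depths,
        trait_names=("Y[%]",),
        trait_offsets=(100.0,),
        trait_loading_matrix=((10.0,) * latent_rank,),
        trait_noise_sd=trait_noise_sd,
        spectral_noise_sd=spectral_noise_sd,
        seed=seed,
    )


def base_leaf_spectrum(grid: np.ndarray) -> np.ndarray:
    """Smooth reflectance curve with the structure of healthy green foliage.

    The curve has a green-region local maximum near 550 nm, low red
    reflectance, a steep red edge (~700-750 nm) up to an NIR plateau, and
    water-band depressions near 1350-1420 and 1680-1700 nm plus the deep
    ~1930 nm band; values are clipped to [0.01, 0.95].
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise InvalidGridError("grid must be a non-empty 1-D array")
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise InvalidGridError("grid must be strictly ascending")

    def gauss(center, width):
        return np.exp(-0.5 * ((grid - center) / width) ** 2)

    def sigmoid(center, scale):
        return 1.0 / (1.0 + np.exp(-(grid - center) / scale))

    r = np.full_like(grid, 0.05)
    r += 0.07 * gauss(550.0, 35.0)        # green reflectance bump
    r -= 0.015 * gauss(680.0, 25.0)       # chlorophyll red absorption
    r += 0.42 * sigmoid(715.0, 13.0)      # red edge -> NIR plateau
    r -= 0.10 * sigmoid(1250.0, 120.0)    # gradual SWIR roll-off
    r -= 0.14 * gauss(1400.0, 40.0)       # 1350-1420 nm water band
    r -= 0.05 * gauss(1690.0, 30.0)       # 1680-1700 nm depression
    r -= 0.26 * gauss(1930.0, 70.0)       # deep SWIR water band
    r -= 0.10 * gauss(2500.0, 260.0)      # long-wave tail decline
    return np.clip(r, 0.01, 0.95)


def generate_dataset(config: SyntheticConfig):
    """Generate ``(SpectraSet, TraitTable, GroundTruth)`` from a config.

    Spectra are the base leaf spectrum minus the score-weighted Gaussian
    absorption features, plus iid Gaussian noise, clipped to [0, 1]; traits
    are the affine map of the latent scores plus iid noise whose SD is
    ``trait_noise_sd`` times the trait's noiseless SD. Identical configs
    (including the seed) produce bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.wavelength_grid
    base = base_leaf_spectrum(grid)

    centers = np.asarray(config.feature_centers, dtype=float)
    widths = np.asarray(config.feature_widths, dtype=float)
    depths = np.asarray(config.feature_depths, dtype=float)
    # (latent_rank, n_wavelengths) absorption feature shapes
    features = depths[:, None] * np.exp(
        -0.5 * ((grid[None, :] - centers[:, None]) / widths[:, None]) ** 2
    )

    scores = rng.standard_normal((config.n_samples, config.latent_rank))
    clean_spectra = base[None, :] - scores @ features
    spectra_vals = clean_spectra
    if config.spectral_noise_sd > 0:
        spectra_vals = spectra_vals + config.spectral_noise_sd * rng.standard_normal(
            clean_spectra.shape
        )
    spectra_vals = np.clip(spectra_vals, 0.0, 1.0)

    L = config.loading_matrix
    offsets = np.asarray(config.trait_offsets, dtype=float)
    clean_traits = offsets[None, :] + scores @ L.T
    trait_sd = np.linalg.norm(L, axis=1)  # noiseless SD under N(0,1) scores
    trait_vals = clean_traits
    if config.trait_noise_sd > 0:
        trait_vals = trait_vals + (
            config.trait_noise_sd * trait_sd[None, :]
        ) * rng.standard_normal(clean_traits.shape)

    width = max(4, len(str(config.n_samples)))
    ids = np.array([f"S{i + 1:0{width}d}" for i in range(config.n_samples)])

    spectra = SpectraSet(ids, grid, spectra_vals)
    names, units = [], {}
    from .containers import parse_trait_header

    for label in config.trait_names:
        try:
            name, unit = parse_trait_header(label)
        except DataError:
            name, unit = label, ""
        names.append(name)
        units[name] = unit
    traits = TraitTable(
        pd.DataFrame(trait_vals, index=pd.Index(ids, name="sample_id"), columns=names),
        units,
    )
    truth = GroundTruth(
        latent_scores=scores,
        noiseless_traits=clean_traits,
        noiseless_spectra=clean_spectra,
    )
    return spectra, traits, truth


def write_fixture(spectra: SpectraSet, traits: TraitTable, path) -> dict[str, Path]:
    """Write ``spectra.csv`` and ``traits.csv`` under directory ``path``.

    The files use the package CSV dialects and round-trip losslessly through
    :func:`leafspec.prep.read_spectra` / :func:`leafspec.prep.read_traits`.
    """
    if traits.n_samples == 0 or not traits.names:
        raise DataError("trait table is empty")
    if list(spectra.sample_ids) != list(traits.sample_ids):
        raise DataError("spectra and trait table sample ids differ")
    path = Path(path)
    os.makedirs(path, exist_ok=True)
    spectra_path = path / "spectra.csv"
    traits_path = path / "traits.csv"
    spectra.to_csv(spectra_path)
    traits.to_csv(traits_path)
    return {"spectra": spectra_path, "traits": traits_path}
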