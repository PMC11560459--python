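"""End-to-end orchestration: ingest -> trim -> stats/correlations ->
per-trait cross-validation -> component selection -> VIP/coefficients ->
reports.

Every artifact is a plain CSV (or JSON manifest) in the run directory, and
identical config + seed produces byte-identical numeric outputs. Per-trait
failures are logged and isolated: an error while modeling one trait aborts
that trait only.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import SpectraSet, TraitTable, align_samples
from .errors import ConfigError, LeafspecError
from .prep import (
    correlation_spectrum,
    read_spectra,
    read_traits,
    trait_correlation_matrix,
    trait_stats,
    trim_spectra,
)
from .selection import (
    CVConfig,
    SelectionResult,
    report_table,
    run_cv,
    select_backward_penalty,
    select_press_min,
    select_voet,
)
from .simpls import export_model_table, fit_simpls
from .synthetic import SyntheticConfig, generate_dataset

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("leafspec")

_METHODS = ("press_min", "press_adj", "voet")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of (``spectra_path`` + ``traits_path``) or ``synthetic``
    must be given.
    """

    out_dir: str | Path
    spectra_path: str | Path | None = None
    traits_path: str | Path | None = None
    synthetic: SyntheticConfig | None = None
    traits: list[str] | None = None
    wavelength_lo: float = 450.0
    wavelength_hi: float = 2400.0
    cv: CVConfig = field(default_factory=CVConfig)
    methods: tuple[str, ...] = _METHODS
    alpha: float = 0.01
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        have_files = self.spectra_path is not None and self.traits_path is not None
        if have_files == (self.synthetic is not None):
            raise ConfigError(
                "exactly one of (spectra_path+traits_path) or synthetic "
                "must be configured"
            )
        bad = [m for m in self.methods if m not in _METHODS]
        if bad:
            raise ConfigError(f"unknown selection methods {bad}; choose from {_METHODS}")

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "spectra_path": None if self.spectra_path is None else str(self.spectra_path),
            "traits_path": None if self.traits_path is None else str(self.traits_path),
            "synthetic": None if self.synthetic is None else self.synthetic.to_dict(),
            "traits": self.traits,
            "wavelength_lo": self.wavelength_lo,
            "wavelength_hi": self.wavelength_hi,
            "cv": vars(self.cv).copy(),
            "methods": list(self.methods),
            "alpha": self.alpha,
            "log_level": self.log_level,
        }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        if "synthetic" in d and d["synthetic"] is not None:
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        if "cv" in d and d["cv"] is not None:
            d["cv"] = CVConfig(**d["cv"])
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        return cls(**d)


def _select(curve, method: str, cv: CVConfig) -> SelectionResult:
    if method == "press_min":
        return select_press_min(curve)
    if method == "press_adj":
        return select_backward_penalty(curve, cv.penalty_percent)
    return select_voet(
        curve, alpha=cv.voet_alpha, n_permutations=cv.n_permutations, seed=cv.seed
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all artifacts to ``out_dir``.

    Returns a dict with the manifest, per-trait selection results, and the
    summary table.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        spectra, traits, _truth = generate_dataset(config.synthetic)
    else:
        spectra = read_spectra(config.spectra_path)
        traits = read_traits(config.traits_path)
    spectra, traits = align_samples(spectra, traits)
    spectra = trim_spectra(spectra, config.wavelength_lo, config.wavelength_hi)

    stats = trait_stats(traits)
    stats.to_csv(out / "trait_stats.csv")
    corr = trait_correlation_matrix(traits, alpha=config.alpha)
    corr.r.to_csv(out / "trait_correlation_r.csv")
    corr.p.to_csv(out / "trait_correlation_p.csv")
    (out / "trait_correlation_counts.json").write_text(
        json.dumps(corr.counts, indent=2, sort_keys=True)
    )

    requested = config.traits if config.traits is not None else traits.names
    errors: dict[str, str] = {}
    selections: dict[str, list[SelectionResult]] = {}
    for trait_name in requested:
        try:
            series = traits.trait(trait_name)
            keep = series.notna().to_numpy()
            y = series.to_numpy(dtype=float)[keep]
            X = spectra.reflectance[keep]

            cs = correlation_spectrum(spectra, series, alpha=config.alpha)
            cs.to_frame().to_csv(out / f"{trait_name}_correlation_spectrum.csv", index=False)

            curve = run_cv(X, y, config.cv)
            curve.to_frame().to_csv(out / f"{trait_name}_curve.csv", index=False)

            results = [_select(curve, m, config.cv) for m in config.methods]
            selections[trait_name] = results
            pd.DataFrame([r.to_dict() for r in results]).to_csv(
                out / f"{trait_name}_selection.csv", index=False
            )

            final_a = next(
                (r.n_components for r in results if r.method == "press_adj"),
                results[0].n_components,
            )
            model = fit_simpls(X, y, final_a, wavelengths=spectra.wavelengths)
            export_model_table(model, out / f"{trait_name}_model.csv")
            for r in results:
                logger.info(
                    "%s/%s: A=%d val R2=%.3f val RPD=%.2f (%s)",
                    trait_name, r.method, r.n_components, r.val_r2,
                    r.val_rpd, r.rpd_class,
                )
        except LeafspecError as exc:
            logger.error("trait %s failed: %s", trait_name, exc)
            errors[trait_name] = str(exc)

    summary = report_table(selections)
    summary.to_csv(out / "summary.csv", index=False)

    cfg_dict = config.to_dict()
    manifest = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.cv.seed,
        "errors": errors,
        "versions": {
            "leafspec": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"manifest": manifest, "selections": selections, "summary": summary}
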