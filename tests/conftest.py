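import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import leafspec as ls

settings.register_profile(
    "leafspec",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("leafspec")


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale synthetic config: 60 samples, 10-nm grid, default traits."""
    return ls.SyntheticConfig(n_samples=60, step_nm=10.0, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return ls.generate_dataset(small_config)


@pytest.fixture(scope="session")
def fitted_models(small_dataset):
    """A few SIMPLS fits reused by invariant checks."""
    spectra, traits, _ = small_dataset
    trimmed = ls.trim_spectra(spectra)
    models = []
    for name, a in (("N", 2), ("Mg", 4), ("MC", 3)):
        y = traits.trait(name).to_numpy()
        models.append(ls.fit_simpls(trimmed.reflectance, y, a,
                                    wavelengths=trimmed.wavelengths))
    return models
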