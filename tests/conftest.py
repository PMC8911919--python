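import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_mixture():
    from seedlipid.synthetic import AcylMixture

    return AcylMixture(0.25, 0.30, 0.35, 0.10)


@pytest.fixture(scope="session")
def pea_oil_spectrum(default_mixture):
    """Noiseless pure-oil spectrum of the default mixture."""
    from seedlipid.synthetic import simulate_nmr

    return simulate_nmr(default_mixture, 100.0, 7.0, 0.0, seed=0)


@pytest.fixture(scope="session")
def clean_nir_dataset():
    """18-sample NIR set with the default corruption, fixed seed."""
    from seedlipid import nir
    from seedlipid.synthetic import NIRSimConfig, simulate_nir

    spectra, y = simulate_nir(NIRSimConfig(seed=1))
    matrix = nir.stack_spectra([nir.to_absorbance(s) for s in spectra], y)
    return nir.truncate(matrix, 1100.0, 2500.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
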