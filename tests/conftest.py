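import numpy as np
import pytest

import quenchmcr as qm

# standard study conditions: K = [5.00, 100, 20.0] 1/M, 21 quencher
# levels 0..0.2 M, 5 excitation lines; noisy variant Q5%/S0.5 per-mille


@pytest.fixture(scope="session")
def exact():
    """Noise-free single-excitation series with ground truth."""
    series, truth = qm.synthesize_series()
    return series, truth


@pytest.fixture(scope="session")
def exact_mset():
    """Noise-free multi-excitation set with ground truth."""
    return qm.synthesize_multi_excitation()


@pytest.fixture(scope="session")
def noisy():
    """One Q5%/S0.5-per-mille realization (seed 1) with ground truth."""
    noise = qm.NoiseSpec(spectral_permille=0.5, concentration_percent=5.0,
                         seed=1)
    return qm.synthesize_series(noise=noise)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
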