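import numpy as np
import pytest

from multiphys.synthetic_data import SynthConfig, make_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def clean_samples():
    """Ten noise-free synthetic samples shared across tests."""
    return make_dataset(SynthConfig(n_samples=10, seed=7, noise_sd=0.0, drift_amplitude=0.0))


@pytest.fixture(scope="session")
def noisy_samples():
    """Twenty moderate-noise synthetic samples shared across tests."""
    return make_dataset(SynthConfig(n_samples=20, seed=11, noise_sd=0.3))


def random_stable_params(rng, n_max=8, delta_range=(0.05, 0.5)):
    """A random strictly stable continuous SSM parameter set."""
    from multiphys.ssm_core import SSMParams

    n = int(rng.integers(1, n_max + 1))
    A = rng.normal(size=(n, n))
    # shift the spectrum left of the imaginary axis
    A = A - (np.abs(np.linalg.eigvals(A).real).max() + 0.5) * np.eye(n)
    return SSMParams(
        A=A,
        B=rng.normal(size=(n, 1)),
        C=rng.normal(size=(1, n)),
        delta=float(rng.uniform(*delta_range)),
    )
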