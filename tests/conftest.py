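import numpy as np
import pytest

from bcsfbasl import PhantomSpec, RelaxationSet, make_phantom, simulate_subject

PAPER_TI = np.array([0.2, 0.75, 1.5, 2.75, 4.0, 6.5])


@pytest.fixture(scope="session")
def ti6():
    return PAPER_TI.copy()


@pytest.fixture(scope="session")
def rel():
    return RelaxationSet()


@pytest.fixture(scope="session")
def default_phantom():
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def noiseless_subject(default_phantom):
    """(phantom, standard-ASL series, BCSFB-ASL series), noise-free."""
    s_std, s_csf = simulate_subject(default_phantom, seed=1, noise_sd=0.0)
    return default_phantom, s_std, s_csf


def random_kinetic_params(rng, m0_cls=None):
    """A random valid parameter draw spanning both compartments' regimes."""
    from bcsfbasl import KineticParams
    return KineticParams(
        f=rng.uniform(1e-4, 0.08),
        delta=rng.uniform(0.0, 2.0),
        tau=rng.uniform(0.5, 8.0),
        alpha=rng.uniform(0.3, 1.0),
        phi=rng.uniform(0.8, 1.2),
        r1app=rng.uniform(0.2, 1.2),
        r1a=rng.uniform(0.3, 0.6),
        m0=rng.uniform(0.5, 200.0),
    )
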