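import numpy as np
import pytest
from hypothesis import settings

import qrl

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_noiseless():
    """Noise-free toy crystal, unperturbed start (true model == start)."""
    return qrl.make_toy_crystal(qrl.ToySpec(seed=7, noise=0.0, perturb_rmsd=0.0))


@pytest.fixture(scope="session")
def toy_perturbed():
    """Noisy toy with a 0.3 Å-perturbed start model."""
    return qrl.make_toy_crystal(qrl.ToySpec(seed=5, noise=0.02, perturb_rmsd=0.3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def fd_gradient(fun, x0, h=1e-5):
    """Central finite differences of a scalar function of a flat vector."""
    x0 = np.asarray(x0, dtype=float)
    g = np.zeros_like(x0)
    for i in range(len(x0)):
        xp = x0.copy()
        xp[i] += h
        xm = x0.copy()
        xm[i] -= h
        g[i] = (fun(xp) - fun(xm)) / (2 * h)
    return g


@pytest.fixture(scope="session")
def fd():
    return fd_gradient
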