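import numpy as np
import pytest

from nqschem.rbm import initialize
from nqschem.workbench import FixtureSpec, generate_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_hamiltonian():
    """Factory for seeded random real Pauli Hamiltonians."""

    def make(n_qubits, seed, n_terms=None, max_locality=2, scale=1.0):
        spec = FixtureSpec(
            n_qubits=n_qubits,
            n_terms=n_terms if n_terms is not None else 3 * n_qubits,
            max_locality=min(max_locality, n_qubits),
            coefficient_scale=scale,
            seed=seed,
        )
        return generate_fixture(spec)

    return make


@pytest.fixture
def random_parameters():
    """Factory for random RBM parameter sets of moderate magnitude."""

    def make(n, m, seed, scale=0.5):
        return initialize(n, m, seed, scale=scale)

    return make
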