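"""Variational energy, covariance gradient, training, transfer learning."""

import numpy as np
import pytest

from nqschem.pauli import (
    BasisState,
    PauliString,
    QubitHamiltonian,
    exact_ground_state,
    parse_hamiltonian,
    to_matrix,
)
from nqschem.rbm import RBMParameters, full_table, initialize
from nqschem.solver import (
    DegenerateGradientError,
    ExcludedStateError,
    TrainConfig,
    exact_energy,
    gradient,
    local_energy,
    train,
    train_multi,
    transfer_train,
)


def identity_hamiltonian(n, c):
    return QubitHamiltonian(n, [PauliString(c, {})])


class TestLocalEnergy:
    def test_identity_hamiltonian_gives_constant(self, random_parameters):
        h = identity_hamiltonian(2, 1.7)
        p = random_parameters(2, 2, 3)
        for i in range(4):
            assert local_energy(h, p, BasisState.from_index(i, 2)) == (
                pytest.approx(1.7, rel=1e-12)
            )

    def test_concentrated_state_recovers_eigenvalue(self):
        # large |a| concentrates P~ on sigma = (+1); for H = 1.0 Z0 the
        # diagonal element there is -1 and off-diagonal terms are absent
        h = parse_hamiltonian("qubits 1\n1.0 Z0\n")
        p = RBMParameters(
            1, 1, np.array([8.0]), np.zeros(1), np.zeros((1, 1)),
            np.array([0.5]), 0.1,
        )
        e = local_energy(h, p, BasisState((1,)))
        assert e == pytest.approx(-1.0, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_weighted_average_equals_quadratic_form(
        self, random_hamiltonian, random_parameters, seed
    ):
        h = random_hamiltonian(3, seed)
        p = random_parameters(3, 3, seed + 50)
        table = full_table(p)
        w = table.normalized_weight()
        e_avg = sum(
            w[i] * local_energy(h, p, BasisState.from_index(i, 3))
            for i in range(8)
            if w[i] > 0
        )
        psi = table.psi()
        mat = to_matrix(h)
        assert e_avg == pytest.approx(
            psi @ mat @ psi / (psi @ psi), abs=1e-10
        )

    def test_sign_floor_raises_excluded_signal(self):
        h = parse_hamiltonian("qubits 1\n1.0 Z0\n")
        p = RBMParameters(1, 1, np.zeros(1), np.zeros(1),
                          np.zeros((1, 1)), np.zeros(1), 0.0)
        with pytest.raises(ExcludedStateError):
            local_energy(h, p, BasisState((1,)))


class TestExactEnergy:
    def test_identity_hamiltonian(self, random_parameters):
        est = exact_energy(identity_hamiltonian(2, 2.0),
                           random_parameters(2, 2, 0))
        assert est.value == pytest.approx(2.0, rel=1e-12)
        assert est.mode == "exact" and est.std_error == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_variational_bound(self, random_hamiltonian, random_parameters, seed):
        h = random_hamiltonian(3, seed)
        p = random_parameters(3, 3, seed + 100, scale=1.0)
        e0, _ = exact_ground_state(h)
        assert exact_energy(h, p).value >= e0 - 1e-10

    def test_gauge_invariance_under_amplitude_scaling(
        self, random_hamiltonian, random_parameters
    ):
        """A hidden unit with zero couplings multiplies P~ by the constant
        2 cosh(b); energy and gradient must be unchanged."""
        h = random_hamiltonian(3, 4)
        p = random_parameters(3, 2, 60)
        p_ext = RBMParameters(
            3, 3,
            p.a, np.append(p.b, 3.7),
            np.hstack([p.w, np.zeros((3, 1))]),
            p.d, p.c,
        )
        assert exact_energy(h, p_ext).value == pytest.approx(
            exact_energy(h, p).value, abs=1e-12
        )
        g, _, _ = gradient(h, p)
        g_ext, _, _ = gradient(h, p_ext)
        # shared components: a, original b's, original w's (block layout)
        assert np.allclose(g[:3], g_ext[:3], atol=1e-12)
        assert np.allclose(g[3:5], g_ext[3:5], atol=1e-12)


def _fd_energy_gradient(h, p, step=1e-6):
    vec0 = p.pack()
    grad = np.zeros_like(vec0)
    for k in range(vec0.size):
        vp, vm = vec0.copy(), vec0.copy()
        vp[k] += step
        vm[k] -= step
        ep = exact_energy(h, RBMParameters.unpack(vp, p.n, p.m)).value
        em = exact_energy(h, RBMParameters.unpack(vm, p.n, p.m)).value
        grad[k] = (ep - em) / (2 * step)
    return grad


class TestGradient:
    def test_identity_hamiltonian_zero_gradient(self, random_parameters):
        g, e, _ = gradient(identity_hamiltonian(2, 1.0),
                           random_parameters(2, 2, 8))
        assert e == pytest.approx(1.0)
        assert np.allclose(g, 0.0, atol=1e-10)

    @pytest.mark.parametrize("case", range(15))
    def test_matches_finite_differences_of_exact_energy(
        self, random_hamiltonian, case
    ):
        rng = np.random.default_rng(7000 + case)
        n = int(rng.integers(2, 4))
        h = random_hamiltonian(n, case + 300)
        p = initialize(n, n, case + 400, scale=0.6)
        g, _, _ = gradient(h, p)
        fd = _fd_energy_gradient(h, p)
        assert np.linalg.norm(g - fd) < 1e-5 * max(np.linalg.norm(fd), 1e-3)

    def test_sampled_gradient_consistent_with_exact(self, random_hamiltonian):
        """Mean of replicated sampled-mode gradients must agree with the
        exact gradient within Monte-Carlo error (4 standard errors)."""
        h = random_hamiltonian(2, 9)
        p = initialize(2, 2, 55, scale=0.6)
        table = full_table(p)
        g_exact, _, _ = gradient(h, p)
        rng = np.random.default_rng(123)
        prob = np.exp(table.log_ptilde)
        prob /= prob.sum()
        reps = []
        for _ in range(12):
            counts = rng.multinomial(10**4, prob)
            weights = (counts / counts.sum()) * table.s**2
            g, _, _ = gradient(h, p, weights=weights, table=table)
            reps.append(g)
        reps = np.array(reps)
        se = reps.std(axis=0, ddof=1) / np.sqrt(reps.shape[0])
        assert np.all(np.abs(reps.mean(axis=0) - g_exact) < 4 * se + 1e-9)

    def test_single_state_distribution_is_degenerate_signal(
        self, random_hamiltonian, random_parameters
    ):
        h = random_hamiltonian(2, 2)
        p = random_parameters(2, 2, 2)
        weights = np.zeros(4)
        weights[1] = 1.0
        with pytest.raises(DegenerateGradientError):
            gradient(h, p, weights=weights)


class TestTrain:
    def test_single_qubit_diagonal_reaches_ground_state(self):
        h = parse_hamiltonian("qubits 1\n-1.0 Z0\n")
        trace = train(h, TrainConfig(seed=0, iterations=500))
        assert trace.min_energy == pytest.approx(-1.0, abs=1e-3)

    def test_trained_distribution_concentrates_on_ground_state(self):
        h = parse_hamiltonian("qubits 1\n-1.0 Z0\n")
        trace = train(h, TrainConfig(seed=1, iterations=2000))
        table = full_table(trace.best_parameters)
        w = table.normalized_weight()
        # ground state of -Z0 is |0>, i.e. sigma = -1, index 0
        assert w[0] >= 0.99

    def test_exact_mode_reproducible_per_seed(self, random_hamiltonian):
        h = random_hamiltonian(2, 6)
        cfg = TrainConfig(seed=9, iterations=50)
        t1, t2 = train(h, cfg), train(h, cfg)
        assert t1.energies == t2.energies
        assert np.array_equal(
            t1.final_parameters.pack(), t2.final_parameters.pack()
        )

    def test_variational_bound_along_whole_trajectory(self, random_hamiltonian):
        h = random_hamiltonian(3, 8)
        e0, _ = exact_ground_state(h)
        trace = train(h, TrainConfig(seed=0, iterations=300))
        assert min(trace.energies) >= e0 - 1e-10
        assert trace.min_energy == pytest.approx(min(trace.energies))

    def test_min_energy_bookkeeping(self, random_hamiltonian):
        h = random_hamiltonian(2, 3)
        trace = train(h, TrainConfig(seed=4, iterations=100))
        k = int(np.argmin(trace.energies))
        assert trace.min_iteration == trace.iterations[k]

    def test_zero_iterations_rejected(self, random_hamiltonian):
        with pytest.raises(ValueError):
            TrainConfig(iterations=0)

    def test_fixture_recovery_at_default_budget(self, random_hamiltonian):
        h = random_hamiltonian(3, 0, n_terms=9)
        e0, _ = exact_ground_state(h)
        trace = train_multi(h, TrainConfig(seed=0), n_restarts=3)
        assert trace.min_energy - e0 < 2e-3

    def test_sampled_mode_enumerate_sampler_converges(self, random_hamiltonian):
        h = random_hamiltonian(2, 0, n_terms=6)
        e0, _ = exact_ground_state(h)
        cfg = TrainConfig(
            seed=0, mode="sampled", sampler="enumerate",
            iterations=800, samples_per_iteration=2000,
        )
        trace = train(h, cfg)
        assert abs(trace.min_energy - e0) < 2e-2


class TestTransfer:
    def _pair(self, delta=0.05):
        def ham(lam):
            return QubitHamiltonian(1, [
                PauliString(-lam, {0: "Z"}),
                PauliString(-(1 - lam), {0: "X"}),
            ])
        return ham(0.5), ham(0.5 + delta)

    def test_fraction_one_equals_full_warm_start(self, random_hamiltonian):
        h = random_hamiltonian(2, 5)
        cfg = TrainConfig(seed=3, iterations=40,
                          warm_start_iteration_fraction=1.0)
        ckpt = initialize(2, 4, 77)
        t1 = transfer_train(h, ckpt, cfg)
        t2 = train(h, cfg, initial=ckpt)
        assert t1.energies == t2.energies

    def test_dimension_mismatch_rejected(self, random_hamiltonian):
        h = random_hamiltonian(4, 1)
        with pytest.raises(ValueError, match="visible units"):
            transfer_train(h, initialize(3, 3, 0), TrainConfig(iterations=10))

    def test_warm_start_beats_cold_start_at_small_budget(self):
        """At 1/40 of the budget, a checkpoint from a neighboring
        Hamiltonian should reach the ground state where a cold start
        typically cannot."""
        h_a, h_b = self._pair()
        e0, _ = exact_ground_state(h_b)
        cfg = TrainConfig(seed=0, iterations=20000)
        warm_wins = 0
        for seed in range(10):
            cfg_s = TrainConfig(seed=seed, iterations=20000)
            ckpt = train(h_a, cfg_s).best_parameters
            warm = transfer_train(h_b, ckpt, cfg_s)
            cold = train(h_b, cfg_s, iterations=len(warm.iterations))
            warm_err = warm.min_energy - e0
            cold_err = cold.min_energy - e0
            if warm_err < 5e-3 and warm_err <= cold_err + 1e-12:
                warm_wins += 1
        assert warm_wins >= 8
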