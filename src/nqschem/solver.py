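"""Variational optimization of the RBM ansatz against a qubit Hamiltonian.

The objective is the Rayleigh quotient

    <H> = sum_{x,x'} psi(x) <x|H|x'> psi(x') / sum_x psi(x)^2,

with ``psi(x) = sqrt(P~(x)) s(x)`` real.  Its gradient with respect to any
trainable weight ``p_k`` is estimated from the covariance of the local
energy ``E_loc(x) = <x|H|psi> / psi(x)`` with the log-derivative
``D_pk(x) = d log psi(x) / d p_k``:

    grad_k = 2 ( <E_loc D_pk> - <E_loc> <D_pk> ),

where ``<.>`` averages over the joint weight ``P~(x) s(x)^2`` — evaluated
either by full enumeration (exact mode) or from an empirical visible
distribution delivered by a sampler (sampled mode).  Optimization is plain
constant-rate gradient descent; the reported observable is the minimum
energy over all iterations, and warm starts with a reduced iteration
budget implement the transfer-learning protocol across neighboring
Hamiltonians of a potential-energy scan.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

from . import gibbs, rbm
from .pauli import BasisState, QubitHamiltonian, matrix_row, to_sparse
from .rbm import RBMParameters, S_FLOOR

__all__ = [
    "EnergyEstimate",
    "TrainConfig",
    "OptimizationTrace",
    "TrainingDiverged",
    "ExcludedStateError",
    "local_energy",
    "exact_energy",
    "gradient",
    "train",
    "train_multi",
    "transfer_train",
]


class ExcludedStateError(ValueError):
    """A basis state whose sign magnitude is below the floor was requested."""


class DegenerateGradientError(ValueError):
    """The averaging distribution has fewer than two effective states."""


class TrainingDiverged(RuntimeError):
    """Parameters became non-finite; carries the partial trace."""

    def __init__(self, message: str, trace: "OptimizationTrace"):
        super().__init__(message)
        self.trace = trace


@dataclass
class EnergyEstimate:
    """A variational energy value with its provenance."""

    value: float
    mode: Literal["exact", "sampled"]
    n_samples: int = 0
    std_error: float = 0.0

    def __post_init__(self) -> None:
        if self.mode == "exact" and self.std_error != 0.0:
            raise ValueError("exact estimates carry no standard error")


@dataclass
class TrainConfig:
    """Gradient-descent run configuration.

    ``hidden_units=None`` defaults to twice the qubit count, the ratio the
    reference molecular runs used most.  ``iterations=None`` defaults to
    20000 in exact mode and 2000 in sampled mode.
    """

    learning_rate: float = 0.01
    iterations: int | None = None
    mode: Literal["exact", "sampled"] = "exact"
    sampler: Literal["enumerate", "circuit"] = "enumerate"
    samples_per_iteration: int = 2000
    hidden_units: int | None = None
    seed: int = 0
    init_scale: float = rbm.INIT_SCALE
    warm_start_iteration_fraction: float = 1.0 / 40.0
    record_every: int = 1

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.iterations is not None and self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.mode not in ("exact", "sampled"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.sampler not in ("enumerate", "circuit"):
            raise ValueError(f"unknown sampler {self.sampler!r}")
        if not 0 < self.warm_start_iteration_fraction <= 1:
            raise ValueError("warm_start_iteration_fraction must be in (0, 1]")

    @property
    def effective_iterations(self) -> int:
        if self.iterations is not None:
            return self.iterations
        return 20000 if self.mode == "exact" else 2000


@dataclass
class OptimizationTrace:
    """Per-iteration energies plus the best state seen.

    ``min_energy`` follows the min-over-all-iterations reporting
    convention (each iteration's energy is itself a variational value, so
    the minimum is still an upper bound on the ground energy in exact
    mode).
    """

    iterations: list[int] = field(default_factory=list)
    energies: list[float] = field(default_factory=list)
    grad_norms: list[float] = field(default_factory=list)
    n_effective_states: list[int] = field(default_factory=list)
    min_energy: float = math.inf
    min_iteration: int = -1
    best_parameters: RBMParameters | None = None
    final_parameters: RBMParameters | None = None
    seed: int | None = None

    def record(
        self, it: int, energy: float, grad_norm: float,
        n_eff: int, p: RBMParameters,
    ) -> None:
        self.iterations.append(it)
        self.energies.append(energy)
        self.grad_norms.append(grad_norm)
        self.n_effective_states.append(n_eff)
        if energy < self.min_energy:
            self.min_energy = energy
            self.min_iteration = it
            self.best_parameters = p.copy()

    def write_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            wr = csv.writer(fh)
            wr.writerow(
                ["iteration", "energy", "grad_norm", "n_effective_states"]
            )
            for row in zip(
                self.iterations, self.energies, self.grad_norms,
                self.n_effective_states,
            ):
                wr.writerow(row)

    def summary(self) -> dict:
        return {
            "min_energy": self.min_energy,
            "min_iteration": self.min_iteration,
            "iterations_run": self.iterations[-1] + 1 if self.iterations else 0,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Energy and gradient
# ---------------------------------------------------------------------------

def local_energy(
    h: QubitHamiltonian, p: RBMParameters, x: BasisState
) -> float:
    """``E_loc(x) = <x|H|psi> / psi(x)`` via the sparse Hamiltonian row.

    Amplitude ratios are formed in log space; only the states connected to
    ``x`` by some Pauli string contribute.
    """
    sx = rbm.sign_value(p, x)
    if abs(sx) <= S_FLOOR:
        raise ExcludedStateError("sign magnitude below floor at x")
    logp_x = rbm.log_unnormalized_prob(p, np.asarray(x.spins, dtype=float))
    total = 0.0
    for xp, elem in matrix_row(h, x):
        logp_xp = rbm.log_unnormalized_prob(
            p, np.asarray(xp.spins, dtype=float)
        )
        ratio = math.exp(0.5 * (logp_xp - logp_x)) * rbm.sign_value(p, xp) / sx
        total += elem * ratio
    return total


def _table_local_energies(
    h_mat, table: rbm.AmplitudeTable
) -> tuple[np.ndarray, np.ndarray]:
    """Local energies on the included support of a full amplitude table."""
    psi = table.psi()
    incl = table.included
    e_loc = np.full(table.n_states, np.nan)
    e_loc[incl] = (h_mat @ psi)[incl] / psi[incl]
    return e_loc, incl


def exact_energy(h: QubitHamiltonian, p: RBMParameters) -> EnergyEstimate:
    """Full-enumeration Rayleigh quotient ``psi^T H psi / psi^T psi``."""
    if p.n != h.n_qubits:
        raise ValueError("parameter/visible dimension mismatch")
    table = rbm.full_table(p)
    if table.degenerate:
        raise ValueError("degenerate amplitude table: all signs at floor")
    psi = np.where(table.included, table.psi(), 0.0)
    h_mat = to_sparse(h)
    value = float(psi @ (h_mat @ psi) / (psi @ psi))
    return EnergyEstimate(value=value, mode="exact")


def gradient(
    h: QubitHamiltonian,
    p: RBMParameters,
    weights: np.ndarray | None = None,
    table: rbm.AmplitudeTable | None = None,
    h_mat=None,
) -> tuple[np.ndarray, float, int]:
    """Covariance gradient over a weight distribution on basis states.

    ``weights`` is a length-``2**n`` vector proportional to the averaging
    distribution; ``None`` means the exact joint weight ``P~ s^2``.
    Returns ``(gradient in pack() layout, energy under the weights,
    number of effective states)``.
    """
    table = table if table is not None else rbm.full_table(p)
    h_mat = h_mat if h_mat is not None else to_sparse(h)
    if weights is None:
        weights = table.weight
    e_loc, incl = _table_local_energies(h_mat, table)
    mask = incl & (weights > 0)
    n_eff = int(mask.sum())
    if n_eff < 2:
        raise DegenerateGradientError(
            "fewer than two effective states: gradient is degenerate"
        )
    wt = weights[mask]
    wt = wt / wt.sum()
    el = e_loc[mask]
    D = rbm.derivative_matrix(p, table.spins[mask])
    mean_el = float(wt @ el)
    mean_D = wt @ D
    mean_elD = (wt * el) @ D
    grad = 2.0 * (mean_elD - mean_el * mean_D)
    return grad, mean_el, n_eff


# ---------------------------------------------------------------------------
# Samplers for the averaging distribution
# ---------------------------------------------------------------------------

def _spins_to_index(spins: tuple[int, ...]) -> int:
    idx = 0
    for s in spins:
        idx = (idx << 1) | (1 if s == 1 else 0)
    return idx


def _sampled_weights(
    p: RBMParameters,
    table: rbm.AmplitudeTable,
    config: TrainConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Empirical visible distribution times ``s^2``.

    ``enumerate``: multinomial draws from the exact RBM marginal ``P(x)``
    (sampling noise without circuit overhead).  ``circuit``: the simulated
    Gibbs circuit with per-iteration divisor ``k = max(1, sum|w|)``,
    power-``k`` recovery, then the visible marginal.
    """
    n_states = table.n_states
    if config.sampler == "enumerate":
        prob = np.exp(table.log_ptilde)
        prob /= prob.sum()
        counts = rng.multinomial(config.samples_per_iteration, prob)
        emp = counts / counts.sum()
    else:
        batch = gibbs.sample_batch(
            p, config.samples_per_iteration,
            gibbs.SamplerConfig(), rng=rng,
        )
        _, visible = gibbs.recover_gibbs(batch, gibbs.choose_k(p))
        emp = np.zeros(n_states)
        for x, v in visible.items():
            emp[_spins_to_index(x)] = v
    return emp * table.s**2


# ---------------------------------------------------------------------------
# Training loops
# ---------------------------------------------------------------------------

def train(
    h: QubitHamiltonian,
    config: TrainConfig,
    initial: RBMParameters | None = None,
    iterations: int | None = None,
) -> OptimizationTrace:
    """Constant-rate gradient descent on the variational energy.

    Exact mode is deterministic given the seed (which fixes only the
    initialization); sampled mode also drives the per-iteration sampler
    from the same generator.
    """
    n = h.n_qubits
    m = config.hidden_units if config.hidden_units is not None else 2 * n
    rng = np.random.default_rng(config.seed)
    if initial is not None:
        if initial.n != n:
            raise ValueError(
                f"checkpoint has {initial.n} visible units but the "
                f"Hamiltonian has {n} qubits"
            )
        p = initial.copy()
        rng = np.random.default_rng(config.seed)
    else:
        p = rbm.initialize(n, m, rng, scale=config.init_scale)
    n_iter = iterations if iterations is not None else config.effective_iterations
    if n_iter < 1:
        raise ValueError("iteration count must be >= 1")

    h_mat = to_sparse(h)
    trace = OptimizationTrace(seed=config.seed)
    for it in range(n_iter):
        table = rbm.full_table(p)
        if table.degenerate:
            raise TrainingDiverged("all sign magnitudes at floor", trace)
        if config.mode == "exact":
            weights = table.weight
        else:
            weights = _sampled_weights(p, table, config, rng)
        try:
            grad, energy, n_eff = gradient(
                h, p, weights=weights, table=table, h_mat=h_mat
            )
        except DegenerateGradientError:
            # The averaging distribution collapsed onto a single basis
            # state (numerically zero weight elsewhere).  The covariance
            # gradient vanishes there; record the state's local energy and,
            # in exact mode, stop — plain gradient descent cannot move.
            e_loc, incl = _table_local_energies(h_mat, table)
            mask = incl & (weights > 0)
            energy = float(e_loc[mask][0]) if mask.any() else math.nan
            if not np.isfinite(energy):
                raise TrainingDiverged(
                    f"degenerate distribution at iteration {it}", trace
                ) from None
            trace.record(it, energy, 0.0, int(mask.sum()), p)
            if config.mode == "exact":
                break
            continue
        if not (np.isfinite(energy) and np.isfinite(grad).all()):
            raise TrainingDiverged(
                f"non-finite energy/gradient at iteration {it}", trace
            )
        if it % config.record_every == 0 or it == n_iter - 1:
            trace.record(it, energy, float(np.linalg.norm(grad)), n_eff, p)
        vec = p.pack() - config.learning_rate * grad
        if not np.isfinite(vec).all():
            raise TrainingDiverged(
                f"non-finite parameters at iteration {it}", trace
            )
        p = RBMParameters.unpack(vec, p.n, p.m)
    trace.final_parameters = p
    return trace


def train_multi(
    h: QubitHamiltonian,
    config: TrainConfig,
    n_restarts: int = 3,
) -> OptimizationTrace:
    """Restart training from ``n_restarts`` seeds and keep the best trace.

    Plain gradient descent can stall in local minima; independent
    initializations are the simple remedy.  Restart ``r`` uses seed
    ``config.seed + r``.
    """
    best: OptimizationTrace | None = None
    for r in range(n_restarts):
        cfg = TrainConfig(**{**config.__dict__, "seed": config.seed + r})
        trace = train(h, cfg)
        if best is None or trace.min_energy < best.min_energy:
            best = trace
    assert best is not None
    return best


def transfer_train(
    h_new: QubitHamiltonian,
    checkpoint: RBMParameters,
    config: TrainConfig,
) -> OptimizationTrace:
    """Warm-start training on a neighboring Hamiltonian at reduced budget.

    Runs ``ceil(fraction * iterations)`` steps from the checkpointed
    parameters; with the default fraction of 1/40 this is the
    transfer-learning protocol used along potential-energy scans.
    """
    if checkpoint.n != h_new.n_qubits:
        raise ValueError(
            f"checkpoint has {checkpoint.n} visible units but the "
            f"Hamiltonian has {h_new.n_qubits} qubits"
        )
    n_iter = math.ceil(
        config.warm_start_iteration_fraction * config.effective_iterations
    )
    return train(h_new, config, initial=checkpoint, iterations=max(1, n_iter))
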