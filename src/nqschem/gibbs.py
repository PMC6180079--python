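"""Classical simulation of the controlled-rotation Gibbs sampling circuit.

The RBM joint distribution over visible and hidden spins
``y = (sigma, h)`` is the Gibbs law ``P(y) ∝ exp(a.sigma + b.h +
sigma.W.h)``.  The quantum sampling scheme does not draw from ``P``
directly: it prepares a product state whose measurement law is the
tempered independent part ``O(y) ∝ exp((a.sigma + b.h)/k)``, then for each
coupling ``w_ij`` rotates a fresh ancilla by an angle that encodes
``exp((w_ij sigma_i h_j - |w_ij|)/k)`` and measures it; any ancilla found
in ``|0>`` aborts the attempt and the whole circuit restarts.  Surviving
runs are distributed as ``Q(y) ∝ P(y)^(1/k)``, and raising the observed
frequencies to the power ``k`` (then normalizing) recovers the Gibbs
distribution.

The simulation works at the level of the circuit's measurement statistics
— independent Bernoulli draws for the R_y preparations plus per-coupling
acceptance tests — which reproduces the output law of the state-vector
description followed by projective ancilla measurements exactly, at cost
``O(nm)`` per attempt.

The divisor ``k`` trades acceptance rate against recovery noise: one
attempt succeeds with probability at least ``exp(-(1/k) sum_ij 2|w_ij|)``,
so ``k`` of order ``sum_ij |w_ij|`` keeps the rate bounded below by a
constant (``e^-2`` at equality).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pauli import ResourceError, all_basis_spins
from .rbm import RBMParameters

__all__ = [
    "SamplerConfig",
    "RotationPlan",
    "SampleBatch",
    "rotation_plan",
    "run_circuit_once",
    "sample_batch",
    "exact_Q",
    "recover_gibbs",
    "acceptance_bound",
    "choose_k",
]

_JOINT_CAP = 20


@dataclass
class SamplerConfig:
    """Sampler knobs: temperature-like divisor, attempt budget, seed."""

    k: float | None = None        # None -> choose_k(p) per call
    max_attempts: int = 10**7
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k is not None and self.k <= 0:
            raise ValueError("k must be positive")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")


@dataclass
class RotationPlan:
    """R_y angles realizing the tempered RBM factors.

    ``theta[i]``/``gamma[j]`` prepare the visible/hidden superpositions;
    ``(theta1[i, j], theta2[i, j])`` are the ancilla angles used when
    ``sigma_i h_j = +1`` (qubits agree) and ``-1`` respectively.
    """

    k: float
    theta: np.ndarray
    gamma: np.ndarray
    theta1: np.ndarray
    theta2: np.ndarray

    @property
    def p_visible(self) -> np.ndarray:
        """P(sigma_i = +1), i.e. sin^2(theta_i / 2)."""
        return np.sin(self.theta / 2.0) ** 2

    @property
    def p_hidden(self) -> np.ndarray:
        return np.sin(self.gamma / 2.0) ** 2

    @property
    def p_accept_agree(self) -> np.ndarray:
        return np.sin(self.theta1 / 2.0) ** 2

    @property
    def p_accept_disagree(self) -> np.ndarray:
        return np.sin(self.theta2 / 2.0) ** 2


@dataclass
class SampleBatch:
    """Accepted configurations with multiplicities plus attempt accounting."""

    n: int
    m: int
    counts: dict[tuple[int, ...], int] = field(default_factory=dict)
    n_attempts: int = 0

    @property
    def n_accepted(self) -> int:
        return sum(self.counts.values())

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_attempts if self.n_attempts else 0.0


def choose_k(p: RBMParameters, multiplier: float = 1.0) -> float:
    """Default divisor ``k = max(1, multiplier * sum_ij |w_ij|)``."""
    return max(1.0, multiplier * float(np.abs(p.w).sum()))


def acceptance_bound(p: RBMParameters, k: float) -> float:
    """Lower bound ``exp(-(1/k) sum_ij 2 |w_ij|)`` on the success rate."""
    if k <= 0:
        raise ValueError("k must be positive")
    return float(np.exp(-2.0 * np.abs(p.w).sum() / k))


def rotation_plan(p: RBMParameters, k: float) -> RotationPlan:
    """Angles for the preparation and coupling rotations at divisor ``k``."""
    if k <= 0:
        raise ValueError("k must be positive")
    # sin^2(theta/2) = e^{a/k} / (e^{a/k} + e^{-a/k}) = sigmoid(2a/k)
    p_vis = 1.0 / (1.0 + np.exp(-2.0 * p.a / k))
    p_hid = 1.0 / (1.0 + np.exp(-2.0 * p.b / k))
    theta = 2.0 * np.arcsin(np.sqrt(p_vis))
    gamma = 2.0 * np.arcsin(np.sqrt(p_hid))
    # sin^2(theta_{ij,.}/2) = e^{±w/k} / e^{|w|/k}
    amp1 = np.exp((p.w - np.abs(p.w)) / k)
    amp2 = np.exp((-p.w - np.abs(p.w)) / k)
    theta1 = 2.0 * np.arcsin(np.sqrt(amp1))
    theta2 = 2.0 * np.arcsin(np.sqrt(amp2))
    return RotationPlan(k, theta, gamma, theta1, theta2)


def run_circuit_once(
    plan: RotationPlan, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray] | None:
    """One circuit attempt: returns ``(sigma, h)`` spins or ``None``.

    The preparation measurements fix every register qubit; each coupling's
    ancilla is then measured in sequence and the first ``|0>`` outcome
    aborts the attempt (the hardware protocol restarts from scratch).
    """
    n, m = plan.theta.size, plan.gamma.size
    sigma = np.where(rng.random(n) < plan.p_visible, 1, -1)
    h = np.where(rng.random(m) < plan.p_hidden, 1, -1)
    agree = sigma[:, None] * h[None, :] > 0
    p_ok = np.where(agree, plan.p_accept_agree, plan.p_accept_disagree)
    for i in range(n):
        for j in range(m):
            if rng.random() >= p_ok[i, j]:
                return None
    return sigma, h


def sample_batch(
    p: RBMParameters,
    n_samples: int,
    config: SamplerConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SampleBatch:
    """Run circuit attempts until ``n_samples`` acceptances (vectorized).

    Attempts are drawn in blocks; an attempt is accepted with probability
    ``prod_ij sin^2(theta_{ij,.}/2)``, which is the joint law of the
    per-coupling ancilla measurements (independent events, any failure
    rejects the whole attempt).
    """
    config = config or SamplerConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    k = config.k if config.k is not None else choose_k(p)
    plan = rotation_plan(p, k)
    batch = SampleBatch(p.n, p.m)
    abs_w_sum = float(np.abs(p.w).sum())
    block = int(min(200_000, max(1024, 4 * n_samples)))
    while batch.n_accepted < n_samples:
        remaining = config.max_attempts - batch.n_attempts
        if remaining <= 0:
            if batch.n_accepted == 0:
                raise RuntimeError(
                    "attempt budget exhausted with no accepted samples"
                )
            break
        nb = int(min(block, remaining))
        sigma = np.where(
            rng.random((nb, p.n)) < plan.p_visible, 1, -1
        ).astype(np.int8)
        h = np.where(
            rng.random((nb, p.m)) < plan.p_hidden, 1, -1
        ).astype(np.int8)
        # prod_ij e^{(w_ij s_i h_j - |w_ij|)/k}
        log_acc = (
            np.einsum("bi,ij,bj->b", sigma.astype(float), p.w, h.astype(float))
            - abs_w_sum
        ) / k
        accept_idx = np.nonzero(rng.random(nb) < np.exp(log_acc))[0]
        need = n_samples - batch.n_accepted
        if accept_idx.size > need:
            # stop at the attempt that produced the target-th acceptance so
            # the attempt count stays an unbiased rate denominator
            batch.n_attempts += int(accept_idx[need - 1]) + 1
            accept_idx = accept_idx[:need]
        else:
            batch.n_attempts += nb
        rows = np.concatenate([sigma[accept_idx], h[accept_idx]], axis=1)
        for row in rows:
            key = tuple(int(v) for v in row)
            batch.counts[key] = batch.counts.get(key, 0) + 1
    return batch


def exact_Q(p: RBMParameters, k: float) -> tuple[np.ndarray, np.ndarray]:
    """Enumerate ``Q(y) ∝ P(y)^(1/k)`` over all joint configurations.

    Returns ``(spins, q)`` where ``spins`` has shape ``(2**(n+m), n+m)``
    (visible spins first) and ``q`` sums to one.
    """
    if p.n + p.m > _JOINT_CAP:
        raise ResourceError(
            f"{p.n + p.m} joint spins exceeds enumeration cap {_JOINT_CAP}"
        )
    if k <= 0:
        raise ValueError("k must be positive")
    spins = all_basis_spins(p.n + p.m).astype(float)
    sigma, h = spins[:, :p.n], spins[:, p.n:]
    energy = sigma @ p.a + h @ p.b + np.einsum("bi,ij,bj->b", sigma, p.w, h)
    logq = energy / k
    logq -= logq.max()
    q = np.exp(logq)
    return spins.astype(np.int8), q / q.sum()


def gibbs_distribution(p: RBMParameters) -> tuple[np.ndarray, np.ndarray]:
    """Exact joint Gibbs law ``P(y)`` (the ``k = 1`` special case)."""
    return exact_Q(p, 1.0)


def recover_gibbs(
    batch: SampleBatch, k: float
) -> tuple[dict[tuple[int, ...], float], dict[tuple[int, ...], float]]:
    """Raise empirical frequencies to the power ``k`` and normalize.

    Returns ``(joint, visible)``: the recovered Gibbs distribution over
    observed joint configurations and its marginal over the visible spins.
    Configurations never observed get probability zero; the power-``k``
    map makes rare-state estimates biased on finite samples, so exact
    enumeration remains the reference for small systems.
    """
    if batch.n_accepted == 0:
        raise ValueError("empty sample batch")
    if k <= 0:
        raise ValueError("k must be positive")
    keys = list(batch.counts)
    logf = np.log(np.array([batch.counts[y] for y in keys], dtype=float))
    logg = k * logf
    logg -= logg.max()
    g = np.exp(logg)
    g /= g.sum()
    joint = {y: float(v) for y, v in zip(keys, g)}
    visible: dict[tuple[int, ...], float] = {}
    for y, v in joint.items():
        x = y[:batch.n]
        visible[x] = visible.get(x, 0.0) + v
    return joint, visible


def effective_sample_size(batch: SampleBatch, k: float) -> float:
    """Kish effective sample size of the power-``k`` reweighting."""
    counts = np.array(list(batch.counts.values()), dtype=float)
    f = counts / counts.sum()
    logw = (k - 1.0) * np.log(f)
    logw -= logw.max()
    w = np.exp(logw)
    return float(counts.sum() * (f @ w) ** 2 / (f @ w**2))
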