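"""Independent brute-force oracles used to cross-check the implementation.

Everything here deliberately avoids the code paths under test: matrices
are assembled by naive dense kron loops, hidden units are marginalized by
explicit summation, and the fermionic Hamiltonian is built directly from
2x2 ladder matrices in Fock space.
"""

from __future__ import annotations

import numpy as np

from nqschem.jordanwigner import IntegralSet
from nqschem.pauli import QubitHamiltonian
from nqschem.rbm import RBMParameters

_P2 = {
    "I": np.eye(2, dtype=complex),
    "X": np.array([[0, 1], [1, 0]], dtype=complex),
    "Y": np.array([[0, -1j], [1j, 0]], dtype=complex),
    "Z": np.array([[1, 0], [0, -1]], dtype=complex),
}


def naive_matrix(h: QubitHamiltonian) -> np.ndarray:
    """Per-term dense kron loop; qubit 0 is the most significant factor."""
    dim = 2 ** h.n_qubits
    acc = np.zeros((dim, dim), dtype=complex)
    for t in h.terms:
        m = np.array([[1.0]], dtype=complex)
        for q in range(h.n_qubits):
            m = np.kron(m, _P2[t.factors.get(q, "I")])
        acc += t.coefficient * m
    return acc


def brute_force_ptilde(p: RBMParameters, sigma: np.ndarray) -> float:
    """Explicit sum over all 2**m hidden configurations."""
    total = 0.0
    for idx in range(2 ** p.m):
        hvec = np.array(
            [1 if (idx >> (p.m - 1 - j)) & 1 else -1 for j in range(p.m)],
            dtype=float,
        )
        total += np.exp(
            p.a @ sigma + p.b @ hvec + sigma @ p.w @ hvec
        )
    return float(total)


# ---------------------------------------------------------------------------
# Fock-space ladder-operator oracle
# ---------------------------------------------------------------------------

def _ladder_matrices(n_so: int) -> list[np.ndarray]:
    """Annihilation matrices a_p with Jordan-Wigner sign strings.

    Single-site basis (|0>, |1>) with |1> = occupied; qubit 0 is the most
    significant bit, matching the package's basis indexing.
    """
    ann = np.array([[0, 1], [0, 0]], dtype=float)
    z = np.diag([1.0, -1.0])
    eye = np.eye(2)
    out = []
    for p in range(n_so):
        m = np.array([[1.0]])
        for q in range(n_so):
            m = np.kron(m, z if q < p else (ann if q == p else eye))
        out.append(m)
    return out


def fock_hamiltonian(ints: IntegralSet) -> np.ndarray:
    """Dense Fock-space matrix of the second-quantized Hamiltonian.

    Spin orbitals are interleaved (alpha0, beta0, alpha1, ...); the
    two-electron part is 1/2 sum_ijkl <ij|lk> a+_i a+_j a_k a_l with the
    physicists'-notation spatial integrals of the IntegralSet.
    """
    n_so = 2 * ints.n_spatial
    dim = 2 ** n_so
    a = _ladder_matrices(n_so)
    adag = [m.T for m in a]
    H = ints.e_const * np.eye(dim)
    for i in range(n_so):
        for j in range(n_so):
            if i % 2 != j % 2:
                continue
            v = ints.h1[i // 2, j // 2]
            if v != 0.0:
                H += v * adag[i] @ a[j]
    g = ints.h2
    for i in range(n_so):
        for j in range(n_so):
            for k in range(n_so):
                for l in range(n_so):
                    if (i % 2) != (l % 2) or (j % 2) != (k % 2):
                        continue
                    v = g[i // 2, j // 2, l // 2, k // 2]
                    if v != 0.0:
                        H += 0.5 * v * adag[i] @ adag[j] @ a[k] @ a[l]
    return H


def number_operator(n_so: int) -> np.ndarray:
    a = _ladder_matrices(n_so)
    return sum(m.T @ m for m in a)


def frozen_subspace_indices(
    n_spatial: int, frozen: list[int], discarded: list[int]
) -> np.ndarray:
    """Fock-basis indices with frozen orbitals doubly occupied, discarded empty.

    Sorted ascending, which matches the active-space basis ordering since
    bit significance is preserved when fixed bits are removed.
    """
    n_so = 2 * n_spatial
    frozen_bits = [2 * p + s for p in frozen for s in (0, 1)]
    discarded_bits = [2 * p + s for p in discarded for s in (0, 1)]
    sel = []
    for idx in range(2 ** n_so):
        bits = [(idx >> (n_so - 1 - q)) & 1 for q in range(n_so)]
        if all(bits[q] == 1 for q in frozen_bits) and all(
            bits[q] == 0 for q in discarded_bits
        ):
            sel.append(idx)
    return np.array(sorted(sel))


def random_integral_set(
    n_spatial: int,
    rng: np.random.Generator,
    n_electrons: int | None = None,
    two_body_scale: float = 0.3,
) -> IntegralSet:
    """Random real integral set with the full 8-fold permutation symmetry."""
    h1 = rng.normal(0.0, 1.0, (n_spatial,) * 2)
    h1 = 0.5 * (h1 + h1.T)
    chem = rng.normal(0.0, two_body_scale, (n_spatial,) * 4)
    chem = chem + chem.transpose(1, 0, 2, 3)
    chem = chem + chem.transpose(0, 1, 3, 2)
    chem = chem + chem.transpose(2, 3, 0, 1)
    h2 = chem.transpose(0, 2, 1, 3)  # (pq|rs) -> <pq|rs>
    if n_electrons is None:
        n_electrons = n_spatial
    return IntegralSet(
        n_spatial, h1, h2,
        e_const=float(rng.normal(0.0, 0.5)),
        n_electrons=n_electrons,
    )
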