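"""Qubit Hamiltonians as weighted sums of Pauli strings.

A molecular electronic-structure Hamiltonian, after the Jordan-Wigner
transformation, is a weighted sum of tensor products of single-qubit Pauli
operators.  This module provides the in-memory representation, a plain-text
file format (``.ham``), dense/sparse matrix assembly, sparse row access
(the matrix elements ``<x|H|x'>`` needed by the local-energy estimator) and
exact diagonalization, which serves as the ground-truth reference
throughout the package.

Basis conventions
-----------------
A computational basis state is labelled by spins ``sigma_i in {+1, -1}``,
one per qubit, with ``sigma_i = +1`` meaning qubit *i* is in state ``|1>``
and ``sigma_i = -1`` meaning ``|0>``.  Consequently the diagonal matrix
element of ``Z_i`` is ``-sigma_i`` (``Z|1> = -|1>``).  The integer index of
a basis state treats qubit 0 as the most significant bit:
``index = sum_i bit_i * 2**(n-1-i)``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "PauliString",
    "QubitHamiltonian",
    "BasisState",
    "HamParseError",
    "ResourceError",
    "parse_hamiltonian",
    "serialize_hamiltonian",
    "read_hamiltonian",
    "write_hamiltonian",
    "to_matrix",
    "to_sparse",
    "matrix_row",
    "exact_ground_state",
    "QUBIT_CAP",
]

#: Largest qubit count for which dense/sparse matrix assembly is attempted.
QUBIT_CAP = 14

#: Above this qubit count matrices are assembled sparsely.
_DENSE_LIMIT = 10

_PAULI_2x2 = {
    "I": np.eye(2),
    "X": np.array([[0.0, 1.0], [1.0, 0.0]]),
    "Y": np.array([[0.0, -1.0j], [1.0j, 0.0]]),
    "Z": np.array([[1.0, 0.0], [0.0, -1.0]]),
}


class HamParseError(ValueError):
    """Raised for malformed Hamiltonian text."""


class ResourceError(RuntimeError):
    """Raised when a request exceeds the configured qubit cap."""


@dataclass(frozen=True)
class PauliString:
    """One tensor product of single-qubit Pauli operators with a real weight.

    Parameters
    ----------
    coefficient
        Real weight in Hartree.
    factors
        Mapping from 0-based qubit index to an operator label in
        ``{"X", "Y", "Z"}``.  Qubits absent from the map carry the identity.
        An empty map denotes the identity term.
    """

    coefficient: float
    factors: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.coefficient):
            raise ValueError(f"non-finite coefficient {self.coefficient!r}")
        for idx, op in self.factors.items():
            if not (isinstance(idx, (int, np.integer)) and idx >= 0):
                raise ValueError(f"bad qubit index {idx!r}")
            if op not in ("X", "Y", "Z"):
                raise ValueError(f"bad operator label {op!r}")

    @property
    def n_y(self) -> int:
        return sum(1 for op in self.factors.values() if op == "Y")

    def key(self) -> tuple[tuple[int, str], ...]:
        """Canonical identity of the operator part (sorted by qubit)."""
        return tuple(sorted(self.factors.items()))

    def __str__(self) -> str:
        parts = [_format_coeff(self.coefficient)]
        parts += [f"{op}{idx}" for idx, op in sorted(self.factors.items())]
        return " ".join(parts)


def _format_coeff(c: float) -> str:
    return repr(float(c))


@dataclass
class QubitHamiltonian:
    """Weighted sum of Pauli strings acting on ``n_qubits`` qubits."""

    n_qubits: int
    terms: list[PauliString] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_qubits < 1:
            raise ValueError("n_qubits must be >= 1")
        for t in self.terms:
            if t.factors and max(t.factors) >= self.n_qubits:
                raise ValueError(
                    f"term {t} touches qubit {max(t.factors)} but the "
                    f"Hamiltonian declares {self.n_qubits} qubits"
                )
            # A Pauli string with an odd number of Y factors and a real
            # coefficient has purely imaginary matrix elements; distinct
            # Pauli strings are linearly independent, so such a term can
            # never cancel and the matrix would be complex.  The real
            # amplitude-times-sign ansatz cannot represent complex ground
            # states, so these Hamiltonians are rejected outright.
            if t.n_y % 2 == 1:
                raise ValueError(
                    f"term {t} has an odd number of Y factors; its matrix "
                    "is imaginary and not representable by a real ansatz"
                )

    def simplify(self, tol: float = 1e-12) -> "QubitHamiltonian":
        """Merge like terms and drop coefficients below ``tol``."""
        acc: dict[tuple, float] = {}
        for t in self.terms:
            acc[t.key()] = acc.get(t.key(), 0.0) + t.coefficient
        terms = [
            PauliString(c, dict(k)) for k, c in acc.items() if abs(c) > tol
        ]
        return QubitHamiltonian(self.n_qubits, terms)

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class BasisState:
    """A computational basis state as a vector of spins over ``{+1, -1}``."""

    spins: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(s not in (-1, 1) for s in self.spins):
            raise ValueError("spins must be +1 or -1")

    @property
    def n(self) -> int:
        return len(self.spins)

    @property
    def index(self) -> int:
        """Integer label; qubit 0 is the most significant bit."""
        idx = 0
        for s in self.spins:
            idx = (idx << 1) | (1 if s == 1 else 0)
        return idx

    @classmethod
    def from_index(cls, index: int, n_qubits: int) -> "BasisState":
        if not 0 <= index < 2**n_qubits:
            raise ValueError(f"index {index} out of range for {n_qubits} qubits")
        bits = [(index >> (n_qubits - 1 - i)) & 1 for i in range(n_qubits)]
        return cls(tuple(1 if b else -1 for b in bits))

    def __iter__(self) -> Iterator[int]:
        return iter(self.spins)


def all_basis_spins(n_qubits: int) -> np.ndarray:
    """Spin matrix of shape ``(2**n, n)``; row ``i`` is the state of index ``i``."""
    idx = np.arange(2**n_qubits)
    shifts = n_qubits - 1 - np.arange(n_qubits)
    bits = (idx[:, None] >> shifts[None, :]) & 1
    return (2 * bits - 1).astype(np.int8)


# ---------------------------------------------------------------------------
# Text format
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^([XYZ])(\d+)$")


def parse_hamiltonian(source: str | TextIO) -> QubitHamiltonian:
    """Parse the ``.ham`` plain-text format.

    Lines: ``#`` starts a comment; the first non-comment line is
    ``qubits N``; every following non-empty line is
    ``<coeff> [<P><idx> ...]`` with ``P`` in ``{X, Y, Z}`` and 0-based
    indices.  An empty factor list denotes the identity term.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    n_qubits: int | None = None
    terms: list[PauliString] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if n_qubits is None:
            m = re.match(r"^qubits\s+(\d+)$", line)
            if not m:
                raise HamParseError(
                    f"line {lineno}: expected 'qubits N' header, got {line!r}"
                )
            n_qubits = int(m.group(1))
            continue
        tokens = line.split()
        try:
            coeff = float(tokens[0].replace("−", "-"))
        except ValueError as exc:
            raise HamParseError(
                f"line {lineno}: bad coefficient {tokens[0]!r}"
            ) from exc
        factors: dict[int, str] = {}
        for tok in tokens[1:]:
            m = _TERM_RE.match(tok)
            if not m:
                raise HamParseError(f"line {lineno}: bad factor {tok!r}")
            op, idx = m.group(1), int(m.group(2))
            if idx in factors:
                raise HamParseError(
                    f"line {lineno}: duplicate qubit index {idx}"
                )
            factors[idx] = op
        terms.append(PauliString(coeff, factors))
    if n_qubits is None:
        raise HamParseError("empty input: missing 'qubits N' header")
    return QubitHamiltonian(n_qubits, terms)


def serialize_hamiltonian(h: QubitHamiltonian) -> str:
    """Write the ``.ham`` format; terms sorted by (factor count, factors)."""
    lines = [f"qubits {h.n_qubits}"]
    for t in sorted(h.terms, key=lambda t: (len(t.factors), t.key())):
        lines.append(str(t))
    return "\n".join(lines) + "\n"


def read_hamiltonian(path) -> QubitHamiltonian:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_hamiltonian(fh)


def write_hamiltonian(h: QubitHamiltonian, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(serialize_hamiltonian(h))


# ---------------------------------------------------------------------------
# Matrix backing
# ---------------------------------------------------------------------------

def _check_cap(n_qubits: int, cap: int) -> None:
    if n_qubits > cap:
        raise ResourceError(
            f"{n_qubits} qubits exceeds the configured cap of {cap}"
        )


def to_sparse(h: QubitHamiltonian, cap: int = QUBIT_CAP) -> sp.csr_matrix:
    """Sparse CSR matrix of the Hamiltonian (real; realness is enforced)."""
    _check_cap(h.n_qubits, cap)
    dim = 2**h.n_qubits
    acc = sp.csr_matrix((dim, dim), dtype=complex)
    for t in h.terms:
        m = sp.identity(1, dtype=complex, format="csr")
        for q in range(h.n_qubits):
            op = t.factors.get(q, "I")
            m = sp.kron(m, sp.csr_matrix(_PAULI_2x2[op]), format="csr")
        acc = acc + t.coefficient * m
    imag_max = abs(acc.imag).max() if acc.nnz else 0.0
    if imag_max > 1e-10:
        raise ValueError(
            f"Hamiltonian matrix has imaginary entries up to {imag_max:.3e}"
        )
    return acc.real.tocsr()


def to_matrix(h: QubitHamiltonian, cap: int = QUBIT_CAP) -> np.ndarray:
    """Dense matrix of the Hamiltonian under the declared basis encoding.

    Dense kron products are used up to 10 qubits; above that the matrix is
    assembled sparsely and densified at the end.
    """
    _check_cap(h.n_qubits, cap)
    if h.n_qubits > _DENSE_LIMIT:
        return to_sparse(h, cap=cap).toarray()
    dim = 2**h.n_qubits
    acc = np.zeros((dim, dim), dtype=complex)
    for t in h.terms:
        m = np.ones((1, 1), dtype=complex)
        for q in range(h.n_qubits):
            m = np.kron(m, _PAULI_2x2[t.factors.get(q, "I")])
        acc += t.coefficient * m
    imag_max = abs(acc.imag).max()
    if imag_max > 1e-10:
        raise ValueError(
            f"Hamiltonian matrix has imaginary entries up to {imag_max:.3e}"
        )
    return acc.real


def matrix_row(
    h: QubitHamiltonian, x: BasisState | Sequence[int]
) -> list[tuple[BasisState, float]]:
    """Nonzero entries ``<x|H|x'>`` of the row of H labelled by ``x``.

    Each Pauli string connects ``x`` to exactly one ``x'``: the state with
    the X/Y positions of the string flipped.  Entries from strings sharing
    a flip pattern are summed.
    """
    if not isinstance(x, BasisState):
        x = BasisState(tuple(x))
    if x.n != h.n_qubits:
        raise ValueError("basis state length does not match qubit count")
    acc: dict[tuple[int, ...], complex] = {}
    for t in h.terms:
        amp: complex = t.coefficient
        spins = list(x.spins)
        for q, op in t.factors.items():
            s = x.spins[q]
            if op == "Z":
                amp *= -s  # Z|1> = -|1>, sigma=+1 <-> |1>
            elif op == "X":
                spins[q] = -s
            else:  # Y: <1|Y|0> = +i, <0|Y|1> = -i; row bit is that of x
                amp *= 1j * s
                spins[q] = -s
        key = tuple(spins)
        acc[key] = acc.get(key, 0.0) + amp
    out: list[tuple[BasisState, float]] = []
    for spins, amp in acc.items():
        if abs(amp.imag) > 1e-10:
            raise ValueError("complex matrix element encountered")
        if amp.real != 0.0:
            out.append((BasisState(spins), float(amp.real)))
    return out


def exact_ground_state(
    h: QubitHamiltonian, cap: int = QUBIT_CAP
) -> tuple[float, np.ndarray]:
    """Lowest eigenvalue and normalized eigenvector of the Hamiltonian."""
    _check_cap(h.n_qubits, cap)
    if h.n_qubits <= _DENSE_LIMIT:
        mat = to_matrix(h, cap=cap)
        vals, vecs = np.linalg.eigh(mat)
        vec = vecs[:, 0]
        return float(vals[0]), vec / np.linalg.norm(vec)
    mat = to_sparse(h, cap=cap)
    vals, vecs = spla.eigsh(mat, k=1, which="SA")
    vec = vecs[:, 0]
    return float(vals[0]), vec / np.linalg.norm(vec)
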