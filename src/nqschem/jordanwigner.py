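"""Second-quantized electronic Hamiltonians and the Jordan-Wigner mapping.

The electronic Hamiltonian over spin orbitals,

    H = sum_ij h_ij a+_i a_j + 1/2 sum_ijkl h_ijkl a+_i a+_j a_k a_l + E_0,

is built from a set of one- and two-electron integrals (read from FCIDUMP
files) and mapped to a qubit Hamiltonian with one qubit per spin orbital,
``|1>`` meaning occupied.  Active-space reduction (frozen doubly occupied
orbitals and discarded virtuals) is applied at the integral level before
the mapping.

Index conventions
-----------------
Two-electron integrals are stored in physicists' notation
``<pq|rs> = integral p*(1) q*(2) r12^-1 r(1) s(2)`` over *spatial*
orbitals, so the second-quantized form above applies literally with
``h_ijkl = <ij|lk>`` over spin orbitals.  FCIDUMP files use chemists'
notation ``(pq|rs)``; the reader converts via ``<pq|rs> = (pr|qs)``.
Spin orbitals are interleaved: qubit ``2p`` is (spatial p, alpha), qubit
``2p + 1`` is (spatial p, beta).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import TextIO

import numpy as np

from .pauli import PauliString, QubitHamiltonian, ResourceError

__all__ = [
    "IntegralSet",
    "ActiveSpaceSpec",
    "FcidumpError",
    "read_fcidump",
    "write_fcidump",
    "apply_active_space",
    "jordan_wigner",
    "spin_orbital_order",
]

#: Spatial-orbital cap so the qubit count stays within the 14-qubit cap.
SPATIAL_CAP = 7


class FcidumpError(ValueError):
    """Raised for malformed FCIDUMP input."""


@dataclass
class IntegralSet:
    """One- and two-electron integrals of a molecular Hamiltonian.

    Attributes
    ----------
    n_spatial
        Number of spatial orbitals.
    h1
        ``(n_spatial, n_spatial)`` symmetric one-electron integrals (Hartree).
    h2
        Rank-4 two-electron integrals in physicists' notation
        ``h2[p, q, r, s] = <pq|rs>`` over spatial orbitals (Hartree).
    e_const
        Scalar constant: nuclear repulsion plus any frozen-core shift.
    n_electrons
        Electron count.
    """

    n_spatial: int
    h1: np.ndarray
    h2: np.ndarray
    e_const: float = 0.0
    n_electrons: int = 0

    def __post_init__(self) -> None:
        n = self.n_spatial
        self.h1 = np.asarray(self.h1, dtype=float)
        self.h2 = np.asarray(self.h2, dtype=float)
        if self.h1.shape != (n, n):
            raise ValueError(f"h1 must be ({n}, {n})")
        if self.h2.shape != (n, n, n, n):
            raise ValueError(f"h2 must be rank-4 with dimension {n}")
        if not (np.isfinite(self.h1).all() and np.isfinite(self.h2).all()):
            raise ValueError("integrals must be finite")
        if not np.allclose(self.h1, self.h1.T, atol=1e-10):
            raise ValueError("h1 must be symmetric")
        g = self.h2
        for perm in [(1, 0, 3, 2), (2, 1, 0, 3), (0, 3, 2, 1)]:
            if not np.allclose(g, g.transpose(perm), atol=1e-10):
                raise ValueError(
                    "h2 lacks the real-integral permutation symmetry "
                    f"(failed transpose {perm})"
                )

    @property
    def n_spin_orbitals(self) -> int:
        return 2 * self.n_spatial


@dataclass
class ActiveSpaceSpec:
    """Orbitals to freeze as doubly occupied or discard as always empty."""

    frozen_occupied: list[int] = field(default_factory=list)
    discarded_virtual: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.frozen_occupied) & set(self.discarded_virtual):
            raise ValueError("frozen and discarded orbital lists overlap")


# ---------------------------------------------------------------------------
# FCIDUMP I/O
# ---------------------------------------------------------------------------

def read_fcidump(source: str | TextIO) -> IntegralSet:
    """Read a Molpro-dialect FCIDUMP file.

    The namelist header must declare ``NORB`` and ``NELEC``.  Records are
    ``value i j k l`` with 1-based indices; ``i=j=k=l=0`` is the core
    energy, ``k=l=0`` a one-electron integral and the rest two-electron
    integrals in chemists' notation, expanded to all eight equivalent index
    orders.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    text = source.read()
    m = re.search(r"&FCI(.*?)(?:&END|/)", text, re.S | re.I)
    if not m:
        raise FcidumpError("missing &FCI namelist header")
    header, body = m.group(1), text[m.end():]

    def _field(name: str) -> int | None:
        fm = re.search(rf"{name}\s*=\s*(\d+)", header, re.I)
        return int(fm.group(1)) if fm else None

    norb = _field("NORB")
    nelec = _field("NELEC")
    if norb is None or nelec is None:
        raise FcidumpError("header must declare NORB and NELEC")

    h1 = np.zeros((norb, norb))
    chem = np.zeros((norb, norb, norb, norb))
    e_const = 0.0
    for lineno, raw in enumerate(body.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) != 5:
            raise FcidumpError(f"record {lineno}: expected 'value i j k l'")
        try:
            value = float(tokens[0].replace("D", "E").replace("d", "e"))
            i, j, k, l = (int(t) for t in tokens[1:])
        except ValueError as exc:
            raise FcidumpError(f"record {lineno}: bad field") from exc
        if any(t < 0 or t > norb for t in (i, j, k, l)):
            raise FcidumpError(f"record {lineno}: index out of range")
        if i == j == k == l == 0:
            e_const = value
        elif k == 0 and l == 0:
            if i == 0 or j == 0:
                raise FcidumpError(f"record {lineno}: bad one-electron index")
            h1[i - 1, j - 1] = value
            h1[j - 1, i - 1] = value
        else:
            if 0 in (i, j, k, l):
                raise FcidumpError(f"record {lineno}: bad two-electron index")
            p, q, r, s = i - 1, j - 1, k - 1, l - 1
            for a, b in ((p, q), (q, p)):
                for c, d in ((r, s), (s, r)):
                    chem[a, b, c, d] = value
                    chem[c, d, a, b] = value
    # chemists' (pq|rs) -> physicists' <pq|rs> = (pr|qs)
    h2 = chem.transpose(0, 2, 1, 3)
    return IntegralSet(norb, h1, h2, e_const=e_const, n_electrons=nelec)


def write_fcidump(ints: IntegralSet, stream: TextIO, ms2: int = 0) -> None:
    """Write an FCIDUMP file (canonical unique records only)."""
    n = ints.n_spatial
    stream.write(
        f"&FCI NORB={n},NELEC={ints.n_electrons},MS2={ms2},\n"
        f" ORBSYM={','.join(['1'] * n)},\n ISYM=1,\n&END\n"
    )
    chem = ints.h2.transpose(0, 2, 1, 3)  # <pq|rs> -> (pq|rs)

    def pair(i, j):
        return (max(i, j), min(i, j))

    seen = set()
    for p in range(n):
        for q in range(p + 1):
            for r in range(n):
                for s in range(r + 1):
                    if (pair(p, q), pair(r, s)) in seen or pair(p, q) < pair(r, s):
                        continue
                    seen.add((pair(p, q), pair(r, s)))
                    v = float(chem[p, q, r, s])
                    if v != 0.0:
                        stream.write(
                            f"{v!r} {p + 1} {q + 1} {r + 1} {s + 1}\n"
                        )
    for p in range(n):
        for q in range(p + 1):
            if ints.h1[p, q] != 0.0:
                stream.write(f"{float(ints.h1[p, q])!r} {p + 1} {q + 1} 0 0\n")
    stream.write(f"{float(ints.e_const)!r} 0 0 0 0\n")


# ---------------------------------------------------------------------------
# Active space
# ---------------------------------------------------------------------------

def apply_active_space(
    ints: IntegralSet, spec: ActiveSpaceSpec
) -> IntegralSet:
    """Freeze doubly occupied orbitals and discard empty virtuals.

    The frozen orbitals' energy (one-electron, Coulomb and exchange) is
    absorbed into ``e_const``; the active one-electron integrals gain the
    mean field of the frozen electrons; discarded virtuals are simply
    removed.  The electron count drops by two per frozen orbital.
    """
    frozen = sorted(spec.frozen_occupied)
    discarded = set(spec.discarded_virtual)
    for idx in list(frozen) + list(discarded):
        if not 0 <= idx < ints.n_spatial:
            raise ValueError(f"orbital index {idx} out of range")
    if 2 * len(frozen) > ints.n_electrons:
        raise ValueError("more frozen orbitals than electron pairs")

    g = ints.h2  # <pq|rs>
    e_const = ints.e_const
    e_const += 2.0 * sum(ints.h1[f, f] for f in frozen)
    for f in frozen:
        for f2 in frozen:
            e_const += 2.0 * g[f, f2, f, f2] - g[f, f2, f2, f]

    h1_eff = ints.h1.copy()
    for f in frozen:
        # Coulomb <pf|qf> (both spins) minus exchange <pf|fq> (same spin)
        h1_eff += 2.0 * g[:, f, :, f] - g[:, f, f, :]

    active = [
        p for p in range(ints.n_spatial)
        if p not in frozen and p not in discarded
    ]
    if not active:
        raise ValueError("active space is empty")
    idx = np.asarray(active)
    return IntegralSet(
        n_spatial=len(active),
        h1=h1_eff[np.ix_(idx, idx)],
        h2=g[np.ix_(idx, idx, idx, idx)],
        e_const=e_const,
        n_electrons=ints.n_electrons - 2 * len(frozen),
    )


# ---------------------------------------------------------------------------
# Jordan-Wigner transformation
# ---------------------------------------------------------------------------

def spin_orbital_order(n_spatial: int) -> dict[tuple[int, str], int]:
    """Interleaved (spatial, spin) -> qubit map: alpha0, beta0, alpha1, ..."""
    return {
        (p, spin): 2 * p + (0 if spin == "alpha" else 1)
        for p in range(n_spatial)
        for spin in ("alpha", "beta")
    }


_MUL = {
    ("X", "X"): (1.0, "I"), ("Y", "Y"): (1.0, "I"), ("Z", "Z"): (1.0, "I"),
    ("X", "Y"): (1j, "Z"), ("Y", "X"): (-1j, "Z"),
    ("Y", "Z"): (1j, "X"), ("Z", "Y"): (-1j, "X"),
    ("Z", "X"): (1j, "Y"), ("X", "Z"): (-1j, "Y"),
}


def _string_mul(
    c1: complex, f1: dict[int, str], c2: complex, f2: dict[int, str]
) -> tuple[complex, dict[int, str]]:
    coeff = c1 * c2
    out = dict(f1)
    for q, op in f2.items():
        if q not in out:
            out[q] = op
        else:
            phase, prod = _MUL[(out[q], op)]
            coeff *= phase
            if prod == "I":
                del out[q]
            else:
                out[q] = prod
    return coeff, out


def _ladder(p: int, dagger: bool) -> list[tuple[complex, dict[int, str]]]:
    """JW image of a_p (or a+_p): Z string below p times (X -+ iY)/2."""
    zs = {q: "Z" for q in range(p)}
    sign = -1j if dagger else 1j
    return [
        (0.5, {**zs, p: "X"}),
        (0.5 * sign, {**zs, p: "Y"}),
    ]


def _product(
    ops: list[list[tuple[complex, dict[int, str]]]]
) -> list[tuple[complex, dict[int, str]]]:
    acc = [(1.0 + 0j, {})]
    for factor in ops:
        nxt = []
        for c1, f1 in acc:
            for c2, f2 in factor:
                nxt.append(_string_mul(c1, f1, c2, f2))
        acc = nxt
    return acc


def jordan_wigner(ints: IntegralSet, tol: float = 1e-12) -> QubitHamiltonian:
    """Map an integral set to a qubit Hamiltonian (one qubit per spin orbital).

    ``a+_p = (prod_{q<p} Z_q)(X_p - i Y_p)/2`` with ``|1>`` meaning
    occupied.  Like terms are merged; coefficients below ``tol`` dropped;
    the result has purely real coefficients.
    """
    if ints.n_spatial > SPATIAL_CAP:
        raise ResourceError(
            f"{ints.n_spatial} spatial orbitals exceeds the cap of "
            f"{SPATIAL_CAP} (qubit cap)"
        )
    n_so = ints.n_spin_orbitals
    acc: dict[tuple[tuple[int, str], ...], complex] = {(): complex(ints.e_const)}

    def add(terms: list[tuple[complex, dict[int, str]]], weight: float) -> None:
        for c, f in terms:
            key = tuple(sorted(f.items()))
            acc[key] = acc.get(key, 0.0) + weight * c

    def spat(i: int) -> int:
        return i // 2

    def spin(i: int) -> int:
        return i % 2

    for i in range(n_so):
        for j in range(n_so):
            if spin(i) != spin(j):
                continue
            hij = ints.h1[spat(i), spat(j)]
            if hij == 0.0:
                continue
            add(_product([_ladder(i, True), _ladder(j, False)]), hij)

    g = ints.h2  # <pq|rs> spatial, physicists'
    for i in range(n_so):
        for j in range(n_so):
            if j == i:
                continue
            for k in range(n_so):
                for l in range(n_so):
                    if l == k:
                        continue
                    # h_ijkl = <ij|lk> with spin conservation i~l, j~k
                    if spin(i) != spin(l) or spin(j) != spin(k):
                        continue
                    v = g[spat(i), spat(j), spat(l), spat(k)]
                    if v == 0.0:
                        continue
                    add(
                        _product([
                            _ladder(i, True), _ladder(j, True),
                            _ladder(k, False), _ladder(l, False),
                        ]),
                        0.5 * v,
                    )

    terms: list[PauliString] = []
    for key, coeff in acc.items():
        if abs(coeff.imag) > 1e-10:
            raise ValueError(
                f"non-real Jordan-Wigner coefficient {coeff} for {key}"
            )
        if abs(coeff.real) > tol:
            terms.append(PauliString(float(coeff.real), dict(key)))
    return QubitHamiltonian(n_so, terms)
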