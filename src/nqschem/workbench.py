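"""Fixture generation, qubit-resource accounting and scan driving.

These are the tool-level conveniences around the solver: reproducible
random Pauli Hamiltonians for testing and benchmarking, the qubit budget
of the sampling circuit, and potential-energy-surface style scans over an
ordered family of Hamiltonians with optional transfer-learning warm
starts between neighboring points.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import solver
from .pauli import (
    PauliString,
    QubitHamiltonian,
    exact_ground_state,
    read_hamiltonian,
    serialize_hamiltonian,
)
from .solver import TrainConfig

__all__ = [
    "FixtureSpec",
    "ScanJob",
    "ScanPointResult",
    "qubit_requirement",
    "generate_fixture",
    "run_scan",
]


def qubit_requirement(n: int, m: int, reuse_ancilla: bool = True) -> int:
    """Qubit budget of the sampling circuit for ``n`` visible and ``m`` hidden units.

    One ancilla per coupling gives ``n + m + n*m`` qubits; measuring and
    re-preparing a single ancilla between couplings reduces the total to
    ``n + m + 1``.
    """
    if n < 1 or m < 1:
        raise ValueError("need n, m >= 1")
    return n + m + 1 if reuse_ancilla else n + m + n * m


@dataclass
class FixtureSpec:
    """Recipe for a reproducible random real Pauli Hamiltonian."""

    n_qubits: int
    n_terms: int = 8
    max_locality: int = 2
    coefficient_scale: float = 1.0
    seed: int = 0
    require_real: bool = True

    def __post_init__(self) -> None:
        if self.n_terms < 1:
            raise ValueError("n_terms must be >= 1")
        if not 1 <= self.max_locality <= self.n_qubits:
            raise ValueError("max_locality must be in [1, n_qubits]")
        if self.coefficient_scale <= 0:
            raise ValueError("coefficient_scale must be positive")


def generate_fixture(spec: FixtureSpec) -> QubitHamiltonian:
    """Draw a random Hamiltonian; identical spec -> identical result.

    Each term picks a locality, distinct qubits and operator labels
    uniformly; with ``require_real`` an odd Y count is repaired by turning
    one Y into an X, which keeps the matrix real symmetric.  Like terms
    are merged, so the final term count may be below ``n_terms``.
    """
    rng = np.random.default_rng(spec.seed)
    terms: list[PauliString] = []
    for _ in range(spec.n_terms):
        loc = int(rng.integers(1, spec.max_locality + 1))
        qubits = sorted(rng.choice(spec.n_qubits, size=loc, replace=False))
        ops = [str(o) for o in rng.choice(["X", "Y", "Z"], size=loc)]
        if spec.require_real and ops.count("Y") % 2 == 1:
            ops[ops.index("Y")] = "X"
        coeff = 0.0
        while coeff == 0.0:
            coeff = float(
                rng.uniform(-spec.coefficient_scale, spec.coefficient_scale)
            )
        terms.append(PauliString(coeff, dict(zip(map(int, qubits), ops))))
    return QubitHamiltonian(spec.n_qubits, terms).simplify()


def write_fixture(spec: FixtureSpec, path) -> QubitHamiltonian:
    h = generate_fixture(spec)
    Path(path).write_text(serialize_hamiltonian(h), encoding="utf-8")
    return h


@dataclass
class ScanPointResult:
    label: str
    min_energy: float
    exact_energy: float
    error: float
    iterations_run: int
    warm_started: bool


@dataclass
class ScanJob:
    """An ordered family of Hamiltonians trained in sequence.

    ``points`` maps opaque labels (e.g. bond lengths) to Hamiltonians or
    ``.ham`` file paths.  With ``transfer_learning`` on, every point after
    the first is warm-started from its predecessor's best parameters and
    run for the configured fraction of the iteration budget.
    """

    points: list[tuple[str, QubitHamiltonian | str | Path]]
    config: TrainConfig = field(default_factory=TrainConfig)
    transfer_learning: bool = False

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("scan needs at least one point")


def run_scan(job: ScanJob) -> list[ScanPointResult]:
    """Train every point of a scan; returns one result row per point."""
    hams: list[tuple[str, QubitHamiltonian]] = []
    for label, source in job.points:
        h = source if isinstance(source, QubitHamiltonian) else read_hamiltonian(source)
        hams.append((str(label), h))
    counts = {h.n_qubits for _, h in hams}
    if len(counts) != 1:
        raise ValueError(f"scan mixes qubit counts {sorted(counts)}")

    results: list[ScanPointResult] = []
    previous = None
    for i, (label, h) in enumerate(hams):
        warm = job.transfer_learning and previous is not None
        if warm:
            trace = solver.transfer_train(h, previous, job.config)
        else:
            trace = solver.train(h, job.config)
        previous = trace.best_parameters
        e_exact, _ = exact_ground_state(h)
        results.append(
            ScanPointResult(
                label=label,
                min_energy=trace.min_energy,
                exact_energy=e_exact,
                error=trace.min_energy - e_exact,
                iterations_run=len(trace.iterations),
                warm_started=warm,
            )
        )
    return results


def write_scan_csv(results: list[ScanPointResult], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        wr = csv.writer(fh)
        wr.writerow(
            ["label", "min_energy", "exact_energy", "error",
             "iterations_run", "warm_started"]
        )
        for r in results:
            wr.writerow(
                [r.label, r.min_energy, r.exact_energy, r.error,
                 r.iterations_run, int(r.warm_started)]
            )
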