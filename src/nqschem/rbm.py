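"""Three-layer restricted Boltzmann machine wavefunction ansatz.

The trial state over ``n`` qubits is ``psi(x) = phi(x) * s(x)`` where
``phi(x) = sqrt(P(x))`` is the square root of an RBM Gibbs marginal over
``m`` hidden spins,

    P~(x) = sum_h exp( a.sigma + b.h + sigma.W.h )
          = exp(a.sigma) * prod_j 2 cosh(b_j + sum_i W_ij sigma_i),

and ``s(x) = tanh(d.sigma + c)`` is a third, sign, layer that lets the
otherwise non-negative amplitude carry negative coefficients.  All spins
take values in ``{+1, -1}``.  Amplitude arithmetic is done in log space
(cosh overflows in double precision near ``|t| ~ 350``); signs are carried
separately by the sign layer, which is smooth rather than hard-thresholded.

Parameter vector layout (used by the gradient and checkpoints):
``[a (n), b (m), w row-major (n*m), d (n), c]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .pauli import BasisState, ResourceError, all_basis_spins

__all__ = [
    "RBMParameters",
    "AmplitudeTable",
    "S_FLOOR",
    "initialize",
    "unnormalized_prob",
    "log_unnormalized_prob",
    "sign_value",
    "log_derivatives",
    "derivative_matrix",
    "full_table",
    "save_checkpoint",
    "load_checkpoint",
]

#: Sign magnitudes at or below this leave E_loc and the log-derivatives
#: undefined (division by s); such states are excluded from averages.
#: Their weight is P~ * s^2, which vanishes quadratically, so exclusion is
#: numerically consistent.
S_FLOOR = 1e-12

#: Default half-width of the uniform initialization interval; small enough
#: to keep tanh well away from saturation at the first iteration.
INIT_SCALE = 0.02

_TABLE_CAP = 14


@dataclass
class RBMParameters:
    """Trainable weights of the three-layer ansatz."""

    n: int
    m: int
    a: np.ndarray
    b: np.ndarray
    w: np.ndarray
    d: np.ndarray
    c: float

    def __post_init__(self) -> None:
        if self.n < 1 or self.m < 0:
            raise ValueError("need n >= 1 visible and m >= 0 hidden units")
        self.a = np.asarray(self.a, dtype=float).reshape(self.n)
        self.b = np.asarray(self.b, dtype=float).reshape(self.m)
        self.w = np.asarray(self.w, dtype=float).reshape(self.n, self.m)
        self.d = np.asarray(self.d, dtype=float).reshape(self.n)
        self.c = float(self.c)
        for arr in (self.a, self.b, self.w, self.d, np.array([self.c])):
            if not np.isfinite(arr).all():
                raise ValueError("parameters must be finite")

    @property
    def n_parameters(self) -> int:
        return self.n + self.m + self.n * self.m + self.n + 1

    def pack(self) -> np.ndarray:
        return np.concatenate(
            [self.a, self.b, self.w.ravel(), self.d, [self.c]]
        )

    @classmethod
    def unpack(cls, vec: np.ndarray, n: int, m: int) -> "RBMParameters":
        vec = np.asarray(vec, dtype=float)
        i = 0
        a = vec[i:i + n]; i += n
        b = vec[i:i + m]; i += m
        w = vec[i:i + n * m].reshape(n, m); i += n * m
        d = vec[i:i + n]; i += n
        c = vec[i]
        return cls(n, m, a, b, w, d, c)

    def copy(self) -> "RBMParameters":
        return RBMParameters(
            self.n, self.m, self.a.copy(), self.b.copy(),
            self.w.copy(), self.d.copy(), self.c,
        )


def initialize(
    n: int, m: int, seed: int | np.random.Generator,
    scale: float = INIT_SCALE,
) -> RBMParameters:
    """Draw every weight i.i.d. uniform on ``(-scale, scale)``."""
    if n < 1 or m < 1:
        raise ValueError("need n, m >= 1")
    rng = np.random.default_rng(seed)
    draw = lambda size: rng.uniform(-scale, scale, size=size)
    return RBMParameters(
        n, m, draw(n), draw(m), draw((n, m)), draw(n), float(draw(()))
    )


def _spins(x) -> np.ndarray:
    if isinstance(x, BasisState):
        return np.asarray(x.spins, dtype=float)
    return np.asarray(x, dtype=float)


def log_unnormalized_prob(p: RBMParameters, spins: np.ndarray) -> np.ndarray:
    """``log P~`` for one spin vector or a batch (last axis = visible)."""
    s = np.asarray(spins, dtype=float)
    theta = p.b + s @ p.w
    # log 2cosh(t) = logaddexp(t, -t), overflow-safe
    return s @ p.a + np.logaddexp(theta, -theta).sum(axis=-1)


def unnormalized_prob(p: RBMParameters, x) -> float:
    """``P~(x) = sum_h exp(a.sigma + b.h + sigma.W.h)`` in closed form."""
    return float(np.exp(log_unnormalized_prob(p, _spins(x))))


def sign_value(p: RBMParameters, x) -> float:
    """Sign-layer output ``tanh(d.sigma + c)``, strictly inside (-1, 1)."""
    return float(np.tanh(_spins(x) @ p.d + p.c))


def derivative_matrix(p: RBMParameters, spins: np.ndarray) -> np.ndarray:
    """Log-derivatives ``D_pk(x) = d log(phi(x) s(x)) / d pk`` for a batch.

    Returns shape ``(n_states, n_parameters)`` in pack() layout.  Rows for
    states with ``|s| <= S_FLOOR`` contain NaN and must be masked out by
    the caller.
    """
    S = np.atleast_2d(np.asarray(spins, dtype=float))
    theta = p.b + S @ p.w          # (N, m)
    t = np.tanh(theta)
    s = np.tanh(S @ p.d + p.c)     # (N,)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(np.abs(s) > S_FLOOR, (1.0 - s**2) / s, np.nan)
    d_a = S / 2.0
    d_b = t / 2.0
    d_w = 0.5 * np.einsum("xi,xj->xij", S, t).reshape(S.shape[0], -1)
    d_d = S * u[:, None]
    d_c = u[:, None]
    return np.concatenate([d_a, d_b, d_w, d_d, d_c], axis=1)


def log_derivatives(p: RBMParameters, x) -> np.ndarray:
    """Log-derivative vector at one basis state (pack() layout).

    Raises ``ValueError`` when the sign magnitude is at or below
    ``S_FLOOR`` — callers treat that as an excluded-state signal.
    """
    s = sign_value(p, x)
    if abs(s) <= S_FLOOR:
        raise ValueError("sign magnitude below floor; state excluded")
    return derivative_matrix(p, _spins(x))[0]


@dataclass
class AmplitudeTable:
    """Exhaustive per-basis-state amplitudes for an RBM parameter set.

    ``weight`` is proportional to ``P~(x) s(x)^2`` (the joint distribution
    the variational energy averages over); ``log_ptilde`` is shifted by a
    common constant for overflow safety, which is a pure gauge.
    """

    spins: np.ndarray      # (2**n, n) in {+1, -1}, row i = index i
    log_ptilde: np.ndarray
    s: np.ndarray
    weight: np.ndarray
    degenerate: bool

    @property
    def n_states(self) -> int:
        return self.spins.shape[0]

    @property
    def included(self) -> np.ndarray:
        """Mask of states whose sign magnitude is above the floor."""
        return np.abs(self.s) > S_FLOOR

    def normalized_weight(self) -> np.ndarray:
        tot = self.weight.sum()
        if tot <= 0.0:
            raise ValueError("degenerate table: all weights vanish")
        return self.weight / tot

    def psi(self) -> np.ndarray:
        """Unnormalized real wavefunction vector ``sqrt(P~) * s``."""
        return np.exp(0.5 * self.log_ptilde) * self.s


def full_table(p: RBMParameters, cap: int = _TABLE_CAP) -> AmplitudeTable:
    """Enumerate all ``2**n`` basis states of the ansatz."""
    if p.n > cap:
        raise ResourceError(f"{p.n} visible units exceeds table cap {cap}")
    S = all_basis_spins(p.n).astype(float)
    logp = log_unnormalized_prob(p, S)
    logp = logp - logp.max()  # gauge shift, overflow safety
    s = np.tanh(S @ p.d + p.c)
    weight = np.exp(logp) * s**2
    degenerate = bool(np.all(np.abs(s) <= S_FLOOR))
    return AmplitudeTable(S, logp, s, weight, degenerate)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(
    p: RBMParameters, path, rng_seed: int | None = None
) -> None:
    doc = {
        "format_version": 1,
        "n": p.n,
        "m": p.m,
        "a": p.a.tolist(),
        "b": p.b.tolist(),
        "w": p.w.ravel().tolist(),
        "d": p.d.tolist(),
        "c": p.c,
        "rng_seed": rng_seed,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def load_checkpoint(path) -> tuple[RBMParameters, int | None]:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    n, m = int(doc["n"]), int(doc["m"])
    p = RBMParameters(
        n, m,
        np.array(doc["a"]), np.array(doc["b"]),
        np.array(doc["w"]).reshape(n, m),
        np.array(doc["d"]), float(doc["c"]),
    )
    return p, doc.get("rng_seed")
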