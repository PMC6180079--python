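# nqschem

Neural-network quantum states for small-molecule electronic structure.
`nqschem` approximates the ground state of a qubit-mapped molecular
Hamiltonian with a **three-layer restricted Boltzmann machine (RBM)**
wavefunction and trains it by gradient descent on the variational energy.
It also ships a classical simulation of a **controlled-rotation quantum
sampling circuit** that draws the RBM's Gibbs distribution by rejection
sampling, so the whole sampled-training pipeline can be studied on a
laptop.

It is aimed at people studying neural quantum states and hybrid
quantum/classical variational algorithms on desk-scale problems (up to
~14 qubits), not at production quantum chemistry.

## The model

A basis state of `n` qubits is a spin vector `x = (σ₁,…,σₙ)`, `σᵢ ∈ {±1}`,
with `σᵢ = +1` meaning qubit `i` in `|1⟩`. The trial wavefunction is

```
ψ(x) = φ(x) · s(x),     φ(x) = √P(x)
```

where `P(x)` is the marginal of an RBM Gibbs distribution over `m` hidden
spins,

```
P̃(x) = Σ_h exp( Σᵢ aᵢσᵢ + Σⱼ bⱼhⱼ + Σᵢⱼ wᵢⱼσᵢhⱼ )
     = exp(Σᵢ aᵢσᵢ) · Πⱼ 2cosh(bⱼ + Σᵢ wᵢⱼσᵢ),
```

and `s(x) = tanh(Σᵢ dᵢσᵢ + c)` is a third, *sign*, layer that lets the
otherwise non-negative RBM amplitude represent the negative coefficients
that electronic wavefunctions require. The energy

```
⟨H⟩ = Σ_{x,x'} ψ(x) ⟨x|H|x'⟩ ψ(x') / Σ_x ψ(x)²
```

is minimized by constant-rate gradient descent with the covariance
estimator `∇ₖ⟨H⟩ = 2(⟨E_loc Dₖ⟩ − ⟨E_loc⟩⟨Dₖ⟩)`, where
`E_loc(x) = ⟨x|H|ψ⟩/ψ(x)` and `Dₖ(x) = ∂ₖ log ψ(x)`, averaged over the
joint weight `P̃(x)s(x)²` — either by full enumeration or from samples.

Hamiltonians come in two ways: directly as weighted Pauli-string lists
(a plain-text `.ham` format), or from molecular one-/two-electron
integrals in FCIDUMP format, which are reduced to an active space
(frozen core, discarded virtuals) and mapped through the Jordan–Wigner
transformation (one qubit per spin orbital).

The quantum sampling algorithm prepares the tempered product
distribution `O(y) ∝ exp((a·σ + b·h)/k)` with single-qubit `R_y`
rotations, encodes each coupling factor `e^{wᵢⱼσᵢhⱼ/k}` in an ancilla
rotation + measurement that restarts the circuit on failure, yielding
samples of `Q(y) ∝ P(y)^{1/k}`; raising observed frequencies to the
power `k` recovers the Gibbs distribution. One attempt succeeds with
probability at least `exp(−(1/k)Σᵢⱼ2|wᵢⱼ|)`, so `k ≈ Σ|wᵢⱼ|` keeps the
acceptance rate above `e⁻²`. With a single reused ancilla the circuit
needs `n + m + 1` qubits.

## Worked example

Generate a random 4-qubit test Hamiltonian and solve it with the default
settings (hidden units `m = 2n`, learning rate 0.01, 20000 exact-mode
iterations, best of 3 restarts):

```python
import nqschem as nq
from nqschem.solver import TrainConfig

h = nq.generate_fixture(nq.FixtureSpec(n_qubits=4, n_terms=10,
                                       max_locality=2, seed=0))
e0, _ = nq.exact_ground_state(h)
trace = nq.train_multi(h, TrainConfig(seed=0), n_restarts=3)
print("exact ", e0)
print("min   ", trace.min_energy, "at iter", trace.min_iteration)
print("err   ", trace.min_energy - e0)
```

prints

```
exact  -3.113017213831618
min    -3.1119505651757633 at iter 19999
err    0.0010666486558545962
```

i.e. the trained RBM reaches the exact ground energy of this Hamiltonian
to about 1 mHa; `min_energy` is the lowest energy seen over the whole
optimization, which in exact mode is still a variational upper bound.

The same from the shell:

```bash
$ nqschem fixtures fix2.ham --n-qubits 2 --n-terms 4 --seed 3
$ nqschem solve fix2.ham --seed 0 --iterations 2000
{
 "min_energy": -0.919581636860821,
 "min_iteration": 1999,
 "iterations_run": 2000,
 "seed": 0,
 "exact_ground_energy": -0.9195858318235896,
 "error": 4.194962768599986e-06,
 "format_version": 1
}
$ nqschem resources --n 4 --m 8
13
```

`resources` reports the sampling circuit's qubit budget (`n + m + 1`
with the reused ancilla). Other subcommands: `jw` (FCIDUMP → `.ham`),
`scan` (train a family of Hamiltonians in order, with `--transfer`
warm-starting each point from its neighbor at 1/40 of the iteration
budget), and `sample` (circuit-sampler diagnostics).

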