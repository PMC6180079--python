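# Methods

This note records the scientific and numerical choices behind `nqschem`:
what the model assumes, what the defaults mean, what the synthetic
fixtures do and do not emulate, and where the method's known limits are.

## Ansatz

The trial state is `ψ(x) = √P̃(x) · s(x)` over computational basis states
`x ∈ {±1}ⁿ` (spin `+1` ↔ qubit state `|1⟩`; a basis state's integer index
treats qubit 0 as the most significant bit). `P̃` is an unnormalized RBM
marginal with `n` visible and `m` hidden ±1 spins; the hidden sum is
carried out in closed form, `P̃(x) = exp(a·σ) Πⱼ 2cosh(bⱼ + Σᵢwᵢⱼσᵢ)`.
`s(x) = tanh(d·σ + c)` supplies the sign (and is used as the smooth value,
not thresholded to ±1, so `|s|` also modulates the amplitude slightly).
All parameters are real; the ansatz therefore represents only real ground
states. Hamiltonian files whose matrix would be complex (any Pauli term
with an odd number of Y factors and a real coefficient) are rejected at
load time rather than truncated.

Two consequences worth knowing:

* **Sign expressivity.** `sign(s(x))` is a linear threshold function of
  the spins, so the ansatz can only realize linearly separable sign
  patterns over the hypercube. Molecular ground states in small active
  spaces — one dominant determinant plus corrections — are typically
  representable; the ground states of *generic* random Pauli
  Hamiltonians sometimes are not, in which case optimization plateaus at
  a finite energy offset with no amount of training fixing it. This is a
  property of the model, not of the optimizer.
* **Sign nodes.** States with `|s(x)| ≤ 1e-12` (`s_floor`) make `E_loc`
  and the log-derivatives undefined (division by `s`). They are excluded
  from all averages; their joint weight `P̃ s²` vanishes quadratically, so
  the exclusion is numerically consistent. A table whose signs vanish
  everywhere is flagged degenerate and aborts training.

## Hamiltonian preparation

FCIDUMP files (Molpro dialect, chemists'-notation integrals with the
8-fold real-orbital symmetry) are converted on read to physicists'
notation `⟨pq|rs⟩`, so the second-quantized Hamiltonian
`H = Σ hᵢⱼ a†ᵢaⱼ + ½ Σ hᵢⱼₖₗ a†ᵢa†ⱼaₖaₗ + E₀` applies literally with
`hᵢⱼₖₗ = ⟨ij|lk⟩` over spin orbitals. Spin orbitals are interleaved
(α₀, β₀, α₁, …). Frozen-core reduction uses the textbook construction
(core energy plus Coulomb/exchange mean field folded into the active
one-electron integrals); its correctness is pinned by a test identity:
the reduced Hamiltonian must equal, element-wise, the full Fock-space
matrix restricted to determinants with the frozen orbitals doubly
occupied and the discarded virtuals empty.

Jordan–Wigner uses `a†_p = (Π_{q<p} Z_q)(X_p − iY_p)/2` with `|1⟩` =
occupied. Any consistent sign-string direction gives an isospectral
result; this one is verified element-wise against an independent dense
ladder-matrix oracle up to 3 spatial orbitals. Like terms are merged and
coefficients below 1e-12 dropped. Caps: 7 spatial orbitals, 14 qubits
for matrix assembly (dense kron up to 10 qubits, sparse above).

## Optimization

Plain constant-rate gradient descent (`η = 0.01`) on the covariance
gradient, matching the simplest published practice; momentum methods are
deliberately not the default but the optimizer loop is small and easy to
extend. Parameters initialize i.i.d. uniform on `(−0.02, 0.02)` — small
enough that no tanh unit starts saturated. Defaults chosen once and used
throughout: hidden units `m = 2n` unless specified; 20000 iterations in
exact mode, 2000 in sampled mode with 2000 samples per iteration. The
reported observable is the *minimum* energy over all iterations (still a
variational bound in exact mode, where every iterate's energy is a true
Rayleigh quotient).

Degenerate gradients: once the exact-mode distribution concentrates all
numerical weight on a single basis state, the covariance gradient is
identically zero; training records the state's local energy and stops
(continuing cannot move). In sampled mode a single-support empirical
batch is treated as a zero-gradient iteration and training continues.

Local minima are handled by independent restarts (`train_multi`, default
3 seeds, keep the best trace), which mirrors how deviating scan points
are usually rescued in practice.

Both training modes evaluate `E_loc` from the model's own amplitudes via
full `2ⁿ` tables (cheap at the package's desk scale); sampled mode only
replaces the *averaging distribution* with an empirical one, reweighted
by `s(x)²` to form the joint weight. With the `enumerate` sampler the
empirical distribution is a multinomial draw from the exact marginal
(sampling noise without circuit overhead); with the `circuit` sampler it
comes from the simulated quantum sampler below.

## The sampling circuit simulation

The circuit is simulated at the level of its measurement statistics:
independent Bernoulli draws with `P(σᵢ=+1) = sin²(θᵢ/2)` (likewise hidden
units), then one acceptance test per coupling with probability
`sin²(θᵢⱼ,·/2)` chosen by whether `σᵢhⱼ = ±1`; any failure rejects the
whole attempt, as in the restart-from-scratch protocol. This reproduces
the output law of the state-vector circuit followed by projective
ancilla measurements exactly, at `O(nm)` cost per attempt, so a full
state-vector simulator is unnecessary. The batched sampler draws the
per-attempt acceptance in one step from the product probability, which
is the same law.

Accepted samples follow `Q(y) ∝ P(y)^{1/k}`; the identity
`Q^k ∝ P` is checked to 1e-12 by enumeration. The divisor defaults to
`k = max(1, Σᵢⱼ|wᵢⱼ|)`, recomputed each iteration from the current
weights, which keeps the acceptance probability above `e⁻² ≈ 0.135` by
the bound `exp(−(1/k)Σ2|wᵢⱼ|)`. Power-`k` recovery on finite samples is
biased for rare configurations (frequencies enter as `f^k`); the module
reports a Kish effective sample size, and exact enumeration remains the
reference for small systems. `max_attempts` (default 10⁷) guards
non-termination under adversarial `k`.

## Transfer learning

`run_scan` trains an ordered family of Hamiltonians; with transfer
enabled, each point after the first starts from its predecessor's best
parameters and runs `ceil(iterations/40)` steps (fraction configurable).
This presumes neighboring points are small perturbations of each other;
with the default 20000-iteration budget the warm phase is 500 steps,
which comfortably re-converges across the synthetic test family. An
occasional seed still inherits a local minimum from its predecessor —
the same failure mode seen on real potential-energy scans — which is why
the protocol's test asserts a success *rate* rather than uniformity.

## Synthetic fixtures

`generate_fixture` draws random real Pauli Hamiltonians (default 2-local,
coefficients uniform on ±1, odd Y counts repaired to keep the matrix
real). Random toy integral sets with the full permutation symmetry stand
in for molecular integrals in the fermionic tests. These fixtures
exercise every code path — parsing, matrix assembly, JW, training,
sampling — but they are *not* molecules: they lack particle-number and
spin structure, their spectra are not chemically scaled, and (see above)
their ground-state sign patterns are occasionally outside the ansatz
class. Passing tests therefore demonstrate correctness of the machinery
and recoverability of representable ground states, not chemical accuracy
on any specific molecule; real molecular inputs enter through FCIDUMP.

Problem sizes used in the test suite — 2–4 qubit training fixtures,
`n = m = 2` sampler enumerations at 10⁵ accepted samples, a 5-point
1-qubit scan family over 10 seeds — were chosen as the smallest systems
that exercise every term type and failure mode while keeping the whole
suite in a few minutes.

## Known limitations

* Real wavefunctions only; no complex phases, no two-qubit
  spin-symmetry reduction of the qubit count.
* The sign layer's linear separability limit (above).
* Exact-mode cost is `O(2ⁿ)` per iteration; sampled mode here also uses
  full tables for `E_loc`, so the package does not scale past ~14 qubits
  by design.
* Plain gradient descent can converge slowly near threshold accuracy;
  the mHa-level targets in the tests need the full default budget.
* No noise or hardware-error modelling in the circuit simulation.
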