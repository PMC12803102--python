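# Methods

## Model

A reaction network with `N` species and `R` mass-action reactions
`Σᵢ sᵢⱼ Xᵢ → Σᵢ rᵢⱼ Xᵢ` defines a continuous-time Markov chain on
copy-number states `n`. Its chemical master equation is realized as a finite
matrix `M` (the generator) on an enumerated state space: for every reaction
`j` applicable in state `n` with target `n + S_j` inside the space,
`M[target, source] += a_j(n)` and the source diagonal absorbs the escape
rate, so columns sum to zero exactly (conservation of probability). All
non-zero eigenvalues of such a matrix have negative real part; this single
spectral fact is why ensemble averages of any purely chemical system damp
out and why sustained coherent ensemble oscillations require an additional,
non-Markovian degree of freedom.

### Propensity convention

Combinatorial mass action with an explicit per-reaction system-size
exponent:

    a_j(n) = c_j · Ω^{w_j} · Π_i n_i (n_i−1) … (n_i−s_ij+1)

The exponent `w_j` is part of the model document (e.g. `−2` for a
trimolecular step, `+1` for constant influx) because volume scaling is a
modelling choice per reaction, not derivable from stoichiometry alone.

### State spaces

* `closed-conserved`: all states with a fixed weighted total (weights
  default to all ones); every reaction must conserve the total. The
  trimolecular shell with total `T` has `(T+1)(T+2)/2` states.
* `truncated-box`: all states within per-species bounds. Jumps leaving the
  box are removed from both flux *and* escape rate (reflecting truncation),
  which keeps `M` a proper generator at the cost of slightly distorting
  boundary dynamics; the box must be chosen large enough that boundary mass
  is negligible for the question at hand.

States are ordered lexicographically so indices, and hence Schur forms, are
reproducible.

## Stochastic simulation

The SSA is the exact direct method: exponential waiting time with the total
propensity as rate, next reaction chosen proportionally. Ensembles derive
per-trajectory RNG streams from `(base_seed, trajectory_index)`, so results
are bit-reproducible independent of execution order. Trajectories are
sampled onto uniform grids by right-continuous step interpolation (the value
is the state after the last jump at or before the grid time). Absorbing
termination (total propensity 0) is a normal outcome carried as a flag.

## Moment closure

Raw-moment equations are derived symbolically (sympy): for a multi-index
`m`, `d⟨n^m⟩/dt = Σ_j ⟨a_j(n)·((n+S_j)^m − n^m)⟩`, expanded exactly into raw
moments. For mass action up to trimolecular, order `|m|` couples to order
`|m|+2` at most. The hierarchy is closed at order `q` (1–5) by
**central-moment-neglect**: every central moment of order `> q` is set to
zero and the corresponding raw moments are rewritten through lower ones via
the binomial central↔raw conversion. Order 1 reproduces the deterministic
rate equations `dμ/dt = S·a(μ)` exactly (all covariances dropped); on
networks with linear propensities the closure is exact at every order.

Oscillation frequency and decay rate of a closure are read from the
eigenvalues of its Jacobian at a fixed point (not from curve fits): the
fixed point is located by root-finding (hybr, then lm, then df-sane as
fallbacks) seeded from the time average of an integrated trajectory, and the
leading complex pair gives `ω = |Im λ|`, `γ = −Re λ`. Conservation-law zero
eigenvalues are skipped when quoting a relaxation rate. Degenerate fixed
point manifolds (e.g. the neutrally stable rate-equation centers of cyclic
competition) can make the search fail; the failure is raised, and callers
that tabulate many orders record it as missing rather than guessing.

Moment ODEs are integrated with LSODA and an analytic Jacobian
(`rtol = atol = 1e−9` by default). A deterministic (point-mass) start has
raw moments `⟨n^m⟩ = n₀^m`.

## Coherence metrics

* **Autocorrelation**: mean-subtracted, biased (1/L) estimator, so the lag-0
  value is exactly 1 and all values lie in `[−1, 1]`; the expected shrink of
  the biased estimator at lag `k` is `(1 − k/L)`. Two modes: ACF of the
  ensemble-mean signal, or the average of per-trajectory ACFs. For
  absorbing systems the per-trajectory ACF uses the pre-constant segment of
  each trajectory, since a constant tail carries no signal.
* **Damped-cosine fit**: nonlinear least squares of
  `A₀e^{−γt}cos(ωt+φ)+c`, initialized from the dominant non-zero FFT peak
  and the log-envelope slope, restarted over four phases; non-convergence is
  flagged, never raised. Negative `γ` (growth) is reported unclamped.
* **Coherence report**: bundles the ensemble-mean fit, both ACF modes and a
  per-trajectory late/early window amplitude ratio. The ratio separates the
  two ways an ensemble average can decay: phase diffusion (ratio ≈ 1 —
  individual trajectories still oscillate, as in the Brusselator) versus
  genuine per-trajectory loss of oscillation (ratio → 0 — absorption, as in
  the closed trimolecular system).

## Coupling design

The real Schur form `M = Q·D1·Qᵀ` is computed with all zero eigenvalues
reordered last. Because the all-ones vector is a left null vector of `M`,
this ordering makes every non-trailing Schur column sum to zero, so coupling
columns `B1` built from those vectors conserve probability automatically —
this is how the zero-column-sum requirement on `B1` is satisfied by
construction rather than imposed.

Coupling a single Schur position is an exact block-triangular similarity:
permuting the auxiliary dimension next to the targeted position leaves a
quasi-triangular matrix whose only modified diagonal block is the coupled
one. The designed eigenvalues are therefore *exact* (verified in the full
spectrum of `A` to 1e−8), and the rest of the Markov spectrum is untouched.
Numerically, eigenvalue agreement degrades to ~1e−6 only for highly
degenerate spectra (symmetric-rate fixtures), which is eigensolver
conditioning, not design error.

* Real-mode design: `σ⁽²⁾ = −σ⁽¹⁾`, product `σ⁽¹⁾σ⁽²⁾ − ω*²`, split
  antisymmetrically `q⁽¹⁾ = −q⁽²⁾ = √(−product)` for conditioning (only the
  product is constrained by the theory).
* Complex-mode design: with the weak-coupling reduction `q_β⁽¹⁾ = 0` the
  block's quartic becomes the cubic of the 3×3 matrix
  `[[d_αα, d_αβ, q⁽¹⁾], [d_βα, d_ββ, 0], [q⁽²⁾, 0, σ⁽²⁾]]`; the product
  solving `bc = ad` (located by bracketing + Brent bisection; `g` is in fact
  linear in the product) with `b, c > 0` yields the stable imaginary pair
  `±i√c`. Feasibility constrains `σ⁽²⁾`: `b > 0` needs `σ⁽²⁾ < −tr(block)`,
  and for weakly rotating blocks the admissible window sits *above*
  `−d_αα`; when no `σ⁽²⁾` is given, the window is scanned numerically and
  its midpoint used. The second auxiliary eigenvalue `σ_β⁽²⁾` (default −1)
  only appends one stable real eigenvalue.
* The imaginary-root criterion is implemented and tested in its sharp form:
  `bc = ad ∧ b > 0 ∧ c > 0` is equivalent to "a purely imaginary conjugate
  pair exists **and** no root lies in the right half-plane" (without the
  stability clause, `b < 0` counterexamples exist).
* Regime classification of the scalar-mode 2×2 reduction uses trace
  `τ = σ⁽¹⁾+σ⁽²⁾` and determinant `Δ = σ⁽¹⁾σ⁽²⁾ − q⁽¹⁾q⁽²⁾`: oscillatory iff
  `τ² < 4Δ`, stable iff the spectrum stays left of zero, coherent on the
  `|τ| ≤ 1e−10, Δ > 0` boundary (excluded from open-region counts, which
  yield four regimes). Reported frequencies are the actual `|Im λ| =
  √(Δ − τ²/4)`, which reduces to the design formula `√Δ` on the coherent
  line. At the coherence threshold the frequency grows as `√ε` in the
  coupling offset ε — the 1/2 scaling, asserted via eigensolves, not the
  closed form.

## Coupled dynamics

Linear coupled systems are propagated by exact matrix-exponential stepping
on uniform grids (dimension ≤ 500; adaptive DOP853 otherwise). The input
variable also satisfies the integral (variation-of-constants) form
`x(t) = e^{tC}x(0) + e^{tC}∫₀ᵗ e^{−sC}B2·P(s) ds`, evaluated by cumulative
Simpson quadrature as an independent cross-check. Note the conditioning of
that comparison: with an unstable `C`, forward evaluation cancels like
`e^{σ⁽²⁾t}`, so the 1e−6 agreement check is run over horizons with
`σ⁽²⁾·t ≈ 10` on fine grids; this is an intrinsic property of the formula,
not of either integrator.

Linear coupling can push components of `P` transiently negative (the model
is a linearization); excursions are reported via `min_probability` and an
optional `halt_below` threshold, never clamped. On small state spaces with
strong coupling the excursions can be large — the linear model is then a
mode-level description, not a probability path.

A cubic saturation `−κx³` in the input equation converts a design detuned
slightly into the growing regime (`σ⁽²⁾ = −σ⁽¹⁾ + δ`) into a genuine limit
cycle: the long-run amplitude becomes independent of the initial condition.
Two caveats found and documented here: the absorbed stationary distribution
feeds a constant drive `B2·P∞` into `x`, shifting its equilibrium to `x̄`
and contributing `3κx̄²` of extra damping (the cycle only survives if
`δ/2 > 3κx̄²`-ish), and large `κ` creates strongly stable outer equilibria
`±√(σ⁽²⁾/κ)` that can capture the transient. The shipped demonstration uses
`δ = 0.2, κ = 0.01`, for which runs started at amplitudes differing tenfold
converge to the same late amplitude within 2%.

## Fixtures and default constants

The rate constants of the example networks are package defaults (the
oscillatory-regime choices a modeller would make), exposed as keyword
overrides:

* **Brusselator** `2X+Y→3X (c₁/Ω²), X→Y (c₂), ∅→X (c₃Ω), X→∅ (c₄)` with
  `(c₁,c₂,c₃,c₄) = (1,3,1,1)`, `Ω = 10`, start `(X,Y) = (1,1)`. In
  concentration units the rate-equation fixed point is `(1, 3)` and
  `c₂ = 3 > 1 + c₃²` places it past the Hopf point, so the rate equations
  show a limit cycle while SSA ensembles dephase.
* **Trimolecular** cyclic competition `A+B→2A, B+C→2B, C+A→2C`, unit rates,
  start `(10, 5, 5)` (conserved total 20). Closed and absorbing: all
  trajectories end with a single surviving species, so here even individual
  trajectories lose their oscillation. With exactly symmetric rates the
  species means are blind (threefold symmetry) to the slowest real Schur
  mode; coupled-system demonstrations therefore track a state probability
  chosen from the designed mode's eigenvector support.
* **birth-death** and **two-state**: linear networks for exactness checks.

Study horizons: trimolecular ensembles use `t ∈ [0, 4]` (absorption is
essentially complete), Brusselator ensembles `t ∈ [0, 40]` (≈5 periods),
1000 trajectories by default for ensemble statistics and fewer in unit
tests where only qualitative contrasts are asserted.

## What the synthetic conditions do and do not show

All validation is against self-generated data and small exactly solvable
systems: matrix exponentials on small shells are the oracle for SSA and
moment dynamics, eigensolves for the design claims. This establishes
internal correctness of the machinery, and the qualitative phenomena
(dephasing, absorption, coherence-by-design) are structural, not tuned.
It does not establish anything about a particular biological oscillator:
real systems have unknown rate constants, extrinsic noise (not modelled),
and nonlinear couplings beyond the cubic saturation studied here. The
designed coupled system is a linear (linearized) model; its probability
paths can transiently leave the simplex, and a physical implementation of
the unstable input would need the saturation mechanism supplied by its own
dynamics.

## Numerical conventions

* Eigenvalues with `|Re| ≤ 1e−10` count as zero (double-precision
  eigensolver noise on generators of desk-scale dimension).
* Generator column sums are asserted to 1e−12 (they are exact by
  construction up to float addition).
* Design verification: `|Re|` of the targeted pair ≤ 1e−8 of the spectral
  scale; frequency to 1e−6 relative.
* Regime boundaries use a 1e−10 tolerance on the trace; boundary cells are
  labelled coherent and excluded from region counts.
* Fixed points: residual below 1e−6 (scaled) required, else an error.

## Limitations

* Exact stationary distributions of open networks, time-dependent rates and
  non-mass-action kinetics are out of scope.
* No accelerated SSA variants (tau-leaping etc.); the direct method is the
  point, being exact and auditable.
* Closure schemes other than central-moment-neglect are not implemented.
* Hybrid jump-process simulation of the coupled system (rates modulated by
  `x`) is deliberately excluded: linear feedback can drive nominal rates
  negative, so a faithful stochastic counterpart needs modelling choices
  outside the linear theory.
* Multi-mode simultaneous targeting is not supported; one mode per design.
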