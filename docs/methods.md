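# Methods

## Model

The package studies the autonomous discrete-time rate dynamics

    x(t+1) = phi(J x(t)),

where `x` collects the activities of `N` neurons, `phi` is an odd, bounded,
nondecreasing activation with `phi'(0) = 1`, and `J` is a random matrix with
modular (two-level) or hierarchical (multilevel) block structure.

**Two-level connectivity.** `P` populations of `n` neurons each
(`N = n P`), with

    J = sigma_mu * Xi(P) ⊗ O(n) + sigma * Xi(N),

where `Xi(m)` has i.i.d. `N(0, 1/m)` entries, `O(n)` is the rank-1
projector onto the uniform direction (every entry `1/n`), and `⊗` is the
Kronecker product.  The first term gives each ordered pair of populations a
random mean synaptic efficacy; the second term is neuron-level disorder.
Populations are stored as contiguous index blocks, so the Kronecker
structure is literal in memory.  We take `O(n) = v v^T` with
`v = (1/sqrt(n)) * 1`, the unique normalization for which `O` is an
orthogonal projector; the per-block generative description
(`J_ij^{ab} ~ N(mu_ab / n, ...)`, `mu_ab ~ N(0, sigma_mu^2 / P)`) is then
recovered exactly with `mu_ab = sigma_mu * Xi(P)_ab`.

**Multilevel connectivity.** The same construction applied recursively:

    J[i] = J[i-1] ⊗ O(P_i) + sigma_i * Xi(N_i),   N_i = P_1 ... P_i,

with `J[0] = 0`.  Level 1 is the coarsest; the two-level model is `L = 2`
with `(P_1, P_2) = (P, n)` and `(sigma_1, sigma_2) = (sigma_mu, sigma)`.
One child random stream per level is spawned from the master seed, making
the level draws mutually independent and individually reproducible.

**Activation.** The default is the saturating error function
`phi_inf(x) = erf((sqrt(pi)/2) x)` with exact derivative
`exp(-pi x^2 / 4)`; all closed forms below are specific to it.  `tanh` is
provided as a second activation for universality experiments; the
quadrature-based machinery accepts either.

## Mean-field theory

In the limit of many large populations (`1 << P << N`) the quenched average
closes the dynamics on the hierarchy of order parameters
`q_j(t) = (1/N_j) * sum (level-j mean activities)^2`.  With cumulative field
variances `A_j = sum_{i<=j} sigma_i^2 q_i`, the update is

    q_j(t+1) = ∫Dz' [ ∫Dz phi( sqrt(A_j) z' + sqrt(A_L - A_j) z ) ]^2 ,

which for `L = 2` reduces to the coupled `(q_m, q)` system.  (The typeset
source equations omit the radicals over `A_j`; variances of independent
Gaussian field components add, so the square roots are restored here — the
reading is confirmed by the internal consistency of the closed forms and
the level-exponent formula below, verified to 1e-12 numerically.)

Fixed points label the phases.  The quiescent state (`q = 0`) is linearly
stable iff `sigma < 1` and `sigma_mu < 1` (strict; the marginal boundary is
reported unstable — it is measure-zero and the convention matches the
transition-line semantics).  The coherence onset is

    sigma_mu*(sigma) = 1 / g(sigma sqrt(q)),   g(a) = ∫Dz phi'(a z),

with `q` the incoherent-branch (`q_m = 0`) fixed point.  For the erf
activation `g(a) = (1 + pi a^2/2)^{-1/2}`.

**Effective macroscopic map.** For `n -> infinity` the population means
close on a `P`-dimensional system: each mean applies the activation smeared
by the microscopic fluctuations it averages over,
`m(t+1) = ∫Dz phi( mu m(t) + sigma sqrt(q) z )`.  The package exposes the
normalized effective transfer function `phi_a(x) = ∫Dz phi(x/g(a) + a z)`,
which has slope exactly 1 at the origin.

**Solvers.** Vector fixed points use damped iteration
(`x <- 0.5 x + 0.5 F(x)`, residual `max|F(x) - x| < 1e-10`, at most 1e4
iterations, coherent start `q_j = 0.9 j / L`); the maps are monotone and
bounded, and damping suppresses period-2 artifacts.  Convergence failures
are flagged on the returned solution, never silent.  The scalar
incoherent-branch equation is solved by bracketed Brent root finding
(`xtol 1e-15`): plain iteration stalls at the critical point `sigma = 1`,
where the decay to quiescence is algebraic.  A solved `q_m` below `1e-8`
counts as the incoherent branch (damped iteration leaves tiny residuals).

## Gaussian quadrature

All `∫Dz` expectations go through explicit rules.  The default is a
101-node probabilists' Gauss–Hermite rule (exact for polynomials of degree
201 under the Gaussian measure).  Rate integrands such as
`phi'(sqrt(A) z)^2` at large `A` are effectively Gaussians of width
`~(pi A)^{-1/2}`, narrower than any fixed-order Hermite rule resolves, so
every expectation of the form `f(c + a z)` automatically switches to a
trimmed uniform rule on `[-12, 12]` with six grid points per feature width
`1/a` when `a` exceeds the base rule's resolution.  For analytic integrands
with Gaussian envelope the trapezoid rule converges exponentially; the
adapted rules reproduce the erf closed forms to machine precision across
`a` from 0.5 to 20 (validated in the test suite).  Double integrals use
per-axis adapted rules and evaluate as one matrix contraction.

## Closed forms for the erf activation

At a fixed point, all Gaussian integrals evaluate exactly, giving the
inverse design map

    sigma_j^2 = [2/(pi q_j)] [sin(pi q_j/2) - sin(pi q_{j-1}/2)] / [1 - sin(pi q_L/2)]

for any admissible profile `0 = q_0 <= q_1 <= ... <= q_L < 1`, and the
per-level squared expansion rates

    R_j^2 = [2/(pi q_j)] [sin(pi q_j/2) - sin(pi q_{j-1}/2)] / cos(pi q_j/2),

with level exponents `lambda_j = (1/2) ln R_j^2`.  For the first active
level (`q_{j-1} = 0`) this reduces to
`lambda = (1/2) ln[tan(u)/u]`, `u = pi q/2` — positive for any `q` in
(0, 1), so a nonquiescent steady state is always chaotic — with the
small-gap law `lambda ~ pi^2 Delta^2 / 24`.  For balanced equal-gap
profiles the largest level exponent therefore shrinks as `1/L^2`: deep,
loosely balanced hierarchies sit arbitrarily close to the edge of chaos.
The solvers never use these closed forms; they remain an independent
cross-check of the quadrature route (both directions are asserted to 1e-6
in the acceptance tests).

## Perturbation theory and diagnostics

Linearizing around a trajectory and averaging over the Gaussian fields
gives per-subspace one-step expansion rates.  Two-level:

    R_coherent^2 = sigma_mu^2 ∫Dz' [ ∫Dz phi'(sigma_mu sqrt(q_m) z' + sigma sqrt(q) z) ]^2
    R_random^2   = sigma^2   ∫Dz  [ phi'( sqrt(sigma_mu^2 q_m + sigma^2 q) z ) ]^2

The squared perturbation amplitudes in the block-constant (macroscopic) and
zero-block-mean (microscopic) subspaces propagate by the lower-triangular
matrix `D = [[R_c^2, 0], [C, R_r^2]]`,
`C = (sigma_mu^2/sigma^2 + 1) R_r^2 - R_c^2 >= 0`: macroscopic kicks feed
microscopic residuals, but microscopic kicks average away before reaching
any population mean.  The maximal Lyapunov exponent is
`max(ln R_c, ln R_r)`.  The theory assumes trajectory and perturbation are
statistically orthogonal; the simulators do not enforce this, and the
residual discrepancy is part of the stated tolerance budgets.

Numerical diagnostics:

* **QR (Benettin) spectra** — tangent vectors re-orthonormalized every step
  (the map's one-step rates are O(1), so longer intervals buy nothing);
  exponents are window averages of `ln |diag R|`.
* **Two-replica MLE** — a perturbation of norm 1e-7 co-evolves with the
  reference trajectory and is renormalized each step.
* **Subspace MLE** — tangent vectors re-projected onto the macroscopic or
  microscopic subspace after every Jacobian application.
* **Kaplan–Yorke dimension** — largest `j` with nonnegative partial sum of
  the sorted spectrum plus linear interpolation; 0 when the leading
  exponent is negative; truncation (all partial sums nonnegative) warns.
* **Participation ratio** — `(sum nu)^2 / sum nu^2` over eigenvalues of the
  time-sampled, per-neuron mean-subtracted activity covariance, computed
  through the smaller Gram matrix; short windows (below 10 samples per
  unit) warn, zero-variance trajectories return 0 with a warning.

## Phase classification

* quiescent: `sigma < 1` and `sigma_mu < 1`;
* micro: active fixed point with `q_m = 0` (high-dimensional chaos);
* multiscale: `q_m > 0` and `R_random^2 > 1` (both subspaces expand);
* macro: `q_m > 0` and `R_random^2 < 1` (chaos confined to the population
  manifold).

The transition lines are `sigma_mu*(sigma)` (explicit) and the edge of
high-dimensional chaos `sigma_mu^EoHC(sigma)` located by bisection of
`R_random^2 = 1` along the coherent branch, with the lower bracket
evaluated on the incoherent branch (the coherent solve is critically slow
exactly at the onset).  For `sigma <= 1`, `R_random^2 <= sigma^2 <= 1`
everywhere, so no edge exists and the line is reported missing rather than
fabricated.  Bracket failures flag the point as missing.

## Simulation protocol and problem sizes

Initial conditions are i.i.d. uniform(-0.5, 0.5) from a seeded stream; any
generic start reaches the same ergodic steady-state statistics.  Steady
state summaries are single-realization time averages unless stated;
tolerance budgets scale as `1/sqrt(window)` plus finite-size terms.

Sizes used by the test suite, chosen to keep the full run at desk scale:

* order-parameter comparisons: `N = 4000` (`n = 100, P = 40`), a
  1000-step window after 500 burn-in steps, averaged over two disorder
  realizations (the window error on `q` is far below the quenched scatter);
* MLE comparisons: `N = 4000`, a 600-step window after 400 burn-in steps,
  three disorder realizations, with the population split chosen per phase
  to resolve the subspace carrying the leading exponent — `(n, P)` =
  (100, 40) in the incoherent phase, (40, 100) in the multiscale phase,
  (20, 200) in the macroscopic phase.  The mean-field rates are `P -> inf`,
  `n -> inf` statements, and the binding constraint flips from `n` to `P`
  once the leading exponent lives on the population manifold;
* Kaplan–Yorke scaling: fixed `n = 20` with `N` in {1000, 2000} (so `P`
  scales with `N`), a 100-step window after 50 burn-in steps (order-of-
  magnitude comparisons tolerate the resulting per-exponent noise), spectra
  truncated where the running partial sum is safely negative (0.35 N
  exponents in the high-dimensional regime, 0.15 N beyond the edge);
* eigenvalue and participation-ratio checks: `N = 2000`, 700-sample
  covariance window.

## Finite-size expectations

The mean-field description is exact only as `n, P -> infinity`.  Two
effects dominate at desk scale and set the tolerances above:

* **Quenched scatter** of the realized mean-efficacy matrix, O(P^{-1/2})
  — at `P = 40` the macroscopic variance scatters by several percent
  between realizations (hence realization averaging).
* **Near-critical amplification**: close to the coherence onset the
  macroscopic map is nearly marginal, and the microscopic chaos it
  averages over acts as an O(n^{-1/2}) dynamical noise that rectifies into
  extra macroscopic variance.  At parameter points a moderate distance
  above the onset, the simulated `q_m` at accessible sizes therefore sits
  systematically above the mean-field value (the corresponding
  theory-vs-simulation case in the acceptance suite documents this
  discrepancy rather than hiding it; the large-`P` effective macroscopic
  map, which removes the finite-`n` effect, recovers the mean-field value
  to ~1%).

## Synthetic data and what passing tests show

There is no external data: all inputs are parameters, and the fixture
generator produces small seeded instances (one per phase at the reference
points `(sigma, sigma_mu)` in {(0.5, 0.5), (4, 0.5), (4, 6), (1, 5)}, with
`n = 20, P = 10`, plus one three-level instance).  The generator realizes
exactly the model above: dense Gaussian blocks, equal population sizes,
shared activation.  It does not emulate features of biological circuits —
sign-constrained (Dale) synapses, sparse or heavy-tailed connectivity,
unequal populations, external drive, or continuous-time dynamics — so
passing tests validate the mathematics of this model class, not any claim
about a particular neural recording.

## Known limitations

* Closed forms (design map, level exponents) are erf-specific; other
  activations get the quadrature route only.
* No time-dependent mean-field correlators `C(t, t')`; fixed points and
  one-step rates only.
* Equal population sizes per level; heterogeneous block strengths are out
  of scope.
* The asymptotic constant in `R_random^2 ~ C0 sigma^2 / (sigma_mu^2 q_m +
  sigma^2 q)` is checked only as a decreasing trend, not fitted.
* Lyapunov spectra of strongly saturated networks involve determinants
  with enormous dynamic range; volume-contraction identities hold to
  conditioning-limited precision (~1e-4 relative), not machine precision.
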