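# Methods

## Model and discretization

The package solves first-order ODE systems dȳ/dx = f(x, ȳ) by least squares:
the residual of the first-order forward finite difference is squared and
summed over all grid points and equations, and the solution is the minimizer
of that functional.  This is an *optimization* formulation of explicit time
stepping, chosen because binary-optimization hardware can only minimize.
Three consequences shape everything else:

* With one step per run (M = 1) the functional separates per equation and
  its continuous minimizer is exactly one forward-Euler step.  The package
  treats this identity as its anchor oracle: the continuous ("QP") backend
  at M = 1 must reproduce forward Euler to float precision, and everything
  binary is judged against the QP backend.
* The functional is quadratic only if f is at most linear in ȳ over a run.
  Nonlinear forces are linearized by a first-order Taylor expansion at the
  run's initial state (no re-linearization inside a run; the run is short
  by construction).  Harmonic forces are naturally linear and incur no
  segmentation error at all.
* Convergence in the grid is first order, matching the finite-difference
  order.  The suite verifies a log–log RMSE slope of 1.0 ± 0.2 on the
  harmonic fixture.

The known initial point of each run is eliminated by substitution rather
than by a penalty term: substitution keeps the functional exactly quadratic
and introduces no penalty-weight tuning.  Constant terms dropped along the
way are tracked explicitly so that QP and QUBO energies are directly
comparable; that equivalence (|ΔE| ≤ 10⁻⁹ relative on random bit states) is
the compiler's central tested contract.

Two dispatch modes exist because they stress the binary solvers
differently: *sequential* (one equation per solve, other variables frozen at
the previous state — a Jacobi update, constant bit budget regardless of N)
and *coupled* (all N equations in one solve, N·M·K bits).  At M = 1 with the
QP backend both reduce to forward Euler and agree exactly.  A Gauss–Seidel
variant of sequential mode (freshly solved components visible to later
equations) is available behind a flag but off by default.

## Fixed-point encoding

Each continuous unknown is a signed fixed-point number with K_I integer and
K_D fractional bits.  Defaults (6, 15): range [−32, 32 − 2⁻¹⁵], rounding
error ≤ 2⁻¹⁶ ≈ 1.5·10⁻⁵, 21 bits per number.  Encoding rounds to nearest
with ties toward +∞, which attains the half-step error bound.  Out-of-range
values are a hard error, never clamped — a clamped coordinate would corrupt
a trajectory silently.  Because decoded solver output is always inside the
range by construction, the propagation driver treats a decoded component
within one resolution step of either end as saturation and aborts with the
step index (relevant for dissociating bonds run long enough to leave ±32).

## Solvers

* **QP (continuous)**: solves (H + Hᵀ)ȳ = −d.  The least-squares
  construction makes the system positive definite after initial-condition
  elimination; singular inputs fall back to the least-norm solution with a
  warning.
* **Exhaustive**: global binary optimum by split-half enumeration,
  O(2^bits) with matrix-product cross terms; refuses above 24 bits.  Energy
  ties break toward the lowest bit-pattern value (bit position 0 least
  significant in the tie-break integer) for determinism.
* **Simulated annealing**: sequential single-bit-flip Metropolis, geometric
  cooling.  Initial temperature defaults to the largest single-flip |ΔE| of
  a random probe state.  The final temperature defaults to 10⁻¹² of the
  initial — much deeper than generic SA practice — because fixed-point bit
  weights make single-flip energy scales span a ~2^(2K_D) dynamic range
  (~10⁹ at K_D = 15); ending near 10⁻³ of the initial temperature would
  leave every low-order bit at an effectively infinite temperature.
* **Greedy descent**: steepest single-bit-flip descent, ties toward the
  lowest bit index, stopping at a 1-flip local minimum.  Energy is
  non-increasing along the path by construction.
* **Hybrid (sa+greedy)**: every annealing read's best state seeds an
  independent greedy descent and the lowest polished energy wins.  The
  annealer locates the global basin; greedy settles to its exact bottom.
  On full 21-bit one-step cells this reaches the exhaustive optimum in
  ≥ 99/100 seeded trials with the default schedule (10 reads × 100 sweeps).
* **Restarts**: any stochastic solver can be wrapped in best-of-N restarts
  with derived seeds (master XOR attempt index, recorded in reports), the
  strategy of re-solving each task and keeping the smallest ε.  By default
  all attempts run; early stopping at an acceptance threshold is opt-in.

A small sampler Protocol (coordinate-list Q in, bit samples + energies out)
defines how an external annealing SDK could be plugged in; no hardware or
network code ships.

## The Morse application

Hamilton's equations for one bond, dr/dt = p/μ, dp/dt = F(r) = −dV/dr, with
V(r) = D_e (1 − e^{−a(r−r_e)})².  Default parameters model H₂ with standard
literature values: D_e = 0.17449 Hartree, a = 1.02764 Bohr⁻¹,
r_e = 1.40201 Bohr, μ = 918.076 mₑ (half the proton mass).  They are
configurable; with the defaults the package's physical anchors come out as
computed by the suite: harmonic period 2π/(a√(2D_e/μ)) ≈ 313.6 a.u., so a
400 a.u. window covers ≈ 1.275 periods; V(0.90 Bohr) ≈ 45.6 % of D_e
(strongly anharmonic but bound); r₀ = 0.70 Bohr at rest lies above the
dissociation threshold.

Reference trajectories: for bound energies E < D_e the closed-form solution
r(t) = r_e + a⁻¹ ln[(1 − √ε cos(ω_b t + φ))/(1 − ε)] with ε = E/D_e and
ω_b = a√(2D_e/μ)·√(1−ε); substitution shows it conserves E identically, and
the suite checks agreement with a rtol = 10⁻¹² adaptive integration to
10⁻⁸ Bohr.  Unbound energies use that integrator directly (an analytic
unbound form exists, but the integrator route is validated and uniform).
All internal computation is in Hartree atomic units; conversions to
fs/as/eV/Å happen only at I/O.

For coupled-mode solves the two variables live on very different scales
(r ≈ 1.3 Bohr versus p up to ≈ μω·Δr), so a momentum rescale s_p = μω is
available (`apply_scaling` / `--scale`); it equalizes the two equations'
residual contributions and round-trips exactly on the QP backend.  Per-
equation penalty weights are exposed with all-ones defaults.

## Accuracy metrics

RMSE is computed on the coordinate only, in Bohr, at identical grid times
(no interpolation) — the accuracy threshold (10⁻² Bohr, strict inequality)
is a length.  A momentum-inclusive weighted variant exists for sensitivity
checks.  Convergence sweeps run one propagation per (grid size, solver),
record per-step residuals and attempt counts, and mark saturation aborts as
failed rows with explicit status rather than dropping them.  "Grid size"
means the number of propagation steps over a fixed total time; the initial
point is not counted (1000 steps over 400 a.u. gives Δt = 0.4 a.u.).

## Problem sizes used in the test suite

The suite favors the smallest problems that still exercise each claim:
exhaustive-oracle comparisons run on ≤ 16-bit random instances plus the full
21-bit one-step cell; the binary-versus-continuous tracking check uses the
harmonic fixture at 50–100 steps; the solver-quality ordering experiment
(plain annealing vs best-of-10 restarts vs hybrid vs QP) propagates the
full 1000-step Morse trajectory with a deliberately weakened schedule
(8 reads × 80 sweeps) so the noisy-annealer regime — restarts and greedy
post-processing visibly rescuing an inaccurate trajectory — is actually
expressed; a pure-annealing reliability check (≥ 95/100 optima) runs on
10-bit cells where the default schedule saturates.

## Known limitations

* First-order differences only; higher-order schemes and higher-order
  (beyond-quadratic) segment approximations are out of scope.
* Linearization at the run start means M > 1 runs accumulate segmentation
  error for strongly nonlinear forces; no adaptive re-segmentation.
* The annealing solver is a classical stand-in: it reproduces the *role* of
  an annealer (stochastic, imperfect, improvable by restarts and greedy
  post-processing), not any specific hardware's noise statistics, chain
  breaks or precision limits.
* The synthetic fixtures (harmonic oscillator, Morse H₂) have smooth,
  one-dimensional force fields; passing tests demonstrate correctness of
  the compilation and solver machinery, not performance on rough
  high-dimensional potential-energy surfaces.
* Dissociating trajectories eventually overflow any fixed-point range; the
  driver aborts rather than clamps, so very long unbound runs require a
  larger K_I.
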