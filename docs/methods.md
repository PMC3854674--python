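# Methods

## The two-variable reduction

A linear chain `B1 → ... → Bn → P` of irreversible first-order reactions is
lumped into the pair `(X, L)`: the total molecule count and the total number
of reaction steps remaining across all molecules ("total length"; a molecule
in `Bi` has length `n - i + 1`, so `X ≤ L ≤ nX` whenever `X > 0`).  Any
reaction event decrements L by exactly one; the final step additionally
decrements X.  Conditional on an event occurring, the probability that it is
the final step is

    f(X, L, n) = E[ Bn / X | L, X ],

because each of the X molecules is equally likely to react (all rates equal)
and only the `Bn` molecules of length 1 can take the final step.  The lumped
model is closed by approximating f with a one-parameter family in the
normalized excess length `r = (L - X)/(X(n-1)) ∈ [0, 1]`:

* linear: `f = 1 - r`
* Type I: `f = 1 - r^q`
* Type II: `f = (1 - r)^q`

All three are exactly 1 at `L = X` and 0 at `L = nX`.  The printed source
formulas for the two one-parameter families are typographically ambiguous
(the transcription loses the parenthesis/exponent placement); the forms above
are fixed by reconstruction: fitted against the Monte-Carlo reference at
(n=8, X=15) they reproduce the reported optima (Type I ≈ 0.3, Type II ≈ 3.9)
and the reported ranking (Type II fits ~150× better in summed squared error),
whereas e.g. a multiplicative reading `1 - q·r` has its optimum near 2.5 and
cannot satisfy the endpoint conditions.  `f_type1(..., form="slope")` keeps
the multiplicative reading available for comparison.

The reference f is sampled by a uniform-reduction process (the Monte-Carlo
sampler): start with X molecules of full length n, apply `nX - L` single-unit
reductions each choosing uniformly among molecules of length > 1, and average
the fraction of length-1 molecules.  One continued pass per trial records the
estimate at *every* L with the same marginal law as independent per-L runs
(the state after m reductions does not depend on when it is observed), which
is what makes the 18×18 calibration grid cheap.  The textual procedure's
redraw-until-eligible step is implemented as a direct draw over the eligible
set (identical law); the literal rejection sampler is kept behind
`sampler="rejection"` and tested against the exact enumeration.  An exact
dynamic program over length multisets (`enumerate_last_step_probability`)
serves as the independent oracle on small instances; it never shares code
with the sampler.

## Calibration of q

**Stochastic route.**  For each condition (n, X) with n, X ∈ 3..20, the
Monte-Carlo reference is built (default 10,000 repetitions; the full-grid
regression uses 2,000 — the optimum is a ratio of smooth sums and is stable
at that size) and q is grid-searched over 0.01:0.01:15 minimizing the sum of
squared differences over every integer L in [X, nX]; ties break toward the
smaller q.  The optima are averaged over X at each n (the X-dependence is
weak — a property the tests assert) and the 18 points (n, q̄) are fitted by
unweighted ordinary least squares, giving the working exponent
`q(n) = 0.3146 n + 1.3615` used by `f_calibrated`.  The discrepancy metric is
a design choice; the sum of absolute differences is available via
`metric="abs"` for sensitivity analysis (the two metrics move the showcase
optima by ~0.04 and ~0.01 respectively).

**ODE route.**  The detailed chain with equal rates k and all mass initially
in `B1` has the closed-form survival `X(t) = X0 · P(Poisson(kt) ≤ n-1)`
(Erlang passage).  The two-variable counterpart is

    dX/dt = -k X (1 - r)^q,      dL/dt = -k X,

integrated from `(X0, nX0)`.  For each (n, X0) with n ∈ {5, 10, 15} and
X0 ∈ {5, 10, 50, 100, 200, 500}, q minimizes the squared difference of X(t)
over a uniform 200-point grid on [0, T].  T is the 1e-4 survival quantile of
Erlang(n, k) — the time by which 99.99% of molecules have completed the chain
— so the window covers the full decay at every n (a fixed multiple of 1/k
would truncate the decay badly already at n = 10, biasing q downward).  The
ODE system scales linearly in X0, so the per-X0 optima coincide; they are
computed per X0 regardless, which doubles as a consistency check.

Numerical integration: the public single-trajectory solver
(`ode_twovar_solve`) uses LSODA with rtol 1e-8 / atol 1e-10 and freezes the
state once X drops below 1e-9 (r is 0/0 at extinction).  The grid searches
(1,500 q values × 18 conditions, and the (k, L0) fits below) instead use a
fixed-step classical RK4 vectorized across the whole parameter grid
(`twovar_rk4_grid`): the system is a smooth two-dimensional decay, the
fixed-step solution agrees with LSODA to ≤ 1e-6 relative (asserted in the
tests), the selected optimum is invariant to the substep count over
10–80, and the vectorization makes the full calibration a ~30-second
computation instead of hours.

## Simulation

`ssa_detailed` is the Gillespie direct method (waiting time `ln(1/r1)/a0`,
channel by cumulative propensity against `r2·a0`, propensities `k_i [B_i]`,
optional zero-order synthesis into `B1`).  `ssa_twovar` replaces the chain by
one channel with propensity `kX`, k the harmonic mean of the step rates; on
each firing a third uniform draw picks the branch (degradation iff
`r3 ≤ f(X, L, n)`; the measure-zero tie goes to the degradation branch since
the strict inequalities of the update rule leave it undefined).  Draws are
consumed strictly in the order r1, r2, r3 per event, so trajectories are
reproducible from the seed alone.

Two boundary guards keep the lumped state physical for *any* supplied f: the
degradation branch is suppressed when `L - 1 > n(X - 1)` (no length-1
molecule can exist above that line, where approximate f need not vanish —
without the guard a trajectory can absorb at X = 0 with L > 0), and forced at
`L = X` (only the final step is possible).  The calibrated f already
satisfies both limits exactly, so the guards only ever act on approximation
error near extinction.

Ensembles derive run seeds as `base_seed + i`, sample each trajectory onto a
shared grid by last-value-carried-forward, and accumulate streaming mean and
population variance, so memory does not grow with the run count.

## mRNA case study

The detailed model is a 10-reaction scheme per minute: zero-order
transcription `S1` (set to 0 after a transcription block), export `S2`
(A → B), seven poly(A)-shortening steps (B → BC1 → ... → BC7) and fragment
production `S10` (BC7 → FG); the nine first-order reactions form an n = 9
chain with `X = [A] + [B] + Σ[BCi]` and `L = 9[A] + 8[B] + ... + [BC7]`, and
the lumped rate is the harmonic mean of s2..s10.  The case study works on
decay curves normalized to 100% at t = 0 and fits, on the percent scale:

* the one-step model `100·e^{-kt}` (bounded scalar least squares);
* the two-variable ODE with the calibrated exponent `q(9) = 4.1929`, fitting
  k jointly with the integer initial total length `L0 ∈ [X0, 9X0]` (L0 is a
  count of remaining steps, so the search is exhaustive over the lattice).
  Because k and L0 are strongly correlated along a ridge, the fit first
  profiles k against the best-over-L0 objective (one vectorized RK4 per k
  evaluation), then polishes k against the adaptive solver at the best
  lattice point and its neighbours.  A half-length variant fixes
  `L0 = round(9X0/2)`.

The one-step model is the `L0 = X0` boundary of the two-variable family, so
its residual sum of squares can never beat the two-variable fit, and on
shouldered data it systematically under-predicts the early levels — both
properties are asserted in the tests.  Fitted k and the ratio `L0/(9X0)` are
insensitive to the assumed copy number X0 (the percent-scale curve carries no
absolute-count information beyond lattice granularity), which the tests bound
at 5% across X0 ∈ {5..50}.

**Synthetic decay data.**  The measured construct curves exist only as
figures, so a seeded generator stands in for them: it solves the two-variable
ODE at (k_true, L0_frac), converts to percent, adds independent Gaussian
observation noise (default sd 3 percentage points, truncated at 0) and pins
the t = 0 point to 100.  Defaults emulate the experimental setting: samples
every 5 minutes over an hour, rates in 0.11–0.17 per minute, initial-length
fractions 0.41–0.53.  The generator reproduces the *shape* features that
matter for the fitting comparison (shoulder, near-exponential tail,
measurement noise); it does not emulate biological replicate structure,
heteroscedastic blotting error, or any deviation of the true chain from equal
step rates, so passing tests demonstrate correct recovery of the model's own
dynamics, not validity of the model for any particular transcript.  For
single-cell illustrations the detailed model needs a per-species initial
allocation; the default `(2, 3, 5, 9, 12, 18, 20, 17, 14)` is a synthetic
stand-in constructed to hold 100 molecules of total length exactly 371,
matching the lumped initial condition used alongside it.

## Known limitations

* Chains are strictly linear and irreversible; no branching, reversibility,
  or general network import.
* The calibrated f assumes equal step rates (the uniform-reduction process
  and the harmonic-mean propensity are exact only then); for strongly
  heterogeneous rates the reduction is an approximation of unquantified
  error.
* The exact enumeration oracle is exponential in (n, X) and guarded by a
  state-space cap; it is a verification tool, not a production path.
* Monte-Carlo-route regression coefficients are sampled quantities; at 2,000
  repetitions per condition they carry noise of a few units in the second
  decimal.
* No tau-leaping or other acceleration: simulators are event-exact by
  design.
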