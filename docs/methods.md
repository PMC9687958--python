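# Methods

`hdoe` implements an iterative experiment recommender for multi-step
bioprocess characterization.  A manufacturing process is modeled as a chain
of unit operations (UOs); each UO carries a regression model of its pool
impurity concentration (the critical quality attribute, CQA) as a function
of its normalized process parameters (PPs) and, for downstream UOs, the
load received from the preceding UO.  The chain — the integrated process
model (IPM) — is simulated end to end by Monte Carlo, and the fraction of
simulated drug-substance (DS) values above the upper specification is the
out-of-specification (OOS) rate.  The recommender proposes, one run at a
time, the experiment (a DoE run at designed PP settings, or a load-spiking
run with PPs at setpoint) at the UO where the IPM predicts the largest OOS
reduction.

## The integrated process model

**Per-UO regression.**  Ordinary least squares over a term scope of
intercept, 5 main effects, 10 two-factor interactions, 5 quadratics and
(downstream) a load term.  Terms are chosen by bi-directional stepwise
selection on partial t-test p-values with entry threshold 0.25 and removal
threshold 0.05.  Because the removal threshold is stricter than the entry
threshold, a naive add-then-prune alternation would oscillate forever on
any term whose p-value lies between the two; the implementation follows
the standard stepwise conventions that prevent this — the term added in an
iteration is exempt from that iteration's backward step, and the forward
step never re-adds the term the previous backward step dropped.  The
selection starts from the intercept; terms that would leave no residual
degrees of freedom or a singular matrix are skipped rather than raising,
because the procedure must operate from six runs per UO upward.  Effect
heredity is not enforced.  The load term competes like
any other scope term: until spiking has created genuine load variation, a
fitted load slope is sampling noise over a hair-thin range, and carrying
such a slope poisons every chained prediction downstream — so the load
term must earn its way in.  Selection is deterministic and invariant to
row order; ties break by scope order.

**Uncertainty inflation.**  Wherever the IPM draws residual noise, the
model RMSE is multiplied by the normal-population tolerance-interval
factor

    k(N, nu) = sqrt( nu * (1 + 1/N) / chi2_{alpha, nu} ),   nu = N - p,

with `alpha = 0.05` (and coverage 0.99 for reported intervals; the
coverage only enters through the z multiplier of interval half-widths, not
the simulation).  The factor is large for small N (about 3.1 at N = 8 with
p = 5) and converges to 1 from above, so a UO fitted on few runs claims
proportionally less certainty.  This is the mechanism by which *any* new
run — even an exact replicate — improves the simulated process capability.

**Conservative load extrapolation.**  Within the observed training load
range a UO's load dependence is the fitted linear term.  Above the largest
observed load, the prediction is frozen at the range edge and every
additional unit of load passes straight into the pool: a piecewise model,
continuous at the knot, with slope one beyond it.  For an impurity this is
the conservative assumption that unexplored clearance does not exist.
Below the smallest observed load the fitted model is used unchanged (the
conservatism argument runs in one direction only for an impurity).  This
rule makes the simulated DS distribution strongly dependent on how far
each load range has been explored — which is precisely the information a
spiking run buys.

**Simulation.**  Each Monte-Carlo trajectory draws every UO's PPs
independently from N(0, sigma_PP^2) with sigma_PP = 1/3, so the screening
range [-1, +1] spans three PP standard deviations; evaluates UO1; passes
its pool to UO2 as the load; and so on, adding per-UO residual noise with
standard deviation RMSE x k(N, nu).  The OOS rate is the fraction of DS
samples strictly above the specification, with binomial standard error.
Default 20,000 samples per evaluation (standard error ~0.2 percentage
points at a 10% rate).

**Intermediate acceptance criteria.**  Pool limits per UO are obtained by
inverting the chain backwards from the DS specification: the load limit of
UO k is the largest load whose upper prediction bound (setpoint mean plus
tolerance half-width) stays below UO k's pool limit, and that load limit
becomes UO k-1's pool limit.  In the slope-one region the inversion is
exact; with a non-positive fitted slope and an infeasible in-range limit
the criterion is reported as unbounded with a warning (ideal clearance).

## The ground-truth laboratory

Four studies share a 4-UO, 5-PPs-per-UO backbone with an impurity CQA and
printed polynomial coefficients; study A is the baseline (4-6 active
effects per UO, heredity respected, load coefficients 0.5/0.3/0.2), study
B sets UO3's load coefficient to 1 (no clearance there), study C sets all
downstream load coefficients to 1 (spiking can teach nothing), and study D
is study A with the noise ratio raised from 0.5 to 0.9 and is
conventionally run with the PRT decision scheme disabled.  At setpoint the
noise-free chain evaluates to 8.0 → 7.4 → 5.22 → 3.844.

**Noise model.**  The stated noise/std ratio is made dimensionless per UO:
the noise standard deviation is ratio x sd(noise-free pool under PP
variation), the latter estimated once per study by a 50,000-trajectory
simulation with a fixed internal seed (a model constant, not experiment
randomness).  Noise attaches to pools only and propagates downstream
through the loads; observed loads carry no separate measurement error.

**Specification.**  The upper DS specification is mean + 3 sd of 100,000
noisy end-to-end trajectories, so a perfectly known process sits near the
one-sided normal floor of (1 - 0.9973)/2 = 0.135%.  The true DS
distribution is mildly right-skewed by the quadratic terms, so its actual
tail beyond the derived spec is a small multiple of that floor.  The
specification seed is derived from the harness master seed once per study
call and shared across repetitions, as is the PP variance — OOS
improvements must come from knowledge, not from shrinking the assumed
variability.

**Load material.**  A DoE run at a downstream UO receives load material
from a noisy *setpoint* trajectory of the upstream UOs: small-scale
experiments are fed representative material, and only batch noise varies
it.  The resulting load spread is narrow, which is exactly why fixed
DoE-only campaigns leave the load-to-pool dependency unexplored and score
poorly, and why spiking runs carry information no DoE run provides.

## Designs

Candidate sets are the full 3^5 grid of level combinations.  D-optimal
selection (fresh or augmenting) uses a Fedorov-style single-row exchange
on |X'X| with seeded multistart (default 10 restarts), ties to the lowest
candidate index, duplicates allowed.  When the requested run count cannot
support the model (|X'X| identically zero) a tiny ridge (1e-6 on the Gram
diagonal) keeps the exchange ranking meaningful — the selection then
spreads rows the way a Bayesian D-criterion with a vague prior would.

The reference ("state of the art") workflow builds one D-optimal design
per UO with 6, 12 or 23 runs — under the full quadratic scope when the run
count supports its 21 terms, otherwise under the main-effects scope — then
realizes responses, selects models stepwise, and evaluates one IPM OOS.
Designs are rebuilt per repetition from the repetition's seed stream, with
a broader multistart (25 restarts) for the large designs: at p = 21 the
exchange landscape is rugged, and design quality measurably shifts the
reference OOS.

The hDoE loop starts from six runs per UO: five D-optimally selected for
the main-effects scope plus one center point.  The center point anchors
the setpoint region — where the IPM simulates — and protects the intercept
from the curvature bias a corner-only minimal design suffers whenever true
quadratic effects exist; it is also what a practitioner would run first.

## The recommender

Each cycle shortlists at most one DoE candidate per UO (the candidate-set
row maximizing the D-criterion of that UO's augmented design under its
currently selected factor terms) and one spiking candidate per downstream
UO (PPs at setpoint, load set to the largest load the current IPM
simulates there, capped at three times the largest observed load — spiking
studies challenge a step at a bounded multiple of what it has seen).

Every candidate is scored by the OOS rate the IPM would report after
hypothetically performing it: the run table is augmented with the
candidate and the current model's mean prediction as its response (no
simulated noise), coefficients are refit keeping the selected term sets,
and the OOS is recomputed with common random numbers (the same Monte-Carlo
seed as the current OOS) so that candidate ranking reflects the model
change, not simulation noise.  Two details matter:

- A hypothetical DoE run at a downstream UO is assigned the *mean observed
  load* of that UO, so it sits inside the observed range and leaves it
  unchanged.  Using a model-predicted load instead can fabricate an
  out-of-range point under a biased model and permanently scare the
  recommender away from the one UO that needs data.
- A hypothetical spiking run extrapolates the *observed trend* (the plain
  linear model, without the conservative slope-one excess): the hypothesis
  being evaluated is that clearance continues as observed, and the refit
  on the realized outcome corrects the model if it does not.

Candidates of a type whose predicted OOS values lie within two Monte-Carlo
standard errors of the type's minimum are statistically indistinguishable;
one of them is chosen uniformly at random.  When even the best candidate's
predicted improvement is below two Monte-Carlo standard errors of the
current OOS — no candidate offers an improvement the simulation can
resolve — the step falls back to a uniformly random DoE candidate: runs
then spread across unit operations instead of resolving noise.  Without
these two rules, a deterministic tie-break funnels every run to a single
UO whenever no candidate predicts a real improvement, and a mis-selected
model elsewhere can never be corrected.

**PRT.**  The best DoE and best spiking candidates enter the
probability-ratio-threshold decision: with predicted improvements d_DoE
and d_spk (floored at 1e-12), alpha = d_DoE/d_spk; draw u ~ U[0, 1] and
accept spiking iff u >= alpha.  DoE is therefore certain whenever its
improvement is at least as large, and spiking is accepted with probability
1 - alpha otherwise — a deliberate bias toward experiments that can detect
new effects.  If the spiking improvement is zero or no spiking candidate
exists, DoE is chosen outright.  Two alternative modes exist:
`"literal"` uses the ratio of the predicted post-run OOS probabilities
themselves, and `"greedy"` disables the randomization (pure argmin,
DoE on ties), the conventional comparison mode for study D.

**Loop.**  After the decision, the chosen run is performed in the
ground-truth laboratory (spiking with its explicit load, DoE with a
realized setpoint-trajectory load), appended to the run table, and the
affected UO's model is re-selected from scratch over the full scope.  The
OOS is recorded; a step whose refit fails is recorded and skipped, never
fatal.  Traces store, per repetition and step, the cumulative run count,
the OOS, the chosen run, and every UO's selected terms and coefficients.

## Problem sizes and reproducibility

Benchmarks default to 20 repetitions (the trade-off we consider a sensible
desk scale for this simulation; repetition-to-repetition spread of the
study-A OOS at fixed step is large, so headline means carry standard
errors of a few percentage points), 30 recommender steps, and 20,000
Monte-Carlo samples per OOS evaluation.  All randomness flows from one
master seed through `numpy` `SeedSequence` spawning (specification
derivation, design multistart, one stream per repetition), so every result
is bit-reproducible given the seed; candidate scoring within a step shares
one Monte-Carlo seed (common random numbers).

## What the synthetic laboratory does and does not emulate

It emulates: multi-step propagation of an impurity through a process
chain, realistic effect sparsity (20-30% of candidate effects active, with
heredity in the truth), load clearance between 0 and 1, batch-level
measurement noise scaled to the process's own variability, and the
closed-loop interaction between what has been measured and what gets
recommended next.

It does not emulate: mechanistic (kinetic/ODE) process behavior,
non-normal or heteroscedastic noise, drifting processes, measurement error
on loads, multiple simultaneous CQAs, two-sided specifications, or
resource constraints on experimentation.  Passing benchmarks here
demonstrates the recommender's behavior under its own modeling
assumptions, not performance on any real process.

## Known limitations

- Convergence speed of the hDoE loop is implementation-sensitive: the
  published trajectory shape (steep early decline driven by spiking, then
  DoE-driven refinement) is reproduced, but a minority of repetitions
  linger at intermediate OOS levels for several extra steps when early
  stepwise fits absorb real effects into spurious terms, which raises the
  small-sample mean above the large-replication published value at the
  same step.
- The hypothetical-outcome scoring is myopic: it cannot credit a run for
  what re-selection might discover from its realized response, only for
  its effect on N, the tolerance factor, and the load range.
- OOS monotonicity along a trace holds only in expectation; individual
  repetitions can jump upward when a realized run forces a model revision
  (the honest behavior of a closed loop under noise).
- Stepwise selection with a 0.25 entry threshold overfits small samples by
  construction; the tolerance-factor inflation compensates in aggregate
  but not per term.
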