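# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `pdsched`.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## PK/PD virtual patients

The drug model is a linear three-compartment oral levodopa system with an
effect compartment.  States are amounts in mg (`a0` gut depot, `a1`
central, `a2` peripheral) and the effect-site concentration `ce` in mg/L;
time is in minutes.  Endogenous synthesis `Rsyn` keeps a small drug-free
steady state (`a1 = Rsyn·V1/CL`, `ce = Rsyn/CL`), which is the initial
condition at wake.  The observed state is the Treatment Response Scale
(TRS): `E(ce) = BASE + EMAX·ceᵞ/(ceᵞ + EC50ᵞ)`, bounded per patient to
`[BASE, BASE+EMAX] ⊆ [−3, 3]`.

Oral intake is modelled as an instantaneous bolus added to `a0` at the
intake time with infusion ≡ 0; between events the system is autonomous
linear, so trajectories are propagated **exactly** with piecewise matrix
exponentials (`x(t+Δ) = e^{AΔ}(x − x*) + x*` with `x* = −A⁻¹b`).  The
one-step propagator for the 10-minute grid is cached per patient
(`GridSimulator`), making a whole-day evaluation cost ~100 4×4
matrix-vector products — fast enough for evolutionary optimization and RL.
An adaptive Runge-Kutta path (`method="ivp"`, rtol 1e-6 / atol 1e-8,
restarted at dose events) is kept as an independent cross-check; the two
agree to ~1e-6 TRS units in the tests, and the sample at a dosing time is
taken before the bolus, so a dose influences strictly later grid points.

### Population model

Published parameter sets for this model family are not reprinted here, so
the package ships its own documented population
(`src/pdsched/data/population.yaml`): a multivariate normal over the 12
constants with literature-flavoured means (absorption t½ ≈ 25 min, central
volume 11 L, clearance 0.52 L/min ⇒ plasma t½ ≈ 50 min, effect
equilibration t½ ≈ 28 min, EC50 1.4 mg/L, Hill coefficient 4, baseline TRS
−2.2, maximum swing 4.6), coefficients of variation of roughly 15–25 %,
and three mild correlations (V1–V2 0.4, Q–CL 0.3, BASE–EMAX −0.5 so that
higher baselines come with smaller swings).  Draws are clipped to
admissible intervals and EMAX is capped at `3 − BASE`, keeping every
simulated trajectory inside the TRS scale.  Patients whose reachable
maximum `BASE+EMAX` is below 0.3 TRS cannot meaningfully be scheduled
against the percentage-based target rule, so optimization cohorts resample
past them.

### Day generation

A medication day draws its waking length uniformly from 14–18 h (10-minute
multiples), a dose count from 3–7, dose sizes uniformly from the 5 mg
lattice in [5, 400] mg, the first dose at wake, and the remaining intake
times uniformly on the grid subject to ≥ 90-minute gaps (rejection
sampling with an equally-spaced fallback).  The trace starts from the
endogenous steady state.  These are deliberately *probing* days — random
dose sizes and timings exercise the patient's response surface the way a
monitored titration period would, not the way a tuned maintenance schedule
would.  Days generated this way put ≈ 1 g/day through steep-sigmoid
patients, so traces sweep most of the patient's TRS range with sharp
transitions; this matters for interpreting the prediction-error magnitudes
below.

## Response models

Both models predict the next TRS state on the 10-minute grid and are
evaluated closed-loop: starting from the measured wake state, each
prediction is fed back as the next step's previous-state input.

* **History model**: a two-hidden-layer ReLU perceptron over the `n`
  previous states (default 1; the initial state is replicated when fewer
  exist) and, for each of the `k` most recent doses (default 2), the pair
  (minutes since the dose, dose size), most recent first, zero-padded.  A
  dose taken at the row's grid time has elapsed time 0.
* **Impulse model**: an LSTM (Glorot input kernel, orthogonal recurrent
  kernel, forget bias 1) fed (previous state, dose at the step), followed
  by two ReLU dense layers.  The recurrent state starts at zero.

Dose times are rounded to the nearest grid point (a dose at 8:17 is
treated as taken at 8:20).  Variants: the target may be the next state or
the state difference, and the output may pass through `3·tanh(·)` to pin
predictions inside the TRS scale.  Architecture identifiers follow the
pattern `H-64,64-diff` / `I-(8)64,64-tanh`.

**Training** treats each day as one sample: days are truncated to the
shortest day in the fitting set, split 80/20 into train/validation, inputs
(and, for non-tanh variants, the output scale) standardized with
train-split statistics, and the whole-day rollout MSE (raw TRS units) is
minimized with Adam (lr 0.001, batch 8 for cohort fits) for up to 300
epochs, early-stopped after 10 epochs without validation improvement, with
the best-on-validation weights checkpointed.  Gradients flow through the
entire predicted day, including the state-feedback path (backprop through
time, finite-difference-checked in the tests).  A global gradient-norm
clip (5.0) and a skip of non-finite updates guard the feedback loop's
occasional early-training blow-ups.  Because rollout optimization from a
random initialization can settle in poor basins, cohort fits repeat the
training from 3 seeds and keep the best-on-validation run.

**Transfer learning** fine-tunes the general model on one patient's three
days (first two train, third validates; the normalizer is inherited from
the general fit): history models update all layers, impulse models freeze
the LSTM and retrain the dense head, for at most 100 epochs with patience
25.  The starting point counts as a checkpoint, so a transfer fit can
never end worse on its validation day than the general model it started
from.

**Metrics** (MSE, MAE, R²) are pooled over all predicted states of all
evaluated days; paired model comparisons use the Wilcoxon signed-rank test
at significance 0.05, with an all-zero-difference pair flagged as
degenerate rather than scored.  On this generator's probing days the
transfer-fitted impulse model I-(8)64,64 typically reaches best-patient
validation R² ≈ 0.98–0.99, while the cohort-mean validation MSE lands
around 0.05–0.10 TRS² — the sharp saturation swings of randomized
400 mg-scale doses bound what a 2-day fit can capture, and readers should
expect calmer real titration data to sit at lower error (the acceptance
script computes both numbers for the chosen seed).

## Schedule optimization

Decision variables are `[times | sizes]` with the four optional
constraints of the encoding table (lattice times, first dose at wake,
morning + maintenance sizes, equal intervals); with all four active an
n-dose day is `[Δt, d_mor, d_main]`.  Bounds: intervals ≥ 90 min and at
most `(day − 10 min)/(n−1)`; doses 0–400 mg (the exhaustive benchmark caps
maintenance doses at 300 mg); when the first dose is not pinned to wake,
`t1` is additionally bounded by a 4-hour window after waking.  The dose
count is fixed per run (default 5) — it is not itself optimized.

Objectives integrate over the waking day with the trapezoidal rule on the
grid (units TRS²·min).  The area criteria use the squared max by default
(`max(0,·)²`), with a switch for the unsquared reading.  Per patient the
threshold and target range sit at 10 % and 20–40 % of the maximum state.
The below-threshold term doubles as a penalty (default weight 10) added to
the area-outside-range objective.  An `after_onset` option starts that
penalty at the first threshold crossing: patients here wake far below the
threshold, so an unconditional penalty would mostly price the unavoidable
morning climb and distort the comparison between constraint sets; with the
onset rule it prices exactly the between-dose relapses, which is what the
benchmark's feasibility rule also checks.

* **Exhaustive search** enumerates the fully-constrained lattice and, in
  benchmark mode, keeps threshold-feasible schedules (after first reaching
  the threshold the state never falls below it) with ties broken by
  smaller total dose, then smaller interval.
* **Genetic algorithm**: tournament selection (k=3), two-point crossover
  (p=0.5), mutation (p=0.2 per individual, 0.1 per gene; gaussian with
  sd = 10 % of the variable range for continuous genes, uniform lattice
  resampling for discrete ones), bounds enforced by clipping, best-ever
  individual returned.
* **Differential evolution**: classic rand/1 with gene-wise crossover
  probability, trial vectors rounded to the admissible lattice and clipped,
  greedy replacement.  Initial populations can be warm-started with known
  schedules; the constraint-relaxation experiment seeds the relaxed run
  with the constrained optimum, which makes the optimized score monotone
  under relaxation by construction.

On coarse fully-constrained lattices all three optimizers agree exactly
(tested), and the in-house DE matches scipy's implementation on the same
problem.

## RL dosing environment

Actions are dose multiples (`a·dose_step`, action 0 = wait one grid step);
taking a dose auto-advances through the 90-minute lockout (9 grid steps)
accumulating reward.  The reward of each traversed segment is the negative
trapezoidal area-outside-range contribution, so the episode return equals
the negative whole-day objective exactly (tested to 1e-6).  Episodes
terminate when the state exceeds a patient-specific maximum — default
halfway between the target ceiling and the patient's maximum effect — and
truncate at 110 grid steps (> 18 h), with lockout sub-steps counting
individually.  Backends: the exact PK/PD propagator (observation =
compartment vector), a transfer-fitted impulse model (observation =
`[tanh(c), h]`, all within [−1, 1]), or the history model (recent state +
dose/elapsed pairs).

The PPO agent is a compact clipped-surrogate actor-critic: separate
two-hidden-layer ReLU policy and value networks, GAE(γ=0.99, λ=0.95),
clip 0.2, Adam 3e-4, 10 epochs × 64-minibatches per 2048-step rollout,
running observation normalization, value bootstrap through truncations,
and an evaluation callback every 50 000 steps (scaled down in tests) that
early-stops after two checks without improvement and restores the best
parameters.  Policy gradients are finite-difference-checked in the tests.

## Numerical and design choices

- Exact linear-system propagation replaces adaptive ODE integration as the
  default simulator; both paths ship and are cross-checked.
- The MAE metric is the mean absolute error (the conventional reading of
  that name).
- Whole-day rollout loss is computed on raw TRS states for every variant,
  including difference-mode models (their state is cumulative, so a
  per-step difference loss would not measure day-level tracking).
- Ties in exhaustive search prefer less medication at equal symptom
  control, then shorter intervals.
- Batch size (unstated in most published configurations of this kind) is
  `min(32, n_days)` by default and 8 for cohort fits; the transfer fit on
  two days is effectively full-batch.
- Per-stage seeds derive from the global seed XOR a CRC32 of the stage
  name, so pipeline stages are independently reproducible.

## Problem sizes

The shipped pipelines use 50 patients × 3 days on the 10-minute grid
(40 general / 10 individual), 3 general-training restarts, DE budgets of
30×80 (3 variables) and 60×200 (9 variables) evaluations, and scaled-down
PPO budgets (tens of thousands of timesteps) for the sanity tasks; these
sizes were chosen so a full reproduction runs in minutes on one CPU while
keeping each conclusion stable across seeds.

## Limitations

- The population and day-generation distributions are this package's own
  synthetic stand-ins; absolute error and objective magnitudes depend on
  them (steep Hill slopes make the 20–40 % target band narrow in
  concentration terms, so band occupancy is intrinsically low for many
  patients and outside-range areas are large compared to gentler cohorts).
- Passing tests on synthetic patients show the machinery is correct and
  the study design reproducible — not that the learned models transfer to
  real wearable-sensor TRS estimates, food/activity effects, or multi-drug
  regimens, none of which the generator emulates.
- The history-model RL backend re-predicts the day prefix each step
  (quadratic in day length); it is provided for completeness, not speed.
- Single-threaded determinism is guaranteed under fixed seeds; BLAS
  threading does not affect results at these sizes but may change timings.
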