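# Methods

## Decision problem

The package treats basal-insulin titration as a finite Markov decision
process. Decision epochs are quarterly clinic visits. The state is the
4-tuple of discretized HbA1c (3 levels), BMI (17 levels), physical activity
(2) and alcohol use (3) — 306 states; the action is one of 6 glargine dose
intervals spanning 6–100 units/day; the reward follows the change in HbA1c
control level. Learning is plain tabular Watkins Q-learning — no function
approximation, eligibility traces, or double estimators — and the policy is
the per-state argmax of the learned Q-table, ties broken toward the lowest
(most conservative) dose interval.

## Discretization details

* HbA1c levels: ≤7, (7,9], >9 (percent). Boundary values belong to the
  lower level.
* BMI bins: edges 18.5, 19, 20, …, 34, 35; the first bin is the half-width
  [18.5,19) and the last is closed [34,35] so the 17 bins tile [18.5,35]
  with no gap (a printed source lists the last bin as open at 34, which
  would leave BMI = 34.0 unassigned; the closed form is the contiguity
  repair). BMI outside [18.5,35] is clamped to the nearest bin with a
  logged warning by default; a strict mode raises instead, since how such
  values were handled clinically is unknown.
* Activity and alcohol accept either pre-coded categories or raw weekly
  frequencies (≥2 sessions/week = active; <2 drinks/week = mild,
  ≥2/week = moderate, daily = heavy).
* Dose-to-action encoding uses half-open partition semantics so every
  logged dose maps to exactly one action. Evaluation membership is
  boundary-inclusive at both ends — the published match labels require it
  (several matched rows sit exactly on an interval endpoint, e.g. dose 15
  against [6,15)). Both rules are named and tested; they are different
  operations with different jobs.

## Reward

r = w·(level_before − level_after) + bonus·1[after = controlled]
− penalty·1[after = uncontrolled], defaults w = bonus = penalty = 1.
The functional form is the simplest one consistent with "reward the change
in HbA1c level, referenced to the controlled target"; all three weights are
exposed because the exact published constants are not available. The greedy
policy is invariant to positive rescaling of rewards, so the headline
evaluation does not hinge on these constants.

## Training

* `fit_offline` replays logged transitions in seeded shuffled sweeps
  (experience replay); trajectory ends are terminal (zero bootstrap). Early
  stopping when the largest |ΔQ| in a sweep falls below `tolerance`.
* `fit_online` interacts with a simulator under ε-greedy behaviour.
* Defaults α = 0.1, γ = 0.9, ε = 0.1, q_init = 0: the published study
  defines these symbols but reports no values, so standard tabular-practice
  defaults are used. An optional 1/n(s,a) visit-count step-size schedule
  (Robbins–Monro) is provided; with it, repeated replay converges to the
  fixed point of the empirical MDP, which is what the convergence and
  recovery analyses use.
* Correctness anchor: on small random deterministic MDPs with exhaustive
  transition sets and α = 1, replay is exact asynchronous value iteration;
  the suite checks agreement with an independent value-iteration oracle to
  1e−6 in max norm.

### Conservative policy extraction from logged data

A plain argmax over a Q-table estimated from a *fixed* logged dataset is
fragile: an action observed only once or twice at a state can win on
sampling noise alone. For offline analyses the package therefore also
provides a lower-confidence-bound extraction rule
(`pessimistic_policy`): each entry is penalized by one standard error,
σ̂/√n(s,a), where n counts distinct data samples and σ̂ is the standard
deviation of the Bellman targets around the converged Q-values (estimated
by the fit itself, typically ≈0.9 here); actions never observed at a state
are excluded. This is the standard conservatism used when deriving
treatment policies from observational data. The user-facing greedy policy
(CLI `recommend`, `greedy_policy`) remains the plain argmax.

## Synthetic cohort

No public dataset accompanies the problem, so the package generates one:
87 patients × 40 quarterly visits (10 years) by default, with the
visit-table schema (patient id, visit, HbA1c, BMI, activity, alcohol,
dose).

Ground truth: every state has a true dose need, linear and nondecreasing in
each state component —
need = 6 + 8·(HbA1c−1) + 1.5·(BMI−1) + 5·(inactive) + 3·(alcohol−1),
clamped to [6,100]. Slopes are chosen so that need patterns qualitatively
mirror the published test rows (poorly controlled, high-BMI, inactive
patients need 50+ units; controlled low-BMI active patients need ≤15).

Dynamics: HbA1c responds to dose *quality*. The relative dosing error
e = |dose − need|/need sets an equilibrium HbA1c of 5.5% + 2.0%·(e/0.2);
each visit HbA1c moves to that set point (plus N(0, 0.3²) noise, clamped to
[5,12]), with per-visit moves capped at −0.6/+0.8 percentage points.
The set point is reached within one visit because a quarterly visit
interval spans a full glycation turnover — HbA1c reflects ~3 months of
average glucose, so last quarter's dose, not older history, determines the
new value. Misdosing beyond the 20% tolerance never improves control
(upward-only drift), however high the starting HbA1c. BMI follows a slow
random walk (sd 0.15 per visit); activity and alcohol stay fixed within a
trajectory by default. Logged prescriptions scatter uniformly within ±20%
of the true need — an imperfect but sensible prescriber.

What the generator does *not* model: meals, exercise events, intra-day
glucose, hypoglycemia, adherence, or any physiological insulin–glucose
dynamics. Passing the recovery test therefore shows that the learner
identifies a known dose–response from realistic visit-structured data — not
that it would dose real patients correctly.

### Policy recovery

The recovery experiment generates the default cohort, replays it offline
with the 1/n schedule (80 sweeps), extracts the policy with the
lower-confidence-bound rule, and asks: among states with ≥30 data visits,
how often does the recommended interval contain the true need
(boundary-inclusive)? At the default conditions this rate is ≈0.93; across
cohort realizations it varies roughly 0.76–0.97. The irreducible part of
the miss rate comes from states whose true need lies close to an interval
boundary: doses just below and just above the boundary are near-equally
good (the response depends on |dose − need|, not on the interval label), so
finite logged data cannot always separate the two neighbouring intervals —
an identification limit of interval-valued actions, not an estimator bug.

## Evaluation harness

For each test case (state, prescribed dose, recommended interval) the
harness recomputes inclusive membership and the per-case error
(0 on a match, else distance from the dose to the nearest interval bound),
and aggregates the match rate and mean error. On the packaged 60-case
reference set the recomputed flags agree with the transcribed published
labels on all 60 rows, giving 53/60 (88.3%) and mean error 0.8 units (the
seven non-matching rows contribute 5+7+7+3+6+10+10 = 48 units). The
reference table assigns different intervals to two cases with the identical
state (2,4,1,1), so no single state-indexed policy can reproduce every row;
the published figure is a per-case property of the printed table, which is
how the harness computes it. When a trained Q-table is supplied instead,
recommendations come from its greedy policy, and cases whose state was
never visited in training are scored but reported separately.

## Numerical and interface choices

* Canonical state index: mixed-radix with HbA1c most significant —
  (a−1)·102 + (b−1)·6 + (c−1)·3 + (d−1) — fixed for serialization
  stability; any bijection would do.
* Q-tables and visit counts serialize as commented CSV; every CLI output
  embeds the command, version and seed in '#' header lines.
* All randomness flows through `numpy.random.default_rng` seeded from
  explicit config fields; same seed ⇒ bit-identical cohorts and Q-tables.
* Exit codes: 0 success, 2 I/O, 3 validation, 4 recommendation for a state
  unvisited in training (the tie-break recommendation is still printed).

## Known limitations

* The learner is plain tabular Q-learning on observational trajectories;
  it has no correction for confounded logged dosing beyond the
  lower-confidence-bound extraction.
* The discretized state makes the process only approximately Markov (raw
  HbA1c within a level carries information the state drops).
* Only long-acting glargine dosing is modelled; no other insulins,
  diabetes types, or state factors (diet, stress, adherence).
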