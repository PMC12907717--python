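# Methods

## The task model

The engine enumerates the full MGT lottery space: pink-box count
`k ∈ 1..5` (blue count `6 − k`) crossed with pink and blue rewards drawn
from {5, 25, 50, 75, 100} points — 125 unique trial types, ordered
lexicographically so `trial_code` is stable everywhere. A run presents
every type twice (250 trials) in a uniformly random order; a session holds
three runs, one per stimulation condition (sham, SPL, VMPFC) in the order
supplied. The token is placed uniformly over the six boxes, independently
per trial, and box coloring is re-randomized per presentation — scoring
depends only on color counts and rewards, so the arrangement is cosmetic.
Sham is a single condition label (the physical coil position alternation
has no behavioral consequence to model).

Randomness follows one contract: a root `SeedSequence` per
participant-session spawns named substreams for trial ordering, token
placement and agent noise, so every output is a pure function of
(inputs, seed) and consuming extra draws in one stream cannot perturb the
others.

**Payment rule.** Eligible trial numbers are 11..260: ten practice trials
precede 250 valid ones, so 260 is the last screen a session shows. An
upper bound of 261 is sometimes quoted for this design; since
10 + 250 = 260, index 261 is treated as out of range here and rejected.
Points convert at €0.10 each.

## Scoring

* **Risk** = payoff SD of the chosen option, computed as the two-outcome
  variance `p(x−EV)² + (1−p)(0−EV)²` and verified in tests against the
  algebraic closed form `x√(p(1−p))` (identity to 1e−12) and against
  Monte-Carlo payoff SDs (3-SE agreement).
* **Choice optimality** compares the two colors' expected values; strictly
  higher → 1, strictly lower → 0. Expected-value ties exist in the
  enumerated space (e.g. 25·(1/6) = 5·(5/6)); on a tie no option is
  suboptimal, so either choice scores 1, and tie trials carry a `tie` flag
  so sensitivity analyses can exclude them.
* **Response time** is seconds from trial onset to key press (millisecond
  timestamps convert via a unit flag).

Averaging the two presentations of each type yields one row per
participant × session × stimulation × trial code with `co ∈ {0, 0.5, 1}`.
A type with a single recorded presentation is averaged over that one
presentation rather than dropped; an unrecorded run removes all 125 of its
rows.

**RT outlier fence.** Tukey's 1.5 × IQR rule with quartiles by linear
interpolation between order statistics (removal counts depend on the
interpolation rule, so it is fixed and stated). The fence is applied
*after* type-averaging and, by default, *globally* over the assembled
table — one fence, one study-wide removal count — because the analysis
design reports a single removal total over all 44,375 averaged
observations; per-participant scope is available as an option. Fenced rows
keep their risk/CO values: the fence only gates the RT model.

## The synthetic cohort

The study design is fixed in `CohortDesign`: 60 participants (31 placebo /
29 probiotics, 36 women — gender is generated as a label but drives no
effects, mirroring its exclusion from the final models), 2 sessions ×
3 stimulation runs in randomized order, and 5 unrecorded runs belonging to
distinct participants. Bookkeeping identities follow exactly:
60·6·125 − 5·125 = 44,375 scored rows (45,000 with nothing dropped).

**Agent route.** No behavioral choice process is specified by the task
itself, so the simulator uses an explicit stand-in: a mean-variance
softmax agent with utility `U = EV + b·Risk` and
`P(pink) = 1/(1 + exp(−λ(U_pink − U_blue)))`. Defaults `b = −0.5`,
`λ = 0.15` were calibrated once against the 125-type grid so the baseline
agent's mean type-averaged risk (≈25.9) and choice optimality (≈0.85) sit
at realistic human levels for this task, and then frozen. Response times
are lognormal (`rt_location = −0.18`, `rt_scale = 0.35`, mean ≈0.89 s)
with additive log-scale condition shifts: a session-2 speed-up (−0.25,
≈−0.19 s on the mean) and a post-intervention probiotics shift (riskier by
`b + 0.05`, slower by +0.07). These modifiers give simulated effects the
directions a real intervention cohort would show; they are configuration,
not empirical claims.

**Mixed-model route.** For estimation checks the scored table is drawn
directly from the generative mirror of the fitted model:
cell mean + `u_participant` + `u_(trial type : participant)` + residual,
with the nested intercept drawn per participant × trial code (matching the
nested, not crossed, random structure). Default components are the fitted
decomposition of the risk outcome — residual 16.88,
trial-type-within-participant 192.99, participant 1.56 (implied ICC 0.92)
— with intercept 25.33 and a session × group effect of 0.27; all other
fixed effects default to zero (`EffectSpec.published()` carries the full
fitted coefficient set).

**What the generator does not emulate.** Within-run learning or fatigue,
sequential dependence between trials, heavy-tailed or lapse RTs,
participant-level heterogeneity in the softmax parameters, and any
physiological signal (heart rate is supported only as per-measurement
means for its model). Passing tests therefore show that the pipeline is
correct and well calibrated under the stated generative families — not
that real MGT data obey them.

## Estimation

Models are fitted with statsmodels `MixedLM`: participant as the grouping
factor, a random intercept per group, and — for the risk/CO/RT models —
the nested trial-type intercept as a variance component
(`0 + C(trial_code)` within participant). Risk, CO and RT use ML; the
heart-rate and scale models (participant-only intercept) use REML. CO is
modeled linearly on its {0, 0.5, 1} scale. The optimizer ladder is
L-BFGS → Powell → CG; the first converged fit is reported, and a
non-converged final state is flagged on the result rather than swallowed.
One test refits a dataset with R's lme4 and checks both routes land on the
same ML optimum (fixed effects to ~1e−6, components to ~1%).

Reported alongside the coefficients (Wald z inference, 95% CIs):

* **ICC** = Στ / (Στ + σ²), exactly, from the fitted components.
* **Marginal / conditional R²** by the variance-decomposition definitions:
  Var(Xβ̂) over the fitted fixed effects against fixed + random + residual.
* **AIC** = 2k − 2ℓ with k counting fixed effects, both variance
  parameters and the residual variance.
* **Standardized β** by response-SD division (predictor factor contrasts
  are left unscaled); the method and the SD used are stamped into the
  output metadata since more than one convention exists.
* **Cohen's f** from partial η²: `f = √(η²/(1−η²))` (0.691 → 1.4954).

**Contrasts.** Estimated marginal means over the session × group ×
stimulation grid (factors absent from a cell — e.g. repetition in the post
hoc model — are averaged with equal weights), pairwise differences with
SEs from the coefficient covariance, asymptotic z ratios, and Bonferroni
adjustment `min(1, m·p)` with the family `m` = the set of contrasts
requested in one call. The standard family has 20 members: 6 session
differences, 6 group differences, and the SPL−sham / VMPFC−SPL ladder in
each group × session. Small-sample df corrections are deliberately not
applied, matching z-based contrast reporting.

The post hoc repetition model crosses session × group × stimulation ×
repetition (A/B/C, the run's position in its session) in full and refuses
a repetition factor with fewer than two observed levels.

## Recovery and calibration scales

The recovery harness replays simulate → fit and summarizes each tracked
coefficient (truth, mean estimate, bias with Monte-Carlo SE, RMSE, CI
coverage, Wald rejection rate), counting failed fits rather than hiding
them. The desk-scale design used by the tests and the acceptance script is
15 participants per group × 25 trial types × 6 runs (4,500 rows,
~0.5 s per fit): 100 replicates for recovery of the 0.27 interaction and
500 null replicates for type-I calibration, where the rejection rate at
α = 0.05 is expected in [0.03, 0.07]. Full-scale replication of the
original coefficient tables requires the deposited study data and is out
of desk scope; at desk scale the recovery harness is the verification
surface instead.

**Variance-decomposition check.** One full-size draw (45,000 rows) is
checked with moment estimators: within-cell variance for σ², between-cell
variance within participant minus σ²/6 for the nested component (both
within 5% relative error), and participant-mean variance minus the nested
inflation for the participant component. That last component (1.56) is of
the same order as its own estimator's sampling noise at 60 participants —
the estimator SD is ≈(τ_p + inflation)·√(2/59) ≈ 0.58 — so it is checked
against a 3-SE sampling band rather than a 5% relative band, which no
unbiased estimator could meet at that n.

## Degenerate inputs and numerical choices

Zero-variance generative specs produce constant tables and are accepted;
zero-variance responses are rejected where a quantity divides by the SD.
Boundary variance estimates (true components at zero) are reported as
fitted, near zero. The IQR fence requires ≥4 finite values. Self-contrasts
return estimate 0 with adjusted p = 1. All RNG consumption goes through
`numpy` `Generator`s seeded from explicit `SeedSequence`s; seeds derived
from user seeds stay below 2³¹.

## Known limitations

* The agent is a stand-in; none of its parameters are estimates of human
  behavior, and agent-route effect sizes are illustrative only.
* Wald z inference ignores small-sample df corrections; at very small
  designs (few participants) coverage can dip below nominal.
* The deposited-data reader ingests trial-level or scored schemas through
  an explicit column map but has only been exercised on synthetic fixtures
  shaped like them.
* CO's linear model on {0, 0.5, 1} inherits the boundedness of its scale;
  no logistic alternative is provided.
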