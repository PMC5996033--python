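# Methods

## The task being modelled

A rodent stands in the hub of a four-arm plus maze. On each trial two of the
four arms are offered; each offered arm carries one of two odors and one of
two LED colors, and the two offers always differ on all three dimensions
(location, odor, LED color). Within a learning *set*, exactly one sensory
dimension is relevant: choosing the option that carries the correct feature
of that dimension is rewarded, deterministically. Location is never the
relevant dimension. Training runs 50–100 trials per day; after a set is
learned the rule changes, either within the relevant dimension (a new odor
pair; an intra-dimensional shift) or across dimensions (odor to LED color or
the reverse; an extra-dimensional shift). Two protocols are built in:
odor-first (ODOR1 → ODOR2 → LED) and LED-first (LED → ODOR1).

The simulator reduces a trial to the tuple (offered pair, choice, reward) —
the only quantities that enter any model below. Nose-poke mechanics, timing
and trial initiation are not modelled. Arm pairs are drawn i.i.d. uniformly
from the six unordered pairs; odor and LED labels are assigned to the two
arms by independent fair coin flips. The per-trial draw order is fixed (arm
pair, odor assignment, LED assignment, choice), so a simulated log is
bit-reproducible from its seed.

## The two models

**NRL (naive reinforcement learning).** Every (arm, odor, led) feature
combination — 16 states — has a value `V`, zero at set start. When a
combination is chosen, `V ← V + α (R − V)` with reward `R ∈ {0, 1}` and
learning rate `α ∈ [0, 1]`; unchosen combinations never change, so all
values stay in `[0, 1]`. The decision index of an offered pair is
`ΔV = V[a] − V[b]` and the choice probability is the logistic
`P(a) = 1 / (1 + exp(−β ΔV))` with inverse temperature `β ∈ [0, 30]`.
Because the schedule is deterministic, combinations lacking the correct
feature only ever receive `R = 0` and stay at value 0 forever; under
sustained reward the index between a correct and an incorrect offer rises
strictly and converges to 1. A consequence used repeatedly in testing: the
deterministic (sign-of-index) NRL prediction can never favor an incorrect
option, so on days without ties its deterministic fit equals the day's
success rate.

**WAM (weighted attention model).** Each *feature* has its own value: four
arm values, two odor values, two LED-color values, all zero at set start and
all updated by the same delta rule, but only for the three features of the
chosen option. Decisions compare attention-weighted composite scores: the
decision index is `I = w_l (l_a − l_b) + w_o (o_a − o_b) + w_c (c_a − c_b)`
with nonnegative weights summing to one, mapped through the same logistic.
The weights quantify how much each dimension is attended to during the
decision, independently of what has been learned about its features.

Predictions always use the pre-trial state; the update applies after
feedback. Values carry over day boundaries within a set and reset to zero at
set boundaries. An optional overnight decay factor `λ ∈ [0, 1]` (default 1,
i.e. none) multiplies carried values at each day boundary, supporting
robustness checks against overnight forgetting.

Ties (decision index exactly zero, e.g. every set's first trial) carry no
deterministic prediction. Because the a/b labelling of the two offers is
arbitrary, breaking ties toward either label would create a labelling
artifact; ties are therefore reported as such and scored 0.5 in every fit
fraction.

## Fitting

Free parameters per set: one learning rate per day, per-day decision weights
(WAM only), and a single `β ∈ [0, 30]` shared by the set's days. Because
values carry across days, per-day parameters are coupled; the set is fit
*jointly* by maximizing `ln L = Σ_t ln P_t(chosen choice)`:

1. **Grid initialization.** Exhaustive search over a thin grid — α step
   0.05, β step 1.0, weights on the 0.1-step simplex lattice — with the same
   (α, weights) applied to every day to keep the grid tractable. Ties break
   toward the lexicographically smallest parameter vector.
2. **Joint refinement.** L-BFGS-B over all per-day parameters plus β.
   The simplex constraint is removed by a smooth log-ratio bijection onto
   the simplex interior (two free coordinates per day, bounded at ±12, which
   keeps weights within ~3·10⁻⁶ of the boundary); α and β keep box bounds.
   Five seeded random restarts (configurable) supplement the grid start and
   the best final likelihood wins; the result never falls below the grid
   optimum. Optimizer failure is reported via `converged=False`, never an
   exception, and β landing on a bound is flagged.

The value trajectory of a replay depends only on the learning rates — never
on β or the weights, which enter only through the decision index. The
likelihood code exploits this: a tight scalar loop replays the trajectory
once per learning-rate vector, and all (weights, β) candidates are then
scored by vectorized numpy. The fast path is tested for exact agreement with
the readable reference replay.

### What the fitted parameters do and do not mean

Parameter-recovery simulations with stationary WAM agents (same α and
weights every day) show that the *effective* per-day decision coefficients
`β·w` are recovered well, but the joint maximum-likelihood point estimate at
realistic data sizes (10 days × 100 trials, 31 free parameters) overfits by
approximately k/2 nats, exactly as classical likelihood theory predicts.
The overfitting is structured: β inflates (it is identified only through the
products `β·w`) while the per-day weights absorb day-specific noise, so
*normalized* weight shares are biased toward uniformity — in our runs a true
`w_o = 0.6` is recovered with mean ≈ 0.39 and a mean absolute error ≈ 0.2,
while mean learning-rate error stays ≈ 0.1. One-dimensional likelihood
profiles through the truth peak exactly at the true parameter values, so
this is a property of the estimator at this scale, not of the
implementation. Directional contrasts between dimensions (e.g. odor weight
vs LED weight within a stage) are much more stable than the absolute shares
and are what the downstream analyses rely on. Recovery error shrinks as
trials per day grow, as the test suite verifies.

## Model comparison

* **Deterministic fit**: fraction of a day's choices matching the sign of
  the model's decision index (ties 0.5), values entering the day obtained by
  replaying the set from its start.
* **AIC score**: `ln L_WAM − ln L_NRL − d` over the days whose deterministic
  NRL fit strictly exceeds 0.5, with `d = 2 × (included days)` the
  parameter-count difference. Positive favors the WAM. The score is used in
  exactly this form — a log-likelihood difference penalized by the raw
  parameter-count difference, without the conventional factor of 2 on the
  log-likelihoods; with identical per-day likelihoods it is −2N, and a WAM
  advantage of 2 nats per included day breaks even. When no day passes the
  filter the result is an explicit "no comparable days" value, never 0.
* **Cross-validation**: per day, parameters are refit from scratch on all
  earlier days plus the first ⌈0.9 n⌉ of that day's trials (the ceiling
  keeps the training split nonempty at small n; later days are excluded to
  preserve out-of-sample discipline), and the day's remaining trials are
  predicted by the maximum-probability choice — equivalent to the sign of
  the index by monotonicity of the logistic, ties 0.5. Days too short for a
  nonempty test split are skipped with a warning. Held-out trials never
  enter fitting; their outcomes do enter the *prediction* replay once they
  are in the past of a later held-out trial, as in any online forecast.

## Behavioral analyses

Daily success rate is rewarded trials over trials. A set counts as learned
on the first day at or above 75% correct; the first day at or above 70%
starts the *late* stage of the set, permanently (the partition never reverts
if performance later dips, matching a two-stage early/late design). Sets
that never cross the threshold are all-early and flagged. The 4×4 choice
matrix counts chosen arm against correct arm per day; the correct arm is
recoverable from the deterministic schedule (the chosen arm when rewarded,
the offered alternative otherwise). Fitted weights are aggregated across a
cohort as mean ± SEM per set, day and dimension — days with fewer than half
the cohort are dropped, single-animal cells are flagged — plus a long-format
per-animal (set, stage, dimension) mean-weight table ready for
repeated-measures ANOVA in any statistics environment; significance testing
itself is out of scope. The location weight is fitted and exported like the
other two even when downstream figures plot only odor and LED.

## Synthetic cohorts: what they emulate and what they do not

Agents generate choices from the NRL or WAM generative rules with known
parameters, under the same task statistics as the experiment (uniform arm
pairs, random odor/LED assignment, deterministic reward, 50–100 trials/day,
value reset at set boundaries). Default protocol lengths follow the observed
mean learning durations (odor-first 5, 2, 13 days; LED-first 9, 10 days) at
100 trials/day. Perseveration after an extra-dimensional shift is emulated
by giving agents a day-by-day generating-weight schedule that starts
odor-dominant and shifts toward the LED dimension as the set progresses.

Synthetic agents are exactly the model being fit: passing recovery tests
demonstrates the estimation machinery, not that real animals obey either
model. Real data add apparatus errors, satiety and motivation drifts,
within-day nonstationarity, and choice dependencies (e.g. win-stay/lose-shift
beyond value learning) that neither generative model produces; the log
reader therefore treats reward inconsistencies as warnings by default rather
than errors.

## Study sizes used by the automated checks

The simulation studies in the test suite use: parameter recovery, 20 agents
at 10 days × 100 trials; cross-validation model recovery, 20 agents at
4 days × 50 trials per condition; the perseveration cohort, 8 agents on a
(3, 2, 6)-day odor-first protocol at 80 trials/day. These sizes were chosen
as the smallest cohorts at which the respective effects are expected to be
resolvable; the heavier studies run the optimizer with two seeded restarts
instead of the default five.

## Numerical choices

* Logistic computed in a branch-free stable form (`logaddexp` for
  likelihoods); no probability is ever exactly 0 or 1 for finite β, so the
  log-likelihood is always finite.
* Values stay in [0, 1] by construction of the delta rule; nothing is
  clipped post hoc.
* Grid tie-breaks are lexicographic and deterministic; optimizer restarts
  are seeded from the fit configuration, so fits are reproducible.
* Floats serialize with shortest round-trip representation; rerunning a
  pipeline with the same configuration and seed reproduces byte-identical
  artifacts.

## Known limitations

* The per-day WAM parameterization is weakly identified at realistic trial
  counts (see above); absolute weight shares should be interpreted with
  care, directional and stage-level contrasts are the robust readouts.
* β is estimated per set; models with day-varying exploration are out of
  scope, as are eligibility traces, forgetting of unchosen options and
  hierarchical pooling across animals.
* Cross-validation on the last 10% of each day compares models on the part
  of the day where performance is best; this mildly favors the NRL (which
  predicts correct choices once values are positive), a bias inherited from
  the design it reproduces.
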