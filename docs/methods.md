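# Methods

## Task structure and schedules

A session presents two objects per trial at 2 of 4 corner locations
(integers 1–4). Protocols: `rat_2day` (5 sample trials in one day, one
test trial 24 h later), `mouse_5day` (5 trials/day × 4 days + 24-h test,
21 trials), `mouse_3trial` (3 trials/day × 4 days + test, 13 trials), and
`mouse_4week` (overlapping only: 3 weeks × 25 trials Mon–Fri plus a final
trial on Wednesday of week 4; trials 26 and 76 repeat the preceding
configuration and act as 3-day and 5-day delayed tests). Days are stored as
calendar indices (Mon–Fri = 1–5, 8–12, 15–19, final trial day 24), so the
gap between consecutive days directly encodes the number of elapsed nights
used by the forgetting models.

Slot semantics: slot 1 is the stable-role location in the stable and
overlapping conditions; in random it is an arbitrary but fixed
pseudo-stable reference (needed so a discrimination index is defined
there — counterbalancing makes its expectation zero). Under this
convention slot 2 is the "novel" DI reference in every condition: the
to-be-moved/moved slot in stable, the moving slot in overlapping, the
reference's partner in random.

Counterbalancing enumerates 24 assignments (4 stable-role locations × 3
partner locations × 2 test destinations); an animal's overlapping
stable-role location is always different from its stable-condition one,
and cohort generation cycles both the 24 assignments and the 6 condition
orders, so any cohort size is balanced to within one animal. The
pseudo-random condition is built per day by rejection sampling (cap
10,000 attempts, then a named infeasibility error): per-day location
counts differ by at most one, the first three trials cover all four
locations, on 5-trial days the last two trials use each location exactly
once, and no trial repeats the previous trial's pair. In overlapping, the
moving location is balanced across the three non-stable locations and
never repeats on consecutive sample trials (the configuration genuinely
"varies"), except where a delayed-test trial is defined to copy its
predecessor. `validate_schedule` re-checks every rule independently of the
generator; generated schedules must validate clean for all conditions,
protocols, and seeds.

The `mouse_4week` protocol is restricted to the overlapping condition: the
delayed-test copy rule is only meaningful there, and a forced copied trial
is incompatible with the random condition's per-day balance rules. Other
conditions raise an error rather than produce an undefined schedule.

## Memory-trace model

State is a 2 × 4 matrix m(o, l) ≥ 0, initialized at m₀ (0 for M1/M2).
Update per trial: m ← (1 − α) m + α δ, both object rows in the same call.
Uncertainty per object is the Shannon entropy (nats) of the row normalized
to sum 1, with 0·ln 0 = 0 and an all-zero row defined as uniform (entropy
ln 4 — maximal uncertainty before any observation, and the continuous
limit of m₀ → 0). Allocation between the two objects is the two-object
softmax p₁ = σ(β (S₁ − S₂)); natural logarithms throughout (β absorbs any
base change, so fits are invariant up to a rescaling of β).

**Observation-then-allocation ordering.** The animal sees the current
trial's configuration before it distributes exploration, so each trial's
observation is integrated into the trace *first* and the post-observation
entropies drive that trial's allocation. This ordering is what produces
the model's test-trial signatures: in the stable condition the displaced
object's trace suddenly spans two locations at test, its entropy jumps
from 0, and the allocation shifts toward it — with the effect maximal near
α ≈ 0.5 (too-small α gives the new observation no weight; too-large α
erases the old location, and α = 1 makes every row one-hot so allocation
is always 50/50). Under the alternative (allocate from the pre-trial
trace) the stable condition would predict exactly zero test DI, which
contradicts the behavior the model exists to explain. The same ordering is
applied to sample and test trials alike.

Day-level forgetting (M2/M3) pulls every entry toward m₀ once per elapsed
night: n nights compose to m ← γⁿ m + (1 − γⁿ) m₀. It is applied at each
day boundary before the first trial of the new day, including the 24-h
pre-test gap and the 3- and 5-night gaps of the 4-week protocol. Free
parameter counts: M1 = 2 (α, β), M2 = 3 (+γ), M3 = 4 (+γ, m₀), M4 = 3
(+m₀, no forgetting).

## Likelihood and fitting

Data enter as per-trial proportions q_t = t₁/(t₁ + t₂); trials with zero
total exploration are skipped. The per-trial likelihood term is the
proportion-weighted Bernoulli cross-entropy q ln p + (1 − q) ln(1 − p)
with p clamped to [1e−12, 1 − 1e−12]. This is the minimal choice that
makes the 50/50 chance model's log-likelihood N·ln ½ regardless of the
data, which the chance comparison and pseudo-R² presuppose. A
time-weighted variant (each term multiplied by the trial's total seconds)
is available via `sample_weight` / `time_weighted=`.

Optimization is Nelder–Mead from `n_starts` random initializations — α and
γ on the logit scale, m₀ on the log scale, β unconstrained with 5× Cauchy
start draws (heavy tails stand in for an unbounded search range) — plus a
deterministic chance start (α = 0.5, β = 0). Since β = 0 reproduces chance
exactly for any α, the reported optimum is floored at the chance
log-likelihood. Defaults: `n_starts=100` in the estimator (raise to ~1000
for publication-grade fits of noisy data; the acceptance computations use
200). The likelihood-ratio test against chance uses χ² with df = the
model's free-parameter count (a conventional, slightly conservative choice
given the boundary). Fitted |β| ≥ 1000 flags a session as an outlier;
outliers are excluded from parameter means/SEMs but retained in criterion
sums. AIC = 2k − 2LL and BIC = k ln n − 2LL are computed per session and
summed over sessions for model comparison; the winner is the lowest total
of each criterion.

Identifiability caveat: in the stable condition every sample-trial
prediction is 0.5 for *any* α (the trace is one-hot throughout training),
so only the single test trial constrains α there and per-session stable
fits of α are essentially unconstrained. Parameter-recovery experiments
therefore default to the overlapping condition, where both parameters are
identified; this is a property of the task design, not of the optimizer.

## Simulation

A simulated session sets the exploration proportion equal to the model's
allocation probability, optionally plus Gaussian noise truncated to
[0, 1]; zero noise (the default) makes simulation a pure function of
(schedule, parameters). Total time per trial is a nominal constant 40 s
unless a profile is supplied — the DI of proportions does not depend on
it. Parameter sweeps reuse one set of counterbalanced schedules across all
grid cells so that cell-to-cell differences reflect parameters, not
schedule resampling.

## Behavioral statistics

DI = (t_novel − t_stable)/(t_novel + t_stable); undefined (missing) for
unexplored trials. Animals whose smallest per-trial total exploration is
below 5 s are excluded (threshold configurable). t-tests against chance
are two-sided one-sample tests; no multiple-testing correction. The
repeated-measures ANOVA requires a complete within-subject design (it
reports missing cells rather than imputing) and uses uncorrected degrees
of freedom by default, matching the integer dfs of the 2-day and 5-day
analyses; a Greenhouse–Geisser-corrected single-factor variant (epsilon-
scaled, fractional dfs) serves the 4-week week analysis. The ANOVA is
delegated to statsmodels `AnovaRM` (uncorrected, any number of within
factors) and pingouin (GG correction); the two routes are cross-checked
against each other in the test suite. Synthetic and simulated test trials
carry both a first-5-min measure (the standard columns, used by default)
and a full 10-min measure (`time_obj*_full_s`).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:
latent per-animal (α, β) heterogeneity (α logit-normal so draws stay in
(0, 1), β Gaussian), counterbalanced schedules, truncated-Gaussian
proportion noise, and positive right-skewed exploration totals (lognormal
around a linear trial/day habituation trend; defaults 30 s base, −5% per
trial within day, −3% per day, σ = 0.25 on the log scale — mild
habituation with near-stable totals, the qualitative pattern of real
exploration). Defaults follow the study conditions: 32 animals, all three
conditions, α centered at 0.6, β ~ N(5, 2²), 5% proportion noise.
Optionally, "planted" low-exploring animals (base 0.8 s) trip the 5-s
exclusion rule downstream. Ground truth (parameters plus per-session RNG
substream seeds) is recorded so the behavior table regenerates
bit-for-bit and recovery can be scored.

What passing synthetic tests do **not** show: the generator's noise is the
fitted model plus symmetric proportion noise, so it cannot detect
misspecification of the likelihood against real animals' bout structure,
object-identity effects, or spatial biases; real-data conclusions still
require the deposited behavioral spreadsheets (a configurable reader shim,
`io.read_supplementary`, accepts those layouts).

## Desk-scale study sizes

The validation computations are sized to run in minutes on one CPU, as the
package's own choice of desk scale: brute-force (α, β) grid 200 × 200 on
6-trial sessions; parameter recovery on 30 overlapping mouse sessions with
200 starts; model recovery on replicate 9-session rat cohorts with 25
starts (10 replicates in the acceptance script, 20 in the test suite);
null calibration on 100 replicate cohorts (ANOVA) and 100 null sessions
(likelihood-ratio test).

## Known limitations

* Only the 2-object × 4-location geometry is exercised; there is no
  spatial generalization between nearby locations and no object-feature
  memory.
* Per-session fitting only — no hierarchical/population model and no
  cross-validated model selection.
* The Greenhouse–Geisser correction is implemented for single-factor
  designs only.
* The continuous-proportion cross-entropy is not a true density, so
  absolute likelihood magnitudes (and hence AIC/BIC totals) are
  comparable across models on the same data but not across likelihood
  conventions.
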