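# Methods

## Task engine

Three levels: level 1 — 2 stimuli, 2 dimensions × 2 features, 60 trials
(2 blocks of 30); level 2 — 2 stimuli, 3 dimensions, 70 trials; level 3 —
3 stimuli, 3 dimensions × 3 features, 70 trials; 200 trials total. Every
dimension's full feature set is displayed on every trial, one feature per
stimulus, with the assignment re-randomised per trial. This guarantees
that (a) within any dimension the displayed stimuli carry pairwise
distinct features, and (b) exactly one stimulus carries the rewarded
feature, so chance accuracy is 1/2, 1/2 and 1/3 across levels.

Covert rule shifts: inter-shift gaps i.i.d. uniform on {6..11} trials;
the first shift falls one gap after the level start (never trial 0);
block boundaries do not reset the gap counter. Each shift is ID or ED
with probability 1/2, resampled so that any block containing at least two
shifts sees both types (a block with fewer shifts cannot satisfy this and
is left unconstrained). The new rule's feature is drawn uniformly within
the (ID: same, excluding the old feature; ED: uniformly drawn other)
dimension. The rule change takes effect on the shift trial itself, so
"distance 1" is the first post-shift trial. Shift schedules are sampled
per participant (a per-cohort fixed schedule is available by passing an
explicit schedule). The random slider start position is recorded as
metadata only.

## Ideal observer

Beliefs over the N unique displayed features, uniform at each level
start; deterministic-feedback likelihoods with the unchosen-feature count
pooled across all unchosen stimuli (at levels 1–2 chosen and unchosen
counts are equal, so the posterior is uniform on its support). A zero
normaliser (all supported hypotheses contradicted) triggers a reset to
uniform. Numerics: probabilities below 1e-15 are truncated to zero before
the zero-normaliser test (tolerance 1e-12), making resets robust to
floating-point residue; entropy uses the 0·log 0 := 0 convention.

General Certainty is implemented as 100·(log₂N − S)/log₂N — the
proportion of maximal entropy eliminated, 0 at uniform and 100 at a point
mass. A "literal" variant 100·(log₂N − log₂S)/log₂N exists behind a flag
for sensitivity analysis only; it is undefined at S = 0 and nonzero at
uniform, and is not used anywhere in the pipeline.

Two trace timings are emitted per trial. The `pre` trace (belief through
trial t−1 plus the trial-t choice) is aligned with the confidence report,
which precedes feedback, and is the default regressor in all models. The
`post` trace (after trial-t feedback) is what shift-locked illustrations
show; it is emitted so both conventions are available explicitly rather
than silently choosing one.

## Synthetic cohorts

The generative agent is the minimal model producing the phenomena the
pipeline targets: matched accuracy, a confidence-intercept group gap,
group-dependent CC coupling, and group-dependent feedback reactivity.
Choices are softmax(inv_temp · CC/100) over the per-stimulus prior Choice
Certainty with a lapse mixture; confidence is b + w_cc·z(CC) +
w_gc·z(GC) + w_fb·(r_prev − ½) + Gaussian noise, rounded and clipped to
[1, 100], with z(·) standardised within participant — the same
convention the pipeline uses for the certainty traces, so generative
weights are directly comparable to fitted coefficients. The explicit
feedback-valence weight w_fb exists because normative CC is
mean-reverting after correct trials (per-trial layout re-randomisation
splits support features across stimuli about as often as it reunites
them), so certainty coupling alone cannot move the average post-correct
confidence change; a group difference in the feedback reactivity of
confidence *changes* therefore needs its own weight. r_prev is the
previous outcome within level, ½ (neutral) on level-first trials. RTs
are lognormal and behaviourally inert (they exercise the RT filter
only).

Defaults (means ± between-participant SD): inv_temp 5 ± 1, lapse
0.05 ± 0.03, intercept 70 ± 10 (control), w_cc 6 ± 1.5, w_gc 1.5 ± 1,
w_fb 1.5 ± 1, noise SD 10 ± 2. The patient preset lowers the intercept by
Δb = 12 slider units and raises w_cc by Δw = 3 and w_fb by Δfb = 2,
leaving choice parameters untouched. The recovery experiment keeps w_fb
group-equal (Δfb = 0) so its null preset is fully null and its targets
are exactly the intercept and CC-coupling effects. Δb sits inside the observed per-level group gaps (≈6.5–17
units) and w_cc/w_gc mirror the relative magnitudes of the reported CC
and GC coefficients. inv_temp and lapse were chosen (once, by grid) so
that accuracy declines monotonically over levels (≈0.78/0.72/0.62); a
softmax-on-certainty agent is relatively better at level 3 than human
participants, so the level-3 drop is milder than in empirical data. What
passing recovery tests show is therefore that the pipeline detects
group structure of realistic size under matched accuracy — not that the
agent reproduces human learning curves, sequential choice biases, or
RT–confidence coupling, which it does not model.

Demographics: age ~ N(31, 11) clipped to 18–55; gender codes 1/2/0
(female/male/non-binary) at probabilities 0.48/0.48/0.04 — the low
non-binary rate exercises the 3-level categorical path; IQ proxy
(cognitive-ability total) ~ N(30, 8). Both groups share these
distributions (matched by construction).

## Analysis pipeline

Exclusions: overall accuracy at or below chance, with chance defined as
the trial-weighted mean of per-level chance ((60·½ + 70·½ + 70·⅓)/200 ≈
0.442); a per-level mode (excluded only if at or below chance at every
level) is available. Constant confidence: excluded if more than 90% of
ratings share one value. RT filter: per participant × level, log RTs,
first trial of each block excluded from both the mean/SD computation and
from removal; trials beyond 3 SD removed; zero variance removes nothing.

Shift-aligned averaging: per-participant means per shift type × distance
(−5..+5, 0 = shift trial), then group mean/SE; windows truncate at level
boundaries.

Mixed models: linear models via statsmodels MixedLM (ML when BICs are
compared), logistic models via the variational BinomialBayesMixedGLM with
a participant random intercept (posterior mean/SD reported as
estimate/SE, normal-approximation p). Functional-form selection for
post-shift recovery compares linear, log, and centred orthonormal
quadratic polynomials of distance by BIC; ties break toward the simpler
form. The orthonormal basis is evaluated on the observed distances, so
quadratic coefficients are large in magnitude by construction; no attempt
is made to match any particular scale. For binary outcomes the BIC
comparison uses fixed-effects logistic GLMs whose participant dummies are
identical across candidates.

Optimisation: each linear mixed model is fit with two optimisers (BFGS
and Powell) and the converged solution with the higher likelihood is
kept — gradient optimisers occasionally terminate in a spurious optimum
with grossly inflated variance components, which silently triples
fixed-effect standard errors.

Random structures: confidence models use a participant random intercept
plus uncorrelated random slopes (variance components) for the trial-level
predictors of interest — lagged accuracy in the feedback model, zGC/zCC
in the normative models. The slope components matter for calibration:
between-participant slope heterogeneity is part of the generative model,
and omitting it makes group-interaction tests anti-conservative. Task
level enters as a fixed factor rather than a random intercept: with three
levels the level variance is not reliably estimable and statsmodels has
no crossed random effects. Singular or non-converged fits retry with the
random intercept only and are flagged (`simplified`). VIF is computed on
the fixed-effects design matrix; VIF ≥ 10 sets a warning flag, never an
error. Note that on synthetic cohorts the GC–CC collinearity of a
near-optimal agent is higher (VIF ≈ 4) than reported for human data.

Classical tests: confidence change Δconf_t = conf_t − conf_{t−1} within
level, conditioned on the previous trial's accuracy, aggregated to
participant level, 1.5·IQR-cleaned; within-group tests against zero
(t-test, or Wilcoxon signed-rank when Shapiro–Wilk rejects normality at
α = 0.05) with Bonferroni over the family of four; between-group
comparisons (t-test, or rank-sum on normality/Levene violation) with
Bonferroni over the family of two. The group × level ANOVAs are
mixed-design ANOVAs (pingouin) on participant × level means.

## Parameter recovery

For each replicate: simulate a cohort under given (Δb, Δw) presets, apply
exclusions, recompute observer traces from the logs, fit the joint
normative model, and record the group main effect (truth −Δb) and the
CC × group interaction (truth +Δw). Reported: mean estimate, bias, RMSE,
sign-recovery rate (correct sign and p < 0.05) and raw rejection rate.
The test suite runs 50 preset replicates and 200 null replicates at
n = 29 per group; the analysis driver runs a compact 15-replicate
demonstration. All replicate seeds are spawned from a single seed.

## Known limitations

The agent has no choice perseveration, no learning-rate asymmetries, no
RT model beyond lognormal noise, and no symptom-severity dimension; the
cohort generator matches groups exactly in expectation rather than
emulating recruitment imbalance. The variational logistic fits
underestimate posterior uncertainty slightly relative to full-likelihood
GLMMs; they are used for estimation and sign/significance summaries, not
for BIC comparison.
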