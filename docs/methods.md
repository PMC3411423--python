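# Methods

This note documents the statistical procedures the package implements, the
generative model behind the synthetic cohorts, how its defaults were
calibrated, and the numerical and design choices that were genuinely open.

## Scoring rules

Knowledge items score one point each; multi-part items split the point over
parts with weights summing to one. The rules, per part:

| response | score |
|---|---|
| correct option / value inside the pre-set interval | weight |
| wrong option, value outside interval, or "I am not sure" | 0 |
| missing | weight / k |

k counts every printed response choice *including* "I am not sure", so a
missing response is scored at the expected value of blind guessing. The
respondent score is 100 × Σ item scores / |item set| and is undefined when
fewer than 50% of the items in the set were completed ("not sure" counts as
completed; the completion rule counts items, not parts). Three item sets are
built in: `initial` (15 items), `reduced` (12, after item analysis) and
`screener` (the 5 published items). Open-ended items have no printed option
count; the default banks set k = 2 (right/wrong) for them, a bank-level
setting users can change.

The item analysis flags: *too easy* (healthy-control correctness > 80%), *too
hard* (provider correctness < 50%), *redundant* (any inter-item correlation
> 0.8), *negative corrected item–total correlation* (computed against the
total excluding the item — the standard correction, chosen because the plain
item–total correlation is self-inflated) and *excess missingness* (> 5%).
Flags are advisory: one retained published item sits at 86% control
correctness, just above the too-easy threshold, so recommendation lists are
reviewed, not applied blindly.

## Concordance model

Patients who had lumpectomy followed by mastectomy (not clinically eligible
for both options) and patients without a definitive surgery on record are
excluded. Missing goal ratings are imputed by EM under a joint multivariate
normal model: the E-step fills each patient's missing block with its
conditional expectation given her observed goals and the current mean and
covariance; the M-step updates both moments including the conditional
second-moment correction. Convergence requires the largest parameter change
below 1e-6 (cap 500 iterations); the observed-data log-likelihood is computed
every iteration and asserted non-decreasing. Imputed values are clipped to
the 0–10 scale *after* convergence but not rounded, preserving the
conditional means for the model fit; observed entries are never altered. A
patient with every goal missing is imputed at the estimated mean with a
warning. Singular observed-block covariances get a 1e-8 ridge.

The treatment model is a maximum-likelihood logistic regression (Newton/IRLS,
tolerance 1e-8, cap 100 iterations, Wald 95% intervals) of mastectomy on a
stage-II indicator and all six goal importances — including the goals whose
published multivariable rows are blank, which we read as non-significant
rather than excluded (configurable). Quasi-separation is flagged when any
|coefficient| exceeds 15. Concordance classifies a patient as matched when
p ≥ 0.5 and mastectomy, or p < 0.5 and lumpectomy; the boundary counts as
predicted mastectomy. There is deliberately no train/test split: the score is
an in-sample goodness-of-fit summary interpreted at the group level. The
c-statistic is the rank/AUC form (ties counted ½), computed directly from
ranks. Univariate screens use Welch t-tests for goals (the unequal-variance
form, since nothing guarantees equal spread across arms) and a chi-square
test without continuity correction for stage.

## Psychometrics

Reliability is ICC(2,1) — two-way random effects, absolute agreement, single
measurement — computed from the ANOVA mean squares of the paired table as
(MSR − MSE) / (MSR + MSE + 2(MSC − MSE)/n), the standard test–retest choice;
the source analysis says only "ICC", so this is a documented interpretation.
Incomplete pairs are dropped listwise per measure; at least three pairs are
required; a fully degenerate table (all values identical) is defined as 1 and
the estimate is clipped below at −1. The a-priori reliability target is 0.7.

Group discrimination uses one-way ANOVA over providers/patients/controls with
planned one-sided contrasts (providers > patients > controls) on the pooled
error, per-contrast α = 0.05 with no multiplicity adjustment (none was
specified); per-goal discrimination uses one-sided Welch t-tests in the
direction declared in the goal bank. Content validity asks whether > 70% of
providers rate coverage 3–4 on the 1–4 scale and whether ≥ 20% of patients
put each goal in their top three. Predictive validity compares decision
confidence (two-sided Welch t) and regret — dichotomised as
definitely/probably-would-do-the-same vs the rest — between concordant and
discordant patients; it is run on analyzable patients only, since the
concordance flag exists only for them. Internal consistency (Cronbach's
alpha) is deliberately not reported: the knowledge items do not draw from a
single construct.

## Synthetic cohort generator

The generator emulates the validation study's three samples (440 patients, 88
providers, 35 controls; 29 lumpectomy-then-mastectomy and 28 patients without
definitive surgery leave 383 analyzable; 100 retest pairs).

*Knowledge.* Each respondent carries a standard-normal latent ability t. Item
j in group g is answered correctly when λt + √(1−λ²)ε exceeds the normal
quantile of the configured correct rate p_gj (a Gaussian copula), so item
marginals match p_gj exactly while the common loading λ governs inter-item
correlation and hence score reliability. The five screener items use the
published per-group response tables; the ten unpublished items carry
synthetic profiles calibrated so the reduced-score group means hit 52.7 /
87.7 / 49.3 (patients/providers/controls). One stand-in item is
reverse-keyed (negative loading) and two are near-ceiling, mirroring the
three deletions of the original item analysis. Retest re-draws ε with the
same t (an optional trait drift is off by default). λ = 0.52 was calibrated
to a knowledge-score retest ICC of 0.70 (50-seed Monte-Carlo); the implied
score SD (~23) is somewhat above the published 21.8 — with 12 near-binary
items, the published SD and ICC cannot both be matched exactly, and
reliability was prioritised.

*Goals.* Patients draw a 6-dimensional latent normal goal vector (plus two
independent placeholder goals standing in for the unpublished items); each
wave's rating is the latent value plus per-goal wave noise, rounded and
clipped to the 0–10 grid. Clipping is doing real work: the large calibrated
latent SDs produce the clumpy, bimodal observed distributions (mass at 0 and
10) that strong goal–treatment discrimination requires, and the
near-ceiling "avoid recurrence" goal (88% rating 10) comes from a latent
mean far above the scale top rather than a point mass.

*Treatment.* Mastectomy is Bernoulli(logistic(b0 + b·x + b_s·stageII)) with
log-odds coefficients fixed at the logs of the published multivariable odds
ratios (0.79, 1.88, 1.23; stage 1.81) applied to the *observed* (discretised)
test-wave ratings, and stage-II prevalence 0.398. Generating goals first and
treatment second means the analysis refits exactly the generative family, so
parameter recovery is a fair test. Non-analyzable patients are a random
subset relabelled after treatment draw.

*Missingness and appraisal.* Knowledge items go missing at 0.8% per item plus
0.9% low-completers who answer only five items (falling under the scoring
floor), giving the published ~1.4% average. Goals go missing at 3.3% each,
except "remove breast for peace of mind" at 10.9% with 94% of skips among
lumpectomy patients (conditional rates computed from realized arm sizes).
Stated preference is a noisy monotone map of the true mastectomy probability;
confidence and regret are near-ceiling with a negligible concordance effect,
matching the study's null predictive-validity result; completion times vary
by education (6.8/6.4/5.3 minutes).

## Calibration

Free parameters (latent goal means/SDs/correlations, intercept, wave noises,
loading, unpublished item profiles) were fixed once by an iterative
moment-matching search against the published quantities: arm-conditional goal
means (achieved within ±0.1 of all twelve), mastectomy fraction 111/383,
observed keep/remove Pearson correlation −0.46, the recurrence-goal ceiling,
the six goal retest ICCs and the knowledge ICC. `calibrate_generator` exposes
the same machinery for user-defined targets with tolerances and a calibration
log. Quantities *not* targeted — overall concordance, per-arm concordance,
the c-statistic, the screener–full correlation, the screener ICC — are
emergent; at the study scale over 20 seeds they come out at ≈88% (81/91),
0.944, 0.83 and 0.51 against published 89% (82/93), 0.95, 0.80 and 0.60. The
screener ICC is the one visible shortfall: with five near-binary items and a
loading pinned by the full-score ICC, a single-factor ability model cannot
reach 0.60, and we did not add a second latent dimension to force it.

## Numerical conventions and edge cases

Percentages are reported to one decimal with half-up rounding; JSON output
keeps six significant digits; report text rounds scores to one decimal and
ICC/OR to two. Top-three goal selection breaks rating ties uniformly at
random inside the generator. All randomness flows through a single
seed-derived generator (PCG64); cohort provenance records seed and generator
version, and identical seeds reproduce byte-identical outputs. Degenerate
inputs (constant treatment, single preference level, empty concordance
classes, arms with n < 2, all-zero contingency margins) either raise with a
named cause or are skipped with an explicit note in the report.

## Limitations

Synthetic cohorts are multivariate-normal latents under the hood: real rating
distributions are more irregular, item difficulties are guesses outside the
five published items, and respondent-level covariance between knowledge and
goals is absent (ability and goals are independent by construction). Passing
tests therefore demonstrate that the estimators and pipeline recover known
structure under the study's own model family and sample sizes — not that the
instrument behaves identically on new clinical data. The concordance score
remains an in-sample summary; no bootstrap intervals are provided.
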