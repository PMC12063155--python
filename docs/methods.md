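# Methods

## Task structure

A run presents word pairs in a uniformly random interleaving constrained
so each pair appears exactly 16 times; the correct option is shown on
the left for exactly 8 of a pair's 16 presentations. Both fixation
jitters are drawn uniformly from {2.0, 2.5, 3.0, 3.5, 4.0} s. Onsets
are run-relative seconds: jitter1 → stimulus (2 s choice window) →
selection frame (0.5 s) → jitter2 → feedback. Feedback display duration
is not part of the published design constants; we use 1.0 s, which only
affects absolute onset bookkeeping, not any analysis. Condition order
follows a cyclic 4×4 Latin square over subjects.

Feedback availability is pre-drawn per trial for both spellings as
i.i.d. Bernoulli(0.80 / 0.20). An exact-frequency option permutes a
fixed number of rewarded trials per pair instead, but with 16
repetitions the closest attainable count is 13/16 ≈ 81%, so i.i.d.
draws are the default.

## Learning model

Outcomes are coded 0/1 (rewarded or not) in all conditions, keeping V in
[0, 1] and prediction errors in [−1, 1] on a single scale; reward
magnitude (1 vs 10 points) influences behavior only through the reward
contrast code in the parameter regression. Both spellings start at
V = 0.5 each run (runs use new stimuli, so values reset between runs),
and only the chosen option updates. The choice rule is the two-option
softmax, equivalently a logistic on β(V_c − V_i). Link-scale inputs are
clamped at ±30 before the inverse links to guard overflow. Missed
trials (default rate 1.1%) carry no choice, trigger no update, and are
excluded from the likelihood.

These are deliberate modeling choices where the estimation details of
the original protocol are not fully specified: logit/log links, 0/1
outcome coding, V₀ = 0.5, softmax choice. Each is the field-standard
option for this model family and is isolated behind one function so a
sensitivity variant is a one-line change.

## Estimation

Each subject is fit jointly across their four runs by maximum
likelihood: L-BFGS-B from 10 standard-normal link-scale starting points
(tolerance 1e-12 on the objective), returning the best solution and
never one worse than the best starting point. The search is confined to
an identifiability box — logit-α base in ±4 (α in [0.02, 0.98]), log-β
base in [−2.3, 3.5] (β in [0.1, 33]), condition/age coefficients in ±2
link units. The α·β likelihood ridge (α → 0 with β → ∞ mimics a
near-deterministic chooser) otherwise sends weakly identified subjects
to arbitrary extremes; the box is wide enough that plausible true
values essentially never touch it. Model variants (with vs without age
coefficients; a 2-parameter baseline-only model) differ only in which
link-scale terms are free. Variants are compared by BIC summed over
subjects (AIC is also reported); ties favor the smaller model, which the
BIC penalty already enforces.

### Limits of per-subject maximum likelihood

Parameter-recovery simulations at the study's scale (192 trials over
four single-condition runs) show the realized sampling spread of the
6-parameter MLE is roughly 1.0 on logit-α and 0.6 on log-β even for
well-behaved agents, and markedly worse for near-random (low-β) or
near-deterministic (high-β) agents, whose learning rate or inverse
temperature is intrinsically unidentifiable. Consequently true-vs-
estimated correlations for the baseline parameters plateau around
0.5–0.6 under realistic population dispersions: the recovery suite
reports this honestly rather than passing a higher floor. The reduced
2-parameter model, which pools all 192 trials into one (α, β), is
recovered essentially unbiasedly (grid-search cross-checks reach
r ≈ 0.74). Group-level (hierarchical) estimation would shrink
per-subject noise substantially but changes the estimator away from the
per-subject MLE this package implements.

## Effort-discounting staircase

The fixed high-effort offer is €2.00; the low-effort offer starts at
€1.00 and moves up after a high-effort choice and down otherwise, each
adjustment half the previous one. The published procedure defines the
halving recursion but not the first step; we take it as €0.50 (half the
starting offer and half the gap to the fixed offer), giving the exact
step ladder 0.5, 0.25, 0.125, 0.0625, 0.03125, 0.015625 and indifference
points on the 1/64-euro grid. "The amount offered after six trials" is
read as the offer that would be presented on a seventh trial (the value
after the sixth adjustment); the sixth presented offer is available
behind a flag. Median-split ties are assigned to the low-SV group.
Noiseless threshold agents are recovered to within one final step
(€0.03125) across the whole (0.05, 1.95) range.

## Behavioral mixed models

Accuracy (correct = 1) is analyzed with a random-intercept logistic
model. Continuous covariates (age, within-run trial index) are
standardized (mean 0, population SD 1) over whatever set of trials
enters the analysis — so subset analyses re-standardize within the
subset — and categorical factors are coded −1/+1. The marginal
likelihood is maximized with adaptive Gauss–Hermite quadrature (15
nodes, centered and scaled at each cluster's posterior mode, the same
integral contract as lme4's nAGQ > 1; the test suite cross-checks
against glmer to ~1e-3 on coefficients). Inference is by Wald z; a
likelihood-ratio helper is provided. Follow-up suites refit reduced
models per effort level (Bonferroni ×2), per effort × SV group (×4), or
per age bin — inclusive integer-year bins 13–15, 16–18, 19–21, 22–25,
with fractional ages truncated. The random-intercept SD is bounded
below at ~2e-3 rather than 0 so homogeneous data converge cleanly to
the pooled solution.

## fMRI regressors and ROI analyses

Each run's GLM events comprise six zero-duration predictors — modulated
and unmodulated positive-PE, negative-PE (feedback onset) and
expected-value (stimulus onset) events — plus missed trials as
zero-weight events. Modulated weights are mean-centered per participant
per regressor per condition (each run is one condition) and never
orthogonalized or standardized; zero prediction errors join the
positive set (a measure-zero tie-break under the forward model).
Convolution uses a double-gamma response (delay 6 s, undershoot 16 s,
ratio 1/6, unit dispersion, peak-normalized), evaluated on a 50 ms grid
and sampled at volume times (TR 2 s); temporal derivatives are first
differences of the convolved column. ROI spheres (8 mm, inclusive
boundary) are built on the 2 mm MNI152 grid around dACC [4, 36, 20],
vmPFC [0, 34, 0] and dorsal striatum [±10, 14/4, −6], and can be
written as NIfTI masks.

The RM-ANOVA computes, per subject, the within-condition contrast
scores (effort difference, reward difference, their interaction, and
the subject mean) and regresses each on an intercept plus standardized
age. Because age is centered, the intercept test is the within effect
at the mean age — Type III for these 1-df contrasts — and the age slope
gives the effect × age interaction, each against its own error stratum.
Contrasts that are identically zero (no variation across conditions)
return F = 0 by definition. Follow-up reward-only ANOVAs per effort
level (×2) or per effort × SV group (×4) reuse the same machinery.

## Synthetic cohorts

The generator mirrors the study conditions the analyses assume: 146
subjects by default, ages uniform on 13–25 (standardized with the
cohort's own mean/SD before entering any link function), four
counterbalanced runs per subject on 80/20 contingencies, 1.1% missed
trials, choices from the learning model's forward pass, discounting
choices from a softmax of (offer − true SV) with temperature €0.10, and
ROI betas as linear condition effects plus Gaussian noise. Default
baseline parameters (logit-α ~ N(−1.0, 0.8); log-β ~ N(1.6, 0.5)) and
condition coefficients (means ∓0.2–0.3, SDs 0.3) produce the
qualitative behavioral pattern of interest — reward helps, effort
hurts, learning improves over trials. ROI effect sizes are illustrative
(a reward × effort and reward × effort × age effect in dACC, reward
effects elsewhere), not estimates of any empirical effect. Every
quantity is reproducible bit-for-bit from one integer seed via spawned
per-subject streams.

What the generator does not emulate: within-run feedback dependencies,
response times, attention or working-memory contributions to learning,
scanner noise or any BOLD time-series structure, and age trends in SV
(true SV is drawn independently of age). Passing tests therefore
validate the machinery — schedules, likelihoods, estimators, event
construction, statistics — on data whose generative process matches the
model, which is the strongest claim synthetic data can support; they do
not certify performance on real behavior, where model misspecification
dominates.

## Validation scales

The heavier suites run at reduced but still informative sizes chosen as
the package's own validation design: parameter recovery at 100 subjects
× 192 trials with 10 starts; model comparison over 20 replicate
8-subject cohorts (4 starts per fit); GLMM null calibration over 200
replicates of 16 subjects × 32 trials; design-constant frequencies over
≥10,000 draws. The full test suite completes in a few minutes on one
CPU.
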