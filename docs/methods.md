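# Methods

## Model and procedure

The package treats responder identification after robot-assisted gait
training (RAGT) as a two-stage problem: *structure-aware variable
screening* with DirectLiNGAM on median-split clinical variables, then
*effect quantification* with logistic regression on the variables the
graph places as direct causes of the outcome.

DirectLiNGAM assumes the observed variables follow a linear structural
equation model `x = Bx + e` with acyclic `B`, mutually independent noise
terms, no unobserved confounders, and at most one Gaussian noise term.
Under these assumptions the full causal order is identifiable.  The
estimator extracts the most exogenous variable iteratively.  For a
candidate pair (x, y), both standardized, with `r_y|x` the least-squares
residual of y on x, the direction measure is

    M(x → y) = Ĥ(y) + Ĥ(r_x|y) − Ĥ(x) − Ĥ(r_y|x),

which by the mutual-information identity is positive exactly when the
pair (x, r_y|x) is the more nearly independent one, i.e. when x → y.
Ĥ is the maximum-entropy approximation of differential entropy

    Ĥ(u) = ½(1 + log 2π) − k₁·(E[log cosh u] − γ)² − k₂·(E[u·e^(−u²/2)])²

with k₁ = 79.047, k₂ = 7.4129, γ = 0.37457, the constants used by
published LiNGAM implementations — chosen for comparability with the
ICA-based cross-check estimator.  The root score for candidate i is
`T(i) = Σ_{j≠i} min(0, M(i → j))²`; the argmin is extracted (ties broken
toward the lowest column index), remaining variables are replaced by their
residuals on it and re-standardized, and the step repeats.  Direct effects
are then plain OLS coefficients of each variable on all its predecessors
in the recovered order; no within-learner pruning is applied, because
pruning is delegated to the ensemble threshold downstream (a
`threshold`-free learner keeps the bootstrap distribution of each
coefficient unbiased around its OLS value).

Applying a linear non-Gaussian model to all-binary (median-split) columns
is a methodological compromise inherited from the analysis design: binary
variables are non-Gaussian, which is what the direction measure exploits,
but the linearity assumption holds only approximately.  The package
follows that design and treats the logistic stage as the quantitative
model; the end-to-end simulations below measure how well the compromise
works rather than assuming it.

## Bootstrap stabilization

1,000 resamples (rows drawn with replacement, same n); per-iteration
effects with |weight| ≤ 0.05 are zeroed; the ensemble mean is taken over
**all** iterations, zeroed entries included.  The alternative — averaging
only over retaining iterations — is exposed as `mean_mode="retained"`,
but the all-iterations mean is the default because the per-iteration
threshold precedes averaging in the protocol, and it makes the reported
mean weight the product of effect size and retention frequency, which is
the quantity the 0.05 display cut is applied to.  Sign-stability is the
fraction of iterations in which an edge appears with the sign of its
ensemble mean; by construction it cannot exceed retention frequency.

Bidirectional pairs keep the direction with larger |mean weight|; exact
ties break lexicographically with a logged warning.  Cycle repair removes
the weakest edge *within* the detected cycle (not globally) — the minimal
perturbation reading of "remove the weakest edge" — iterating until
acyclic, which terminates because each step deletes one edge.  Cycle
detection order is fixed by sorted node iteration, so repair is
deterministic.  Reported edges must pass |mean| > 0.05 **and**
sign-stability ≥ 0.20; the display style cut (solid vs dashed) sits at
|mean| > 0.20.

Bootstrap iteration b uses a child seed derived from (root seed, b), so
runs are reproducible and iterations independent of each other.

## Outcome models

The confirmatory model is maximum-likelihood logistic regression
(statsmodels Newton iterations to gradient tolerance 1e-8; quasi-Newton
fallback when perfect separation makes the Hessian singular, with any
|coefficient| > 15 on the logit scale flagged as separation).  Wald 95%
CIs are `exp(β ± 1.96·SE)` with SEs from the observed information.

The LASSO path minimizes mean binomial deviance + λ‖β‖₁ on standardized
columns (intercept unpenalized), with a 100-point log-spaced λ grid from
the analytic full-shrinkage point λ_max = max|Xᵀ(y − ȳ)|/n down four
decades.  λ* minimizes mean cross-validated deviance over five seeded,
stratified folds; the one-standard-error rule is available as
`rule="1se"` and is what the selection-consistency checks use, because at
simulation sample sizes (n = 5,000) the min-deviance λ retains noise
terms with near-zero coefficients, as LASSO generically does.  CIs for
exponentiated coefficients are 95% bootstrap percentile intervals from
500 resamples refit at the fixed λ* — a pragmatic choice, clearly
labelled, since no standard interval exists for LASSO estimates; zeroed
terms report OR = 1 with no interval.

## Synthetic cohort

The generator emulates three things and nothing more: (a) the intake
screening cascade, engineered so the 250-record fixture reproduces the
published per-reason exclusion counts (11/15/59/5/7/10/4/4/9, 126
survivors) under first-failure attribution; (b) the published baseline
marginals — age mean 61.2 (SD 11.8), days-to-RAGT lognormal with median
42.5 and IQR [34.0, 54.8], ordinal level probabilities whose implied
median/IQR match the published table, and exact nominal counts (37/126
female, 47/126 infarction, 54/126 left-sided) via shuffled exact-count
assignment; (c) a planted causal structure: a sparse clinically-shaped
DAG over the baseline variables (motor-item chain, trunk from abdominal
strength, proprioception from tactile sensation, baseline walking score
from motor and trunk function) and a logistic outcome equation over nine
median-split parents with log-odds anchored at the published odds ratios —
trunk verticality log 7.79, joint position sense log 3.37, days-to-RAGT
log 0.19 — plus six moderate effects (ORs 1.6–2.2).  The intercept is
calibrated by root-finding on the realized linear predictor so expected
prevalence is 66/126.

Ordinal variables are produced by rank-based quantile binning of the
latent SEM draw, which preserves the planted dependence through rank
order and makes level counts deterministic (`round(n·p)`), so the
descriptive table of the n = 126 fixture reproduces its target cells
exactly rather than in expectation.  Default SEM noise is uniform on
[−√3·s, √3·s] (variance s²): bounded, strongly sub-Gaussian, and the
standard choice in LiNGAM test fixtures.  All generators derive
independent streams from one root seed via fixed CRC-32 labels, so adding
a generator never perturbs another's draws.

One deliberate deviation from the published marginals: trunk verticality
is targeted at median 2 [2, 3] rather than the published 3.0 [2.0, 3.0].
The published median sits at the 0–3 scale ceiling, so a strict
">" median split — the default here, chosen because several items
(e.g. ankle dorsiflexion, median 0.0 [0.0, 0.0]) sit at the scale floor
where "≥" degenerates to an all-1 column — would make trunk verticality
constant and unusable as the planted headline predictor.  On the real
marginals *either* split direction degenerates one of the two reported
predictors; the simulator resolves the tension by keeping trunk
verticality off the ceiling.  Both split directions remain available
(`direction=">="`), and every split is recorded per column in the coding
log.

What passing tests do **not** show about real data: the simulator matches
marginals and one planted graph, not the true joint distribution of a
clinical cohort; real data carry measurement error, informative
censoring of the screening attributes, and confounders outside the
variable roster, all absent here.  Recovery rates measured on the
simulator are therefore statements about the algorithmic pipeline under
its own assumptions, not about clinical validity.

## Numerical choices

Quartiles use linear interpolation (numpy's default, type 7).  Display
rounding is one decimal for percentages, means and SDs.  The direction
measure's entropy statistics are computed in single precision (the
pairwise residual tensor dominates runtime; the ~1e-6 absolute error is
orders of magnitude below decision margins), while residualization and
OLS stay in double precision.  Degenerate inputs fail loudly: constant
columns are rejected in the learner and flagged-and-excluded in the
coding stage; rank-deficient residual steps and collinear predecessors
raise errors naming the offending variable.  λ = 0 is accepted in the
LASSO solver and maps to an effectively unpenalized fit (it matches the
MLE on the standardized design to < 1e-4).

## Problem sizes

Structure-recovery checks use dense 5-node SEMs (unique causal order) at
n = 5,000 over 50 seeds, and 20 seeds at n = 2,000 for agreement with the
independent ICA-based estimator (FastICA unmixing, Hungarian
row-assignment, exhaustive near-triangular permutation — a different
algorithmic route to the same model, feasible for small p).  End-to-end
planted-effect recovery uses simulated cohorts of n = 5,000 with 200
bootstrap iterations across 10 seeds in the test suite, and 5 seeds with
100 iterations in the acceptance script; planted odds-ratio recovery in
the acceptance script uses one n = 20,000 cohort.  The worked example in
`analysis/` runs the full 1,000-iteration protocol at the study scale
(n = 126), where — as in any 126-patient cohort — only the strongest
planted effects are individually significant.

## Known limitations

* The LiM (mixed-data) estimator itself is out of scope; only the
  bootstrap-stability reporting criteria it shares with the main
  procedure are implemented, applied to a pluggable learner.
* The ICA cross-check is restricted to small variable counts (exhaustive
  permutation step), which is all the cross-check requires.
* Direction identification on all-binary data has no formal guarantee;
  its empirical behaviour is exactly what the end-to-end checks measure.
* LASSO CIs are bootstrap-percentile at fixed λ* and ignore selection
  uncertainty in λ; they are labelled as such and used only descriptively.
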