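# gaitcausal

Which stroke patients regain supervised walking after robot-assisted gait
training (RAGT)?  This package re-implements, as tested reusable code, a
responder-identification analysis for severely hemiplegic subacute stroke
patients trained with a single-legged gait-assistance robot: causal
discovery over clinical baseline variables with **DirectLiNGAM**,
stabilized by bootstrap aggregation, followed by confirmatory **logistic
regression** and an **L1-penalized (LASSO) logistic** robustness check.
Because the underlying patient records are not public, a synthetic-cohort
simulator with a planted causal structure stands in for the data and makes
every stage of the analysis verifiable.

## The analysis

Patients are screened through a fixed eligibility cascade (first-ever
supratentorial stroke, severe lower-limb paresis, unable to walk with
supervision, ≥ 10 training sessions, ...); each excluded record is counted
under the first criterion it fails.  The binary outcome is *walking with
supervision or better* — a Gait Ability Assessment (GAA) score ≥ 5 after
the 4-week training block.  Explanatory variables (age, sex, stroke type,
affected side, days from onset to RAGT, baseline GAA, FIM cognitive items,
SIAS motor/sensory/trunk items) are dichotomized at their sample medians.

**Structure learning.**  DirectLiNGAM assumes a linear SEM
`x = Bx + e` with mutually independent non-Gaussian noise and an acyclic
`B`.  The most exogenous variable is identified iteratively: for each
candidate pair the direction measure

```
M(x → y) = Ĥ(y) + Ĥ(r_x|y) − Ĥ(x) − Ĥ(r_y|x)
```

(Ĥ a fixed maximum-entropy approximation of differential entropy, `r_a|b`
the least-squares residual of a on b) is positive when x causes y; the
candidate minimizing `Σ_j min(0, M(i → j))²` is extracted and the
remaining variables are residualized on it.  Direct effects are then
ordinary-least-squares coefficients along the recovered order.

**Stabilization.**  The learner runs on 1,000 bootstrap resamples;
per-iteration effects with |weight| ≤ 0.05 are dropped; effects are
averaged across all iterations; where both directions of an edge survive,
the stronger one is kept; remaining cycles are repaired by deleting the
weakest edge of each detected cycle.  Edges with |mean weight| > 0.05 and
sign-stability ≥ 0.20 (fraction of resamples agreeing with the ensemble
sign) are reported.

**Confirmation.**  Parents of the outcome node enter a maximum-likelihood
logistic regression (ORs, 95% Wald CIs); a LASSO logistic path with
five-fold cross-validated penalty re-checks the selection.

## Worked example

The numbered scripts under `analysis/` run the full study on the frozen
synthetic fixtures (`data/`), writing tables to `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_screening_and_descriptives.py
python analysis/03_causal_discovery.py
python analysis/04_outcome_models.py
python analysis/05_run_pipeline.py
```

Script 02 reports `250 screened -> 126 included (124 excluded)` and a
baseline table whose nominal cells are `37 (29.4)` female, `47 (37.3)`
infarctions and `54 (42.9)` left-sided — the simulator's marginal targets.
Script 03 (1,000 bootstrap iterations on the 126-patient cohort) prints
the direct causes of `walking_with_supervision`, led by

```
days_to_ragt: mean weight -0.279
sias_trunk_verticality: mean weight +0.193
```

and script 04 fits the confirmatory model on the selected parents:

```
days_to_ragt             OR   0.10 [ 0.04,   0.29]  p=0.0000*
sias_trunk_verticality   OR   5.81 [ 2.05,  16.42]  p=0.0009*
gaa_baseline             OR   1.97 [ 0.48,   8.17]  p=0.3482
...
LASSO (lambda* = 0.04657, 6 nonzero):
  days_to_ragt             OR   0.51 [ 0.35,   0.74]
  sias_trunk_verticality   OR   1.72 [ 1.16,   2.52]
```

Read: at the 126-patient scale, a late training start sharply reduces the
odds of reaching supervised walking, preserved trunk verticality raises
them, and both survive the LASSO shrinkage — the planted signal structure
coming back out of the full pipeline.  The weaker planted effects are
recovered reliably only at larger simulated sample sizes (see
`docs/methods.md`).

Library usage in four lines:

```python
from gaitcausal.pipeline import PipelineConfig, run_pipeline
from gaitcausal.simulate import default_cohort_spec
report = run_pipeline(PipelineConfig(simulator=default_cohort_spec(5000, seed=1), seed=1))
print(report.selected_parents)
```

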