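# trialhte

Heterogeneous treatment effect (HTE) analysis for two-arm randomized
trials with binary outcomes, built around an **honest causal forest** with
the full analysis surface a trialist needs around it: doubly robust
subgroup aggregation, an omnibus heterogeneity test, a fixed-parametric
comparator, post-hoc CATE description by recursive partitioning, multiple
imputation with Rubin's-rules pooling, and a synthetic trial generator
with known potential outcomes so every stage is testable end to end.

## The problem

Prespecified one-at-a-time subgroup analyses of trials rely on fixed
parametric models and miss effect modification driven by covariate
combinations; flexible models fitted and interpreted on the same data
overfit.  The estimand here is the conditional average treatment effect

τ(x) = E[Y(1) − Y(0) | X = x]

on the risk-difference scale (negative τ = mortality benefit; reported as
the absolute risk reduction ARR = −τ × 100 percentage points).  The causal
forest estimates τ(x) nonparametrically with *honest* trees — each tree's
subsample is split so that one half chooses the recursive partition (by
maximizing the between-child variance of the estimated effect) and the
other half estimates the leaf effects, so no observation does both.
Individual estimates τ̂ᵢ are aggregated into subgroup ATEs through
augmented inverse propensity weighted (AIPW) scores

Γᵢ = τ̂ᵢ + Dᵢ(Yᵢ − m̂(xᵢ,1))/e − (1−Dᵢ)(Yᵢ − m̂(xᵢ,0))/(1−e),

whose group means are doubly robust risk differences; calibration and the
evidence for heterogeneity come from the omnibus regression of Γᵢ on the
mean and demeaned out-of-bag forest predictions (both coefficients target
1 for a well-calibrated forest).  A subgroup logistic model
`logit P(Y=1) = β₀ + β_G G + α₁ D + α₂ D·G` with recycled predictions
(G-computation) and bootstrap SEs provides the fixed-parametric
comparator, and the estimated individual effects are described post hoc by
a cp-pruned CART, honest split-sample subgroup effects, and
best-tree-from-forest summaries with explained-variation (R²) accounting.

Details, assumptions, defaults and limitations: [docs/methods.md](docs/methods.md).

## Worked example

```python
import trialhte as t
from trialhte.aggregate import aipw_scores, group_ate
from trialhte.calibration import omnibus_test

# synthetic two-arm trial emulating a critical-care population:
# tau = -0.06 for chronic hypertension, -0.02 otherwise
trial = t.generate_trial(t.SimulationConfig(n=2000, seed=7))

model = t.CausalForest.from_dataframe(
    trial, config=t.ForestConfig(num_trees=500, seed=1, min_leaf_per_arm=20))
results = model.fit()          # two-pass importance-filtered honest forest
print(results.summary())

scores = aipw_scores(results)  # doubly robust per-patient scores
overall = group_ate(scores)
hyp = (trial.chronic_hypertension == 1).to_numpy()
print("overall ARR (pp):", round(-100 * overall.estimate, 1),
      "SE", round(100 * overall.se, 1))
print("hypertensive ARR (pp):",
      round(-100 * group_ate(scores, hyp, "hyp").estimate, 1))
om = omnibus_test(scores)
```

Output:

```
Honest causal forest
========================================================
n = 2000   trees = 500   propensity = 0.500
covariates fitted: 9 of 32 (importance-filtered refit)
mean CATE (OOB): -0.0432
CATE range (OOB): [-0.1087, +0.0317]
top importances: age=0.215, icnarc_physiology=0.145, apache_ii=0.145, ...

overall ARR (pp): 4.1 SE 2.0
hypertensive ARR (pp): 7.0
non-hypertensive ARR (pp): 1.8
omnibus: ate coef 0.94 (p=0.91), het coef 0.35 (one-sided p=0.341)
```

Reading this: the forest kept 9 of 32 encoded covariates after the
mean-importance filter; the overall absolute risk reduction is 4.1
percentage points (the generator's true overall effect is ~3.8 pp); the
hypertensive subgroup shows the larger benefit, as built into the
simulation.  The omnibus ATE coefficient near 1 with a large p-value says
the mean forest prediction is well calibrated; at n = 2000 the
heterogeneity coefficient is weakly identified, so the one-sided p of 0.34
gives no firm evidence of heterogeneity — the expected behaviour for a 4 pp
effect gap at this sample size.

The same pipeline runs from the shell:

```bash
trialhte simulate --n 2000 --seed 7 --out trial.csv
trialhte report --seed 7 --num-trees 500 --out results_dir
```

writing the forest-plot table (both methods), the sorted individual-CATE
table with the headline shares, the omnibus JSON, the pruned and honest
subgroup trees, the R² comparison ladder and a run log; reruns under the
same configuration reproduce every file byte for byte.

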