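# Methods

`trialhte` estimates heterogeneous treatment effects in a two-arm randomized
trial with a binary outcome.  The estimand throughout is the conditional
average treatment effect on the risk-difference scale,

    tau(x) = E[Y(1) - Y(0) | X = x],

where Y(1), Y(0) are potential outcomes under treatment and control and X
the baseline covariates.  Negative tau means the treatment reduces
mortality; reports use the absolute risk reduction ARR = -tau x 100 in
percentage points.  Randomization makes the identification assumptions
(consistency, no interference, exchangeability) plausible, and the design
propensity e = P(D=1) is treated as known (default 0.5) rather than
estimated; an `estimate_propensity` switch exists for observational use.

## Honest causal forest

Each causal tree takes a subsample of the data and splits it into a *split
half* and an *estimate half* (the honesty device: no observation both
chooses a split and estimates an effect).  Splits are chosen greedily to
maximize the spread of the estimated treatment effect across children:

    criterion = n_L tau_L^2 + n_R tau_R^2,

where tau_c is the within-child difference in arm means on the split half
and n_c the split-half child size (the parent term is constant, so this is
the between-child variance criterion).  Candidate thresholds are the
midpoints between consecutive distinct observed values on the split half;
categorical covariates enter one-hot.  A split is admissible only if every
child keeps at least `min_leaf_per_arm` rows per arm in *both* halves.
Ties are broken toward the lowest covariate index, then the smallest
threshold, so builds are deterministic given the per-tree seed.  Leaf
effects are the estimate-half difference in arm means — exactly the
quantity an independent recomputation over that leaf's estimate rows gives,
which is how the test suite checks them.

**Local centering.**  By default (`center_outcomes=True`) the outcome is
residualized on an out-of-bag marginal-outcome regression-forest fit m(x)
before causal splitting.  In a randomized trial this leaves all treatment
contrasts unchanged in expectation while removing purely prognostic
variation, which sharpens the split criterion's signal-to-noise.  It mirrors
the orthogonalization of the generalized-random-forest estimator this
package emulates.

**Forest aggregation and OOB.**  The forest CATE is the unweighted mean of
leaf effects over trees; for training rows, out-of-bag predictions use only
trees whose subsample excluded the row.  An equivalent adaptive-neighbor
view (`forest_weights`) expresses the prediction as a weighted average over
training rows with weights that sum to one.

**Variance estimator.**  Trees are grown in groups of `ci_group_size`
(default 25) that share a random half-sample of the data; the variance of a
prediction is estimated by the between-group variance of the group mean
predictions.  For a linear statistic, the variance of a half-sample mean
over a fixed dataset equals the sampling variance of the full-sample mean
(the finite-population correction exactly offsets the halved sample size),
which motivates the construction.  The residual within-group Monte-Carlo
noise (tree-level variance divided by group size) is deliberately *not*
subtracted: with ~25 trees per bag it inflates the SE mildly (~15-30%) and
makes the intervals conservative, which measured coverage confirms
(individual 95% CIs cover true effects for 93-99% of patients in the
simulation designs, against a nominal 95%).  With very small groups the
uncorrected estimator would be far too wide; that is why the default group
size is 25 rather than pairs.  SEs require `subsample_fraction <= 0.5`
(each tree's subsample is drawn inside its group's half-sample) and are NaN
otherwise.

**Variable importance and the two-pass fit.**  Importance is a
depth-weighted split frequency: a split at depth k (root = 1) contributes
weight k^(-2), counted over the first 4 levels and normalized to sum to 1
(both the decay exponent and depth cap are documented knobs).  The fitting
procedure is two-pass: rank covariates by pass-one importance, retain those
at or above `importance_multiplier` x mean importance (default multiplier
1; ties at the threshold retained; multiplier 0 disables filtering), refit
on the retained set.  Pass-one importances are kept for audit.

**Defaults and tuning.**  `num_trees=5000`, `subsample_fraction=0.5`,
`honesty_fraction=0.5`, `min_leaf_per_arm=5`, `mtry=min(ceil(sqrt p)+20,
p)` (the generalized-random-forest convention; plain `"sqrt"` is
available).  No automatic tuning runs by default; `grid_search_forest`
optionally scores a user grid over (min_leaf_per_arm, mtry,
subsample_fraction) by the out-of-bag AIPW error, the R-loss proxy
mean[(Gamma - tau_oob)^2].  An analysis of a binary-outcome trial
benefits from larger honest leaves than the all-purpose default (the
study scripts use `min_leaf_per_arm=20`, since a leaf contrast of two
Bernoulli means needs ~20 rows per arm for its SD to fall near 0.15).

## Doubly robust aggregation (AIPW)

Per-patient scores

    Gamma_i = tau_oob(x_i) + D_i (Y_i - m(x_i,1))/e - (1-D_i)(Y_i - m(x_i,0))/(1-e)

are conditionally unbiased for tau(x_i) if either nuisance is correct.  Two
constructions of m(x,d) are provided:

* `"centered"` (default): m(x,d) = m(x) + (d - e) tau_oob(x) from the
  marginal outcome fit.  The tau_oob term then cancels algebraically,
  Gamma_i = (D_i - e)(Y_i - m(x_i))/(e(1-e)), so the score shares no
  mechanical component with the forest prediction — this keeps the omnibus
  test calibrated under a homogeneous effect (measured one-sided type-I
  ~0.05-0.07 at nominal 0.05).
* `"arm_forests"`: two arm-wise honest regression forests.  Available for
  comparison; its score correlates with the forest prediction through
  shared data and measurably inflates the omnibus type-I rate (~0.10).

Group ATEs are group means of Gamma with SE = SD(Gamma)/sqrt(n_group);
groups therefore decompose exactly (n-weighted group estimates sum to the
overall estimate).  These SEs ignore estimation error in the nuisance fits
beyond the score variance — standard AIPW practice, and a documented
limitation.

## Omnibus calibration / heterogeneity test

Regress Gamma_i without intercept on (a) the constant mean OOB prediction
tau_bar and (b) the demeaned OOB prediction tau_oob_i - tau_bar, with HC3
robust SEs.  Coefficient 1 on the first regressor means the mean forest
prediction is correct (tested two-sided against 1); coefficient 1 on the
second means the predicted heterogeneity matches the true heterogeneity,
and a one-sided test against 0 gives the evidence for any real
heterogeneity.  Constant predictions make the heterogeneity coefficient
inestimable; it is reported as such with p = 1.

## Parametric comparator

For each subgroup indicator G the logistic model
`logit P(Y=1) = b0 + bG G + a1 D + a2 D G` is fitted by maximum likelihood
(an intercept is included; the model is saturated in the (D, G) cells, and
cells with zero events or non-events raise an explicit separation error
naming the cell).  Recycled predictions evaluate each patient under all
four (d, g) combinations; the subgroup total effect is
mean[Yhat(1,1) - Yhat(0,1)] and the interaction contrast
mean[Yhat(1,1) - (Yhat(0,1) + Yhat(1,0) - Yhat(0,0))].  Uncertainty is by
case-resampling percentile bootstrap (percentile rather than BCa — simpler
and adequate at these sample sizes).  Multi-level subgroups are handled by
one-vs-rest fits per level.  An identity-link (linear probability) variant
exists mainly because its interaction contrast equals a2 exactly, a useful
algebraic check.

## Describing the estimated individual effects

* **Second-stage OLS** of tau_hat on the covariates with intercept; aliased
  columns are dropped greedily with a warning.
* **Pruned CART** on tau_hat: variance-reduction regression tree with
  cost-complexity pruning at alpha = cp x root variance, which is the
  standard recursive-partitioning cp convention (a split survives only if
  it improves relative error by more than cp; boundary equality prunes, so
  cp = 1 always collapses to the root).  Default cp = 0.2 with an optional
  search for at most 10 leaves.  Fits are unweighted by default, with an
  optional inverse-variance weighting flag; the per-patient SEs are
  otherwise ignored here.
* **Honest subgroup re-estimation**: the tree is grown on a seeded 50/50
  half; each leaf's effect is re-estimated as the AIPW group ATE of the
  held-out rows falling in it (leaves with fewer than 2 held-out rows per
  arm are flagged not-estimable, never an exception).  Training leaf means
  are kept alongside, since a single CART's in-sample leaf means are
  optimistic.
* **Best tree**: a regression forest on tau_hat with per-leaf minimum minN
  (ladder 1, 50, 100, 200); the member tree with the highest R^2 against
  the forest's aggregate predictions is returned (ties to the lowest
  index).
* **Explained variation**: R^2 = 1 - SSE/SST against the evaluation set's
  mean; out-of-sample values may be negative.

## Multiple imputation

Chained equations over incomplete covariates: linear regression with
predictive-mean matching (5 donors) for continuous variables, logistic
draws for binaries, multinomial draws for categoricals; observed-value
initialization; default m = 5 completed datasets and 10 iterations (the
conventional defaults of chained-equation software).
Treatment, outcome and truth columns are never imputed.  Estimates are
pooled with Rubin's rules (T = W + (1 + 1/m) B, df = (m-1)(1 +
W/((1+1/m)B))^2); per-patient CATEs are pooled by matching patient id.
Imputation happens once, before any bootstrap, and the bootstrap resamples
completed data — the alternative (imputing inside each replicate) is more
expensive and was not used in the emulated analysis pipeline.

## Synthetic trial generator

The default covariate specification reproduces the *marginal* distributions
of a large critical-care trial's baseline table: age truncated at 65
(pre-truncation location/scale calibrated so the observed mean is 75.2 and
SD 6.8), chronic hypertension 45.8%, septic shock 48.3%, categorical
admission source, vasopressor type, ethnicity and CPR status, generic
continuous severity scores (APACHE II, ICNARC physiology, SOFA), a
log-normal vasopressor-duration reconstructed from its median and IQR, and
a predicted risk of death simulated as a logistic function of the severity
scores (the proprietary prognostic model is not public).  Marginals are
independent by default; a Gaussian-copula `score_correlation` knob
correlates the continuous severity scores for realism studies.  The default
control-arm risk model is logistic in the severity scores, calibrated to
~43% mortality.

Potential outcomes are drawn as y0 ~ Bern(p0(x)), y1 ~ Bern(p0(x) +
tau(x)) with risks clipped to [0.001, 0.999]; clip events are counted and
the stored `true_tau` is the post-clipping risk difference, i.e. exactly
E[y1 - y0 | x].  The default treatment-effect function is a step on
chronic hypertension (tau = -0.06 if hypertensive, -0.02 otherwise);
`zero`, `constant`, `smooth` (a logistic ramp in the physiology score plus
a hypertension shift, range about [-0.11, +0.01]) and `linear` functions
are registered and selectable by name, so configurations serialize to JSON.
Quintile subgroups are formed from sample quintiles with ties assigned to
the lower quintile.

What the generator does **not** emulate: the joint covariate distribution
of a real ICU population (only marginals, optionally rank-correlated
scores), the actual severity-score formulas, informative missingness
(injection is MCAR only), or any outcome model misspecification beyond what
the logistic risk surface provides.  Passing tests therefore demonstrate
internal correctness and statistical calibration under these conditions,
not performance on real trial data.

## Study conditions and problem sizes

The simulation studies in the test suite use: parameter recovery at
n = 4000 with 1000-tree forests over 20 seeds; omnibus type-I control at
n = 1000, 200 trees, 200 replicates; CI coverage at n = 4000 with 1000
trees; CART subgroup recovery at n = 1600 over 20 seeds; null bootstrap
calibration at n = 500 with 300 bootstrap replicates over 100 simulations;
the imputation perturbation study at n = 2000 over 6 seeds.  These sizes
are the package's chosen demonstration scale — large enough for the
asymptotic approximations to be visible, small enough to run routinely.

A note on one hard limit: with ~43% mortality the sampling SE of the
difference between the two step-design subgroup effects at n = 4000 is
about 0.03 against a true gap of 0.04, so *any* estimator — including an
oracle that knows hypertension is the only modifier — mislabels the
direction of the contrast in a non-trivial fraction of datasets.  Subgroup
ATE recovery (mean absolute error ~0.02) is comfortably achievable at this
scale; near-perfect per-seed correlation between individual predictions and
the true step is not, and the corresponding test documents the measured
rate rather than hiding it.

## Known limitations

* Group SEs and honest-leaf SEs ignore nuisance-estimation error beyond
  the score variance.
* The forest variance estimator is deliberately conservative (see above);
  "share of patients with CI excluding zero" summaries are accordingly
  conservative too.
* No survival outcomes, no clustered designs, no observational-study
  propensity modelling beyond a constant estimate, no rank-weighted
  (RATE/TOC) analyses, no policy learning.
* Serial fitting only; determinism is guaranteed by per-tree seeds derived
  from a single forest seed.
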