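# Methods

This note documents the models, the synthetic study conditions, and the numerical
and design choices behind `akiphen`.

## Risk model

The AKI risk model is an additive logistic regression

    logit P(AKI = 1 | x) = beta0 + sum_b beta_b x_b + sum_s f_s(x_s)

with one linear coefficient per binary covariate and one smooth `f_s` per numeric
covariate.  Smooths use restricted (natural) cubic spline bases in the truncated-
power parameterisation: `K` knots at equally spaced quantiles give `K - 1` columns
(the covariate itself plus `K - 2` restricted cubic terms), linear beyond the
boundary knots.  Univariable screening uses 3 knots (two degrees of freedom, knots
at the 10th/50th/90th percentiles); the multivariable model uses 5 knots by default.

Fitting is penalized IRLS: each Newton step maximizes the Bernoulli log-likelihood
minus a ridge penalty `0.5 * lambda_s * ||beta_s,nonlinear||^2` on the nonlinear
columns of each smooth block, with step-halving so the penalized objective is
monotone across iterations.  Because only the nonlinear columns are penalized,
`lambda -> infinity` degenerates each smooth to a straight line (effective df -> 1).
Basis columns are standardized at fit time so the penalty — and hence the selected
smoothing — is invariant to affine rescaling of any covariate.

Smoothing parameters are selected per term by coordinate-wise generalized
cross-validation, `GCV(lambda) = n * deviance / (n - gamma * edf)^2` over a
log-spaced grid (two sweeps, warm starts), with `gamma = 1.4`: the GCV minimum is
often extremely shallow in `lambda`, and the standard df-inflation counteracts its
known tendency to undersmooth.  Effective df per term is the trace of the
corresponding block of `(X'WX + P)^{-1} X'WX`.

Per-term p-values are likelihood-ratio tests against the model refitted without the
term (other smoothing parameters held fixed), referred to a chi-square with the
term's effective df.  Backward stepwise selection repeatedly drops the least
significant non-forced term until all remaining non-forced terms have p < 0.05; the
severity score (APACHE) is always retained so the final model stays
severity-adjusted.  Complete separation in univariable screens is detected
(diverging coefficients) and the p-value recomputed under a small ridge (1e-2),
never reported silently from a divergent fit.

Evaluation: AUC by the midrank Mann-Whitney formulation with a 2000-replicate
class-stratified bootstrap CI; Hosmer-Lemeshow over 10 equal-count risk groups with
`df = 8` (the model-based convention); calibration bins of mean predicted vs
observed rates.

### Sensitivity refits

* **LOESS variant** — a local-scoring additive fit: outer IRLS loop, inner weighted
  backfitting where each smooth is a local-linear tricube smoother over a
  span-fraction neighborhood (default span 0.75).  It exposes the same
  partial-dependence contract as the spline model so the two smoothers can be
  overlaid; agreement of the curves is the sensitivity check.
* **Regularized selection** — a logistic lasso over a decreasing lambda path
  (lambda chosen by repeated-CV AUC; selected = nonzero coefficients) and a
  regularized random forest implemented as importance-gated feature entry: a
  candidate joins the selected set only when its impurity importance exceeds a
  penalty fraction `gamma = 0.3` of the best selected importance, iterated to a
  fixed point, with final importances as permutation AUC drops.  There is no
  gain-penalized tree learner in the supported dependency set, so the gate operates
  at the forest level; it preserves the defining behavior (new features must beat a
  penalty threshold to enter).

## Shapley attribution

Attributions are exact: all `2^p` coalition values are enumerated (bounded at
p <= 15) and combined with the Shapley weights `|S|! (p-|S|-1)! / p!`.  A coalition
value `v(S)` estimates `E[f(X) | X_S = x_S]` from a background sample (the full
cohort, so the base value `phi_0 = v(empty)` is the cohort-level expected risk):

* **marginal** (default): the mean prediction over background rows with the
  coalition's columns overwritten by the patient's values;
* **empirical_conditional**: the same overwritten predictions weighted by a
  Gaussian kernel (bandwidth sigma, default 0.1 on the standardized scale) on the
  distance between each background row and the patient restricted to `S`.

The full coalition is evaluated at the patient directly, so efficiency
(`phi_0 + sum_j phi_ij = f(x_i)`) holds to float precision for either value
function.  Attributions are on the probability scale by default (each AKI patient's
row sums to their predicted AKI probability); the logit scale is available via the
config.

The **marginal** value function is the default by design: with strongly correlated
covariates the conditional expectation divides credit among correlated factors,
which blurs exactly the per-patient dominant-factor signal that the downstream
clustering uses (on the default cohort, clustering quality in attribution space
drops from ARI ~0.7 to ~0 when switching to the conditional kernel).  The marginal
(interventional) expectation respects the fitted model's own additive structure.

## Clustering and validation

UMAP (delegated to `umap-learn`, treated as a black box behind the `embed`
contract) with Euclidean metric, `min_dist = 0.1`, 15 neighbors, 2 output
dimensions, and a fixed `random_state` for determinism.  DBSCAN is implemented
in-package to pin deterministic semantics: a point is core iff >= `min_pts` (=5)
points lie within `eps` (=1, in embedding units); clusters are connected components
of core points under eps-reachability; a border point joins the cluster of the
lowest-index core point within eps; everything else is noise.  Noise points are
reported but excluded from outcome comparisons.

Separability validation: per cluster, a one-vs-rest linear SVM; the cost parameter
is tuned on a stratified 80% training split by repeated cross-validation (3 repeats
x 10 folds) maximizing AUC over a log-spaced grid, and the tuned model is scored on
2000 bootstrap resamples of the held-out 20%.  (Training on the larger split and
evaluating on the held-out split is the only sensible reading of the protocol.)

Cluster profiles report per-cluster mean attribution and mean |attribution| per
factor; a cluster's *defining factor* is the feature whose cluster-mean attribution
deviates most (in absolute value) from the overall mean, and a feature's
*discriminativeness* is the across-cluster variance of its cluster means.  Note the
defining factor is relative to the cohort: a cluster can be "defined" by a factor
it lacks when other clusters express it strongly.

## Outcome scoring

**KDIGO detection** uses rolling-minimum references over half-open windows ending at
each measurement: AKI fires at the first time with a >= 1.5-fold rise over the
minimum of the preceding 7 days, or a >= 26.4 umol/L rise over the minimum of the
preceding 48 h.  **Staging** uses the peak over baseline (first value after
hospital admission): stage 1 for ratio in [1.5, 2.0) or absolute-criterion-only
episodes, stage 2 for [2.0, 3.0), stage 3 for >= 3.0 or an absolute peak
>= 353.6 umol/L; any RRT makes the episode stage 3-RRT (with a warning if the
creatinine criteria never fired).  **Recovery** is the first post-onset measurement
strictly below 1.5 x baseline with no ongoing RRT ("1.5 times below baseline" is
read as `< 1.5 x baseline`); otherwise censored at the last measurement.

**Metabolic patterns**: cohort-level thresholds are linear-interpolation quantiles
of the pooled ICU measurements (lactate median; glucose q25/q50/q75).  The five
profiles use ">= median" for "above" and "<" for "below"; the printed rule leaves
glucose in [q50, q75) under low lactate unassigned, and the package closes that gap
into the baseline profile (baseline = low lactate with glucose in [q25, q75)) so
the classification is a total partition.  Per-patient occupancy is a step function:
each measurement's profile holds until the next measurement (the last until ICU
discharge, the pre-first interval belongs to the first profile); relative times
divide by the ICU length of stay and sum to 1.

**Comparison**: with cluster as the single categorical predictor, the Naive-Bayes
posterior reduces to the (Laplace-smoothed, alpha = 0 by default) conditional
frequency `P(outcome | cluster)`; CIs are percentile intervals over 2000
patient-level bootstrap resamples (a resample missing a cluster is redrawn up to 10
times, then dropped) and pairwise p-values are two-sided percentile bootstrap
p-values on posterior differences.  Cox contrasts delegate to `lifelines` (Newton
with tightened precision 1e-10); event times in this package are continuous, so
tie-handling conventions do not bite.  The severity-mortality association fits, per
cluster, a logistic regression of death on the restricted-cubic-spline basis of the
peak/baseline creatinine ratio (suppressed below 10 patients or with a single death
class; separation handled by a small ridge refit), with an LRT against the
intercept-only model.

## Synthetic study conditions

The generator emulates a ~300-patient ICU cohort with a 40% AKI rate (the scale of
a single-centre pandemic-era cohort) and three planted phenotype groups.  Ten
covariates mimic an admission table: age, BMI, APACHE II, eGFR, FiO2, CRP
(continuous, truncated normals) and diabetes, lopinavir/ritonavir (LPV/r),
dexamethasone, mechanical ventilation (binary).  Seven carry risk on the logit
scale; effect shapes on the standardized covariate are `linear`, `u_shape`
(`z^2 - 1`) or `saturating` (logistic ramp `2 / (1 + e^{-1.5 z}) - 1`).  The
intercept is calibrated by bisection on the mean simulated probability (tolerance
1e-4) so the cohort AKI rate hits the target.

Group patterns shift covariate distributions so each group's risk is dominated by a
distinct factor: group 0 by LPV/r exposure (with diabetes as a co-marker), group 1
by low eGFR without dexamethasone, group 2 by high APACHE with low eGFR under
dexamethasone.  Three properties of the defaults matter for recoverability and were
chosen as the package's study conditions: (i) every group sits on a *plateau* of
each strong saturating driver — a group left on the steep region of a driver's
curve acquires a wide attribution spread along that axis that bridges clusters;
(ii) binary risk factors are patterned near-deterministically per group (0.9-0.99
vs 0.01-0.1), because a free mid-prevalence binary factor splits every cluster into
bimodal attribution sub-blobs; (iii) group AKI counts stay balanced so each group
retains enough AKI rows for the embedding's 15-neighbor graph.  This mirrors the
crisply separated phenotypes the analysis is designed to detect (linear-SVM
separability near 1.0).

Trajectories: baseline creatinine is loosely inverse to eGFR, bounded to
[45, 140] umol/L so benign jitter can never trip the absolute criterion.  AKI
patients get a planted stage (peak at 1.6 / 2.2 / 3.5 x baseline for stages 1/2/3)
at an onset day drawn uniformly from 1-6 days after ICU admission, then an
exponential decay that crosses the 1.5 x baseline recovery threshold near an
exponential recovery time (baseline mean 7 days from onset, scaled by the group's
hazard ratio — defaults 1.0/1.0/1.6); non-recoverers plateau at 1.55 x baseline.
RRT accompanies a stage-3 subset, ending before the recovery crossing for
recoverers.  Deaths are Bernoulli per group (defaults 0.20/0.25/0.55) with
exponential timing.  The generator re-scores every trajectory before returning and
raises if the planted stage is not reproduced, so KDIGO round-trip consistency is
an enforced invariant, not a hope.  Glucose/lactate pairs are sampled every 4 h
(configurable) from group-specific lognormal regimes, with group 2 at higher
lactate (an impaired-metabolism-leaning profile).

What the generator does **not** emulate — and hence what passing tests do not show
about real data: the joint dependence structure of real admission variables (drug
exposure decided by indication, severity correlated with everything), urine-output
data, measurement artefacts and irregular sampling, informative missingness beyond
a single-driver MAR mechanism, competing risks between death and recovery, and any
COVID-specific biology or pharmacology.  Real cohorts will also rarely present
phenotypes as crisply separated as the planted ones; the end-to-end recovery
results characterise the pipeline's behaviour when distinct risk-factor patterns
exist, not how often they exist.

## Numerical choices and degenerate inputs

* Yeo-Johnson lambda: profile log-likelihood maximized on a grid over [-3, 3]
  (step 0.05) with bounded local refinement to 1e-4; constant input is rejected.
  Binary features bypass the transform and scaling.
* Bagged imputation: 25 unlimited-depth CART trees, minimum leaf size 5, per
  feature with missingness; predictor-side missing values are median-filled; a
  feature missing in every row is an error.
* Collinearity pruning: removal only (merging is undefined); the member of the
  worst pair with the larger mean absolute correlation to the remaining features is
  dropped, iterated until no pair exceeds the threshold.
* IRLS: weights clipped at 1e-10; up to 40 step-halvings; non-convergence warns
  with diagnostics.  AUC ties get midranks.  Bootstrap resamples are stratified by
  outcome class.
* DBSCAN border ties are resolved by the lowest core index; iteration order is
  deterministic, so reruns and row permutations give the same partition (up to
  renumbering).
* Boundary conventions are explicit everywhere: KDIGO ratio fires at `>= 1.5`,
  recovery requires `< 1.5`, metabolic "above" is `>=`, dominant-profile ties go to
  the earliest-listed profile.

## Known limitations

* Exact Shapley enumeration is bounded at 15 features; no sampling approximation is
  provided (the pipeline's selected sets are small by construction).
* Smooths are univariate; no interactions or tensor-product smooths.
* The stepwise procedure inherits the usual post-selection inference caveats;
  p-values of the final model are not selection-adjusted (the regularized selectors
  are the intended robustness check).
* Planted binary co-markers of the same group (LPV/r and diabetes in group 0) are
  nearly collinear by design; selection procedures may legitimately keep either,
  and cluster profiles may name either as a cluster's defining factor.
* Single imputation only; imputation uncertainty is not propagated.
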