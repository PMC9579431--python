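# akiphen

Risk-factor sub-phenotyping of acute kidney injury (AKI) in ICU cohorts.

Intensive-care cohorts are heterogeneous: two patients can reach the same AKI stage
through entirely different causal routes (nephrotoxic drug exposure, pre-existing
renal impairment, severity of critical illness).  `akiphen` implements a three-step
analysis that phenotypes AKI patients **by the pattern of risk factors expressed at
the individual level**, rather than by clustering raw clinical variables:

1. **Risk modelling.**  A generalized additive logistic model for AKI with penalized
   restricted-cubic-spline smooths for numeric covariates,
   `logit P(AKI=1 | x) = beta0 + sum_j f_j(x_j)`,
   fitted by penalized IRLS with per-term smoothing parameters chosen by GCV.
   Candidates are screened univariably (keep if p < 0.2), then reduced by backward
   stepwise selection (keep if p < 0.05, with the APACHE severity score always
   retained).  Preprocessing: Yeo-Johnson normalisation with centring/scaling,
   bagged-tree imputation, and pruning of collinear features (|r| > 0.8).
   Discrimination and calibration are reported as AUC (stratified bootstrap CI) and
   the Hosmer-Lemeshow test; sensitivity refits (LOESS smoother, lasso and
   regularized-forest selection) validate the selected set.
2. **Attribution and clustering.**  Exact Shapley values (full coalition
   enumeration, 2^p coalition values) attribute each patient's predicted AKI
   probability to the selected factors: phi_0 + sum_j phi_ij = p_hat_i exactly.
   The AKI-restricted attribution matrix is embedded with UMAP (Euclidean metric,
   min_dist 0.1, 15 neighbors) and clustered with DBSCAN (eps = 1, min_pts = 5);
   cluster separability is validated with one-vs-rest linear SVMs on bootstrap
   resamples of a held-out split.
3. **Outcome comparison.**  Clusters are contrasted on KDIGO severity (creatinine
   criteria: >= 1.5-fold rise within 7 days or > 26.4 umol/L rise within 48 h;
   stages at 1.5/2.0/3.0-fold or 353.6 umol/L, stage 3 split by renal replacement
   therapy), renal recovery (creatinine below 1.5 x baseline off RRT), five-state
   lactate/glucose metabolic patterns, and hospital mortality — via Naive-Bayes
   posteriors with bootstrap inference and Cox proportional-hazards models.

Because patient-level ICU data cannot be redistributed, the package ships a
**synthetic cohort generator** (`akiphen.synthetic`) that plants phenotype groups,
an additive nonlinear risk mechanism, KDIGO-consistent creatinine trajectories,
metabolic regimes and group-specific outcome hazards — with full ground truth, so
every step of the pipeline is testable end to end.

## Worked example

```bash
python examples/attribution_clustering.py
```

```
attribution matrix: 117 AKI patients x 7 factors, base value 0.390
max efficiency deficit 5.6e-16 (rows sum exactly to predicted probabilities)

DBSCAN found 4 clusters (0 noise points); adjusted Rand index vs planted groups: 0.75
cluster 0: defining factor 'apache', top-3 ['apache', 'dexamethasone', 'diabetes']
cluster 1: defining factor 'diabetes', top-3 ['diabetes', 'egfr', 'dexamethasone']
cluster 2: defining factor 'dexamethasone', top-3 ['dexamethasone', 'apache', 'diabetes']
cluster 3: defining factor 'diabetes', top-3 ['diabetes', 'dexamethasone', 'egfr']
cluster 0: one-vs-rest linear SVM bootstrap AUC 1.000 +/- 0.000
```

The base value 0.390 is the cohort-level expected AKI risk; each patient's
attribution row sums (with the base value) to their predicted probability.  The
adjusted Rand index of 0.75 says the density clusters recover the planted phenotype
groups well, and the defining factors name which risk factor dominates each cluster
(here severity, diabetes/drug exposure, and dexamethasone use — `diabetes` and
`lpv_r` are planted as near-interchangeable markers of the same group, so either
may be named).  SVM bootstrap AUC of 1.000 +/- 0.000 means the cluster is linearly
separable from the rest of the embedding.

Other entry points: `examples/generate_cohort.py` (the generator and its ground
truth), `examples/fit_risk_model.py` (screening, stepwise selection, calibration),
`examples/outcome_comparison.py` (KDIGO scoring, metabolic patterns, posteriors,
Cox), `examples/run_full_pipeline.py` (one-call orchestration with a reproducible
run directory).

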