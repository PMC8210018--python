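# Methods

## Model and procedure

The package identifies prognostic expression signatures by combining an L1
(LASSO) penalized Cox proportional-hazards regression with an
attribute-wise bootstrap, then validates signatures with standard survival
analysis. All Cox likelihoods use the Breslow tie convention; synthetic
survival times are continuous, so ties only arise in user data, where the
difference from Efron handling is negligible at expression-cohort tie
densities.

### Stage I: bootstrap regression

1. **Viability.** A cohort needs ≥ 10 samples (each per-group fit runs a
   10-fold cross-validation, so folds must stay populated). With < 20
   features the bootstrap is pointless and a single penalized regression
   over all features is run instead. Cohorts whose endpoint barely varies
   (fewer than 2 events or 2 censored samples, configurable) are rejected.
2. **Variance filter.** Features with sample variance below a cutoff
   (default 0.01 on the analysis scale; boundary retained) are removed.
   Low-variance expression carries little prognostic contrast and
   destabilizes penalized fits.
3. **Proportional-hazards screen.** Each remaining feature is fitted in a
   univariate Cox model and its scaled Schoenfeld residuals are tested for
   correlation with Kaplan–Meier-transformed time (the transform is
   configurable: identity/rank/log). Features with test p < α (default
   0.05) violate the PH assumption the downstream model relies on and are
   removed. For a univariate model the per-covariate and global tests
   coincide, so the per-covariate test is used. Features whose Cox fit
   fails numerically are removed with a warning rather than aborting a
   thousand-feature screen. No multiplicity correction is applied — the
   screen is a per-feature model check, not an inference.
4. **Bootstrap.** B iterations; iteration *i* draws G distinct features
   uniformly without replacement using an independent counter-derived RNG
   stream (master seed, iteration index), so runs are reproducible and
   parallelizable. If more than a fraction P (default 0.3) of the C(G,2)
   feature pairs are correlated (|Spearman ρ| > 0.8 with p < 0.05,
   precomputed once), the whole group is redrawn, up to 100 times;
   redrawing the group rather than swapping members preserves the uniform
   marginal inclusion probability. Selection counts are therefore
   Binomial(B, G/N) with mean f = B·G/N; the default B = ⌈(N/G)²⌉ targets
   a coverage of N/G appearances per feature.
5. **Per-group fit.** Features are standardized (zero mean, unit variance)
   before penalization — the L1 penalty is scale sensitive and expression
   features differ by orders of magnitude — and coefficients are mapped
   back to the expression scale. The λ grid is the glmnet-style geometric
   path (50 points down to 10⁻³·λ_max, where λ_max is the smallest
   all-zero penalty), computed by scikit-survival's coxnet. λ is chosen by
   maximizing the Verweij–van Houwelingen cross-validated partial
   log-likelihood, Σ_k [pl(β̂_{−k}; all) − pl(β̂_{−k}; train_k)], over
   10 folds stratified by event status (plain random folds can leave a
   fold without events at realistic censoring); ties prefer the stronger
   penalty. A ridge (L2) variant exists purely as a shrinkage-profile
   comparison mode; its path is a warm-started Newton–Raphson over the
   same grid.
6. **Aggregation.** A feature's signature coefficient is the mean of its
   fitted coefficients over the iterations in which it was sampled,
   zero-shrunk values included; `times_sampled` and `times_nonzero` are
   recorded. Including zeros penalizes features that only survive in
   favorable random contexts and reproduces the characteristic
   zero-massed coefficient histogram of L1 fits. Features never sampled
   are absent. Feature order is canonicalized (sorted) before sampling,
   so permuting input columns cannot change the result.

### Stage II: survival validation

The risk score is the linear combination Σ C·E over signature features.
Stratification is at the score median by default (scores ≤ cutoff are
"low" — a deterministic tie rule), or at the cut-point maximizing Youden's
J = sensitivity + specificity − 1 for classifying ever-event status on an
ROC curve smoothed with a nearest-neighbour (logistic) kernel of bandwidth
sd(score)·n^(−1/5); an exact empirical-ROC mode exists (and is what the
threshold-scan oracle tests exercise). Ever-event status is used as the ROC
outcome because no horizon is singled out; a fixed-horizon variant would
only change the outcome column. Group prognosis is compared with the
unweighted (Mantel–Haenszel) log-rank test, Kaplan–Meier curves with
at-risk counts (median survival = smallest time with S(t) ≤ 0.5, undefined
if never reached), and a Cox hazard ratio with Wald 95% CI. The HR is
reported for the low-score group (HR < 1 ⇔ high scores are deleterious);
an `exposed="high"` flag inverts the convention. A Schoenfeld check of the
continuous score warns — but does not stop the analysis — when the score
violates proportional hazards.

With clinical covariates, each covariate is screened in its own univariate
Cox model (categoricals dummy-coded against their most frequent level,
which keeps the reference stable across bootstrap resamples; complete
cases per covariate); covariates with Wald p below a lenient threshold
(default 0.2) join the score group indicator in the multivariate model.
The score never passes through the screen — it is the quantity under
evaluation. The patient-oriented bootstrap resamples patients with
replacement each cycle, removes rows with missing covariate cells, and
uses the cycle only if (i) the remaining rows still cover ≥ 70% of the
original cohort size, and (ii) at least 2 covariates are eligible, where a
categorical covariate is eligible only if its minority category holds
≥ 20% of the cycle's rows. A covariate counts as *relevant* in a cycle
when its multivariate term p < 0.05 — the only p-based reading consistent
with a per-cycle relevance tally. The relevance frequency is
relevant/eligible cycles, and covariates at ≥ 25% make the plot list. Note
the 70% rule counts retained rows, not distinct patients: a
with-replacement resample contains only ~63.2% distinct patients in
expectation, so a distinct-patient reading would void every cycle; the
rule exists to guard against null-removal erosion. Per-cycle
proportional-hazards vetting is limited to the score-level Schoenfeld
warning; cycles are not excluded on PH grounds.

## Synthetic cohorts

`survsig.simulate` generates ground-truth cohorts used by every test:

* **Expression**: log-normal (default median 10, log-sd 1 — a TPM-like
  scale), from standard-normal latents; collinear blocks share a latent
  factor with the Pearson level chosen to achieve the target Spearman ρ
  (r = 2·sin(πρ/6)); planted low-variance features are near-constant
  (1 + 0.01·z).
* **Survival**: Weibull proportional hazards, shape 1.2 and scale 800 days
  (cancer-cohort follow-up scales, median OS in the hundreds of days),
  with linear predictor Σ β_f·z_f over *standardized expression values* —
  the covariates the downstream Cox models actually fit, so planted
  log-hazard coefficients are on the model's own scale and tests measure
  the pipeline rather than an unstated transform mismatch.
* **Censoring**: administrative-uniform C ~ U(0, c_max) with c_max solved
  on the drawn sample (bisection) so the realized censoring fraction
  matches the target.
* **Clinical covariates**: balanced and imbalanced categoricals, numeric
  age, an optional confounder correlated with the true linear predictor,
  and missing-completely-at-random cells.

What the generator does *not* emulate: RNA-seq count noise, library-size
or batch effects, isoform structure, non-PH hazards, informative
censoring, or correlated clinical covariates. Passing tests therefore
demonstrate the statistical machinery under the model's own assumptions,
not robustness to the full messiness of real cohorts.

## Numerical choices and edge cases

* Sample joins are inner, with dropped identifiers logged; joined tables
  are sorted by sample id so input row order can never leak into results.
* Constant columns inside a sampled group get coefficient 0 (guarded
  standardization) instead of NaN.
* Iterations whose penalized fit fails to converge are skipped with a
  warning; a run where *every* iteration fails is an error.
* `lam=0` requests the unpenalized fit (in-package Newton–Raphson,
  gradient tolerance 1e-9); lifelines fits use `precision=1e-9` so results
  agree with independent partial-likelihood maximizers to ≤ 1e-6.
* Groups with no events in one stratum make the group HR non-estimable
  (monotone likelihood); this is reported, not guessed.
* Rendering failures never corrupt numeric output: every plot's TSV twin
  is written first, and images are best-effort.

## Problem sizes in the standard runs

The test suite and `scripts/acceptance.py` size their simulations to
single-CPU desk scale: sampling-law checks at N=500, G=10, B=2500;
shrinkage contrast on one n=150 / 50-feature cohort at B=200 (tests) or
B=100 (script); planted-feature recovery at n=150 with 200 features,
5 effects of |β|=0.8, 30% censoring, B=400, G=10 (20 seeded runs in the
test suite, 8 in the script); screen calibrations over 200–500 null
simulations and log-rank level over 500–1000.

## Known limitations

* With several strong effects active at once, each feature's *marginal*
  association is attenuated by the unobserved remainder of the linear
  predictor (omitted-covariate attenuation). Since a G-of-N group fit is
  near-marginal when G ≪ N, ranking by aggregated coefficient inherits
  that ceiling: in the recovery setting above, roughly a quarter of
  cohorts place the weakest planted feature outside the top 10 no matter
  how many iterations are run. A single full-dimension CV LASSO — full
  conditioning — recovers more, at the cost of the stability the bootstrap
  exists to provide. The recovery acceptance test documents this gap and
  intentionally does not relax its threshold.
* The per-cycle relevance indicators of the covariate bootstrap are
  strongly correlated across cycles (they resample one cohort), so a null
  covariate lands on the plot list whenever its full-data Wald |z| happens
  to sit near the threshold — about 20% of null cohorts, not 5%.
* The Youden cut-point uses ever-event status; with heavy administrative
  censoring a time-dependent ROC would be preferable and is not
  implemented.
* No imputation, no interaction terms, no competing risks, no
  time-dependent covariates. Alternative endpoints (DSS/PFI/DFI) are just
  different time/status column choices.
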