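# survsig

Prognostic gene and transcript signatures from high-dimensional expression
cohorts, via bootstrap-resampled LASSO Cox regression — plus the survival
machinery to validate the signatures it finds.

## Who this is for

Researchers with an expression matrix (TPM/FPKM-scale genes or splicing
isoforms), follow-up times and event statuses, who want a small, stable set
of features whose combined risk score separates good- from poor-prognosis
patients — and who then need the standard survival toolkit (Kaplan–Meier
curves, log-rank tests, hazard ratios, multivariate Cox adjustment for
clinical covariates) to judge that signature.

## The method

A single penalized Cox regression over thousands of collinear, low-variance
expression features converges poorly and picks unstable feature sets. The
pipeline instead works in two stages.

**Stage I — signature identification.** After gatekeeping filters (at least
10 samples and, for bootstrap mode, at least 20 features; both endpoint
statuses represented; a variance filter; a univariate Schoenfeld
proportional-hazards screen per feature), the regression runs *B* bootstrap
iterations. Each iteration draws *G* of the *N* features uniformly at
random, redraws the group while more than a fraction *P* of its pairs are
Spearman-correlated (|ρ| > 0.8, p < 0.05), and fits an L1-penalized Cox
model on the group, choosing the penalty weight λ by 10-fold
cross-validated partial log-likelihood. Each feature's number of
appearances follows Binomial(B, G/N), with expectation

    f = B·G / N

so choosing a target coverage of f = N/G gives the default iteration count

    B = (N/G)²

The signature coefficient of a feature is the mean of its fitted
coefficients over the iterations in which it was sampled (zero-shrunk fits
included) — features that never hold up across random contexts are pulled
toward zero.

**Stage II — survival validation.** Each sample receives the risk score

    score = Σ_f C_f · E_f

(C = signature coefficient, E = expression value). The cohort is split
into low/high score groups at the score median (or at the Youden-optimal
cut-point of an NNE-smoothed ROC curve of score vs event status), and the
groups are compared by log-rank test, Kaplan–Meier curves and a Cox hazard
ratio — reported for the low-score group, so HR < 1 means high scores
carry worse prognosis. A Schoenfeld test checks that the score itself
respects proportional hazards. With clinical covariates, univariately
screened covariates join the score in a multivariate Cox model, and an
optional patient-oriented bootstrap (100 cycles, with null-removal, 70%
retention, ≥2-covariable and 20%-minority-category eligibility rules)
estimates each covariate's relevance frequency; covariates at ≥25% are
plotted.

## Worked example

Simulate a cohort with 3 planted prognostic features among 40, then run
both stages:

```sh
survsig simulate --n-samples 120 --n-features 40 --n-true 3 \
    --censoring 0.3 --seed 11 -O toy
survsig complete -E toy.expression.tsv -S toy.survival.tsv \
    -G 8 -B 100 --seed 2 -O run
```

which prints

```
features in: 40
removed (low variance): 0
removed (proportional-hazards screen): 2
features out: 38
cohort: ok 120 samples, 40 features
signature: 38 features -> run.signature.tsv
cutoff_method   cutoff  n_low  n_high  median_survival_low  median_survival_high  hazard_ratio_low_vs_high  hr_ci_low  hr_ci_high         hr_p  logrank_stat    logrank_p schoenfeld_status  schoenfeld_p
       median 0.581226     60      60          1149.819531            257.945905                  0.189606   0.115687    0.310756 4.211566e-11     52.379483 4.574787e-13                ok      0.544559
```

Reading the output: the three planted features head the signature
(`run.signature.tsv` starts with G0002, G0000, G0001 — each sampled in
22–29 of the 100 iterations and non-zero every time); the median-split
high-score group has a median overall survival of 258 days against 1150
days for the low group; the hazard ratio of the low-score group is 0.19
(95% CI 0.12–0.31), i.e. high scores mean roughly five-fold higher hazard,
and the log-rank test confirms the separation (p ≈ 5e-13). The run also
writes a lollipop plot of the top-10 coefficients, a coefficient histogram,
a Schoenfeld diagnostic and a Kaplan–Meier plot, each with a TSV twin
carrying the exact plotted numbers.

The same analyses are available as library functions
(`survsig.run_regression`, `survsig.run_survival`, `survsig.run_complete`,
and the individual operations they compose).

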