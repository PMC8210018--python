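import numpy as np
import pandas as pd
import pytest

from survsig import (SurvivalTable, bootstrap_covariable_frequency,
                     fit_multivariate_cox, stratify, univariate_hr,
                     univariate_screen)
from survsig.simulate import SyntheticSpec, generate_clinical, generate_cohort

from oracles import cox_fit_bruteforce


def make_cohort(n=200, seed=0, censoring=0.3, n_true=2, beta=0.8):
    spec = SyntheticSpec.with_planted(n_samples=n, n_features=6, n_true=n_true,
                                      beta=beta, censoring_fraction=censoring,
                                      seed=seed)
    return generate_cohort(spec)


def score_table_from(surv, eta, seed=0):
    """Median-stratified score table from a given linear predictor."""
    scores = pd.Series(eta, index=surv.sample_ids, name="score")
    return stratify(scores, method="median")


class TestUnivariateScreen:
    def test_constant_covariate_dropped(self):
        _, surv, _ = make_cohort(seed=1)
        cov = pd.DataFrame({"flat": ["x"] * surv.n_samples},
                           index=surv.sample_ids)
        res = univariate_screen(surv, cov)
        assert res.dropped == ["flat"] and res.kept == []

    def test_strong_driver_always_kept(self):
        kept = 0
        for k in range(20):
            _, surv, truth = make_cohort(seed=200 + k, n_true=2, beta=1.0)
            eta = truth["eta"].loc[surv.sample_ids]
            cov = pd.DataFrame({"driver": eta,
                                "noise": np.random.default_rng(k).normal(
                                    size=surv.n_samples)},
                               index=surv.sample_ids)
            res = univariate_screen(surv, cov, threshold=0.2)
            kept += "driver" in res.kept
        assert kept == 20

    def test_null_keep_rate_tracks_threshold(self):
        threshold, n_sims, kept = 0.2, 200, 0
        for k in range(n_sims):
            rng = np.random.default_rng(4000 + k)
            _, surv, _ = make_cohort(n=300, seed=4000 + k, n_true=0)
            cov = pd.DataFrame({"noise": rng.normal(size=surv.n_samples)},
                               index=surv.sample_ids)
            kept += "noise" in univariate_screen(surv, cov,
                                                 threshold=threshold).kept
        rate = kept / n_sims
        se = np.sqrt(threshold * (1 - threshold) / n_sims)
        assert abs(rate - threshold) < 3 * se + 0.02


class TestMultivariateCox:
    def test_score_alone_reduces_to_univariate_hr(self):
        _, surv, truth = make_cohort(seed=7)
        st = score_table_from(surv, truth["eta"])
        multi = fit_multivariate_cox(surv, None, st)
        uni = univariate_hr(st, surv)
        row = multi.terms.iloc[0]
        assert row["hr"] == pytest.approx(uni.hr, rel=1e-8)
        assert row["ci_low"] == pytest.approx(uni.ci_low, rel=1e-6)

    def test_coefficients_match_bruteforce_partial_likelihood(self):
        rng = np.random.default_rng(11)
        _, surv, truth = make_cohort(n=60, seed=11)
        st = score_table_from(surv, truth["eta"])
        cov = pd.DataFrame({
            "age": rng.normal(60, 8, size=surv.n_samples),
            "marker": rng.lognormal(size=surv.n_samples),
        }, index=surv.sample_ids)
        multi = fit_multivariate_cox(surv, cov, st)
        X = np.column_stack([
            (st.groups == "low").astype(float).to_numpy(),
            cov["age"].to_numpy(), cov["marker"].to_numpy(),
        ])
        beta = cox_fit_bruteforce(X, surv.time.to_numpy(),
                                  surv.status.to_numpy().astype(bool))
        got = np.log(multi.terms[~multi.terms["reference"]]["hr"].to_numpy())
        np.testing.assert_allclose(got, beta, atol=1e-5)

    def test_reference_level_has_unit_hr(self):
        _, surv, truth = make_cohort(seed=13)
        st = score_table_from(surv, truth["eta"])
        clin = generate_clinical(surv, seed=13)
        multi = fit_multivariate_cox(surv, clin[["sex"]], st)
        ref = multi.terms[multi.terms["reference"]]
        assert len(ref) == 1 and ref.iloc[0]["hr"] == 1.0

    def test_confounder_attenuates_score_effect(self):
        """Adjusting for a confounder correlated with the truth pulls the
        score HR toward the null and recovers the confounder's own effect."""
        spec = SyntheticSpec.with_planted(n_samples=500, n_features=6, n_true=2,
                                          beta=0.8, censoring_fraction=0.2,
                                          seed=21)
        _, surv, truth = generate_cohort(spec)
        clin = generate_clinical(surv, eta=truth["eta"], seed=21,
                                 confounder_rho=0.7)
        st = score_table_from(surv, truth["eta"])
        uni = univariate_hr(st, surv)
        multi = fit_multivariate_cox(surv, clin[["confounder"]], st)
        score_hr = multi.terms.iloc[0]["hr"]
        assert abs(np.log(score_hr)) < abs(np.log(uni.hr))
        conf = multi.terms[multi.terms["covariate"] == "confounder"].iloc[0]
        assert conf["p"] < 0.05


class TestCovariableBootstrap:
    def test_identity_resample_reduces_to_single_fit(self):
        _, surv, truth = make_cohort(seed=31)
        st = score_table_from(surv, truth["eta"])
        rng = np.random.default_rng(31)
        cov = pd.DataFrame({
            "driver": truth["eta"].loc[surv.sample_ids] + rng.normal(
                scale=0.3, size=surv.n_samples),
            "noise": rng.normal(size=surv.n_samples),
        }, index=surv.sample_ids)
        freq = bootstrap_covariable_frequency(surv, cov, st, cycles=1,
                                              resample=False, seed=0)
        multi = fit_multivariate_cox(surv, cov, st)
        for name in cov.columns:
            assert freq.frequency[name] == float(multi.term_p(name) < 0.05)

    def test_rare_minority_category_excluded(self):
        _, surv, truth = make_cohort(n=300, seed=37)
        st = score_table_from(surv, truth["eta"])
        clin = generate_clinical(surv, seed=37, minority_fraction=0.10)
        freq = bootstrap_covariable_frequency(
            surv, clin[["sex", "rare_group", "age"]], st, cycles=20, seed=5)
        assert "rare_group" not in freq.eligible
        assert "rare_group" not in freq.frequency

    def test_planted_strong_covariate_is_relevant(self):
        _, surv, truth = make_cohort(n=400, seed=41, beta=1.0)
        rng = np.random.default_rng(41)
        st = score_table_from(surv, truth["eta"])
        # balanced binary covariate that is itself a strong hazard driver:
        # use the sign of a noisy copy of the linear predictor
        noisy = truth["eta"].loc[surv.sample_ids] + rng.normal(
            size=surv.n_samples)
        cov = pd.DataFrame({
            "strong": np.where(noisy > noisy.median(), "yes", "no"),
            "noise": rng.normal(size=surv.n_samples),
        }, index=surv.sample_ids)
        freq = bootstrap_covariable_frequency(surv, cov, st, cycles=100, seed=3)
        assert freq.frequency["strong"] >= 0.9
        assert "strong" in freq.plotted

    def test_pure_noise_covariate_usually_not_plotted(self):
        """Null covariates mostly stay under the 25% plotting threshold.

        Cycles resample the same cohort, so per-cycle relevance is highly
        correlated: a null covariate whose full-data Wald z happens to land
        near the threshold keeps a high frequency in every cycle.  The
        theoretical not-plotted rate under the null is ~0.8, not 1 - alpha.
        """
        not_plotted = 0
        reps = 10
        for k in range(reps):
            _, surv, truth = make_cohort(n=250, seed=600 + k)
            rng = np.random.default_rng(600 + k)
            st = score_table_from(surv, truth["eta"])
            cov = pd.DataFrame({
                "noise": rng.normal(size=surv.n_samples),
                "noise2": np.where(rng.uniform(size=surv.n_samples) < 0.5,
                                   "a", "b"),
            }, index=surv.sample_ids)
            freq = bootstrap_covariable_frequency(surv, cov, st, cycles=30,
                                                  seed=k)
            not_plotted += "noise" not in freq.plotted
        assert not_plotted >= 6

    def test_missingness_can_break_retention_rule(self):
        """Heavy missingness leaves <70% of patients and voids every cycle."""
        _, surv, truth = make_cohort(n=100, seed=51)
        st = score_table_from(surv, truth["eta"])
        clin = generate_clinical(surv, seed=51, missing_fraction=0.4)
        with pytest.raises(RuntimeError, match="no bootstrap cycle"):
            bootstrap_covariable_frequency(surv, clin[["sex", "age"]], st,
                                           cycles=10, seed=1)

    def test_frequencies_bounded_and_reproducible(self):
        _, surv, truth = make_cohort(seed=61)
        rng = np.random.default_rng(61)
        st = score_table_from(surv, truth["eta"])
        cov = pd.DataFrame({
            "a": rng.normal(size=surv.n_samples),
            "b": np.where(rng.uniform(size=surv.n_samples) < 0.5, "x", "y"),
        }, index=surv.sample_ids)
        f1 = bootstrap_covariable_frequency(surv, cov, st, cycles=20, seed=9)
        f2 = bootstrap_covariable_frequency(surv, cov, st, cycles=20, seed=9)
        assert f1.frequency == f2.frequency
        assert all(0 <= v <= 1 for v in f1.frequency.values())
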