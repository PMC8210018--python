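import numpy as np
import pandas as pd
import pytest

from survsig import (ExpressionMatrix, Signature, SurvivalTable,
                     analyze_survival, compute_risk_score, km_estimate,
                     logrank_test, score_schoenfeld_check, stratify,
                     univariate_hr)
from survsig.simulate import SyntheticSpec, generate_cohort

from oracles import (cox_fit_bruteforce, km_bruteforce, logrank_bruteforce,
                     youden_best_cutoff)


def surv_from(times, status):
    idx = [f"s{i}" for i in range(len(times))]
    return SurvivalTable(pd.Series(np.asarray(times, float), index=idx, name="time"),
                         pd.Series(np.asarray(status, float), index=idx, name="status"))


class TestRiskScore:
    def test_zero_coefficients_give_zero_scores(self, tiny_cohort):
        expr, _ = tiny_cohort
        sig = Signature.from_items([(f, 0.0) for f in expr.feature_ids])
        assert (compute_risk_score(expr, sig) == 0).all()

    def test_single_feature_product(self):
        expr = ExpressionMatrix(pd.DataFrame({"g": [3.0]}, index=["s1"]))
        sig = Signature.from_items([("g", 2.0)])
        assert compute_risk_score(expr, sig).iloc[0] == 6.0

    def test_matches_bruteforce_dot_product(self, tiny_cohort, rng):
        expr, _ = tiny_cohort
        coefs = rng.normal(size=3)
        sig = Signature.from_items(list(zip(expr.feature_ids, coefs)))
        scores = compute_risk_score(expr, sig)
        for s in expr.sample_ids:
            brute = sum(float(expr.data.loc[s, f]) * c
                        for f, c in zip(expr.feature_ids, coefs))
            assert scores[s] == pytest.approx(brute, abs=1e-12)

    def test_linearity_in_coefficients(self, tiny_cohort):
        expr, _ = tiny_cohort
        sig1 = Signature.from_items([(f, 0.3) for f in expr.feature_ids])
        sig2 = Signature.from_items([(f, 0.9) for f in expr.feature_ids])
        np.testing.assert_allclose(3 * compute_risk_score(expr, sig1),
                                   compute_risk_score(expr, sig2), rtol=1e-12)

    def test_missing_feature_listed(self, tiny_cohort):
        expr, _ = tiny_cohort
        sig = Signature.from_items([("absent_gene", 1.0)])
        with pytest.raises(KeyError, match="absent_gene"):
            compute_risk_score(expr, sig)


class TestStratify:
    def test_median_split_low_is_at_or_below(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        st = stratify(scores, method="median")
        assert st.sample_ids("low") == ["a", "b"]
        assert st.sample_ids("high") == ["c", "d"]
        assert st.cutoff == 2.5

    def test_perfect_separation_youden_is_one(self):
        scores = pd.Series([1.0, 2.0, 3.0, 10.0, 11.0, 12.0],
                           index=[f"s{i}" for i in range(6)])
        surv = surv_from([50, 60, 70, 20, 25, 30], [0, 0, 0, 1, 1, 1])
        st = stratify(scores, method="roc-youden", surv=surv, smoothing="none")
        assert st.roc["j"].max() == pytest.approx(1.0)
        assert 3.0 < st.cutoff < 10.0

    def test_exact_youden_matches_exhaustive_scan(self, rng):
        n = 60
        scores = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        status = (rng.uniform(size=n) < 0.5).astype(float)
        status[:2] = [0, 1]  # both classes present
        surv = surv_from(rng.uniform(10, 100, size=n), status)
        st = stratify(scores, method="roc-youden", surv=surv, smoothing="none")
        c_oracle, j_oracle = youden_best_cutoff(scores, status)
        got_j = st.roc["j"].max()
        assert got_j == pytest.approx(j_oracle, abs=1e-12)
        assert st.cutoff == pytest.approx(c_oracle, abs=1e-12)

    def test_identical_scores_rejected(self):
        scores = pd.Series([1.0] * 5, index=[f"s{i}" for i in range(5)])
        with pytest.raises(ValueError, match="identical"):
            stratify(scores)


class TestScoreSchoenfeld:
    def test_null_warn_rate_near_alpha(self):
        alpha, n_sims, warns = 0.05, 200, 0
        for k in range(n_sims):
            rng = np.random.default_rng(5000 + k)
            n = 200
            surv = surv_from(rng.exponential(500, size=n),
                             (rng.uniform(size=n) < 0.7).astype(float))
            scores = pd.Series(rng.normal(size=n), index=surv.sample_ids)
            warns += not score_schoenfeld_check(scores, surv, alpha=alpha).ok
        rate = warns / n_sims
        se = np.sqrt(alpha * (1 - alpha) / n_sims)
        assert abs(rate - alpha) < 3 * se + 0.01

    def test_time_decaying_effect_warns(self):
        hits = 0
        n_sims = 20
        for k in range(n_sims):
            rng = np.random.default_rng(6000 + k)
            n = 300
            x = rng.standard_normal(n)
            t1 = rng.exponential(1.0 / np.exp(1.5 * x))
            time = np.where(t1 < 0.8, t1,
                            0.8 + rng.exponential(1.0 / np.exp(-1.5 * x)))
            surv = surv_from(time * 100 + 1e-3, np.ones(n))
            scores = pd.Series(x, index=surv.sample_ids)
            hits += not score_schoenfeld_check(scores, surv).ok
        assert hits / n_sims >= 0.8

    def test_constant_score_takes_warning_path(self):
        surv = surv_from([10, 20, 30, 40], [1, 0, 1, 0])
        scores = pd.Series([1.0, 1.0, 1.0, 1.0], index=surv.sample_ids)
        check = score_schoenfeld_check(scores, surv)
        assert not check.ok and check.p is None


class TestLogrank:
    def _table(self, groups):
        idx = [f"s{i}" for i in range(len(groups))]
        from survsig.scoring import ScoreTable
        return ScoreTable(
            table=pd.DataFrame({"score": np.arange(len(groups), dtype=float),
                                "group": groups}, index=idx),
            cutoff=0.0, cutoff_method="median")

    def test_identical_groups_statistic_zero(self):
        surv = surv_from([10, 20, 30, 10, 20, 30], [1, 0, 1, 1, 0, 1])
        st = self._table(["low"] * 3 + ["high"] * 3)
        stat, p = logrank_test(st, surv)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_toy_matches_hand_arithmetic(self):
        surv = surv_from([1, 3, 5, 2, 4, 6], [1, 1, 1, 1, 1, 1])
        st = self._table(["low"] * 3 + ["high"] * 3)
        stat, _ = logrank_test(st, surv)
        oracle = logrank_bruteforce([1, 3, 5], [1, 1, 1], [2, 4, 6], [1, 1, 1])
        assert stat == pytest.approx(oracle, abs=1e-10)

    def test_random_fixture_matches_bruteforce(self, rng):
        n = 30
        times = rng.uniform(1, 100, size=n)
        status = (rng.uniform(size=n) < 0.7).astype(int)
        groups = np.where(rng.uniform(size=n) < 0.5, "low", "high")
        groups[:2] = ["low", "high"]
        surv = surv_from(times, status)
        st = self._table(list(groups))
        stat, _ = logrank_test(st, surv)
        lo = groups == "low"
        oracle = logrank_bruteforce(times[lo], status[lo],
                                    times[~lo], status[~lo])
        assert stat == pytest.approx(oracle, abs=1e-10)

    def test_relabeling_invariance(self, rng):
        times = rng.uniform(1, 100, size=20)
        status = (rng.uniform(size=20) < 0.7).astype(int)
        groups = ["low"] * 10 + ["high"] * 10
        surv = surv_from(times, status)
        s1, _ = logrank_test(self._table(groups), surv)
        flipped = ["high" if g == "low" else "low" for g in groups]
        s2, _ = logrank_test(self._table(flipped), surv)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_null_type_one_error(self):
        rejections = 0
        n_sims = 500
        for k in range(n_sims):
            rng = np.random.default_rng(3000 + k)
            n = 100
            times = rng.exponential(100, size=n)
            status = (rng.uniform(size=n) < 0.7).astype(int)
            groups = np.array(["low"] * 50 + ["high"] * 50)
            rng.shuffle(groups)
            surv = surv_from(times, status)
            _, p = logrank_test(self._table(list(groups)), surv)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_sims <= 0.07


class TestKaplanMeier:
    def test_closed_form_three_events(self):
        km = km_estimate(pd.Series([1.0, 2.0, 3.0]), pd.Series([1, 1, 1]))
        np.testing.assert_allclose(km.survival[-3:], [2 / 3, 1 / 3, 0.0],
                                   atol=1e-12)
        assert km.median == 2.0

    def test_all_censored_flat_curve_no_median(self):
        km = km_estimate(pd.Series([5.0, 10.0, 15.0]), pd.Series([0, 0, 0]))
        assert np.all(km.survival == 1.0)
        assert km.median is None

    def test_random_fixture_matches_product_limit_oracle(self, rng):
        times = np.round(rng.uniform(1, 50, size=40))  # force ties
        status = (rng.uniform(size=40) < 0.6).astype(int)
        km = km_estimate(pd.Series(times), pd.Series(status))
        o_times, o_surv, o_median = km_bruteforce(times, status)
        got = pd.Series(km.survival, index=km.times).loc[o_times]
        np.testing.assert_allclose(got.to_numpy(), o_surv, atol=1e-12)
        assert km.median == o_median

    def test_curve_monotone_from_one(self, medium_cohort):
        _, surv, _ = medium_cohort
        km = km_estimate(surv.time, surv.status)
        assert km.survival[0] == 1.0
        assert np.all(np.diff(km.survival) <= 1e-15)


class TestHazardRatio:
    def _table(self, groups, idx):
        from survsig.scoring import ScoreTable
        return ScoreTable(
            table=pd.DataFrame({"score": np.arange(len(groups), dtype=float),
                                "group": groups}, index=idx),
            cutoff=0.0, cutoff_method="median")

    def test_identical_groups_hr_near_one(self):
        surv = surv_from([10, 20, 30, 40, 10, 20, 30, 40],
                         [1, 0, 1, 1, 1, 0, 1, 1])
        st = self._table(["low"] * 4 + ["high"] * 4, surv.sample_ids)
        hr = univariate_hr(st, surv)
        assert hr.estimable
        assert hr.ci_low < 1 < hr.ci_high

    def test_small_fixture_matches_bruteforce_cox(self, rng):
        n = 40
        times = rng.uniform(1, 100, size=n)
        status = (rng.uniform(size=n) < 0.8).astype(int)
        groups = ["low"] * 20 + ["high"] * 20
        surv = surv_from(times, status)
        st = self._table(groups, surv.sample_ids)
        hr = univariate_hr(st, surv)
        x = np.array([[1.0 if g == "low" else 0.0] for g in groups])
        beta = cox_fit_bruteforce(x, times, status.astype(bool))[0]
        assert np.log(hr.hr) == pytest.approx(beta, abs=1e-6)

    def test_group_log_hazard_recovered(self):
        """Planted group effect beta=0.7 is recovered within 3 s.e. at n=400."""
        rng = np.random.default_rng(77)
        n = 400
        low = np.array([True] * (n // 2) + [False] * (n // 2))
        eta = np.where(low, -0.7, 0.0)
        times = rng.exponential(1.0 / np.exp(eta)) * 365
        status = np.ones(n)
        surv = surv_from(times, status)
        st = self._table(np.where(low, "low", "high"), surv.sample_ids)
        hr = univariate_hr(st, surv)
        se = (np.log(hr.ci_high) - np.log(hr.ci_low)) / (2 * 1.96)
        assert abs(np.log(hr.hr) - (-0.7)) < 3 * se

    def test_no_events_in_group_non_estimable(self):
        surv = surv_from([10, 20, 30, 40], [0, 0, 1, 1])
        st = self._table(["low", "low", "high", "high"], surv.sample_ids)
        hr = univariate_hr(st, surv)
        assert not hr.estimable and "low" in hr.note


class TestEndToEndDirection:
    def test_high_score_group_has_worse_survival(self):
        """Positive planted coefficients: high-score KM at or below low KM,
        HR(low vs high) < 1 — high scores carry worse prognosis."""
        spec = SyntheticSpec.with_planted(n_samples=300, n_features=6, n_true=2,
                                          beta=1.0, censoring_fraction=0.2,
                                          seed=88)
        expr, surv, truth = generate_cohort(spec)
        sd = expr.data.std()
        sig = Signature.from_items([(f, b / sd[f]) for f, b in truth["beta"].items()
                                    if b > 0])
        res = analyze_survival(expr, surv, sig)
        assert res.hazard_ratio.hr < 1
        # compare KM curves on the common event-time grid
        grid = np.union1d(res.km_low.times, res.km_high.times)
        s_low = pd.Series(res.km_low.survival, index=res.km_low.times)
        s_high = pd.Series(res.km_high.survival, index=res.km_high.times)
        lo = s_low.reindex(grid).ffill().fillna(1.0)
        hi = s_high.reindex(grid).ffill().fillna(1.0)
        assert (hi <= lo + 1e-12).all()
        assert res.logrank_p < 0.001
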