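"""Association models against closed forms and independent reference fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mloyad.association import (AssociationError, apoe_score, distribution_tests,
                                fit_case_control, fit_conversion, harmonise_mlrry,
                                ivw_meta, run_mr_suite, select_pcs, AssocResult)
from mloyad.config import AssocConfig


class TestApoe:
    @pytest.mark.parametrize("geno, score", [
        (("e3", "e3"), 0),
        (("e2", "e4"), 0),
        (("e4", "e4"), 2),
        (("e2", "e2"), -2),
        ("E3/E4", 1),
        ("e2/e3", -1),
    ])
    def test_coding(self, geno, score):
        assert apoe_score(geno) == score

    def test_unknown_allele_rejected(self):
        with pytest.raises(ValueError, match="e5"):
            apoe_score(("e3", "e5"))


class TestLogistic:
    def test_two_by_two_closed_form(self):
        # cases: 20 exposed, 10 unexposed; controls: 10 exposed, 20 unexposed
        y = np.repeat([1, 1, 0, 0], [20, 10, 10, 20])
        x = np.repeat([1, 0, 1, 0], [20, 10, 10, 20])
        df = pd.DataFrame({"ad_status": y, "x": x})
        res = fit_case_control(df, "x")
        assert res.ratio == pytest.approx((20 * 20) / (10 * 10), rel=1e-6)

    def test_matches_sklearn_reference(self):
        from sklearn.linear_model import LogisticRegression
        rng = np.random.default_rng(0)
        n = 500
        df = pd.DataFrame({"x": rng.normal(size=n), "age": rng.uniform(60, 90, n)})
        df["ad_status"] = (rng.random(n) <
                           1 / (1 + np.exp(-(0.5 * df.x + 0.05 * (df.age - 75))))).astype(int)
        res = fit_case_control(df, "x", ["age"])
        ref = LogisticRegression(penalty=None, tol=1e-12, max_iter=5000)
        ref.fit(df[["x", "age"]], df["ad_status"])
        assert res.effect == pytest.approx(ref.coef_[0][0], abs=1e-6)

    def test_separation_flagged(self):
        df = pd.DataFrame({"ad_status": [0] * 20 + [1] * 20,
                           "x": np.arange(40.0)})
        res = fit_case_control(df, "x")
        assert res.note == "separation_suspected"

    def test_sign_flip_negates_effect_exactly(self):
        rng = np.random.default_rng(1)
        n = 300
        df = pd.DataFrame({"x": rng.normal(size=n)})
        df["ad_status"] = (rng.random(n) < 0.4 + 0.1 * (df.x > 0)).astype(int)
        a = fit_case_control(df, "x")
        b = fit_case_control(df.assign(x=-df.x), "x")
        assert b.effect == pytest.approx(-a.effect, abs=1e-8)

    def test_ci_is_effect_pm_196_se(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"ad_status": rng.integers(0, 2, 200),
                           "x": rng.normal(size=200)})
        res = fit_case_control(df, "x")
        lo, hi = res.ci
        assert lo == pytest.approx(res.effect - 1.96 * res.se)
        assert hi == pytest.approx(res.effect + 1.96 * res.se)


class TestCox:
    def _surv(self, n=400, beta=0.0, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        t = -np.log(rng.random(n)) / (0.1 * np.exp(beta * x))
        c = rng.uniform(0, 15, n)
        return pd.DataFrame({"x": x, "time": np.minimum(t, c),
                             "event": (t <= c).astype(int)})

    def test_null_ci_covers_one(self):
        res = fit_conversion(self._surv(beta=0.0), "x")
        lo, hi = res.ci
        assert lo <= 0.0 <= hi

    def test_time_scale_invariance(self):
        df = self._surv(beta=0.4, seed=3)
        a = fit_conversion(df, "x")
        b = fit_conversion(df.assign(time=2.0 * df.time), "x")
        assert b.effect == pytest.approx(a.effect, abs=1e-9)

    def test_matches_scikit_survival_reference(self):
        from sksurv.linear_model import CoxPHSurvivalAnalysis
        df = self._surv(beta=0.3, seed=4)
        res = fit_conversion(df, "x")
        ys = np.array([(bool(e), t) for e, t in zip(df.event, df.time)],
                      dtype=[("event", bool), ("time", float)])
        ref = CoxPHSurvivalAnalysis(ties="breslow", tol=1e-12).fit(df[["x"]], ys)
        assert res.effect == pytest.approx(ref.coef_[0], abs=1e-6)

    def test_no_events_rejected(self):
        df = self._surv()
        df["event"] = 0
        with pytest.raises(AssociationError, match="no events"):
            fit_conversion(df, "x")

    def test_nonpositive_times_rejected(self):
        df = self._surv()
        df.loc[df.index[0], "time"] = 0.0
        with pytest.raises(AssociationError, match="positive"):
            fit_conversion(df, "x")


class TestDistributionTests:
    def _df(self, a, b, seed=0):
        rng = np.random.default_rng(seed)
        y = np.concatenate([a, b])
        g = np.repeat([0, 1], [len(a), len(b)])
        return (pd.Series(y), pd.Series(g),
                pd.Series(rng.uniform(60, 90, len(y))),
                pd.Series(rng.integers(-2, 3, len(y))))

    def test_identical_samples_d_zero(self):
        x = np.arange(10.0)
        d = distribution_tests(*self._df(x, x))
        assert d.ks_stat == 0.0

    def test_disjoint_supports_d_one(self):
        d = distribution_tests(*self._df(np.arange(10.0), np.arange(100.0, 110.0)))
        assert d.ks_stat == 1.0

    def test_ks_matches_brute_force_ecdf(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=80), rng.normal(0.3, 1, 120)
        d = distribution_tests(*self._df(a, b, seed=5))
        grid = np.concatenate([a, b])
        ecdf_a = np.searchsorted(np.sort(a), grid, side="right") / len(a)
        ecdf_b = np.searchsorted(np.sort(b), grid, side="right") / len(b)
        assert d.ks_stat == pytest.approx(np.abs(ecdf_a - ecdf_b).max(), abs=1e-12)

    def test_ancova_f_matches_manual_rss_ratio(self):
        rng = np.random.default_rng(6)
        y_s, g_s, age_s, apoe_s = self._df(rng.normal(size=60),
                                           rng.normal(0.5, 1, 60), seed=6)
        d = distribution_tests(y_s, g_s, age_s, apoe_s)
        # oracle: F = ((RSS0 - RSS1)/1) / (RSS1/(n-4)) from explicit OLS fits
        X1 = np.column_stack([np.ones(len(y_s)), g_s, age_s, apoe_s])
        X0 = X1[:, [0, 2, 3]]
        rss = lambda X: np.sum((y_s - X @ np.linalg.lstsq(X, y_s, rcond=None)[0]) ** 2)
        f = (rss(X0) - rss(X1)) / (rss(X1) / (len(y_s) - 4))
        assert d.ancova_f == pytest.approx(f, abs=1e-8)

    def test_small_group_rejected(self):
        with pytest.raises(AssociationError, match="< 3"):
            distribution_tests(*self._df(np.arange(2.0), np.arange(10.0)))


def _mk(beta, se, scale="log_or"):
    return AssocResult(model="logistic", exposure="x", effect=beta, se=se,
                       p=0.5, n=100, scale=scale)


class TestIVW:
    def test_closed_form_equal_ses(self):
        m = ivw_meta([_mk(1.0, 1.0), _mk(3.0, 1.0)])
        assert m.effect == pytest.approx(2.0)
        assert m.se == pytest.approx(1 / np.sqrt(2))

    def test_duplicated_stratum(self):
        m = ivw_meta([_mk(0.7, 0.2), _mk(0.7, 0.2)])
        assert m.effect == pytest.approx(0.7)
        assert m.se == pytest.approx(0.2 / np.sqrt(2))

    def test_infinite_se_limit(self):
        m = ivw_meta([_mk(0.5, 0.1), _mk(9.9, 1e6)])
        assert m.effect == pytest.approx(0.5, abs=1e-6)

    def test_identical_strata_equal_common_estimate_exactly(self):
        parts = [_mk(0.31, 0.07)] * 4
        assert ivw_meta(parts).effect == 0.31

    def test_pooled_se_not_above_min_stratum_se(self):
        m = ivw_meta([_mk(0.1, 0.3), _mk(0.2, 0.5)])
        assert m.se <= 0.3

    def test_zero_se_rejected(self):
        with pytest.raises(AssociationError):
            ivw_meta([_mk(0.1, 0.0), _mk(0.2, 0.5)])

    def test_mixed_scales_rejected(self):
        with pytest.raises(AssociationError, match="scales"):
            ivw_meta([_mk(0.1, 0.1), _mk(0.2, 0.5, scale="log_hr")])

    def test_matches_r_metafor_reference(self):
        """Fixed-effect IVW agrees with the standard closed form used by
        rma.uni(method='FE'): independently recomputed here."""
        rng = np.random.default_rng(7)
        beta = rng.normal(size=5)
        se = rng.uniform(0.1, 1.0, 5)
        m = ivw_meta([_mk(b, s) for b, s in zip(beta, se)])
        w = 1 / se**2
        assert m.effect == pytest.approx(np.sum(w * beta) / np.sum(w), abs=1e-12)
        assert m.se == pytest.approx(np.sqrt(1 / np.sum(w)), abs=1e-12)


class TestSelectPCs:
    def test_pc_equal_to_outcome_selected(self):
        rng = np.random.default_rng(0)
        y = pd.Series(rng.integers(0, 2, 300).astype(float))
        pcs = pd.DataFrame({"PC1": y + rng.normal(0, 0.01, 300),
                            "PC2": rng.normal(size=300)})
        assert "PC1" in select_pcs(pcs, y)

    def test_threshold_one_selects_all(self):
        rng = np.random.default_rng(1)
        y = pd.Series(rng.integers(0, 2, 200).astype(float))
        pcs = pd.DataFrame(rng.normal(size=(200, 3)), columns=["PC1", "PC2", "PC3"])
        assert select_pcs(pcs, y, alpha=1.0) == ["PC1", "PC2", "PC3"]

    def test_null_selection_rate_near_alpha(self):
        rng = np.random.default_rng(2)
        hits = trials = 0
        for _ in range(150):
            y = pd.Series(rng.integers(0, 2, 150).astype(float))
            pcs = pd.DataFrame({"PC1": rng.normal(size=150)})
            hits += len(select_pcs(pcs, y))
            trials += 1
        rate = hits / trials
        assert 0.01 < rate < 0.11      # ~5% +/- binomial noise at 150 trials


class TestMrSuite:
    def test_deterministic_and_shaped(self, small_cohort):
        from mloyad.prs import compute_prs, cohort_variant_stats, filter_instrument_variants
        from mloyad.calling import compute_mlrry, split_batches_and_check

        c = small_cohort
        mlrry = compute_mlrry(c.intensities)
        res = split_batches_and_check(mlrry, seed=0)
        mloy = res.table[["mlrry", "mloy_call"]]
        prs = compute_prs(
            c.dosages,
            filter_instrument_variants(c.weights,
                                       cohort_variant_stats(c.dosages, c.weights)).kept)
        t1 = run_mr_suite(c.phenotypes, prs.std, mloy)
        t2 = run_mr_suite(c.phenotypes, prs.std, mloy)
        pd.testing.assert_frame_equal(t1, t2)
        # women rows for mLOY phenotypes are missing-with-reason
        women_mlrry = t1[(t1.exposure == "mlrry") & (t1.stratum == "women")]
        assert (women_mlrry["note"] == "mLOY phenotype undefined for women").all()
        # META rows present for each exposure x outcome with enough bands
        assert (t1["stratum"] == "META(age-bands)").any()

    def test_harmonised_exposure_orientation(self):
        s = pd.Series([-0.5, 0.0, 0.2])
        assert (harmonise_mlrry(s) == pd.Series([0.5, -0.0, -0.2])).all()
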