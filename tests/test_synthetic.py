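"""Generator tests: determinism, calibration, planted-truth recovery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from mloyad.config import CellFractionLaw, GeneratorConfig
from mloyad.synthetic import (CalibrationError, calibrate_alpha0, gen_genotypes,
                              gen_intensities, gen_mloy_status, gen_phenotypes,
                              generate_cohort, standardized_prs)


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestGenotypes:
    def test_deterministic_under_seed(self):
        cfg = GeneratorConfig(n_samples=50, n_instrument_snps=10, seed=3)
        d1, w1 = gen_genotypes(cfg, _rng(3))
        d2, w2 = gen_genotypes(cfg, _rng(3))
        pd.testing.assert_frame_equal(d1, d2)
        pd.testing.assert_frame_equal(w1, w2)

    def test_degenerate_frequency_gives_fixed_dosage(self):
        cfg = GeneratorConfig(n_samples=30, n_instrument_snps=3)
        freqs = np.array([1.0, 0.5, 0.0])
        d, _ = gen_genotypes(cfg, _rng(0), freqs=freqs)
        assert (d.iloc[:, 0] == 2.0).all()
        assert (d.iloc[:, 2] == 0.0).all()

    def test_mean_dosage_matches_binomial_expectation(self):
        cfg = GeneratorConfig(n_samples=50_000, n_instrument_snps=1)
        d, _ = gen_genotypes(cfg, _rng(11), freqs=np.array([0.3]))
        # E[dosage] = 2p = 0.6; MC error ~ sqrt(2*0.3*0.7/n) ~ 0.003
        assert d.iloc[:, 0].mean() == pytest.approx(0.6, abs=0.01)

    def test_nonpositive_sample_count_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_samples=0)


class TestMloyStatus:
    def _cohort(self, n, seed, **kw):
        cfg = GeneratorConfig(n_samples=n, seed=seed, **kw)
        rng = _rng(seed)
        d, w = gen_genotypes(cfg, rng)
        prs = standardized_prs(d, w["beta"].to_numpy())
        ages = pd.Series(rng.uniform(*cfg.age_range, n), index=prs.index)
        sexes = pd.Series(np.where(rng.random(n) < cfg.sex_ratio, "M", "F"),
                          index=prs.index)
        return cfg, prs, ages, sexes

    def test_null_model_prevalence_uniform_in_age(self):
        cfg, prs, ages, sexes = self._cohort(20_000, 5, prs_or_per_sd=1.0,
                                             age_or_per_year=1.0, sex_ratio=1.0)
        res = gen_mloy_status(cfg, prs, ages, sexes == "M", _rng(5))
        # with no effects the liability is flat at the target everywhere
        assert np.allclose(res["p_loy"].unique(),
                           cfg.target_mloy_prevalence, atol=1e-3)
        young = res["loy"][(ages < 70)].mean()
        old = res["loy"][(ages > 85)].mean()
        assert abs(young - old) < 0.03

    def test_all_females_zero_carriers(self):
        cfg, prs, ages, sexes = self._cohort(500, 1)
        res = gen_mloy_status(cfg, prs, ages, pd.Series(False, index=prs.index),
                              _rng(1))
        assert res["loy"].sum() == 0
        assert (res["cell_fraction"] == 0).all()

    def test_prevalence_calibration_at_scale(self):
        """Empirical prevalence in 65-85 males within 0.5 pp of the target."""
        cfg, prs, ages, sexes = self._cohort(60_000, 2, sex_ratio=1.0)
        res = gen_mloy_status(cfg, prs, ages, sexes == "M", _rng(2))
        win = (ages >= 65) & (ages <= 85)
        assert res["loy"][win].mean() == pytest.approx(0.189, abs=0.005)

    def test_logistic_refit_recovers_generative_or(self):
        """Refitting the liability model covers OR 1.80/SD at n=50k."""
        cfg, prs, ages, sexes = self._cohort(50_000, 9, sex_ratio=1.0)
        res = gen_mloy_status(cfg, prs, ages, sexes == "M", _rng(9))
        X = sm.add_constant(pd.DataFrame({"prs": prs, "age": ages - 75.0}))
        fit = sm.Logit(res["loy"].astype(float), X).fit(disp=0)
        lo = fit.params["prs"] - 1.96 * fit.bse["prs"]
        hi = fit.params["prs"] + 1.96 * fit.bse["prs"]
        assert lo <= np.log(1.80) <= hi

    def test_unreachable_target_reports_bracket(self):
        cfg, prs, ages, sexes = self._cohort(200, 3)
        cfg2 = GeneratorConfig(**{**cfg.__dict__, "target_mloy_prevalence": 1.0 - 1e-12})
        with pytest.raises(CalibrationError, match="bracket"):
            calibrate_alpha0(prs.to_numpy(), ages.to_numpy(), cfg2)


class TestIntensities:
    def _truth(self, fractions, karyo="XY"):
        n = len(fractions)
        return pd.DataFrame({
            "karyotype": karyo, "cell_fraction": fractions,
            "trisomy21": False, "planted_par1_loh": False,
        }, index=pd.Index([f"S{i}" for i in range(n)], name="sample"))

    def test_noise_free_f0_gives_zero_msy_lrr(self):
        cfg = GeneratorConfig(noise_sd_lrr=0.0)
        data = gen_intensities(self._truth([0.0]), cfg, _rng(0))
        assert np.all(data.lrr[:, data.region_mask("MSY")] == 0.0)

    def test_noise_free_f_half_gives_minus_one(self):
        cfg = GeneratorConfig(noise_sd_lrr=0.0)
        data = gen_intensities(self._truth([0.5]), cfg, _rng(0))
        msy = data.lrr[:, data.region_mask("MSY")]
        assert np.allclose(msy, -1.0, atol=1e-12)

    def test_expected_msy_lrr_decreasing_in_fraction(self):
        cfg = GeneratorConfig(noise_sd_lrr=0.0)
        fs = np.linspace(0, 0.89, 15)
        data = gen_intensities(self._truth(fs), cfg, _rng(0))
        means = data.lrr[:, data.region_mask("MSY")].mean(axis=1)
        assert np.all(np.diff(means) < 0)

    def test_xx_floor_and_xyy_gain(self):
        cfg = GeneratorConfig(noise_sd_lrr=0.0)
        d_xx = gen_intensities(self._truth([0.0], karyo="XX"), cfg, _rng(0))
        d_xyy = gen_intensities(self._truth([0.0], karyo="XYY"), cfg, _rng(0))
        assert np.all(d_xx.lrr[:, d_xx.region_mask("MSY")] == cfg.lrr_floor)
        assert np.all(d_xx.lrr[:, d_xx.region_mask("X")] == cfg.lrr_gain)
        assert np.all(d_xyy.lrr[:, d_xyy.region_mask("MSY")] == cfg.lrr_gain)

    def test_empty_manifest_region_rejected(self):
        cfg = GeneratorConfig()
        with pytest.raises(ValueError):
            gen_intensities(self._truth([0.0]), cfg, _rng(0),
                            probes=pd.DataFrame(columns=["probe", "chrom",
                                                         "position", "region"]))


class TestPhenotypes:
    def _truth(self, n, seed, **cfg_kw):
        cfg = GeneratorConfig(n_samples=n, seed=seed, **cfg_kw)
        rng = _rng(seed)
        idx = pd.Index([f"S{i:06d}" for i in range(n)], name="sample")
        truth = pd.DataFrame({
            "sex": np.where(rng.random(n) < cfg.sex_ratio, "M", "F"),
            "age": rng.uniform(*cfg.age_range, n),
            "cell_fraction": 0.0,
            "prs_true": rng.standard_normal(n),
        }, index=idx)
        return cfg, truth

    def test_null_conversion_hr_ci_covers_one(self):
        from lifelines import CoxPHFitter
        cfg, truth = self._truth(8000, 4, conversion_hr_per_sd_male=1.0,
                                 conversion_hr_per_sd_female=1.0, mci_fraction=1.0)
        pheno = gen_phenotypes(truth, cfg, _rng(4))
        df = pheno.join(truth["prs_true"]).dropna(subset=["time"])
        cph = CoxPHFitter().fit(df[["time", "event", "prs_true"]], "time", "event")
        lo, hi = cph.confidence_intervals_.loc["prs_true"]
        assert lo <= 0.0 <= hi

    def test_tau_unaffected_when_gamma_zero(self):
        cfg, truth = self._truth(6000, 6, gamma_tau=0.0, mci_fraction=1.0,
                                 sex_ratio=1.0, lp_fraction=1.0)
        truth["cell_fraction"] = np.random.default_rng(6).uniform(0, 0.5, len(truth))
        pheno = gen_phenotypes(truth, cfg, _rng(6))
        sub = pheno.dropna(subset=["tau"]).join(truth["cell_fraction"], rsuffix="_t")
        r = np.corrcoef(sub["tau"], sub["cell_fraction"])[0, 1]
        assert abs(r) < 0.04

    def test_negative_hazard_parameters_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(baseline_hazard=-0.1)


class TestCohortDeterminism:
    def test_identical_seed_identical_outputs(self):
        a = generate_cohort(GeneratorConfig(n_samples=300, seed=42))
        b = generate_cohort(GeneratorConfig(n_samples=300, seed=42))
        pd.testing.assert_frame_equal(a.truth, b.truth)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        assert np.array_equal(a.intensities.lrr, b.intensities.lrr)
        assert np.array_equal(a.intensities.baf, b.intensities.baf)
        pd.testing.assert_frame_equal(a.proteins, b.proteins)

    def test_different_seed_differs(self):
        a = generate_cohort(GeneratorConfig(n_samples=300, seed=1))
        b = generate_cohort(GeneratorConfig(n_samples=300, seed=2))
        assert not np.array_equal(a.intensities.lrr, b.intensities.lrr)

    def test_truth_invariants(self, small_cohort):
        t = small_cohort.truth
        assert (t.loc[t["sex"] == "F", "cell_fraction"] == 0).all()
        assert (t.loc[t["loy"], "cell_fraction"] > 0).all()
        assert not t.loc[t["karyotype"] != "XY", "loy"].any()


class TestCellFractionLaw:
    def test_support_and_determinism(self):
        law = CellFractionLaw()
        x = law.sample(_rng(0), 5000)
        assert x.min() >= 0.05 and x.max() <= 0.90
        assert np.array_equal(x, CellFractionLaw().sample(_rng(0), 5000))
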