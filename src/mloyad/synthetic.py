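"""Synthetic cohort generator emulating the statistical structure of an
mLOY-in-Alzheimer's study.

The generator plants a known ground truth so that every downstream stage
(QC cascade, threshold caller, instrument, association grid, biomarker scans)
can be tested for recovery without any external data:

* an autosomal polygenic instrument whose standardized score raises mLOY
  liability (default OR 1.80 per SD) alongside age (OR 1.08 per year), with
  the intercept calibrated by bisection so the expected carrier prevalence in
  65-85-year-old men hits the target (default 18.9%);
* carriers receive a mosaic cell fraction from a rescaled Beta law, and their
  MSY probe intensities follow LRR = log2(1 - f) plus Gaussian array noise;
* an age-confounded AD case-control structure with a male-only LOY liability
  term, and MCI phenoconversion from a proportional-hazards law whose PRS
  effect acts in men only (default HR 1.23 per SD) unless a both-sex
  pleiotropic term is switched on;
* CSF total tau raised by the LOY cell fraction, p-tau proportional to tau,
  Abeta-42 independent, and two 184-analyte fluid panels loading on tau;
* planted QC violations (sex-karyotype anomalies, low call rate, excess
  heterozygosity, a relatedness pair, ancestry outliers, PAR1 LOH) recorded
  per sample for planted-truth tests.

All randomness flows from ``GeneratorConfig.seed`` through named child
streams, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import bisect
from scipy.special import expit, logit

from .config import GeneratorConfig
from .io_qc import IntensityData
from .regions import build_probes

_STREAMS = ("genotypes", "liability", "fractions", "intensities",
            "phenotypes", "proteins", "qc")


class CalibrationError(RuntimeError):
    """Target prevalence unreachable within the searched intercept bracket."""


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


# ---------------------------------------------------------------------------
# genotypes and the instrument


def gen_genotypes(config: GeneratorConfig, rng: np.random.Generator,
                  freqs: np.ndarray | None = None,
                  sample_ids: pd.Index | None = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hardy-Weinberg dosages plus an instrument-weights table.

    Allele frequencies are drawn uniformly in [0.05, 0.95] unless supplied;
    per-allele weights come from a zero-mean normal law.  Dosages are
    Binomial(2, p) per sample and variant (independent variants: the source
    GWAS clumped its signals, so no LD is modelled).
    """
    if config.n_samples <= 0:
        raise ValueError("non-positive sample count")
    m = config.n_instrument_snps
    if freqs is None:
        freqs = rng.uniform(0.05, 0.95, size=m)
    freqs = np.asarray(freqs, float)
    betas = rng.normal(0.0, config.prs_beta_sd, size=m)
    r2 = rng.uniform(0.7, 1.0, size=m)
    chroms = rng.integers(1, 23, size=m).astype(str)
    if sample_ids is None:
        sample_ids = pd.Index([f"S{i:06d}" for i in range(config.n_samples)],
                              name="sample")
    dosages = pd.DataFrame(
        rng.binomial(2, freqs, size=(len(sample_ids), m)).astype(float),
        index=sample_ids, columns=[f"snp_{j:04d}" for j in range(m)])
    weights = pd.DataFrame({
        "variant": dosages.columns,
        "chrom": chroms,
        "position": (1 + np.arange(m)) * 100_000,
        "effect_allele": "A",
        "other_allele": "B",
        "beta": betas,
        "maf": np.minimum(freqs, 1.0 - freqs),
        "imputation_r2": r2,
    })
    return dosages, weights


def standardized_prs(dosages: pd.DataFrame, betas: np.ndarray) -> pd.Series:
    raw = dosages.to_numpy(float) @ np.asarray(betas, float)
    sd = raw.std()
    if sd == 0:
        raise ValueError("zero-variance raw PRS")
    return pd.Series((raw - raw.mean()) / sd, index=dosages.index, name="prs_true")


# ---------------------------------------------------------------------------
# mLOY liability


def calibrate_alpha0(prs: np.ndarray, ages: np.ndarray, config: GeneratorConfig,
                     *, window: tuple[float, float] = (65.0, 85.0),
                     tol: float = 1e-4) -> float:
    """Bisect the liability intercept so expected prevalence in the age window
    matches ``target_mloy_prevalence``."""
    b_prs = np.log(config.prs_or_per_sd)
    b_age = np.log(config.age_or_per_year)
    inw = (ages >= window[0]) & (ages <= window[1])
    if not inw.any():
        raise CalibrationError("no eligible men in the calibration age window")
    lin = b_prs * prs[inw] + b_age * (ages[inw] - 75.0)

    def gap(a0: float) -> float:
        return float(expit(a0 + lin).mean()) - config.target_mloy_prevalence

    lo, hi = -30.0, 10.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise CalibrationError(
            f"target prevalence {config.target_mloy_prevalence} unreachable in "
            f"bracket [{lo}, {hi}]: gap({lo})={gap(lo):.4g}, gap({hi})={gap(hi):.4g}")
    return float(bisect(gap, lo, hi, xtol=tol))


def gen_mloy_status(config: GeneratorConfig, prs: pd.Series, ages: pd.Series,
                    eligible: pd.Series, rng: np.random.Generator) -> pd.DataFrame:
    """Draw carrier status and cell fractions from the calibrated liability model.

    ``eligible`` marks XY men; everyone else gets probability (and fraction) 0.
    ``prs`` must be standardized (mean 0, SD 1 over the cohort).
    """
    idx = prs.index
    el = eligible.reindex(idx).to_numpy(bool)
    a = ages.reindex(idx).to_numpy(float)
    s = prs.to_numpy(float)
    if el.any():
        a0 = calibrate_alpha0(s[el], a[el], config)
        p = np.zeros(len(idx))
        p[el] = expit(a0 + np.log(config.prs_or_per_sd) * s[el]
                      + np.log(config.age_or_per_year) * (a[el] - 75.0))
    else:
        p = np.zeros(len(idx))
    loy = rng.random(len(idx)) < p
    frac = np.zeros(len(idx))
    if loy.any():
        frac[loy] = config.cell_fraction_law.sample(rng, int(loy.sum()))
    return pd.DataFrame({"p_loy": p, "loy": loy, "cell_fraction": frac}, index=idx)


# ---------------------------------------------------------------------------
# intensities


def gen_intensities(truth: pd.DataFrame, config: GeneratorConfig,
                    rng: np.random.Generator,
                    probes: pd.DataFrame | None = None) -> IntensityData:
    """LRR/BAF matrices for the array samples described by ``truth``.

    ``truth`` rows (one per array sample, typically the reported-male cohort)
    need columns ``karyotype``, ``cell_fraction``, ``trisomy21`` and
    ``planted_par1_loh``.  The LRR law is log2(copy ratio) against an XY
    reference: a one-copy gain shows as ``lrr_gain * compression``, an absent
    chromosome as the background floor, and a mosaic LOY fraction ``f`` as
    log2(1 - f) over MSY probes.
    """
    if probes is None:
        probes = build_probes(config.n_probes)
    if probes.empty:
        raise ValueError("empty probe manifest")
    n, p = len(truth), len(probes)
    region = probes["region"].to_numpy()
    gain = config.lrr_gain * config.compression
    floor = config.lrr_floor

    karyo = truth["karyotype"].to_numpy()
    f = truth["cell_fraction"].to_numpy(float)
    tri = truth.get("trisomy21", pd.Series(False, index=truth.index)).to_numpy(bool)
    loh = truth.get("planted_par1_loh", pd.Series(False, index=truth.index)).to_numpy(bool)

    lrr = np.zeros((n, p))
    is_msy = np.isin(region, ("MSY", "XTR"))
    is_x = region == "X"
    is_auto = region == "AUTO"
    is_par1 = region == "PAR1"

    # per-karyotype Y-region and X-region means
    y_mean = np.where(karyo == "XY",
                      np.maximum(np.log2(np.maximum(1.0 - f, 2.0 ** floor)), floor),
                      0.0)
    y_mean = np.where(karyo == "XX", floor, y_mean)
    y_mean = np.where(karyo == "XYY", gain, y_mean)        # XXY keeps one Y -> 0
    x_mean = np.where(np.isin(karyo, ("XX", "XXY")), gain, 0.0)

    lrr[:, is_msy] = y_mean[:, None]
    lrr[:, is_x] = x_mean[:, None]
    # trisomy 21: gain over the chr21 autosomal probes
    chr21 = is_auto & (probes["chrom"].to_numpy() == "21")
    if chr21.any() and tri.any():
        lrr[np.ix_(tri, chr21)] = gain
    if config.noise_sd_lrr > 0:
        lrr += rng.normal(0.0, config.noise_sd_lrr, size=(n, p))

    # BAF: diploid regions mix heterozygous (around 0.5) and homozygous (0/1)
    baf = np.empty((n, p))
    het = rng.random((n, p)) < config.het_rate
    hom_allele = rng.random((n, p)) < 0.5
    noise = rng.normal(0.0, config.baf_sd, size=(n, p))
    baf = np.where(het, 0.5 + noise, np.where(hom_allele, np.abs(noise) * 0.5,
                                              1.0 - np.abs(noise) * 0.5))
    # haploid in males: X and Y regions carry no heterozygotes
    male = np.isin(karyo, ("XY", "XYY"))
    hap = np.ix_(male, is_msy | is_x)
    baf[hap] = np.where(hom_allele[hap], np.abs(noise[hap]) * 0.5,
                        1.0 - np.abs(noise[hap]) * 0.5)
    # planted PAR1 loss-of-heterozygosity: het BAF splits to 0.5 +/- Bdev
    if loh.any() and is_par1.any():
        sel = np.ix_(loh, is_par1)
        split = np.where(rng.random((int(loh.sum()), int(is_par1.sum()))) < 0.5,
                         -config.planted_bdev, config.planted_bdev)
        baf[sel] = np.where(het[sel], 0.5 + split + noise[sel], baf[sel])
    np.clip(baf, 0.0, 1.0, out=baf)

    return IntensityData(probes=probes, samples=pd.Index(truth.index, name="sample"),
                         lrr=lrr, baf=baf)


# ---------------------------------------------------------------------------
# phenotypes, biomarkers, proteome


def gen_phenotypes(truth: pd.DataFrame, config: GeneratorConfig,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Diagnosis labels, conversion times and CSF biomarkers from the truth table.

    AD case-control status comes from a logistic law in age and APOE with a
    male-only LOY cell-fraction term; the prospective MCI subcohort gets
    conversion times from a Weibull proportional-hazards law (exponential by
    default) whose PRS effect is sex-specific, with independent uniform
    censoring; CSF total tau increases with the LOY cell fraction.
    """
    n = len(truth)
    idx = truth.index
    age = truth["age"].to_numpy(float)
    male = (truth["sex"] == "M").to_numpy()
    f = truth["cell_fraction"].to_numpy(float)
    prs = truth["prs_true"].to_numpy(float)

    # APOE score from HWE allele draws
    freqs = config.apoe_freqs
    alleles = list(freqs)
    pvec = np.array([freqs[a] for a in alleles], float)
    pvec = pvec / pvec.sum()
    draws = rng.choice(len(alleles), p=pvec, size=(n, 2))
    a_names = np.array(alleles, dtype=object)
    apoe = ((a_names[draws] == "e4").sum(axis=1)
            - (a_names[draws] == "e2").sum(axis=1)).astype(int)

    is_mci = rng.random(n) < config.mci_fraction

    # case-control AD status (age-confounded by construction)
    lin = (logit(config.ad_base_rate)
           + np.log(config.ad_or_per_year) * (age - 75.0)
           + np.log(config.ad_or_apoe) * apoe
           + np.where(male, np.log(config.ad_or_loy_male) * f, 0.0))
    ad = (rng.random(n) < expit(lin)).astype(float)
    ad[is_mci] = np.nan            # prospective MCI samples leave the case-control set

    # phenoconversion for the MCI subcohort
    hr_sex = np.where(male, config.conversion_hr_per_sd_male,
                      config.conversion_hr_per_sd_female)
    rate = config.baseline_hazard * np.exp(
        np.log(hr_sex) * prs
        + np.log(config.pleiotropy_hr_per_sd) * prs
        + np.log(config.conversion_hr_per_year) * (age - 75.0))
    shape = config.weibull_shape
    t_event = (-np.log(rng.random(n)) / rate) ** (1.0 / shape)
    censor = rng.uniform(0.5, config.followup_years, size=n)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor) & is_mci
    diag_ad = rng.random(n) < config.ad_fraction_of_converters
    event_ad = event & diag_ad
    cohort = (rng.random(n) < 0.5).astype(int)

    pheno = pd.DataFrame({
        "sex": truth["sex"], "age": age, "apoe": apoe, "ad_status": ad,
        "is_mci": is_mci, "time": time, "event": event.astype(int),
        "event_ad": event_ad.astype(int), "cohort": cohort,
    }, index=idx)
    pheno.loc[~is_mci, ["time", "event", "event_ad"]] = np.nan

    # lumbar-puncture subset: men with MCI or AD dementia
    eligible = male & (is_mci | (ad == 1.0))
    has_lp = eligible & (rng.random(n) < config.lp_fraction)
    gap = rng.uniform(0.0, config.lp_gap_max, size=n)
    tau = (config.tau_mean + config.gamma_tau * f + config.apoe_tau * apoe
           + rng.normal(0.0, config.tau_noise_sd, size=n))
    ptau = (config.ptau_intercept + config.ptau_slope * tau
            + rng.normal(0.0, config.ptau_noise_sd, size=n))
    abeta = rng.normal(config.abeta_mean, config.abeta_sd, size=n)
    pheno["has_lp"] = has_lp
    pheno["syndrome"] = np.where(is_mci, "MCI", "dementia")
    pheno["lp_gap"] = np.where(has_lp, gap, np.nan)
    pheno["age_at_lp"] = np.where(has_lp, age + gap, np.nan)
    pheno["tau"] = np.where(has_lp, tau, np.nan)
    pheno["ptau"] = np.where(has_lp, ptau, np.nan)
    pheno["abeta42"] = np.where(has_lp, abeta, np.nan)
    return pheno


def gen_proteins(pheno: pd.DataFrame, config: GeneratorConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Long-format Olink-like panels: ``n_proteins`` analytes per fluid.

    Each analyte carries a fixed loading on standardized total tau; CSF keeps
    the full loading, plasma an attenuated one.  With the default tau law this
    reproduces the tau-mediated structure in which a base proteome scan against
    mosaicism is inflated and a tau-adjusted scan is not.
    """
    lp = pheno[pheno["has_lp"] & pheno["tau"].notna()]
    if lp.empty:
        return pd.DataFrame(columns=["sample", "fluid", "analyte", "level"])
    z_tau = (lp["tau"] - lp["tau"].mean()) / lp["tau"].std()
    lo, hi = config.protein_loading_range
    loadings = rng.uniform(lo, hi, size=config.n_proteins)
    frames = []
    for fluid, scale in (("CSF", 1.0), ("plasma", config.plasma_attenuation)):
        lam = loadings * scale
        noise = rng.normal(0.0, 1.0, size=(len(lp), config.n_proteins))
        levels = z_tau.to_numpy()[:, None] * lam + np.sqrt(1.0 - lam**2) * noise
        frames.append(pd.DataFrame({
            "sample": np.repeat(lp.index.to_numpy(), config.n_proteins),
            "fluid": fluid,
            "analyte": np.tile([f"prot_{j:03d}" for j in range(config.n_proteins)],
                               len(lp)),
            "level": levels.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# planted QC features


def gen_qc_features(truth: pd.DataFrame, config: GeneratorConfig,
                    rng: np.random.Generator
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-sample QC metrics with planted violations, kinship pairs and PCs.

    Returns (sample_stats, kinship_pairs, pcs, truth-with-planted-flags);
    computed for the whole genotyped cohort (PCs are genotype-derived and women
    need them for the instrument analyses).
    """
    n = len(truth)
    idx = truth.index
    low_call = rng.random(n) < config.rate_low_call
    high_het = rng.random(n) < config.rate_excess_het
    out_pc = rng.random(n) < config.rate_ancestry_outlier

    call_rate = rng.uniform(0.975, 0.999, size=n)
    call_rate[low_call] = rng.uniform(0.90, 0.969, size=int(low_call.sum()))
    het = rng.normal(0.30, 0.004, size=n)
    het[high_het] = rng.normal(0.33, 0.004, size=int(high_het.sum()))

    pcs = pd.DataFrame(rng.normal(0.0, 1.0, size=(n, 2)), index=idx,
                       columns=["PC1", "PC2"])
    signs = np.where(rng.random(int(out_pc.sum())) < 0.5, -8.0, 8.0)
    pcs.loc[out_pc, "PC1"] = signs

    n_pairs = int(round(config.rate_related * n / 2))
    related = np.zeros(n, bool)
    pairs = []
    if n_pairs:
        chosen = rng.choice(np.where(~low_call)[0], size=2 * n_pairs, replace=False)
        related[chosen] = True
        kin = rng.uniform(0.06, 0.25, size=n_pairs)
        for k in range(n_pairs):
            pairs.append((idx[chosen[2 * k]], idx[chosen[2 * k + 1]], kin[k]))
    kinship = pd.DataFrame(pairs, columns=["id1", "id2", "kinship"])

    stats = pd.DataFrame({
        "call_rate": call_rate,
        "het_rate": het,
        "chromosomopathy": truth.get("trisomy21", pd.Series(False, index=idx)),
    }, index=idx)
    truth = truth.copy()
    truth["planted_low_call"] = low_call
    truth["planted_excess_het"] = high_het
    truth["planted_ancestry"] = out_pc
    truth["planted_related"] = related
    return stats, kinship, pcs, truth


# ---------------------------------------------------------------------------
# whole-cohort orchestration


@dataclass
class SyntheticCohort:
    """Everything one pipeline run consumes, plus the planted ground truth."""

    config: GeneratorConfig
    truth: pd.DataFrame
    weights: pd.DataFrame
    dosages: pd.DataFrame
    intensities: IntensityData           # reported-male array samples only
    sample_stats: pd.DataFrame
    kinship: pd.DataFrame
    pcs: pd.DataFrame
    phenotypes: pd.DataFrame
    proteins: pd.DataFrame

    @property
    def males(self) -> pd.Index:
        return self.intensities.samples

    def write(self, out_dir, *, include_intensities: bool = True) -> dict[str, str]:
        """Write the generator outputs as TSVs; returns {name: path}."""
        import os
        os.makedirs(out_dir, exist_ok=True)
        paths = {}

        def _w(name, df, index):
            p = os.path.join(out_dir, f"{name}.tsv")
            df.to_csv(p, sep="\t", index=index)
            paths[name] = p

        _w("truth", self.truth, True)
        _w("weights", self.weights, False)
        _w("dosages", self.dosages, True)
        _w("sample_stats", self.sample_stats, True)
        _w("kinship", self.kinship, False)
        _w("pcs", self.pcs, True)
        _w("phenotypes", self.phenotypes, True)
        _w("proteins", self.proteins, False)
        if include_intensities:
            _w("intensities", self.intensities.to_long(), False)
        return paths


def generate_cohort(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort under the configured study conditions."""
    cfg = config or GeneratorConfig()
    rngs = _rngs(cfg.seed)
    n = cfg.n_samples
    idx = pd.Index([f"S{i:06d}" for i in range(n)], name="sample")

    r = rngs["liability"]
    sex = np.where(r.random(n) < cfg.sex_ratio, "M", "F")
    age = r.uniform(cfg.age_range[0], cfg.age_range[1], size=n)

    # karyotype anomalies among reported males
    karyo = np.where(sex == "M", "XY", "XX")
    male_mask = sex == "M"
    u = r.random(n)
    karyo[male_mask & (u < cfg.rate_xx_mislabel)] = "XX"
    karyo[male_mask & (u >= cfg.rate_xx_mislabel)
          & (u < cfg.rate_xx_mislabel + cfg.rate_xxy)] = "XXY"
    karyo[male_mask & (u >= cfg.rate_xx_mislabel + cfg.rate_xxy)
          & (u < cfg.rate_xx_mislabel + cfg.rate_xxy + cfg.rate_xyy)] = "XYY"
    trisomy = male_mask & (karyo == "XY") & (r.random(n) < cfg.rate_trisomy)
    par1_loh = male_mask & (karyo == "XY") & (r.random(n) < cfg.rate_par1_loh)

    dosages, weights = gen_genotypes(cfg, rngs["genotypes"], sample_ids=idx)
    prs = standardized_prs(dosages, weights["beta"].to_numpy())

    truth = pd.DataFrame({"sex": sex, "age": age, "karyotype": karyo,
                          "trisomy21": trisomy, "planted_par1_loh": par1_loh,
                          "prs_true": prs}, index=idx)

    eligible = pd.Series(male_mask & (karyo == "XY"), index=idx)
    loy = gen_mloy_status(cfg, prs, truth["age"], eligible, rngs["fractions"])
    truth = truth.join(loy)

    male_truth = truth[truth["sex"] == "M"]
    intensities = gen_intensities(male_truth, cfg, rngs["intensities"])

    stats, kinship, pcs, truth = gen_qc_features(truth, cfg, rngs["qc"])
    stats["lrr_sd"] = intensities.autosomal_lrr_sd().reindex(stats.index)

    pheno = gen_phenotypes(truth, cfg, rngs["phenotypes"])
    pheno = pheno.join(pcs)
    proteins = gen_proteins(pheno, cfg, rngs["proteins"])

    return SyntheticCohort(config=cfg, truth=truth, weights=weights,
                           dosages=dosages, intensities=intensities,
                           sample_stats=stats, kinship=kinship, pcs=pcs,
                           phenotypes=pheno, proteins=proteins)
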