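"""End-to-end orchestration: simulate -> QC -> call mLOY -> PRS -> MR -> biomarkers.

``run_all`` executes every stage on a synthetic cohort and writes a results
bundle (TSV tables plus a JSON run manifest with file digests and the QC
funnel).  All randomness derives from ``config.generator.seed``, and re-running
with the same configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .association import distribution_tests, harmonise_mlrry, run_mr_suite
from .biomarkers import apply_panel_filters, fit_biomarker, inflation_lambda, proteome_scan
from .calling import compute_par1_bdev, flag_anomalies, split_batches_and_check
from .calling import compute_mlrry
from .config import PipelineConfig
from .io_qc import classify_sex_karyotype, qc_filter_samples
from .prs import cohort_variant_stats, compute_prs, filter_instrument_variants
from .synthetic import generate_cohort


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and a partial manifest."""

    def __init__(self, stage: str, cause: Exception, manifest: "RunManifest"):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    seed: int
    config: dict
    version: str = __version__
    funnel: list[tuple[str, int]] = field(default_factory=list)
    counts: dict = field(default_factory=dict)
    digests: dict = field(default_factory=dict)
    completed_stages: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True,
                      default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig | None = None, out_dir: str = "results",
            *, seed: int | None = None) -> RunManifest:
    """Run every stage on a synthetic cohort and write the results bundle.

    ``seed`` overrides ``config.generator.seed`` when given.  Any stage error
    aborts with a :class:`StageError` naming the stage and carrying the partial
    manifest.
    """
    cfg = config or PipelineConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, generator=dataclasses.replace(
            cfg.generator, seed=int(seed)))
    os.makedirs(out_dir, exist_ok=True)
    manifest = RunManifest(seed=cfg.generator.seed, config=cfg.to_dict())
    outputs: dict[str, pd.DataFrame] = {}
    stage = "simulate"
    try:
        cohort = generate_cohort(cfg.generator)
        manifest.counts["n_samples"] = len(cohort.truth)
        manifest.counts["n_reported_males"] = int(len(cohort.intensities.samples))
        manifest.completed_stages.append(stage)

        # ---- sample QC on the reported-male array cohort -------------------
        stage = "qc"
        males = cohort.intensities.samples
        karyo = classify_sex_karyotype(
            cohort.intensities.mean_lrr("X"), cohort.intensities.mean_lrr("MSY"),
            gain=cfg.generator.lrr_gain * cfg.generator.compression,
            floor=cfg.generator.lrr_floor,
            min_margin=cfg.qc.karyotype_min_margin)
        stats = cohort.sample_stats.loc[males].copy()
        stats["karyotype"] = karyo["karyotype"].to_numpy()
        kin = cohort.kinship
        kin = kin[kin["id1"].isin(males) & kin["id2"].isin(males)]
        report = qc_filter_samples(stats, kin, cohort.pcs.loc[males], cfg.qc)
        outputs["qc_report"] = report.table.reset_index()
        manifest.funnel = list(report.funnel)
        survivors = report.survivors
        manifest.counts["n_qc_survivors"] = int(len(survivors))
        manifest.completed_stages.append(stage)

        # ---- mLOY calling ---------------------------------------------------
        stage = "call_mloy"
        sub = cohort.intensities.subset(survivors)
        cal = cfg.calling
        mlrry = compute_mlrry(sub, min_msy_probes=cal.min_msy_probes,
                              min_auto_probes=cal.min_auto_probes, trim=cal.trim)
        batches = split_batches_and_check(
            mlrry, n_batches=cal.n_batches, seed=cfg.generator.seed,
            quantile=cal.quantile, min_cohort=cal.min_cohort, method=cal.method)
        bdev = compute_par1_bdev(sub, het_window=cal.het_window,
                                 min_het_snps=cal.min_het_snps)
        anomalies = flag_anomalies(mlrry, bdev["bdev"], k=cal.bdev_k,
                                   partial_band=cal.partial_band)
        mloy = pd.concat([batches.table, bdev, anomalies], axis=1)
        outputs["mloy"] = mloy.reset_index()
        outputs["batch_check"] = pd.DataFrame([{
            "n_batches": cal.n_batches, "ks_stat": batches.ks_stat,
            "ks_p": batches.ks_p, "proportion_p": batches.proportion_p,
            **{f"threshold_batch{b}": t for b, t in batches.thresholds.items()}}])
        clean = mloy[~mloy["anomaly"]]
        manifest.counts["n_post_anomaly"] = int(len(clean))
        manifest.counts["n_mloy_calls"] = int(clean["mloy_call"].sum())
        manifest.completed_stages.append(stage)

        # ---- instrument -----------------------------------------------------
        stage = "prs"
        vstats = cohort_variant_stats(cohort.dosages, cohort.weights)
        filt = filter_instrument_variants(cohort.weights, vstats,
                                          min_maf=cfg.instrument.min_maf,
                                          min_r2=cfg.instrument.min_r2)
        prs_res = compute_prs(cohort.dosages, filt.kept)
        outputs["prs"] = prs_res.table.reset_index()
        outputs["instrument_exclusions"] = filt.exclusions
        manifest.counts["n_instrument_variants"] = int(len(filt.kept))
        manifest.completed_stages.append(stage)

        # ---- association grid ----------------------------------------------
        stage = "association"
        pheno = cohort.phenotypes
        mr = run_mr_suite(pheno, prs_res.std, clean[["mlrry", "mloy_call"]],
                          cfg.assoc)
        outputs["assoc_results"] = mr
        cc_men = pheno.loc[pheno.index.isin(clean.index)
                           & pheno["ad_status"].notna()]
        dist_rows = []
        if cc_men["ad_status"].nunique() == 2:
            dt = distribution_tests(clean["mlrry"].reindex(cc_men.index),
                                    cc_men["ad_status"], cc_men["age"],
                                    cc_men["apoe"])
            dist_rows.append({"comparison": "mlrry_by_ad_status",
                              "ks_stat": dt.ks_stat, "ks_p": dt.ks_p,
                              "ancova_f": dt.ancova_f, "ancova_p": dt.ancova_p,
                              "n": dt.n})
        outputs["distribution_tests"] = pd.DataFrame(dist_rows)
        manifest.completed_stages.append(stage)

        # ---- biomarkers and proteome ---------------------------------------
        stage = "biomarkers"
        bio = pheno[pheno["has_lp"]].copy()
        bio["mlrry_neg"] = harmonise_mlrry(clean["mlrry"]).reindex(bio.index)
        bio = bio[bio["mlrry_neg"].notna()]
        bio = apply_panel_filters(bio, max_gap_years=cfg.biomarker.max_gap_years,
                                  lp_age_window=cfg.biomarker.lp_age_window)
        core_rows = []
        for analyte in ("abeta42", "ptau", "tau"):
            try:
                bm = fit_biomarker(bio, analyte)
            except Exception as exc:        # zero-variance / empty group
                core_rows.append({"analyte": analyte, "stratum": "META",
                                  "note": str(exc)})
                continue
            for g, r in bm.groups.items():
                row = r.to_row()
                row["analyte"] = analyte
                core_rows.append(row)
            lo, hi = bm.meta.ci
            core_rows.append({"analyte": analyte, "model": "meta",
                              "stratum": "META", "effect": bm.meta.effect,
                              "se": bm.meta.se, "p": bm.meta.p,
                              "ci_low": lo, "ci_high": hi, "n": bm.meta.n})
        outputs["biomarker_core"] = pd.DataFrame(core_rows)

        scan_frames, lam_rows = [], []
        panel = cohort.proteins
        panel = panel[panel["sample"].isin(bio.index[bio["syndrome"] == "MCI"])]
        if len(panel):
            covs = bio[["age_at_lp", "lp_gap", "apoe"]]
            for adjust in (False, True):
                scan = proteome_scan(panel, bio["mlrry_neg"], covs,
                                     tau=bio["tau"], adjust_tau=adjust,
                                     min_obs=cfg.biomarker.min_obs)
                scan_frames.append(scan)
                for fluid, sub_scan in scan.groupby("fluid"):
                    z = sub_scan["z"].dropna()
                    if len(z) >= 20:
                        lam_rows.append({
                            "fluid": fluid,
                            "variant": "tau_adjusted" if adjust else "base",
                            "lambda": inflation_lambda(z),
                            "n_analytes": int(len(z))})
        outputs["proteome_scan"] = (pd.concat(scan_frames, ignore_index=True)
                                    if scan_frames else pd.DataFrame())
        outputs["inflation"] = pd.DataFrame(lam_rows)
        manifest.completed_stages.append(stage)
    except Exception as exc:
        raise StageError(stage, exc, manifest) from exc

    # ---- write the bundle ---------------------------------------------------
    funnel_df = pd.DataFrame(manifest.funnel, columns=["stage", "n"])
    funnel_df = pd.concat([funnel_df, pd.DataFrame(
        [("anomaly_screen", manifest.counts["n_post_anomaly"])],
        columns=["stage", "n"])], ignore_index=True)
    outputs["funnel"] = funnel_df
    cfg.to_yaml(os.path.join(out_dir, "config.yaml"))
    manifest.digests["config.yaml"] = _sha256(os.path.join(out_dir, "config.yaml"))
    for name, df in outputs.items():
        path = os.path.join(out_dir, f"{name}.tsv")
        df.to_csv(path, sep="\t", index=False)
        manifest.digests[f"{name}.tsv"] = _sha256(path)
    manifest.to_json(os.path.join(out_dir, "manifest.json"))
    return manifest
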