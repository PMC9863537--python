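"""Sex- and age-stratified Mendelian-randomisation association models.

This module fits the study's model grid: logistic case-control regressions of
AD status, Cox proportional-hazards models of MCI phenoconversion (to all-cause
dementia and to AD), distribution tests (two-sample KS and ANCOVA) for the
mosaicism statistic, and fixed-effect inverse-variance-weighted (IVW)
meta-analysis across strata.

Conventions shared by every model:

* effect directions are harmonised by multiplying mLRR-Y by -1 (lower mLRR-Y
  means more loss-of-Y, so the flipped variable increases with mosaicism);
* APOE genotype enters as a -2..+2 score (+1 per e4 allele, -1 per e2 allele);
* population structure is adjusted with only those principal components that
  are themselves associated with the outcome;
* all tests are two-sided, and confidence intervals are effect +/- 1.96 SE on
  the log-odds / log-hazard / linear scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats as sps
from statsmodels.stats.anova import anova_lm

from .config import AssocConfig

Z95 = 1.96


class AssociationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# result containers


@dataclass
class AssocResult:
    """One fitted effect: estimate on its log/linear scale plus uncertainty."""

    model: str                       # "logistic" | "cox" | "linear" | "meta"
    exposure: str
    effect: float                    # log-OR, log-HR, or beta
    se: float
    p: float
    n: int
    stratum: str = ""
    covariates: tuple[str, ...] = ()
    scale: str = "log_or"            # "log_or" | "log_hr" | "beta"
    n_events: int | None = None
    note: str = ""

    @property
    def ci(self) -> tuple[float, float]:
        return (self.effect - Z95 * self.se, self.effect + Z95 * self.se)

    @property
    def ratio(self) -> float:
        """OR or HR (exp of the effect); meaningless for linear scale."""
        return float(np.exp(self.effect))

    def to_row(self) -> dict:
        lo, hi = self.ci
        row = {"model": self.model, "exposure": self.exposure, "stratum": self.stratum,
               "effect": self.effect, "se": self.se, "p": self.p, "n": self.n,
               "ci_low": lo, "ci_high": hi, "scale": self.scale,
               "covariates": ",".join(self.covariates), "note": self.note}
        if self.scale in ("log_or", "log_hr"):
            with np.errstate(over="ignore"):
                row["ratio"] = self.ratio
                row["ratio_ci_low"] = float(np.exp(lo))
                row["ratio_ci_high"] = float(np.exp(hi))
        return row


@dataclass
class MetaResult:
    """Fixed-effect IVW pool of stratum estimates."""

    effect: float
    se: float
    p: float
    weights: tuple[float, ...]
    q_het: float                    # Cochran's Q
    q_p: float
    n: int
    scale: str = "log_or"

    @property
    def ci(self) -> tuple[float, float]:
        return (self.effect - Z95 * self.se, self.effect + Z95 * self.se)


@dataclass
class DistributionTests:
    ks_stat: float
    ks_p: float
    ancova_f: float
    ancova_p: float
    n: int


# ---------------------------------------------------------------------------
# APOE coding

_APOE_ALLELES = {"e2": -1, "e3": 0, "e4": +1}


def apoe_score(genotype) -> int:
    """APOE genotype as an integer score in [-2, 2]: count(e4) - count(e2).

    Accepts a pair of alleles (("e2", "e4")) or a slash string ("E3/E4").
    """
    if isinstance(genotype, str):
        alleles = genotype.replace("ε", "e").lower().split("/")
    else:
        alleles = [str(a).replace("ε", "e").lower() for a in genotype]
    if len(alleles) != 2:
        raise ValueError(f"APOE genotype needs two alleles, got {genotype!r}")
    try:
        return sum(_APOE_ALLELES[a] for a in alleles)
    except KeyError as exc:
        raise ValueError(f"unknown APOE allele {exc.args[0]!r}") from exc


# ---------------------------------------------------------------------------
# model fits


def _design(df: pd.DataFrame, cols) -> pd.DataFrame:
    x = df[list(cols)].astype(float)
    return sm.add_constant(x, has_constant="add")


def fit_case_control(df: pd.DataFrame, exposure: str, covariates=(),
                     *, outcome: str = "ad_status", stratum: str = "",
                     model_label: str = "logistic") -> AssocResult:
    """Maximum-likelihood logistic regression of a binary outcome on an exposure.

    ``df`` must already hold the sign-harmonised exposure column.  Suspected
    (quasi-)separation is flagged in ``note`` rather than silently returned.
    """
    use = df[[outcome, exposure, *covariates]].dropna()
    if use.empty or use[outcome].nunique() < 2:
        raise AssociationError(f"degenerate outcome in stratum {stratum!r}")
    y = use[outcome].astype(float)
    X = _design(use, [exposure, *covariates])
    note = ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception as exc:                      # includes PerfectSeparationError
            raise AssociationError(f"logistic fit failed: {exc}") from exc
    if not converged or abs(res.params[exposure]) > 15 or res.bse[exposure] > 50:
        note = "separation_suspected"
    return AssocResult(model=model_label, exposure=exposure,
                       effect=float(res.params[exposure]), se=float(res.bse[exposure]),
                       p=float(res.pvalues[exposure]), n=int(len(use)),
                       stratum=stratum, covariates=tuple(covariates),
                       scale="log_or", note=note)


def fit_conversion(df: pd.DataFrame, exposure: str, covariates=(),
                   *, time_col: str = "time", event_col: str = "event",
                   stratum: str = "") -> AssocResult:
    """Cox proportional-hazards model of phenoconversion (Breslow ties).

    ``df`` carries follow-up times (> 0), boolean event indicators and the
    exposure/covariate columns.  Selecting conversion to AD versus all-cause
    dementia is done upstream by passing the corresponding event column.
    """
    cols = [time_col, event_col, exposure, *covariates]
    use = df[cols].dropna().astype(float)
    if (use[time_col] <= 0).any():
        raise AssociationError("follow-up times must be positive")
    n_events = int(use[event_col].sum())
    if n_events == 0:
        raise AssociationError(f"no events in stratum {stratum!r}")
    if use[exposure].nunique() < 2:
        raise AssociationError(f"zero variance in exposure in stratum {stratum!r}")
    kept = [exposure] + [c for c in covariates if use[c].nunique() > 1]
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(use[[time_col, event_col, *kept]], duration_col=time_col,
                    event_col=event_col)
    except Exception as exc:
        raise AssociationError(f"cox fit failed: {exc}") from exc
    eff = float(cph.params_[exposure])
    se = float(cph.standard_errors_[exposure])
    p = float(2.0 * sps.norm.sf(abs(eff / se)))
    return AssocResult(model="cox", exposure=exposure, effect=eff, se=se, p=p,
                       n=int(len(use)), n_events=n_events, stratum=stratum,
                       covariates=tuple(kept[1:]), scale="log_hr")


def distribution_tests(values: pd.Series, groups: pd.Series,
                       age: pd.Series, apoe: pd.Series) -> DistributionTests:
    """Unadjusted two-sample KS plus age/APOE-adjusted ANCOVA for a 2-group split.

    The ANCOVA F is the type-II F for the group factor in a linear model of
    ``values`` on group + age + APOE.
    """
    df = pd.DataFrame({"y": values, "g": groups, "age": age, "apoe": apoe}).dropna()
    levels = df["g"].unique()
    if len(levels) < 2:
        raise AssociationError("need >= 2 groups")
    counts = df["g"].value_counts()
    if (counts < 3).any():
        raise AssociationError(f"group with < 3 samples: {counts.to_dict()}")
    a = df.loc[df["g"] == levels[0], "y"].to_numpy()
    b = df.loc[df["g"] == levels[1], "y"].to_numpy()
    ks = sps.ks_2samp(a, b)
    ols = sm.OLS.from_formula("y ~ C(g) + age + apoe", data=df).fit()
    tab = anova_lm(ols, typ=2)
    return DistributionTests(ks_stat=float(ks.statistic), ks_p=float(ks.pvalue),
                             ancova_f=float(tab.loc["C(g)", "F"]),
                             ancova_p=float(tab.loc["C(g)", "PR(>F)"]),
                             n=int(len(df)))


def ivw_meta(results: list[AssocResult]) -> MetaResult:
    """Fixed-effect inverse-variance-weighted pooling of stratum estimates.

    pooled = sum(w_i b_i) / sum(w_i) with w_i = 1/SE_i^2 and
    pooled SE = 1/sqrt(sum w_i); heterogeneity reported as Cochran's Q.
    """
    if len(results) < 2:
        raise AssociationError("IVW meta-analysis needs >= 2 strata")
    scales = {r.scale for r in results}
    if len(scales) > 1:
        raise AssociationError(f"mixed effect scales: {scales}")
    beta = np.array([r.effect for r in results], float)
    se = np.array([r.se for r in results], float)
    if (se <= 0).any() or not np.isfinite(se).all():
        raise AssociationError("non-positive or non-finite SE in meta input")
    w = 1.0 / se**2
    pooled = float(np.sum(w * beta) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    z = pooled / pooled_se
    q = float(np.sum(w * (beta - pooled) ** 2))
    q_p = float(sps.chi2.sf(q, df=len(results) - 1))
    return MetaResult(effect=pooled, se=pooled_se,
                      p=float(2.0 * sps.norm.sf(abs(z))),
                      weights=tuple(w), q_het=q, q_p=q_p,
                      n=int(sum(r.n for r in results)), scale=scales.pop())


def select_pcs(pcs: pd.DataFrame, outcome: pd.Series, *, kind: str = "binary",
               time: pd.Series | None = None, alpha: float = 0.05) -> list[str]:
    """Keep the PCs marginally associated (p < alpha) with the model's outcome.

    ``kind`` is "binary" (logistic screen), "survival" (univariate Cox; pass
    follow-up ``time`` and event indicator as ``outcome``) or "continuous"
    (OLS).  Returns the selected column names in input order.
    """
    if kind not in ("binary", "survival", "continuous"):
        raise ValueError(f"unknown outcome kind {kind!r}")
    selected = []
    for col in pcs.columns:
        df = pd.DataFrame({"pc": pcs[col], "y": outcome})
        if time is not None:
            df["t"] = time
        df = df.dropna()
        if df["pc"].nunique() < 2:
            continue
        try:
            if kind == "binary":
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = sm.Logit(df["y"].astype(float),
                                       sm.add_constant(df[["pc"]].astype(float))
                                       ).fit(disp=0)
                    p = float(res.pvalues["pc"])
                except np.linalg.LinAlgError:
                    p = np.nan
                if not np.isfinite(p):   # separation: fall back to a mean test
                    g0 = df.loc[df["y"] == 0, "pc"]
                    g1 = df.loc[df["y"] != 0, "pc"]
                    p = float(sps.ttest_ind(g0, g1, equal_var=False).pvalue)
            elif kind == "survival":
                cph = CoxPHFitter()
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cph.fit(df.rename(columns={"t": "time", "y": "event"})
                            [["time", "event", "pc"]], "time", "event")
                z = float(cph.params_["pc"] / cph.standard_errors_["pc"])
                p = float(2.0 * sps.norm.sf(abs(z)))
            else:
                res = sm.OLS(df["y"].astype(float),
                             sm.add_constant(df[["pc"]].astype(float))).fit()
                p = float(res.pvalues["pc"])
        except Exception:        # unfit screen (separation, singularity): skip PC
            continue
        if p < alpha:
            selected.append(col)
    return selected


# ---------------------------------------------------------------------------
# the full Mendelian-randomisation grid


EXPOSURES = ("mlrry", "mloy_call", "prs")
OUTCOMES = ("ad_status", "mci_to_dementia", "mci_to_ad")


def harmonise_mlrry(mlrry: pd.Series) -> pd.Series:
    """Sign-harmonised mosaicism exposure: (-1) * mLRR-Y, increasing with LOY."""
    return (-1.0 * mlrry).rename("mlrry_neg")


def run_mr_suite(pheno: pd.DataFrame, prs_std: pd.Series | None = None,
                 mloy: pd.DataFrame | None = None,
                 config: AssocConfig | None = None) -> pd.DataFrame:
    """Fit the whole exposure x outcome x stratum grid and return a tidy table.

    Parameters
    ----------
    pheno
        Sample-indexed phenotypes: sex ('M'/'F'), age, apoe, ad_status
        (0/1/NaN for the case-control subset), is_mci, time, event,
        event_ad, cohort, and PC columns (PC1, PC2, ...).
    prs_std
        Standardized instrument (SD units), indexed by sample.
    mloy
        mLOY phenotypes, sample-indexed with ``mlrry`` and ``mloy_call``
        columns (typically males surviving QC and anomaly screening).

    Strata are all / men / women plus the configured age bands, with an IVW
    META row over the age bands.  Strata that are empty, or for which an
    exposure is undefined, yield a row with missing estimates and a reason.
    """
    cfg = config or AssocConfig()
    df = pheno.copy()
    if prs_std is not None:
        df["prs"] = prs_std.reindex(df.index)
    if mloy is not None:
        df["mlrry"] = harmonise_mlrry(mloy["mlrry"]).reindex(df.index)
        df["mloy_call"] = mloy["mloy_call"].reindex(df.index).astype(float)
    pc_cols = [c for c in df.columns if c.startswith("PC")]
    lo, hi = cfg.age_window

    strata: list[tuple[str, pd.Series]] = [
        ("all", pd.Series(True, index=df.index)),
        ("men", df["sex"] == "M"),
        ("women", df["sex"] == "F"),
    ]
    band_names = []
    for a, b in cfg.age_bands:
        name = f"{a:g}-{b:g}"
        band_names.append(name)
        strata.append((name, (df["age"] >= a) & (df["age"] < b)))

    rows: list[dict] = []

    def _missing(exposure, outcome, stratum, reason):
        rows.append({"model": "cox" if outcome != "ad_status" else "logistic",
                     "outcome": outcome, "exposure": exposure, "stratum": stratum,
                     "effect": np.nan, "se": np.nan, "p": np.nan, "n": 0,
                     "note": reason})

    for exposure in EXPOSURES:
        if exposure not in df.columns:
            continue
        for outcome in OUTCOMES:
            band_results: list[AssocResult] = []
            for stratum, mask in strata:
                if exposure in ("mlrry", "mloy_call"):
                    mask = mask & (df["sex"] == "M")  # phenotype defined in men only
                    if stratum == "women":
                        _missing(exposure, outcome, stratum,
                                 "mLOY phenotype undefined for women")
                        continue
                sub = df[mask & df[exposure].notna()]
                try:
                    if outcome == "ad_status":
                        sub_cc = sub[sub["ad_status"].notna()]
                        if sub_cc.empty:
                            raise AssociationError("empty stratum")
                        pcs_sel = select_pcs(sub_cc[pc_cols], sub_cc["ad_status"],
                                             kind="binary", alpha=cfg.pc_alpha)
                        covs = ["age", "apoe"] + pcs_sel
                        res = fit_case_control(sub_cc, exposure, covs,
                                               stratum=stratum)
                    else:
                        mci = sub[sub["is_mci"].astype(bool)]
                        if mci.empty:
                            raise AssociationError("empty stratum")
                        ev = "event" if outcome == "mci_to_dementia" else "event_ad"
                        pcs_sel = select_pcs(mci[pc_cols], mci[ev], kind="survival",
                                             time=mci["time"], alpha=cfg.pc_alpha)
                        covs = ["age", "apoe"] + pcs_sel
                        if exposure == "prs" and "cohort" in mci.columns:
                            covs = covs + ["cohort"]
                        res = fit_conversion(mci, exposure, covs, event_col=ev,
                                             stratum=stratum)
                except AssociationError as exc:
                    _missing(exposure, outcome, stratum, str(exc))
                    continue
                row = res.to_row()
                row["outcome"] = outcome
                rows.append(row)
                if stratum in band_names:
                    band_results.append(res)
            if len(band_results) >= 2:
                meta = ivw_meta(band_results)
                z_note = f"Q={meta.q_het:.2f}, p_het={meta.q_p:.3f}"
                rows.append({"model": "meta", "outcome": outcome, "exposure": exposure,
                             "stratum": "META(age-bands)", "effect": meta.effect,
                             "se": meta.se, "p": meta.p, "n": meta.n,
                             "ci_low": meta.ci[0], "ci_high": meta.ci[1],
                             "ratio": float(np.exp(meta.effect)),
                             "scale": meta.scale, "note": z_note})
    out = pd.DataFrame(rows)
    col_order = ["model", "outcome", "exposure", "stratum", "effect", "se", "p",
                 "ci_low", "ci_high", "ratio", "ratio_ci_low", "ratio_ci_high",
                 "n", "scale", "covariates", "note"]
    return out.reindex(columns=[c for c in col_order if c in out.columns])
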