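"""CSF/plasma biomarker regressions and the proteome-wide mosaicism scan.

Core AD biomarkers (Abeta-42, p-tau181, total tau) are regressed on the
sign-harmonised mosaicism statistic within syndrome groups (MCI, dementia) and
pooled by fixed-effect IVW meta-analysis.  The proteome scan runs one linear
model per analyte per fluid, in a base variant and a total-tau-adjusted
variant, reporting z-scores, normal-theory p-values, genomic-control inflation
lambda, and Benjamini-Hochberg FDR q-values within each fluid x variant family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .association import AssocResult, MetaResult, ivw_meta
from .config import BiomarkerConfig

PANEL_COLUMNS = ["sample", "fluid", "analyte", "level"]

#: median of the chi-square distribution with 1 degree of freedom
CHI2_1_MEDIAN = float(sps.chi2.ppf(0.5, df=1))


class BiomarkerError(ValueError):
    pass


@dataclass
class BiomarkerMeta:
    """Per-syndrome-group estimates plus their IVW pool for one analyte."""

    analyte: str
    groups: dict[str, AssocResult]
    meta: MetaResult


def apply_panel_filters(df: pd.DataFrame, *, max_gap_years: float = 5.0,
                        lp_age_window: tuple[float, float] = (65.0, 85.0)) -> pd.DataFrame:
    """Keep samples punctured inside the age window with a DNA-to-LP gap <= 5 years."""
    lo, hi = lp_age_window
    keep = ((df["lp_gap"] <= max_gap_years)
            & (df["age_at_lp"] >= lo) & (df["age_at_lp"] <= hi))
    return df[keep]


def _ols_effect(y: np.ndarray, X: pd.DataFrame) -> tuple[float, float]:
    res = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    return float(res.params.iloc[1]), float(res.bse.iloc[1])


def fit_biomarker(df: pd.DataFrame, level_col: str, *, exposure: str = "mlrry_neg",
                  group_col: str = "syndrome",
                  covariates=("age_at_lp", "lp_gap", "apoe")) -> BiomarkerMeta:
    """Per-syndrome OLS of a biomarker level on the mosaicism exposure, then IVW.

    The exposure column is expected sign-harmonised ((-1) * mLRR-Y).  Raises if
    any group is empty or has a zero-variance exposure.
    """
    results: dict[str, AssocResult] = {}
    for g, sub in df.groupby(group_col, sort=True):
        use = sub[[level_col, exposure, *covariates]].dropna()
        if use.empty:
            raise BiomarkerError(f"group {g!r} is empty")
        if use[exposure].nunique() < 2:
            raise BiomarkerError(f"zero variance in exposure within group {g!r}")
        eff, se = _ols_effect(use[level_col].to_numpy(float),
                              use[[exposure, *covariates]].astype(float))
        z = eff / se
        results[str(g)] = AssocResult(
            model="linear", exposure=exposure, effect=eff, se=se,
            p=float(2.0 * sps.norm.sf(abs(z))), n=int(len(use)),
            stratum=str(g), covariates=tuple(covariates), scale="beta")
    meta = ivw_meta(list(results.values()))
    return BiomarkerMeta(analyte=level_col, groups=results, meta=meta)


def proteome_scan(panel: pd.DataFrame, exposure: pd.Series,
                  covariates: pd.DataFrame, tau: pd.Series | None = None,
                  *, adjust_tau: bool = False, min_obs: int = 10) -> pd.DataFrame:
    """One regression per analyte per fluid of level on the mosaicism exposure.

    Parameters
    ----------
    panel
        Long table (sample, fluid, analyte, level).
    exposure
        Sample-indexed, sign-harmonised (-mLRR-Y).
    covariates
        Sample-indexed adjustment frame (age, DNA-to-LP gap, APOE score).
    tau
        Sample-indexed total tau, required when ``adjust_tau`` is True.

    Returns a ScanResult table (analyte, fluid, n, beta, se, z, p, q, variant)
    with BH q-values computed within each fluid family.  Analytes with fewer
    than ``min_obs`` observations are skipped with a log row (NaN estimates).
    """
    if adjust_tau and tau is None:
        raise BiomarkerError("tau adjustment requested but no tau provided")
    variant = "tau_adjusted" if adjust_tau else "base"
    rows = []
    for (fluid, analyte), sub in panel.groupby(["fluid", "analyte"], sort=True):
        s = sub.set_index("sample")["level"]
        X = covariates.reindex(s.index).copy()
        X.insert(0, "exposure", exposure.reindex(s.index))
        if adjust_tau:
            X["tau"] = tau.reindex(s.index)
        use = pd.concat([s.rename("y"), X], axis=1).dropna()
        if len(use) < min_obs:
            rows.append({"analyte": analyte, "fluid": fluid, "n": len(use),
                         "beta": np.nan, "se": np.nan, "z": np.nan, "p": np.nan,
                         "variant": variant, "note": "skipped: too few observations"})
            continue
        beta, se = _ols_effect(use["y"].to_numpy(float), use.drop(columns="y"))
        z = beta / se
        rows.append({"analyte": analyte, "fluid": fluid, "n": int(len(use)),
                     "beta": beta, "se": se, "z": z,
                     "p": float(2.0 * sps.norm.sf(abs(z))),
                     "variant": variant, "note": ""})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for fluid, idx in out.groupby("fluid").groups.items():
        sel = idx[out.loc[idx, "p"].notna().to_numpy()]
        if len(sel):
            out.loc[sel, "q"] = bh_fdr(out.loc[sel, "p"].to_numpy())
    return out


def inflation_lambda(z_scores, *, min_n: int = 20) -> float:
    """Genomic-control inflation factor: median(z^2) / median(chi^2_1).

    Under the null, z^2 ~ chi^2_1 and lambda ~= 1; systematic inflation of the
    test statistics pushes lambda above 1.
    """
    z = np.asarray(z_scores, float)
    z = z[np.isfinite(z)]
    if len(z) == 0:
        raise BiomarkerError("no z-scores provided")
    if len(z) < min_n:
        raise BiomarkerError(f"need >= {min_n} z-scores, got {len(z)}")
    return float(np.median(z**2) / CHI2_1_MEDIAN)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in the p-value ranks)."""
    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise BiomarkerError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
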