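"""Construction of the autosomal mLOY polygenic instrument (mloy-PRS).

The instrument is the weighted dosage sum PRS_s = sum_v d_{s,v} * beta_v over a
published list of independent autosomal variants, filtered to those usable in
the scoring cohort (present, common, well-imputed, autosomal), and then
standardized to SD = 1 over all scored samples of both sexes.  Being built
from germline genotypes it is age-independent, which is what makes it usable
as a Mendelian-randomisation instrument for the (strongly age-dependent) mLOY
cell phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEX_CHROMS = {"X", "Y", "23", "24", "chrX", "chrY"}


class InstrumentError(ValueError):
    """Raised for unusable instruments (duplicates, empty after filtering...)."""


@dataclass
class FilterResult:
    kept: pd.DataFrame
    exclusions: pd.DataFrame        # variant, reason


@dataclass
class PRSResult:
    """Raw and standardized scores plus a log of per-variant adjustments."""

    table: pd.DataFrame             # sample-indexed: prs_raw, prs_std
    log: list[str] = field(default_factory=list)

    @property
    def raw(self) -> pd.Series:
        return self.table["prs_raw"]

    @property
    def std(self) -> pd.Series:
        return self.table["prs_std"]


def filter_instrument_variants(weights: pd.DataFrame,
                               cohort_stats: pd.DataFrame,
                               *, min_maf: float = 0.01,
                               min_r2: float = 0.3) -> FilterResult:
    """Apply the instrument inclusion filters against cohort variant statistics.

    ``cohort_stats`` is indexed by variant id with columns ``available``
    (bool), ``maf`` (cohort minor-allele frequency) and ``imputation_r2``.
    Variants are kept when available, autosomal, MAF >= ``min_maf`` and
    R^2 >= ``min_r2``; each exclusion logs exactly one reason, checked in the
    order unavailable -> sex chromosome -> rare -> low imputation quality.
    """
    if weights["variant"].duplicated().any():
        dups = weights.loc[weights["variant"].duplicated(), "variant"].tolist()
        raise InstrumentError(f"duplicate variant id(s) in weights: {dups[:5]}")
    stats = cohort_stats.reindex(weights["variant"])
    available = stats["available"].fillna(False).to_numpy(bool)
    maf = stats["maf"].to_numpy(float)
    r2 = stats["imputation_r2"].to_numpy(float)
    on_sex = weights["chrom"].astype(str).isin(SEX_CHROMS).to_numpy()

    reason = np.array([""] * len(weights), dtype=object)
    reason[(reason == "") & ~available] = "unavailable"
    reason[(reason == "") & on_sex] = "sex_chromosome"
    with np.errstate(invalid="ignore"):
        reason[(reason == "") & (maf < min_maf)] = "rare"
        reason[(reason == "") & (r2 < min_r2)] = "low_imputation_quality"

    kept = weights.loc[reason == ""].reset_index(drop=True)
    excl = pd.DataFrame({"variant": weights.loc[reason != "", "variant"].to_numpy(),
                         "reason": reason[reason != ""]})
    return FilterResult(kept=kept, exclusions=excl)


def compute_prs(dosages: pd.DataFrame, weights: pd.DataFrame,
                dosage_alleles: pd.Series | None = None,
                *, standardize: bool = True) -> PRSResult:
    """Score a cohort: raw weighted dosage sum and the standardized instrument.

    Parameters
    ----------
    dosages
        Samples x variants frame of effect-allele dosages in [0, 2].
    weights
        Filtered instrument table (variant, effect_allele, beta, ...).
    dosage_alleles
        Optional per-variant counted allele of the dosage matrix.  Where it
        equals the weight row's ``other_allele`` the dosage is flipped to
        ``2 - d`` (with a log note) so every column counts the effect allele.

    Missing dosages are mean-imputed per variant (logged).  Standardization
    uses the population SD over all scored samples; a zero-variance score is
    flagged in the log and left as NaN rather than raised.
    """
    log: list[str] = []
    if len(weights) == 0:
        raise InstrumentError("empty instrument: no variants left to score")
    missing = [v for v in weights["variant"] if v not in dosages.columns]
    if missing:
        raise InstrumentError(f"variant(s) in weights absent from dosage matrix: "
                              f"{missing[:5]}")
    mat = dosages[list(weights["variant"])].to_numpy(float).copy()
    beta = weights["beta"].to_numpy(float)

    if dosage_alleles is not None:
        counted = dosage_alleles.reindex(weights["variant"])
        flip = (counted.to_numpy() == weights["other_allele"].to_numpy())
        bad = counted.isna() | (~flip & (counted.to_numpy() != weights["effect_allele"].to_numpy()))
        if bad.any():
            raise InstrumentError(
                f"counted allele matches neither allele for variant(s): "
                f"{weights.loc[bad.to_numpy(), 'variant'].tolist()[:5]}")
        if flip.any():
            mat[:, flip] = 2.0 - mat[:, flip]
            for v in weights.loc[flip, "variant"]:
                log.append(f"flipped dosage orientation for {v}")

    nan_mask = np.isnan(mat)
    if nan_mask.any():
        col_means = np.nanmean(mat, axis=0)
        for j in np.where(nan_mask.any(axis=0))[0]:
            n_imp = int(nan_mask[:, j].sum())
            log.append(f"mean-imputed {n_imp} missing dosage(s) for "
                       f"{weights['variant'].iloc[j]}")
            mat[nan_mask[:, j], j] = col_means[j]

    raw = mat @ beta
    sd = raw.std()
    if standardize and sd > 0:
        std = (raw - raw.mean()) / sd
    else:
        std = np.full_like(raw, np.nan)
        if standardize:
            log.append("standardization failed: zero variance in raw PRS")
    table = pd.DataFrame({"prs_raw": raw, "prs_std": std}, index=dosages.index)
    table.index.name = "sample"
    return PRSResult(table=table, log=log)


def cohort_variant_stats(dosages: pd.DataFrame, weights: pd.DataFrame) -> pd.DataFrame:
    """Derive per-variant availability and cohort MAF from a dosage matrix.

    Imputation R^2 is carried over from the weights table (it is a property of
    the cohort's imputation, supplied upstream).
    """
    stats = pd.DataFrame(index=pd.Index(weights["variant"], name="variant"))
    stats["available"] = [v in dosages.columns for v in stats.index]
    freq = pd.Series(
        {v: dosages[v].mean() / 2.0 for v in stats.index if v in dosages.columns})
    maf = np.minimum(freq, 1.0 - freq)
    stats["maf"] = maf.reindex(stats.index)
    stats["imputation_r2"] = weights.set_index("variant")["imputation_r2"]
    return stats
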