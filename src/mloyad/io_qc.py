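"""Tabular IO, validation, sex-karyotype classification and the sample-QC cascade.

The QC cascade applies, in a fixed documented order, the standard array-QC
exclusions used before mosaic loss-of-Y calling:

1. non-XY sex karyotype (XX, XXY, XYY or unclassifiable sex-chromosome dosage)
2. relatedness (kinship above the second-degree threshold; one of each pair kept)
3. genotype call rate (per sample, and per plate where a plate annotation exists)
4. heterozygosity excess (> mean + k*SD of the samples reaching this step)
5. ancestry outliers (> k SD on either of the leading principal components)
6. autosomal chromosomopathy (consumed as a precomputed flag, e.g. trisomy 21)
7. noisy intensities (autosomal LRR SD above threshold)

Each excluded sample records exactly one reason: the first rule it failed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import QCThresholds
from .regions import assign_regions

INTENSITY_COLUMNS = ["sample", "probe", "chrom", "position", "LRR", "BAF"]
WEIGHTS_COLUMNS = ["variant", "chrom", "position", "effect_allele", "other_allele",
                   "beta", "maf", "imputation_r2"]
PHENOTYPE_COLUMNS = ["sample", "sex", "age"]

KARYOTYPES = ("XY", "XX", "XXY", "XYY")


class ValidationError(ValueError):
    """Raised when an input table violates its schema."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class IntensityData:
    """Per-probe LRR/BAF intensities for a cohort, stored as dense matrices.

    ``lrr`` and ``baf`` are (n_samples, n_probes) arrays aligned with
    ``samples`` and ``probes`` (probe, chrom, position, region).
    """

    probes: pd.DataFrame
    samples: pd.Index
    lrr: np.ndarray
    baf: np.ndarray

    def __post_init__(self) -> None:
        n, p = len(self.samples), len(self.probes)
        if self.lrr.shape != (n, p) or self.baf.shape != (n, p):
            raise ValidationError("lrr/baf shapes do not match samples x probes")

    def subset(self, samples) -> "IntensityData":
        """Restrict to the given sample ids (order preserved from ``samples``)."""
        pos = self.samples.get_indexer(pd.Index(samples))
        if (pos < 0).any():
            missing = list(pd.Index(samples)[pos < 0][:5])
            raise ValidationError(f"unknown sample id(s): {missing}")
        return IntensityData(probes=self.probes, samples=pd.Index(samples, name="sample"),
                             lrr=self.lrr[pos], baf=self.baf[pos])

    def region_mask(self, region: str) -> np.ndarray:
        return (self.probes["region"] == region).to_numpy()

    def mean_lrr(self, region: str) -> pd.Series:
        m = self.region_mask(region)
        if not m.any():
            raise ValidationError(f"no probes in region {region!r}")
        return pd.Series(self.lrr[:, m].mean(axis=1), index=self.samples,
                         name=f"mean_lrr_{region.lower()}")

    def autosomal_lrr_sd(self) -> pd.Series:
        m = self.region_mask("AUTO")
        return pd.Series(self.lrr[:, m].std(axis=1, ddof=1), index=self.samples,
                         name="lrr_sd")

    def to_long(self) -> pd.DataFrame:
        n, p = self.lrr.shape
        return pd.DataFrame({
            "sample": np.repeat(np.asarray(self.samples, dtype=object), p),
            "probe": np.tile(self.probes["probe"].to_numpy(), n),
            "chrom": np.tile(self.probes["chrom"].to_numpy(), n),
            "position": np.tile(self.probes["position"].to_numpy(), n),
            "LRR": self.lrr.ravel(),
            "BAF": self.baf.ravel(),
        })

    @classmethod
    def from_long(cls, df: pd.DataFrame, regions: pd.DataFrame | None = None) -> "IntensityData":
        _require_columns(df, INTENSITY_COLUMNS, "intensity table")
        _validate_intensities(df)
        probes = (df[["probe", "chrom", "position"]]
                  .drop_duplicates("probe").reset_index(drop=True))
        probes["region"] = assign_regions(probes["chrom"], probes["position"], regions)
        samples = pd.Index(pd.unique(df["sample"]), name="sample")
        wide_l = df.pivot_table(index="sample", columns="probe", values="LRR", sort=False)
        wide_b = df.pivot_table(index="sample", columns="probe", values="BAF", sort=False)
        wide_l = wide_l.reindex(index=samples, columns=probes["probe"])
        wide_b = wide_b.reindex(index=samples, columns=probes["probe"])
        return cls(probes=probes, samples=samples,
                   lrr=wide_l.to_numpy(float), baf=wide_b.to_numpy(float))


@dataclass
class QCReport:
    """Outcome of the QC cascade: per-sample metrics, exclusions and the funnel."""

    table: pd.DataFrame               # indexed by sample: metrics, excluded, reason
    funnel: list[tuple[str, int]] = field(default_factory=list)

    @property
    def survivors(self) -> pd.Index:
        return self.table.index[~self.table["excluded"]]

    @property
    def exclusions(self) -> pd.Series:
        t = self.table[self.table["excluded"]]
        return t["reason"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# readers / writers


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} is missing column(s): {', '.join(missing)}")


def _validate_intensities(df: pd.DataFrame) -> None:
    bad = df.index[(df["BAF"] < 0) | (df["BAF"] > 1)]
    if len(bad):
        raise ValidationError(f"BAF outside [0, 1] at row(s) {list(bad[:5])}")
    bad = df.index[df["position"] <= 0]
    if len(bad):
        raise ValidationError(f"non-positive position at row(s) {list(bad[:5])}")
    dup = df.duplicated(["sample", "probe"])
    if dup.any():
        raise ValidationError(
            f"duplicate (sample, probe) rows, first at {int(df.index[dup][0])}")


def read_intensities(path, regions: pd.DataFrame | None = None) -> IntensityData:
    """Read a long-format intensity TSV and fold it into matrices."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, INTENSITY_COLUMNS, "intensity table")
    for col in ("position", "LRR", "BAF"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"malformed numeric in column {col!r}: {exc}") from exc
    return IntensityData.from_long(df, regions)


def write_intensities(data: IntensityData, path) -> None:
    data.to_long().to_csv(path, sep="\t", index=False)


def read_weights(path) -> pd.DataFrame:
    """Read an instrument-weights TSV (one row per variant)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, WEIGHTS_COLUMNS, "weights table")
    for col in ("beta", "maf", "imputation_r2"):
        df[col] = pd.to_numeric(df[col])
    if not np.isfinite(df["beta"]).all():
        raise ValidationError("non-finite beta in weights table")
    if (df["effect_allele"] == df["other_allele"]).any():
        raise ValidationError("effect and other allele identical for some variant")
    if df["variant"].duplicated().any():
        dups = df.loc[df["variant"].duplicated(), "variant"].tolist()
        raise ValidationError(f"duplicate variant id(s): {dups[:5]}")
    return df


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype TSV; unknown columns are preserved."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, PHENOTYPE_COLUMNS, "phenotype table")
    df["age"] = pd.to_numeric(df["age"])
    bad = ~df["sex"].isin(["M", "F"])
    if bad.any():
        raise ValidationError(f"sex must be 'M'/'F'; bad row(s) {list(df.index[bad][:5])}")
    return df


def read_dosages(path) -> pd.DataFrame:
    """Read a samples x variants dosage TSV (values in [0, 2], first column = sample)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy(float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 2:
        raise ValidationError("dosages must lie in [0, 2]")
    return df


# ---------------------------------------------------------------------------
# sex-karyotype classification


def karyotype_centroids(gain: float = 0.55, floor: float = -3.0) -> dict[str, tuple[float, float]]:
    """(mean LRR-X, mean LRR-Y) centroids under the log2-copy-ratio convention.

    Reference is XY (one X, one Y) so XY sits at the origin; one extra copy
    shows as ``gain`` and an absent chromosome as the background ``floor``.
    """
    return {"XY": (0.0, 0.0), "XX": (gain, floor), "XXY": (gain, 0.0), "XYY": (0.0, gain)}


def classify_sex_karyotype(mean_lrr_x, mean_lrr_y, *, gain: float = 0.55,
                           floor: float = -3.0, min_margin: float = 0.10) -> pd.DataFrame:
    """Nearest-centroid sex-karyotype call in (mean LRR-X, mean LRR-Y) space.

    Returns a frame with columns ``karyotype``, ``distance`` (to the winning
    centroid) and ``margin`` (runner-up minus winner); calls with margin below
    ``min_margin`` become ``"unclassified"``.
    """
    x = np.atleast_1d(np.asarray(mean_lrr_x, float))
    y = np.atleast_1d(np.asarray(mean_lrr_y, float))
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("mean LRR-X / LRR-Y must be finite")
    cents = karyotype_centroids(gain, floor)
    labels = list(cents)
    d = np.stack([np.hypot(x - cx, y - cy) for cx, cy in cents.values()], axis=1)
    order = np.argsort(d, axis=1)
    best, second = order[:, 0], order[:, 1]
    rows = np.arange(len(x))
    margin = d[rows, second] - d[rows, best]
    karyo = np.array(labels, dtype=object)[best]
    karyo[margin < min_margin] = "unclassified"
    index = mean_lrr_x.index if isinstance(mean_lrr_x, pd.Series) else None
    return pd.DataFrame({"karyotype": karyo, "distance": d[rows, best], "margin": margin},
                        index=index)


# ---------------------------------------------------------------------------
# QC cascade

_STAGES = ("karyotype", "relatedness", "call_rate", "heterozygosity",
           "ancestry", "chromosomopathy", "lrr_sd")


def qc_filter_samples(sample_stats: pd.DataFrame,
                      kinship_pairs: pd.DataFrame | None = None,
                      pcs: pd.DataFrame | None = None,
                      thresholds: QCThresholds | None = None) -> QCReport:
    """Apply the sample-QC cascade and report first-failure reasons.

    Parameters
    ----------
    sample_stats
        Indexed by sample id; requires ``call_rate``, ``het_rate``, ``lrr_sd``
        and ``karyotype``; optional ``plate_call_rate`` and ``chromosomopathy``.
    kinship_pairs
        Long table (id1, id2, kinship); pairs above the threshold drop the
        member with the lower call rate (tie: the lexicographically later id).
    pcs
        Indexed by sample id, columns = principal components (leading first).
    """
    thr = thresholds or QCThresholds()
    stats = sample_stats.copy()
    for col in ("call_rate", "het_rate", "lrr_sd", "karyotype"):
        if col not in stats.columns:
            raise ValidationError(f"sample_stats is missing column {col!r}")
    reason = pd.Series("", index=stats.index, dtype=object)
    alive = pd.Series(True, index=stats.index)
    funnel = [("input", int(alive.sum()))]

    def _exclude(mask: pd.Series, label: str) -> None:
        newly = mask & alive
        reason[newly] = label
        alive[newly] = False

    # 1. sex karyotype
    _exclude(stats["karyotype"] != "XY", "non_xy_karyotype")
    funnel.append(("karyotype", int(alive.sum())))

    # 2. relatedness
    if kinship_pairs is not None and len(kinship_pairs):
        kp = kinship_pairs.copy()
        missing = set(kp["id1"]).union(kp["id2"]) - set(stats.index)
        if missing:
            raise ValidationError(f"kinship matrix references unknown sample(s): "
                                  f"{sorted(missing)[:5]}")
        kp = kp[kp["kinship"] > thr.kinship]
        # normalise pair order, then process deterministically
        a = kp[["id1", "id2"]].min(axis=1)
        b = kp[["id1", "id2"]].max(axis=1)
        for i, j in sorted(zip(a, b)):
            if not (alive.get(i, False) and alive.get(j, False)):
                continue
            ci, cj = stats.at[i, "call_rate"], stats.at[j, "call_rate"]
            # drop the lower call rate; on a tie the lexicographically later id
            drop = i if ci < cj else (j if cj < ci else max(i, j))
            _exclude(pd.Series(stats.index == drop, index=stats.index), "relatedness")
    funnel.append(("relatedness", int(alive.sum())))

    # 3. call rate (sample, and plate annotation when provided)
    _exclude(stats["call_rate"] <= thr.min_call_rate, "low_call_rate")
    if "plate_call_rate" in stats.columns:
        _exclude(stats["plate_call_rate"] <= thr.min_plate_call_rate, "low_plate_call_rate")
    funnel.append(("call_rate", int(alive.sum())))

    # 4. heterozygosity excess, statistics over samples entering this step
    het = stats.loc[alive, "het_rate"]
    cut = het.mean() + thr.het_sd * het.std(ddof=1)
    _exclude(stats["het_rate"] > cut, "excess_heterozygosity")
    funnel.append(("heterozygosity", int(alive.sum())))

    # 5. ancestry outliers on the leading PCs; the reference scale is a robust
    #    (median/MAD) SD so the outliers themselves cannot mask the rule
    if pcs is not None and len(pcs.columns):
        use = pcs.columns[: thr.n_ancestry_pcs]
        sub = pcs.reindex(stats.index)
        ref = sub.loc[alive, use]
        out = pd.Series(False, index=stats.index)
        for c in use:
            center = ref[c].median()
            sd = 1.4826 * (ref[c] - center).abs().median()
            out |= (sub[c] - center).abs() > thr.ancestry_sd * sd
        _exclude(out.fillna(False), "ancestry_outlier")
    funnel.append(("ancestry", int(alive.sum())))

    # 6. autosomal chromosomopathy flag
    if "chromosomopathy" in stats.columns:
        _exclude(stats["chromosomopathy"].astype(bool), "chromosomopathy")
    funnel.append(("chromosomopathy", int(alive.sum())))

    # 7. noisy intensities
    _exclude(stats["lrr_sd"] > thr.max_lrr_sd, "high_lrr_sd")
    funnel.append(("lrr_sd", int(alive.sum())))

    table = stats.copy()
    table["excluded"] = ~alive
    table["reason"] = reason
    return QCReport(table=table, funnel=funnel)
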