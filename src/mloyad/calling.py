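"""mLRR-Y computation, PAR1 B-deviation, and threshold-based mLOY calling.

The mosaicism summary statistic is

    mLRR-Y = mean LRR over MSY probes  -  5%-trimmed mean LRR over autosomes,

where MSY is the male-specific region of chromosome Y (between PAR1 and PAR2,
X-transposed region excluded) and the trim removes 5% of values from *each*
tail.  Under the log2 copy-ratio convention a fraction ``f`` of cells lacking
Y gives an expected mLRR-Y of ``log2(1 - f)``, so more negative means more
mosaicism.

Calls use the positive-side 99% rule: deviations of the cohort distribution
above its median estimate the null spread (carriers only ever pull the left
tail down), and their 0.99 quantile mirrored below the median is the calling
threshold.  A parametric half-normal variant of the same idea is available
behind ``method="halfnormal"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportions_ztest

from .config import CallingConfig
from .io_qc import IntensityData


class CallingError(ValueError):
    """Raised for degenerate inputs to the caller."""


# ---------------------------------------------------------------------------
# summary statistics


def trimmed_mean(values: np.ndarray, trim: float = 0.05, axis=None):
    """Mean after removing ``floor(trim * n)`` values from each tail.

    Computed by sorting and averaging the retained slice, so the result is
    bitwise-reproducible from the definition.
    """
    v = np.asarray(values, float)
    if axis is None:
        v = v.ravel()
        axis = 0
    v = np.sort(v, axis=axis)
    n = v.shape[axis]
    k = int(np.floor(trim * n))
    if 2 * k >= n:
        raise CallingError(f"trim {trim} removes all {n} values")
    sl = [slice(None)] * v.ndim
    sl[axis] = slice(k, n - k)
    return v[tuple(sl)].mean(axis=axis)


def compute_mlrry(data: IntensityData, *, min_msy_probes: int = 20,
                  min_auto_probes: int = 1000, trim: float = 0.05) -> pd.Series:
    """Per-sample mLRR-Y for a cohort.

    Raises :class:`CallingError` when the manifest carries fewer MSY or
    autosomal probes than the configured minima.
    """
    msy = data.region_mask("MSY")
    auto = data.region_mask("AUTO")
    if msy.sum() < min_msy_probes or auto.sum() < min_auto_probes:
        raise CallingError(
            f"too few probes: {int(msy.sum())} MSY (need >= {min_msy_probes}), "
            f"{int(auto.sum())} autosomal (need >= {min_auto_probes})")
    msy_mean = data.lrr[:, msy].mean(axis=1)
    auto_trim = trimmed_mean(data.lrr[:, auto], trim=trim, axis=1)
    return pd.Series(msy_mean - auto_trim, index=data.samples, name="mlrry")


def compute_par1_bdev(data: IntensityData, *, het_window: tuple[float, float] = (0.1, 0.9),
                      min_het_snps: int = 5) -> pd.DataFrame:
    """Per-sample PAR1 B-deviation: mean |BAF - 0.5| over heterozygous PAR1 probes.

    Heterozygotes are probes with BAF strictly inside ``het_window``.  Samples
    with fewer than ``min_het_snps`` informative probes get ``bdev = NaN`` with
    a reason, not an exception.
    """
    par1 = data.region_mask("PAR1")
    baf = data.baf[:, par1]
    lo, hi = het_window
    het = (baf > lo) & (baf < hi)
    n_het = het.sum(axis=1)
    dev_sum = np.where(het, np.abs(baf - 0.5), 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        bdev = np.where(n_het >= min_het_snps, dev_sum / n_het, np.nan)
    reason = np.where(n_het >= min_het_snps, "",
                      "too_few_het_snps")
    return pd.DataFrame({"bdev": bdev, "n_het": n_het, "bdev_reason": reason},
                        index=data.samples)


# ---------------------------------------------------------------------------
# threshold calling


def call_mloy_threshold(mlrry, *, quantile: float = 0.99, min_cohort: int = 100,
                        method: str = "empirical") -> tuple[float, pd.Series]:
    """Positive-side threshold and mLOY calls for a cohort mLRR-Y vector.

    The cohort median centres the distribution; positive deviations
    ``d = x - median`` for ``x > median`` estimate the null half-width, and

        threshold = median - Q_{quantile}(d)            (empirical)
        threshold = median - sigma_hat * z_{(1+q)/2}    (halfnormal)

    with ``sigma_hat = sqrt(mean(d^2))`` (MLE of the half-normal scale).
    Samples strictly below the threshold are called mLOY.
    """
    x = pd.Series(mlrry).astype(float)
    if len(x) < min_cohort:
        raise CallingError(f"cohort of {len(x)} below the stability minimum {min_cohort}")
    center = float(x.median())
    d = x[x > center] - center
    if len(d) == 0:
        raise CallingError("degenerate mLRR-Y distribution: no positive deviations")
    if method == "empirical":
        spread = float(np.quantile(d.to_numpy(), quantile))
    elif method == "halfnormal":
        sigma = float(np.sqrt(np.mean(d.to_numpy() ** 2)))
        spread = sigma * float(sps.norm.ppf(0.5 + quantile / 2.0))
    else:
        raise ValueError(f"unknown method {method!r}")
    if spread <= 0:
        raise CallingError("degenerate mLRR-Y distribution: zero positive spread")
    threshold = center - spread
    calls = (x < threshold).rename("mloy_call")
    return threshold, calls


@dataclass
class BatchCallResult:
    """Per-batch calls plus the batch-effect checks."""

    table: pd.DataFrame                     # sample-indexed: mlrry, batch, threshold, mloy_call
    thresholds: dict[int, float]
    ks_p: float = np.nan                    # two-sample KS on mLRR-Y between batches
    ks_stat: float = np.nan
    proportion_p: float = np.nan            # two-proportion z-test on call rates
    notes: list[str] = field(default_factory=list)


def split_batches_and_check(mlrry, *, n_batches: int = 2, seed: int = 0,
                            quantile: float = 0.99, min_cohort: int = 100,
                            method: str = "empirical") -> BatchCallResult:
    """Randomly partition the cohort, call mLOY per batch, and test for batch effects.

    With ``n_batches=1`` this reduces exactly to pooled calling.  For two
    batches the batch effect is assessed with a two-sample KS test on mLRR-Y
    and a two-proportion z-test on the call rates; for more batches the
    reported p-values are the smallest pairwise ones (conservative screen).
    """
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    x = pd.Series(mlrry).astype(float)
    rng = np.random.default_rng(seed)
    assignment = pd.Series(rng.permutation(np.arange(len(x)) % n_batches),
                           index=x.index, name="batch")
    smallest = assignment.value_counts().min()
    if smallest < min_cohort:
        raise CallingError(
            f"smallest batch ({int(smallest)}) below the stability minimum {min_cohort}")
    thresholds: dict[int, float] = {}
    calls = pd.Series(False, index=x.index, name="mloy_call")
    thr_col = pd.Series(np.nan, index=x.index, name="threshold")
    for b in range(n_batches):
        idx = assignment.index[assignment == b]
        thr, c = call_mloy_threshold(x.loc[idx], quantile=quantile,
                                     min_cohort=min_cohort, method=method)
        thresholds[b] = thr
        calls.loc[idx] = c
        thr_col.loc[idx] = thr
    ks_p = ks_stat = prop_p = np.nan
    if n_batches >= 2:
        ks_ps, ks_stats, prop_ps = [], [], []
        for a in range(n_batches):
            for b in range(a + 1, n_batches):
                xa = x[assignment == a].to_numpy()
                xb = x[assignment == b].to_numpy()
                ks = sps.ks_2samp(xa, xb)
                ks_ps.append(ks.pvalue)
                ks_stats.append(ks.statistic)
                ca = int(calls[assignment == a].sum())
                cb = int(calls[assignment == b].sum())
                _, p = proportions_ztest([ca, cb], [len(xa), len(xb)])
                prop_ps.append(p)
        i = int(np.argmin(ks_ps))
        ks_p, ks_stat = float(ks_ps[i]), float(ks_stats[i])
        prop_p = float(np.min(prop_ps))
    table = pd.concat([x.rename("mlrry"), assignment, thr_col, calls], axis=1)
    return BatchCallResult(table=table, thresholds=thresholds,
                           ks_p=ks_p, ks_stat=ks_stat, proportion_p=prop_p)


# ---------------------------------------------------------------------------
# anomaly screening


def flag_anomalies(mlrry, bdev, *, k: float = 5.0,
                   partial_band: tuple[float, float] | None = None) -> pd.DataFrame:
    """Screen for PAR1-LOH and partial-Y anomalies.

    Flags samples whose Bdev exceeds ``median + k * MAD`` (raw median absolute
    deviation; ``k = inf`` disables the rule) and, optionally, samples whose
    mLRR-Y falls inside an intermediate "partial loss" band.  Flagged samples
    are meant to be excluded from association inputs.
    """
    x = pd.Series(mlrry).astype(float)
    b = pd.Series(bdev).astype(float).reindex(x.index)
    flags = pd.Series(False, index=x.index, name="anomaly")
    reason = pd.Series("", index=x.index, dtype=object)
    if np.isfinite(k):
        med = b.median()
        mad = (b - med).abs().median()
        loh = b > med + k * mad
        flags |= loh.fillna(False)
        reason[loh.fillna(False)] = "par1_loh"
    if partial_band is not None:
        lo, hi = partial_band
        part = (x > lo) & (x < hi)
        reason[part & ~flags] = "partial_y"
        flags |= part
    out = pd.DataFrame({"anomaly": flags, "anomaly_reason": reason})
    return out


def cell_fraction_from_mlrry(mlrry) -> np.ndarray:
    """Invert the noise-free relation mLRR-Y = log2(1 - f) (testing utility)."""
    return 1.0 - np.exp2(np.asarray(mlrry, float))
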