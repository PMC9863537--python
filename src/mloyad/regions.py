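"""Probe-manifest regions for Y-mosaicism analysis (hg19/GRCh37 coordinates).

The manifest is a BED-like table of 1-based inclusive windows labelled with the
region classes the caller needs: the male-specific region of Y (``MSY``,
chrY:6611498-24510581, i.e. between PAR1 and PAR2 with the X-transposed region
``XTR`` excluded), the pseudoautosomal regions ``PAR1``/``PAR2``, chromosome X
(``X``) and autosomal background (``AUTO``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MANIFEST_COLUMNS = ["chrom", "start", "end", "region"]

#: hg19 windows; AUTO windows are one arbitrary interior slice per autosome.
DEFAULT_REGIONS = pd.DataFrame(
    [("Y", 60001, 2699520, "PAR1"),
     ("Y", 3000000, 6611497, "XTR"),
     ("Y", 6611498, 24510581, "MSY"),
     ("Y", 59034050, 59363566, "PAR2"),
     ("X", 3000000, 154000000, "X")]
    + [(str(c), 1_000_000, 40_000_000, "AUTO") for c in range(1, 23)],
    columns=MANIFEST_COLUMNS,
)


def build_probes(n_probes: dict[str, int], regions: pd.DataFrame | None = None) -> pd.DataFrame:
    """Lay out ``n_probes[region]`` evenly spaced probes inside each region window.

    Autosomal probes are distributed round-robin over the 22 autosome windows.
    Returns a probe table (probe, chrom, position, region) suitable for
    :class:`~mloyad.io_qc.IntensityData`.
    """
    regions = DEFAULT_REGIONS if regions is None else regions
    rows = []
    for label, n in n_probes.items():
        if n <= 0:
            continue
        windows = regions[regions["region"] == label]
        if windows.empty:
            raise ValueError(f"manifest has no window for region {label!r}")
        per = np.array_split(np.arange(n), len(windows))
        for (_, win), idx in zip(windows.iterrows(), per):
            k = len(idx)
            if k == 0:
                continue
            pos = np.linspace(win["start"], win["end"], k + 2)[1:-1].astype(int)
            for j, p in zip(idx, pos):
                rows.append((f"{label}_{j:05d}", str(win["chrom"]), int(p), label))
    return pd.DataFrame(rows, columns=["probe", "chrom", "position", "region"])


def assign_regions(chrom: pd.Series, position: pd.Series,
                   regions: pd.DataFrame | None = None) -> pd.Series:
    """Label probe coordinates with their region class (NaN if unmatched)."""
    regions = DEFAULT_REGIONS if regions is None else regions
    chrom = chrom.astype(str)
    out = pd.Series(np.nan, index=chrom.index, dtype=object)
    for _, win in regions.iterrows():
        m = (chrom == str(win["chrom"])) & (position >= win["start"]) & (position <= win["end"])
        out[m] = win["region"]
    return out


def read_manifest(path) -> pd.DataFrame:
    """Read a BED-like region manifest TSV (1-based inclusive coordinates)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest is missing column(s): {', '.join(missing)}")
    return df


def write_manifest(regions: pd.DataFrame, path) -> None:
    regions.to_csv(path, sep="\t", index=False)
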