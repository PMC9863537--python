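import numpy as np
import pandas as pd
import pytest

from mloyad.config import GeneratorConfig
from mloyad.io_qc import IntensityData
from mloyad.synthetic import generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort shared by read-only tests."""
    return generate_cohort(GeneratorConfig(n_samples=1200, seed=7))


def make_intensities(lrr_by_region: dict[str, np.ndarray],
                     baf_by_region: dict[str, np.ndarray] | None = None,
                     sample_ids=None) -> IntensityData:
    """Assemble an IntensityData from per-region (n_samples, n_probes) blocks."""
    baf_by_region = baf_by_region or {}
    probes, lrr_cols, baf_cols = [], [], []
    chrom_for = {"MSY": "Y", "XTR": "Y", "PAR1": "Y", "PAR2": "Y", "X": "X"}
    for region, block in lrr_by_region.items():
        block = np.atleast_2d(np.asarray(block, float))
        n, p = block.shape
        for j in range(p):
            probes.append((f"{region}_{j:05d}", chrom_for.get(region, "1"), j + 1, region))
        lrr_cols.append(block)
        b = baf_by_region.get(region)
        baf_cols.append(np.full((n, p), 0.5) if b is None else np.atleast_2d(np.asarray(b, float)))
    probe_df = pd.DataFrame(probes, columns=["probe", "chrom", "position", "region"])
    lrr = np.hstack(lrr_cols)
    baf = np.hstack(baf_cols)
    if sample_ids is None:
        sample_ids = pd.Index([f"S{i:03d}" for i in range(lrr.shape[0])], name="sample")
    return IntensityData(probes=probe_df, samples=pd.Index(sample_ids, name="sample"),
                         lrr=lrr, baf=baf)
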