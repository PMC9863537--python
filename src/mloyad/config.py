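"""Configuration objects for the mLOY analysis pipeline.

All stage parameters live in small dataclasses so a whole run is described by one
:class:`PipelineConfig`, serialisable to/from YAML.  The defaults encode the
published analysis profile for this kind of study: per-sample call rate > 0.97,
heterozygosity cut at mean + 3 SD, ancestry outliers at 6 SD on the leading PCs,
kinship 0.046875 (second degree), LRR SD 0.46, the 65-85 year analysis window,
instrument filters MAF >= 0.01 and imputation R^2 >= 0.3, and generator effect
sizes OR 1.80/SD (PRS on mLOY liability), OR 1.08/year (age on mLOY), and
HR 1.23/SD (male MCI->AD conversion).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


@dataclass
class CellFractionLaw:
    """Distribution of the mosaic LOY cell fraction among carriers.

    A Beta(a, b) variate rescaled onto [low, high].  The default Beta(2, 4) on
    [0.05, 0.90] is right-spread: most carriers have modest mosaicism, a tail
    approaches clonal loss.
    """

    a: float = 2.0
    b: float = 4.0
    low: float = 0.05
    high: float = 0.90

    def sample(self, rng, size: int):
        return self.low + (self.high - self.low) * rng.beta(self.a, self.b, size=size)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Rates are fractions in (0, 1); odds/hazard ratios are per the stated unit
    (per SD of the standardized PRS, per year of age, per unit of LOY cell
    fraction).  All randomness flows from ``seed``.
    """

    n_samples: int = 2000
    sex_ratio: float = 0.5                      # fraction male
    age_range: tuple[float, float] = (60.0, 95.0)

    # instrument
    n_instrument_snps: int = 114
    prs_beta_sd: float = 0.05                   # spread of per-allele weights

    # mLOY liability
    prs_or_per_sd: float = 1.80
    age_or_per_year: float = 1.08
    target_mloy_prevalence: float = 0.189       # males aged 65-85
    cell_fraction_law: CellFractionLaw = field(default_factory=CellFractionLaw)

    # case-control structure (age-confounded by construction)
    ad_base_rate: float = 0.35                  # P(AD) at age 75, APOE score 0
    ad_or_per_year: float = 1.16
    ad_or_apoe: float = 2.5
    ad_or_loy_male: float = 2.0                 # per unit cell fraction, men only

    # MCI phenoconversion
    mci_fraction: float = 0.20                  # prospective MCI subcohort
    conversion_hr_per_sd_male: float = 1.23
    conversion_hr_per_sd_female: float = 1.00
    pleiotropy_hr_per_sd: float = 1.00          # both-sex direct PRS effect
    conversion_hr_per_year: float = 1.10
    baseline_hazard: float = 0.08               # events / person-year
    weibull_shape: float = 1.0                  # 1.0 = exponential baseline
    followup_years: float = 12.0
    ad_fraction_of_converters: float = 0.70

    # APOE
    apoe_freqs: dict[str, float] = field(
        default_factory=lambda: {"e2": 0.07, "e3": 0.78, "e4": 0.15}
    )

    # intensities
    noise_sd_lrr: float = 0.15
    baf_sd: float = 0.03
    het_rate: float = 0.30
    lrr_gain: float = 0.55                      # LRR of a one-copy gain
    compression: float = 1.0
    lrr_floor: float = -3.0                     # LRR of an absent chromosome
    n_probes: dict[str, int] = field(
        default_factory=lambda: {"MSY": 120, "PAR1": 40, "XTR": 20, "X": 60, "AUTO": 2000}
    )

    # planted karyotype / QC anomalies (fractions of the cohort)
    rate_xx_mislabel: float = 0.010             # reported-male samples that are XX
    rate_xxy: float = 0.0008
    rate_xyy: float = 0.0008
    rate_trisomy: float = 0.0010
    rate_low_call: float = 0.004
    rate_excess_het: float = 0.004
    rate_related: float = 0.004                 # fraction of samples in a planted pair
    rate_ancestry_outlier: float = 0.004
    rate_par1_loh: float = 0.002
    planted_bdev: float = 0.15

    # CSF biomarkers and proteome
    lp_fraction: float = 0.6                    # eligible men with a lumbar puncture
    tau_mean: float = 450.0
    tau_noise_sd: float = 150.0
    gamma_tau: float = 400.0                    # tau units per unit LOY cell fraction
    apoe_tau: float = 30.0
    ptau_intercept: float = 5.0
    ptau_slope: float = 0.10
    ptau_noise_sd: float = 8.0
    abeta_mean: float = 800.0
    abeta_sd: float = 250.0
    lp_gap_max: float = 6.0                     # years; > 5 exercises the gap filter
    n_proteins: int = 184
    protein_loading_range: tuple[float, float] = (0.2, 0.8)
    plasma_attenuation: float = 0.3

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.n_instrument_snps < 1:
            raise ValueError("n_instrument_snps must be >= 1")
        for name in ("sex_ratio", "target_mloy_prevalence", "mci_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "prs_or_per_sd",
            "age_or_per_year",
            "conversion_hr_per_sd_male",
            "conversion_hr_per_sd_female",
            "pleiotropy_hr_per_sd",
            "conversion_hr_per_year",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive odds/hazard ratio")
        if self.baseline_hazard <= 0 or self.weibull_shape <= 0:
            raise ValueError("hazard parameters must be positive")


@dataclass
class QCThresholds:
    """Sample-QC cascade thresholds (defaults = published profile)."""

    min_call_rate: float = 0.97
    min_plate_call_rate: float = 0.985
    het_sd: float = 3.0
    ancestry_sd: float = 6.0
    n_ancestry_pcs: int = 2
    kinship: float = 0.046875
    max_lrr_sd: float = 0.46
    karyotype_min_margin: float = 0.10


@dataclass
class CallingConfig:
    """mLRR-Y computation and mLOY threshold-calling parameters."""

    min_msy_probes: int = 20
    min_auto_probes: int = 1000
    trim: float = 0.05                          # per tail
    min_cohort: int = 100
    quantile: float = 0.99
    method: str = "empirical"                   # or "halfnormal"
    het_window: tuple[float, float] = (0.1, 0.9)
    min_het_snps: int = 5
    bdev_k: float = 5.0                         # Bdev > median + k * MAD flags LOH
    partial_band: tuple[float, float] | None = None
    n_batches: int = 2


@dataclass
class InstrumentConfig:
    min_maf: float = 0.01
    min_r2: float = 0.3


@dataclass
class AssocConfig:
    age_window: tuple[float, float] = (65.0, 85.0)
    age_bands: tuple[tuple[float, float], ...] = (
        (65.0, 70.0),
        (70.0, 75.0),
        (75.0, 80.0),
        (80.0, 85.0),
    )
    pc_alpha: float = 0.05


@dataclass
class BiomarkerConfig:
    max_gap_years: float = 5.0
    lp_age_window: tuple[float, float] = (65.0, 85.0)
    min_obs: int = 10
    winsorise: bool = False


@dataclass
class PipelineConfig:
    """Full configuration of a pipeline run; ``generator.seed`` drives everything."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    calling: CallingConfig = field(default_factory=CallingConfig)
    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)
    assoc: AssocConfig = field(default_factory=AssocConfig)
    biomarker: BiomarkerConfig = field(default_factory=BiomarkerConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plainify(self.to_dict()), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        kw = {}
        for fld, sub in (
            ("generator", GeneratorConfig),
            ("qc", QCThresholds),
            ("calling", CallingConfig),
            ("instrument", InstrumentConfig),
            ("assoc", AssocConfig),
            ("biomarker", BiomarkerConfig),
        ):
            if fld in d:
                kw[fld] = _build(sub, d[fld])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _build(dc_type, d):
    if dataclasses.is_dataclass(d):
        return d
    kw = dict(d)
    types = {f.name: f for f in dataclasses.fields(dc_type)}
    for k in list(kw):
        if k not in types:
            raise ValueError(f"unknown {dc_type.__name__} field: {k}")
    if dc_type is GeneratorConfig and "cell_fraction_law" in kw and isinstance(
        kw["cell_fraction_law"], dict
    ):
        kw["cell_fraction_law"] = CellFractionLaw(**kw["cell_fraction_law"])
    # YAML has no tuple type; restore tuples where the defaults use them
    for name in ("age_range", "protein_loading_range", "het_window", "age_window",
                 "lp_age_window", "partial_band"):
        if name in kw and isinstance(kw[name], list):
            kw[name] = tuple(kw[name])
    if "age_bands" in kw and isinstance(kw["age_bands"], list):
        kw["age_bands"] = tuple(tuple(b) for b in kw["age_bands"])
    return dc_type(**kw)


def _plainify(obj):
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    return obj


def published_profile() -> PipelineConfig:
    """The default analysis profile with every published threshold spelled out."""
    return PipelineConfig()
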