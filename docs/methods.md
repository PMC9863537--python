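# Methods

## The mosaicism statistic and its generative model

Array intensities enter as log R ratios (LRR, log2 of observed over expected
probe intensity) and B-allele frequencies (BAF). The package adopts the log2
copy-ratio convention throughout, with the XY male as reference: a one-copy
gain appears at `lrr_gain` (default +0.55, the empirical single-copy-gain
level of SNP arrays, optionally shrunk by a `compression` factor) and an
absent chromosome at the background floor `lrr_floor` (default −3; log2 of a
zero copy ratio is −∞, and −3 mimics residual array background). A mosaic
fraction *f* of cells lacking Y places the expected MSY intensity at
log2(1 − *f*), clipped at the floor — so the noise-free identity
mLRR-Y = log2(1 − *f*) holds for *f* ≤ 1 − 2^floor ≈ 0.875.

mLRR-Y normalises the MSY mean against the per-sample 5% trimmed mean of
autosomal LRR ("trimmed" means floor(0.05·n) values removed from *each* tail;
the trimmed mean is computed by sorting and averaging the retained slice so it
is bitwise-reproducible from the definition). The normalisation is a
subtraction (median-shift), which makes the statistic invariant to per-sample
intensity offsets.

### Threshold calling

Carriers only ever pull the left tail of the cohort mLRR-Y distribution down,
so the positive half estimates the null. With `d = x − median(x)` for
`x > median(x)`:

* `empirical` (default): threshold = median − Q₀.₉₉(d);
* `halfnormal`: threshold = median − σ̂·Φ⁻¹(0.995) with σ̂ = sqrt(mean d²),
  the half-normal scale MLE.

For a carrier-free Normal(0, σ) cohort both converge to −σ·Φ⁻¹(0.995) ≈
−2.576σ, i.e. a ~0.5% null call rate. The empirical variant is the default
because it is assumption-light; the parametric one sits behind a config
switch. Cohorts below `min_cohort` (default 100) are refused — the upper-tail
quantile is too unstable below that. Thresholds are computed per batch when
the cohort is split (the batch split exists to mirror the two-randomised-batch
processing of large cohorts; a two-sample KS test on mLRR-Y and a
two-proportion z-test on call rates screen for batch effects). Whether
production thresholds should be pooled or per-batch is not fixed by the
method; per-batch is the default here, and `n_batches=1` gives pooled calling
exactly.

### PAR1 B-deviation and anomaly screening

Bdev is the mean |BAF − 0.5| over heterozygous PAR1 probes, with
heterozygotes taken as BAF ∈ (0.1, 0.9) (a standard het band; the method
itself does not fix one) and at least 5 informative probes required —
otherwise the value is missing-with-reason rather than an error. Samples with
Bdev above median + k·MAD (raw MAD, k = 5) are flagged as PAR1
loss-of-heterozygosity; an optional mLRR-Y band flags partial-Y losses. The
exact visual rule used in practice for "detectable anomalies" is not
recoverable; the MAD rule is a deterministic stand-in and both parameters are
exposed.

## Sample QC cascade

Rules run in a fixed order (sex karyotype → relatedness → call rate →
heterozygosity → ancestry → chromosomopathy → LRR SD) and every exclusion
records the *first* rule failed, which makes the funnel auditable. Choices the
method leaves open, resolved here:

* **Karyotype** is nearest-centroid in (mean LRR-X, mean LRR-Y) with centroids
  from the copy-ratio convention (XY at the origin, XX at (gain, floor), XXY
  at (gain, 0), XYY at (0, gain)); calls with margin < `min_margin` become
  `unclassified` and are excluded. Limitation: a near-clonal LOY male
  (f ≳ 0.8) drifts toward the XX centroid and can be excluded as non-XY;
  under the default carrier cell-fraction law such samples are rare (~2% of
  carriers).
* **Relatedness** drops, per kinship pair above 0.046875, the member with the
  lower call rate (tie: the lexicographically later id) — deterministic, so
  the survivor set is invariant to input row order.
* **Heterozygosity** (> mean + 3 SD) and **ancestry** statistics are computed
  over the samples *entering* that step. The ancestry scale is a robust SD
  (1.4826·MAD) per PC over the first two PCs: with a naive SD the outlier
  inflates its own scale and the max studentized residual is bounded by
  (n−1)/√n, so a ">6 SD" rule could never fire in a small cohort.
* **Plate call rate** (> 0.985) and **chromosomopathy** (e.g. trisomy 21) are
  consumed as precomputed annotations; detecting them is out of scope.

Idempotence (re-running QC on survivors excludes nobody) is exact for the
fixed-threshold rules and holds on the planted fixture for the recomputed
statistics; it cannot be guaranteed universally for mean+k·SD rules on
continuous data.

## The polygenic instrument

The instrument is raw PRS_s = Σ_v d_{s,v}·β_v over the published independent
autosomal mLOY variants (modelled as LD-free, since the source GWAS clumped at
r² > 0.05), filtered against *cohort* statistics: present, autosomal,
cohort MAF ≥ 0.01, imputation R² ≥ 0.3 — each exclusion logged with one
reason. Dosage columns counting the other allele are flipped (d → 2−d) with a
log note; missing dosages are mean-imputed per variant (keeping n constant)
and logged. Standardization is to mean 0, SD 1 (population SD) over **all**
scored samples of both sexes, because the instrument is also analysed in
women. Orientation flips and positive rescaling of all weights leave the
standardized score unchanged — both are tested.

## Association models

All effect directions are harmonised by multiplying mLRR-Y by −1 (the flipped
variable increases with mosaicism). APOE enters as count(ε4) − count(ε2) ∈
[−2, 2]. Logistic models use maximum likelihood (statsmodels `Logit`;
suspected separation is flagged, not silently returned); Cox models use the
partial likelihood with Breslow ties (lifelines; tie handling is a
convention choice, the method being silent). Only principal components
marginally associated with the model's own outcome (p < 0.05, per stratum)
are included — "associated" is unquantified in the source method, and 0.05 is
the conventional screen; for survival outcomes the screen is a univariate
Cox fit. The PRS conversion models additionally adjust for a dichotomous
cohort-ascertainment indicator. All tests are two-sided; confidence intervals
are effect ± 1.96·SE on the log scale.

The grid runs {−mLRR-Y, mLOY call, PRS} × {AD status, MCI→dementia,
MCI→AD} × {all, men, women, 65–70, 70–75, 75–80, 80–85}, with a fixed-effect
IVW META row (w = 1/SE², pooled SE = 1/√Σw, Cochran's Q reported) over the
age bands. mLOY-phenotype exposures are undefined for women; those rows are
emitted as missing-with-reason, as is any empty or degenerate stratum.
AD converters are the subset of dementia converters with an AD diagnosis;
in the MCI→AD model non-AD dementia converters are **censored at
conversion** — a design choice, since competing-risk modelling is out of
scope.

## Biomarkers and the proteome scan

Core CSF analytes are regressed per syndrome group (MCI, dementia) on the
harmonised mosaicism statistic adjusted by age at lumbar puncture, the
DNA-sampling-to-LP gap and APOE, then pooled by IVW; samples with a gap above
5 years or punctured outside 65–85 are excluded first. The proteome scan fits
one OLS per analyte per fluid, in base and total-tau-adjusted variants;
z = β/SE with normal-theory p-values (consistent with the λ definition),
analytes under 10 observations are skipped with a log row, and BH-FDR is
applied within each fluid × variant family (the conservative reading of an
unspecified family). Inflation is genomic-control λ = median(z²)/median(χ²₁);
the method never defines its λ, and median-χ² on the regression z-scores is
the standard convention matching a QQ-plot framing. Outliers are not
winsorised by default (a config switch exists).

Note that λ estimated from 184 analytes has a sampling SD of ≈ 0.17 even under
perfect calibration (the median of 184 χ² draws is noisy), so single-scan λ
values should be read with that in mind; the acceptance measurement pools both
fluids (368 z-scores) and averages three generator replicates for stability.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes; its
defaults are the study conditions and are not tuned per test.

* **Instrument**: allele frequencies U(0.05, 0.95), Hardy–Weinberg dosages,
  zero-mean normal weights, no LD.
* **mLOY liability**: P(LOY) = expit(α₀ + log(1.80)·PRS + log(1.08)·(age−75))
  for XY men, with α₀ calibrated by bisection (tolerance 1e-4) so the expected
  prevalence in 65–85-year-old men equals 18.9%; unreachable targets raise an
  error carrying the searched bracket. Carrier cell fractions follow
  Beta(2, 4) rescaled to [0.05, 0.90] — no published distribution of carrier
  mosaic fractions exists, so this right-spread law covering detectable and
  borderline events is an explicit stand-in.
* **Intensities**: the LRR law above plus Gaussian probe noise (SD 0.15,
  typical array-grade noise); BAF mixes heterozygous (N(0.5, 0.03), ~30% of
  diploid probes) and homozygous clusters; male X/Y probes are homozygous.
  Ordinary LOY carriers do **not** get a PAR1 BAF split — only explicitly
  planted PAR1-LOH anomaly samples do (split to 0.5 ± 0.15) — because the
  anomaly screen removes Bdev outliers and must not strip true carriers.
  Real-data features deliberately not emulated: probe-specific biases, GC
  waves, LD between instrument variants, clonal dynamics over time. Passing
  tests therefore demonstrate correctness of the statistical machinery, not
  robustness to array artefacts.
* **Phenotypes**: AD case-control status from a logistic law in age (OR
  1.16/year), APOE (OR 2.5/score unit) and a male-only LOY cell-fraction term
  — age-confounded case-control structure by construction; a prospective MCI
  subcohort (20%) receives conversion times from a Weibull
  proportional-hazards law (shape 1 = exponential baseline, the simplest
  PH-compatible choice; shape is exposed) with the PRS effect HR 1.23/SD in
  men only, HR 1.00 in women, an optional both-sex pleiotropic term for
  sex-specificity experiments, age effect HR 1.10/year, baseline hazard
  0.08/year and independent uniform censoring over ≤ 12 years of follow-up;
  70% of converters are diagnosed AD.
* **Biomarkers**: total tau = 450 + 400·f + 30·APOE + N(0, 150) (so the
  planted tau effect is 400 units per unit *cell fraction*; the fitted β per
  unit −mLRR-Y is smaller because −log2(1−f) stretches the exposure axis);
  p-tau ∝ tau; Abeta-42 independent of f. Each of 184 analytes per fluid
  loads on standardized tau with loading U(0.2, 0.8) (plasma attenuated
  ×0.3), which produces the tau-mediated inflation pattern: a base proteome
  scan against mosaicism is inflated, the tau-adjusted scan is calibrated.
* **Planted QC violations** (XX mislabels 1%, XXY/XYY 0.08% each, trisomy 21
  0.1%, low call rate / excess heterozygosity / relatedness pairs / ancestry
  outliers 0.4% each, PAR1-LOH 0.2%) are recorded per sample for
  planted-truth recovery tests.

All randomness flows from one seed through named `SeedSequence` child
streams, so identical configurations are byte-identical end to end.

## Problem sizes and numerical choices

Test and acceptance runs use sizes chosen for statistical stability of the
quantity being measured: caller accuracy at n = 2,000 (15% carriers,
f ∈ [0.3, 0.9]); threshold closed form at n = 10,000; parameter-recovery
coverage over 100 replicates at n = 20,000; sex-specificity calibration and
power over 200 replicates at n = 1,500 per replicate; inflation pattern over
three replicates at n = 6,000; end-to-end determinism at n = 10,000. The
calibration check for the generator's prevalence runs at n = 60,000 men,
where the binomial noise (±0.2 pp) is well inside the ±0.5 pp tolerance.

Degenerate inputs are first-class: all-equal mLRR-Y distributions, empty
strata, zero-variance exposures and empty instruments raise typed errors or
produce missing-with-reason rows as documented above; NaN dosages are imputed,
NaN Bdev values carry reasons. Ties in the kinship resolution and the BH
step-up use deterministic rules (stated above) so every pipeline output is
reproducible bit-for-bit under a fixed seed.

## Known limitations

* The intensity model is deliberately simple (no GC waves, no probe effects);
  the caller's measured sensitivity/specificity on synthetic data are upper
  bounds for real arrays.
* Extreme-mosaicism males can be lost at the karyotype gate (above).
* One-sample instrument association only; two-sample MR estimators (IVW over
  per-variant summary statistics, MR-Egger) are a natural extension and out
  of scope.
* No competing-risk model for non-AD dementia; censoring at conversion is a
  stated approximation.
* The mLOY phenotype pipeline covers reported-male samples only; women enter
  through the instrument analyses.
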