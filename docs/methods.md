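# Methods

This note documents the models, generative assumptions, numerical choices
and known limitations of `msqmri`. It states no empirical result beyond
what the test suite and `scripts/acceptance.py` compute.

## 1. Image-level traits

The magnetization transfer ratio is computed per voxel as
`MTR = 100 (M0 − Ms) / M0` from a co-registered gradient-echo pair without
(`M0`) and with (`Ms`) an off-resonance saturation pulse. Voxels with
`M0 ≤ 0` carry no signal and become NaN — a documented missing-value
contract, not an error. Co-registration, segmentation and lesion
delineation are inputs, never performed here: the package expects a hard
GM/WM/CSF label volume, a soft (probabilistic) segmentation and two lesion
masks from the lesion-growing family — the most sensitive setting
(kappa = 0) and the most specific (kappa = 1).

Normal-appearing masks are defined as `NAGM = GM ∧ ¬lesion(kappa=0)` and
`NAWM = WM ∧ ¬lesion(kappa=0)`. The lesion class analysed downstream uses
the kappa = 1 mask, which must be contained in the kappa = 0 mask (checked;
this containment is what guarantees the three analysed tissue classes are
pairwise disjoint). Where only one lesion mask exists it serves both roles.

Histogram summaries per tissue class:

* voxels that are NaN or outside the validity range (default [0, 100] MTR
  units — noise can push recomputed MTR outside the physical range) are
  excluded first; the peak-height denominator is the *included* count, so
  peak height is "unit percent" of the plotted histogram;
* bins of width `bin_width` (default 1.0 MTR unit) tile the validity range
  from its lower edge. Peak height and peak location depend on this width;
  it is a configurable analysis parameter, not a property of the data;
* modal-bin ties resolve to the lowest bin (determinism);
* percentiles use linear interpolation; `mean90` averages the values lying
  in `[P5, P95]` with both boundaries included;
* an empty tissue (e.g. no lesions) yields a flagged missing summary, not
  an exception.

All four histogram parameters are emitted, and
`histogram_intercorrelation` reports their correlation matrix as a
diagnostic; only median and peak height enter the statistical analyses
because the four are strongly inter-correlated.

Volumetrics: class volume = Σ(class probability) × voxel volume, total
brain volume = GM + WM + CSF, WM%/GM% as percent of total brain, lesion
volume = lesion voxel count × voxel volume; all volumes in ml. The identity
`gm_pct + wm_pct + csf_pct = 100` holds to float tolerance whenever the
total is positive.

## 2. Linear models and variance decomposition

All regression is ordinary least squares (Gaussian identity link), fitted
through `statsmodels` with explicit term bookkeeping: categorical terms are
expanded to reference-level dummies (first level in sorted order), a
k-level term contributing k − 1 to the predictor count. "Variance
explained" is always the adjusted r²,
`1 − (1 − r²)(n − 1)/(n − p − 1)`, which may be negative; model p-values
are overall F tests against intercept-only (term-wise Wald tests are
emitted as supplementary columns, since which of the two a model "p-value"
denotes is a reporting convention). Rank-deficient designs raise an error
naming the aliased columns — the canonical case being a patient-identifier
term combined with a covariate constant within patients.

The longitudinal decomposition fits the generic model
`trait ~ patient_id + time_days` (time in days since each patient's first
scan; patients with a single scan are retained and inform only the
intercepts) and measures each term's contribution by deletion:
adj r²(full) − adj r²(without the term). Deletion differences of adjusted
r² can be negative; negative raw contributions are floored at zero before
the two shares are normalized to 100% (the raw values are still reported).
Normalizing over the summed contributions — rather than over the full
model's adj r² — is what makes a two-term decomposition sum exactly to
100%. Note the two measures answer different questions: with a sizeable
time effect the adjusted-r² deletion contribution of time exceeds its raw
variance share, because deleting time from a 33-parameter patient model is
penalized differently than deleting 32 patient parameters. In the emulated regime (within-patient drift well below between-patient spread) the two
agree to a couple of percentage points, which is what the recovery tests
check.

Multiple testing uses Bonferroni thresholds α/n: the longitudinal family
is 10 traits × 2 models = 20 tests (0.0025 at α = 0.05); the
cross-sectional family is 10 traits × 10 predictors + 6 cross-tissue tests
= 106 (0.00047 at two significant figures; full precision is used for
decisions, rounding only for display). The 6 cross-tissue tests are the
median and peak-height regressions over the three tissue-class pairs
(lesion–NAWM, lesion–NAGM, NAWM–NAGM), each fitted as
`trait_a ~ trait_b + age + gender + protocol` with the t test on the
partner trait.

The 10 cross-sectional predictors are gender, age, disease duration, OCB
status (binary positive/negative, unknown → missing), IgG index, MSSS
(entered as continuous), treatment status (binary on/off therapy; per-drug
detail is descriptive only), and the three genetic burden scores (total,
HLA, non-HLA PRS). Each predictor is tested adjusted for age, gender and
MRI protocol (minus itself when it is one of those).

## 3. Genetics

Variant QC keeps a variant iff MAF ≥ 0.01, call rate ≥ 0.98 and
Hardy–Weinberg exact p ≥ 10⁻⁶ (thresholds configurable). The HWE test is
the exact conditional test: given the observed allele counts, the p-value
sums the probabilities of all heterozygote counts whose conditional
probability does not exceed the observed one, computed by the standard
recurrence over heterozygote counts (exact for any sample size; validated
exhaustively against a direct log-factorial enumeration for all allele
counts up to 200 chromosomes). MAF and call rate use all non-missing
calls; HWE uses hard calls only (dosages within 10⁻⁶ of an integer).

Allele alignment orients every variant so its stored effect increases MS
risk: if the weight's effect allele is the genotype's A allele the dosage
is reflected (d → 2 − d), and odds ratios < 1 are inverted with an
accompanying allele swap, so all stored log-ORs are ≥ 0. Variants whose
allele pair does not match the weight table's pair as a set are dropped
with a logged reason — strand resolution for ambiguous (A/T, C/G) variants
is upstream curation, out of scope. The PRS is the unstandardized sum
Σ dosage × ln(OR) (association inference is scale-invariant either way),
over all variants or the HLA / non-HLA subsets; missing dosages are
skipped by default (score over observed variants) with mean-imputation
available via `missing="mean"`. Imputation-quality filtering and
relatedness estimation are honored only as metadata (an info-score column
can be filtered on; relatedness appears as a boolean exclusion flag in the
patient table), since imputation and IBD estimation are out of scope.

Single-variant tests are additive OLS Wald tests
(`trait ~ dosage + age + gender + protocol`); monomorphic variants are
skipped and excluded from denominators. The per-category nominal fraction,
100 × (#p < 0.05)/#tests, is the chance-level benchmark for a null panel.

## 4. The synthetic cohort generator

The generator defines the conditions every statistical claim is tested
under. Latent traits follow an additive Gaussian model,

    trait(i, j) = grand mean + protocol effect + β_age (age_i − 40)
                  + β_female female_i + b_i + slope · t_ij + ε_ij,

with `b_i ~ N(0, σ_between²)` and `ε ~ N(0, σ_within²)`. This is the
minimal generative model under which fixed-effect OLS decomposition is
consistent; no mixed-model (REML) estimation is implied or provided.

Key defaults (all overridable per trait via `CohortConfig`):

| parameter | default | rationale |
|---|---|---|
| design, longitudinal | 33 patients: 29×2, 3×3, 1×5 scans, one protocol | a realistic clinical longitudinal design (72 scans) |
| design, cross-sectional | 213 patients, 1 scan, 5 protocols; 209 genetically eligible | a realistic cross-sectional extension |
| inter-scan interval | Normal(13.2, 7.9) months, truncated at 1 month | typical clinical follow-up spacing |
| gender | Bernoulli(0.71 female) | typical MS cohort composition (~71% female) |
| age | Normal(40, 12) years truncated to [19, 71] | typical adult MS age distribution |
| MTR medians (lesion/NAWM/NAGM) | 30 / 38 / 32 MTR units | known tissue contrast ordering (lesions < NAGM < NAWM); exact values are config entries, not claims — per-tissue means for such cohorts are not publicly anchored |
| σ_between (medians) | 1.5 / 1.2 / 1.0 | dominant between-patient variance |
| σ_within | 0.2 × σ_between | high intraclass correlation (~0.96) |
| time slopes | ≈ −2·10⁻⁴ … −3·10⁻⁴ per day | slow decline, small against σ_within over a typical interval, so the patient share of explained variance lands near 100% |
| covariate shares | age+gender ≈ 34% of total brain volume, 30% of GM%, ~6% of peak heights, ~1% of medians | anchored to physiological effect sizes reported in the MS imaging literature; β values are derived analytically from these target fractions |
| cross-tissue intercept correlations | NAWM–NAGM 0.55 (median) / 0.65 (peak), lesion–NA 0.42 / 0.31 | produce covariate-adjusted cross-tissue r² in the moderate bands reported in the MS imaging literature (~0.3–0.4 between normal-appearing tissues, ~0.1 with lesions) |
| genotypes | 155 variants (22 HLA + 133 non-HLA), MAF ~ U(0.05, 0.5), dosage ~ Binomial(2, p), OR ~ lognormal(0, 0.15), no trait effect | Hardy–Weinberg by construction; a null panel, so chance-level association rates are the expected outcome |
| image grid | 32³ voxels at 1 mm³ | desk-scale speed; volumes are phantom-scale (total brain ≈ 16 ml), percentages anatomically plausible |

Image synthesis inverts the trait extraction: a central sphere sized to the
latent total brain volume is partitioned into WM core / GM shell / CSF rim
matching the latent percentages; the lesion is a blob of WM voxels nearest
a random seed voxel sized to the latent lesion volume; per-voxel target MTR
is drawn around the latent tissue median, and `M0 = 1000 + noise`,
`Ms = M0 (1 − MTR/100)`. The voxel-noise SD per tissue is inverted from the
latent peak-height trait (σ = w / (2 Φ⁻¹((1 + ph/100)/2)) for bin width w),
so image-derived peak heights approximately recover their latents —
approximate because a median straddling a bin edge splits the modal bin;
median and volume recovery are the quantitative contracts (volumes recover
to voxel quantization, medians exactly in the noise-free case and to
within histogram sampling error otherwise).

What the generator does **not** emulate: scanner artifacts, bias fields,
motion, registration error, realistic lesion morphology or spatial
statistics, genotype LD structure, and any genotype–trait effect. Passing
tests therefore demonstrate correctness of the estimators under the stated
generative model — not robustness to real-world acquisition artifacts.

## 5. Pipeline and reproducibility

`run_pipeline` executes simulate → traits → longitudinal → genetics →
cross-sectional (genetics before cross-sectional because the
cross-sectional scan includes the three PRS predictors; the manifest lists
the five stages). A single global seed fans out to per-stage child seeds by
fixed offsets so any stage subset reruns identically; each stage records
input/output content hashes in `manifest.json`, and a completed stage with
unchanged inputs is skipped. Tabular outputs are byte-identical across
runs with the same seed. NIfTI images are written uncompressed (`.nii`) by
default: gzip containers embed timestamps, which would break byte-level
determinism; `.nii.gz` is accepted on read.

Problem sizes used by the test suite and acceptance script — 32³ phantoms,
the 33/72 longitudinal design, 213/209 cross-sectional/genetic cohorts,
200-replicate decomposition studies, 150-replicate family-wise-error
simulations — are the package's chosen desk-scale study conditions; they
complete in about a minute on one CPU.

## 6. Known limitations

* Fixed-effect OLS treats patient identity as fixed; variance shares are
  deletion-based adjusted-r² contributions, not REML variance components.
* Peak height and peak location depend on the histogram bin width; results
  are comparable only at a fixed width (default 1.0 MTR unit).
* The exact HWE test assumes diallelic variants and hard calls; imputed
  dosages are rounded only if already near-integral, otherwise excluded
  from the HWE computation.
* Cross-sectional p-values assume independent patients; no relatedness or
  population-structure correction beyond the exclusion flag is applied.
* The synthetic gender/covariate effect sizes are calibrated to reported
  explained-variance fractions, not to any per-patient data; absolute
  trait scales (especially volumes) are phantom-scale conventions.
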