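# msqmri

Quantitative MRI phenotyping for multiple sclerosis (MS) cohorts: a tested,
reusable implementation of the analysis chain that takes magnetization
transfer (MT) image pairs and tissue segmentations to per-scan trait
vectors, and those traits to longitudinal variance decompositions,
cross-sectional covariate-adjusted associations, and polygenic-risk-score
(PRS) analyses. Because clinical MS imaging/genetics cohorts are rarely
shareable, the package includes a first-class synthetic cohort generator
that reproduces the statistical structure these analyses assume, so every
stage is runnable and testable end to end without patient data.

**Who it is for.** Neuroimaging/statistics researchers who need a
transparent reference implementation of MTR histogram phenotyping and its
downstream statistics, or a controllable synthetic benchmark for method
development.

## The quantities computed

* **MTR map** — per voxel, `MTR = 100 (M0 − Ms) / M0`, where `M0`/`Ms` are
  the gradient-echo images without/with the off-resonance saturation pulse.
* **Tissue traits** — in lesions, normal-appearing white matter (NAWM =
  WM voxels outside the most sensitive lesion segmentation) and
  normal-appearing grey matter (NAGM): histogram **median** and **peak
  height** (modal-bin frequency in percent of included voxels; peak
  location and mean90 are also emitted). Volumetrics from the soft
  segmentation: class volume = Σ probability × voxel volume; total brain =
  GM + WM + CSF; WM% and GM% of total brain; lesion volume. Ten traits per
  scan enter the statistics.
* **Longitudinal decomposition** — per trait, the generic model
  `trait ~ patient_id + time` (OLS with a fixed effect per patient, time in
  days since first scan) and the clinical model
  `trait ~ age + gender + disease_duration + time`. The contribution of a
  term is by deletion: adj r² (full) − adj r² (without the term); relative
  shares normalize the two contributions to 100%.
* **Cross-sectional associations** — always adjusted for age, gender and
  MRI protocol: cross-tissue MTR regressions, explained variance by
  age+gender (adj r² increment over the protocol-only model), and a
  10 traits × 10 predictors scan with Bonferroni correction
  (α/n: 0.05/20 = 0.0025 longitudinally, 0.05/106 ≈ 0.00047
  cross-sectionally).
* **Genetics** — variant QC (MAF ≥ 1%, call rate ≥ 98%, Hardy–Weinberg
  exact test p ≥ 10⁻⁶), risk-allele alignment (all stored log odds ratios
  ≥ 0), PRS = Σ dosage × ln(OR) over all / HLA / non-HLA variants, and
  covariate-adjusted PRS and single-variant association scans with
  nominal-significance fractions.

## Worked example

```python
from msqmri import CohortConfig, simulate_cohort
from msqmri.longitudinal import longitudinal_report

patients, scans = simulate_cohort(CohortConfig(seed=3))   # 33 patients, 72 scans
report = longitudinal_report(scans, patients)
print(report[["trait", "generic_adj_r2", "patient_share_pct",
              "time_share_pct", "clinical_adj_r2"]].round(3).to_string(index=False))
```

prints (abridged):

```
             trait  generic_adj_r2  patient_share_pct  time_share_pct  clinical_adj_r2
   nawm_mtr_median           0.959             98.947           1.053           -0.043
   nagm_mtr_median           0.979             99.863           0.137           -0.050
total_brain_volume           0.964             99.350           0.650            0.367
            gm_pct           0.967            100.000           0.000            0.479
```

Read: the generic model explains ~95% of trait variance and virtually all
of it attaches to the patient identifier — differences between patients at
inclusion dwarf within-patient change over follow-up — while the known
clinical covariates recover only a fraction of those differences (more for
volumes than for MTR). The `examples/` directory has one short script per
capability (cohort simulation, image-trait extraction, longitudinal,
cross-sectional, genetics, full pipeline).

A thin CLI mirrors the library:

```bash
msqmri run --seed 1 --outdir out/run1       # full pipeline + report.md
msqmri simulate --seed 1 --outdir out/sim   # tables only
msqmri qc --dosages d.tsv --variants v.tsv --out qc.tsv
```

`msqmri run` accepts `--config config.yaml`; the YAML keys are exactly the
fields of `CohortConfig` (see `docs/methods.md` for the parameter table).

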