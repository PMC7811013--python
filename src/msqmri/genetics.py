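"""Variant QC, polygenic risk scoring, and genetic association scans.

Implements the genetic arm of the phenotyping pipeline:

* per-variant quality control (minor allele frequency >= 1%, call rate
  >= 98%, Hardy-Weinberg exact test p >= 1e-6);
* allele alignment so every stored effect corresponds to an *increase* in MS
  risk (odds ratios < 1 are inverted and the effect allele swapped);
* the polygenic risk score: per patient, the sum of risk-allele dosages
  weighted by ln(odds ratio), over all variants or the HLA / non-HLA
  subsets;
* covariate-adjusted association of scores and of single variants with the
  10 MRI traits (OLS Wald tests with age, sex and MRI protocol as
  covariates).

The Hardy-Weinberg test is the exact conditional test: given the observed
allele counts, the p-value sums the probabilities of all heterozygote counts
whose conditional probability does not exceed that of the observed count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DesignError, DomainError, FormatError
from .image_traits import TRAIT_NAMES
from .models import Term, fit_linear_model

logger = logging.getLogger(__name__)

CATEGORIES = ("HLA", "non-HLA")


# --------------------------------------------------------------------------
# containers


@dataclass
class GenotypeMatrix:
    """Per-patient allele dosages plus per-variant metadata.

    ``dosages`` is patients x variants with values in [0, 2] (NaN = missing
    call); dosage counts copies of ``allele_b``.  ``variants`` is indexed by
    variant id with columns ``chrom, pos, allele_a, allele_b, category``.
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.variants.index.is_unique:
            raise FormatError("variant ids must be unique")
        if list(self.dosages.columns) != list(self.variants.index):
            raise FormatError("dosage columns must match variant metadata index")
        vals = self.dosages.to_numpy(dtype=float)
        bad = np.isfinite(vals) & ((vals < 0) | (vals > 2))
        if bad.any():
            raise FormatError("dosages must lie in [0, 2] or be missing")

    @property
    def n_patients(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, dosage_path, variant_path) -> None:
        self.dosages.to_csv(dosage_path, sep="\t", index_label="patient_id")
        self.variants.to_csv(variant_path, sep="\t", index_label="variant_id")

    @classmethod
    def from_tsv(cls, dosage_path, variant_path) -> "GenotypeMatrix":
        dos = pd.read_csv(dosage_path, sep="\t", index_col="patient_id")
        var = pd.read_csv(variant_path, sep="\t", index_col="variant_id")
        return cls(dosages=dos, variants=var)

    def to_vcf(self, path) -> None:
        """Write a minimal plain-text VCF with GT and DS FORMAT fields."""
        patients = list(self.dosages.index)
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT allele">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(patients) + "\n")
            for vid, row in self.variants.iterrows():
                calls = []
                for d in self.dosages[vid]:
                    if pd.isna(d):
                        calls.append("./.:.")
                    else:
                        n = int(round(d))
                        gt = {0: "0/0", 1: "0/1", 2: "1/1"}.get(n, "./.") if abs(d - round(d)) < 1e-6 else "./."
                        calls.append(f"{gt}:{d:g}")
                fh.write(
                    f"{row['chrom']}\t{int(row['pos'])}\t{vid}\t{row['allele_a']}\t{row['allele_b']}"
                    "\t.\tPASS\t.\tGT:DS\t" + "\t".join(calls) + "\n"
                )

    @classmethod
    def from_vcf(cls, path, category_map: dict[str, str] | None = None) -> "GenotypeMatrix":
        """Read dosages from a VCF (DS field preferred, GT fallback).

        Requires :mod:`cyvcf2`.  ``category_map`` optionally assigns the
        HLA / non-HLA category per variant id (default "non-HLA").
        """
        from cyvcf2 import VCF  # optional dependency

        vcf = VCF(str(path))
        patients = list(vcf.samples)
        dosage_cols: dict[str, np.ndarray] = {}
        meta_rows = []
        for rec in vcf:
            vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
            try:
                ds = np.asarray(rec.format("DS"), dtype=float).reshape(-1)
            except (KeyError, TypeError, ValueError):
                gts = np.asarray(rec.gt_types, dtype=float)  # 0,1,3 = hom ref/het/hom alt; 2 = unknown
                ds = np.where(gts == 3, 2.0, gts)
                ds = np.where(gts == 2, np.nan, ds)
            ds = np.where((ds < -0.5) | (ds > 2.5), np.nan, ds)
            dosage_cols[vid] = np.clip(ds, 0, 2)
            cat = (category_map or {}).get(vid, "non-HLA")
            meta_rows.append(
                {"variant_id": vid, "chrom": rec.CHROM, "pos": rec.POS,
                 "allele_a": rec.REF, "allele_b": rec.ALT[0], "category": cat}
            )
        variants = pd.DataFrame(meta_rows).set_index("variant_id")
        dosages = pd.DataFrame(dosage_cols, index=patients)
        return cls(dosages=dosages, variants=variants)


@dataclass
class QCThresholds:
    """Variant-QC cutoffs: keep iff maf >= maf, call_rate >= call_rate, hwe_p >= hwe_p."""

    maf: float = 0.01
    call_rate: float = 0.98
    hwe_p: float = 1e-6


@dataclass
class QCReport:
    """Per-variant QC metrics, kept flags, and exclusion tallies."""

    table: pd.DataFrame  # index variant_id; maf, call_rate, hwe_p, kept, reason
    thresholds: QCThresholds
    exclusion_counts: dict[str, int]

    @property
    def kept_ids(self) -> list[str]:
        return list(self.table.index[self.table["kept"]])


# --------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Given genotype counts (heterozygotes, and the two homozygote classes),
    conditions on the allele counts and sums the probabilities of all
    heterozygote counts at most as probable as the observed one.  Uses the
    standard recurrence over heterozygote counts; exact for any sample size.
    """
    if min(n_het, n_hom1, n_hom2) < 0:
        raise DomainError("genotype counts must be non-negative")
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        raise DomainError("no genotyped samples")
    rare = 2 * min(n_hom1, n_hom2) + n_het  # minor allele count
    # heterozygote counts share the parity of the minor allele count
    h_min = rare % 2
    h_max = min(rare, 2 * n - rare)
    if h_max < h_min:  # monomorphic
        return 1.0

    hs = np.arange(h_min, h_max + 1, 2)
    probs = np.empty(hs.size)
    # start from the mode region: compute unnormalized probabilities via the
    # ratio P(h+2)/P(h) = (rare-h)(2n-rare-h) / ((h+2)(h+1)) in log space
    logp = np.empty(hs.size)
    logp[0] = 0.0
    for i in range(hs.size - 1):
        h = hs[i]
        num = (rare - h) * (2 * n - rare - h)
        den = (h + 2.0) * (h + 1.0)
        logp[i + 1] = logp[i] + math.log(num) - math.log(den)
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()

    obs = int(n_het)
    i_obs = (obs - h_min) // 2
    p_obs = probs[i_obs]
    p = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    return min(1.0, p)


# --------------------------------------------------------------------------
# QC


def variant_qc(genotypes: GenotypeMatrix, thresholds: QCThresholds | None = None) -> QCReport:
    """Per-variant QC on minor allele frequency, call rate and HWE.

    MAF and call rate use all non-missing calls (dosages allowed); the HWE
    exact test uses hard calls only (dosages within 1e-6 of an integer).  A
    variant with no data at all is excluded with reason "no data"; a variant
    with no hard calls gets ``hwe_p = NaN`` and is not excluded on HWE.
    """
    thresholds = thresholds or QCThresholds()
    n = genotypes.n_patients
    rows = []
    counts = {"no data": 0, "maf": 0, "call_rate": 0, "hwe": 0, "kept": 0}
    for vid in genotypes.dosages.columns:
        d = genotypes.dosages[vid].to_numpy(dtype=float)
        obs = d[np.isfinite(d)]
        if obs.size == 0:
            rows.append({"variant_id": vid, "maf": np.nan, "call_rate": 0.0,
                         "hwe_p": np.nan, "kept": False, "reason": "no data"})
            counts["no data"] += 1
            continue
        call_rate = obs.size / n
        freq_b = obs.mean() / 2.0
        maf = min(freq_b, 1.0 - freq_b)
        hard = obs[np.abs(obs - np.round(obs)) < 1e-6].round().astype(int)
        if hard.size:
            hwe_p = hwe_exact_test(
                n_het=int((hard == 1).sum()),
                n_hom1=int((hard == 0).sum()),
                n_hom2=int((hard == 2).sum()),
            )
        else:
            hwe_p = np.nan
        reasons = []
        if maf < thresholds.maf:
            reasons.append("maf")
        if call_rate < thresholds.call_rate:
            reasons.append("call_rate")
        if np.isfinite(hwe_p) and hwe_p < thresholds.hwe_p:
            reasons.append("hwe")
        kept = not reasons
        for r in reasons:
            counts[r] += 1
        if kept:
            counts["kept"] += 1
        rows.append({"variant_id": vid, "maf": maf, "call_rate": call_rate,
                     "hwe_p": hwe_p, "kept": kept, "reason": ";".join(reasons)})
    table = pd.DataFrame(rows).set_index("variant_id")
    logger.info("variant QC: %s", counts)
    return QCReport(table=table, thresholds=thresholds, exclusion_counts=counts)


# --------------------------------------------------------------------------
# alignment and scoring


@dataclass
class AlignedPanel:
    """Risk-allele-aligned dosages and non-negative log-odds weights."""

    dosages: pd.DataFrame          # counts of the risk allele
    weights: pd.DataFrame          # index variant_id; risk_allele, other_allele, log_or, category
    dropped: pd.DataFrame          # variant_id, reason


def align_effect_alleles(genotypes: GenotypeMatrix, weights: pd.DataFrame) -> AlignedPanel:
    """Orient dosages and weights so every effect increases MS risk.

    ``weights`` must carry columns ``effect_allele, other_allele, odds_ratio``
    (and optionally ``category``), indexed by variant id.  For each variant:

    * if the weight's allele pair does not match the genotype's allele pair
      as a set, the variant is dropped (strand resolution is out of scope);
    * if the effect allele is the genotype's allele A (dosage counts allele
      B), the dosage is reflected ``d -> 2 - d``;
    * if the odds ratio is < 1, effect and other allele are swapped, the OR
      inverted, and the dosage reflected, so stored ``log_or >= 0``.
    """
    required = {"effect_allele", "other_allele", "odds_ratio"}
    if not required <= set(weights.columns):
        raise FormatError(f"weight table must have columns {sorted(required)}")
    if (weights["odds_ratio"] <= 0).any():
        raise FormatError("odds ratios must be > 0")

    aligned_cols: dict[str, pd.Series] = {}
    out_rows = []
    dropped = []
    for vid in weights.index:
        if vid not in genotypes.dosages.columns:
            dropped.append({"variant_id": vid, "reason": "not genotyped"})
            continue
        w = weights.loc[vid]
        meta = genotypes.variants.loc[vid]
        geno_pair = {meta["allele_a"], meta["allele_b"]}
        weight_pair = {w["effect_allele"], w["other_allele"]}
        if geno_pair != weight_pair:
            dropped.append({"variant_id": vid, "reason": "allele mismatch"})
            continue
        d = genotypes.dosages[vid].astype(float)
        eff, oth, orr = w["effect_allele"], w["other_allele"], float(w["odds_ratio"])
        if eff == meta["allele_a"]:
            d = 2.0 - d
        if orr < 1.0:
            eff, oth = oth, eff
            orr = 1.0 / orr
            d = 2.0 - d
        aligned_cols[vid] = d
        out_rows.append({
            "variant_id": vid,
            "risk_allele": eff,
            "other_allele": oth,
            "log_or": math.log(orr),
            "category": w.get("category", meta.get("category", "non-HLA")),
        })
    if dropped:
        logger.info("allele alignment dropped %d variants", len(dropped))
    weights_out = pd.DataFrame(out_rows).set_index("variant_id") if out_rows else pd.DataFrame(
        columns=["risk_allele", "other_allele", "log_or", "category"]
    )
    dosages = pd.DataFrame(aligned_cols, index=genotypes.dosages.index)
    return AlignedPanel(
        dosages=dosages,
        weights=weights_out,
        dropped=pd.DataFrame(dropped, columns=["variant_id", "reason"]),
    )


def compute_prs(
    panel: AlignedPanel,
    subset: str = "all",
    missing: str = "skip",
) -> pd.Series:
    """Polygenic risk score: sum of risk-allele dosages times ln(OR).

    ``subset`` selects "all", "HLA" or "non-HLA" variants.  Missing dosages
    are skipped (score over observed variants) or, with ``missing="mean"``,
    imputed with the variant's mean dosage.
    """
    if subset == "all":
        ids = list(panel.weights.index)
    elif subset in CATEGORIES:
        ids = list(panel.weights.index[panel.weights["category"] == subset])
    else:
        raise DomainError(f"unknown subset {subset!r}")
    if not ids:
        raise DomainError(f"subset {subset!r} selects no variants")
    dos = panel.dosages[ids]
    if missing == "mean":
        dos = dos.fillna(dos.mean())
    elif missing != "skip":
        raise DomainError("missing must be 'skip' or 'mean'")
    w = panel.weights.loc[ids, "log_or"]
    score = dos.mul(w, axis=1).sum(axis=1, skipna=True)
    score.name = f"prs_{subset}"
    return score


def prs_table(panel: AlignedPanel, missing: str = "skip") -> pd.DataFrame:
    """Total, HLA and non-HLA scores per patient as one table."""
    cols = {}
    cols["prs_all"] = compute_prs(panel, "all", missing=missing)
    for cat in CATEGORIES:
        if (panel.weights["category"] == cat).any():
            cols[f"prs_{cat}"] = compute_prs(panel, cat, missing=missing)
    return pd.DataFrame(cols)


# --------------------------------------------------------------------------
# association scans


def prs_trait_association(
    scores: pd.DataFrame,
    table: pd.DataFrame,
    traits: list[str] | None = None,
) -> pd.DataFrame:
    """Regress each MRI trait on each PRS with age, sex, protocol covariates.

    ``table`` must be indexed compatibly with ``scores`` (joined on index)
    and carry ``age``, ``gender``, ``protocol_id`` plus the trait columns.
    Returns one row per (trait, score) with beta, se, p, adjusted r2.
    """
    traits = traits or [t for t in TRAIT_NAMES if t in table.columns]
    merged = table.join(scores, how="inner")
    rows = []
    for score_col in scores.columns:
        for trait in traits:
            terms = [Term(score_col), Term("age"), Term("gender", categorical=True),
                     Term("protocol_id", categorical=True)]
            fit = fit_linear_model(merged, trait, terms)
            rows.append({
                "trait": trait,
                "predictor": score_col,
                "beta": float(fit.coefficients[score_col]),
                "se": float(fit.bse[score_col]),
                "p": fit.term_pvalues[score_col],
                "adj_r2_full": fit.adj_r2,
                "n": fit.n,
            })
    return pd.DataFrame(rows)


def single_variant_scan(
    panel: AlignedPanel,
    table: pd.DataFrame,
    traits: list[str] | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Additive single-variant association tests across traits.

    For each (variant, trait): OLS ``trait ~ dosage + age + gender +
    protocol`` with the Wald p-value for the dosage term.  Monomorphic
    variants (no dosage variation among complete rows) are skipped and
    excluded from denominators.  Returns the per-test table and a per-category
    summary with ``nominal_fraction`` = 100 * (#p < alpha) / (#tests).
    """
    traits = traits or [t for t in TRAIT_NAMES if t in table.columns]
    merged = table.join(panel.dosages, how="inner")
    rows = []
    for vid in panel.weights.index:
        cat = panel.weights.loc[vid, "category"]
        for trait in traits:
            sub = merged[[trait, vid, "age", "gender", "protocol_id"]].dropna()
            if sub[vid].nunique() < 2:
                rows.append({"variant_id": vid, "trait": trait, "category": cat,
                             "beta": np.nan, "se": np.nan, "p": np.nan,
                             "n": len(sub), "tested": False})
                continue
            fit = fit_linear_model(
                sub, trait,
                [Term(vid), Term("age"), Term("gender", categorical=True),
                 Term("protocol_id", categorical=True)],
            )
            rows.append({"variant_id": vid, "trait": trait, "category": cat,
                         "beta": float(fit.coefficients[vid]),
                         "se": float(fit.bse[vid]),
                         "p": fit.term_pvalues[vid], "n": fit.n, "tested": True})
    results = pd.DataFrame(rows)
    summaries = []
    for cat, grp in results[results["tested"]].groupby("category"):
        summaries.append({
            "category": cat,
            "n_tests": len(grp),
            "n_nominal": int((grp["p"] < alpha).sum()),
            "nominal_fraction": nominal_fraction(int((grp["p"] < alpha).sum()), len(grp)),
        })
    return results, pd.DataFrame(summaries)


def nominal_fraction(n_hits: int, n_tests: int) -> float:
    """Percentage of tests reaching nominal significance: 100 * hits / tests."""
    if n_tests <= 0:
        raise DomainError("n_tests must be >= 1")
    if not 0 <= n_hits <= n_tests:
        raise DomainError("n_hits must lie in [0, n_tests]")
    return 100.0 * n_hits / n_tests
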