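"""End-to-end pipeline: simulate -> traits -> longitudinal -> cross-sectional
-> genetics, with a run manifest and a consolidated report.

Each stage reads only files written by earlier stages, so a completed run is
reproducible from its output directory alone.  A single global seed fans out
to per-stage child seeds by fixed offsets, which keeps any stage subset
re-runnable with identical results; re-running a completed stage whose
inputs are unchanged (by content hash) is a no-op.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    CohortConfig,
    cross_sectional_config,
    describe_cohort,
    simulate_cohort,
    simulate_genotypes,
    simulate_scan_images,
)
from .cross_sectional import CROSS_SECTIONAL_N_TESTS, bonferroni_threshold, cross_sectional_report
from .errors import ConfigurationError, DependencyError
from .genetics import align_effect_alleles, prs_table, prs_trait_association, single_variant_scan, variant_qc
from .image_traits import extract_scan_traits, scan_traits_frame
from .longitudinal import LONGITUDINAL_N_TESTS, longitudinal_report
from .volume import VolumeImage

logger = logging.getLogger(__name__)

STAGES = ("simulate", "traits", "longitudinal", "cross_sectional", "genetics")

#: Fixed per-stage seed offsets (stage reproducibility under subset reruns).
STAGE_SEED_OFFSET = {
    "simulate": 0,
    "traits": 101,
    "longitudinal": 202,
    "cross_sectional": 303,
    "genetics": 404,
}

_STAGE_INPUTS = {
    "simulate": [],
    "traits": ["scans.tsv", "images"],
    "longitudinal": ["traits.tsv", "patients.tsv"],
    "cross_sectional": ["patients_cs.tsv", "scans_cs.tsv", "prs.tsv"],
    "genetics": ["patients_cs.tsv", "scans_cs.tsv", "genotype_dosages.tsv",
                 "genotype_variants.tsv", "variant_weights.tsv"],
}

#: Execution order differs from the reporting order: the cross-sectional scan
#: includes the three PRS predictors, so genetics runs first.
_EXECUTION_ORDER = ("simulate", "traits", "longitudinal", "genetics", "cross_sectional")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_target(outdir: Path, name: str) -> str:
    p = outdir / name
    if p.is_dir():
        h = hashlib.sha256()
        for f in sorted(p.rglob("*")):
            if f.is_file():
                h.update(f.name.encode())
                h.update(_sha256(f).encode())
        return h.hexdigest()
    if p.is_file():
        return _sha256(p)
    raise DependencyError(f"stage input missing: {name}")


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seed, per-stage hashes, version."""

    seed: int
    config: dict
    version: str = __version__
    stages: dict = field(default_factory=dict)

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        m = cls(seed=d["seed"], config=d["config"], version=d.get("version", "?"))
        m.stages = d.get("stages", {})
        return m


def run_pipeline(
    config: CohortConfig | str | Path,
    outdir: str | Path,
    seed: int | None = None,
    stages: list[str] | None = None,
    write_images: bool = True,
) -> RunManifest:
    """Run the requested pipeline stages into ``outdir``.

    ``config`` is a :class:`CohortConfig` (the longitudinal design; the
    cross-sectional companion design is derived from it) or a path to its
    YAML form.  ``seed`` overrides the config seed.  Requesting a stage whose
    inputs are absent raises :class:`DependencyError` naming the stage.
    """
    if not isinstance(config, CohortConfig):
        config = CohortConfig.from_yaml(config)
    if seed is not None:
        config = CohortConfig.from_dict({**config.to_dict(), "seed": int(seed)})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    requested = list(stages) if stages else list(STAGES)
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages: {sorted(unknown)}")

    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        manifest = RunManifest.load(manifest_path)
        manifest.seed = config.seed
        manifest.config = config.to_dict()
    else:
        manifest = RunManifest(seed=config.seed, config=config.to_dict())

    runners = {
        "simulate": _stage_simulate,
        "traits": _stage_traits,
        "longitudinal": _stage_longitudinal,
        "cross_sectional": _stage_cross_sectional,
        "genetics": _stage_genetics,
    }
    for stage in _EXECUTION_ORDER:
        if stage not in requested:
            continue
        in_hashes = {}
        for name in _STAGE_INPUTS[stage]:
            if name == "images" and not write_images:
                continue
            in_hashes[name] = _hash_target(outdir, name)
        prev = manifest.stages.get(stage)
        if prev and prev.get("inputs") == in_hashes and all(
            (outdir / f).exists() for f in prev.get("outputs", {})
        ):
            logger.info("stage %s up to date; skipping", stage)
            continue
        t0 = time.time()
        stage_seed = config.seed + STAGE_SEED_OFFSET[stage]
        outputs = runners[stage](config, outdir, stage_seed, write_images=write_images)
        manifest.stages[stage] = {
            "inputs": in_hashes,
            "outputs": {name: _hash_target(outdir, name) for name in outputs},
            "seed": stage_seed,
            "elapsed_s": round(time.time() - t0, 3),
            "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        manifest.save(manifest_path)
        logger.info("stage %s done (%.1fs)", stage, time.time() - t0)
    manifest.save(manifest_path)
    return manifest


# --------------------------------------------------------------------------
# stages


def _stage_simulate(config: CohortConfig, outdir: Path, seed: int, write_images: bool) -> list[str]:
    long_cfg = CohortConfig.from_dict({**config.to_dict(), "seed": seed})
    patients, scans = simulate_cohort(long_cfg)
    patients.to_csv(outdir / "patients.tsv", sep="\t", index=False)
    scans.to_csv(outdir / "scans.tsv", sep="\t", index=False)

    cs_cfg = cross_sectional_config(seed=seed + 1)
    patients_cs, scans_cs = simulate_cohort(cs_cfg)
    patients_cs.to_csv(outdir / "patients_cs.tsv", sep="\t", index=False)
    scans_cs.to_csv(outdir / "scans_cs.tsv", sep="\t", index=False)

    eligible = patients_cs.loc[
        patients_cs["genetic_exclusion"].fillna("").astype(str) == "", "patient_id"
    ].tolist()
    genotypes, weights = simulate_genotypes(
        cs_cfg, eligible, rng=np.random.default_rng(seed + 2)
    )
    genotypes.to_tsv(outdir / "genotype_dosages.tsv", outdir / "genotype_variants.tsv")
    weights.to_csv(outdir / "variant_weights.tsv", sep="\t", index_label="variant_id")

    outputs = ["patients.tsv", "scans.tsv", "patients_cs.tsv", "scans_cs.tsv",
               "genotype_dosages.tsv", "genotype_variants.tsv", "variant_weights.tsv"]
    if write_images:
        img_rng = np.random.default_rng(seed + 3)
        img_dir = outdir / "images"
        img_dir.mkdir(exist_ok=True)
        for _, row in scans.iterrows():
            m0, ms, soft, hard, lesion = simulate_scan_images(row.to_dict(), long_cfg, rng=img_rng)
            stem = f"{row['patient_id']}_s{int(row['scan_index'])}"
            m0.to_nifti(img_dir / f"{stem}_m0.nii")
            ms.to_nifti(img_dir / f"{stem}_ms.nii")
            VolumeImage(hard.astype(float), long_cfg.voxel_size, "phantom").to_nifti(
                img_dir / f"{stem}_hardseg.nii")
            VolumeImage(lesion.astype(float), long_cfg.voxel_size, "phantom").to_nifti(
                img_dir / f"{stem}_lesion.nii")
        outputs.append("images")
    return outputs


def _stage_traits(config: CohortConfig, outdir: Path, seed: int, write_images: bool) -> list[str]:
    scans = pd.read_csv(outdir / "scans.tsv", sep="\t")
    img_dir = outdir / "images"
    if not img_dir.is_dir():
        raise DependencyError("traits stage requires images from the simulate stage")
    rows = []
    for _, row in scans.iterrows():
        stem = f"{row['patient_id']}_s{int(row['scan_index'])}"
        m0 = VolumeImage.from_nifti(img_dir / f"{stem}_m0.nii", space_tag="phantom")
        ms = VolumeImage.from_nifti(img_dir / f"{stem}_ms.nii", space_tag="phantom")
        hard = VolumeImage.from_nifti(img_dir / f"{stem}_hardseg.nii").data.astype(int)
        lesion = VolumeImage.from_nifti(img_dir / f"{stem}_lesion.nii").data > 0.5
        soft = {"gm": (hard == 1).astype(float), "wm": (hard == 2).astype(float),
                "csf": (hard == 3).astype(float)}
        rows.append(extract_scan_traits(
            m0, ms, hard, soft, lesion_mask_kappa0=lesion, lesion_mask_kappa1=lesion,
            patient_id=row["patient_id"], scan_index=int(row["scan_index"]),
            time_days=float(row["time_days"]), protocol_id=str(row["protocol_id"]),
        ))
    scan_traits_frame(rows).to_csv(outdir / "traits.tsv", sep="\t", index=False)
    return ["traits.tsv"]


def _stage_longitudinal(config: CohortConfig, outdir: Path, seed: int, write_images: bool) -> list[str]:
    traits = pd.read_csv(outdir / "traits.tsv", sep="\t")
    patients = pd.read_csv(outdir / "patients.tsv", sep="\t")
    report = longitudinal_report(traits, patients)
    report.to_csv(outdir / "longitudinal.tsv", sep="\t", index=False)
    summary = {
        "bonferroni_threshold": bonferroni_threshold(0.05, LONGITUDINAL_N_TESTS),
        "n_tests": LONGITUDINAL_N_TESTS,
        "min_generic_adj_r2": float(report["generic_adj_r2"].min()),
        "min_patient_share_pct": float(report["patient_share_pct"].min()),
        "max_time_share_pct": float(report["time_share_pct"].max()),
    }
    with open(outdir / "longitudinal_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return ["longitudinal.tsv", "longitudinal_summary.json"]


def _stage_genetics(config: CohortConfig, outdir: Path, seed: int, write_images: bool) -> list[str]:
    from .genetics import GenotypeMatrix

    genotypes = GenotypeMatrix.from_tsv(
        outdir / "genotype_dosages.tsv", outdir / "genotype_variants.tsv")
    weights = pd.read_csv(outdir / "variant_weights.tsv", sep="\t", index_col="variant_id")
    patients_cs = pd.read_csv(outdir / "patients_cs.tsv", sep="\t")
    scans_cs = pd.read_csv(outdir / "scans_cs.tsv", sep="\t")

    qc = variant_qc(genotypes)
    qc.table.to_csv(outdir / "variant_qc.tsv", sep="\t")
    kept = qc.kept_ids
    filtered = GenotypeMatrix(
        dosages=genotypes.dosages[kept], variants=genotypes.variants.loc[kept])
    panel = align_effect_alleles(filtered, weights.loc[[v for v in weights.index if v in kept]])
    scores = prs_table(panel)
    scores.to_csv(outdir / "prs.tsv", sep="\t", index_label="patient_id")

    from .cross_sectional import first_scans

    table = first_scans(scans_cs, patients_cs).set_index("patient_id")
    assoc = prs_trait_association(scores, table)
    assoc.to_csv(outdir / "prs_associations.tsv", sep="\t", index=False)
    results, summary = single_variant_scan(panel, table)
    results.to_csv(outdir / "single_variant_scan.tsv", sep="\t", index=False)
    summary.to_csv(outdir / "single_variant_summary.tsv", sep="\t", index=False)
    return ["variant_qc.tsv", "prs.tsv", "prs_associations.tsv",
            "single_variant_scan.tsv", "single_variant_summary.tsv"]


def _stage_cross_sectional(config: CohortConfig, outdir: Path, seed: int, write_images: bool) -> list[str]:
    patients_cs = pd.read_csv(outdir / "patients_cs.tsv", sep="\t")
    scans_cs = pd.read_csv(outdir / "scans_cs.tsv", sep="\t")
    prs = pd.read_csv(outdir / "prs.tsv", sep="\t", index_col="patient_id")
    tables = cross_sectional_report(scans_cs, patients_cs, extra_predictors=prs)
    tables["age_gender"].to_csv(outdir / "age_gender_variance.tsv", sep="\t", index=False)
    tables["cross_tissue"].to_csv(outdir / "cross_tissue.tsv", sep="\t", index=False)
    tables["clinical_scan"].to_csv(outdir / "clinical_scan.tsv", sep="\t", index=False)
    with open(outdir / "cross_sectional_summary.json", "w") as fh:
        json.dump({
            "bonferroni_threshold": bonferroni_threshold(0.05, CROSS_SECTIONAL_N_TESTS),
            "n_tests": CROSS_SECTIONAL_N_TESTS,
            "cohort": describe_cohort(patients_cs),
        }, fh, indent=2)
    return ["age_gender_variance.tsv", "cross_tissue.tsv", "clinical_scan.tsv",
            "cross_sectional_summary.json"]


# --------------------------------------------------------------------------
# report


def render_report(outdir: str | Path) -> tuple[str, dict]:
    """Consolidated Markdown + JSON report from whatever stage outputs exist.

    Missing sections are noted, never fatal.  All numbers are re-read from
    the stage TSV/JSON files so the report can be regenerated at any time.
    """
    outdir = Path(outdir)
    md: list[str] = ["# Synthetic MS cohort quantitative-MRI report", ""]
    js: dict = {}

    def table_md(df: pd.DataFrame, cols: list[str]) -> list[str]:
        cols = [c for c in cols if c in df.columns]
        lines = ["| " + " | ".join(cols) + " |", "|" + "---|" * len(cols)]
        for _, r in df.iterrows():
            cells = [f"{r[c]:.4g}" if isinstance(r[c], float) else str(r[c]) for c in cols]
            lines.append("| " + " | ".join(cells) + " |")
        return lines

    p = outdir / "longitudinal.tsv"
    if p.exists():
        rep = pd.read_csv(p, sep="\t")
        md += ["## Longitudinal variance decomposition",
               f"Bonferroni threshold: {bonferroni_threshold(0.05, LONGITUDINAL_N_TESTS):.4g} "
               f"({LONGITUDINAL_N_TESTS} tests)", ""]
        md += table_md(rep, ["trait", "generic_adj_r2", "generic_p", "patient_share_pct",
                             "time_share_pct", "clinical_adj_r2", "clinical_p"])
        md.append("")
        js["longitudinal"] = rep.to_dict(orient="records")
    else:
        md += ["## Longitudinal variance decomposition", "_absent_", ""]

    p = outdir / "cross_tissue.tsv"
    if p.exists():
        ct = pd.read_csv(p, sep="\t")
        md += ["## Cross-tissue MTR correlation (covariate-adjusted)", ""]
        md += table_md(ct, ["trait", "predictor", "adj_r2_full", "p", "n"])
        md.append("")
        js["cross_tissue"] = ct.to_dict(orient="records")
    else:
        md += ["## Cross-tissue MTR correlation", "_absent_", ""]

    p = outdir / "age_gender_variance.tsv"
    if p.exists():
        ag = pd.read_csv(p, sep="\t")
        md += ["## Variance explained by age and gender", ""]
        md += table_md(ag, ["trait", "delta_adj_r2", "p", "n"])
        md.append("")
        js["age_gender"] = ag.to_dict(orient="records")

    p = outdir / "clinical_scan.tsv"
    if p.exists():
        cs = pd.read_csv(p, sep="\t")
        tested = cs[cs["tested"]] if "tested" in cs else cs
        nominal = float((tested["p"] < 0.05).mean() * 100) if len(tested) else float("nan")
        md += ["## Clinical/demographic/genetic association scan",
               f"{len(tested)} tests performed; {nominal:.1f}% nominally significant; "
               f"Bonferroni threshold {bonferroni_threshold(0.05, CROSS_SECTIONAL_N_TESTS):.4g}.", ""]
        js["clinical_scan_nominal_pct"] = nominal

    p = outdir / "single_variant_summary.tsv"
    if p.exists():
        sv = pd.read_csv(p, sep="\t")
        md += ["## Single-variant association scan", ""]
        md += table_md(sv, ["category", "n_tests", "n_nominal", "nominal_fraction"])
        md.append("")
        js["single_variant"] = sv.to_dict(orient="records")
    else:
        md += ["## Single-variant association scan", "_absent_", ""]

    p = outdir / "prs_associations.tsv"
    if p.exists():
        pa = pd.read_csv(p, sep="\t")
        js["prs_min_p"] = float(pa["p"].min())
        md += ["## Polygenic risk score associations",
               f"minimum p over {len(pa)} (trait, score) tests: {js['prs_min_p']:.3g}", ""]

    text = "\n".join(md)
    with open(outdir / "report.md", "w") as fh:
        fh.write(text)
    with open(outdir / "report.json", "w") as fh:
        json.dump(js, fh, indent=2)
    return text, js
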