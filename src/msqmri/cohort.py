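"""Synthetic MS cohort generator.

No public imaging/genetic dataset accompanies this kind of clinical MS
cohort, so every downstream stage is exercised on synthetic data whose
statistical structure matches the analyses' assumptions:

* latent per-scan MRI traits follow an additive Gaussian model —
  ``trait(i, j) = grand mean + protocol effect + beta_age * (age - 40)
  + beta_female * female + b_i + time_ij * slope + eps_ij`` with patient
  random intercepts ``b_i ~ N(0, sigma_between^2)`` dominating the residual
  scan noise ``eps ~ N(0, sigma_within^2)`` (high intraclass correlation,
  small longitudinal drift);
* voxel-level image pairs (M0/Ms) are generated by inverting the MTR
  definition around the latent tissue medians, on a phantom geometry whose
  compartment sizes realize the latent volumetric traits;
* genotypes are Binomial(2, p) draws — Hardy-Weinberg by construction —
  with null effects on all traits, plus a risk-variant weight table
  (22 HLA + 133 non-HLA variants by default).

The default longitudinal design is 33 patients / 72 scans (29 patients with
two scans, 3 with three, 1 with five, all on one protocol, mean inter-scan
interval 13.2 +/- 7.9 months); the default cross-sectional design is 213
patients on 5 protocols, 209 eligible for genetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .errors import ConfigurationError, DomainError
from .genetics import GenotypeMatrix
from .image_traits import (
    LABEL_BACKGROUND,
    LABEL_CSF,
    LABEL_GM,
    LABEL_WM,
    MTR_TRAITS,
    TRAIT_NAMES,
)
from .volume import VolumeImage

MEDIAN_TRAITS = ("lesion_mtr_median", "nawm_mtr_median", "nagm_mtr_median")
PEAK_TRAITS = ("lesion_mtr_peak_height", "nawm_mtr_peak_height", "nagm_mtr_peak_height")

DAYS_PER_MONTH = 30.4375

#: Latent grand means.  MTR medians keep the known tissue contrast
#: (lesions < NAGM < NAWM); volumes are phantom-scale (a 32^3 mm grid), not
#: human-scale, so absolute volumes are arbitrary while percentages are
#: anatomically plausible.
DEFAULT_TRAIT_MEANS = {
    "lesion_mtr_median": 30.0,
    "nawm_mtr_median": 38.0,
    "nagm_mtr_median": 32.0,
    "lesion_mtr_peak_height": 8.0,
    "nawm_mtr_peak_height": 14.0,
    "nagm_mtr_peak_height": 11.0,
    "total_brain_volume": 16.0,
    "wm_pct": 40.0,
    "gm_pct": 45.0,
    "lesion_volume": 0.5,
}

DEFAULT_SIGMA_BETWEEN = {
    "lesion_mtr_median": 1.5,
    "nawm_mtr_median": 1.2,
    "nagm_mtr_median": 1.0,
    "lesion_mtr_peak_height": 2.0,
    "nawm_mtr_peak_height": 2.0,
    "nagm_mtr_peak_height": 2.0,
    "total_brain_volume": 1.5,
    "wm_pct": 2.0,
    "gm_pct": 2.0,
    "lesion_volume": 0.2,
}

#: Per-day longitudinal drift: slow MTR / volume decline, slow lesion growth.
DEFAULT_TIME_SLOPE = {
    "lesion_mtr_median": -2e-4,
    "nawm_mtr_median": -2e-4,
    "nagm_mtr_median": -2e-4,
    "lesion_mtr_peak_height": -2.5e-4,
    "nawm_mtr_peak_height": -2.5e-4,
    "nagm_mtr_peak_height": -2.5e-4,
    "total_brain_volume": -3e-4,
    "wm_pct": -1e-4,
    "gm_pct": -1.5e-4,
    "lesion_volume": 5e-5,
}

#: Fractions of trait variance jointly produced by (age, gender), anchored
#: to the reported physiology: age+gender determine about a third of total
#: brain volume and GM percentage variance, mid-single-digit percent of MTR
#: peak heights, and ~1% of MTR medians.
DEFAULT_COVARIATE_SHARES = {
    "lesion_mtr_median": (0.012, 0.0),
    "nawm_mtr_median": (0.012, 0.0),
    "nagm_mtr_median": (0.012, 0.0),
    "lesion_mtr_peak_height": (0.06, 0.0),
    "nawm_mtr_peak_height": (0.06, 0.0),
    "nagm_mtr_peak_height": (0.06, 0.0),
    "total_brain_volume": (0.17, 0.17),
    "wm_pct": (0.01, 0.02),
    "gm_pct": (0.22, 0.08),
    "lesion_volume": (0.0, 0.0),
}

#: Signs of the age effect and the female-gender effect per trait.
DEFAULT_COVARIATE_SIGNS = {
    "lesion_mtr_median": (-1, -1),
    "nawm_mtr_median": (-1, -1),
    "nagm_mtr_median": (-1, -1),
    "lesion_mtr_peak_height": (-1, -1),
    "nawm_mtr_peak_height": (-1, -1),
    "nagm_mtr_peak_height": (-1, -1),
    "total_brain_volume": (-1, -1),
    "wm_pct": (-1, -1),
    "gm_pct": (-1, +1),
    "lesion_volume": (+1, -1),
}

#: Cross-tissue correlations of the patient random intercepts: MTR traits
#: correlate across tissues within a patient, strongest between the two
#: normal-appearing tissues, weaker between lesions and normal-appearing
#: tissue.
DEFAULT_CROSS_TISSUE_CORR = {
    "median_na": 0.55,
    "median_lesion": 0.42,
    "peak_na": 0.65,
    "peak_lesion": 0.31,
}


def _per_trait(value, default: Mapping[str, float]) -> dict[str, float]:
    """Resolve a scalar / partial-dict / None parameter to a full per-trait dict."""
    if value is None:
        return dict(default)
    if isinstance(value, (int, float)):
        return {t: float(value) for t in TRAIT_NAMES}
    out = dict(default)
    unknown = set(value) - set(TRAIT_NAMES)
    if unknown:
        raise ConfigurationError(f"unknown trait names in config: {sorted(unknown)}")
    out.update({k: float(v) for k, v in value.items()})
    return out


@dataclass
class CohortConfig:
    """Study-design and generative parameters for one synthetic cohort.

    ``sigma_between`` / ``sigma_within`` / ``time_slope`` / ``beta_age`` /
    ``beta_gender`` accept a scalar (applied to every trait), a partial
    per-trait mapping, or None for the documented defaults; ``sigma_within``
    defaults to ``0.2 * sigma_between`` and the covariate betas are derived
    from ``covariate_shares`` (target fractions of trait variance explained
    by age and gender).
    """

    scans_per_patient: dict[int, int] = field(default_factory=lambda: {2: 29, 3: 3, 5: 1})
    n_patients: int | None = None
    n_protocols: int = 1
    image_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    trait_means: dict | None = None
    sigma_between: object = None
    sigma_within: object = None
    time_slope: object = None
    beta_age: object = None
    beta_gender: object = None
    covariate_shares: dict | None = None
    protocol_effect_scale: float = 0.15
    cross_tissue_corr: dict | None = None
    p_female: float = 0.71
    age_mean: float = 40.0
    age_sd: float = 12.0
    age_range: tuple[float, float] = (19.0, 71.0)
    duration_shape: float = 2.0
    duration_scale: float = 5.0
    interval_months_mean: float = 13.2
    interval_months_sd: float = 7.9
    interval_months_min: float = 1.0
    m0_mean: float = 1000.0
    m0_noise_sd: float = 20.0
    mtr_noise_sd: float | None = None
    csf_mtr: float = 5.0
    n_variants: int = 155
    n_hla: int = 22
    maf_range: tuple[float, float] = (0.05, 0.5)
    log_or_sd: float = 0.15
    n_genetic_excluded: int = 0
    seed: int = 0

    # ------------------------------------------------------------ validation
    def __post_init__(self) -> None:
        self.scans_per_patient = {int(k): int(v) for k, v in self.scans_per_patient.items()}
        if any(k < 1 or v < 0 for k, v in self.scans_per_patient.items()):
            raise ConfigurationError("scans_per_patient needs scan counts >= 1, patient counts >= 0")
        total = sum(self.scans_per_patient.values())
        if self.n_patients is None:
            self.n_patients = total
        elif self.n_patients != total:
            raise ConfigurationError(
                f"scans_per_patient counts sum to {total}, not n_patients={self.n_patients}"
            )
        if self.n_patients < 1:
            raise ConfigurationError("need at least one patient")
        if self.n_protocols < 1:
            raise ConfigurationError("n_protocols must be >= 1")
        if any(s < 8 for s in self.image_shape):
            raise ConfigurationError("image_shape must be >= 8 voxels per axis")
        self.image_shape = tuple(int(s) for s in self.image_shape)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

        self.trait_means = _per_trait(self.trait_means, DEFAULT_TRAIT_MEANS)
        self.sigma_between = _per_trait(self.sigma_between, DEFAULT_SIGMA_BETWEEN)
        default_within = {t: 0.2 * s for t, s in self.sigma_between.items()}
        self.sigma_within = _per_trait(self.sigma_within, default_within)
        self.time_slope = _per_trait(self.time_slope, DEFAULT_TIME_SLOPE)
        if any(v < 0 for v in self.sigma_between.values()):
            raise ConfigurationError("sigma_between must be >= 0")
        if any(v < 0 for v in self.sigma_within.values()):
            raise ConfigurationError("sigma_within must be >= 0")
        for t in MEDIAN_TRAITS:
            if not 0 < self.trait_means[t] < 100:
                raise ConfigurationError(f"tissue MTR center {t} must lie in (0, 100)")

        shares = dict(DEFAULT_COVARIATE_SHARES)
        if self.covariate_shares:
            shares.update({k: tuple(v) for k, v in self.covariate_shares.items()})
        self.covariate_shares = shares
        if self.beta_age is None or self.beta_gender is None:
            ba, bg = derive_covariate_betas(
                self.sigma_between, self.sigma_within, shares,
                age_sd=self.age_sd, p_female=self.p_female,
            )
            if self.beta_age is None:
                self.beta_age = ba
            if self.beta_gender is None:
                self.beta_gender = bg
        self.beta_age = _per_trait(self.beta_age, {t: 0.0 for t in TRAIT_NAMES})
        self.beta_gender = _per_trait(self.beta_gender, {t: 0.0 for t in TRAIT_NAMES})

        corr = dict(DEFAULT_CROSS_TISSUE_CORR)
        if self.cross_tissue_corr:
            corr.update(self.cross_tissue_corr)
        self.cross_tissue_corr = corr

        self.maf_range = tuple(float(v) for v in self.maf_range)
        self.age_range = tuple(float(v) for v in self.age_range)
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must be within (0, 0.5], got {self.maf_range}")
        if not 0 <= self.n_hla <= self.n_variants:
            raise ConfigurationError("n_hla must lie in [0, n_variants]")
        if self.n_variants < 1:
            raise ConfigurationError("n_variants must be >= 1")
        if not 0 <= self.n_genetic_excluded <= self.n_patients:
            raise ConfigurationError("n_genetic_excluded out of range")

    # ------------------------------------------------------------ serde
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def longitudinal_config(**overrides) -> CohortConfig:
    """The longitudinal study design: 33 patients, 72 scans, one protocol."""
    return CohortConfig(**overrides)


def cross_sectional_config(n_patients: int = 213, **overrides) -> CohortConfig:
    """The cross-sectional design: one scan per patient, 5 protocols, 209 of
    213 patients eligible for genetics (1 without genetic data, 3 excluded
    for cryptic relatedness)."""
    overrides.setdefault("scans_per_patient", {1: n_patients})
    overrides.setdefault("n_protocols", 5)
    overrides.setdefault("n_genetic_excluded", 4 if n_patients >= 5 else 0)
    return CohortConfig(**overrides)


def derive_covariate_betas(
    sigma_between: Mapping[str, float],
    sigma_within: Mapping[str, float],
    shares: Mapping[str, tuple[float, float]],
    age_sd: float,
    p_female: float,
) -> tuple[dict[str, float], dict[str, float]]:
    """Effect sizes hitting target explained-variance fractions.

    For target joint share ``s = s_age + s_gender`` of total trait variance,
    the explained variance must equal ``s / (1 - s)`` times the residual
    (random intercept + scan noise) variance; each beta then follows from the
    covariate's variance (``age_sd^2`` for age, ``p(1-p)`` for the female
    indicator).
    """
    beta_age, beta_gender = {}, {}
    var_gender = p_female * (1.0 - p_female)
    for t in TRAIT_NAMES:
        s_age, s_gender = shares.get(t, (0.0, 0.0))
        s = s_age + s_gender
        if not 0 <= s < 1:
            raise ConfigurationError(f"covariate share for {t} must lie in [0, 1)")
        resid = sigma_between[t] ** 2 + sigma_within[t] ** 2
        scale = resid / (1.0 - s) if s > 0 else 0.0
        sign_age, sign_gender = DEFAULT_COVARIATE_SIGNS[t]
        beta_age[t] = sign_age * math.sqrt(s_age * scale) / age_sd if s_age > 0 else 0.0
        beta_gender[t] = (
            sign_gender * math.sqrt(s_gender * scale / var_gender) if s_gender > 0 else 0.0
        )
    return beta_age, beta_gender


# --------------------------------------------------------------------------
# latent cohort simulation


def _intercept_correlation(config: CohortConfig) -> np.ndarray:
    """10x10 correlation matrix of the patient random intercepts."""
    C = np.eye(len(TRAIT_NAMES))
    idx = {t: i for i, t in enumerate(TRAIT_NAMES)}
    cc = config.cross_tissue_corr

    def set_corr(a, b, r):
        C[idx[a], idx[b]] = C[idx[b], idx[a]] = r

    set_corr("nawm_mtr_median", "nagm_mtr_median", cc["median_na"])
    set_corr("lesion_mtr_median", "nawm_mtr_median", cc["median_lesion"])
    set_corr("lesion_mtr_median", "nagm_mtr_median", cc["median_lesion"])
    set_corr("nawm_mtr_peak_height", "nagm_mtr_peak_height", cc["peak_na"])
    set_corr("lesion_mtr_peak_height", "nawm_mtr_peak_height", cc["peak_lesion"])
    set_corr("lesion_mtr_peak_height", "nagm_mtr_peak_height", cc["peak_lesion"])
    # guard: must be positive semdefinite
    eigmin = np.linalg.eigvalsh(C).min()
    if eigmin < -1e-10:
        raise ConfigurationError("cross-tissue correlation matrix is not positive semidefinite")
    return C


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, bad.sum())
    return np.clip(out, lo, hi)


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the patient table and the latent per-scan trait table.

    Returns ``(patients, scans)``.  ``patients`` carries demographics,
    protocol, clinical covariates and the genetic-exclusion flag; ``scans``
    one row per (patient, scan) with days since that patient's first scan
    (first scan at 0) and the 10 latent traits.  Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    ids = [f"P{i + 1:03d}" for i in range(n)]
    scan_counts = np.repeat(
        list(config.scans_per_patient.keys()), list(config.scans_per_patient.values())
    )
    rng.shuffle(scan_counts)

    age = _truncated_normal(rng, config.age_mean, config.age_sd, *config.age_range, n)
    female = rng.random(n) < config.p_female
    duration = rng.gamma(config.duration_shape, config.duration_scale, n)
    protocols = [chr(ord("A") + i) for i in range(config.n_protocols)]
    protocol = rng.choice(protocols, size=n) if config.n_protocols > 1 else np.array(["D"] * n)

    # protocol offsets per trait, scaled to the between-patient SD
    proto_offsets = {
        t: {
            p: (config.protocol_effect_scale * config.sigma_between[t] * rng.standard_normal()
                if config.n_protocols > 1 else 0.0)
            for p in np.unique(protocol)
        }
        for t in TRAIT_NAMES
    }

    # correlated random intercepts
    C = _intercept_correlation(config)
    sds = np.array([config.sigma_between[t] for t in TRAIT_NAMES])
    cov = C * np.outer(sds, sds)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(TRAIT_NAMES)))
    intercepts = rng.standard_normal((n, len(TRAIT_NAMES))) @ L.T

    # clinical covariates (null with respect to the traits)
    ocb_missing = rng.random(n) < 0.09
    ocb_pos = rng.random(n) < 0.906
    ocb = np.where(ocb_missing, None, np.where(ocb_pos, "positive", "negative"))
    igg = np.exp(rng.normal(math.log(0.9), 0.35, n))
    msss = np.clip(rng.gamma(1.5, 1.5, n), 0.11, 9.45)
    treatment = np.where(rng.random(n) < 0.625, "on", "off")

    exclusion = np.array([""] * n, dtype=object)
    if config.n_genetic_excluded:
        excluded = rng.choice(n, size=config.n_genetic_excluded, replace=False)
        exclusion[excluded[0]] = "no_genetic_data"
        for j in excluded[1:]:
            exclusion[j] = "relatedness"

    patients = pd.DataFrame({
        "patient_id": ids,
        "age": age,
        "gender": np.where(female, "female", "male"),
        "disease_duration": duration,
        "protocol_id": protocol,
        "n_scans": scan_counts,
        "ocb_status": ocb,
        "igg_index": igg,
        "msss": msss,
        "treatment_status": treatment,
        "genetic_exclusion": exclusion,
    })

    interval_days_mean = config.interval_months_mean * DAYS_PER_MONTH
    interval_days_sd = config.interval_months_sd * DAYS_PER_MONTH
    interval_days_min = config.interval_months_min * DAYS_PER_MONTH

    rows = []
    for i in range(n):
        k = int(scan_counts[i])
        t = 0.0
        for j in range(k):
            if j > 0:
                t += float(
                    _truncated_normal(
                        rng, interval_days_mean, interval_days_sd,
                        interval_days_min, np.inf, 1,
                    )[0]
                )
            row = {
                "patient_id": ids[i],
                "scan_index": j,
                "time_days": t,
                "protocol_id": patients.loc[i, "protocol_id"],
            }
            for m, trait in enumerate(TRAIT_NAMES):
                val = (
                    config.trait_means[trait]
                    + config.beta_age[trait] * (age[i] - config.age_mean)
                    + config.beta_gender[trait] * (1.0 if female[i] else 0.0)
                    + proto_offsets[trait][patients.loc[i, "protocol_id"]]
                    + intercepts[i, m]
                    + config.time_slope[trait] * t
                    + rng.normal(0.0, config.sigma_within[trait])
                )
                row[trait] = val
            rows.append(row)
    scans = pd.DataFrame(rows)

    # keep latents inside their physical domains (negligible probability at
    # the default scales, but required for image generation)
    for t in MEDIAN_TRAITS:
        scans[t] = scans[t].clip(0.5, 99.5)
    for t in PEAK_TRAITS:
        scans[t] = scans[t].clip(1.0, 99.0)
    scans["total_brain_volume"] = scans["total_brain_volume"].clip(lower=1.0)
    scans["lesion_volume"] = scans["lesion_volume"].clip(lower=0.02)
    scans["wm_pct"] = scans["wm_pct"].clip(5.0, 80.0)
    scans["gm_pct"] = scans["gm_pct"].clip(5.0, 80.0)
    return patients, scans


# --------------------------------------------------------------------------
# image simulation


def sigma_from_peak_height(peak_height: float, bin_width: float = 1.0) -> float:
    """Gaussian voxel-noise SD whose modal-bin mass equals ``peak_height``%.

    For MTR values ~ N(mu, sigma) with mu at a bin center, the modal bin of
    width w captures ``2 Phi(w / (2 sigma)) - 1`` of the voxels; inverting
    gives sigma.  Used to plant the latent peak-height trait in images.
    """
    if not 0 < peak_height < 100:
        raise DomainError("peak_height must lie in (0, 100)")
    q = norm.ppf(0.5 + peak_height / 200.0)
    return bin_width / (2.0 * q)


def peak_height_from_sigma(sigma: float, bin_width: float = 1.0) -> float:
    """Inverse of :func:`sigma_from_peak_height`."""
    if sigma <= 0:
        return 100.0
    return 100.0 * (2.0 * norm.cdf(bin_width / (2.0 * sigma)) - 1.0)


def simulate_scan_images(
    latents: Mapping[str, float],
    config: CohortConfig,
    rng: np.random.Generator | None = None,
):
    """Generate one scan's image set from its latent traits.

    Builds a spherical brain phantom whose voxel counts realize the latent
    volumetric traits (WM core, GM shell, CSF rim; lesion = blob of WM voxels
    around a random seed voxel), draws per-voxel target MTR around each
    tissue's latent median (noise SD from the latent peak height unless
    ``config.mtr_noise_sd`` overrides it), and inverts the MTR definition:
    M0 is a positive constant plus noise and ``Ms = M0 * (1 - MTR/100)``.

    Returns ``(m0, ms, soft_seg, hard_seg, lesion_mask)`` where ``soft_seg``
    is a dict of gm/wm/csf probability grids (one-hot, summing to 1 at every
    brain voxel).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    for t in MEDIAN_TRAITS:
        if not 0 < latents[t] < 100:
            raise DomainError(f"latent median {t}={latents[t]} outside (0, 100)")
    shape = config.image_shape
    if any(s < 8 for s in shape):
        raise ConfigurationError("image_shape must be >= 8 voxels per axis")
    vox_mm3 = float(np.prod(config.voxel_size))
    n_vox = int(np.prod(shape))

    n_brain = int(round(latents["total_brain_volume"] * 1000.0 / vox_mm3))
    if n_brain < 10:
        raise DomainError("total brain volume too small for the voxel grid")
    if n_brain > 0.95 * n_vox:
        raise DomainError("total brain volume exceeds the voxel grid")

    # voxels ordered by distance from the grid center (stable ties)
    coords = np.indices(shape).reshape(3, -1).T.astype(float)
    center = (np.asarray(shape) - 1) / 2.0
    r2 = ((coords - center) ** 2 * np.asarray(config.voxel_size) ** 2).sum(axis=1)
    order = np.argsort(r2, kind="stable")
    brain = order[:n_brain]

    n_wm = int(round(latents["wm_pct"] / 100.0 * n_brain))
    n_gm = int(round(latents["gm_pct"] / 100.0 * n_brain))
    if n_wm + n_gm > n_brain:
        raise DomainError("wm_pct + gm_pct exceed 100% of brain volume")
    wm_idx = brain[:n_wm]
    gm_idx = brain[n_wm:n_wm + n_gm]
    csf_idx = brain[n_wm + n_gm:]

    n_lesion = int(round(latents["lesion_volume"] * 1000.0 / vox_mm3))
    n_lesion = min(n_lesion, n_wm)
    if n_lesion > 0:
        seed_vox = wm_idx[rng.integers(len(wm_idx))]
        d2 = ((coords[wm_idx] - coords[seed_vox]) ** 2).sum(axis=1)
        lesion_idx = wm_idx[np.argsort(d2, kind="stable")[:n_lesion]]
    else:
        lesion_idx = np.array([], dtype=int)

    hard = np.full(n_vox, LABEL_BACKGROUND, dtype=np.int16)
    hard[gm_idx] = LABEL_GM
    hard[wm_idx] = LABEL_WM
    hard[csf_idx] = LABEL_CSF
    lesion_mask = np.zeros(n_vox, dtype=bool)
    lesion_mask[lesion_idx] = True

    if config.mtr_noise_sd is not None:
        sd = {t: float(config.mtr_noise_sd) for t in ("lesion", "nawm", "nagm")}
    else:
        sd = {
            "lesion": sigma_from_peak_height(latents["lesion_mtr_peak_height"]),
            "nawm": sigma_from_peak_height(latents["nawm_mtr_peak_height"]),
            "nagm": sigma_from_peak_height(latents["nagm_mtr_peak_height"]),
        }

    mtr = np.zeros(n_vox)
    nawm_idx = np.setdiff1d(wm_idx, lesion_idx, assume_unique=True)
    mtr[lesion_idx] = latents["lesion_mtr_median"] + rng.normal(0, sd["lesion"], lesion_idx.size)
    mtr[nawm_idx] = latents["nawm_mtr_median"] + rng.normal(0, sd["nawm"], nawm_idx.size)
    mtr[gm_idx] = latents["nagm_mtr_median"] + rng.normal(0, sd["nagm"], gm_idx.size)
    mtr[csf_idx] = np.clip(config.csf_mtr + rng.normal(0, 1.0, csf_idx.size), 0, None)

    m0 = np.zeros(n_vox)
    noise = rng.normal(0, config.m0_noise_sd, n_brain) if config.m0_noise_sd > 0 else 0.0
    m0[brain] = np.clip(config.m0_mean + noise, 1.0, None)
    ms = m0 * (1.0 - mtr / 100.0)

    soft = {
        "gm": (hard == LABEL_GM).astype(float).reshape(shape),
        "wm": (hard == LABEL_WM).astype(float).reshape(shape),
        "csf": (hard == LABEL_CSF).astype(float).reshape(shape),
    }
    m0_img = VolumeImage(m0.reshape(shape), config.voxel_size, space_tag="phantom")
    ms_img = VolumeImage(ms.reshape(shape), config.voxel_size, space_tag="phantom")
    return m0_img, ms_img, soft, hard.reshape(shape), lesion_mask.reshape(shape)


# --------------------------------------------------------------------------
# genotype simulation


def simulate_genotypes(
    config: CohortConfig,
    patient_ids: list[str],
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Null-effect genotypes and a risk-variant weight table.

    Each variant's dosage is Binomial(2, p) with p uniform in ``maf_range``
    — Hardy-Weinberg proportions hold by construction — and has no effect on
    any trait.  The weight table carries effect/other allele and an odds
    ratio drawn log-normally around 1 (some < 1, exercising allele flips);
    the first ``n_hla`` variants are flagged HLA (chromosome 6).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 7919)
    nv, n = config.n_variants, len(patient_ids)
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, nv)
    dosages = rng.binomial(2, freqs, size=(n, nv)).astype(float)

    bases = np.array(list("ACGT"))
    ids, meta = [], []
    for v in range(nv):
        vid = f"rs{100000 + v}"
        ids.append(vid)
        a, b = rng.choice(4, size=2, replace=False)
        hla = v < config.n_hla
        meta.append({
            "variant_id": vid,
            "chrom": "6" if hla else str(1 + v % 22),
            "pos": 29_000_000 + 1000 * v if hla else 1_000_000 + 10_000 * v,
            "allele_a": bases[a],
            "allele_b": bases[b],
            "category": "HLA" if hla else "non-HLA",
        })
    variants = pd.DataFrame(meta).set_index("variant_id")
    genotypes = GenotypeMatrix(
        dosages=pd.DataFrame(
            dosages, index=pd.Index(patient_ids, name="patient_id"), columns=ids),
        variants=variants,
    )

    effect_is_b = rng.random(nv) < 0.5
    weights = pd.DataFrame({
        "variant_id": ids,
        "effect_allele": np.where(effect_is_b, variants["allele_b"], variants["allele_a"]),
        "other_allele": np.where(effect_is_b, variants["allele_a"], variants["allele_b"]),
        "odds_ratio": np.exp(rng.normal(0.0, config.log_or_sd, nv)),
        "category": variants["category"].to_numpy(),
    }).set_index("variant_id")
    return genotypes, weights


# --------------------------------------------------------------------------
# descriptives and I/O


def describe_cohort(patients: pd.DataFrame) -> dict:
    """Descriptive cohort summary (counts, percentages, medians)."""
    n = len(patients)
    n_female = int((patients["gender"] == "female").sum())
    out = {
        "n_patients": n,
        "n_female": n_female,
        "n_male": n - n_female,
        "pct_female": 100.0 * n_female / n if n else math.nan,
    }
    for col, key in [("age", "median_age"), ("disease_duration", "median_disease_duration"),
                     ("msss", "median_msss")]:
        if col in patients:
            out[key] = float(patients[col].median())
    if "treatment_status" in patients:
        out["pct_on_treatment"] = 100.0 * float((patients["treatment_status"] == "on").mean())
    if "genetic_exclusion" in patients:
        flagged = patients["genetic_exclusion"].fillna("").astype(str) != ""
        out["n_genetic_eligible"] = int((~flagged).sum())
    return out


def write_cohort_tables(outdir, patients: pd.DataFrame, scans: pd.DataFrame) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": outdir / "patients.tsv",
        "scans": outdir / "scans.tsv",
    }
    patients.to_csv(paths["patients"], sep="\t", index=False)
    scans.to_csv(paths["scans"], sep="\t", index=False)
    return paths
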