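"""Per-scan quantitative MRI traits.

Computes, for one co-registered scan:

* the magnetization transfer ratio map, ``MTR = 100 * (M0 - Ms) / M0``,
  from the gradient-echo image pair acquired without (M0) and with (Ms)
  the off-resonance saturation pulse;
* normal-appearing tissue masks (NAGM/NAWM = grey/white matter voxels
  outside the most sensitive, kappa=0, lesion segmentation);
* MTR histogram summaries per tissue class (median, peak height, peak
  location, mean90);
* brain volumetrics from the soft segmentation (class volume = sum of the
  class probability times voxel volume; total brain = GM + WM + CSF; WM and
  GM also expressed as percent of total brain);

and assembles the 10 analysed traits (median + peak-height MTR in lesions /
NAWM / NAGM, total brain volume, WM%, GM%, lesion volume) into a
:class:`ScanTraits` row.

Segmentations (hard tissue labels, soft probabilities, lesion masks at the
sensitive kappa=0 and specific kappa=1 settings of the lesion-growing
algorithm) are *inputs*: lesion segmentation and tissue classification are
out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import AlignmentError, DesignError, DomainError, FormatError
from .volume import VolumeImage

# Hard segmentation label convention.
LABEL_BACKGROUND = 0
LABEL_GM = 1
LABEL_WM = 2
LABEL_CSF = 3
KNOWN_LABELS = frozenset({LABEL_BACKGROUND, LABEL_GM, LABEL_WM, LABEL_CSF})

#: Stable column schema of the 10 analysed traits.
TRAIT_NAMES = (
    "lesion_mtr_median",
    "nawm_mtr_median",
    "nagm_mtr_median",
    "lesion_mtr_peak_height",
    "nawm_mtr_peak_height",
    "nagm_mtr_peak_height",
    "total_brain_volume",
    "wm_pct",
    "gm_pct",
    "lesion_volume",
)

MTR_TRAITS = TRAIT_NAMES[:6]
VOLUME_TRAITS = TRAIT_NAMES[6:]


# --------------------------------------------------------------------------
# result containers


@dataclass
class TissueMasks:
    """Disjoint boolean masks for the three analysed tissue classes.

    ``nagm``/``nawm`` exclude the sensitive (kappa=0) lesion segmentation by
    construction; ``lesion`` is the analysis-time lesion class (kappa=1).
    """

    nagm: np.ndarray
    nawm: np.ndarray
    lesion: np.ndarray


@dataclass
class MTRHistogramSummary:
    """Histogram statistics of MTR values inside one tissue mask.

    peak_height is the modal-bin frequency in "unit percent" — percent of the
    included voxels — and peak_location the modal bin center; mean90 is the
    mean of values between the 5th and 95th percentiles (inclusive).
    A summary with ``n_voxels == 0`` flags a missing trait (empty tissue).
    """

    median: float
    peak_height: float
    peak_location: float
    mean90: float
    n_voxels: int

    @property
    def is_missing(self) -> bool:
        return self.n_voxels == 0

    @classmethod
    def missing(cls) -> "MTRHistogramSummary":
        return cls(math.nan, math.nan, math.nan, math.nan, 0)


@dataclass
class VolumetricSummary:
    """Brain compartment volumes (ml) and relative compositions (percent)."""

    gm_volume: float
    wm_volume: float
    csf_volume: float
    total_brain_volume: float
    lesion_volume: float
    wm_pct: float
    gm_pct: float

    @property
    def csf_pct(self) -> float:
        if self.total_brain_volume == 0:
            return math.nan
        return 100.0 * self.csf_volume / self.total_brain_volume


@dataclass
class ScanTraits:
    """The 10 analysed MRI traits for one scan plus scan metadata."""

    patient_id: str
    scan_index: int
    time_days: float
    protocol_id: str
    traits: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(TRAIT_NAMES) - set(self.traits)
        if missing:
            raise FormatError(f"ScanTraits missing trait slots: {sorted(missing)}")
        extra = set(self.traits) - set(TRAIT_NAMES)
        if extra:
            raise FormatError(f"unknown trait names: {sorted(extra)}")

    def to_row(self) -> dict:
        row = {
            "patient_id": self.patient_id,
            "scan_index": self.scan_index,
            "time_days": self.time_days,
            "protocol_id": self.protocol_id,
        }
        row.update({name: self.traits[name] for name in TRAIT_NAMES})
        return row


def scan_traits_frame(rows: list[ScanTraits]) -> pd.DataFrame:
    """Stack :class:`ScanTraits` rows into the stable tabular schema."""
    return pd.DataFrame([r.to_row() for r in rows])


# --------------------------------------------------------------------------
# operations


def compute_mtr_map(m0: VolumeImage, ms: VolumeImage) -> VolumeImage:
    """Magnetization transfer ratio map: ``100 * (M0 - Ms) / M0``.

    Voxels where M0 <= 0 (no signal without saturation, e.g. background)
    carry no MTR information and are set to NaN rather than raising.
    """
    m0.check_aligned(ms)
    with np.errstate(divide="ignore", invalid="ignore"):
        mtr = 100.0 * (m0.data - ms.data) / m0.data
    mtr = np.where(m0.data > 0, mtr, np.nan)
    return VolumeImage(mtr, voxel_size=m0.voxel_size, space_tag=m0.space_tag)


def derive_normal_appearing_masks(
    hard_seg: np.ndarray,
    lesion_mask_kappa0: np.ndarray,
    lesion_mask_kappa1: np.ndarray | None = None,
) -> TissueMasks:
    """Normal-appearing tissue masks.

    NAGM/NAWM are grey/white-matter voxels of the hard segmentation that do
    not belong to the lesion segmentation at its most sensitive setting
    (kappa = 0).  The lesion class analysed downstream uses the specific
    (kappa = 1) segmentation when provided; it must be contained in the
    kappa = 0 mask, which guarantees disjointness from NAGM/NAWM.
    """
    hard_seg = np.asarray(hard_seg)
    kappa0 = np.asarray(lesion_mask_kappa0, dtype=bool)
    if hard_seg.shape != kappa0.shape:
        raise AlignmentError(
            f"shape mismatch: hard_seg {hard_seg.shape} vs lesion mask {kappa0.shape}"
        )
    labels = set(np.unique(hard_seg).tolist())
    unknown = labels - KNOWN_LABELS
    if unknown:
        raise FormatError(f"unknown segmentation labels: {sorted(unknown)}")

    if lesion_mask_kappa1 is None:
        lesion = kappa0
    else:
        lesion = np.asarray(lesion_mask_kappa1, dtype=bool)
        if lesion.shape != kappa0.shape:
            raise AlignmentError("kappa=1 lesion mask shape mismatch")
        if np.any(lesion & ~kappa0):
            raise FormatError(
                "kappa=1 lesion mask must be contained in the kappa=0 mask"
            )

    nagm = (hard_seg == LABEL_GM) & ~kappa0
    nawm = (hard_seg == LABEL_WM) & ~kappa0
    return TissueMasks(nagm=nagm, nawm=nawm, lesion=lesion)


def summarize_mtr_histogram(
    mtr: VolumeImage,
    mask: np.ndarray,
    bin_width: float = 1.0,
    valid_range: tuple[float, float] = (0.0, 100.0),
) -> MTRHistogramSummary:
    """Histogram summary of MTR values inside ``mask``.

    Voxels that are NaN or fall outside ``valid_range`` (noise can push MTR
    negative or above 100) are excluded before anything is computed; the
    peak-height denominator is the included-voxel count.  Bins of width
    ``bin_width`` tile ``valid_range`` starting at its lower edge; ties for
    the modal bin resolve to the lowest bin.  An empty mask after filtering
    returns the flagged missing summary rather than raising.
    """
    if bin_width <= 0:
        raise DomainError("bin_width must be positive")
    lo, hi = valid_range
    if not lo < hi:
        raise DomainError("valid_range must be an increasing interval")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != mtr.shape:
        raise AlignmentError("mask shape does not match MTR map")

    vals = mtr.data[mask]
    vals = vals[np.isfinite(vals)]
    vals = vals[(vals >= lo) & (vals <= hi)]
    if vals.size == 0:
        return MTRHistogramSummary.missing()

    n_bins = int(math.ceil((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    modal = int(np.argmax(counts))  # first (lowest) bin wins ties
    peak_height = 100.0 * counts[modal] / vals.size
    peak_location = float(edges[modal] + bin_width / 2.0)

    median = float(np.percentile(vals, 50))
    p5, p95 = np.percentile(vals, [5, 95])
    middle = vals[(vals >= p5) & (vals <= p95)]
    mean90 = float(middle.mean())
    return MTRHistogramSummary(
        median=median,
        peak_height=float(peak_height),
        peak_location=peak_location,
        mean90=mean90,
        n_voxels=int(vals.size),
    )


def compute_volumetrics(
    soft_seg: Mapping[str, np.ndarray],
    lesion_mask: np.ndarray,
    voxel_size: tuple[float, float, float],
) -> VolumetricSummary:
    """Compartment volumes from a soft segmentation.

    Each class volume is the sum of its per-voxel probability times the voxel
    volume; total brain volume is the sum of the GM, WM and CSF compartments
    and WM/GM are also reported as percent of total.  Lesion volume counts
    binary lesion voxels.  Volumes are in ml (mm^3 / 1000).
    """
    required = {"gm", "wm", "csf"}
    if not required <= set(soft_seg):
        raise FormatError(f"soft segmentation must provide classes {sorted(required)}")
    vox_ml = float(np.prod(voxel_size)) / 1000.0
    vols = {}
    for cls in ("gm", "wm", "csf"):
        p = np.asarray(soft_seg[cls], dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise FormatError(f"{cls} probabilities outside [0, 1]")
        vols[cls] = float(p.sum()) * vox_ml
    total = vols["gm"] + vols["wm"] + vols["csf"]
    lesion_ml = float(np.asarray(lesion_mask, dtype=bool).sum()) * vox_ml
    if total > 0:
        wm_pct = 100.0 * vols["wm"] / total
        gm_pct = 100.0 * vols["gm"] / total
    else:
        wm_pct = gm_pct = math.nan
    return VolumetricSummary(
        gm_volume=vols["gm"],
        wm_volume=vols["wm"],
        csf_volume=vols["csf"],
        total_brain_volume=total,
        lesion_volume=lesion_ml,
        wm_pct=wm_pct,
        gm_pct=gm_pct,
    )


def extract_scan_traits(
    m0: VolumeImage,
    ms: VolumeImage,
    hard_seg: np.ndarray,
    soft_seg: Mapping[str, np.ndarray],
    lesion_mask_kappa0: np.ndarray,
    lesion_mask_kappa1: np.ndarray | None = None,
    *,
    patient_id: str = "",
    scan_index: int = 0,
    time_days: float = 0.0,
    protocol_id: str = "",
    bin_width: float = 1.0,
    valid_range: tuple[float, float] = (0.0, 100.0),
) -> ScanTraits:
    """Assemble the 10-trait vector for one scan.

    Composes the MTR map, normal-appearing masks, per-tissue histogram
    summaries and soft-segmentation volumetrics.  MTR traits of an empty
    tissue class (e.g. a scan without lesions) are NaN; lesion volume is then
    simply 0.
    """
    mtr = compute_mtr_map(m0, ms)
    masks = derive_normal_appearing_masks(hard_seg, lesion_mask_kappa0, lesion_mask_kappa1)
    tissue_masks = {"lesion": masks.lesion, "nawm": masks.nawm, "nagm": masks.nagm}
    traits: dict[str, float] = {}
    for tissue, mask in tissue_masks.items():
        summ = summarize_mtr_histogram(mtr, mask, bin_width=bin_width, valid_range=valid_range)
        traits[f"{tissue}_mtr_median"] = summ.median
        traits[f"{tissue}_mtr_peak_height"] = summ.peak_height
    volu = compute_volumetrics(soft_seg, masks.lesion, m0.voxel_size)
    traits["total_brain_volume"] = volu.total_brain_volume
    traits["wm_pct"] = volu.wm_pct
    traits["gm_pct"] = volu.gm_pct
    traits["lesion_volume"] = volu.lesion_volume
    return ScanTraits(
        patient_id=patient_id,
        scan_index=scan_index,
        time_days=time_days,
        protocol_id=protocol_id,
        traits=traits,
    )


def histogram_intercorrelation(traits: pd.DataFrame, summaries: pd.DataFrame | None = None) -> pd.DataFrame:
    """Diagnostic inter-correlation of histogram parameters.

    The four histogram parameters (median, peak height, peak location,
    mean90) are strongly inter-correlated, which is why only median and peak
    height enter the statistical analysis; this helper reports the Pearson
    correlation matrix of whatever histogram-parameter columns are present so
    the restriction can be checked on any dataset.  Purely diagnostic — no
    filtering is applied.
    """
    cols = [
        c
        for c in traits.columns
        if any(k in c for k in ("median", "peak_height", "peak_location", "mean90"))
    ]
    if not cols:
        raise DesignError("no histogram-parameter columns found")
    return traits[cols].corr()
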