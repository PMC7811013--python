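"""3-D scalar volumes with voxel geometry.

:class:`VolumeImage` is the carrier for M0/Ms signal images, MTR maps and
probabilistic segmentations.  It is a thin wrapper over a numpy array plus the
voxel size in mm and a ``space_tag`` asserting that two images live on the
same (already co-registered) grid — registration itself is out of scope and
never performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import AlignmentError, FormatError


@dataclass
class VolumeImage:
    """A 3-D scalar grid with voxel dimensions.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values.  NaN marks missing voxels (e.g. MTR where M0 <= 0).
    voxel_size : tuple of float
        Voxel edge lengths in mm, all > 0.
    space_tag : str
        Identifier of the grid/space the image lives on.  Operations that
        combine images require equal tags.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    space_tag: str = "native"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(f"expected a 3-D volume, got ndim={self.data.ndim}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise FormatError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def check_aligned(self, other: "VolumeImage") -> None:
        """Raise :class:`AlignmentError` unless both images share a grid."""
        if self.shape != other.shape:
            raise AlignmentError(f"shape mismatch: {self.shape} vs {other.shape}")
        if not np.allclose(self.voxel_size, other.voxel_size):
            raise AlignmentError(
                f"voxel size mismatch: {self.voxel_size} vs {other.voxel_size}"
            )
        if self.space_tag != other.space_tag:
            raise AlignmentError(
                f"space tag mismatch: {self.space_tag!r} vs {other.space_tag!r}"
            )

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_nifti(cls, path, space_tag: str = "native") -> "VolumeImage":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=float)
        zooms = img.header.get_zooms()[:3]
        return cls(data=data, voxel_size=tuple(float(z) for z in zooms), space_tag=space_tag)

    def to_nifti(self, path) -> None:
        affine = np.diag(list(self.voxel_size) + [1.0])
        img = nib.Nifti1Image(self.data.astype(np.float32), affine)
        img.header.set_zooms(self.voxel_size)
        nib.save(img, str(path))
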