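"""Reading, validation and normalization of 3D binary segmentation masks.

Conventions: voxel centers sit at physical position ``origin + index * spacing``
(mm); masks are strictly binary after loading. Partial-volume or probability
maps are rejected rather than thresholded silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
from scipy import ndimage


class MaskError(ValueError):
    """Raised for invalid or degenerate segmentation masks."""


@dataclass
class SegmentationMask:
    """A 3D binary voxel grid with physical spacing.

    Attributes
    ----------
    voxels : ndarray of uint8, shape (nx, ny, nz)
        Foreground (tumor) voxels are 1, background 0.
    spacing : tuple of float
        Voxel edge lengths (sx, sy, sz) in mm; strictly positive.
    origin : tuple of float
        Physical position (mm) of the center of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise MaskError(f"mask must be 3D, got ndim={self.voxels.ndim}")
        uniq = np.unique(self.voxels)
        if not np.isin(uniq, (0, 1)).all():
            raise MaskError("mask voxels must be strictly binary {0,1}")
        self.voxels = self.voxels.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise MaskError(f"spacing must be three positive values, got {self.spacing}")
        if self.voxels.sum() == 0:
            raise MaskError("empty mask: no foreground voxels")

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in mm^3."""
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def foreground_count(self) -> int:
        return int(self.voxels.sum())

    def voxel_centers(self) -> np.ndarray:
        """Physical (mm) coordinates of all foreground voxel centers, (N, 3)."""
        idx = np.argwhere(self.voxels > 0).astype(float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)


@dataclass
class CaseRecord:
    """One cohort case: identity, grade, mitotic rate and (optionally) features."""

    case_id: str
    who_grade: int
    mitotic_rate: float
    features: Optional[object] = None  # ShapeFeatures, set lazily
    mask: Optional[SegmentationMask] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.who_grade not in (1, 2, 3):
            raise ValueError(f"who_grade must be 1, 2 or 3, got {self.who_grade}")
        if self.mitotic_rate < 0:
            raise ValueError(f"mitotic_rate must be >= 0, got {self.mitotic_rate}")


def load_mask(path: str | Path, label: Optional[int] = None) -> SegmentationMask:
    """Load a NIfTI volume as a binary segmentation mask.

    Parameters
    ----------
    path : path to a .nii / .nii.gz file
    label : if given, only voxels equal to ``label`` become foreground;
        otherwise any nonzero voxel does. Non-integer-valued volumes
        (probability maps) are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise MaskError(f"expected a 3D volume, got shape {data.shape}")
    if not np.allclose(data, np.round(data), atol=1e-6):
        raise MaskError(
            "volume has non-integer values (probability map?); "
            "threshold explicitly before loading"
        )
    data = np.round(data).astype(np.int64)
    if label is not None:
        if label <= 0:
            raise ValueError(f"label must be a positive integer, got {label}")
        fg = data == label
        if not fg.any():
            raise MaskError(f"no voxel matching label {label}")
    else:
        fg = data != 0
        if not fg.any():
            raise MaskError("empty mask: no nonzero voxels")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise MaskError(f"non-positive voxel spacing in header: {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return SegmentationMask(fg.astype(np.uint8), spacing=tuple(map(float, zooms)), origin=origin)


def save_mask(mask: SegmentationMask, path: str | Path) -> Path:
    """Write a mask to NIfTI with a diagonal affine from spacing/origin."""
    path = Path(path)
    affine = np.diag(list(mask.spacing) + [1.0])
    affine[:3, 3] = mask.origin
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
    return path


def resample_isotropic(mask: SegmentationMask, target: float) -> SegmentationMask:
    """Nearest-neighbor resample to isotropic spacing ``target`` (mm).

    Keeps masks binary by construction; preserves foreground physical volume
    within ~5% for masks of >= 100 voxels.
    """
    if target <= 0:
        raise ValueError(f"target spacing must be > 0, got {target}")
    if mask.spacing == (target, target, target):
        return SegmentationMask(mask.voxels.copy(), mask.spacing, mask.origin)
    new_axes = []
    for n, s in zip(mask.voxels.shape, mask.spacing):
        n_new = max(1, int(round(n * s / target)))
        # source index of each new voxel center, clipped to the grid
        src = np.clip(np.round(np.arange(n_new) * target / s).astype(int), 0, n - 1)
        new_axes.append(src)
    ix, iy, iz = np.ix_(*new_axes)
    vox = mask.voxels[ix, iy, iz]
    if vox.sum() == 0:
        raise MaskError("resampling emptied the mask; target spacing too coarse")
    return SegmentationMask(vox, spacing=(target, target, target), origin=mask.origin)


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def largest_component(mask: SegmentationMask) -> SegmentationMask:
    """Keep only the largest 26-connected foreground component.

    Ties are broken deterministically toward the component containing the
    lowest linear (C-order) voxel index.
    """
    labeled, n = ndimage.label(mask.voxels, structure=_STRUCT_26)
    if n <= 1:
        return SegmentationMask(mask.voxels.copy(), mask.spacing, mask.origin)
    sizes = np.bincount(labeled.ravel())[1:]  # skip background
    best = sizes.max()
    candidates = np.flatnonzero(sizes == best) + 1
    if len(candidates) == 1:
        keep = candidates[0]
    else:
        flat = labeled.ravel()
        keep = min(candidates, key=lambda lab: int(np.flatnonzero(flat == lab)[0]))
    return SegmentationMask(
        (labeled == keep).astype(np.uint8), mask.spacing, mask.origin
    )
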