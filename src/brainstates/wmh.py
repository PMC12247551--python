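"""White-matter-hyperintensity (WMH) mask post-processing.

Takes binary lesion segmentations (produced upstream by any segmentation
tool) and applies the study's quantification steps: removal of connected
components below a minimum voxel count, partition of the surviving lesion
voxels into periventricular and deep classes by Euclidean distance to the
ventricular system, and volume computation in millilitres.

Conventions
-----------
* Connected components use 26-connectivity (voxels sharing a face, edge or
  corner belong to the same lesion).
* Distances are measured voxel-center to nearest ventricle voxel center, in
  millimetres, honouring anisotropic voxel spacing.
* The partition is voxel-wise: a single lesion may straddle both classes.
* A lesion voxel exactly at the cutoff distance counts as periventricular.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "MaskVolume",
    "WMHPartition",
    "filter_min_cluster",
    "partition_by_ventricle_distance",
    "volume_ml",
    "quantify",
]

_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class MaskVolume:
    """A binary 3-D mask with voxel spacing (mm) and optional affine."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError("mask must be a 3-D array")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be binary (0/1)")
        self.data = arr.astype(bool)
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0.0 for s in sp):
            raise ValueError("voxel spacing must be three strictly positive mm values")
        self.spacing = sp

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @classmethod
    def from_nifti(cls, path) -> "MaskVolume":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(data=(data > 0.5).astype(np.uint8), spacing=spacing, affine=img.affine)

    def to_nifti(self, path) -> None:
        import nibabel as nib

        affine = self.affine
        if affine is None:
            affine = np.diag([*self.spacing, 1.0])
        img = nib.Nifti1Image(self.data.astype(np.uint8), affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))


@dataclass
class WMHPartition:
    """Total, periventricular and deep WMH volumes (mL) plus cluster counts."""

    total_ml: float
    periventricular_ml: float
    deep_ml: float
    n_clusters_kept: int | None = None
    n_clusters_removed: int | None = None

    def __post_init__(self) -> None:
        if min(self.total_ml, self.periventricular_ml, self.deep_ml) < 0.0:
            raise ValueError("volumes must be non-negative")
        if abs(self.periventricular_ml + self.deep_ml - self.total_ml) > 1e-9:
            raise ValueError("periventricular + deep must equal total within 1e-9 mL")


def _check_grid(a: MaskVolume, b: MaskVolume) -> None:
    if a.data.shape != b.data.shape or a.spacing != b.spacing:
        raise ValueError("masks must share grid shape and voxel spacing")


def filter_min_cluster(mask: MaskVolume, min_voxels: int = 30) -> MaskVolume:
    """Zero out 26-connected components smaller than ``min_voxels``."""
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    labels, n = ndimage.label(mask.data, structure=_CONNECTIVITY_26)
    if n == 0:
        return MaskVolume(mask.data.copy(), mask.spacing, mask.affine)
    counts = np.bincount(labels.ravel())
    keep = counts >= min_voxels
    keep[0] = False
    return MaskVolume(keep[labels], mask.spacing, mask.affine)


def _cluster_counts(mask: MaskVolume, min_voxels: int) -> tuple[int, int]:
    labels, n = ndimage.label(mask.data, structure=_CONNECTIVITY_26)
    if n == 0:
        return 0, 0
    counts = np.bincount(labels.ravel())[1:]
    kept = int((counts >= min_voxels).sum())
    return kept, int(n - kept)


def partition_by_ventricle_distance(
    mask: MaskVolume, ventricles: MaskVolume, cutoff_mm: float = 10.0
) -> WMHPartition:
    """Split lesion voxels into periventricular (distance <= cutoff) and deep.

    The distance map is the Euclidean distance transform of the ventricle
    mask complement with the voxel spacing as sampling, i.e. the distance
    from every voxel center to the nearest ventricle voxel center in mm.
    """
    _check_grid(mask, ventricles)
    if not ventricles.data.any():
        raise ValueError("ventricle mask is empty")
    dist = ndimage.distance_transform_edt(~ventricles.data, sampling=mask.spacing)
    lesion = mask.data
    vml = mask.voxel_volume_ml
    n_peri = int((lesion & (dist <= cutoff_mm)).sum())
    n_total = int(lesion.sum())
    return WMHPartition(
        total_ml=n_total * vml,
        periventricular_ml=n_peri * vml,
        deep_ml=(n_total - n_peri) * vml,
    )


def volume_ml(mask: MaskVolume) -> float:
    """Lesion volume in mL: voxel count times voxel volume."""
    return float(mask.data.sum()) * mask.voxel_volume_ml


def quantify(
    mask: MaskVolume,
    ventricles: MaskVolume,
    min_voxels: int = 30,
    cutoff_mm: float = 10.0,
) -> WMHPartition:
    """Full quantification: size filter first, then the distance partition."""
    kept, removed = _cluster_counts(mask, min_voxels)
    filtered = filter_min_cluster(mask, min_voxels)
    part = partition_by_ventricle_distance(filtered, ventricles, cutoff_mm)
    part.n_clusters_kept = kept
    part.n_clusters_removed = removed
    return part
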