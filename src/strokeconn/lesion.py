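"""Corticospinal-tract (CST) weighted lesion load.

Lesion load quantifies how much of the descending motor pathway a stroke
lesion destroys.  The lesion mask is overlaid with a CST mask (both
binary, co-registered), the overlapping voxels are counted per axial
slice, and each slice's count is weighted so that damage in *narrower*
portions of the tract — where a lesion of the same size severs a larger
fraction of the fibres — contributes more:

    LL = sum_k  overlap_k * w_k,     w_k = max_slice_area / area_k

where area_k is the CST voxel count in slice k and the maximum runs over
slices with nonzero CST.  A slice whose CST area is zero contributes
nothing.  The weight function is pluggable for alternative narrowness
weightings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np


@dataclass
class LesionVolumePair:
    """Co-registered binary lesion and CST masks."""

    lesion_mask: np.ndarray
    cst_mask: np.ndarray
    voxel_dims_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    axial_axis: int = 2

    def __post_init__(self) -> None:
        les = np.asarray(self.lesion_mask)
        cst = np.asarray(self.cst_mask)
        if les.shape != cst.shape:
            raise ValueError("lesion and CST masks must share a shape")
        if les.ndim != 3:
            raise ValueError("masks must be 3-D")
        for name, m in (("lesion", les), ("cst", cst)):
            if not np.isin(m, (0, 1)).all():
                raise ValueError(f"{name} mask must be binary")
        self.lesion_mask = les.astype(np.uint8)
        self.cst_mask = cst.astype(np.uint8)


def _slice_sums(mask: np.ndarray, axial_axis: int) -> np.ndarray:
    axes = tuple(a for a in range(mask.ndim) if a != axial_axis)
    return mask.sum(axis=axes)


def cst_slice_areas(cst_mask: np.ndarray, axial_axis: int = 2) -> np.ndarray:
    """CST voxel count per axial slice; rejects an empty tract mask."""
    cst = np.asarray(cst_mask)
    if cst.sum() == 0:
        raise ValueError("CST mask is empty")
    return _slice_sums(cst, axial_axis)


def max_over_area_weight(areas: np.ndarray) -> np.ndarray:
    """Default narrowness weight: max slice area divided by slice area."""
    areas = np.asarray(areas, dtype=float)
    w = np.zeros_like(areas)
    nz = areas > 0
    w[nz] = areas[nz].max() / areas[nz]
    return w


def weighted_lesion_load(
    pair: LesionVolumePair,
    weight_fn: Callable[[np.ndarray], np.ndarray] = max_over_area_weight,
) -> float:
    """Slice-weighted lesion-CST overlap summed over axial slices."""
    areas = cst_slice_areas(pair.cst_mask, pair.axial_axis)
    overlap = _slice_sums(pair.lesion_mask * pair.cst_mask, pair.axial_axis)
    weights = weight_fn(areas)
    return float(np.sum(overlap * weights))


def detect_axial_axis(img) -> int:
    """Index of the superior-inferior axis from a NIfTI header affine."""
    import nibabel as nib

    codes = nib.aff2axcodes(img.affine)
    for axis, code in enumerate(codes):
        if code in ("S", "I"):
            return axis
    return 2


def load_pair(lesion_path: str | Path, cst_path: str | Path,
              axial_axis: int | None = None) -> LesionVolumePair:
    """Read co-registered lesion and CST NIfTI masks."""
    import nibabel as nib

    les_img = nib.load(str(lesion_path))
    cst_img = nib.load(str(cst_path))
    axis = detect_axial_axis(cst_img) if axial_axis is None else axial_axis
    zooms = tuple(float(z) for z in les_img.header.get_zooms()[:3])
    return LesionVolumePair(
        lesion_mask=(np.asanyarray(les_img.dataobj) > 0).astype(np.uint8),
        cst_mask=(np.asanyarray(cst_img.dataobj) > 0).astype(np.uint8),
        voxel_dims_mm=zooms,
        axial_axis=axis,
    )


def save_mask(mask: np.ndarray, path: str | Path,
              voxel_dims_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    """Write a binary mask as NIfTI with a diagonal affine."""
    import nibabel as nib

    affine = np.diag(list(voxel_dims_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), str(path))
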