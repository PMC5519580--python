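"""NIfTI-1 I/O helpers shared by the whole pipeline.

BOLD runs are single 4D ``.nii``/``.nii.gz`` files; ROI masks are binary 3D
images on the same voxel grid as the BOLD data (affine and shape must match
bit-exactly, otherwise the mask is rejected — registration is upstream of
this package).
"""

from __future__ import annotations

import numpy as np
import nibabel as nib

__all__ = ["load_bold", "load_mask", "save_volume", "check_same_grid"]


class GridMismatchError(ValueError):
    """Images do not share a voxel grid (shape and/or affine differ)."""


def load_bold(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 4D BOLD series; returns ``(data, affine)`` with float64 data."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D BOLD image, got shape {data.shape}")
    return data, img.affine


def check_same_grid(shape_a, affine_a, shape_b, affine_b, what: str = "image") -> None:
    if tuple(shape_a)[:3] != tuple(shape_b)[:3]:
        raise GridMismatchError(
            f"{what}: voxel grid shape {tuple(shape_b)[:3]} does not match "
            f"reference {tuple(shape_a)[:3]}"
        )
    if not np.array_equal(np.asarray(affine_a), np.asarray(affine_b)):
        raise GridMismatchError(f"{what}: affine does not match the reference affine")


def load_mask(path, ref_shape=None, ref_affine=None) -> tuple[np.ndarray, np.ndarray]:
    """Load a binary ROI/analysis mask; returns ``(bool_array, affine)``.

    Values must be exactly 0 or 1. When a reference grid is given, shape and
    affine must match it bit-exactly.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got shape {data.shape}")
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError(f"{path}: mask must be binary {{0,1}}, found values {uniq[:5]}")
    if ref_shape is not None:
        check_same_grid(ref_shape, ref_affine, data.shape, img.affine, what=str(path))
    return data.astype(bool), img.affine


def save_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a 3D or 4D volume as NIfTI-1 (float32 for real data, uint8 for bool)."""
    if data.dtype == bool:
        out = data.astype(np.uint8)
    else:
        out = data.astype(np.float32)
    nib.Nifti1Image(out, np.asarray(affine, dtype=float)).to_filename(str(path))
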