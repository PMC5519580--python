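"""Grid orientation estimation from quadrature betas.

A voxel whose signal is modulated as cos(fold*(alpha - phi_v)) loads on the
sin(fold*alpha) and cos(fold*alpha) regressors with betas proportional to
(sin(fold*phi_v), cos(fold*phi_v)). The voxel's orientation is therefore
recovered with the four-quadrant arctangent of beta_sin over beta_cos,
divided by the fold, which maps the result into orientation space
[0, 360/fold) degrees. The ROI-level mean grid orientation averages the two
betas over ROI voxels (and, if requested, over runs) *before* the
arctangent — averaging in the quadrature plane, which is the vector mean of
the per-voxel modulation phasors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .design import check_fold
from .glm import BetaMaps
from . import niftiio

__all__ = [
    "OrientationMap",
    "RoiOrientation",
    "voxel_orientation",
    "orientation_map",
    "roi_mean_orientation",
    "circular_mean_orientation",
    "export_orientation",
]


class UndefinedOrientationError(ValueError):
    """Both quadrature betas are exactly zero: no orientation exists."""


@dataclass
class OrientationMap:
    """Voxel-wise grid orientation phi_v and modulation amplitude.

    ``phi`` and ``amplitude`` are 3D volumes with NaN outside ``mask``;
    orientations are degrees in [0, 360/fold). The amplitude
    sqrt(beta_sin^2 + beta_cos^2) is a derived quality metric (magnitude of
    the quadrature phasor), exported for weighting and QC.
    """

    phi: np.ndarray
    amplitude: np.ndarray
    mask: np.ndarray
    fold: int
    affine: np.ndarray | None = None

    @property
    def phi_values(self) -> np.ndarray:
        return self.phi[self.mask]

    @property
    def amplitude_values(self) -> np.ndarray:
        return self.amplitude[self.mask]


@dataclass(frozen=True)
class RoiOrientation:
    """ROI mean grid orientation phi with its ingredients."""

    phi: float
    fold: int
    roi_name: str
    n_voxels: int
    mean_beta_sin: float
    mean_beta_cos: float
    runs_used: tuple[int, ...]


def voxel_orientation(beta_sin, beta_cos, fold: int = 6):
    """Orientation in degrees [0, 360/fold) from a quadrature beta pair.

    Uses the four-quadrant arctangent atan2(beta_sin, beta_cos) so the full
    orientation range is recoverable; scale-invariant in the betas. Accepts
    scalars or arrays; raises if any pair is exactly (0, 0).
    """
    fold = check_fold(fold)
    bs = np.asarray(beta_sin, dtype=float)
    bc = np.asarray(beta_cos, dtype=float)
    if np.any((bs == 0) & (bc == 0)):
        raise UndefinedOrientationError(
            "orientation undefined where both quadrature betas are exactly zero"
        )
    phi = np.degrees(np.arctan2(bs, bc)) / fold
    phi = np.mod(phi, 360.0 / fold)
    if np.isscalar(beta_sin) and np.isscalar(beta_cos):
        return float(phi)
    return phi


def orientation_map(betas: BetaMaps, fold: int = 6,
                    sin_name: str = "grid_sin", cos_name: str = "grid_cos") -> OrientationMap:
    """Voxel-wise orientation and amplitude volumes from fitted betas."""
    fold = check_fold(fold)
    bs = betas.beta(sin_name)
    bc = betas.beta(cos_name)
    phi_flat = voxel_orientation(bs, bc, fold)
    amp_flat = np.hypot(bs, bc)
    phi = np.full(betas.mask.shape, np.nan)
    amp = np.full(betas.mask.shape, np.nan)
    phi[betas.mask] = phi_flat
    amp[betas.mask] = amp_flat
    return OrientationMap(phi, amp, betas.mask.copy(), fold, betas.affine)


def roi_mean_orientation(
    betas: BetaMaps | Sequence[BetaMaps],
    roi: np.ndarray | None = None,
    fold: int = 6,
    roi_name: str = "roi",
    sin_name: str = "grid_sin",
    cos_name: str = "grid_cos",
    runs: Sequence[int] | None = None,
) -> RoiOrientation:
    """Mean grid orientation over an ROI (and optionally over runs).

    The quadrature betas are each averaged over all ROI voxels — and across
    the supplied per-run fits — and the two means are passed through the
    four-quadrant arctangent divided by the fold. Averaging the betas rather
    than the angles keeps low-amplitude voxels from dominating.
    """
    fold = check_fold(fold)
    if isinstance(betas, BetaMaps):
        betas = [betas]
    if runs is None:
        runs = tuple(range(1, len(betas) + 1))
    sins, coss, n_vox = [], [], 0
    for b in betas:
        if roi is None:
            sel = np.ones(b.n_voxels, dtype=bool)
        else:
            roi_b = np.asarray(roi, dtype=bool)
            if roi_b.shape != b.mask.shape:
                raise ValueError("ROI grid does not match the fitted mask grid")
            sel = roi_b[b.mask]
        if not sel.any():
            raise ValueError(f"ROI '{roi_name}' is empty after masking")
        sins.append(b.beta(sin_name)[sel].mean())
        coss.append(b.beta(cos_name)[sel].mean())
        n_vox = int(sel.sum())
    mean_sin = float(np.mean(sins))
    mean_cos = float(np.mean(coss))
    if mean_sin == 0.0 and mean_cos == 0.0:
        raise UndefinedOrientationError("mean quadrature betas are exactly zero")
    phi = voxel_orientation(mean_sin, mean_cos, fold)
    return RoiOrientation(phi, fold, roi_name, n_vox, mean_sin, mean_cos, tuple(runs))


def circular_mean_orientation(phis, fold: int = 6, weights=None) -> float:
    """Amplitude-weighted circular mean of voxel orientations.

    Alternative ROI summary to beta-averaging: orientations are mapped to
    the full circle (times fold), averaged as unit (or weighted) vectors,
    and mapped back. On a coherent ROI the two summaries agree closely.
    """
    fold = check_fold(fold)
    a = np.deg2rad(np.asarray(phis, dtype=float) * fold)
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    s = np.sum(w * np.sin(a))
    c = np.sum(w * np.cos(a))
    if s == 0 and c == 0:
        raise UndefinedOrientationError("circular mean undefined (zero resultant)")
    return float(np.mod(np.degrees(np.arctan2(s, c)) / fold, 360.0 / fold))


def export_orientation(omap: OrientationMap, path, mode: str = "nifti") -> None:
    """Write an orientation map as NIfTI (phi volume, NaN background) or TSV.

    The NIfTI background is NaN, never 0, because 0 degrees is a valid
    orientation. The TSV vector has one row per masked voxel with columns
    i, j, k, phi_deg, amplitude.
    """
    if not omap.mask.any():
        raise ValueError("orientation map is empty")
    if mode == "nifti":
        if omap.affine is None:
            raise ValueError("orientation map has no affine; cannot write NIfTI")
        niftiio.save_volume(omap.phi, omap.affine, path)
    elif mode == "vector":
        ii, jj, kk = np.nonzero(omap.mask)
        pd.DataFrame(
            {
                "i": ii,
                "j": jj,
                "k": kk,
                "phi_deg": omap.phi[omap.mask],
                "amplitude": omap.amplitude[omap.mask],
            }
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export mode {mode!r}")
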