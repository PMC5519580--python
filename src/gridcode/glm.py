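"""Mass-univariate ordinary-least-squares fitting of a design to 4D BOLD data.

One OLS solve is shared across all voxels (the design is common), so the
whole brain is fit with a single pseudo-inverse application. No
autocorrelation prewhitening is performed: the model is plain OLS, with
high-pass filtering handled by drift columns inside the design rather than
by pre-filtering the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import DesignMatrix

__all__ = ["BetaMaps", "fit_glm", "contrast"]


class RankDeficientDesignError(ValueError):
    """The design matrix has linearly dependent columns."""


@dataclass
class BetaMaps:
    """Voxel-wise OLS parameter estimates.

    ``betas`` is ``n_masked_voxels x n_columns`` in the flat order of
    ``np.flatnonzero(mask)``; ``mask`` is the boolean 3D analysis mask;
    ``residual_variance`` is SSR / (n - rank) per voxel.
    """

    betas: np.ndarray
    column_names: list[str]
    mask: np.ndarray
    residual_variance: np.ndarray
    dof: int
    affine: np.ndarray | None = None

    @property
    def n_voxels(self) -> int:
        return int(self.betas.shape[0])

    def beta(self, name: str) -> np.ndarray:
        """Beta vector (over masked voxels) for one named column."""
        return self.betas[:, self.column_names.index(name)]

    def beta_volume(self, name: str) -> np.ndarray:
        """Beta map as a 3D volume with NaN outside the mask."""
        vol = np.full(self.mask.shape, np.nan)
        vol[self.mask] = self.beta(name)
        return vol

    def standard_error(self, name: str) -> np.ndarray:
        """OLS standard error of one column's beta, per masked voxel."""
        j = self.column_names.index(name)
        return np.sqrt(self.residual_variance * self._xtx_inv_diag[j])

    # filled in by fit_glm
    _xtx_inv_diag: np.ndarray | None = None


def _name_collinear(X: np.ndarray, names: list[str]) -> list[str]:
    """Identify a minimal set of columns involved in a rank deficiency."""
    bad = []
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    for j, d in enumerate(diag):
        if d < tol:
            bad.append(names[j])
    return bad or names


def fit_glm(
    bold: np.ndarray,
    design: DesignMatrix,
    mask: np.ndarray | None = None,
    mask_threshold: float = 0.8,
    affine: np.ndarray | None = None,
) -> BetaMaps:
    """Fit the design to every voxel by OLS.

    Parameters
    ----------
    bold : ndarray
        4D array (i, j, k, frames) or 2D array (frames, voxels).
    design : DesignMatrix
        Frames must match the BOLD frame count.
    mask : ndarray of bool, optional
        Explicit analysis/ROI mask. When omitted, voxels whose mean signal
        falls below ``mask_threshold`` times the global mean signal are
        excluded (the conventional implicit masking threshold).
    """
    X = design.values
    if bold.ndim == 4:
        n_frames = bold.shape[3]
        vol_shape = bold.shape[:3]
        Y_all = bold.reshape(-1, n_frames).T  # frames x voxels
    elif bold.ndim == 2:
        n_frames = bold.shape[0]
        vol_shape = (bold.shape[1], 1, 1)
        Y_all = bold
    else:
        raise ValueError(f"bold must be 2D or 4D, got shape {bold.shape}")
    if n_frames != X.shape[0]:
        raise ValueError(
            f"BOLD has {n_frames} frames but the design has {X.shape[0]} rows"
        )

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _name_collinear(X, design.column_names)
        raise RankDeficientDesignError(
            f"design is rank deficient (rank {rank} < {X.shape[1]} columns); "
            f"collinear columns involve: {bad}"
        )

    if mask is None:
        mean_sig = Y_all.mean(axis=0)
        global_mean = mean_sig.mean()
        mask = (mean_sig >= mask_threshold * global_mean).reshape(vol_shape)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != vol_shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match BOLD grid {vol_shape}"
            )
    flat = mask.reshape(-1)
    if not flat.any():
        raise ValueError("all voxels excluded: empty analysis mask")
    Y = Y_all[:, flat]

    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = n_frames - rank
    if dof <= 0:
        raise ValueError("no residual degrees of freedom (frames <= design rank)")
    rvar = np.einsum("ij,ij->j", resid, resid) / dof

    out = BetaMaps(
        betas=beta.T,
        column_names=list(design.column_names),
        mask=mask,
        residual_variance=rvar,
        dof=dof,
        affine=affine,
    )
    out._xtx_inv_diag = np.diag(np.linalg.inv(X.T @ X))
    return out


def contrast(betas: BetaMaps, weights) -> np.ndarray:
    """Linear combination of betas per voxel (over masked voxels).

    ``weights`` is either a sequence with one entry per design column or a
    mapping from column name to weight (unnamed columns get 0).
    """
    if isinstance(weights, dict):
        w = np.zeros(len(betas.column_names))
        for name, val in weights.items():
            w[betas.column_names.index(name)] = val
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != len(betas.column_names):
            raise ValueError(
                f"{w.size} weights for {len(betas.column_names)} design columns"
            )
    return betas.betas @ w
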