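"""GLM2: quantifying grid-code response magnitude on the test partition.

Given the mean grid orientation phi estimated from the estimation
partition, the events of the held-out test partition are re-modeled with
respect to their alignment with phi, under one of three model families in
common use:

``parametric``
    One parametric modulator per event, cos(fold*(alpha - phi)): +1 for
    events aligned with phi (or a 360/fold multiple), -1 for events
    maximally misaligned (phi + 180/fold). The modulator beta is the
    magnitude.
``aligned_misaligned``
    Events within ``align_threshold`` degrees (inclusive) of the nearest
    grid axis form one regressor, the rest another; the magnitude is the
    aligned-minus-misaligned contrast.
``binned``
    Events are sorted into 360/bin_width angular bins anchored on phi
    (bin 1 centered on phi, half-open intervals); one regressor per bin,
    with betas extracted per bin. With bin_width = 360/(2*fold) the
    odd-numbered bins are the aligned ones.

A control analysis re-runs the full estimate-then-test pipeline under
alternative angular symmetries (folds 3-8); a genuine grid code should
maximize the magnitude at fold 6.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .design import (DesignMatrix, HrfSpec, check_fold, convolved_event_matrix,
                     dct_highpass_basis, stack_runs)
from .events import GridEventTable
from .glm import BetaMaps, contrast, fit_glm
from .orientation import RoiOrientation, roi_mean_orientation

__all__ = [
    "Glm2Spec",
    "Glm2Result",
    "parametric_modulator",
    "classify_alignment",
    "bin_index",
    "fit_glm2",
    "fold_sweep",
]


class EmptyConditionError(ValueError):
    """A GLM2 condition regressor has no events (e.g., no misaligned events)."""


@dataclass(frozen=True)
class Glm2Spec:
    """Model family and parameters for magnitude quantification."""

    method: str = "parametric"
    fold: int = 6
    align_threshold: float = 15.0
    bin_width: float = 30.0

    _METHODS = ("parametric", "aligned_misaligned", "binned")

    def __post_init__(self) -> None:
        check_fold(self.fold)
        if self.method not in self._METHODS:
            raise ValueError(f"method must be one of {self._METHODS}, got {self.method!r}")
        if not 0 < self.align_threshold <= 180.0 / self.fold:
            raise ValueError(
                f"align_threshold must lie in (0, {180.0 / self.fold}] for fold "
                f"{self.fold}, got {self.align_threshold}"
            )
        if 360.0 % self.bin_width != 0:
            raise ValueError(f"360 must be divisible by bin_width, got {self.bin_width}")


@dataclass
class Glm2Result:
    """Voxel-wise and ROI-mean grid-code magnitude."""

    voxel_map: np.ndarray          # per masked voxel
    roi_mean: float
    roi_se: float
    spec: Glm2Spec
    phi_used: float
    n_roi_voxels: int
    per_bin_betas: np.ndarray | None = None   # ROI means, binned method only
    betas: BetaMaps | None = None

    def summary_row(self) -> dict:
        return {
            "method": self.spec.method,
            "fold": self.spec.fold,
            "phi_used": self.phi_used,
            "roi_mean": self.roi_mean,
            "roi_se": self.roi_se,
            "n_roi_voxels": self.n_roi_voxels,
        }


def parametric_modulator(angle, phi, fold: int = 6):
    """cos(fold * (alpha - phi)) with degree inputs; range exactly [-1, 1].

    Equals 1 when the event angle coincides with the mean grid orientation
    (or any 360/fold multiple of it) and -1 at maximal misalignment
    (phi + 180/fold plus multiples). Even around every grid axis and
    periodic with 360/fold. Accepts arrays.
    """
    fold = check_fold(fold)
    val = np.cos(np.deg2rad((np.asarray(angle, dtype=float) - phi) * fold))
    if np.isscalar(angle):
        return float(val)
    return val


def classify_alignment(angle, phi, fold: int = 6, threshold: float = 15.0):
    """Label events aligned/misaligned with the nearest grid axis.

    An event is aligned when its fold-wrapped angular distance to the
    nearest grid axis (phi + k*360/fold) is <= ``threshold`` degrees
    (the threshold itself counts as aligned; "more than threshold" is
    misaligned). Returns 'aligned'/'misaligned' for scalars, a boolean
    aligned-array otherwise.
    """
    fold = check_fold(fold)
    if not 0 < threshold <= 180.0 / fold:
        raise ValueError(f"threshold must lie in (0, {180.0 / fold}]")
    period = 360.0 / fold
    d = np.mod(np.asarray(angle, dtype=float) - phi, period)
    d = np.minimum(d, period - d)
    aligned = d <= threshold
    if np.isscalar(angle):
        return "aligned" if bool(aligned) else "misaligned"
    return aligned


def bin_index(angle, phi, fold: int = 6, bin_width: float = 30.0):
    """1-based angular bin of an event relative to phi.

    Bin 1 is centered on phi; bins are half-open
    [center - width/2, center + width/2), so an event exactly at the upper
    boundary falls in the next bin. With bin_width = 360/(2*fold), the
    odd-numbered bins are aligned and the even-numbered misaligned. Accepts
    arrays.
    """
    fold = check_fold(fold)
    if 360.0 % bin_width != 0:
        raise ValueError("360 must be divisible by bin_width")
    n_bins = int(round(360.0 / bin_width))
    rel = np.mod(np.asarray(angle, dtype=float) - phi + bin_width / 2.0, 360.0)
    idx = (np.floor(rel / bin_width).astype(int) % n_bins) + 1
    if np.isscalar(angle):
        return int(idx)
    return idx


# -- GLM2 fitting ------------------------------------------------------------


def _phi_value(phi) -> float:
    return float(phi.phi) if isinstance(phi, RoiOrientation) else float(phi)


def _glm2_design_one_run(
    events_run: GridEventTable,
    phi: float,
    spec: Glm2Spec,
    frame_times: np.ndarray,
    hrf: HrfSpec,
    drift_cutoff: float,
    microtime: tuple[int, int],
    unused: GridEventTable | None,
    nuisance: np.ndarray | None,
    run: int,
) -> DesignMatrix:
    tr = events_run.tr
    onsets = [e.onset for e in events_run.events]
    durations = [e.duration for e in events_run.events]
    angles = events_run.angles()
    E = convolved_event_matrix(onsets, durations, frame_times, tr, hrf, microtime)

    cols: list[np.ndarray] = []
    names: list[str] = []
    if spec.method == "parametric":
        w = parametric_modulator(angles, phi, spec.fold)
        cols += [E.sum(axis=1), E @ w]
        names += ["grid_main", "grid_pm"]
    elif spec.method == "aligned_misaligned":
        aligned = classify_alignment(angles, phi, spec.fold, spec.align_threshold)
        for label, sel in (("grid_aligned", aligned), ("grid_misaligned", ~aligned)):
            if not np.any(sel):
                raise EmptyConditionError(
                    f"run {run}: no events in condition '{label.removeprefix('grid_')}'"
                    " — the contrast cannot be formed"
                )
            cols.append(E @ sel.astype(float))
            names.append(label)
    else:  # binned
        n_bins = int(round(360.0 / spec.bin_width))
        idx = bin_index(angles, phi, spec.fold, spec.bin_width)
        for b in range(1, n_bins + 1):
            sel = idx == b
            if not np.any(sel):
                raise EmptyConditionError(
                    f"run {run}: angular bin {b} of {n_bins} contains no events"
                )
            cols.append(E @ sel.astype(float))
            names.append(f"grid_bin_{b:02d}")

    if unused is not None and unused.events:
        Eu = convolved_event_matrix(
            [e.onset for e in unused.events], [e.duration for e in unused.events],
            frame_times, tr, hrf, microtime)
        cols.append(Eu.sum(axis=1))
        names.append("unused_events")
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        for m in range(nuisance.shape[1]):
            cols.append(nuisance[:, m])
            names.append(f"nuisance_{m + 1}")
    drift = dct_highpass_basis(frame_times.size, tr, drift_cutoff)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        names.append(f"drift_{k + 1}")
    cols.append(np.ones(frame_times.size))
    names.append("intercept")
    return DesignMatrix(np.column_stack(cols), names, frame_times, run)


def fit_glm2(
    bold_runs: Sequence[np.ndarray],
    events: GridEventTable,
    phi,
    spec: Glm2Spec | None = None,
    roi: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    hrf: HrfSpec | None = None,
    drift_cutoff: float = 128.0,
    microtime: tuple[int, int] = (16, 8),
    nuisance: Sequence[np.ndarray] | None = None,
    affine: np.ndarray | None = None,
) -> Glm2Result:
    """Fit the magnitude model to the test partition.

    ``bold_runs`` holds one 4D (or frames x voxels) array per run, in run
    order; ``events`` must carry estimation/test labels (the test events
    are modeled, the estimation events enter as an unused-events nuisance
    regressor). ``phi`` is the mean grid orientation (degrees, or a
    :class:`RoiOrientation`). The ROI mean magnitude is the average of the
    voxel map over ``roi``; its standard error is across-voxel.
    """
    spec = spec or Glm2Spec()
    hrf = hrf or HrfSpec()
    phi_val = _phi_value(phi)
    if not np.isfinite(phi_val):
        raise ValueError("phi must be finite")
    runs = events.runs
    if len(bold_runs) != len(runs):
        raise ValueError(f"{len(bold_runs)} BOLD runs supplied for runs {runs}")
    designs = []
    used_bold = []
    for i, run in enumerate(runs):
        test = events.subset(run=run, set_label="test")
        if not test.events:
            continue  # runs without test events (e.g. odd/even-runs split) are skipped
        unused = events.subset(run=run, set_label="estimation")
        n_frames = bold_runs[i].shape[-1] if bold_runs[i].ndim == 4 else bold_runs[i].shape[0]
        frame_times = np.arange(n_frames) * events.tr
        nuis = None if nuisance is None else nuisance[i]
        designs.append(
            _glm2_design_one_run(test, phi_val, spec, frame_times, hrf,
                                 drift_cutoff, microtime, unused, nuis, run)
        )
        used_bold.append(bold_runs[i])
    if not designs:
        raise EmptyConditionError("no run contains test events")
    design = stack_runs(designs)
    if len(used_bold) > 1:
        if any(b.ndim != used_bold[0].ndim for b in used_bold):
            raise ValueError("all BOLD runs must have the same dimensionality")
        bold = np.concatenate(used_bold, axis=-1 if used_bold[0].ndim == 4 else 0)
    else:
        bold = used_bold[0]
    betas = fit_glm(bold, design, mask=mask, affine=affine)

    per_bin = None
    if spec.method == "parametric":
        voxel_map = betas.beta("grid_pm")
    elif spec.method == "aligned_misaligned":
        voxel_map = contrast(betas, {"grid_aligned": 1.0, "grid_misaligned": -1.0})
    else:
        n_bins = int(round(360.0 / spec.bin_width))
        bin_names = [f"grid_bin_{b:02d}" for b in range(1, n_bins + 1)]
        odd = [n for i, n in enumerate(bin_names) if i % 2 == 0]
        even = [n for i, n in enumerate(bin_names) if i % 2 == 1]
        w = {**{n: 1.0 / len(odd) for n in odd}, **{n: -1.0 / len(even) for n in even}}
        voxel_map = contrast(betas, w)

    if roi is None:
        sel = np.ones(betas.n_voxels, dtype=bool)
    else:
        roi_b = np.asarray(roi, dtype=bool)
        if roi_b.shape != betas.mask.shape:
            raise ValueError("ROI grid does not match the fitted mask grid")
        sel = roi_b[betas.mask]
    if not sel.any():
        raise ValueError("ROI is empty after masking")
    roi_vals = voxel_map[sel]
    if spec.method == "binned":
        n_bins = int(round(360.0 / spec.bin_width))
        per_bin = np.array(
            [betas.beta(f"grid_bin_{b:02d}")[sel].mean() for b in range(1, n_bins + 1)]
        )
    n_roi = int(sel.sum())
    se = float(roi_vals.std(ddof=1) / np.sqrt(n_roi)) if n_roi > 1 else float("nan")
    return Glm2Result(voxel_map, float(roi_vals.mean()), se, spec, phi_val,
                      n_roi, per_bin, betas)


def fold_sweep(
    bold_runs: Sequence[np.ndarray],
    events: GridEventTable,
    roi: np.ndarray | None = None,
    folds: Sequence[int] = (3, 4, 5, 6, 7, 8),
    spec: Glm2Spec | None = None,
    mask: np.ndarray | None = None,
    hrf: HrfSpec | None = None,
    drift_cutoff: float = 128.0,
    microtime: tuple[int, int] = (16, 8),
) -> pd.DataFrame:
    """Re-run the full estimate-then-test pipeline under each symmetry fold.

    For every fold the orientation is re-estimated on the estimation
    partition under that fold's quadrature model (each candidate symmetry
    gets its own best orientation), then the test-partition magnitude is
    computed. Returns a table with one row per fold: the estimated phi, the
    ROI mean magnitude and its across-voxel standard error.
    """
    from .design import build_design  # local import to avoid cycle at module load

    base = spec or Glm2Spec()
    hrf = hrf or HrfSpec()
    runs = events.runs
    rows = []
    for fold in folds:
        fold = check_fold(fold)
        betas_runs = []
        est_runs = []
        for i, run in enumerate(runs):
            est = events.subset(run=run, set_label="estimation")
            if not est.events:
                continue
            unused = events.subset(run=run, set_label="test")
            n_frames = (bold_runs[i].shape[-1] if bold_runs[i].ndim == 4
                        else bold_runs[i].shape[0])
            frame_times = np.arange(n_frames) * events.tr
            d1 = build_design(est, frame_times, fold=fold, hrf=hrf,
                              drift_cutoff=drift_cutoff, microtime=microtime,
                              unused_events=unused, run=run)
            betas_runs.append(fit_glm(bold_runs[i], d1, mask=mask))
            est_runs.append(run)
        if not betas_runs:
            raise EmptyConditionError("no run contains estimation events")
        phi = roi_mean_orientation(betas_runs, roi=roi, fold=fold, runs=est_runs)
        spec_f = Glm2Spec(method=base.method, fold=fold,
                          align_threshold=min(base.align_threshold, 180.0 / fold),
                          bin_width=base.bin_width)
        res = fit_glm2(bold_runs, events, phi, spec_f, roi=roi, mask=mask,
                       hrf=hrf, drift_cutoff=drift_cutoff, microtime=microtime)
        rows.append({"fold": fold, "phi": phi.phi, "roi_mean": res.roi_mean,
                     "roi_se": res.roi_se})
    return pd.DataFrame(rows)
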