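"""Model/Results interface to the full hexadirectional analysis.

:class:`HexadirectionalModel` bundles the data (BOLD runs, grid-event
table, ROI) and the modeling choices (partition scheme, symmetry fold, HRF,
drift and microtime settings, GLM2 family); :meth:`HexadirectionalModel.fit`
runs partition -> orientation-estimation GLM (GLM1) -> ROI mean orientation
-> Rayleigh coherence -> magnitude GLM (GLM2) and returns a
:class:`HexadirectionalResults` carrying the estimates, their
uncertainties, diagnostics and a ``summary()`` table. Simulation
(:meth:`from_simulation`) and the fold-sweep control hang off the same
objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import magnitude as mag
from . import niftiio
from .design import HrfSpec, build_design, check_fold
from .events import GridEventTable, PartitionScheme, partition_events, read_event_table
from .glm import BetaMaps, fit_glm
from .orientation import (OrientationMap, RoiOrientation, orientation_map,
                          roi_mean_orientation)
from .stability import RayleighResult, StabilityResult, rayleigh_test, within_voxel_stability

__all__ = ["HexadirectionalModel", "HexadirectionalResults"]


def _average_betas(betas_runs: Sequence[BetaMaps]) -> BetaMaps:
    """Voxel-wise mean of per-run beta maps (shared mask and columns)."""
    b0 = betas_runs[0]
    stacked = np.mean([b.betas for b in betas_runs], axis=0)
    rvar = np.mean([b.residual_variance for b in betas_runs], axis=0)
    return BetaMaps(stacked, list(b0.column_names), b0.mask.copy(), rvar,
                    b0.dof, b0.affine)


class HexadirectionalModel:
    """Hexadirectional (grid-code) model of directional fMRI events.

    Parameters
    ----------
    bold_runs : sequence of ndarray
        One 4D array (i, j, k, frames) per run, in run order.
    events : GridEventTable
        Grid events for all runs; labels may be pre-assigned
        (``scheme='user_defined'``) or left ``auto``.
    roi : ndarray of bool, optional
        ROI over which the mean orientation and magnitude are summarized.
    mask : ndarray of bool, optional
        Analysis mask for the voxel-wise fits; defaults to the implicit
        mean-signal threshold mask.
    scheme : PartitionScheme
        How to split events into estimation and test sets
        (default: odd vs. even events within each run).
    fold : int
        Angular symmetry of the model (6 = hexadirectional).
    """

    def __init__(
        self,
        bold_runs: Sequence[np.ndarray],
        events: GridEventTable,
        roi: np.ndarray | None = None,
        mask: np.ndarray | None = None,
        scheme: PartitionScheme | None = None,
        fold: int = 6,
        hrf: HrfSpec | None = None,
        drift_cutoff: float = 128.0,
        microtime: tuple[int, int] = (16, 8),
        nuisance: Sequence[np.ndarray] | None = None,
        glm2: mag.Glm2Spec | None = None,
        stability_threshold: float = 15.0,
        affine: np.ndarray | None = None,
    ) -> None:
        self.bold_runs = list(bold_runs)
        self.events = events
        if len(self.bold_runs) != len(events.runs):
            raise ValueError(
                f"{len(self.bold_runs)} BOLD runs for event-table runs {events.runs}"
            )
        self.roi = None if roi is None else np.asarray(roi, dtype=bool)
        self.mask = None if mask is None else np.asarray(mask, dtype=bool)
        self.scheme = scheme or PartitionScheme("odd_even_events")
        self.fold = check_fold(fold)
        self.hrf = hrf or HrfSpec()
        self.drift_cutoff = drift_cutoff
        self.microtime = microtime
        self.nuisance = nuisance
        self.glm2 = glm2 or mag.Glm2Spec(fold=self.fold)
        self.stability_threshold = stability_threshold
        self.affine = affine

    # -- constructors --------------------------------------------------------

    @classmethod
    def from_files(cls, bold_paths: Sequence, events_path, tr: float,
                   roi_path=None, mask_path=None, nuisance_paths=None,
                   **kwargs) -> "HexadirectionalModel":
        """Build the model from NIfTI/TSV files on disk."""
        bold_runs, affines = [], []
        for p in bold_paths:
            data, aff = niftiio.load_bold(p)
            bold_runs.append(data)
            affines.append(aff)
        for i, p in enumerate(bold_paths[1:], start=1):
            niftiio.check_same_grid(bold_runs[0].shape, affines[0],
                                    bold_runs[i].shape, affines[i], what=str(p))
        run_lengths = [b.shape[3] * tr for b in bold_runs]
        events = read_event_table(events_path, tr, run_lengths)
        roi = mask = None
        if roi_path is not None:
            roi, _ = niftiio.load_mask(roi_path, bold_runs[0].shape, affines[0])
        if mask_path is not None:
            mask, _ = niftiio.load_mask(mask_path, bold_runs[0].shape, affines[0])
        nuis = None
        if nuisance_paths is not None:
            nuis = [pd.read_csv(p, sep="\t").to_numpy(dtype=float) for p in nuisance_paths]
        return cls(bold_runs, events, roi=roi, mask=mask, nuisance=nuis,
                   affine=affines[0], **kwargs)

    @classmethod
    def from_simulation(cls, session, **kwargs) -> "HexadirectionalModel":
        """Build the model directly from a :class:`~gridcode.simulate.SimulatedSession`."""
        kwargs.setdefault("roi", session.truth.roi_mask)
        kwargs.setdefault("mask", np.ones(session.truth.roi_mask.shape, dtype=bool))
        kwargs.setdefault("affine", session.affine)
        return cls(session.bold_runs, session.events, **kwargs)

    # -- fitting -------------------------------------------------------------

    def _partitioned(self) -> GridEventTable:
        if self.scheme.kind == "user_defined" or all(
            e.set_label == "auto" for e in self.events.events
        ):
            return partition_events(self.events, self.scheme)
        return self.events  # labels already assigned upstream

    def fit(self) -> "HexadirectionalResults":
        events = self._partitioned()
        betas_runs: list[BetaMaps] = []
        maps_runs: list[OrientationMap] = []
        est_runs: list[int] = []
        for i, run in enumerate(events.runs):
            est = events.subset(run=run, set_label="estimation")
            if not est.events:
                continue  # e.g. even runs under the odd/even-runs scheme
            unused = events.subset(run=run, set_label="test")
            n_frames = self.bold_runs[i].shape[-1]
            frame_times = np.arange(n_frames) * events.tr
            nuis = None if self.nuisance is None else self.nuisance[i]
            d1 = build_design(est, frame_times, fold=self.fold, hrf=self.hrf,
                              nuisance=nuis, drift_cutoff=self.drift_cutoff,
                              microtime=self.microtime, unused_events=unused, run=run)
            b = fit_glm(self.bold_runs[i], d1, mask=self.mask, affine=self.affine)
            betas_runs.append(b)
            maps_runs.append(orientation_map(b, self.fold))
            est_runs.append(run)
        if not betas_runs:
            raise ValueError("no run contains estimation events")

        pooled = _average_betas(betas_runs)
        pooled_map = orientation_map(pooled, self.fold)
        phi = roi_mean_orientation(betas_runs, roi=self.roi, fold=self.fold,
                                   runs=est_runs)
        roi_sel = (pooled.mask if self.roi is None else (pooled.mask & self.roi))
        rayleigh = rayleigh_test(pooled_map.phi[roi_sel], self.fold)

        glm2 = mag.fit_glm2(self.bold_runs, events, phi, self.glm2, roi=self.roi,
                            mask=self.mask, hrf=self.hrf,
                            drift_cutoff=self.drift_cutoff,
                            microtime=self.microtime, nuisance=self.nuisance,
                            affine=self.affine)

        stab = None
        if len(maps_runs) >= 2:
            stab = within_voxel_stability(maps_runs[0], maps_runs[-1], roi=self.roi,
                                          threshold=self.stability_threshold)
        return HexadirectionalResults(self, events, betas_runs, maps_runs,
                                      pooled_map, phi, rayleigh, glm2, stab)

    def fold_sweep(self, folds: Sequence[int] = (3, 4, 5, 6, 7, 8)) -> pd.DataFrame:
        """Re-run estimation and test under each candidate symmetry fold."""
        events = self._partitioned()
        return mag.fold_sweep(self.bold_runs, events, roi=self.roi, folds=folds,
                              spec=self.glm2, mask=self.mask, hrf=self.hrf,
                              drift_cutoff=self.drift_cutoff,
                              microtime=self.microtime)


@dataclass
class HexadirectionalResults:
    """Fitted hexadirectional analysis: orientation, coherence, magnitude."""

    model: HexadirectionalModel
    events: GridEventTable
    betas_runs: list[BetaMaps]
    orientation_maps: list[OrientationMap]
    pooled_map: OrientationMap
    phi: RoiOrientation
    rayleigh: RayleighResult
    magnitude: mag.Glm2Result
    stability: StabilityResult | None = None

    def summary(self) -> str:
        """Human-readable summary table of the fitted grid-code metrics."""
        L = []
        add = L.append
        period = 360.0 / self.phi.fold
        add("Hexadirectional grid-code analysis")
        add("=" * 54)
        add(f"{'Runs':<34}{len(self.betas_runs)}")
        add(f"{'Events (est/test)':<34}"
            f"{sum(e.set_label == 'estimation' for e in self.events.events)}/"
            f"{sum(e.set_label == 'test' for e in self.events.events)}")
        add(f"{'Symmetry fold':<34}{self.phi.fold}")
        add(f"{'ROI voxels':<34}{self.phi.n_voxels}")
        add("-" * 54)
        add(f"{'Mean grid orientation phi (deg)':<34}{self.phi.phi:.2f}  "
            f"[0, {period:.0f})")
        add(f"{'Rayleigh mean resultant R':<34}{self.rayleigh.mean_resultant_length:.3f}")
        add(f"{'Rayleigh z':<34}{self.rayleigh.z:.2f}")
        add(f"{'Rayleigh p':<34}{self.rayleigh.p_value:.2e}")
        add(f"{'GLM2 method':<34}{self.magnitude.spec.method}")
        add(f"{'Grid-code magnitude (ROI mean)':<34}{self.magnitude.roi_mean:.4f}")
        add(f"{'  across-voxel SE':<34}{self.magnitude.roi_se:.4f}")
        if self.stability is not None:
            add(f"{'Within-voxel stability':<34}"
                f"{100 * self.stability.fraction_stable:.1f}% "
                f"(threshold +/-{self.stability.threshold:.0f} deg)")
        add("=" * 54)
        return "\n".join(L)

    def to_dict(self) -> dict:
        """Machine-readable summary of the main metrics."""
        out = {
            "phi": self.phi.phi,
            "fold": self.phi.fold,
            "n_roi_voxels": self.phi.n_voxels,
            "rayleigh_rbar": self.rayleigh.mean_resultant_length,
            "rayleigh_z": self.rayleigh.z,
            "rayleigh_p": self.rayleigh.p_value,
            "glm2_method": self.magnitude.spec.method,
            "roi_mean_magnitude": self.magnitude.roi_mean,
            "roi_se_magnitude": self.magnitude.roi_se,
        }
        if self.stability is not None:
            out["fraction_stable"] = self.stability.fraction_stable
            out["stability_threshold"] = self.stability.threshold
        return out
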