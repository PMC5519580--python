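"""Synthetic BOLD sessions with a known hexadirectional ground truth.

The generator implements the signal model the analysis assumes: a
subpopulation of conjunctive grid cells whose response to a directed event
with angle alpha is modulated sinusoidally around the voxel's true grid
orientation phi_v,

    neural amplitude = amplitude * (1 + g * cos(fold * (alpha - phi_v))),

so events aligned with phi_v (or a 360/fold multiple) evoke the largest
response and events at phi_v + 180/fold the smallest. Event boxcars at that
amplitude are convolved with the canonical HRF, sampled at the TR, and
corrupted with linear drift and i.i.d. Gaussian noise. Voxels inside the
ROI carry the modulation; control voxels are identical but with g = 0.
Everything is driven by a single seeded generator, so a spec plus seed
reproduces the session bit-for-bit.

The default noise level is anchored to a per-event signal-to-noise ratio of
0.5: the peak response of one unmodulated event (amplitude 2.0, 2 s
duration, canonical HRF) is ~3.87 signal units, and noise_sd defaults to
twice that.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .design import HrfSpec, check_fold, convolved_event_matrix
from .events import GridEvent, GridEventTable, write_event_table
from . import niftiio

__all__ = ["SimSpec", "GroundTruth", "SimulatedSession",
           "make_angle_schedule", "simulate_session"]

#: Peak response of a single unmodulated default event (amplitude 2.0, 2 s
#: boxcar, canonical HRF); noise_sd default = peak / 0.5.
_DEFAULT_EVENT_PEAK = 3.87


@dataclass(frozen=True)
class SimSpec:
    """Parameters of a simulated session.

    Defaults describe a small but realistic two-run directional-event
    experiment: 200 events of 2 s per 600 s run at TR 1.5 s, uniform event
    angles, a contiguous ROI of ~15% of a 12 x 12 x 6 voxel volume carrying
    a six-fold modulation of gain 0.3 around a shared orientation of 20
    degrees with 3 degrees of between-voxel jitter, and white noise giving a
    per-event SNR of about 0.5.
    """

    n_runs: int = 2
    run_length: float = 600.0
    tr: float = 1.5
    grid_shape: tuple[int, int, int] = (12, 12, 6)
    roi_fraction: float = 0.15
    phi_true: float = 20.0
    phi_jitter_sd: float = 3.0
    fold_true: int = 6
    n_events_per_run: int = 200
    event_duration: float = 2.0
    angle_sampling: str = "uniform"           # uniform | von_mises | listed
    von_mises_mu: float = 0.0                  # degrees, von_mises only
    von_mises_kappa: float = 4.0               # concentration, von_mises only
    angle_list: tuple[float, ...] | None = None
    baseline: float = 100.0
    amplitude: float = 2.0
    modulation_gain: float = 0.3
    noise_sd: float = 2.0 * _DEFAULT_EVENT_PEAK
    drift: float = 0.01                        # signal units per second
    rectified: bool = False
    ar1: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.n_runs < 1:
            problems.append("n_runs must be >= 1")
        if self.run_length <= 0 or self.tr <= 0:
            problems.append("run_length and tr must be positive")
        if not 0 < self.roi_fraction <= 1:
            problems.append("roi_fraction must lie in (0, 1]")
        if self.noise_sd < 0 or self.phi_jitter_sd < 0:
            problems.append("noise_sd and phi_jitter_sd must be non-negative")
        if self.fold_true not in (3, 4, 5, 6, 7, 8):
            problems.append(f"fold_true {self.fold_true} not in 3..8")
        if self.n_events_per_run < 1:
            problems.append("n_events_per_run must be >= 1")
        if self.angle_sampling not in ("uniform", "von_mises", "listed"):
            problems.append(f"unknown angle_sampling {self.angle_sampling!r}")
        if self.angle_sampling == "von_mises" and self.von_mises_kappa < 0:
            problems.append("von_mises_kappa must be >= 0")
        if self.angle_sampling == "listed" and not self.angle_list:
            problems.append("listed angle_sampling requires angle_list")
        n_ev = len(self.angle_list) if self.angle_sampling == "listed" else self.n_events_per_run
        isi = self.run_length / n_ev
        if isi <= self.event_duration:
            problems.append(
                f"events do not fit: inter-onset interval {isi:.2f} s <= "
                f"duration {self.event_duration} s"
            )
        if not -1 < self.ar1 < 1:
            problems.append("ar1 must lie in (-1, 1)")
        if problems:
            raise ValueError("invalid SimSpec: " + "; ".join(problems))

    @property
    def n_frames(self) -> int:
        return int(np.floor(self.run_length / self.tr))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class GroundTruth:
    """What the generator actually injected, for scoring recovery."""

    phi_voxel_true: np.ndarray   # 3D volume, NaN outside the ROI
    roi_mask: np.ndarray
    control_mask: np.ndarray
    spec: SimSpec


@dataclass
class SimulatedSession:
    """In-memory simulated session: BOLD runs, events, masks and truth."""

    bold_runs: list[np.ndarray]  # each (i, j, k, frames)
    events: GridEventTable
    truth: GroundTruth
    affine: np.ndarray


def make_angle_schedule(spec: SimSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw one run's event angles (degrees in [0, 360)) per the sampling mode."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.angle_sampling == "listed":
        return np.mod(np.asarray(spec.angle_list, dtype=float), 360.0)
    if spec.angle_sampling == "uniform":
        return rng.uniform(0.0, 360.0, size=spec.n_events_per_run)
    # von Mises on the full directional circle
    a = rng.vonmises(np.deg2rad(spec.von_mises_mu), spec.von_mises_kappa,
                     size=spec.n_events_per_run)
    return np.mod(np.degrees(a), 360.0)


def _noise(rng: np.random.Generator, shape: tuple[int, ...], sd: float, ar1: float) -> np.ndarray:
    eps = rng.standard_normal(shape)
    if ar1 != 0.0:
        out = np.empty_like(eps)
        out[0] = eps[0]
        for t in range(1, shape[0]):
            out[t] = ar1 * out[t - 1] + eps[t]
        eps = out * np.sqrt(1.0 - ar1**2)  # keep marginal variance ~1
    return sd * eps


def _build_masks(spec: SimSpec) -> tuple[np.ndarray, np.ndarray]:
    n_vox = int(np.prod(spec.grid_shape))
    n_roi = max(1, int(round(spec.roi_fraction * n_vox)))
    flat_roi = np.zeros(n_vox, dtype=bool)
    flat_roi[:n_roi] = True
    roi = flat_roi.reshape(spec.grid_shape)
    return roi, ~roi


def simulate_session(spec: SimSpec, out_dir: str | Path | None = None) -> SimulatedSession:
    """Generate a full synthetic session (and optionally write it to disk).

    Returns the session in memory; when ``out_dir`` is given, also writes
    one 4D NIfTI per run (``run-XX_bold.nii.gz``), the grid-event TSV
    (``events.tsv``), binary ROI and control masks, the true per-voxel
    orientation volume, and the spec as JSON (seed included), all in the
    dialects the analysis modules read.
    """
    rng = np.random.default_rng(spec.seed)
    fold = check_fold(spec.fold_true)
    roi, control = _build_masks(spec)
    n_vox = roi.size
    roi_flat = roi.reshape(-1)

    # per-voxel true orientations are a property of the voxel: fixed across runs
    period = 360.0 / fold
    jitter = rng.normal(0.0, spec.phi_jitter_sd, size=int(roi_flat.sum()))
    phi_v = np.mod(spec.phi_true + jitter, period)
    phi_vol = np.full(spec.grid_shape, np.nan)
    phi_vol[roi] = phi_v

    n_ev = len(spec.angle_list) if spec.angle_sampling == "listed" else spec.n_events_per_run
    isi = spec.run_length / n_ev
    n_frames = spec.n_frames
    frame_times = np.arange(n_frames) * spec.tr
    hrf = HrfSpec()

    events: list[GridEvent] = []
    bold_runs: list[np.ndarray] = []
    for run in range(1, spec.n_runs + 1):
        angles = make_angle_schedule(spec, rng)
        onsets = np.arange(len(angles)) * isi
        durations = np.full(len(angles), spec.event_duration)
        for on, du, an in zip(onsets, durations, angles):
            events.append(GridEvent(run, float(on), float(du), float(an)))

        E = convolved_event_matrix(onsets, durations, frame_times, spec.tr, hrf)
        # per-event, per-voxel neural amplitudes
        A = np.full((len(angles), n_vox), spec.amplitude)
        delta = np.deg2rad((angles[:, None] - phi_v[None, :]) * fold)
        if spec.rectified:
            mod = 1.0 + spec.modulation_gain * np.maximum(np.cos(delta), 0.0)
        else:
            mod = 1.0 + spec.modulation_gain * np.cos(delta)
        A[:, roi_flat] = spec.amplitude * mod
        Y = spec.baseline + E @ A
        Y += spec.drift * frame_times[:, None]
        if spec.noise_sd > 0:
            Y += _noise(rng, Y.shape, spec.noise_sd, spec.ar1)
        bold_runs.append(np.ascontiguousarray(Y.T.reshape(*spec.grid_shape, n_frames)))

    table = GridEventTable(events, {r: spec.run_length for r in range(1, spec.n_runs + 1)},
                           spec.tr)
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    truth = GroundTruth(phi_vol, roi, control, spec)
    session = SimulatedSession(bold_runs, table, truth, affine)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, data in enumerate(bold_runs, start=1):
            niftiio.save_volume(data, affine, out / f"run-{i:02d}_bold.nii.gz")
        write_event_table(table, out / "events.tsv")
        niftiio.save_volume(roi, affine, out / "roi_mask.nii.gz")
        niftiio.save_volume(control, affine, out / "control_mask.nii.gz")
        niftiio.save_volume(phi_vol, affine, out / "phi_true.nii.gz")
        (out / "sim_spec.json").write_text(spec.to_json())
    return session
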