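"""GLM design construction for hexadirectional analysis.

The estimation model (GLM1) represents each grid event three times: a main
boxcar regressor marking *when* events happen, and two quadrature parametric
regressors carrying sin(fold*alpha) and cos(fold*alpha) per event, where
``alpha`` is the grid event angle and ``fold`` the assumed angular symmetry
(6 for grid cells). Multiplying the angle by the fold maps it into
360/fold-degree space, so a voxel whose signal is modulated at that angular
period loads on the quadrature pair with a phase equal to fold times its
preferred orientation. All neural regressors are convolved with a canonical
double-gamma haemodynamic response function on a microtime grid and sampled
at the scanner frame times; slow scanner drift is absorbed by a
discrete-cosine high-pass basis included in the model.

The quadrature modulators are deliberately neither mean-centred nor
serially orthogonalised: the arctangent orientation estimator assumes the
raw quadrature phase, which orthogonalisation would rotate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.stats import gamma as gamma_dist

from .events import GridEventTable

__all__ = [
    "VALID_FOLDS",
    "check_fold",
    "HrfSpec",
    "DesignMatrix",
    "quadrature_modulators",
    "canonical_hrf",
    "dct_highpass_basis",
    "build_design",
    "convolved_event_matrix",
    "stack_runs",
]

VALID_FOLDS = (3, 4, 5, 6, 7, 8)


def check_fold(fold: int) -> int:
    """Validate an angular symmetry fold (6 = hexadirectional grid code)."""
    if fold not in VALID_FOLDS:
        raise ValueError(f"fold must be one of {VALID_FOLDS}, got {fold!r}")
    return int(fold)


@dataclass(frozen=True)
class HrfSpec:
    """Canonical double-gamma haemodynamic response function parameters.

    The kernel is the difference of two gamma densities — a positive peak
    and a delayed undershoot scaled down by ``peak_undershoot_ratio`` —
    truncated at ``kernel_length`` seconds and scaled to unit peak. Defaults
    are the conventional canonical values (peak at ~5 s, undershoot at
    ~15 s, 32 s support).
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    kernel_length: float = 32.0
    add_temporal_derivative: bool = False
    add_dispersion_derivative: bool = False

    def __post_init__(self) -> None:
        for name in ("peak_delay", "undershoot_delay", "peak_dispersion",
                     "undershoot_dispersion", "kernel_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"HrfSpec.{name} must be positive")
        if self.peak_undershoot_ratio <= 0:
            raise ValueError("HrfSpec.peak_undershoot_ratio must be positive")


@dataclass
class DesignMatrix:
    """Per-run regressor matrix with named columns."""

    values: np.ndarray  # frames x columns
    column_names: list[str]
    frame_times: np.ndarray
    run: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.values.shape != (len(self.frame_times), len(self.column_names)):
            raise ValueError(
                f"design shape {self.values.shape} does not match "
                f"{len(self.frame_times)} frames x {len(self.column_names)} names"
            )
        if len(set(self.column_names)) != len(self.column_names):
            raise ValueError("design column names must be unique")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_names.index(name)]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, columns=self.column_names)


def quadrature_modulators(angle: float, fold: int = 6):
    """Quadrature weights ``(sin(fold*alpha), cos(fold*alpha))`` for one event.

    ``angle`` is in degrees in ``[0, 360)``; the returned pair always lies on
    the unit circle, so sin^2 + cos^2 == 1 to machine precision. Accepts
    arrays of angles.
    """
    fold = check_fold(fold)
    a = np.deg2rad(np.asarray(angle, dtype=float) * fold)
    s, c = np.sin(a), np.cos(a)
    if np.isscalar(angle):
        return float(s), float(c)
    return s, c


def _double_gamma(t: np.ndarray, spec: HrfSpec) -> np.ndarray:
    peak = gamma_dist.pdf(t, a=spec.peak_delay / spec.peak_dispersion,
                          scale=spec.peak_dispersion)
    if np.isinf(spec.peak_undershoot_ratio):
        return peak
    under = gamma_dist.pdf(t, a=spec.undershoot_delay / spec.undershoot_dispersion,
                           scale=spec.undershoot_dispersion)
    return peak - under / spec.peak_undershoot_ratio


def canonical_hrf(tr: float, oversampling: int = 16, spec: HrfSpec | None = None,
                  derivative: str = "none") -> np.ndarray:
    """Sample the canonical HRF kernel at ``tr / oversampling`` seconds.

    The base kernel is zero at t=0 (gamma shape > 1), truncated at
    ``spec.kernel_length`` and scaled so its peak is 1. ``derivative``
    selects the temporal derivative (d/dt of the scaled kernel) or the
    dispersion derivative (finite difference in ``peak_dispersion``), which
    share the base kernel's scaling so their amplitudes stay comparable.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if oversampling < 1:
        raise ValueError("oversampling must be >= 1")
    spec = spec or HrfSpec()
    dt = tr / oversampling
    t = np.arange(0.0, spec.kernel_length + dt / 2, dt)
    h = _double_gamma(t, spec)
    scale = h.max()
    if scale <= 0:
        raise ValueError("HRF kernel has non-positive peak; check HrfSpec")
    h = h / scale
    if derivative == "none":
        return h
    if derivative == "temporal":
        return np.gradient(h, dt)
    if derivative == "dispersion":
        dd = 0.01
        h2 = _double_gamma(t, replace(spec, peak_dispersion=spec.peak_dispersion + dd))
        return (h - h2 / scale) / dd
    raise ValueError(f"unknown derivative kind {derivative!r}")


def dct_highpass_basis(n_frames: int, tr: float, cutoff: float = 128.0) -> np.ndarray:
    """Low-frequency discrete cosine drift columns for high-pass filtering.

    Returns the K lowest-frequency non-constant DCT-II columns whose period
    exceeds ``cutoff`` seconds, K = floor(2 * n_frames * tr / cutoff). The
    columns are mutually orthogonal and unit-norm; the constant term is
    excluded (the intercept is modeled separately). ``cutoff=inf`` disables
    drift modeling (K = 0).
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if np.isinf(cutoff):
        return np.empty((n_frames, 0))
    if cutoff <= 2 * tr:
        raise ValueError(f"cutoff {cutoff} s must exceed twice the TR ({2 * tr} s)")
    K = int(np.floor(2.0 * n_frames * tr / cutoff))
    K = min(K, n_frames - 1)
    n = np.arange(n_frames)
    cols = [np.cos(np.pi * (2 * n + 1) * k / (2.0 * n_frames)) for k in range(1, K + 1)]
    if not cols:
        return np.empty((n_frames, 0))
    X = np.column_stack(cols)
    return X / np.linalg.norm(X, axis=0)


def convolved_event_matrix(
    onsets: Sequence[float],
    durations: Sequence[float],
    frame_times: np.ndarray,
    tr: float,
    hrf: HrfSpec | None = None,
    microtime: tuple[int, int] = (16, 8),
    derivative: str = "none",
) -> np.ndarray:
    """HRF responses of individual events, sampled at the frame times.

    Builds one boxcar per event on the microtime grid (bin width
    ``tr / resolution``), convolves all of them with the requested kernel
    and samples at frame onsets offset by the microtime onset bin. Returns a
    ``frames x events`` matrix; any per-event weighted regressor is then a
    single matrix-vector product, which keeps re-weighting (quadrature,
    parametric modulation, alignment bins) cheap.
    """
    resolution, onset_bin = microtime
    if resolution < 1 or not (1 <= onset_bin <= resolution):
        raise ValueError(f"invalid microtime (resolution, onset) = {microtime}")
    frame_times = np.asarray(frame_times, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    durations = np.asarray(durations, dtype=float)
    if onsets.size == 0:
        return np.empty((frame_times.size, 0))
    dt = tr / resolution
    t_end = frame_times[-1] + tr
    n_bins = int(np.ceil(t_end / dt)) + 1
    U = np.zeros((n_bins, onsets.size))
    for j, (on, du) in enumerate(zip(onsets, durations)):
        b0 = int(np.round(on / dt))
        b1 = max(b0 + 1, int(np.round((on + du) / dt)))
        U[b0:min(b1, n_bins), j] = 1.0
    kernel = canonical_hrf(tr, resolution, hrf, derivative=derivative)
    C = signal.fftconvolve(U, kernel[:, None], mode="full", axes=0)[:n_bins] * dt
    idx = np.round(frame_times / dt).astype(int) + (onset_bin - 1)
    idx = np.clip(idx, 0, n_bins - 1)
    return C[idx]


def build_design(
    events: GridEventTable,
    frame_times: np.ndarray,
    fold: int = 6,
    hrf: HrfSpec | None = None,
    nuisance: np.ndarray | None = None,
    drift_cutoff: float = 128.0,
    microtime: tuple[int, int] = (16, 8),
    unused_events: GridEventTable | None = None,
    run: int | None = None,
) -> DesignMatrix:
    """Assemble the GLM1 design matrix for one run's estimation events.

    Columns, in order: ``grid_main`` (event boxcars convolved with the HRF),
    ``grid_sin`` / ``grid_cos`` (the same boxcars weighted per event by the
    quadrature modulators before convolution), optional temporal and
    dispersion derivatives of each, ``unused_events`` (a single convolved
    boxcar for the other partition's events, modeled as a nuisance of no
    interest), user nuisance columns, DCT drift columns, and the intercept.
    """
    fold = check_fold(fold)
    hrf = hrf or HrfSpec()
    frame_times = np.asarray(frame_times, dtype=float)
    if frame_times.size < 2 or np.any(np.diff(frame_times) <= 0):
        raise ValueError("frame_times must be strictly increasing with >= 2 frames")
    runs = {e.run for e in events.events}
    if len(runs) > 1:
        raise ValueError(f"events span runs {sorted(runs)}; build one design per run")
    if not events.events:
        raise ValueError("no events to model: the partition for this run is empty")
    run = run if run is not None else next(iter(runs))
    tr = events.tr

    onsets = [e.onset for e in events.events]
    durations = [e.duration for e in events.events]
    sin_w, cos_w = quadrature_modulators(np.array([e.angle for e in events.events]), fold)

    names: list[str] = []
    cols: list[np.ndarray] = []
    kinds = ["none"]
    if hrf.add_temporal_derivative:
        kinds.append("temporal")
    if hrf.add_dispersion_derivative:
        kinds.append("dispersion")
    suffix = {"none": "", "temporal": "_dt", "dispersion": "_dd"}
    for kind in kinds:
        E = convolved_event_matrix(onsets, durations, frame_times, tr, hrf,
                                   microtime, derivative=kind)
        cols += [E.sum(axis=1), E @ sin_w, E @ cos_w]
        names += [f"grid_main{suffix[kind]}", f"grid_sin{suffix[kind]}",
                  f"grid_cos{suffix[kind]}"]

    if unused_events is not None and unused_events.events:
        Eu = convolved_event_matrix(
            [e.onset for e in unused_events.events],
            [e.duration for e in unused_events.events],
            frame_times, tr, hrf, microtime)
        cols.append(Eu.sum(axis=1))
        names.append("unused_events")

    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != frame_times.size:
            raise ValueError(
                f"nuisance has {nuisance.shape[0]} rows, expected {frame_times.size}"
            )
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


def stack_runs(designs: Sequence[DesignMatrix],
               shared_prefixes: tuple[str, ...] = ("grid_", "unused_events")) -> DesignMatrix:
    """Concatenate per-run designs for a joint multi-run fit.

    Grid columns (and the unused-events nuisance) are shared across runs —
    stacked vertically — while nuisance, drift and intercept columns are
    kept run-specific in a block-diagonal arrangement, giving per-run
    intercepts and drift models.
    """
    if len(designs) == 1:
        return designs[0]
    shared_names = [n for n in designs[0].column_names
                    if any(n.startswith(p) for p in shared_prefixes)]
    for d in designs[1:]:
        other = [n for n in d.column_names if any(n.startswith(p) for p in shared_prefixes)]
        if other != shared_names:
            raise ValueError("runs have incompatible shared (grid) columns")
    n_total = sum(d.n_frames for d in designs)
    blocks: list[np.ndarray] = []
    names: list[str] = []
    shared = np.vstack([
        np.column_stack([d.column(n) for n in shared_names]) for d in designs
    ])
    blocks.append(shared)
    names += shared_names
    offset = 0
    for d in designs:
        local = [n for n in d.column_names if n not in shared_names]
        blk = np.zeros((n_total, len(local)))
        blk[offset:offset + d.n_frames] = np.column_stack([d.column(n) for n in local])
        blocks.append(blk)
        names += [f"run{d.run}_{n}" for n in local]
        offset += d.n_frames
    times = np.concatenate([d.frame_times for d in designs])
    out = DesignMatrix(np.hstack(blocks), names,
                       np.arange(n_total, dtype=float), run=-1)
    out.frame_times = times  # bypass monotonicity; concatenated sessions
    return out
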