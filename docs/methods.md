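# Methods

## Signal model and estimation logic

The analysis assumes that the BOLD response to a directed event (a
"grid event" with angle α, in degrees from a nominal 0° reference) in a
grid-code-carrying voxel is modulated sinusoidally with angular period
360/fold around the voxel's preferred orientation φ_v:

    neural amplitude ∝ 1 + g · cos(fold · (α − φ_v)),

with fold = 6 for hexadirectional (grid-cell) codes and g the modulation
gain. Expanding the cosine shows why quadrature regressors identify φ_v:

    cos(fold·(α − φ_v)) = cos(fold·φ_v)·cos(fold·α) + sin(fold·φ_v)·sin(fold·α),

so a GLM containing sin(fold·α) and cos(fold·α) parametric regressors
(per-event weights on the event boxcar, convolved with the HRF) yields
betas β₁ ∝ sin(fold·φ_v) and β₂ ∝ cos(fold·φ_v), and

    φ_v = atan2(β₁, β₂) / fold,  wrapped into [0°, 360/fold°).

We use the four-quadrant arctangent rather than the principal-branch
arctan of the ratio β₁/β₂: the principal branch collapses orientations
into half of the orientation space and cannot represent an arbitrary φ,
whereas atan2 recovers the full [0°, 60°) range shown in grid-code polar
plots. The ROI mean orientation averages β₁ and β₂ over ROI voxels (and
over runs, when requested) *before* the arctangent — a vector average in
the quadrature plane, which weights voxels implicitly by their modulation
amplitude. An explicit amplitude-weighted circular mean of the voxel
orientations is also provided (`circular_mean_orientation`); on a coherent
ROI the two summaries agree to within a couple of degrees, and
beta-averaging is the default.

Estimation and test are strictly partitioned (odd/even runs, temporal
bins, odd/even events, run halves, or user-defined labels in the event
table) so that the orientation used by the magnitude model is never fitted
on the data that tests it. Events of the opposite partition are modeled as
a single unweighted nuisance boxcar ("unused events"). A consequence worth
knowing: the directional *modulation* of those unused events is not in the
model, so within-run partitions (odd/even events, half runs) leave a small
residual that can bias φ by a fraction of a degree and shrink the
parametric magnitude by a few percent; the odd/even-runs partition, where
an entire run is either estimation or test, is free of this leakage. This
is inherent to the single-nuisance-regressor convention, not an artifact
of this implementation.

## GLM details

- **HRF**: canonical double-gamma — gamma-density peak (delay 6 s,
  dispersion 1 s) minus a gamma-density undershoot (delay 16 s, dispersion
  1 s) divided by the peak:undershoot ratio 6, truncated at 32 s and
  scaled to unit peak. Optional temporal (d/dt) and dispersion
  (finite-difference in peak dispersion) derivatives.
- **Microtime**: regressors are built on a grid of tr/16 s and sampled at
  the 8th of 16 bins within each TR (resolution 16, onset 8), the
  conventional defaults.
- **Parametric modulators are not mean-centered and not orthogonalized**
  against the main boxcar or each other. Orthogonalization would rotate
  the quadrature phase that the arctangent formula assumes; any shared
  mean is absorbed by the main regressor and intercept. A sensitivity flag
  is deliberately not offered: centering changes β₁/β₂ only through the
  main-regressor column, leaving φ̂ invariant in balanced designs.
- **Drift**: K = floor(2·T/cutoff) low-frequency discrete-cosine columns
  (cutoff default 128 s) inside the design, rather than pre-filtering the
  data — one linear model, simpler contracts.
- **Fitting**: plain mass-univariate OLS (single shared pseudo-inverse);
  no prewhitening — the AR(1) option in the simulator exists to probe
  robustness, not because the fitter models autocorrelation. Voxels are
  selected by an explicit mask, or else by the implicit masking threshold
  (mean signal ≥ 0.8 × global mean). Rank-deficient designs are a hard
  error naming the collinear columns.
- **Multi-run fits** share the grid/event columns across runs and keep
  per-run intercept, drift and nuisance blocks (block-diagonal).

## Magnitude models (GLM2)

Given φ from the estimation partition, test events are modeled as:

- **parametric**: main boxcar + modulator cos(fold·(α − φ)); the modulator
  beta is the magnitude. Under the generative model above its expectation
  is amplitude·g.
- **aligned_misaligned**: events within ±15° (inclusive — "within" counts
  the boundary) of the nearest grid axis (φ + k·360/fold) vs. the rest;
  magnitude = aligned − misaligned contrast. At fold 6 the aligned set is
  exactly half the angular domain.
- **binned**: 360/bin_width regressors (default twelve 30° bins), bin 1
  centered on φ with half-open intervals [center − w/2, center + w/2), so
  no event is double-counted and, at bin_width = 360/(2·fold), odd bins
  are exactly the aligned ones. Per-bin ROI-mean betas are reported; the
  summary contrast is mean(odd bins) − mean(even bins).

An empty condition (e.g., no misaligned events sampled — possible in free
exploration where directions are unevenly sampled) is a hard error naming
the condition, never a silently dropped column.

The fold sweep re-runs GLM1 *and* GLM2 per candidate fold, re-estimating φ
under each fold's own quadrature model: each symmetry hypothesis gets its
best orientation, which is the fair model comparison.

## Circular statistics

Orientations live on a 360/fold-degree circle; all distances are computed
modulo 360/fold (maximum 180/fold). The Rayleigh test maps orientations to
the full circle by multiplying by the fold, computes the mean resultant
length R̄, z = n·R̄², and the closed-form approximation

    p = exp( √(1 + 4n + 4(n² − (nR̄)²)) − (1 + 2n) ),

the formula in standard use in circular-statistics toolboxes; its type-I
error at α = 0.05 is verified to lie in [0.04, 0.06] by simulation. An
exact permutation option is not provided: a one-sample uniformity test has
no exchangeable structure to permute, and the closed form is accurate from
small n upward. A zero resultant (antipodal cancellation) leaves the mean
direction undefined; it is reported as NaN with a warning rather than an
arbitrary angle. Within-voxel stability classifies a voxel stable when its
fold-wrapped orientation difference across two maps is ≤ threshold
(default ±15°, inclusive); chance level for independent orientations is
2·threshold·fold/360 (0.5 at fold 6, ±15°).

## Synthetic sessions: what they emulate, and what not

`simulate_session` produces the signal model exactly as assumed by the
analysis: signed cosine modulation (1 + g·cos) of event amplitudes
(matching the linear-sinusoidal analysis model; a rectified variant that
only boosts aligned events exists for robustness checks), HRF convolution
on the microtime grid, linear drift, and i.i.d. Gaussian noise (optional
AR(1), default off, matching the OLS fitter). Defaults, chosen once as a
realistic directional-event experiment at desk scale:

| parameter | default | note |
|---|---|---|
| runs × events | 2 × 200 | 600 s runs, TR 1.5 s, 2 s events every 3 s |
| volume | 12 × 12 × 6 voxels | ROI = contiguous 15% block (130 voxels); the rest is the g = 0 control region |
| φ_true / jitter | 20° / 3° SD | between-voxel orientation jitter, fixed per voxel across runs |
| gain g | 0.3 | fraction of event amplitude |
| amplitude / baseline | 2.0 / 100 | signal units |
| noise_sd | 7.74 | = (peak response of one event, 3.87) / SNR 0.5 |
| drift | 0.01 units/s | linear |

The per-event SNR is defined as the peak amplitude of a single
unmodulated event's HRF-convolved response divided by the noise standard
deviation; 0.5 makes single events invisible but leaves the 400-event,
130-voxel aggregate comfortably estimable — per-voxel orientation SD of a
few degrees, ROI-level φ error well under 1°.

Not emulated: spatial noise correlations and smoothing, physiological
noise, motion, susceptibility dropout, trajectory physics of any task, and
unequal directional sampling (available via the von Mises schedule but not
the default). Passing tests therefore demonstrate correctness of the
estimators under the assumed signal model, not detectability of grid codes
in any particular real acquisition; true BOLD grid-code effect sizes are
unknown, and g = 0.3 is a testing convenience, not a physiological claim.

## Numerical and interface choices

- Angles are stored in degrees everywhere and converted to radians only
  inside trigonometric calls; the rotational sense of the angle convention
  is declared metadata and affects no computation.
- Event tables are TSV with header `run onset duration angle_deg [set]`,
  onsets in seconds from each run's first volume. Events labeled
  `excluded` are kept out of both partitions under every scheme.
- `half_runs` splits at run_length/2 by onset (the onset determines the
  modeled impulse); `temporal_bins` uses equal-duration windows with
  odd-indexed bins as estimation.
- ROI masks must match the BOLD grid bit-exactly (shape and affine);
  registration is out of scope.
- Orientation NIfTI exports use NaN backgrounds — 0° is a valid
  orientation.
- Exactly-zero quadrature betas make the orientation undefined and raise,
  rather than returning an arbitrary 0°.
- Problem sizes in the statistical tests (e.g., 100 seeds for orientation
  recovery, 50 seeds per generative fold for model selection, 10,000
  draws for Rayleigh calibration, a reduced 150-replicate volume for the
  null-gain calibration) are chosen to make sampling error small relative
  to the tested tolerance while keeping the suite fast to run.

## Known limitations

- No prewhitening or variance-component modeling; inference on single
  fits uses OLS standard errors.
- No group-level statistics, no representational-similarity analysis, no
  preprocessing (realignment, smoothing, normalization) — all upstream or
  out of scope.
- The unused-events nuisance models only the timing, not the directional
  modulation, of the opposite partition (see above).
- Plotting (`gridcode.plot`) aims at clarity, not figure-for-figure parity
  with any particular toolbox.
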