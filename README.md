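# gridcode

Hexadirectional (grid-cell) code analysis for human fMRI, as a scriptable
Python library and command-line tool.

Grid cells in the entorhinal cortex fire on the vertices of a hexagonal
lattice, and a subpopulation (conjunctive grid cells) fires preferentially
when movement is aligned with one of the grid's six axes. At the macroscopic
scale this predicts a *six-fold (hexadirectional) modulation* of the BOLD
signal by movement or event direction: activity should peak whenever the
event angle α is aligned with the population's mean grid orientation φ or a
60° multiple of it. `gridcode` estimates and tests this signature:

1. **Orientation estimation (GLM1).** On an *estimation* partition of the
   data, each directed event enters the design three times: a main boxcar
   and two quadrature parametric modulators, sin(6·α<sub>t</sub>) and
   cos(6·α<sub>t</sub>), convolved with a canonical double-gamma HRF. The
   voxel-wise grid orientation is
   φ<sub>v</sub> = atan2(β₁, β₂) / 6 ∈ [0°, 60°),
   and the ROI mean grid orientation averages β₁ and β₂ over ROI voxels
   (and runs) before the arctangent: φ = atan2(mean β₁, mean β₂)/6.
2. **Magnitude quantification (GLM2).** On the held-out *test* partition,
   events are re-modeled with respect to φ under any of the three families
   in common use: a parametric modulator cos[6·(α<sub>t</sub> − φ)]; an
   aligned (within ±15° of a grid axis) vs. misaligned contrast; or twelve
   30° bins anchored on φ (six aligned, six misaligned).
3. **Coherence and stability.** Rayleigh's test for non-uniformity of the
   voxel orientations (computed in 60°-periodic space), and within-voxel
   cross-run stability: the percentage of voxels whose orientation agrees
   across runs within ±15°.
4. **Controls.** The whole estimate-then-test pipeline can be re-run under
   alternative angular symmetries (3- to 8-fold); a genuine grid code should
   be strongest at 6.

No external dataset is required: `gridcode.simulate` generates BOLD runs,
event tables and masks with known ground truth (orientation, modulation
gain, fold), so every pipeline stage is testable end to end.

## Worked example

```python
from gridcode.simulate import SimSpec, simulate_session
from gridcode.model import HexadirectionalModel

session = simulate_session(SimSpec(seed=3))       # 2 runs, true phi = 20 deg
model = HexadirectionalModel.from_simulation(session)
results = model.fit()
print(results.summary())
```

```
Hexadirectional grid-code analysis
======================================================
Runs                              2
Events (est/test)                 200/200
Symmetry fold                     6
ROI voxels                        130
------------------------------------------------------
Mean grid orientation phi (deg)   19.51  [0, 60)
Rayleigh mean resultant R         0.870
Rayleigh z                        98.34
Rayleigh p                        1.78e-57
GLM2 method                       parametric
Grid-code magnitude (ROI mean)    0.7285
  across-voxel SE                 0.0261
Within-voxel stability            87.7% (threshold +/-15 deg)
======================================================
```

The generator injected a six-fold modulation at φ = 20° with gain 0.3; the
fit recovers φ = 19.51°, the voxel orientations cluster strongly (Rayleigh
R = 0.87, p ≈ 10⁻⁵⁷), the held-out parametric magnitude is positive at
~28 standard errors, and 87.7% of ROI voxels keep their orientation across
the two runs within ±15°. A control re-fit under other folds
(`model.fold_sweep()`) peaks at fold 6.

The same analysis runs from files (NIfTI BOLD runs, a TSV event table with
columns `run onset duration angle_deg [set]`, binary NIfTI masks) via
`HexadirectionalModel.from_files(...)` or the CLI:

```bash
gridcode simulate --seed 7 --out demo/
gridcode run --config demo/cfg.json
gridcode sweep --config demo/cfg.json --folds 4,5,6,7,8
```

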