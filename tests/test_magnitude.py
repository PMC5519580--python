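"""GLM2 magnitude models: parametric, aligned/misaligned, binned; fold sweep."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gridcode.magnitude import (EmptyConditionError, Glm2Spec, bin_index,
                                classify_alignment, fit_glm2, fold_sweep,
                                parametric_modulator)
from gridcode.events import PartitionScheme, partition_events
from gridcode.simulate import SimSpec, simulate_session


def _bruteforce_axis_distance(angle, phi, fold):
    return min(abs(angle - (phi + k * 360.0 / fold)) for k in range(-8, 9))


class TestParametricModulator:
    def test_aligned_is_one(self):
        assert parametric_modulator(23.0, 23.0, 6) == pytest.approx(1.0)
        assert parametric_modulator(23.0 + 60.0, 23.0, 6) == pytest.approx(1.0)

    def test_antialigned_is_minus_one(self):
        assert parametric_modulator(53.0, 23.0, 6) == pytest.approx(-1.0)

    def test_quarter_offset_is_zero(self):
        assert parametric_modulator(38.0, 23.0, 6) == pytest.approx(0.0, abs=1e-12)

    @given(phi=st.floats(0, 360, exclude_max=True),
           delta=st.floats(-180, 180))
    @settings(max_examples=200, deadline=None)
    def test_even_symmetry_and_period(self, phi, delta):
        f = parametric_modulator
        assert f(phi + delta, phi, 6) == pytest.approx(f(phi - delta, phi, 6), abs=1e-9)
        assert f(phi + delta + 60.0, phi, 6) == pytest.approx(
            f(phi + delta, phi, 6), abs=1e-9)

    def test_range(self):
        a = np.linspace(0, 360, 721)
        v = parametric_modulator(a, 17.0, 6)
        assert v.min() >= -1.0 and v.max() <= 1.0
        assert v.max() == pytest.approx(1.0)
        assert v.min() == pytest.approx(-1.0)


class TestClassifyAlignment:
    @pytest.mark.parametrize("angle,phi,expected", [
        (10.0, 0.0, "aligned"),
        (30.0, 0.0, "misaligned"),   # the anti-axis
        (75.0, 0.0, "aligned"),      # nearest axis 60, distance 15 (inclusive)
        (15.0, 0.0, "aligned"),      # boundary inclusive
        (15.0001, 0.0, "misaligned"),
    ])
    def test_reference_cases(self, angle, phi, expected):
        assert classify_alignment(angle, phi, 6, 15.0) == expected

    @given(angle=st.floats(0, 360, exclude_max=True),
           phi=st.floats(0, 60, exclude_max=True))
    @settings(max_examples=200, deadline=None)
    def test_matches_bruteforce_axis_distance(self, angle, phi):
        d = _bruteforce_axis_distance(angle, phi, 6)
        assert (classify_alignment(angle, phi, 6, 15.0) == "aligned") == (d <= 15.0)

    def test_half_domain_aligned_under_default_threshold(self):
        # 1-degree grid enumeration: exactly half the circle is aligned
        grid = np.arange(0.5, 360.0, 1.0)
        aligned = classify_alignment(grid, 0.0, 6, 15.0)
        assert aligned.mean() == pytest.approx(0.5)


class TestBinIndex:
    def test_center_is_bin_one(self):
        assert bin_index(40.0, 40.0, 6, 30.0) == 1

    def test_upper_boundary_goes_to_next_bin(self):
        assert bin_index(55.0, 40.0, 6, 30.0) == 2   # phi + 15 exactly
        assert bin_index(54.999, 40.0, 6, 30.0) == 1

    def test_twelve_bins_six_aligned(self):
        # half-degree grid: bins alternate aligned/misaligned, 6 of each
        grid = np.arange(0.25, 360.0, 0.5)
        idx = bin_index(grid, 10.0, 6, 30.0)
        assert set(idx) == set(range(1, 13))
        aligned_bins = {b for b in range(1, 13)
                        if b % 2 == 1}
        for b in range(1, 13):
            sel = idx == b
            frac_aligned = np.mean(classify_alignment(grid[sel], 10.0, 6, 15.0))
            assert frac_aligned == pytest.approx(1.0 if b in aligned_bins else 0.0,
                                                 abs=0.01)

    def test_interval_table(self):
        # explicit half-open interval enumeration around phi = 0
        for b, lo in [(1, -15.0), (2, 15.0), (3, 45.0), (12, -45.0)]:
            assert bin_index((lo + 1e-6) % 360.0, 0.0, 6, 30.0) == b
            assert bin_index((lo + 29.999) % 360.0, 0.0, 6, 30.0) == b


def _noiseless(seed=1, **kw):
    return simulate_session(SimSpec(seed=seed, noise_sd=0.0, phi_jitter_sd=0.0,
                                    drift=0.0, n_runs=1, **kw))


class TestFitGlm2:
    def test_parametric_recovers_gain_noiseless(self):
        ses = _noiseless()
        spec = ses.truth.spec
        ev = ses.events.with_labels(["test"] * len(ses.events))
        res = fit_glm2(ses.bold_runs, ev, phi=spec.phi_true, spec=Glm2Spec(),
                       roi=ses.truth.roi_mask,
                       mask=np.ones(spec.grid_shape, dtype=bool))
        g_hat = res.roi_mean / spec.amplitude
        assert g_hat == pytest.approx(spec.modulation_gain, rel=0.02)

    def test_aligned_misaligned_positive_in_roi_null_in_control(self, default_session):
        ses = default_session
        ev = partition_events(ses.events, PartitionScheme("odd_even_events"))
        mask = np.ones(ses.truth.spec.grid_shape, dtype=bool)
        phi = ses.truth.spec.phi_true
        spec2 = Glm2Spec(method="aligned_misaligned")
        roi_res = fit_glm2(ses.bold_runs, ev, phi, spec2,
                           roi=ses.truth.roi_mask, mask=mask)
        ctl_res = fit_glm2(ses.bold_runs, ev, phi, spec2,
                           roi=ses.truth.control_mask, mask=mask)
        assert roi_res.roi_mean > 0
        assert abs(ctl_res.roi_mean) <= 2.0 * ctl_res.roi_se

    def test_binned_profile_is_cosine_shaped(self, default_session):
        ses = default_session
        ev = partition_events(ses.events, PartitionScheme("odd_even_events"))
        res = fit_glm2(ses.bold_runs, ev, ses.truth.spec.phi_true,
                       Glm2Spec(method="binned"),
                       roi=ses.truth.roi_mask,
                       mask=np.ones(ses.truth.spec.grid_shape, dtype=bool))
        assert res.per_bin_betas is not None and len(res.per_bin_betas) == 12
        centers = np.arange(12) * 30.0
        template = np.cos(np.deg2rad(centers * 6))
        r = np.corrcoef(res.per_bin_betas, template)[0, 1]
        assert r > 0.9
        # the phi-centered bin beats every misaligned bin
        assert res.per_bin_betas[0] > res.per_bin_betas[1::2].max()

    def test_binned_agrees_in_sign_with_contrast(self, default_session):
        ses = default_session
        ev = partition_events(ses.events, PartitionScheme("odd_even_events"))
        mask = np.ones(ses.truth.spec.grid_shape, dtype=bool)
        phi = ses.truth.spec.phi_true
        binned = fit_glm2(ses.bold_runs, ev, phi, Glm2Spec(method="binned"),
                          roi=ses.truth.roi_mask, mask=mask)
        am = fit_glm2(ses.bold_runs, ev, phi, Glm2Spec(method="aligned_misaligned"),
                      roi=ses.truth.roi_mask, mask=mask)
        aligned_mean = binned.per_bin_betas[::2].mean()
        misaligned_mean = binned.per_bin_betas[1::2].mean()
        assert np.sign(aligned_mean - misaligned_mean) == np.sign(am.roi_mean)

    def test_empty_condition_is_loud_error(self):
        # all events aligned with phi: no misaligned regressor possible
        ses = _noiseless(angle_sampling="listed",
                         angle_list=tuple(float(a % 360) for a in range(0, 360, 60)),
                         n_events_per_run=6)
        ev = ses.events.with_labels(["test"] * len(ses.events))
        with pytest.raises(EmptyConditionError, match="misaligned"):
            fit_glm2(ses.bold_runs, ev, phi=0.0,
                     spec=Glm2Spec(method="aligned_misaligned"),
                     roi=ses.truth.roi_mask,
                     mask=np.ones(ses.truth.spec.grid_shape, dtype=bool))

    def test_quadrature_amplitude_equivalence_noiseless(self):
        # parametric magnitude == quadrature amplitude when phi is estimated
        # on the same noiseless data
        from gridcode.design import build_design
        from gridcode.glm import fit_glm
        from gridcode.orientation import roi_mean_orientation

        ses = _noiseless(seed=4)
        spec = ses.truth.spec
        mask = np.ones(spec.grid_shape, dtype=bool)
        ft = np.arange(spec.n_frames) * spec.tr
        d1 = build_design(ses.events.subset(run=1), ft)
        b = fit_glm(ses.bold_runs[0], d1, mask=mask)
        ro = roi_mean_orientation([b], roi=ses.truth.roi_mask)
        amp = np.hypot(ro.mean_beta_sin, ro.mean_beta_cos)
        ev = ses.events.with_labels(["test"] * len(ses.events))
        res = fit_glm2(ses.bold_runs, ev, ro.phi, Glm2Spec(),
                       roi=ses.truth.roi_mask, mask=mask)
        assert res.roi_mean == pytest.approx(amp, rel=0.02)


class TestFoldSweep:
    def test_recovers_generative_fold_six(self, default_session):
        ses = default_session
        ev = partition_events(ses.events, PartitionScheme("odd_even_events"))
        table = fold_sweep(ses.bold_runs, ev, roi=ses.truth.roi_mask,
                           folds=(4, 5, 6, 7, 8),
                           mask=np.ones(ses.truth.spec.grid_shape, dtype=bool))
        assert len(table) == 5
        assert int(table.loc[table["roi_mean"].idxmax(), "fold"]) == 6

    def test_recovers_generative_fold_four(self):
        ses = simulate_session(SimSpec(seed=13, fold_true=4))
        ev = partition_events(ses.events, PartitionScheme("odd_even_events"))
        table = fold_sweep(ses.bold_runs, ev, roi=ses.truth.roi_mask,
                           folds=(4, 5, 6, 7, 8),
                           mask=np.ones(ses.truth.spec.grid_shape, dtype=bool))
        assert int(table.loc[table["roi_mean"].idxmax(), "fold"]) == 4

    def test_null_data_magnitudes_are_small(self):
        ses = simulate_session(SimSpec(seed=31, modulation_gain=0.0))
        ev = partition_events(ses.events, PartitionScheme("odd_even_events"))
        table = fold_sweep(ses.bold_runs, ev, roi=ses.truth.roi_mask,
                           folds=(4, 5, 6, 7, 8),
                           mask=np.ones(ses.truth.spec.grid_shape, dtype=bool))
        assert np.all(np.abs(table["roi_mean"]) <= 3.0 * table["roi_se"])
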