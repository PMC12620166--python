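"""Motion curves, displacement metric, PCA augmentation and k-space corruption."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from phimo.forward import RigidState, acquisition_times, static_multicoil_kspace
from phimo.motion import (
    B0Config,
    MotionCurve,
    average_displacement,
    center_on_median_state,
    fit_pca_motion_model,
    mark_corrupted_lines,
    pca_augment,
    reference_mask_from_timings,
    sample_b0_perturbation,
    simulate_corrupted_kspace,
    synthetic_motion_curve,
)


def _constant_curve(times, t=(0, 0, 0), r=(0, 0, 0)):
    return MotionCurve(times, [RigidState(t=np.array(t), r=np.array(r)) for _ in times])


class TestAverageDisplacement:
    def test_identity_state_is_zero(self):
        assert average_displacement(RigidState()) == 0.0

    def test_pure_translation_is_its_norm(self):
        assert average_displacement(RigidState(t=[3.0, 0, 0])) == pytest.approx(3.0)
        assert average_displacement(RigidState(t=[1.0, 2.0, 2.0])) == pytest.approx(3.0)

    def test_rotation_matches_monte_carlo_oracle(self):
        state = RigidState(r=[0, 0, 10.0])
        value = average_displacement(state)
        rng = np.random.default_rng(42)
        pts = rng.uniform(-64, 64, (4_000_000, 3))
        pts = pts[(pts**2).sum(axis=1) <= 64.0**2][:1_000_000]
        rot = Rotation.from_euler("xyz", [0, 0, 10], degrees=True)
        oracle = float(np.mean(np.linalg.norm(rot.apply(pts) - pts, axis=1)))
        assert value == pytest.approx(oracle, rel=5e-3)


class TestMedianCentering:
    def test_identity_curve_unchanged(self):
        curve = _constant_curve(np.arange(5.0))
        centered = center_on_median_state(curve)
        assert all(s.is_identity() for s in centered.states)

    def test_constant_offset_curve_becomes_identity(self):
        curve = _constant_curve(np.arange(4.0), t=(2.0, -1.0, 0.5), r=(3.0, 0.0, -5.0))
        centered = center_on_median_state(curve)
        for s in centered.states:
            assert np.max(np.abs(s.params)) < 1e-10

    def test_median_displacement_is_zero_after_centering(self):
        times = np.arange(10.0)
        states = [RigidState() for _ in range(7)] + [
            RigidState(t=[4.0, 0, 0]), RigidState(t=[0, 5.0, 0]), RigidState(r=[0, 0, 8.0])
        ]
        centered = center_on_median_state(MotionCurve(times, states))
        disp = np.array([average_displacement(s) for s in centered.states])
        assert np.median(disp) < 1e-10


class TestPCAAugmentation:
    def _training_curves(self, n=6, n_times=20, seed=0):
        rng = np.random.default_rng(seed)
        times = np.arange(float(n_times))
        curves = []
        for _ in range(n):
            params = rng.standard_normal((n_times, 6)).cumsum(axis=0) * 0.2
            curves.append(MotionCurve(times, [RigidState(t=p[:3], r=p[3:]) for p in params]))
        return curves

    def test_zero_weights_reproduce_the_mean_curve(self):
        curves = self._training_curves()
        out = pca_augment(curves, n_out=3, seed=0, alpha_scale=0.0)
        mean = np.mean([c.params_matrix() for c in curves], axis=0)
        for c in out:
            assert np.allclose(c.params_matrix(), mean, atol=1e-10)

    def test_full_component_reconstruction_recovers_training_curve(self):
        curves = self._training_curves()
        model = fit_pca_motion_model(curves)
        x0 = curves[0].params_matrix().ravel()
        scores = model.components @ (x0 - model.mean)
        rebuilt = model.mean + scores @ model.components
        assert np.max(np.abs(rebuilt - x0)) < 1e-8

    def test_requested_sample_count_is_returned(self):
        out = pca_augment(self._training_curves(), n_out=90, seed=1)
        assert len(out) == 90

    def test_fewer_than_two_curves_rejected(self):
        with pytest.raises(ValueError):
            pca_augment(self._training_curves(n=1), n_out=5, seed=0)

    def test_augmented_variance_bounded_by_training_variance(self):
        curves = self._training_curves(n=10)
        out = pca_augment(curves, n_out=500, seed=2, alpha_scale=1.0)
        model = fit_pca_motion_model(curves)
        train = np.stack([c.params_matrix().ravel() for c in curves]) - model.mean
        aug = np.stack([c.params_matrix().ravel() for c in out]) - model.mean
        n_comp = int(np.ceil(0.2 * len(curves)))
        # project onto the retained subspace and compare variances
        basis = model.components[:n_comp]
        var_train = np.var(train @ basis.T, axis=0)
        var_aug = np.var(aug @ basis.T, axis=0)
        assert np.all(var_aug <= var_train * (1 + 1.0**2) + 1e-9)


class TestCorruptionBookkeeping:
    def test_identity_curve_marks_nothing(self):
        scheme = acquisition_times(16, 1000.0)
        curve = _constant_curve(np.arange(0.0, 17.0, 0.5))
        masks = mark_corrupted_lines(curve, scheme)
        assert masks["odd"].line_labels.min() == 1
        assert masks["even"].line_labels.min() == 1

    def test_single_event_marks_exactly_the_covered_lines(self):
        scheme = acquisition_times(32, 1000.0)  # odd line k at k seconds
        times = np.arange(0.0, 33.0, 1.0)
        states = [
            RigidState(t=[5.0, 0, 0]) if 10 <= t <= 20 else RigidState() for t in times
        ]
        masks = mark_corrupted_lines(MotionCurve(times, states), scheme)
        assert set(np.flatnonzero(masks["odd"].line_labels == 0)) == set(range(10, 21))

    def test_infinite_threshold_marks_nothing(self):
        scheme = acquisition_times(8, 1000.0)
        curve = _constant_curve(np.arange(0.0, 9.0, 0.5), t=(50.0, 0, 0))
        masks = mark_corrupted_lines(curve, scheme, threshold_mm=np.inf)
        assert masks["odd"].line_labels.min() == 1


class TestB0Perturbation:
    def test_zero_amplitude_gives_zero_field(self):
        assert not np.any(sample_b0_perturbation((8, 8), 0.0, seed=3))

    def test_seeded_determinism(self):
        a = sample_b0_perturbation((16, 16), 50.0, 3.0, seed=9)
        b = sample_b0_perturbation((16, 16), 50.0, 3.0, seed=9)
        assert np.array_equal(a, b)
        assert np.abs(a).max() == pytest.approx(50.0)

    def test_smoothness_increases_spatial_autocorrelation(self):
        def lag1(f):
            return np.corrcoef(f[:-1].ravel(), f[1:].ravel())[0, 1]

        rough = np.mean([lag1(sample_b0_perturbation((32, 32), 10, 1.0, s)) for s in range(100)])
        smooth = np.mean([lag1(sample_b0_perturbation((32, 32), 10, 4.0, s)) for s in range(100)])
        assert smooth > rough


class TestSimulateCorruptedKspace:
    def test_identity_curve_reproduces_static_kspace(self, tiny_phantom):
        ph = tiny_phantom
        scheme = ph.scheme()
        curve = _constant_curve(np.arange(0.0, scheme.scan_duration_s + 1, 1.0))
        vol, ref = simulate_corrupted_kspace(
            ph.clean_images, ph.csm, curve, scheme, ph.te_ms, b0_cfg=None
        )
        static = static_multicoil_kspace(ph.clean_images, ph.csm)
        assert np.array_equal(vol.data, static)
        assert ref["odd"].line_labels.min() == 1

    def test_only_flagged_lines_differ_from_static(self, tiny_phantom):
        ph = tiny_phantom
        scheme = ph.scheme()
        curve = synthetic_motion_curve(
            scheme.scan_duration_s, 1, amplitude_mm=5.0, seed=2,
            event_times_s=[(3.0, 12.0)],
        )
        vol, ref = simulate_corrupted_kspace(
            ph.clean_images, ph.csm, curve, scheme, ph.te_ms,
            b0_cfg=B0Config(amplitude_rad_s=80.0),
        )
        static = static_multicoil_kspace(ph.clean_images, ph.csm)
        from phimo.forward import slice_indices_for_package

        for pkg in ("odd", "even"):
            slices = slice_indices_for_package(ph.n_slices, pkg)
            for line in range(ph.pe_size):
                diff = np.max(np.abs(vol.data[:, :, slices, line] - static[:, :, slices, line]))
                if ref[pkg].line_labels[line]:
                    assert diff < 1e-10
                else:
                    assert diff > 0

    def test_reference_mask_matches_mark_corrupted_lines(self, tiny_phantom):
        ph = tiny_phantom
        scheme = ph.scheme()
        curve = synthetic_motion_curve(scheme.scan_duration_s, 2, amplitude_mm=4.0, seed=5)
        _, ref = simulate_corrupted_kspace(
            ph.clean_images, ph.csm, curve, scheme, ph.te_ms, b0_cfg=None
        )
        marked = mark_corrupted_lines(curve, scheme)
        for pkg in ("odd", "even"):
            assert np.array_equal(ref[pkg].line_labels, marked[pkg].line_labels)


class TestSyntheticCurve:
    def test_no_events_gives_identity_curve(self):
        curve = synthetic_motion_curve(60.0, 0, seed=0)
        assert all(s.is_identity() for s in curve.states)

    def test_events_fit_inside_scan_and_are_disjoint(self):
        curve = synthetic_motion_curve(200.0, 4, amplitude_mm=3.0, seed=11)
        moving = np.array([not s.is_identity() for s in curve.states])
        assert moving.any()
        assert curve.times_s[0] >= 0 and curve.times_s[-1] <= 200.0 + 0.25

    def test_peak_displacement_tracks_requested_amplitude(self):
        peaks = []
        for amp in (1.0, 3.0, 6.0):
            curve = synthetic_motion_curve(100.0, 1, amplitude_mm=amp, seed=7,
                                           event_times_s=[(10.0, 20.0)])
            peaks.append(max(average_displacement(s) for s in curve.states))
        assert peaks[0] < peaks[1] < peaks[2]
        assert peaks[2] == pytest.approx(6.0, rel=1e-2)

    def test_impossible_packing_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            synthetic_motion_curve(20.0, 5, event_duration_s_range=(9.0, 10.0), seed=0)


class TestReferenceFromTimings:
    def test_no_intervals_keep_all_lines(self):
        scheme = acquisition_times(16, 1000.0)
        masks = reference_mask_from_timings([], scheme)
        assert masks["odd"].line_labels.min() == 1

    def test_interval_covering_nine_lines_yields_nine_zeros(self):
        scheme = acquisition_times(32, 1000.0)
        masks = reference_mask_from_timings([(10.0, 19.0)], scheme)
        assert int((masks["odd"].line_labels == 0).sum()) == 9

    def test_whole_scan_interval_marks_everything(self):
        scheme = acquisition_times(8, 1000.0)
        masks = reference_mask_from_timings([(0.0, scheme.scan_duration_s)], scheme)
        assert masks["odd"].line_labels.max() == 0
        assert masks["even"].line_labels.max() == 0
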