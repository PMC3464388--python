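import numpy as np
import pytest

from mousequant.phantom import sample_subject
from mousequant.registration import (
    PyramidLevel,
    PyramidSchedule,
    RegistrationConfig,
    body_mask_from_ct,
    build_pyramid,
    ncc,
    optimize_asgd,
    register_affine,
    register_bspline,
    sample_points,
)
from mousequant.transforms import AffineTransform, resample
from mousequant.volumes import ImageVolume


def _fast_config(seed=0):
    """Reduced sampling/iteration budget for unit-scale problems."""
    sched = PyramidSchedule([PyramidLevel(4, 600), PyramidLevel(2, 400)])
    return RegistrationConfig(schedule=sched, n_samples=1200, seed=seed)


class TestPyramid:
    def test_factor_one_without_smoothing_is_identity(self, rng):
        v = ImageVolume(rng.normal(size=(16, 16, 16)))
        sched = PyramidSchedule([PyramidLevel(1, 10, smoothing=False)])
        (_, lv), = build_pyramid(v, sched)
        np.testing.assert_array_equal(lv.data, v.data)

    def test_factor_two_halves_shape_doubles_spacing(self, rng):
        v = ImageVolume(rng.normal(size=(64, 64, 64)), spacing=(0.4, 0.4, 0.4))
        sched = PyramidSchedule([PyramidLevel(2, 10)])
        (_, lv), = build_pyramid(v, sched)
        assert lv.shape == (32, 32, 32)
        assert lv.spacing == pytest.approx((0.8, 0.8, 0.8))
        assert lv.origin == pytest.approx(v.origin)

    def test_constant_volume_preserved(self):
        v = ImageVolume(np.full((64, 64, 64), 3.25))
        for _, lv in build_pyramid(v, PyramidSchedule.default()):
            np.testing.assert_allclose(lv.data, 3.25, atol=1e-9)

    def test_small_axes_skip_coarse_levels(self, rng):
        v = ImageVolume(rng.normal(size=(128, 16, 16)))
        levels = build_pyramid(v, PyramidSchedule.default())
        assert [lv.factor for lv, _ in levels] == [4, 2]

    def test_nondecreasing_factors_rejected(self):
        with pytest.raises(ValueError):
            PyramidSchedule([PyramidLevel(4, 10), PyramidLevel(4, 10)])


class TestNcc:
    def test_self_correlation(self, rng):
        x = rng.normal(size=500)
        assert ncc(x, x) == pytest.approx(1.0)

    def test_affine_intensity_invariance(self, rng):
        x = rng.normal(size=500)
        assert ncc(x, 3.7 * x + 11.0) == pytest.approx(1.0, abs=1e-12)
        assert ncc(2.0 * x - 5.0, x) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_pearson(self):
        f = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        m = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        # direct formula evaluation
        expect = (np.sum((f - 3.0) * (m - m.mean()))
                  / np.sqrt(np.sum((f - 3.0) ** 2) * np.sum((m - m.mean()) ** 2)))
        assert ncc(f, m) == pytest.approx(expect, abs=1e-12)

    def test_degenerate_samples_warn_zero(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert ncc(np.ones(10), np.arange(10.0)) == 0.0


class TestSamplePoints:
    def test_single_voxel_mask(self, rng):
        v = ImageVolume(np.zeros((8, 8, 8)), spacing=(1, 1, 1))
        mask = np.zeros((8, 8, 8), bool)
        mask[3, 4, 5] = True
        pts = sample_points(v, 200, rng, mask)
        assert np.all(np.abs(pts - [3, 4, 5]) <= 0.5 + 1e-12)

    def test_determinism(self):
        v = ImageVolume(np.zeros((8, 8, 8)))
        a = sample_points(v, 100, np.random.default_rng(7))
        b = sample_points(v, 100, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_half_domain_mask_containment(self, rng):
        v = ImageVolume(np.zeros((16, 16, 16)))
        mask = np.zeros((16, 16, 16), bool)
        mask[:8] = True
        pts = sample_points(v, 10000, rng, mask)
        assert np.all(pts[:, 0] <= 7.5 + 1e-12)

    def test_empty_mask_raises(self, rng):
        v = ImageVolume(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match="empty"):
            sample_points(v, 10, rng, np.zeros((4, 4, 4), bool))


class TestAsgd:
    def test_quadratic_convergence(self):
        h = np.diag([4.0, 1.0, 2.0])
        target = np.array([1.0, -2.0, 0.5])

        def objective(theta):
            d = theta - target
            return 0.5 * d @ h @ d, h @ d

        cfg = RegistrationConfig(seed=0)
        theta, trace = optimize_asgd(objective, np.zeros(3), 500, cfg, a_eff=1.0)
        assert np.max(np.abs(theta - target)) < 1e-3
        assert len(trace) == 500

    def test_zero_gradient_returns_init(self):
        def objective(theta):
            return 1.0, np.zeros_like(theta)

        cfg = RegistrationConfig(seed=0)
        theta, _ = optimize_asgd(objective, np.array([2.0, 3.0]), 100, cfg, a_eff=1.0)
        np.testing.assert_array_equal(theta, [2.0, 3.0])

    def test_nonadaptive_gain_strictly_decreasing(self):
        """With a constant gradient, the step lengths trace the gain sequence."""
        iterates = []

        def objective(theta):
            iterates.append(theta.copy())
            return 0.0, np.array([1.0])

        cfg = RegistrationConfig(seed=0, adaptive=False, tail_average_frac=1e-9)
        optimize_asgd(objective, np.zeros(1), 50, cfg, a_eff=1.0)
        steps = -np.diff(np.array(iterates).ravel())
        assert np.all(np.diff(steps) < 0)

    def test_nonfinite_objective_raises(self):
        def objective(theta):
            return float("nan"), np.ones_like(theta)

        with pytest.raises(Exception, match="non-finite"):
            optimize_asgd(objective, np.zeros(2), 10, RegistrationConfig(seed=0))


class TestAffineRegistration:
    def test_self_registration_near_identity(self, atlas08):
        res = register_affine(atlas08.ct, atlas08.ct, _fast_config())
        t = res.transform
        vox = atlas08.ct.spacing[0]
        assert np.max(np.abs(t.translation)) < 0.5 * vox
        assert np.max(np.abs(t.rotation)) < 0.01
        assert res.final_metric > 0.99

    def test_known_shift_recovery(self, atlas08):
        truth = AffineTransform(translation=(0.0, 0.0, 3.0))
        moving = resample(atlas08.ct, truth.inverted(), atlas08.ct, order=1)
        res = register_affine(atlas08.ct, moving, _fast_config(seed=3))
        vox = atlas08.ct.spacing[0]
        assert np.max(np.abs(np.subtract(res.transform.translation,
                                         truth.translation))) < 0.5 * vox
        assert res.final_metric > 0.99

    def test_known_scale_recovery(self, atlas08):
        lo, hi = atlas08.ct.extent()
        truth = AffineTransform(scale=(1.05, 1.05, 1.05), center=tuple(0.5 * (lo + hi)))
        moving = resample(atlas08.ct, truth.inverted(), atlas08.ct, order=1)
        res = register_affine(atlas08.ct, moving, _fast_config(seed=4))
        assert np.max(np.abs(np.subtract(res.transform.scale, truth.scale))) < 0.01

    def test_determinism(self, atlas08, spec08):
        subj = sample_subject(atlas08, spec08, 0.0, seed=21)
        r1 = register_affine(atlas08.ct, subj.ct, _fast_config(seed=5))
        r2 = register_affine(atlas08.ct, subj.ct, _fast_config(seed=5))
        np.testing.assert_array_equal(r1.transform.params, r2.transform.params)
        assert r1.final_metric == r2.final_metric


class TestBsplineRegistration:
    def test_self_registration_stays_near_zero(self, atlas08):
        res = register_bspline(atlas08.ct, atlas08.ct, None, _fast_config(),
                               grid_spacing_mm=8.0)
        coeff = res.transform.transforms[-1].coefficients
        assert np.max(np.abs(coeff)) < 0.5 * atlas08.ct.spacing[0]

    def test_recovers_known_bump(self, atlas08, spec08):
        """A 2 mm B-spline warp is recovered to within one voxel RMS in the body."""
        subj = sample_subject(atlas08, spec08, deform_magnitude=2.0, seed=13,
                              translation_mm=0.0, rotation_deg=0.0,
                              scale_range=(1.0, 1.0), shear_max=0.0)
        res = register_bspline(atlas08.ct, subj.ct, None, _fast_config(seed=6),
                               grid_spacing_mm=8.0)
        from mousequant.transforms import apply_point
        body_idx = np.argwhere(atlas08.labels.data != 0)[::23]
        pts = (np.asarray(atlas08.ct.origin)
               + body_idx * np.asarray(atlas08.ct.spacing))
        err = apply_point(res.transform, pts) - apply_point(subj.truth_transform, pts)
        rms = float(np.sqrt((err ** 2).sum(axis=1).mean()))
        assert rms < atlas08.ct.spacing[0]

    def test_masked_registration_runs_and_mask_respected(self, atlas08, rng):
        mask = body_mask_from_ct(atlas08.ct)
        assert mask.sum() > 0
        # the sampler contract: with a mask, all drawn points lie inside it
        pts = sample_points(atlas08.ct, 5000, rng, mask)
        idx = np.round((pts - np.asarray(atlas08.ct.origin))
                       / np.asarray(atlas08.ct.spacing)).astype(int)
        idx = np.clip(idx, 0, np.asarray(atlas08.ct.shape) - 1)
        assert mask[idx[:, 0], idx[:, 1], idx[:, 2]].all()
        res = register_bspline(atlas08.ct, atlas08.ct, None, _fast_config(seed=8),
                               mask=mask, grid_spacing_mm=8.0)
        assert res.final_metric > 0.99
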