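import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mousequant.transforms import (
    AffineTransform,
    BSplineTransform,
    CompositeTransform,
    TransformParseError,
    affine_matrix,
    apply_point,
    cubic_bspline_weight,
    displacement_at,
    invert_points,
    read_transform,
    resample,
    resample_labels,
    write_transform,
)
from mousequant.volumes import ImageVolume, LabelVolume


def _random_affine(rng, center=(5.0, -3.0, 2.0)):
    return AffineTransform(
        translation=tuple(rng.uniform(-5, 5, 3)),
        rotation=tuple(rng.uniform(-0.3, 0.3, 3)),
        scale=tuple(rng.uniform(0.8, 1.2, 3)),
        shear=tuple(rng.uniform(-0.1, 0.1, 3)),
        center=center,
    )


class TestAffine:
    def test_identity_matrix(self):
        m = affine_matrix(AffineTransform())
        np.testing.assert_allclose(m, np.eye(4), atol=1e-15)

    def test_pure_translation(self):
        t = AffineTransform(translation=(1, 2, 3))
        np.testing.assert_allclose(apply_point(t, (0, 0, 0)), (1, 2, 3))

    def test_matrix_inverse_is_identity(self, rng):
        for _ in range(50):
            m = _random_affine(rng).matrix()
            np.testing.assert_allclose(m @ np.linalg.inv(m), np.eye(4), atol=1e-10)

    def test_apply_point_matches_matrix_product(self, rng):
        """Point mapping agrees with homogeneous matrix multiplication."""
        for _ in range(1000):
            t = _random_affine(rng, center=tuple(rng.uniform(-10, 10, 3)))
            p = rng.uniform(-20, 20, 3)
            expected = (t.matrix() @ np.append(p, 1.0))[:3]
            np.testing.assert_allclose(apply_point(t, p), expected, atol=1e-12)

    def test_from_matrix_round_trip(self, rng):
        for _ in range(50):
            t = _random_affine(rng)
            back = AffineTransform.from_matrix(t.matrix(), center=t.center)
            np.testing.assert_allclose(back.params, t.params, atol=1e-9)

    def test_inverted_composes_to_identity(self, rng):
        t = _random_affine(rng)
        comp = CompositeTransform([t, t.inverted()])
        p = rng.uniform(-20, 20, (10, 3))
        np.testing.assert_allclose(apply_point(comp, p), p, atol=1e-9)

    def test_zero_scale_rejected(self):
        with pytest.raises(ValueError):
            AffineTransform(scale=(1.0, 0.0, 1.0))


class TestBsplineKernel:
    def test_closed_form_values(self):
        assert cubic_bspline_weight(0.0) == pytest.approx(2.0 / 3.0)
        assert cubic_bspline_weight(1.0) == pytest.approx(1.0 / 6.0)
        assert cubic_bspline_weight(-1.0) == pytest.approx(1.0 / 6.0)
        assert cubic_bspline_weight(2.0) == 0.0
        assert cubic_bspline_weight(3.7) == 0.0

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(min_value=-10.0, max_value=10.0))
    def test_partition_of_unity(self, u):
        base = np.floor(u)
        shifts = base + np.arange(-2, 3)
        assert abs(cubic_bspline_weight(u - shifts).sum() - 1.0) < 1e-12


def _brute_force_displacement(t: BSplineTransform, p):
    """Independent oracle: full summation over every lattice control point."""
    u = (np.asarray(p, dtype=float) - t.grid_origin) / t.grid_spacing
    out = np.zeros(3)
    nx, ny, nz, _ = t.coefficients.shape
    for l in range(nx):
        for m in range(ny):
            for n in range(nz):
                w = (cubic_bspline_weight(u[0] - l) * cubic_bspline_weight(u[1] - m)
                     * cubic_bspline_weight(u[2] - n))
                out += w * t.coefficients[l, m, n]
    return out


class TestDisplacement:
    def test_zero_coefficients(self, rng):
        t = BSplineTransform((0, 0, 0), (2, 2, 2), np.zeros((6, 6, 6, 3)))
        pts = rng.uniform(0, 8, (20, 3))
        np.testing.assert_array_equal(displacement_at(t, pts), 0.0)

    def test_constant_field_partition_of_unity(self, rng):
        coeff = np.zeros((8, 8, 8, 3))
        coeff[..., 0] = 1.0
        t = BSplineTransform((0, 0, 0), (2, 2, 2), coeff)
        pts = rng.uniform(4.0, 10.0, (30, 3))  # interior: full cubic support
        d = displacement_at(t, pts)
        np.testing.assert_allclose(d[:, 0], 1.0, atol=1e-12)
        np.testing.assert_allclose(d[:, 1:], 0.0, atol=1e-12)

    def test_matches_full_lattice_summation(self, rng):
        coeff = np.zeros((6, 5, 7, 3))
        coeff[3, 2, 4] = (1.5, -2.0, 0.7)
        coeff[1, 1, 1] = (0.2, 0.3, -0.1)
        t = BSplineTransform((-3, 1, 0), (2.5, 3.0, 2.0), coeff)
        pts = rng.uniform(-3, 10, (20, 3))
        got = displacement_at(t, pts)
        want = np.array([_brute_force_displacement(t, p) for p in pts])
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_identity_off_lattice(self):
        t = BSplineTransform((0, 0, 0), (1, 1, 1), np.ones((4, 4, 4, 3)))
        far = np.array([[100.0, 100.0, 100.0]])
        np.testing.assert_array_equal(displacement_at(t, far), 0.0)


class TestComposite:
    def test_composite_is_sequential(self, rng):
        a = _random_affine(rng)
        coeff = rng.normal(0, 0.5, (6, 6, 6, 3))
        b = BSplineTransform((-20, -20, -20), (8, 8, 8), coeff)
        comp = CompositeTransform([a, b])
        p = rng.uniform(-10, 10, (15, 3))
        mid = apply_point(a, p)
        manual = mid + displacement_at(b, mid)
        np.testing.assert_allclose(apply_point(comp, p), manual, atol=1e-12)

    def test_empty_composite_rejected(self):
        with pytest.raises(ValueError):
            CompositeTransform([])

    def test_numeric_inverse_round_trip(self, rng):
        a = _random_affine(rng)
        coeff = rng.normal(0, 0.4, (8, 8, 8, 3))
        b = BSplineTransform((-30, -30, -30), (10, 10, 10), coeff)
        comp = CompositeTransform([a, b])
        y = rng.uniform(-15, 15, (25, 3))
        x = invert_points(comp, y)
        np.testing.assert_allclose(apply_point(comp, x), y, atol=1e-6)


class TestResample:
    def _ramp(self):
        ii, jj, kk = np.meshgrid(np.arange(12), np.arange(10), np.arange(11),
                                 indexing="ij")
        return ImageVolume(2.0 * ii - 3.0 * jj + 0.5 * kk + 7.0, spacing=(1, 1, 1))

    @pytest.mark.parametrize("order", [0, 1, 3])
    def test_identity_resample(self, order, rng):
        v = ImageVolume(rng.normal(size=(10, 10, 10)))
        out = resample(v, AffineTransform(), v, order=order)
        np.testing.assert_allclose(out.data, v.data, atol=1e-9)

    def test_one_voxel_translation_order0(self, rng):
        v = ImageVolume(rng.normal(size=(8, 8, 8)), spacing=(0.5, 0.5, 0.5))
        t = AffineTransform(translation=(0.5, 0, 0))  # one voxel in x
        out = resample(v, t, v, order=0, cval=0.0)
        np.testing.assert_array_equal(out.data[:-1], v.data[1:])

    def test_cubic_reproduces_linear_ramp(self):
        """Prefiltered cubic interpolation is a true interpolator: exact on
        the samples under identity, and reproduces a linear ramp at fractional
        offsets away from the padded boundary (whose influence decays
        geometrically, ~0.27 per voxel)."""
        v = self._ramp()
        out_id = resample(v, AffineTransform(), v, order=3, cval=0.0)
        np.testing.assert_allclose(out_id.data, v.data, atol=1e-9)

        n = 24
        ii, jj, kk = np.meshgrid(*(np.arange(n),) * 3, indexing="ij")
        big = ImageVolume(2.0 * ii - 3.0 * jj + 0.5 * kk + 7.0)
        t = AffineTransform(translation=(0.37, -0.21, 0.5))
        out = resample(big, t, big, order=3, cval=0.0)
        expect = 2.0 * (ii + 0.37) - 3.0 * (jj - 0.21) + 0.5 * (kk + 0.5) + 7.0
        interior = (slice(8, -8),) * 3
        np.testing.assert_allclose(out.data[interior], expect[interior], atol=1e-2)

    def test_invalid_order_rejected(self, rng):
        v = ImageVolume(rng.normal(size=(4, 4, 4)))
        with pytest.raises(ValueError, match="order"):
            resample(v, AffineTransform(), v, order=2)

    def test_ct_pad_outside_domain(self):
        v = ImageVolume(np.zeros((6, 6, 6)), modality="CT")
        t = AffineTransform(translation=(100.0, 0, 0))
        out = resample(v, t, v, order=1)
        assert np.all(out.data == -1000.0)


class TestResampleLabels:
    def _cube(self):
        data = np.zeros((10, 10, 10), dtype=np.int32)
        data[3:6, 3:6, 3:6] = 2
        return LabelVolume(data, region_table={2: "cube"})

    def test_identity(self):
        lab = self._cube()
        out = resample_labels(lab, AffineTransform(), lab)
        np.testing.assert_array_equal(out.data, lab.data)
        assert out.region_table == lab.region_table

    def test_alphabet_preserved(self, rng):
        lab = self._cube()
        t = AffineTransform(translation=tuple(rng.uniform(-2, 2, 3)),
                            rotation=(0.1, 0.0, 0.05))
        out = resample_labels(lab, t, lab)
        assert set(np.unique(out.data)) <= {0, 2}

    def test_one_voxel_shift_preserves_volume(self):
        lab = self._cube()
        out = resample_labels(lab, AffineTransform(translation=(1.0, 0, 0)), lab)
        np.testing.assert_array_equal(out.data[3:6][:, 3:6, 3:6] * 0, 0)
        assert (out.data == 2).sum() == 27
        assert np.all(out.data[2:5, 3:6, 3:6] == 2)


class TestTransformIO:
    def test_affine_round_trip(self, tmp_path, rng):
        t = _random_affine(rng)
        path = str(tmp_path / "t.txt")
        write_transform(t, path)
        back = read_transform(path)
        np.testing.assert_allclose(back.params, t.params, rtol=1e-12)
        np.testing.assert_allclose(back.center, t.center, rtol=1e-12)

    def test_composite_order_preserved(self, tmp_path, rng):
        a1, a2 = _random_affine(rng), _random_affine(rng)
        b = BSplineTransform((0, 0, 0), (5, 5, 5), rng.normal(0, 1, (5, 5, 5, 3)))
        path = str(tmp_path / "comp.txt")
        write_transform(CompositeTransform([a1, b, a2]), path)
        back = read_transform(path)
        assert [type(x).__name__ for x in back.transforms] == \
            ["AffineTransform", "BSplineTransform", "AffineTransform"]
        np.testing.assert_allclose(back.transforms[0].params, a1.params, rtol=1e-12)
        np.testing.assert_allclose(back.transforms[1].coefficients, b.coefficients)

    def test_resample_with_read_back_transform(self, tmp_path, rng):
        v = ImageVolume(rng.normal(size=(12, 12, 12)))
        b = BSplineTransform((-5, -5, -5), (6, 6, 6),
                             rng.normal(0, 1.0, (6, 6, 6, 3)))
        t = CompositeTransform([_random_affine(rng), b])
        path = str(tmp_path / "t.txt")
        write_transform(t, path)
        out1 = resample(v, t, v, order=1, cval=0.0)
        out2 = resample(v, read_transform(path), v, order=1, cval=0.0)
        np.testing.assert_allclose(out1.data, out2.data, atol=1e-9)

    def test_malformed_file_raises(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("translation = 1 2 3\n")  # key before any section
        with pytest.raises(TransformParseError):
            read_transform(str(p))
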