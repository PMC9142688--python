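"""ECC objective, transforms, warping and maximization."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from patchreg.ecc import (
    AffineMatrix,
    EccConfig,
    EuclideanMatrix,
    ecc_loss,
    ecc_maximize,
    ecc_maximize_pyramid,
    ecc_score,
    euclidean_about,
    transform_from_json,
    transform_to_json,
    warp_image,
)
from patchreg.rigid import apply_shift


@pytest.fixture(scope="module")
def smooth_template():
    rng = np.random.default_rng(7)
    return gaussian_filter(rng.normal(size=(128, 128)), 3.0)


class TestTransforms:
    def test_affine_last_row_enforced(self):
        with pytest.raises(ValueError, match="last row"):
            AffineMatrix(np.ones((3, 3)))

    def test_euclidean_matrix_structure(self):
        e = EuclideanMatrix(0.3, 2.0, -1.0)
        m = e.matrix
        np.testing.assert_allclose(m[0, 0], np.cos(0.3))
        np.testing.assert_allclose(m[1, 0], np.sin(0.3))
        assert (m[2] == [0, 0, 1]).all()

    def test_theta_wraps_into_half_open_interval(self):
        assert EuclideanMatrix(3 * np.pi, 0, 0).theta == pytest.approx(np.pi)

    def test_inverse_composes_to_identity(self):
        e = euclidean_about(0.2, (31.5, 31.5), (3.0, -4.0))
        np.testing.assert_allclose(e.matrix @ e.inverse().matrix, np.eye(3),
                                   atol=1e-12)
        a = AffineMatrix.from_params([1.1, 0.05, 3, -0.02, 0.95, -2])
        np.testing.assert_allclose(a.compose(a.inverse()).matrix, np.eye(3),
                                   atol=1e-12)

    def test_json_round_trip(self):
        for t in (AffineMatrix.from_params([1.1, 0.05, 3, -0.02, 0.95, -2]),
                  EuclideanMatrix(0.2, 1.5, -2.5)):
            back = transform_from_json(transform_to_json(t))
            np.testing.assert_allclose(back.matrix, t.matrix, atol=1e-15)


class TestScore:
    def test_self_score_is_one(self, smooth_template):
        assert ecc_score(smooth_template, smooth_template) == pytest.approx(1.0)

    def test_gain_and_bias_invariance(self, smooth_template):
        t = smooth_template
        assert ecc_score(t, 3.0 * t + 7.0) == pytest.approx(1.0, abs=1e-12)

    def test_negated_image_scores_minus_one(self, smooth_template):
        t = smooth_template
        assert ecc_score(t, -t) == pytest.approx(-1.0, abs=1e-12)

    def test_loss_identity(self, smooth_template):
        """L = 2 - 2*rho exactly, for random image pairs."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            a = rng.normal(size=(32, 32))
            b = rng.normal(size=(32, 32))
            assert ecc_loss(a, b) == pytest.approx(2 - 2 * ecc_score(a, b),
                                                   abs=1e-12)

    def test_zero_variance_returns_zero_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            assert ecc_score(np.ones((8, 8)), np.random.default_rng(0).normal(size=(8, 8))) == 0.0


class TestWarpImage:
    def test_identity_preserves_image_and_support(self, smooth_template):
        out, sup = warp_image(smooth_template, AffineMatrix.identity())
        np.testing.assert_allclose(out, smooth_template, atol=1e-12)
        assert sup.all()

    def test_translation_matches_apply_shift(self, smooth_template):
        t = AffineMatrix.translation(3.0, -2.0)
        out, sup = warp_image(smooth_template, t)
        shifted = apply_shift(smooth_template, 3.0, -2.0)
        np.testing.assert_allclose(out[sup], shifted[sup], atol=1e-10)

    def test_scale_round_trip_within_bilinear_error(self, smooth_template):
        double = AffineMatrix.from_params([0.5, 0, 0, 0, 0.5, 0])  # samples at half coords
        halve = AffineMatrix.from_params([2.0, 0, 0, 0, 2.0, 0])
        up, _ = warp_image(smooth_template, double)
        back, sup = warp_image(up, halve)
        interior = np.zeros_like(sup)
        interior[8:-8, 8:-8] = True
        rng_range = smooth_template.max() - smooth_template.min()
        err = np.abs(back - smooth_template)[interior & sup].max()
        assert err < 0.02 * rng_range

    def test_singular_transform_raises(self, smooth_template):
        with pytest.raises(ValueError, match="singular"):
            warp_image(smooth_template, AffineMatrix.from_params([0, 0, 0, 0, 0, 0]))


class TestMaximize:
    def test_identity_problem_converges_immediately(self, smooth_template):
        res = ecc_maximize(smooth_template, smooth_template, "affine")
        assert res.rho == pytest.approx(1.0, abs=1e-9)
        assert res.iterations <= 2
        np.testing.assert_allclose(res.transform.matrix, np.eye(3), atol=1e-6)

    def test_small_affine_recovered(self, smooth_template):
        a_true = AffineMatrix(np.array([
            [np.cos(0.035), -np.sin(0.035), 1.5],
            [np.sin(0.035), np.cos(0.035) + 0.02, -1.0],
            [0, 0, 1],
        ]))
        target, _ = warp_image(smooth_template, a_true.inverse())
        res = ecc_maximize(smooth_template, target, "affine")
        assert res.converged
        h, w = smooth_template.shape
        corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], float)
        err = np.linalg.norm(
            res.transform.map_points(corners) - a_true.map_points(corners), axis=1
        )
        assert err.mean() <= 0.3

    def test_gain_offset_leaves_parameter_trace_unchanged(self, smooth_template):
        a_true = AffineMatrix.from_params([1.0, 0.01, 1.0, -0.01, 1.0, 0.5])
        target, _ = warp_image(smooth_template, a_true.inverse())
        r1 = ecc_maximize(smooth_template, target, "affine")
        r2 = ecc_maximize(smooth_template, 5.0 * target + 40.0, "affine")
        np.testing.assert_allclose(r1.transform.params, r2.transform.params,
                                   atol=1e-6)

    def test_euclidean_matches_constrained_affine(self, smooth_template):
        e_true = euclidean_about(0.02, (63.5, 63.5), (1.5, -2.0))
        target, _ = warp_image(smooth_template, e_true.inverse())
        res_e = ecc_maximize(smooth_template, target, "euclidean")
        res_a = ecc_maximize(smooth_template, target, "affine")
        corners = np.array([[0, 0], [127, 0], [0, 127], [127, 127]], float)
        gap = np.linalg.norm(
            res_e.transform.map_points(corners) - res_a.transform.map_points(corners),
            axis=1,
        )
        assert gap.max() < 0.2

    def test_rho_trace_monotone_for_accepted_steps(self, smooth_template):
        a_true = AffineMatrix.from_params([1.02, 0.01, 2.0, 0.0, 0.98, -1.0])
        target, _ = warp_image(smooth_template, a_true.inverse())
        res = ecc_maximize(smooth_template, target, "affine")
        assert all(b >= a for a, b in zip(res.rho_trace, res.rho_trace[1:]))

    def test_flat_image_fails_gracefully(self):
        rng = np.random.default_rng(0)
        flat = rng.normal(0, 1e-3, size=(32, 32))
        res = ecc_maximize(np.ones((32, 32)) + flat, np.ones((32, 32)), "affine")
        assert not res.converged


class TestPyramid:
    def test_zero_displacement_gives_identity(self, cell_scene):
        res = ecc_maximize_pyramid(cell_scene, cell_scene, "euclidean")
        assert res.rho == pytest.approx(1.0, abs=1e-6)
        assert abs(res.transform.theta) < 1e-4
        assert abs(res.transform.e1) < 0.05 and abs(res.transform.e2) < 0.05

    def test_large_displacement_recovered(self):
        rng = np.random.default_rng(9)
        template = gaussian_filter(rng.normal(size=(256, 256)), 3.0)
        e_f = euclidean_about(np.deg2rad(10), (127.5, 127.5), (25.0, -18.0))
        target, _ = warp_image(template, e_f)
        res = ecc_maximize_pyramid(template, target, "euclidean")
        e_exp = e_f.inverse()
        assert abs(np.rad2deg(res.transform.theta - e_exp.theta)) <= 0.2
        assert abs(res.transform.e1 - e_exp.e1) <= 0.5
        assert abs(res.transform.e2 - e_exp.e2) <= 0.5

    def test_pyramid_beats_single_level_on_large_displacement(self):
        rng = np.random.default_rng(10)
        template = gaussian_filter(rng.normal(size=(256, 256)), 3.0)
        e_f = euclidean_about(np.deg2rad(10), (127.5, 127.5), (25.0, -18.0))
        target, _ = warp_image(template, e_f)
        res_pyr = ecc_maximize_pyramid(template, target, "euclidean")
        res_flat = ecc_maximize(template, target, "euclidean")
        assert res_pyr.rho >= res_flat.rho - 1e-6
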