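"""Patch grid, per-block warp estimation, warping and stitching."""

import numpy as np
import pytest

from patchreg.ecc import AffineMatrix, warp_image
from patchreg.io_stacks import FrameStack
from patchreg.patchwork import (
    build_warp_template,
    estimate_block_warps,
    load_warpfield,
    make_patch_grid,
    save_warpfield,
    warp_correct_session,
    warp_frame,
)
from patchreg.synthetic import (
    expected_block_affine,
    patch_corners,
)


class TestPatchGrid:
    def test_printed_parameters_for_512_m8(self):
        g = make_patch_grid(512, 512, 8)
        assert g.overlap_y == 19 and g.overlap_x == 19  # round(0.3 * 512 / 8)
        y0, y1, x0, x1 = g.bounds(3, 3)  # interior patch
        assert y1 - y0 == 64 + 2 * 19
        assert x1 - x0 == 64 + 2 * 19

    def test_single_patch_is_full_fov(self):
        g = make_patch_grid(128, 96, 1)
        assert g.bounds(0, 0) == (0, 128, 0, 96)
        assert g.overlap_y == 0

    @pytest.mark.parametrize("h, w, m", [(512, 512, 8), (256, 256, 4), (120, 200, 5)])
    def test_patches_cover_fov(self, h, w, m):
        g = make_patch_grid(h, w, m)
        covered = np.zeros((h, w), dtype=int)
        for _, _, (y0, y1, x0, x1) in g.patches():
            covered[y0:y1, x0:x1] += 1
        assert (covered >= 1).all()

    def test_m_too_large_raises(self):
        with pytest.raises(ValueError, match="too large"):
            make_patch_grid(64, 64, 16)


class TestWarpTemplate:
    def test_constant_stack_gives_constant_template(self):
        stack = FrameStack(np.full((100, 64, 64), 9.0), origin="rigid")
        template = build_warp_template(stack, 5500)
        np.testing.assert_allclose(template, 9.0, atol=1e-9)

    def test_template_window_is_clipped_middle(self, cell_scene):
        # a stack whose middle frames are the scene and outer frames are noise:
        # with template_len < T only the middle window contributes
        rng = np.random.default_rng(0)
        frames = np.tile(cell_scene, (9, 1, 1))
        frames[:3] += rng.normal(0, 50, size=(3, 128, 128))
        frames[-3:] += rng.normal(0, 50, size=(3, 128, 128))
        stack = FrameStack(frames, origin="rigid")
        t_mid = build_warp_template(stack, 3)
        t_all = build_warp_template(stack, 5500)
        from patchreg.normalization import local_normalize

        np.testing.assert_allclose(t_mid, local_normalize(cell_scene), atol=1e-9)
        assert np.abs(t_all - t_mid).max() > 0.1


class TestWarpFrame:
    def test_identity_transforms_reproduce_frame(self, cell_scene):
        g = make_patch_grid(128, 128, 4)
        ident = [[AffineMatrix.identity() for _ in range(4)] for _ in range(4)]
        out = warp_frame(cell_scene, ident, g)
        np.testing.assert_allclose(out, cell_scene, atol=1e-9)

    def test_single_patch_translation_equals_global_warp(self, cell_scene):
        g = make_patch_grid(128, 128, 1)
        t = AffineMatrix.translation(2.5, -1.5)
        out = warp_frame(cell_scene, [[t]], g)
        ref, sup = warp_image(cell_scene, t)
        np.testing.assert_allclose(out[sup], ref[sup], atol=1e-9)

    def test_uniform_global_transform_stitches_like_single_warp(self, cell_scene):
        """When every patch carries the same global transform (expressed in
        its local frame), overlap averaging of identical contributors equals
        the whole-frame warp."""
        g = make_patch_grid(128, 128, 4)
        a_global = AffineMatrix.from_params([1.01, 0.005, 0.8, -0.005, 0.99, -0.6])
        locals_ = []
        for i in range(4):
            row = []
            for j in range(4):
                y0, _, x0, _ = g.bounds(i, j)
                to_global = AffineMatrix.translation(-x0, -y0)
                to_local = AffineMatrix.translation(x0, y0)
                row.append(to_local.compose(a_global).compose(to_global))
            locals_.append(row)
        out = warp_frame(cell_scene, locals_, g)
        ref, sup = warp_image(cell_scene, a_global)
        # compare away from patch-support edges, where local out-of-bounds
        # fallbacks differ from the global warp by construction
        core = np.zeros_like(sup)
        core[4:-4, 4:-4] = sup[4:-4, 4:-4]
        np.testing.assert_allclose(out[core], ref[core], atol=1e-9)

    def test_ground_truth_inverse_restores_distorted_frame(
        self, small_distorted_session, cell_scene
    ):
        """Warping a fully distorted frame with the inverse ground-truth
        field recovers the undistorted frame in the interior."""
        from patchreg.patchwork import PatchSampler

        s = small_distorted_session
        gt, grid = s["gt"], s["grid"]
        scene = cell_scene
        forward = gt.patch_transforms_at_frame(gt.T - 1)
        distorted = PatchSampler(forward, grid).apply(scene)
        inverse = [[forward[i][j].inverse() for j in range(4)] for i in range(4)]
        restored = PatchSampler(inverse, grid).apply(distorted)
        interior = np.s_[12:-12, 12:-12]
        rng_range = scene.max() - scene.min()
        rmse = np.sqrt(((restored - scene)[interior] ** 2).mean())
        assert rmse < 0.02 * rng_range


class TestEstimation:
    def test_undistorted_session_yields_near_identity(self):
        """With nothing to correct, every recovered patch affine stays at
        identity (transient activity alone must not masquerade as warp)."""
        from patchreg.synthetic import NoiseSpec, generate_movie

        stack, _ = generate_movie(T=100, H=128, W=128, n_cells=60,
                                  jitter_sigma_px=0.0,
                                  noise_spec=NoiseSpec(0.5, False), seed=3,
                                  event_rate_per_frame=0.0)
        rigid = stack.with_frames(stack.frames, origin="rigid")
        grid = make_patch_grid(128, 128, 4)
        template = build_warp_template(rigid)
        wf = estimate_block_warps(rigid, template, grid, block_size=50)
        for b in range(wf.n_blocks):
            for i, j, bounds in grid.patches():
                c = patch_corners(bounds)
                disp = np.linalg.norm(
                    wf.transforms[b][i][j].map_points(c) - c, axis=1)
                assert disp.max() <= 0.2

    def test_structureless_patch_falls_back_to_identity(self, cell_scene):
        """A patch with no landmarks (flat noise, independent between the
        template and the target block) cannot anchor a fit and keeps
        identity with a failed-convergence record."""
        scene = cell_scene.copy()
        # blank the first patch plus the normalization-kernel reach around
        # it, so no structure leaks into the patch via the local background
        scene[:80, :80] = scene.mean()
        rng = np.random.default_rng(4)
        frames = scene[None] + rng.normal(0, 0.5, size=(40, 128, 128))
        stack = FrameStack(frames, origin="rigid")
        template_stack = FrameStack(
            scene[None] + rng.normal(0, 0.5, size=(40, 128, 128)), origin="rigid")
        grid = make_patch_grid(128, 128, 4)
        template = build_warp_template(template_stack)
        wf = estimate_block_warps(stack, template, grid, block_size=20)
        res = wf.results[0][0][0]
        assert not res.converged
        np.testing.assert_array_equal(wf.transforms[0][0][0].matrix, np.eye(3))
        # patches with landmarks still converge
        assert wf.results[0][3][3].converged

    def test_known_distortion_recovered(self, small_distorted_session):
        s = small_distorted_session
        gt, wf, grid = s["gt"], s["warpfield"], s["grid"]
        est = np.array([[e.dx, e.dy] for e in s["estimates"]])
        resid = est - np.array(gt.jitter)
        errs = []
        for b, brange in enumerate(wf.block_frame_ranges):
            for i, j, bounds in grid.patches():
                exp = expected_block_affine(gt, brange, s["template_range"],
                                            i, j, resid)
                got = wf.transforms[b][i][j]
                c = patch_corners(bounds)
                errs.append(np.linalg.norm(
                    got.map_points(c) - exp.map_points(c), axis=1).mean())
        assert np.median(errs) <= 0.5


class TestSessionWarp:
    def test_identity_warpfield_preserves_frames(self, small_distorted_session):
        from patchreg.patchwork import WarpField

        s = small_distorted_session
        rigid, grid = s["rigid"], s["grid"]
        wf = s["warpfield"]
        ident = WarpField(
            grid=grid, block_frame_ranges=wf.block_frame_ranges,
            transforms=[[[AffineMatrix.identity() for _ in range(4)]
                         for _ in range(4)] for _ in wf.block_frame_ranges],
        )
        out = warp_correct_session(rigid, ident)
        np.testing.assert_allclose(out.frames, rigid.frames, atol=1e-9)
        assert out.origin == "warped"
        assert out.shape == rigid.shape

    def test_warp_improves_metrics(self, small_distorted_session):
        from patchreg.metrics import mmd, self_mcm

        s = small_distorted_session
        assert mmd(s["rigid"], s["warped"]) < 0
        assert self_mcm(s["warped"]) > self_mcm(s["rigid"])


def test_warpfield_h5_round_trip(tmp_path, small_distorted_session):
    wf = small_distorted_session["warpfield"]
    path = save_warpfield(wf, tmp_path / "wf.h5")
    back = load_warpfield(path)
    assert back.grid.M == wf.grid.M
    assert back.block_frame_ranges == wf.block_frame_ranges
    for b in range(wf.n_blocks):
        for i in range(4):
            for j in range(4):
                np.testing.assert_array_equal(
                    back.transforms[b][i][j].matrix, wf.transforms[b][i][j].matrix)
                assert back.results[b][i][j].rho == pytest.approx(
                    wf.results[b][i][j].rho)
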