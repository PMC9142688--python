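"""Rigid motion correction: schedule, hill climbing, shift application."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from patchreg.metrics import self_mcm
from patchreg.rigid import (
    RigidConfig,
    apply_shift,
    build_schedule,
    hill_climb_shift,
    rigid_correct_session,
    write_shift_csv,
)


def exhaustive_best_shift(template, frame, max_shift=10):
    """Brute-force oracle: the integer content shift maximizing rank
    correlation, with the implementation's tie-break."""
    from patchreg.normalization import rank_transform
    from patchreg.rigid import _shift_corr, _tie_key

    t = rank_transform(template)
    f = rank_transform(frame)
    best = None
    for sy in range(-max_shift, max_shift + 1):
        for sx in range(-max_shift, max_shift + 1):
            c = _shift_corr(t, f, sx, sy, 0.25)
            if np.isfinite(c):
                key = _tie_key(c, sx, sy)
                if best is None or key < best[0]:
                    best = (key, sx, sy)
    return -best[1], -best[2]  # correction shift -> content shift


class TestSchedule:
    def test_five_equal_blocks_and_centered_template(self):
        s = build_schedule(12500)
        assert s.block_bounds == [(i * 2500, (i + 1) * 2500) for i in range(5)]
        assert s.t1_window == (5000, 7500)

    def test_short_session_clips_window(self):
        s = build_schedule(100)
        assert s.t1_window == (0, 100)
        assert s.block_bounds == [(i * 20, (i + 1) * 20) for i in range(5)]

    def test_remainder_goes_to_last_block(self):
        s = build_schedule(12503)
        assert s.block_bounds[-1] == (10000, 12503)

    @pytest.mark.parametrize("n", [10, 97, 2000, 12503])
    def test_every_frame_targeted_exactly_once(self, n):
        s = build_schedule(n)
        targeted = np.zeros(n, dtype=int)
        for _, _, (a, b) in s.template_plan:
            targeted[a:b] += 1
        assert (targeted == 1).all()

    def test_bidirectional_order_middle_first(self):
        s = build_schedule(1000)
        order = [tgt for _, _, tgt in s.template_plan]
        blocks = s.block_bounds
        assert order == [blocks[2], blocks[1], blocks[3], blocks[0], blocks[4]]


class TestHillClimb:
    def test_identical_images_give_zero_shift(self, smooth_image):
        est = hill_climb_shift(smooth_image, smooth_image)
        assert (est.dx, est.dy) == (0.0, 0.0)
        assert est.corr == pytest.approx(1.0)

    @pytest.mark.parametrize("shift", [(3, -2), (-7, 5), (8, 8), (0, -6)])
    def test_integer_roll_recovered_exactly(self, smooth_image, shift):
        dx, dy = shift
        frame = np.roll(smooth_image, (dy, dx), axis=(0, 1))
        est = hill_climb_shift(frame, smooth_image, config=RigidConfig(subpixel=False))
        assert (est.dx, est.dy) == (dx, dy)
        oracle = exhaustive_best_shift(smooth_image, frame)
        assert (est.dx, est.dy) == oracle

    def test_subpixel_against_dense_search(self, smooth_image):
        frame = apply_shift(smooth_image, 0.5, 0.0)
        est = hill_climb_shift(frame, smooth_image)
        assert abs(est.dx - 0.5) <= 0.25
        assert abs(est.dy) <= 0.25

    def test_invariant_to_monotone_intensity_remapping(self, smooth_image):
        frame = np.roll(smooth_image, (2, -3), axis=(0, 1))
        a = hill_climb_shift(frame, smooth_image)
        b = hill_climb_shift(np.exp(frame), smooth_image)
        assert (a.dx, a.dy) == (b.dx, b.dy)

    def test_shape_mismatch_raises(self, smooth_image):
        with pytest.raises(ValueError):
            hill_climb_shift(smooth_image[:32], smooth_image)


class TestApplyShift:
    def test_zero_shift_is_bit_exact(self, smooth_image):
        np.testing.assert_array_equal(apply_shift(smooth_image, 0.0, 0.0), smooth_image)

    def test_integer_shift_equals_slice_with_edge_fill(self, smooth_image):
        out = apply_shift(smooth_image, 2.0, 0.0)
        np.testing.assert_allclose(out[:, 2:], smooth_image[:, :-2], atol=1e-12)
        # edge replication on the vacated columns
        np.testing.assert_allclose(out[:, 0], smooth_image[:, 0], atol=1e-12)

    def test_round_trip_error_is_small_on_interior(self):
        img = gaussian_filter(np.random.default_rng(8).normal(size=(64, 64)), 4.0)
        rng_range = img.max() - img.min()
        back = apply_shift(apply_shift(img, 0.3, -0.7), -0.3, 0.7)
        err = np.abs(back - img)[8:-8, 8:-8].max()
        assert err < 0.01 * rng_range

    def test_mean_fill_policy(self):
        img = np.ones((16, 16))
        img[8, 8] = 100.0
        out = apply_shift(img, 4.0, 0.0, fill="mean")
        assert out[0, 0] == pytest.approx(img.mean())


class TestSessionCorrection:
    def test_jitter_free_session_needs_no_correction(self):
        from patchreg.synthetic import NoiseSpec, generate_movie

        stack, _ = generate_movie(T=60, H=64, W=64, n_cells=25, jitter_sigma_px=0.0,
                                  noise_spec=NoiseSpec(1.0, False), seed=2)
        _, estimates = rigid_correct_session(stack)
        shifts = np.array([[e.dx, e.dy] for e in estimates])
        assert np.abs(shifts).max() <= 0.25

    def test_random_walk_shifts_recovered(self, jitter_only_movie):
        """RMS recovery error of the known jitter, after removing the global
        offset (template registration fixes positions only relative to the
        template's own mean position)."""
        stack, gt = jitter_only_movie
        rigid, estimates = rigid_correct_session(stack)
        est = np.array([[e.dx, e.dy] for e in estimates])
        resid = est - np.array(gt.jitter)
        resid -= resid.mean(axis=0)
        assert np.sqrt((resid**2).mean()) <= 0.3
        assert rigid.origin == "rigid"
        assert rigid.n_frames == stack.n_frames

    def test_self_mcm_improves_after_correction(self, jitter_only_movie):
        stack, _ = jitter_only_movie
        rigid, _ = rigid_correct_session(stack)
        assert self_mcm(rigid) > self_mcm(stack)

    def test_results_independent_of_worker_count(self, jitter_only_movie):
        stack, _ = jitter_only_movie
        sub = stack.with_frames(stack.frames[:50], origin="raw")
        r1, e1 = rigid_correct_session(sub, config=RigidConfig(n_jobs=1))
        r2, e2 = rigid_correct_session(sub, config=RigidConfig(n_jobs=2))
        np.testing.assert_array_equal(r1.frames, r2.frames)
        assert [(e.dx, e.dy) for e in e1] == [(e.dx, e.dy) for e in e2]

    def test_shift_csv(self, tmp_path, jitter_only_movie):
        stack, _ = jitter_only_movie
        sub = stack.with_frames(stack.frames[:20], origin="raw")
        _, est = rigid_correct_session(sub)
        path = write_shift_csv(est, tmp_path / "shifts.csv")
        lines = path.read_text().splitlines()
        assert lines[0] == "frame_index,dx,dy,corr,flagged"
        assert len(lines) == 21
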