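"""Shared fixtures: small seeded synthetic datasets, reused across modules."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from patchreg.synthetic import DistortionSpec, NoiseSpec, generate_movie
from patchreg.synthetic import _render_scene


@pytest.fixture(scope="session")
def cell_scene():
    """A static 128 x 128 scene of Gaussian-blob somata (no noise)."""
    rng = np.random.default_rng(42)
    bg, xy, radii, base, fps = _render_scene(rng, 128, 128, 60)
    return np.full((128, 128), bg) + np.tensordot(base, np.stack(fps), axes=1)


@pytest.fixture(scope="session")
def smooth_image():
    """Smooth random 64 x 64 test image for shift-estimation tests."""
    rng = np.random.default_rng(0)
    return gaussian_filter(rng.normal(size=(64, 64)), 2.0)


@pytest.fixture(scope="session")
def small_distorted_session():
    """A small session (400 frames, 128 x 128, M=4) with known jitter and
    slow distortion, plus its rigid/warp-corrected versions.

    Session-scoped because the pipeline run dominates test runtime; tests
    only read from it.
    """
    from patchreg.io_stacks import centered_window
    from patchreg.patchwork import (
        build_warp_template,
        estimate_block_warps,
        make_patch_grid,
        warp_correct_session,
    )
    from patchreg.rigid import rigid_correct_session

    spec = DistortionSpec(M=4)
    stack, gt = generate_movie(
        T=400, H=128, W=128, n_cells=60, jitter_sigma_px=1.0,
        distortion_spec=spec, seed=1,
    )
    rigid, estimates = rigid_correct_session(stack)
    grid = make_patch_grid(128, 128, 4)
    template = build_warp_template(rigid)
    wf = estimate_block_warps(rigid, template, grid, block_size=100)
    warped = warp_correct_session(rigid, wf)
    return {
        "raw": stack,
        "gt": gt,
        "rigid": rigid,
        "estimates": estimates,
        "grid": grid,
        "warpfield": wf,
        "warped": warped,
        "template_range": centered_window(400, 5500),
    }


@pytest.fixture(scope="session")
def jitter_only_movie():
    """Jitter-only movie (no slow distortion) with known random-walk shifts."""
    stack, gt = generate_movie(
        T=300, H=128, W=128, n_cells=60, jitter_sigma_px=1.0,
        distortion_spec=None, noise_spec=NoiseSpec(gaussian_sigma=2.0), seed=5,
    )
    return stack, gt
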