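"""Seeded generator of ground-truth movies and session pairs.

Every pipeline stage is testable without real data: the generator emulates
the structure the registration algorithm assumes —

* a static scene of blob-like somata (or curvilinear axon segments) on a dim
  background, each with a baseline brightness plus calcium transients
  (Poisson-timed events with instantaneous rise and exponential decay,
  tau ~ 15 frames, approximating slow indicator kinetics);
* fast, spatially uniform translational jitter: a bounded random walk,
  reflected at +/- 8 px;
* slow, spatially non-uniform distortion: per-patch ground-truth affines
  ramped linearly over the session and rendered through the *same*
  patchwork warp-and-stitch operator the correction uses, so inversion
  tests are self-consistent;
* additive Gaussian read noise plus Poisson shot noise;
* for across-session tests: a Euclidean displacement (rotation +
  translation) plus barrel distortion ``r' = r (1 + k r^2)`` about the FOV
  center between sessions, with a fraction of cells silenced in one session.

All randomness flows from a single seeded generator; the draw order is
scene geometry, transient events, jitter walk, then per-frame noise, so a
seed fully determines the movie.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .ecc import AffineMatrix, EuclideanMatrix, euclidean_about
from .io_stacks import FrameStack, SummaryImage, summary_images
from .patchwork import PatchGrid, PatchSampler, make_patch_grid
from .rigid import apply_shift

DEFAULT_TAU_FRAMES = 15.0
JITTER_BOUND_PX = 8.0


@dataclass
class DistortionSpec:
    """Bounds for the per-patch ground-truth affine ramp.

    Each patch gets an end-of-session affine composed of a rotation and
    shear/scale about the patch center plus a translation, each drawn
    uniformly within the stated bound; the affine is ramped linearly from
    identity at frame 0 to the drawn transform at the last frame.  With
    ``zero_mean_translation`` the net (across-patch mean) translation is
    removed so the slow distortion carries no global drift component.
    """

    M: int = 8
    max_rotation_deg: float = 3.0
    max_shear: float = 0.03
    max_translation_px: float = 3.0
    zero_mean_translation: bool = True


@dataclass
class NoiseSpec:
    """Additive Gaussian sigma (intensity units) and Poisson shot noise.

    ``photon_scale`` converts intensity units to expected photon counts for
    the Poisson draw (higher = less shot noise).
    """

    gaussian_sigma: float = 3.0
    shot_noise: bool = True
    photon_scale: float = 0.5


@dataclass
class GroundTruth:
    """Everything needed to reconstruct and score a synthetic dataset."""

    kind: str  # "movie" | "pair"
    seed: int
    T: int = 0
    H: int = 0
    W: int = 0
    cell_xy: list = field(default_factory=list)
    cell_radius: list = field(default_factory=list)
    cell_baseline: list = field(default_factory=list)
    events: list = field(default_factory=list)  # per cell: [[frame, amp], ...]
    tau_frames: float = DEFAULT_TAU_FRAMES
    jitter: list = field(default_factory=list)  # per frame (dx, dy)
    distortion_m: int = 0
    distortion_end_params: list = field(default_factory=list)  # (M, M, 6)
    noise: dict = field(default_factory=dict)
    # across-session fields
    euclidean: dict = field(default_factory=dict)  # theta, e1, e2 (forward map)
    barrel: dict = field(default_factory=dict)  # k, cx, cy
    silenced: list = field(default_factory=list)

    # -- distortion helpers ------------------------------------------------
    def ramp_value(self, frame_index: float) -> float:
        return 0.0 if self.T <= 1 else float(frame_index) / (self.T - 1)

    def affine_at_ramp(self, r: float, i: int, j: int) -> AffineMatrix:
        """Ground-truth patch affine at ramp position r in [0, 1]."""
        end = np.asarray(self.distortion_end_params)[i, j]
        ident = np.array([1.0, 0.0, 0.0, 0.0, 1.0, 0.0])
        return AffineMatrix.from_params(ident + r * (end - ident))

    def patch_transforms_at_frame(self, t: int) -> list[list[AffineMatrix]]:
        r = self.ramp_value(t)
        M = self.distortion_m
        return [[self.affine_at_ramp(r, i, j) for j in range(M)] for i in range(M)]

    def mean_ramp(self, frame_range: tuple[int, int]) -> float:
        a, b = frame_range
        return self.ramp_value((a + b - 1) / 2.0)

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self))
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GroundTruth":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# Scene construction
# ---------------------------------------------------------------------------


def _stratified_positions(rng: np.random.Generator, n: int, H: int, W: int,
                          margin: float) -> np.ndarray:
    """Jittered-grid placement so every FOV region holds landmarks."""
    g = max(1, int(np.ceil(np.sqrt(n))))
    cy = np.linspace(margin, H - margin, g)
    cx = np.linspace(margin, W - margin, g)
    xx, yy = np.meshgrid(cx, cy)
    pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
    jitter_scale = min((H - 2 * margin) / g, (W - 2 * margin) / g) / 2.5
    pts = pts + rng.uniform(-jitter_scale, jitter_scale, size=pts.shape)
    order = rng.permutation(len(pts))[:n]
    pts = pts[order]
    return np.clip(pts, margin, [W - margin, H - margin])


def _stamp_blob(scene: np.ndarray, x: float, y: float, radius: float,
                amp: float) -> None:
    h, w = scene.shape
    r_ext = int(np.ceil(3 * radius))
    y0, y1 = max(0, int(y) - r_ext), min(h, int(y) + r_ext + 1)
    x0, x1 = max(0, int(x) - r_ext), min(w, int(x) + r_ext + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    scene[y0:y1, x0:x1] += amp * np.exp(
        -((xx - x) ** 2 + (yy - y) ** 2) / (2 * (radius / 1.5) ** 2)
    )


def _stamp_axon(scene: np.ndarray, rng: np.random.Generator, x: float, y: float,
                amp: float, length: int = 60, width: float = 1.2) -> None:
    h, w = scene.shape
    theta = rng.uniform(0, 2 * np.pi)
    px, py = x, y
    for _ in range(length):
        theta += rng.normal(0, 0.15)
        px += np.cos(theta)
        py += np.sin(theta)
        if not (1 <= px < w - 1 and 1 <= py < h - 1):
            break
        _stamp_blob(scene, px, py, width, amp / 3.0)


def _render_scene(rng: np.random.Generator, H: int, W: int, n_cells: int,
                  mode: str = "soma"):
    """Static scene plus per-cell footprints (positions, radii, baselines)."""
    background = 20.0
    margin = 8.0
    xy = _stratified_positions(rng, n_cells, H, W, margin)
    radii = rng.uniform(3.0, 6.0, size=n_cells)
    baselines = rng.uniform(40.0, 90.0, size=n_cells)
    footprints = []
    for (x, y), r in zip(xy, radii):
        fp = np.zeros((H, W))
        if mode == "axon":
            _stamp_axon(fp, rng, x, y, 1.0)
        else:
            _stamp_blob(fp, x, y, r, 1.0)
        footprints.append(fp)
    return background, xy, radii, baselines, footprints


def _draw_events(rng: np.random.Generator, n_cells: int, T: int,
                 rate_per_frame: float = 0.01):
    """Poisson-timed transient onsets with random amplitudes, per cell."""
    events = []
    for _ in range(n_cells):
        onsets = np.flatnonzero(rng.random(T) < rate_per_frame)
        amps = rng.uniform(60.0, 150.0, size=onsets.size)
        events.append([[int(f), float(a)] for f, a in zip(onsets, amps)])
    return events


def _traces_from_events(events: list, T: int, tau: float) -> np.ndarray:
    """Instantaneous-rise, exponential-decay transient traces (n_cells, T)."""
    n = len(events)
    impulses = np.zeros((n, T))
    for c, evs in enumerate(events):
        for f, a in evs:
            impulses[c, int(f)] += a
    decay = np.exp(-1.0 / tau)
    return lfilter([1.0], [1.0, -decay], impulses, axis=1)


def _reflected_walk(rng: np.random.Generator, T: int, sigma: float,
                    bound: float = JITTER_BOUND_PX) -> np.ndarray:
    """Random walk in 2-D, reflected at +/- bound (shape (T, 2))."""
    steps = rng.normal(0.0, sigma, size=(T, 2))
    steps[0] = 0.0
    walk = np.cumsum(steps, axis=0)
    # fold into [-bound, bound] by repeated reflection
    period = 4.0 * bound
    folded = np.mod(walk + bound, period)
    walk = np.where(folded <= 2 * bound, folded - bound, 3 * bound - folded)
    return walk


def draw_distortion_field(rng: np.random.Generator, spec: DistortionSpec,
                          grid: PatchGrid) -> np.ndarray:
    """(M, M, 6) end-of-ramp affine parameters (patch-local) per patch.

    Tissue-scale distortion varies smoothly across the FOV, so the per-patch
    affines are the first-order Taylor expansions of one global smooth
    (quadratic) displacement field at the patch centers.  Independent draws
    per patch would put displacement discontinuities at patch seams, which
    real data never shows and which the stitching operator would render as
    ghosts; with a smooth field, adjacent patches disagree in their overlap
    only by the field's curvature (hundredths of a pixel at these
    magnitudes).  The field is scaled so that the largest local rotation,
    shear/scale deviation and translation over the FOV stay within the spec
    bounds (the binding one reaching 70-100% of its bound).
    """
    M = spec.M
    H, W = grid.H, grid.W
    cy = np.array([[(b[0] + b[1] - 1) / 2.0 for b in row]
                   for row in grid.patch_bounds])
    cx = np.array([[(b[2] + b[3] - 1) / 2.0 for b in row]
                   for row in grid.patch_bounds])
    u = 2.0 * cx / max(W - 1, 1) - 1.0
    v = 2.0 * cy / max(H - 1, 1) - 1.0

    # displacement delta(u, v) in px: full quadratic per component
    coeff = rng.uniform(-1.0, 1.0, size=(2, 6))  # basis: 1, u, v, u^2, uv, v^2

    def field_and_jac(c):
        basis = np.stack([np.ones_like(u), u, v, u * u, u * v, v * v])
        dbu = np.stack([np.zeros_like(u), np.ones_like(u), np.zeros_like(u),
                        2 * u, v, np.zeros_like(u)])
        dbv = np.stack([np.zeros_like(u), np.zeros_like(u), np.ones_like(u),
                        np.zeros_like(u), u, 2 * v])
        delta = np.tensordot(c, basis, axes=1)          # (2, M, M) px
        du = np.tensordot(c, dbu, axes=1) * (2.0 / max(W - 1, 1))
        dv = np.tensordot(c, dbv, axes=1) * (2.0 / max(H - 1, 1))
        return delta, du, dv

    delta, du, dv = field_and_jac(coeff)
    rot = 0.5 * np.abs(du[1] - dv[0])
    shear = np.max(np.abs(np.stack([du[0], dv[1], 0.5 * (dv[0] + du[1])])), axis=0)
    trans = np.max(np.abs(delta), axis=0)
    ratios = [
        rot.max() / np.deg2rad(spec.max_rotation_deg) if spec.max_rotation_deg else 0,
        shear.max() / spec.max_shear if spec.max_shear else 0,
        trans.max() / spec.max_translation_px if spec.max_translation_px else 0,
    ]
    worst = max(ratios)
    if worst > 0:
        coeff = coeff * (rng.uniform(0.7, 1.0) / worst)
    delta, du, dv = field_and_jac(coeff)
    if spec.zero_mean_translation:
        coeff[0, 0] -= delta[0].mean()
        coeff[1, 0] -= delta[1].mean()
        delta, du, dv = field_and_jac(coeff)

    params = np.zeros((M, M, 6))
    for i, j, bounds in grid.patches():
        y0, y1, x0, x1 = bounds
        p_c = np.array([cx[i, j] - x0, cy[i, j] - y0])  # patch-local center
        jac = np.array([[1 + du[0, i, j], dv[0, i, j]],
                        [du[1, i, j], 1 + dv[1, i, j]]])
        d_c = delta[:, i, j]
        trans_loc = p_c + d_c - jac @ p_c
        params[i, j] = [jac[0, 0], jac[0, 1], trans_loc[0],
                        jac[1, 0], jac[1, 1], trans_loc[1]]
    return params


# ---------------------------------------------------------------------------
# Movie generation
# ---------------------------------------------------------------------------


def generate_movie(
    T: int,
    H: int,
    W: int,
    n_cells: int = 120,
    jitter_sigma_px: float = 1.0,
    distortion_spec: DistortionSpec | None = None,
    noise_spec: NoiseSpec | None = None,
    seed: int = 0,
    mode: str = "soma",
    event_rate_per_frame: float = 0.01,
    frame_rate_hz: float = 29.0,
) -> tuple[FrameStack, GroundTruth]:
    """Render a synthetic session movie with known jitter and distortion.

    Rendering order per frame: static scene + transients, then the patchwork
    distortion at the frame's ramp position, then the rigid jitter shift,
    then shot + read noise.
    """
    if T < 10:
        raise ValueError("T must be >= 10")
    if n_cells < 1:
        raise ValueError("need at least one cell")
    noise_spec = noise_spec if noise_spec is not None else NoiseSpec()
    rng = np.random.default_rng(seed)

    background, xy, radii, baselines, footprints = _render_scene(rng, H, W,
                                                                 n_cells, mode)
    events = _draw_events(rng, n_cells, T, event_rate_per_frame)
    traces = _traces_from_events(events, T, DEFAULT_TAU_FRAMES)
    jitter = (_reflected_walk(rng, T, jitter_sigma_px)
              if jitter_sigma_px > 0 else np.zeros((T, 2)))

    static = np.full((H, W), background)
    fp_stack = np.stack(footprints)
    static = static + np.tensordot(baselines, fp_stack, axes=1)

    gt = GroundTruth(
        kind="movie", seed=seed, T=T, H=H, W=W,
        cell_xy=xy.tolist(), cell_radius=np.asarray(radii).tolist(),
        cell_baseline=np.asarray(baselines).tolist(), events=events,
        tau_frames=DEFAULT_TAU_FRAMES, jitter=jitter.tolist(),
        noise=asdict(noise_spec),
    )

    grid = None
    if distortion_spec is not None:
        grid = make_patch_grid(H, W, distortion_spec.M)
        end_params = draw_distortion_field(rng, distortion_spec, grid)
        gt.distortion_m = distortion_spec.M
        gt.distortion_end_params = end_params.tolist()

    frames = np.empty((T, H, W), dtype=np.float32)
    for t in range(T):
        clean = static + np.tensordot(traces[:, t], fp_stack, axes=1)
        if grid is not None:
            sampler = PatchSampler(gt.patch_transforms_at_frame(t), grid)
            clean = sampler.apply(clean)
        dx, dy = jitter[t]
        if dx != 0.0 or dy != 0.0:
            clean = apply_shift(clean, dx, dy, fill="edge")
        if noise_spec.shot_noise and noise_spec.photon_scale > 0:
            lam = np.clip(clean, 0, None) * noise_spec.photon_scale
            clean = rng.poisson(lam).astype(np.float64) / noise_spec.photon_scale
        if noise_spec.gaussian_sigma > 0:
            clean = clean + rng.normal(0.0, noise_spec.gaussian_sigma,
                                       size=clean.shape)
        frames[t] = clean
    stack = FrameStack(frames, frame_rate_hz=frame_rate_hz, origin="synthetic")
    return stack, gt


# ---------------------------------------------------------------------------
# Across-session pairs
# ---------------------------------------------------------------------------


def barrel_warp(image: np.ndarray, k: float,
                center: tuple[float, float] | None = None) -> np.ndarray:
    """Radial distortion: the output at radius r samples the input at
    ``r' = r (1 + k r^2)`` about the given center (default FOV center)."""
    from scipy.ndimage import map_coordinates

    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    cx, cy = center if center is not None else ((w - 1) / 2.0, (h - 1) / 2.0)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dx, dy = xx - cx, yy - cy
    scale = 1.0 + k * (dx * dx + dy * dy)
    return map_coordinates(image, [cy + dy * scale, cx + dx * scale],
                           order=1, mode="nearest")


def barrel_map_points(xy: np.ndarray, k: float,
                      center: tuple[float, float]) -> np.ndarray:
    """The sampling map of :func:`barrel_warp` applied to (N, 2) points."""
    xy = np.atleast_2d(np.asarray(xy, dtype=np.float64))
    c = np.asarray(center)
    d = xy - c
    scale = 1.0 + k * np.sum(d * d, axis=1, keepdims=True)
    return c + d * scale


def generate_session_pair(
    base_seed: int,
    rotation_deg: float = 5.0,
    shift_px: tuple[float, float] = (10.0, -7.0),
    barrel_k: float = 1e-7,
    seed: int = 0,
    H: int = 512,
    W: int = 512,
    T: int = 150,
    n_cells: int = 250,
    silenced_frac: float = 0.1,
    noise_spec: NoiseSpec | None = None,
) -> tuple[tuple[SummaryImage, SummaryImage], tuple[SummaryImage, SummaryImage], GroundTruth]:
    """Two sessions of the same scene, the second displaced and distorted.

    Both sessions share the cell layout (drawn from ``base_seed``) but have
    independent transients and noise.  The moving session's summary images
    are additionally transformed by a Euclidean displacement (rotation about
    the FOV center plus translation) followed by barrel distortion, and a
    fraction of its cells is silenced entirely (neurons can be invisible in
    some sessions).
    """
    if abs(rotation_deg) > 30:
        raise ValueError("rotation must be within +/- 30 degrees")
    if barrel_k < 0:
        raise ValueError("barrel k must be >= 0")
    noise_spec = noise_spec if noise_spec is not None else NoiseSpec()
    rng = np.random.default_rng(seed)

    scene_rng = np.random.default_rng(base_seed)
    background, xy, radii, baselines, footprints = _render_scene(
        scene_rng, H, W, n_cells)
    fp_stack = np.stack(footprints)

    n_silenced = int(round(silenced_frac * n_cells))
    silenced = rng.choice(n_cells, size=n_silenced, replace=False) if n_silenced else []
    silenced = sorted(int(i) for i in np.atleast_1d(silenced))

    def render_session(active_mask: np.ndarray, sub_rng: np.random.Generator):
        base = baselines * active_mask
        static = np.full((H, W), background) + np.tensordot(base, fp_stack, axes=1)
        events = _draw_events(sub_rng, n_cells, T)
        traces = _traces_from_events(events, T, DEFAULT_TAU_FRAMES)
        traces = traces * active_mask[:, None]
        frames = np.empty((T, H, W), dtype=np.float32)
        for t in range(T):
            img = static + np.tensordot(traces[:, t], fp_stack, axes=1)
            if noise_spec.shot_noise and noise_spec.photon_scale > 0:
                lam = np.clip(img, 0, None) * noise_spec.photon_scale
                img = sub_rng.poisson(lam).astype(np.float64) / noise_spec.photon_scale
            if noise_spec.gaussian_sigma > 0:
                img = img + sub_rng.normal(0.0, noise_spec.gaussian_sigma,
                                           size=img.shape)
            frames[t] = img
        return FrameStack(frames, origin="synthetic")

    all_active = np.ones(n_cells)
    mov_active = all_active.copy()
    mov_active[list(silenced)] = 0.0

    ref_stack = render_session(all_active, np.random.default_rng(seed + 1))
    mov_stack = render_session(mov_active, np.random.default_rng(seed + 2))
    ref_summaries = summary_images(ref_stack, session_id="G")
    mov_mean, mov_max = summary_images(mov_stack, session_id="H")

    center = ((W - 1) / 2.0, (H - 1) / 2.0)
    e_forward = euclidean_about(np.deg2rad(rotation_deg), center, shift_px)

    def displace(img: SummaryImage) -> SummaryImage:
        from .ecc import warp_image

        warped, _ = warp_image(img.pixels, e_forward)
        if barrel_k > 0:
            warped = barrel_warp(warped, barrel_k, center)
        return SummaryImage(warped, img.statistic, img.session_id)

    moving = (displace(mov_mean), displace(mov_max))
    gt = GroundTruth(
        kind="pair", seed=seed, T=T, H=H, W=W,
        cell_xy=xy.tolist(), cell_radius=np.asarray(radii).tolist(),
        cell_baseline=np.asarray(baselines).tolist(),
        euclidean={"theta": e_forward.theta, "e1": e_forward.e1,
                   "e2": e_forward.e2},
        barrel={"k": barrel_k, "cx": center[0], "cy": center[1]},
        silenced=silenced,
        noise=asdict(noise_spec),
    )
    return ref_summaries, moving, gt


def expected_block_affine(
    gt: GroundTruth,
    block_range: tuple[int, int],
    template_range: tuple[int, int],
    i: int,
    j: int,
    shift_residuals: np.ndarray | None = None,
) -> AffineMatrix:
    """The patch affine the warp step should recover for one block.

    The warp correction maps each block's mean image onto the session
    template, so the expected transform is the *relative* distortion
    ``A_block^-1 . A_template`` evaluated at the blocks' mean ramp
    positions.  ``shift_residuals`` (per-frame estimated-minus-true rigid
    shift, shape (T, 2)) folds in the reference frame the rigid step
    established: registration to a template fixes positions only up to that
    residual, which enters as small translations on either side.
    """
    a_blk = gt.affine_at_ramp(gt.mean_ramp(block_range), i, j)
    a_tmp = gt.affine_at_ramp(gt.mean_ramp(template_range), i, j)
    expected = a_blk.inverse().compose(a_tmp)
    if shift_residuals is not None:
        res = np.asarray(shift_residuals, dtype=np.float64)
        d_blk = res[block_range[0]:block_range[1]].mean(axis=0)
        d_tmp = res[template_range[0]:template_range[1]].mean(axis=0)
        pre = AffineMatrix.from_params([1, 0, -d_blk[0], 0, 1, -d_blk[1]])
        post = AffineMatrix.from_params([1, 0, d_tmp[0], 0, 1, d_tmp[1]])
        expected = pre.compose(a_blk.inverse()).compose(a_tmp).compose(post)
    return expected


def patch_corners(bounds) -> np.ndarray:
    """Patch-local (x, y) corner coordinates for a (y0, y1, x0, x1) bound."""
    y0, y1, x0, x1 = bounds
    h, w = y1 - y0, x1 - x0
    return np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], dtype=np.float64)


def forward_pair_map(gt: GroundTruth, xy: np.ndarray) -> np.ndarray:
    """The generating (output -> sample) map of the session pair at the
    given points: Euclidean first, barrel applied to its output coords,
    matching the rendering order of :func:`generate_session_pair`."""
    e = EuclideanMatrix(gt.euclidean["theta"], gt.euclidean["e1"],
                        gt.euclidean["e2"])
    center = (gt.barrel["cx"], gt.barrel["cy"])
    pts = barrel_map_points(xy, gt.barrel["k"], center)
    return e.map_points(pts)
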