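"""Within-session slow-distortion correction by patchwise affine warping.

Slow image distortions in chronic two-photon imaging are not uniform across
the field of view, so no single affine transform can undo them.  Instead the
FOV is split into an M x M grid of overlapping square patches (M = 8 for
cellular resolution; 12-15 for the more independently moving axons), one
affine transform is estimated per patch against a fixed mid-session
template, and the warped patches are stitched back together by averaging
intensities over the overlaps.

Estimation runs on temporally downsampled data: frames are averaged in
non-overlapping 500-frame blocks (distortion is negligible within ~17 s),
each block mean is locally intensity-normalized, and one affine per patch
per block is fit by ECC maximization starting from identity.  Every raw
frame of a block is then warped with that block's transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from joblib import Parallel, delayed
from scipy.ndimage import map_coordinates

from .ecc import AffineMatrix, EccConfig, EccResult, ecc_maximize
from .io_stacks import FrameStack, block_ranges, centered_window, downsample_mean
from .normalization import DiskKernel, local_normalize

DEFAULT_BLOCK_SIZE = 500
DEFAULT_WARP_TEMPLATE_LEN = 5500
DEFAULT_M = 8

Bounds = tuple[int, int, int, int]  # (y0, y1, x0, x1), half-open


@dataclass
class PatchGrid:
    """M x M decomposition of an H x W field of view with interior overlaps.

    Nominal tiles of ``ceil(H/M) x ceil(W/M)`` are extended by
    ``overlap_y = round(0.3 * H / M)`` rows on each interior horizontal edge
    (and analogously in x), then clipped at the image border.
    """

    M: int
    H: int
    W: int
    overlap_y: int
    overlap_x: int
    patch_bounds: list[list[Bounds]]

    def bounds(self, i: int, j: int) -> Bounds:
        return self.patch_bounds[i][j]

    def patches(self):
        for i in range(self.M):
            for j in range(self.M):
                yield i, j, self.patch_bounds[i][j]


def _round_nearest(x: float) -> int:
    return int(np.floor(x + 0.5))


def make_patch_grid(H: int, W: int, M: int = DEFAULT_M) -> PatchGrid:
    """Build the overlapping patch grid for an H x W FOV."""
    if M < 1:
        raise ValueError("M must be >= 1")
    if M > min(H, W) / 8:
        raise ValueError(f"M={M} is too large for a {H} x {W} FOV")
    ty = -(-H // M)  # ceil
    tx = -(-W // M)
    ov_y = _round_nearest(0.3 * H / M) if M > 1 else 0
    ov_x = _round_nearest(0.3 * W / M) if M > 1 else 0
    rows: list[list[Bounds]] = []
    for i in range(M):
        y0 = i * ty
        y1 = min((i + 1) * ty, H)
        if i > 0:
            y0 -= ov_y
        if i < M - 1:
            y1 += ov_y
        y0, y1 = max(0, y0), min(H, y1)
        row: list[Bounds] = []
        for j in range(M):
            x0 = j * tx
            x1 = min((j + 1) * tx, W)
            if j > 0:
                x0 -= ov_x
            if j < M - 1:
                x1 += ov_x
            row.append((y0, y1, max(0, x0), min(W, x1)))
        rows.append(row)
    return PatchGrid(M=M, H=H, W=W, overlap_y=ov_y, overlap_x=ov_x, patch_bounds=rows)


@dataclass
class WarpField:
    """Per-block, per-patch affine transforms with convergence diagnostics.

    ``transforms[b][i][j]`` is the affine for patch (i, j) in temporal block
    ``b`` (identity where estimation failed); ``results`` holds the matching
    :class:`EccResult` diagnostics.  The total transform count is
    (number of patches) x (number of downsampled frames).
    """

    grid: PatchGrid
    block_frame_ranges: list[tuple[int, int]]
    transforms: list[list[list[AffineMatrix]]]
    results: list[list[list[EccResult | None]]] = field(default_factory=list)

    @property
    def n_blocks(self) -> int:
        return len(self.block_frame_ranges)


# ---------------------------------------------------------------------------
# Template and estimation
# ---------------------------------------------------------------------------


def build_warp_template(
    rigid_stack: FrameStack,
    template_len: int = DEFAULT_WARP_TEMPLATE_LEN,
    kernel: DiskKernel | None = None,
) -> np.ndarray:
    """Fixed warp-correction template: the locally normalized mean of the
    middle ``template_len`` frames of the (rigid-corrected) session."""
    a, b = centered_window(rigid_stack.n_frames, template_len)
    mean_img = np.asarray(rigid_stack.frames[a:b], dtype=np.float64).mean(axis=0)
    return local_normalize(mean_img, kernel)


def _estimate_patch(template: np.ndarray, block_img: np.ndarray, bounds: Bounds,
                    config: EccConfig) -> tuple[AffineMatrix, EccResult]:
    y0, y1, x0, x1 = bounds
    res = ecc_maximize(
        template[y0:y1, x0:x1], block_img[y0:y1, x0:x1], model="affine",
        init=AffineMatrix.identity(), config=config,
    )
    if res.converged:
        return res.transform, res  # type: ignore[return-value]
    return AffineMatrix.identity(), res


def estimate_block_warps(
    rigid_stack: FrameStack,
    template: np.ndarray,
    grid: PatchGrid,
    block_size: int = DEFAULT_BLOCK_SIZE,
    config: EccConfig | None = None,
    kernel: DiskKernel | None = None,
    n_jobs: int = 1,
) -> WarpField:
    """One affine per patch per temporal block, against the fixed template.

    Each block is the mean of ``block_size`` consecutive frames, locally
    normalized before ECC.  Blocks are mutually independent (every fit starts
    from identity), so no drift can accumulate across blocks.  Patches whose
    fit does not converge keep the identity transform, with the failed fit
    recorded in the diagnostics.
    """
    config = config or EccConfig()
    ranges = block_ranges(rigid_stack.n_frames, block_size)
    down = downsample_mean(rigid_stack, block_size)
    bounds_flat = [b for _, _, b in grid.patches()]

    def fit_block(block_img: np.ndarray):
        norm = local_normalize(block_img, kernel)
        return [_estimate_patch(template, norm, b, config) for b in bounds_flat]

    if n_jobs != 1:
        per_block = Parallel(n_jobs=n_jobs)(
            delayed(fit_block)(down.frames[k]) for k in range(len(ranges))
        )
    else:
        per_block = [fit_block(down.frames[k]) for k in range(len(ranges))]

    transforms, results = [], []
    for fits in per_block:
        tmat = [[fits[i * grid.M + j][0] for j in range(grid.M)] for i in range(grid.M)]
        rmat = [[fits[i * grid.M + j][1] for j in range(grid.M)] for i in range(grid.M)]
        transforms.append(tmat)
        results.append(rmat)
    return WarpField(grid=grid, block_frame_ranges=ranges,
                     transforms=transforms, results=results)


# ---------------------------------------------------------------------------
# Applying warps
# ---------------------------------------------------------------------------


class PatchSampler:
    """Precomputed sampling coordinates for one set of M x M patch affines.

    Transforms are fixed per temporal block, so the bilinear sampling
    coordinates and the stitching weights can be reused for every frame in
    the block.
    """

    def __init__(self, patch_transforms: list[list[AffineMatrix]], grid: PatchGrid):
        self.grid = grid
        self.entries = []
        weight = np.zeros((grid.H, grid.W))
        for i, j, (y0, y1, x0, x1) in grid.patches():
            m = patch_transforms[i][j].matrix
            yy, xx = np.mgrid[0 : y1 - y0, 0 : x1 - x0].astype(np.float64)
            xs = m[0, 0] * xx + m[0, 1] * yy + m[0, 2]
            ys = m[1, 0] * xx + m[1, 1] * yy + m[1, 2]
            h_p, w_p = y1 - y0, x1 - x0
            sup = (xs >= 0) & (xs <= w_p - 1) & (ys >= 0) & (ys <= h_p - 1)
            self.entries.append(((y0, y1, x0, x1), ys, xs, sup))
            weight[y0:y1, x0:x1] += sup
        self.weight = weight
        self.uncovered = weight == 0

    def apply(self, frame: np.ndarray) -> np.ndarray:
        frame = np.asarray(frame, dtype=np.float64)
        acc = np.zeros_like(frame)
        for (y0, y1, x0, x1), ys, xs, sup in self.entries:
            patch = frame[y0:y1, x0:x1]
            warped = map_coordinates(patch, [ys, xs], order=1, mode="nearest")
            acc[y0:y1, x0:x1] += np.where(sup, warped, 0.0)
        out = np.divide(acc, self.weight, out=np.zeros_like(acc),
                        where=~self.uncovered)
        # pixels with no valid contributor keep the input value
        if self.uncovered.any():
            out[self.uncovered] = frame[self.uncovered]
        return out


def warp_frame(frame: np.ndarray, patch_transforms: list[list[AffineMatrix]],
               grid: PatchGrid) -> np.ndarray:
    """Warp one frame patch-by-patch (patch-local affine coordinates, origin
    at each patch's upper-left corner) and stitch by overlap averaging."""
    return PatchSampler(patch_transforms, grid).apply(frame)


def warp_correct_session(
    rigid_stack: FrameStack,
    warpfield: WarpField,
    grid: PatchGrid | None = None,
) -> FrameStack:
    """Apply each block's patch transforms to every frame of the block."""
    grid = grid or warpfield.grid
    frames = np.asarray(rigid_stack.frames, dtype=np.float64)
    if warpfield.block_frame_ranges[-1][1] != rigid_stack.n_frames:
        raise ValueError("warp field does not cover the stack's frames")
    out = np.empty_like(frames)
    for b, (a, z) in enumerate(warpfield.block_frame_ranges):
        sampler = PatchSampler(warpfield.transforms[b], grid)
        for k in range(a, z):
            out[k] = sampler.apply(frames[k])
    return rigid_stack.with_frames(out, origin="warped")


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_warpfield(wf: WarpField, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as fh:
        g = fh.create_group("grid")
        g.attrs["M"] = wf.grid.M
        g.attrs["H"] = wf.grid.H
        g.attrs["W"] = wf.grid.W
        g.attrs["overlap_y"] = wf.grid.overlap_y
        g.attrs["overlap_x"] = wf.grid.overlap_x
        g.create_dataset(
            "patch_bounds",
            data=np.array(
                [[wf.grid.patch_bounds[i][j] for j in range(wf.grid.M)]
                 for i in range(wf.grid.M)], dtype=np.int64),
        )
        blocks = fh.create_group("blocks")
        for b in range(wf.n_blocks):
            bg = blocks.create_group(str(b))
            bg.attrs["frame_start"], bg.attrs["frame_stop"] = wf.block_frame_ranges[b]
            mats = np.array(
                [[wf.transforms[b][i][j].matrix for j in range(wf.grid.M)]
                 for i in range(wf.grid.M)])
            bg.create_dataset("patch_transforms", data=mats)
            if wf.results:
                rho = np.array(
                    [[wf.results[b][i][j].rho if wf.results[b][i][j] else np.nan
                      for j in range(wf.grid.M)] for i in range(wf.grid.M)])
                conv = np.array(
                    [[bool(wf.results[b][i][j].converged) if wf.results[b][i][j]
                      else False for j in range(wf.grid.M)] for i in range(wf.grid.M)])
                bg.create_dataset("rho", data=rho)
                bg.create_dataset("converged", data=conv)
    return path


def load_warpfield(path: str | Path) -> WarpField:
    with h5py.File(Path(path), "r") as fh:
        g = fh["grid"]
        grid = PatchGrid(
            M=int(g.attrs["M"]), H=int(g.attrs["H"]), W=int(g.attrs["W"]),
            overlap_y=int(g.attrs["overlap_y"]), overlap_x=int(g.attrs["overlap_x"]),
            patch_bounds=[
                [tuple(int(v) for v in g["patch_bounds"][i, j])
                 for j in range(int(g.attrs["M"]))]
                for i in range(int(g.attrs["M"]))
            ],
        )
        blocks = fh["blocks"]
        order = sorted(blocks.keys(), key=int)
        ranges, transforms, results = [], [], []
        for name in order:
            bg = blocks[name]
            ranges.append((int(bg.attrs["frame_start"]), int(bg.attrs["frame_stop"])))
            mats = bg["patch_transforms"][()]
            transforms.append(
                [[AffineMatrix(mats[i, j]) for j in range(grid.M)]
                 for i in range(grid.M)])
            if "rho" in bg:
                rho = bg["rho"][()]
                conv = bg["converged"][()]
                results.append(
                    [[EccResult(AffineMatrix(mats[i, j]), float(rho[i, j]), 0,
                                bool(conv[i, j]))
                      for j in range(grid.M)] for i in range(grid.M)])
    return WarpField(grid=grid, block_frame_ranges=ranges,
                     transforms=transforms, results=results)
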