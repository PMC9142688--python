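"""Rigid (translation-only) motion correction with template re-estimation.

At frame rates above ~10 Hz, motion artifacts from body movements of a
head-fixed animal are almost purely frame-wide translations.  Each frame is
aligned to a template by the integer shift maximizing Pearson correlation,
found by greedy hill climbing on a 4-level image pyramid, then refined to
subpixel precision by a per-axis parabola fit.  Frames and templates are
rank transformed first, so the estimate is invariant to any monotone
intensity remapping (calcium transients, slow bleaching).

Because the field of view also distorts slowly over a session, a single
template is a poor match for temporally distant frames.  The session is
split into 5 temporal blocks and correction proceeds bidirectionally from
the middle: a bootstrap template (mean of the middle frames) is refined into
T1' and used for block 3; new templates built from the first/last corrected
frames of block 3 register blocks 2 and 4; templates from the outer edges of
blocks 2 and 4 register blocks 1 and 5.  Each block is thus corrected
against a template built from temporally adjacent, already-corrected frames.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from joblib import Parallel, delayed
from scipy.ndimage import map_coordinates

from .ecc import build_pyramid
from .io_stacks import FrameStack, centered_window
from .normalization import rank_transform

DEFAULT_TEMPLATE_LEN = 2500
N_BLOCKS = 5


@dataclass
class RigidConfig:
    """Tunables for rigid motion correction.

    ``max_shift`` bounds the search (default ``min(H, W) / 4``; larger shifts
    are not physiological for head-fixed imaging).  ``levels`` is the number
    of pyramid halvings (3 gives scales 1/8, 1/4, 1/2, 1).
    """

    template_len: int = DEFAULT_TEMPLATE_LEN
    max_shift: int | None = None
    levels: int = 3
    subpixel: bool = True
    rank: bool = True
    fill: str = "edge"
    min_overlap_frac: float = 0.25
    n_jobs: int = 1

    def resolve_max_shift(self, shape: tuple[int, int]) -> int:
        if self.max_shift is not None:
            return int(self.max_shift)
        return max(1, min(shape) // 4)


@dataclass
class TranslationEstimate:
    """Estimated per-frame translation (content shift, +x right, +y down)."""

    dx: float
    dy: float
    corr: float
    level_trace: list[tuple[int, tuple[int, int]]] = field(default_factory=list)
    failed: bool = False


@dataclass
class TemplateSchedule:
    """The 5-block bidirectional template re-estimation plan.

    ``template_plan`` entries are ``(template_id, source_frame_range,
    target_frame_range)``: the template is the mean of the (already
    corrected) source frames and registers every frame of the target range.
    ``t1_window`` is the middle window used to bootstrap the first template.
    """

    n_frames: int
    template_len: int
    block_bounds: list[tuple[int, int]]
    t1_window: tuple[int, int]
    template_plan: list[tuple[str, tuple[int, int], tuple[int, int]]]


def build_schedule(n_frames: int, template_len: int = DEFAULT_TEMPLATE_LEN) -> TemplateSchedule:
    """Split a session into 5 equal blocks (remainder to the last) and lay
    out the bidirectional template plan (block 3, then 2 and 4, then 1 and 5)."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    b = n_frames // N_BLOCKS
    bounds = [(i * b, (i + 1) * b) for i in range(N_BLOCKS)]
    bounds[-1] = (bounds[-1][0], n_frames)
    window = centered_window(n_frames, template_len)
    blk = bounds
    length = template_len

    def head(rng: tuple[int, int]) -> tuple[int, int]:
        return rng[0], min(rng[0] + length, rng[1])

    def tail(rng: tuple[int, int]) -> tuple[int, int]:
        return max(rng[0], rng[1] - length), rng[1]

    plan = [
        ("T1p", window, blk[2]),
        ("T2p", head(blk[2]), blk[1]),
        ("T3p", tail(blk[2]), blk[3]),
        ("T4p", head(blk[1]), blk[0]),
        ("T5p", tail(blk[3]), blk[4]),
    ]
    return TemplateSchedule(n_frames, template_len, bounds, window, plan)


# ---------------------------------------------------------------------------
# Shift estimation
# ---------------------------------------------------------------------------


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def _shift_corr(template: np.ndarray, frame: np.ndarray, sx: int, sy: int,
                min_overlap_frac: float) -> float:
    """Correlation between template and frame translated by (sx, sy),
    evaluated only on the overlap; -inf when the overlap is too small."""
    h, w = template.shape
    y0, y1 = max(0, sy), h + min(0, sy)
    x0, x1 = max(0, sx), w + min(0, sx)
    if (y1 - y0) * (x1 - x0) < min_overlap_frac * h * w:
        return -np.inf
    t = template[y0:y1, x0:x1]
    f = frame[y0 - sy : y1 - sy, x0 - sx : x1 - sx]
    return _pearson(t, f)


def _tie_key(corr: float, sx: int, sy: int) -> tuple:
    # maximize corr; break ties by smaller ||shift||, then smaller dy, then dx
    return (-corr, sx * sx + sy * sy, sy, sx)


def _greedy_level(template: np.ndarray, frame: np.ndarray, start: tuple[int, int],
                  max_shift: int, min_overlap_frac: float) -> tuple[int, int, float, bool]:
    sx, sy = start
    sx = int(np.clip(sx, -max_shift, max_shift))
    sy = int(np.clip(sy, -max_shift, max_shift))
    cache: dict[tuple[int, int], float] = {}

    def corr_at(cx: int, cy: int) -> float:
        key = (cx, cy)
        if key not in cache:
            cache[key] = _shift_corr(template, frame, cx, cy, min_overlap_frac)
        return cache[key]

    current = corr_at(sx, sy)
    if not np.isfinite(current):
        sx, sy = 0, 0
        current = corr_at(0, 0)
        if not np.isfinite(current):
            return 0, 0, _shift_corr(template, frame, 0, 0, 0.0), True
    while True:
        candidates = [(current, sx, sy)]
        for ddy in (-1, 0, 1):
            for ddx in (-1, 0, 1):
                if ddx == 0 and ddy == 0:
                    continue
                nx, ny = sx + ddx, sy + ddy
                if abs(nx) > max_shift or abs(ny) > max_shift:
                    continue
                c = corr_at(nx, ny)
                if np.isfinite(c):
                    candidates.append((c, nx, ny))
        candidates.sort(key=lambda t: _tie_key(*t))
        best_c, best_x, best_y = candidates[0]
        if (best_x, best_y) == (sx, sy):
            return sx, sy, current, False
        sx, sy, current = best_x, best_y, best_c


def _parabola_offset(c_minus: float, c_0: float, c_plus: float) -> float:
    if not (np.isfinite(c_minus) and np.isfinite(c_plus)):
        return 0.0
    denom = c_minus - 2 * c_0 + c_plus
    if denom >= 0:  # not concave at the optimum
        return 0.0
    delta = 0.5 * (c_minus - c_plus) / denom
    return float(np.clip(delta, -0.999, 0.999))


def prepare_reference(template: np.ndarray, config: RigidConfig) -> list[np.ndarray]:
    """Rank-transform a template and build its pyramid (coarse reuse across
    frames of a block)."""
    t = rank_transform(template) if config.rank else np.asarray(template, dtype=np.float64)
    return build_pyramid(t, config.levels)


def estimate_shift(frame: np.ndarray, ref_pyramid: list[np.ndarray],
                   config: RigidConfig) -> TranslationEstimate:
    """Pyramid hill-climbing shift of one frame against a prepared template."""
    f = rank_transform(frame) if config.rank else np.asarray(frame, dtype=np.float64)
    frame_pyr = build_pyramid(f, config.levels)
    max_shift = config.resolve_max_shift(frame.shape)
    # internally (sx, sy) is the shift applied to the frame that best matches
    # the template; the returned estimate is the content shift, its negation
    sx, sy = 0, 0
    trace: list[tuple[int, tuple[int, int]]] = []
    failed = False
    corr = 0.0
    for level in range(config.levels, -1, -1):
        lvl_max = max(1, int(np.ceil(max_shift / 2**level)))
        sx, sy, corr, lvl_failed = _greedy_level(
            ref_pyramid[level], frame_pyr[level], (sx, sy), lvl_max,
            config.min_overlap_frac,
        )
        failed = failed or lvl_failed
        trace.append((level, (-sx, -sy)))
        if level > 0:
            sx, sy = 2 * sx, 2 * sy
    dx, dy = float(sx), float(sy)
    if config.subpixel and not failed:
        t0, f0 = ref_pyramid[0], frame_pyr[0]
        mo = config.min_overlap_frac
        c0 = corr
        dxo = _parabola_offset(
            _shift_corr(t0, f0, sx - 1, sy, mo), c0, _shift_corr(t0, f0, sx + 1, sy, mo)
        )
        dyo = _parabola_offset(
            _shift_corr(t0, f0, sx, sy - 1, mo), c0, _shift_corr(t0, f0, sx, sy + 1, mo)
        )
        dx += dxo
        dy += dyo
    # the estimate is the shift *of the frame content relative to the
    # template*; correcting the frame applies the negated shift
    return TranslationEstimate(dx=-dx, dy=-dy, corr=corr, level_trace=trace, failed=failed)


def hill_climb_shift(frame: np.ndarray, template: np.ndarray,
                     max_shift: int | None = None,
                     config: RigidConfig | None = None) -> TranslationEstimate:
    """Best translation of ``frame`` relative to ``template``.

    Positive ``dx``/``dy`` mean the frame content sits right/down of the
    template; ``apply_shift(frame, -dx, -dy)`` aligns it.
    """
    if frame.shape != template.shape:
        raise ValueError("frame and template must share a shape")
    config = config or RigidConfig()
    if max_shift is not None:
        config = RigidConfig(**{**config.__dict__, "max_shift": max_shift})
    return estimate_shift(frame, prepare_reference(template, config), config)


def apply_shift(frame: np.ndarray, dx: float, dy: float, fill: str = "edge") -> np.ndarray:
    """Translate a frame by (+dx, +dy) with subpixel bilinear resampling.

    Out-of-bounds samples are filled by edge replication (default) or the
    frame mean.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if dx == 0.0 and dy == 0.0:
        return frame.copy()
    h, w = frame.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    coords = [yy - dy, xx - dx]
    if fill == "edge":
        return map_coordinates(frame, coords, order=1, mode="nearest")
    if fill == "mean":
        return map_coordinates(frame, coords, order=1, mode="constant",
                               cval=float(frame.mean()))
    raise ValueError(f"unknown fill policy {fill!r}")


# ---------------------------------------------------------------------------
# Session-level correction
# ---------------------------------------------------------------------------


def _register_range(frames: np.ndarray, corrected: np.ndarray,
                    estimates: list, rng: tuple[int, int],
                    template: np.ndarray, config: RigidConfig) -> None:
    a, b = rng
    if b <= a:
        return
    ref = prepare_reference(template, config)
    idx = range(a, b)
    if config.n_jobs != 1:
        results = Parallel(n_jobs=config.n_jobs)(
            delayed(estimate_shift)(frames[i], ref, config) for i in idx
        )
    else:
        results = [estimate_shift(frames[i], ref, config) for i in idx]
    for i, est in zip(idx, results):
        estimates[i] = est
        corrected[i] = apply_shift(frames[i], -est.dx, -est.dy, fill=config.fill)


def rigid_correct_session(
    stack: FrameStack,
    schedule: TemplateSchedule | None = None,
    config: RigidConfig | None = None,
) -> tuple[FrameStack, list[TranslationEstimate]]:
    """Motion-correct a whole session following the 5-block template plan.

    Returns the corrected stack (origin ``rigid``) and one
    :class:`TranslationEstimate` per frame.  Templates are plain means of
    already-corrected frames; the rank transform is applied inside the shift
    estimator, never to the stored templates.  Raises if more than half of
    the frames fail to register.
    """
    config = config or RigidConfig()
    if schedule is None:
        schedule = build_schedule(stack.n_frames, config.template_len)
    if schedule.n_frames != stack.n_frames:
        raise ValueError("schedule was built for a different frame count")
    frames = np.asarray(stack.frames, dtype=np.float64)
    t = stack.n_frames
    corrected = np.empty_like(frames)
    estimates: list[TranslationEstimate | None] = [None] * t

    # bootstrap: register the middle window to its own raw mean, then
    # average the corrected frames into the refined first template
    w0, w1 = schedule.t1_window
    t1 = frames[w0:w1].mean(axis=0)
    ref = prepare_reference(t1, config)
    boot = np.empty((w1 - w0, *stack.frame_shape))
    for k, i in enumerate(range(w0, w1)):
        est = estimate_shift(frames[i], ref, config)
        boot[k] = apply_shift(frames[i], -est.dx, -est.dy, fill=config.fill)
    t1_refined = boot.mean(axis=0)

    for template_id, src, tgt in schedule.template_plan:
        if template_id == "T1p":
            template = t1_refined
        else:
            a, b = src
            if b <= a:
                template = t1_refined
            else:
                template = corrected[a:b].mean(axis=0)
        _register_range(frames, corrected, estimates, tgt, template, config)

    final = [e if e is not None else TranslationEstimate(0.0, 0.0, 0.0, [], True)
             for e in estimates]
    n_failed = sum(e.failed for e in final)
    if n_failed > 0.5 * t:
        raise RuntimeError(
            f"rigid correction failed on {n_failed}/{t} frames; session unregistrable"
        )
    out = stack.with_frames(corrected, origin="rigid")
    return out, final


def write_shift_csv(estimates: Sequence[TranslationEstimate], path: str | Path) -> Path:
    """Shift table: frame_index, dx, dy, corr, flagged."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_index", "dx", "dy", "corr", "flagged"])
        for i, est in enumerate(estimates):
            writer.writerow([i, f"{est.dx:.4f}", f"{est.dy:.4f}",
                             f"{est.corr:.6f}", int(est.failed)])
    return path
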