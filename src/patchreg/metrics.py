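"""Registration-quality metrics: mMD and mCM.

**mMD (mean max-intensity difference).**  Motion smears bright structures
across more pixels of the max projection, raising its mean intensity.  mMD
is ``mean(maxproj(post)) - mean(maxproj(pre))`` where each max projection is
taken after 50-frame non-overlapping averaging (to suppress the noise
contribution to per-pixel maxima); negative mMD means registration reduced
motion artifacts.

**mCM (mean correlation with mean image).**  The mean, over frames, of the
Pearson correlation between each frame and a mean image: *self*-mCM uses
the stack's own mean, *cross*-mCM the mean of the compared condition.
Successful registration raises both.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .io_stacks import FrameStack, downsample_mean

DEFAULT_MMD_WINDOW = 50


def max_projection_downsampled(stack: FrameStack, window: int = DEFAULT_MMD_WINDOW) -> np.ndarray:
    """Per-pixel max over ``window``-frame block averages."""
    down = downsample_mean(stack, window)
    return np.asarray(down.frames, dtype=np.float64).max(axis=0)


def mmd(pre: FrameStack, post: FrameStack, window: int = DEFAULT_MMD_WINDOW) -> float:
    """Mean max-intensity difference (post minus pre); negative = improved."""
    if pre.frame_shape != post.frame_shape:
        raise ValueError("stacks must share a frame shape")
    pre_img = max_projection_downsampled(pre, window)
    post_img = max_projection_downsampled(post, window)
    return float(post_img.mean() - pre_img.mean())


def mcm(stack: FrameStack, reference_mean: np.ndarray,
        stride: int = 1) -> float:
    """Mean Pearson correlation between individual frames and a mean image.

    Zero-variance frames are skipped (and simply reduce the count).  The
    optional ``stride`` subsamples frames for speed; the default uses every
    frame.
    """
    ref = np.asarray(reference_mean, dtype=np.float64)
    if ref.shape != stack.frame_shape:
        raise ValueError("reference mean must match the frame shape")
    rbar = ref.ravel() - ref.mean()
    rnorm = np.linalg.norm(rbar)
    if rnorm == 0.0:
        raise ValueError("reference mean image has zero variance")
    frames = stack.frames[::stride]
    n_px = rbar.size
    corrs: list[np.ndarray] = []
    # chunked so large stacks are cast to float64 a slice at a time
    for a in range(0, frames.shape[0], 256):
        flat = np.asarray(frames[a : a + 256], dtype=np.float64).reshape(-1, n_px)
        s = flat.sum(axis=1)
        ss = np.einsum("ij,ij->i", flat, flat)
        var = ss - s * s / n_px  # centered squared norm
        dot = flat @ rbar  # rbar is zero-mean, so centering flat is implicit
        valid = var > 0
        corrs.append(dot[valid] / (np.sqrt(var[valid]) * rnorm))
    allc = np.concatenate(corrs)
    if allc.size == 0:
        raise ValueError("all frames have zero variance")
    return float(allc.mean())


def self_mcm(stack: FrameStack, stride: int = 1) -> float:
    """mCM of a stack against its own mean image."""
    mean_img = np.asarray(stack.frames, dtype=np.float64).mean(axis=0)
    return mcm(stack, mean_img, stride=stride)


@dataclass
class MetricReport:
    """Pre/post comparison of one registration step."""

    mmd: float
    self_mcm_pre: float
    self_mcm_post: float
    cross_mcm_pre: float
    cross_mcm_post: float
    n_frames_used: int
    downsample_window: int

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def compare_conditions(pre: FrameStack, post: FrameStack,
                       window: int = DEFAULT_MMD_WINDOW,
                       stride: int = 1) -> MetricReport:
    """Full metric report for a pre/post registration pair.

    cross-mCM correlates each condition's frames with the *other*
    condition's mean image.
    """
    pre_mean = np.asarray(pre.frames, dtype=np.float64).mean(axis=0)
    post_mean = np.asarray(post.frames, dtype=np.float64).mean(axis=0)
    return MetricReport(
        mmd=mmd(pre, post, window),
        self_mcm_pre=mcm(pre, pre_mean, stride=stride),
        self_mcm_post=mcm(post, post_mean, stride=stride),
        cross_mcm_pre=mcm(pre, post_mean, stride=stride),
        cross_mcm_post=mcm(post, pre_mean, stride=stride),
        n_frames_used=pre.n_frames,
        downsample_window=window,
    )


def qc_figure(pre: FrameStack, post: FrameStack, report: MetricReport,
              path: str | Path, titles: tuple[str, str] = ("pre", "post")) -> Path:
    """One-page QC figure: pre/post max projections and the metric values."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for ax, stack, title in zip(axes[:2], (pre, post), titles):
        img = max_projection_downsampled(stack, report.downsample_window)
        ax.imshow(img, cmap="gray")
        ax.set_title(f"{title} max projection")
        ax.axis("off")
    ax = axes[2]
    names = ["self-mCM pre", "self-mCM post", "cross-mCM pre", "cross-mCM post"]
    values = [report.self_mcm_pre, report.self_mcm_post,
              report.cross_mcm_pre, report.cross_mcm_post]
    ax.bar(range(len(values)), values)
    ax.set_xticks(range(len(values)), names, rotation=45, ha="right")
    ax.set_title(f"mMD = {report.mmd:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
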