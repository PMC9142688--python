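"""Movie-stack I/O and temporal utilities.

Movies are multi-page grayscale TIFF stacks (single channel, single plane),
optionally split across several files per imaging session, as resonant-scanner
acquisition software typically writes them.  The in-memory container is
:class:`FrameStack`: a T x H x W array plus frame-rate metadata and a
provenance tag tracking which pipeline stage produced it.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(row=y, col=x)`` with pixel centers at
  integer coordinates;
* registration math runs in float64 regardless of the stored pixel type;
  the stored dtype is purely a writer policy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import tifffile

Origin = Literal["raw", "rigid", "warped", "synthetic"]

DEFAULT_FRAME_RATE_HZ = 29.0


@dataclass
class FrameStack:
    """An ordered movie of T frames of shape H x W.

    Parameters
    ----------
    frames
        3-D array ``(T, H, W)`` of fluorescence intensity (arbitrary units).
        Signed integer pixels (common for 12/16-bit PMT data) are preserved.
    frame_rate_hz
        Acquisition frame rate; metadata only.
    origin
        Provenance tag: ``raw`` (as read), ``rigid`` (after translation
        correction), ``warped`` (after patchwise affine correction) or
        ``synthetic`` (generated).
    """

    frames: np.ndarray
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
    origin: Origin = "raw"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T x H x W, got shape {self.frames.shape}")
        t, h, w = self.frames.shape
        if t < 1:
            raise ValueError("stack must contain at least one frame")
        if h < 8 or w < 8:
            raise ValueError(f"frames must be at least 8 x 8 pixels, got {h} x {w}")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def with_frames(self, frames: np.ndarray, origin: Origin) -> "FrameStack":
        """A copy of this stack's metadata around new frame data."""
        return FrameStack(frames, frame_rate_hz=self.frame_rate_hz, origin=origin)


@dataclass
class SummaryImage:
    """A per-session projection image (mean or max over frames)."""

    pixels: np.ndarray
    statistic: Literal["mean", "max"]
    session_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("summary image must be 2-D")
        if self.statistic not in ("mean", "max"):
            raise ValueError(f"statistic must be 'mean' or 'max', got {self.statistic!r}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("summary image pixels must be finite")


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------


def _load_pages(path: Path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(
            f"{path}: expected single-channel grayscale pages, got array of shape {arr.shape}"
        )
    return arr


def read_stack(
    paths: str | Path | Sequence[str | Path],
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
) -> FrameStack:
    """Read one session from one or more multi-page grayscale TIFF files.

    Frames are concatenated in the given path order, then page order within
    each file.  A bare directory is expanded to its ``*.tif``/``*.tiff``
    members in lexical order (acquisition software numbers split files so
    lexical order is acquisition order).
    """
    if isinstance(paths, (str, Path)):
        p = Path(paths)
        if p.is_dir():
            found = sorted(
                q for q in p.iterdir() if q.suffix.lower() in (".tif", ".tiff")
            )
            if not found:
                raise FileNotFoundError(f"no TIFF files in directory {p}")
            paths = found
        else:
            paths = [p]
    path_list = [Path(p) for p in paths]
    if not path_list:
        raise ValueError("no paths given")

    chunks = []
    shape: tuple[int, int] | None = None
    for p in path_list:
        if not p.exists():
            raise FileNotFoundError(f"missing stack file: {p}")
        pages = _load_pages(p)
        if shape is None:
            shape = pages.shape[1:]
        elif pages.shape[1:] != shape:
            raise ValueError(
                f"{p}: frame shape {pages.shape[1:]} differs from {shape} in earlier files"
            )
        chunks.append(pages)
    frames = chunks[0] if len(chunks) == 1 else np.concatenate(chunks, axis=0)
    return FrameStack(frames, frame_rate_hz=frame_rate_hz, origin="raw")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # np.rint rounds half to even; the writer contract is half away from zero.
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def write_stack(
    stack: FrameStack,
    path: str | Path,
    dtype_policy: Literal["preserve", "float32"] = "preserve",
    source_dtype: np.dtype | None = None,
) -> Path:
    """Write a stack as an uncompressed multi-page TIFF.

    With ``preserve``, float frames are rounded half away from zero and
    clipped to the range of the original integer dtype (``source_dtype``
    overrides the stack's own dtype, for stacks already promoted to float).
    """
    path = Path(path)
    frames = stack.frames
    if dtype_policy == "float32":
        out = frames.astype(np.float32)
    elif dtype_policy == "preserve":
        target = np.dtype(source_dtype) if source_dtype is not None else frames.dtype
        if np.issubdtype(target, np.integer):
            info = np.iinfo(target)
            out = _round_half_away(frames.astype(np.float64))
            out = np.clip(out, info.min, info.max).astype(target)
        else:
            out = frames
    else:
        raise ValueError(f"unknown dtype policy {dtype_policy!r}")
    try:
        tifffile.imwrite(path, out, photometric="minisblack")
    except OSError as exc:  # unwritable parent, permissions, ...
        raise OSError(f"cannot write stack to {path}: {exc}") from exc
    return path


def read_summary_image(path: str | Path, statistic: Literal["mean", "max"],
                       session_id: str = "") -> SummaryImage:
    arr = tifffile.imread(Path(path))
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    return SummaryImage(np.asarray(arr, dtype=np.float64), statistic, session_id)


def write_summary_image(img: SummaryImage, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, img.pixels.astype(np.float32), photometric="minisblack")
    return path


# ---------------------------------------------------------------------------
# Temporal blocking and projections
# ---------------------------------------------------------------------------


def block_ranges(n_frames: int, window: int) -> list[tuple[int, int]]:
    """Half-open frame ranges for non-overlapping temporal blocks.

    Full windows of ``window`` frames; a trailing remainder keeps its own
    block if it is at least half a window long, otherwise it is merged into
    the previous block (a warp estimated from very few frames is unreliable).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > n_frames:
        warnings.warn(
            f"window ({window}) exceeds frame count ({n_frames}); using a single block",
            stacklevel=2,
        )
        return [(0, n_frames)]
    n_full = n_frames // window
    rem = n_frames - n_full * window
    bounds = [(i * window, (i + 1) * window) for i in range(n_full)]
    if rem:
        if rem >= window / 2 or not bounds:
            bounds.append((n_full * window, n_frames))
        else:
            last = bounds[-1]
            bounds[-1] = (last[0], n_frames)
    return bounds


def downsample_mean(stack: FrameStack, window: int) -> FrameStack:
    """Non-overlapping moving average over ``window``-frame blocks.

    Output frame ``k`` is the arithmetic mean of the ``k``-th block of input
    frames (see :func:`block_ranges` for the trailing-remainder rule).
    """
    ranges = block_ranges(stack.n_frames, window)
    frames = stack.frames
    out = np.stack([frames[a:b].mean(axis=0, dtype=np.float64) for a, b in ranges])
    return FrameStack(out, frame_rate_hz=stack.frame_rate_hz, origin=stack.origin)


def summary_images(stack: FrameStack, session_id: str = "") -> tuple[SummaryImage, SummaryImage]:
    """Per-pixel mean and max projections over all frames."""
    frames = np.asarray(stack.frames, dtype=np.float64)
    return (
        SummaryImage(frames.mean(axis=0), "mean", session_id),
        SummaryImage(frames.max(axis=0), "max", session_id),
    )


def centered_window(n_frames: int, length: int) -> tuple[int, int]:
    """Half-open range of the middle ``length`` frames, clipped to the session."""
    if length >= n_frames:
        return 0, n_frames
    start = (n_frames - length) // 2
    return start, start + length
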