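"""Local intensity normalization and rank transform.

Calcium-dependent fluorescence makes the same neuron bright in one frame and
dim in the next, which misleads intensity-based registration.  Two
preprocessing transforms suppress this:

* **local normalization** divides each pixel by the mean intensity of its
  disk-shaped neighborhood (radius 32 px by default), rescaled by the global
  image mean, making the image approximately invariant to slow gain changes
  and to transient-driven brightness while preserving local structure;
* **rank transform** replaces each pixel by its intensity rank within the
  frame, making translational correlation invariant to any monotone
  intensity remapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.stats import rankdata

DEFAULT_DISK_RADIUS_PX = 32


def disk_mask(radius_px: int) -> np.ndarray:
    """Binary inscribed-disk mask of shape (2r+1, 2r+1).

    A pixel offset (dy, dx) from the center belongs to the disk iff
    dy^2 + dx^2 <= r^2.
    """
    if radius_px < 1:
        raise ValueError("radius must be a positive integer")
    r = int(radius_px)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    return (dy * dy + dx * dx <= r * r).astype(np.float64)


@dataclass
class DiskKernel:
    """Circular averaging kernel for local background estimation."""

    radius_px: int = DEFAULT_DISK_RADIUS_PX
    mask: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = disk_mask(self.radius_px)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def _check_kernel_fits(image: np.ndarray, kernel: DiskKernel) -> None:
    h, w = image.shape
    if kernel.radius_px >= min(h, w):
        raise ValueError(
            f"kernel radius {kernel.radius_px} does not fit a {h} x {w} image"
        )


def blur_disk(image: np.ndarray, kernel: DiskKernel | None = None) -> np.ndarray:
    """Zero-padded 2-D convolution with the binary disk (unnormalized sum)."""
    kernel = kernel or DiskKernel()
    image = np.asarray(image, dtype=np.float64)
    _check_kernel_fits(image, kernel)
    # FFT overlap-add convolution: the kernel is 65x65 at the default radius,
    # direct convolution would dominate pipeline runtime.
    out = signal.fftconvolve(image, kernel.mask, mode="same")
    return out


def padding_compensation(blurred: np.ndarray, kernel: DiskKernel | None = None) -> np.ndarray:
    """Divide a disk-blurred image by the blur of an all-ones image.

    Interior pixels end up divided by the full disk pixel count; pixels near
    the border by the in-bounds count, exactly cancelling the dimming that
    zero padding introduces at the edges.
    """
    kernel = kernel or DiskKernel()
    blurred = np.asarray(blurred, dtype=np.float64)
    denom = signal.fftconvolve(np.ones_like(blurred), kernel.mask, mode="same")
    return blurred / denom


def local_background(image: np.ndarray, kernel: DiskKernel | None = None) -> np.ndarray:
    """Padding-compensated disk blur: the local neighborhood mean at each pixel."""
    kernel = kernel or DiskKernel()
    return padding_compensation(blur_disk(image, kernel), kernel)


def local_normalize(image: np.ndarray, kernel: DiskKernel | None = None) -> np.ndarray:
    """Normalize each pixel by its local disk-neighborhood mean.

    Returns ``global_mean(f) * f / g`` where ``g`` is the padding-compensated
    disk blur of ``f``.  The global-mean prefactor keeps the output on the
    intensity scale of the input.  Pixels whose local mean is (near) zero are
    set to 0 and counted in a warning; this happens only on all-dark regions
    such as vignetted GRIN-lens borders.

    The transform is homogeneous of degree 1 (``a*f`` maps to ``a*output``),
    which combined with the gain/bias invariance of the correlation objectives
    downstream makes registration invariant to brightness and contrast
    changes.
    """
    kernel = kernel or DiskKernel()
    image = np.asarray(image, dtype=np.float64)
    g = local_background(image, kernel)
    gmean = image.mean()
    eps = 1e-12 * abs(gmean)
    bad = np.abs(g) <= eps
    out = np.zeros_like(image)
    np.divide(gmean * image, g, out=out, where=~bad)
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(
            f"local_normalize: {n_bad} pixels with near-zero local mean set to 0",
            stacklevel=2,
        )
    return out


def rank_transform(image: np.ndarray) -> np.ndarray:
    """Replace each pixel by its rank among all pixels (ties -> average rank).

    Output is a permutation-with-ties of 1..H*W; invariant to any strictly
    increasing remapping of the intensities.
    """
    image = np.asarray(image)
    if not np.all(np.isfinite(image)):
        raise ValueError("rank_transform requires finite input")
    ranks = rankdata(image.ravel(), method="average")
    return ranks.reshape(image.shape)
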