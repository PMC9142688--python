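"""Across-session registration of summary images.

Chronically imaged fields of view drift between sessions: the FOV is
re-found with some rotation and translation, and optical/tissue changes add
smooth non-uniform distortion.  Given the mean- and max-projection images of
a reference session G and a moving session H, registration proceeds in two
fully automated steps:

1. **Euclidean step** — a coarse-to-fine (pyramid) ECC fit of a rotation +
   translation over the whole FOV, run separately on the mean pair and the
   max pair; the transform with the larger full-FOV ECC wins (``E_best``)
   and is applied to *both* moving summaries.
2. **Patchwise affine step** — the FOV is split into an M x M overlapping
   grid and one affine per patch is fit (no pyramid needed after step 1),
   again on both summary pairs, keeping per patch whichever summary gives
   the larger ECC.  A patch whose fits both fail keeps the identity.

The result is ``M*M + 1`` transforms.  Selecting between mean and max
summaries per stage (and per patch) makes the procedure robust when a patch
lacks landmarks in one of the summaries, e.g. neurons visible only while
active (max) or only as baseline structure (mean).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from scipy.ndimage import map_coordinates

from .ecc import (
    AffineMatrix,
    EccConfig,
    EccResult,
    EuclideanMatrix,
    ecc_maximize,
    ecc_maximize_pyramid,
    warp_image,
)
from .io_stacks import SummaryImage
from .normalization import DiskKernel, local_normalize
from .patchwork import PatchGrid, PatchSampler, make_patch_grid

DEFAULT_M_ACROSS = 8


@dataclass
class SessionTransform:
    """One Euclidean plus M x M patch affines mapping session H onto G.

    ``selection`` records which summary statistic (mean or max) won each
    stage and the ECC values of both candidates.
    """

    e_best: EuclideanMatrix
    patch_affines: list[list[AffineMatrix]]
    grid: PatchGrid
    selection: dict

    @property
    def n_transforms(self) -> int:
        return self.grid.M * self.grid.M + 1


def _as_array(img: SummaryImage | np.ndarray) -> np.ndarray:
    if isinstance(img, SummaryImage):
        return np.asarray(img.pixels, dtype=np.float64)
    return np.asarray(img, dtype=np.float64)


def register_sessions(
    ref: tuple[SummaryImage, SummaryImage],
    moving: tuple[SummaryImage, SummaryImage],
    M: int = DEFAULT_M_ACROSS,
    config: EccConfig | None = None,
    kernel: DiskKernel | None = None,
) -> SessionTransform:
    """Two-step registration of session H summaries onto session G.

    ``ref`` and ``moving`` are (mean, max) summary-image pairs.  Raises
    ``RuntimeError`` when the Euclidean step fails on both summary pairs
    (the session pair is unregistrable).
    """
    config = config or EccConfig()
    ref_mean, ref_max = (_as_array(i) for i in ref)
    mov_mean, mov_max = (_as_array(i) for i in moving)
    if not (ref_mean.shape == ref_max.shape == mov_mean.shape == mov_max.shape):
        raise ValueError("all four summary images must share a shape")

    n_ref_mean = local_normalize(ref_mean, kernel)
    n_ref_max = local_normalize(ref_max, kernel)
    n_mov_mean = local_normalize(mov_mean, kernel)
    n_mov_max = local_normalize(mov_max, kernel)

    # step 1: whole-FOV Euclidean, pyramid, on both summary pairs
    res_mean = ecc_maximize_pyramid(n_ref_mean, n_mov_mean, model="euclidean",
                                    config=config)
    res_max = ecc_maximize_pyramid(n_ref_max, n_mov_max, model="euclidean",
                                   config=config)
    if not (res_mean.converged or res_max.converged):
        raise RuntimeError(
            "Euclidean step failed on both the mean and the max summary pair; "
            "session pair is unregistrable"
        )
    candidates = [("mean", res_mean), ("max", res_max)]
    winner, best = max(
        (c for c in candidates if c[1].converged), key=lambda c: c[1].rho
    )
    e_best: EuclideanMatrix = best.transform  # type: ignore[assignment]
    selection = {
        "euclidean": {"winner": winner, "rho_mean": res_mean.rho,
                      "rho_max": res_max.rho},
        "patches": [],
    }

    # apply the single winning Euclidean to both normalized moving summaries
    mov_mean_e, _ = warp_image(n_mov_mean, e_best)
    mov_max_e, _ = warp_image(n_mov_max, e_best)

    # step 2: per-patch affine, no pyramid, init identity
    grid = make_patch_grid(*ref_mean.shape, M)
    patch_affines: list[list[AffineMatrix]] = [
        [AffineMatrix.identity() for _ in range(M)] for _ in range(M)
    ]
    for i, j, (y0, y1, x0, x1) in grid.patches():
        fits: dict[str, EccResult] = {}
        for name, ref_img, mov_img in (
            ("mean", n_ref_mean, mov_mean_e),
            ("max", n_ref_max, mov_max_e),
        ):
            fits[name] = ecc_maximize(
                ref_img[y0:y1, x0:x1], mov_img[y0:y1, x0:x1],
                model="affine", init=AffineMatrix.identity(), config=config,
            )
        ok = {k: r for k, r in fits.items() if r.converged}
        record = {
            "patch": (i, j),
            "rho_mean": fits["mean"].rho,
            "rho_max": fits["max"].rho,
        }
        if ok:
            pwinner = max(ok, key=lambda k: ok[k].rho)
            patch_affines[i][j] = ok[pwinner].transform  # type: ignore[assignment]
            record["winner"] = pwinner
        else:
            record["winner"] = "identity"  # keep the patch as is
        selection["patches"].append(record)
    return SessionTransform(e_best=e_best, patch_affines=patch_affines,
                            grid=grid, selection=selection)


# ---------------------------------------------------------------------------
# Applying the transform
# ---------------------------------------------------------------------------


def _nearest_patchwork(image: np.ndarray, st: SessionTransform) -> np.ndarray:
    """Patchwise nearest-neighbor warp with per-pixel majority vote in
    overlaps; keeps label images (ROI masks) label-valued."""
    grid = st.grid
    layers: list[tuple[slice, slice, np.ndarray, np.ndarray]] = []
    for i, j, (y0, y1, x0, x1) in grid.patches():
        m = st.patch_affines[i][j].matrix
        yy, xx = np.mgrid[0 : y1 - y0, 0 : x1 - x0].astype(np.float64)
        xs = m[0, 0] * xx + m[0, 1] * yy + m[0, 2]
        ys = m[1, 0] * xx + m[1, 1] * yy + m[1, 2]
        h_p, w_p = y1 - y0, x1 - x0
        sup = (xs >= 0) & (xs <= w_p - 1) & (ys >= 0) & (ys <= h_p - 1)
        warped = map_coordinates(image[y0:y1, x0:x1], [ys, xs], order=0,
                                 mode="nearest")
        layers.append((slice(y0, y1), slice(x0, x1), warped, sup))
    labels = np.unique(image)
    counts = np.zeros((len(labels), *image.shape), dtype=np.int32)
    covered = np.zeros(image.shape, dtype=bool)
    for sy, sx, warped, sup in layers:
        covered[sy, sx] |= sup
        for li, lab in enumerate(labels):
            counts[li, sy, sx] += ((warped == lab) & sup).astype(np.int32)
    out = labels[np.argmax(counts, axis=0)]
    out = np.where(covered, out, image)
    return out.astype(image.dtype)


def apply_session_transform(
    image: np.ndarray,
    st: SessionTransform,
    interp: str = "bilinear",
) -> np.ndarray:
    """Transport an image (frame, projection, or ROI mask) from session H
    coordinates into session G coordinates.

    ``bilinear`` stitches overlapping patches by averaging; ``nearest`` uses
    a per-pixel majority vote so label masks stay label-valued.
    """
    image = np.asarray(image)
    if image.shape != (st.grid.H, st.grid.W):
        raise ValueError(
            f"image shape {image.shape} does not match the transform's grid "
            f"({st.grid.H} x {st.grid.W})"
        )
    if interp == "bilinear":
        step1, _ = warp_image(np.asarray(image, dtype=np.float64), st.e_best)
        return PatchSampler(st.patch_affines, st.grid).apply(step1)
    if interp == "nearest":
        m = st.e_best.matrix
        h, w = image.shape
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        xs = m[0, 0] * xx + m[0, 1] * yy + m[0, 2]
        ys = m[1, 0] * xx + m[1, 1] * yy + m[1, 2]
        step1 = map_coordinates(image, [ys, xs], order=0, mode="nearest")
        return _nearest_patchwork(step1, st)
    raise ValueError(f"unknown interpolation {interp!r}")


def session_correlation(ref_img: np.ndarray, moved_img: np.ndarray,
                        support: np.ndarray | None = None) -> float:
    """Pearson correlation between two summary images over the valid support."""
    a = np.asarray(ref_img, dtype=np.float64)
    b = np.asarray(moved_img, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if support is not None:
        a = a[support]
        b = b[support]
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        warnings.warn("session_correlation: zero-variance image, returning 0",
                      stacklevel=2)
        return 0.0
    return float(np.dot(a, b) / (na * nb))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_session_transform(st: SessionTransform, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("e_best", data=st.e_best.matrix)
        fh["e_best"].attrs["theta"] = st.e_best.theta
        fh["e_best"].attrs["e1"] = st.e_best.e1
        fh["e_best"].attrs["e2"] = st.e_best.e2
        M = st.grid.M
        mats = np.array([[st.patch_affines[i][j].matrix for j in range(M)]
                         for i in range(M)])
        fh.create_dataset("patch_affines", data=mats)
        g = fh.create_group("grid")
        g.attrs["M"] = M
        g.attrs["H"] = st.grid.H
        g.attrs["W"] = st.grid.W
        g.attrs["overlap_y"] = st.grid.overlap_y
        g.attrs["overlap_x"] = st.grid.overlap_x
        fh.create_dataset("selection", data=json.dumps(st.selection))
    return path


def load_session_transform(path: str | Path) -> SessionTransform:
    with h5py.File(Path(path), "r") as fh:
        e = fh["e_best"]
        e_best = EuclideanMatrix(float(e.attrs["theta"]), float(e.attrs["e1"]),
                                 float(e.attrs["e2"]))
        mats = fh["patch_affines"][()]
        g = fh["grid"]
        grid = make_patch_grid(int(g.attrs["H"]), int(g.attrs["W"]),
                               int(g.attrs["M"]))
        M = grid.M
        affines = [[AffineMatrix(mats[i, j]) for j in range(M)] for i in range(M)]
        selection = json.loads(fh["selection"][()].decode()
                               if isinstance(fh["selection"][()], bytes)
                               else str(fh["selection"][()]))
    return SessionTransform(e_best=e_best, patch_affines=affines, grid=grid,
                            selection=selection)
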