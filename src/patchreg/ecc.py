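"""Enhanced-correlation-coefficient (ECC) image alignment.

The ECC between a template pixel vector ``p_t`` and a warped-image pixel
vector ``p_w(a)`` is the normalized inner product of their zero-centered
versions::

    rho(a) = (p_t_bar . p_w_bar(a)) / (||p_t_bar|| ||p_w_bar(a)||)

Maximizing ``rho`` is equivalent to minimizing the loss
``L(a) = 2 - 2 rho(a)``, i.e. the squared distance between the two
unit-normalized zero-mean vectors.  Because both vectors are zero-centered
and normalized, the objective is invariant to changes in bias, gain,
brightness and contrast — only geometry is matched.

Two transform families are supported:

* :class:`AffineMatrix` — 6 parameters ``a1..a6`` acting as
  ``(x', y', 1)^T = A (x, y, 1)^T`` (translation, rotation, scaling, shear);
* :class:`EuclideanMatrix` — 3 parameters (rotation angle plus translation),
  the restriction of the affine family used for across-session alignment.

:func:`ecc_maximize` runs a forward-additive Gauss-Newton-style ECC update;
:func:`ecc_maximize_pyramid` wraps it in a coarse-to-fine image pyramid so
large displacements (tens of pixels) stay inside the convergence basin.

Convention: a transform maps *output* pixel coordinates to the coordinate at
which the *input* image is sampled (inverse mapping).  Consequently the
transform returned by :func:`ecc_maximize` is directly the one that
:func:`warp_image` needs to bring the moving image onto the template.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

Model = Literal["affine", "euclidean"]


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------


@dataclass
class AffineMatrix:
    """3x3 homogeneous 2-D affine transform with 6 free parameters.

    ``matrix = [[a1, a2, a3], [a4, a5, a6], [0, 0, 1]]`` and the coordinate
    action is ``x' = a1 x + a2 y + a3``, ``y' = a4 x + a5 y + a6``.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (3, 3):
            raise ValueError("affine matrix must be 3 x 3")
        if not np.array_equal(m[2], [0.0, 0.0, 1.0]):
            raise ValueError("last row of an affine matrix must be (0, 0, 1)")
        self.matrix = m

    @classmethod
    def identity(cls) -> "AffineMatrix":
        return cls(np.eye(3))

    @classmethod
    def from_params(cls, params: Sequence[float]) -> "AffineMatrix":
        a1, a2, a3, a4, a5, a6 = params
        return cls(np.array([[a1, a2, a3], [a4, a5, a6], [0, 0, 1]], dtype=np.float64))

    @classmethod
    def translation(cls, dx: float, dy: float) -> "AffineMatrix":
        """Transform whose application by :func:`warp_image` shifts image
        content by (+dx, +dy) pixels (matching ``apply_shift(dx, dy)``)."""
        return cls.from_params([1, 0, -dx, 0, 1, -dy])

    @property
    def params(self) -> np.ndarray:
        m = self.matrix
        return np.array([m[0, 0], m[0, 1], m[0, 2], m[1, 0], m[1, 1], m[1, 2]])

    @property
    def linear_det(self) -> float:
        m = self.matrix
        return float(m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0])

    def inverse(self) -> "AffineMatrix":
        return AffineMatrix(np.linalg.inv(self.matrix))

    def compose(self, other: "AffineMatrix | EuclideanMatrix") -> "AffineMatrix":
        """The transform equivalent to applying ``self`` after ``other``
        in sampling order: ``(self @ other)(p) = self(other(p))``."""
        return AffineMatrix(self.matrix @ as_matrix(other))

    def map_points(self, xy: np.ndarray) -> np.ndarray:
        """Apply to an (N, 2) array of (x, y) points."""
        xy = np.atleast_2d(np.asarray(xy, dtype=np.float64))
        ones = np.ones((xy.shape[0], 1))
        mapped = (self.matrix @ np.hstack([xy, ones]).T).T
        return mapped[:, :2]


@dataclass
class EuclideanMatrix:
    """Rotation-plus-translation transform: 3 parameters (theta, e1, e2).

    Expands to ``[[cos t, -sin t, e1], [sin t, cos t, e2], [0, 0, 1]]`` with
    theta in (-pi, pi].
    """

    theta: float
    e1: float
    e2: float

    def __post_init__(self) -> None:
        # wrap into (-pi, pi]
        t = float(self.theta)
        t = (t + np.pi) % (2 * np.pi) - np.pi
        if t == -np.pi:
            t = np.pi
        self.theta = t
        self.e1 = float(self.e1)
        self.e2 = float(self.e2)

    @classmethod
    def identity(cls) -> "EuclideanMatrix":
        return cls(0.0, 0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.theta), np.sin(self.theta)
        return np.array(
            [[c, -s, self.e1], [s, c, self.e2], [0, 0, 1]], dtype=np.float64
        )

    @property
    def params(self) -> np.ndarray:
        return np.array([self.theta, self.e1, self.e2])

    def inverse(self) -> "EuclideanMatrix":
        c, s = np.cos(self.theta), np.sin(self.theta)
        # inverse of [R | e] is [R^T | -R^T e]
        e1 = -(c * self.e1 + s * self.e2)
        e2 = -(-s * self.e1 + c * self.e2)
        return EuclideanMatrix(-self.theta, e1, e2)

    def as_affine(self) -> AffineMatrix:
        return AffineMatrix(self.matrix)

    def map_points(self, xy: np.ndarray) -> np.ndarray:
        return self.as_affine().map_points(xy)


Transform = AffineMatrix | EuclideanMatrix


def as_matrix(transform: Transform) -> np.ndarray:
    return transform.matrix


def euclidean_about(theta: float, center_xy: tuple[float, float],
                    shift_xy: tuple[float, float] = (0.0, 0.0)) -> EuclideanMatrix:
    """Euclidean transform rotating by ``theta`` about ``center_xy`` and then
    sampling with an extra offset ``shift_xy`` (inverse-map convention)."""
    cx, cy = center_xy
    c, s = np.cos(theta), np.sin(theta)
    e1 = cx - c * cx + s * cy + shift_xy[0]
    e2 = cy - s * cx - c * cy + shift_xy[1]
    return EuclideanMatrix(theta, e1, e2)


def transform_to_json(transform: Transform) -> dict:
    if isinstance(transform, EuclideanMatrix):
        return {
            "model": "euclidean",
            "theta": transform.theta,
            "e1": transform.e1,
            "e2": transform.e2,
            "matrix": transform.matrix.tolist(),
        }
    return {"model": "affine", "matrix": transform.matrix.tolist()}


def transform_from_json(obj: dict) -> Transform:
    if obj["model"] == "euclidean":
        return EuclideanMatrix(obj["theta"], obj["e1"], obj["e2"])
    if obj["model"] == "affine":
        return AffineMatrix(np.asarray(obj["matrix"]))
    raise ValueError(f"unknown transform model {obj['model']!r}")


# ---------------------------------------------------------------------------
# Warping and scoring
# ---------------------------------------------------------------------------


def warp_image(
    image: np.ndarray,
    transform: Transform,
    out_shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-mapping bilinear resampling of ``image`` under ``transform``.

    For each output pixel ``(x, y)`` the input is sampled at
    ``transform @ (x, y, 1)``.  Returns the warped image and a boolean
    support mask marking output pixels whose sample lies fully inside the
    input bounds (edge-replicated values fill the rest).
    """
    image = np.asarray(image, dtype=np.float64)
    m = as_matrix(transform)
    if abs(np.linalg.det(m)) < 1e-12:
        raise ValueError("singular transform cannot be applied")
    h_out, w_out = out_shape if out_shape is not None else image.shape
    h_in, w_in = image.shape
    yy, xx = np.mgrid[0:h_out, 0:w_out].astype(np.float64)
    xs = m[0, 0] * xx + m[0, 1] * yy + m[0, 2]
    ys = m[1, 0] * xx + m[1, 1] * yy + m[1, 2]
    support = (xs >= 0) & (xs <= w_in - 1) & (ys >= 0) & (ys <= h_in - 1)
    warped = map_coordinates(image, [ys, xs], order=1, mode="nearest")
    return warped, support


def ecc_score(
    template: np.ndarray,
    warped: np.ndarray,
    support: np.ndarray | None = None,
) -> float:
    """ECC between two images over a common support mask.

    Both pixel vectors are zero-centered over the support; the score is their
    normalized inner product, so ``L = 2 - 2 rho`` is the squared distance
    between the unit-normalized vectors.  Returns 0 (with a warning) when
    either operand has zero variance on the support.
    """
    t = np.asarray(template, dtype=np.float64)
    w = np.asarray(warped, dtype=np.float64)
    if support is not None:
        sup = np.asarray(support, dtype=bool)
        if sup.sum() < 16:
            raise ValueError("support mask must contain at least 16 pixels")
        t = t[sup]
        w = w[sup]
    t = t.ravel() - t.mean()
    w = w.ravel() - w.mean()
    nt = np.linalg.norm(t)
    nw = np.linalg.norm(w)
    if nt == 0.0 or nw == 0.0:
        warnings.warn("ecc_score: zero-variance operand, returning 0", stacklevel=2)
        return 0.0
    return float(np.dot(t, w) / (nt * nw))


def ecc_loss(template: np.ndarray, warped: np.ndarray,
             support: np.ndarray | None = None) -> float:
    """Squared distance between unit-normalized zero-mean pixel vectors
    (equals ``2 - 2 * ecc_score`` identically)."""
    t = np.asarray(template, dtype=np.float64)
    w = np.asarray(warped, dtype=np.float64)
    if support is not None:
        sup = np.asarray(support, dtype=bool)
        t, w = t[sup], w[sup]
    t = t.ravel() - t.mean()
    w = w.ravel() - w.mean()
    nt = np.linalg.norm(t)
    nw = np.linalg.norm(w)
    if nt == 0.0 or nw == 0.0:
        return 2.0
    return float(np.sum((t / nt - w / nw) ** 2))


# ---------------------------------------------------------------------------
# ECC maximization
# ---------------------------------------------------------------------------


@dataclass
class EccConfig:
    """Tunables for the iterative ECC update.

    ``grad_sigma`` is the Gaussian pre-smoothing (px) applied before the
    central-difference spatial gradients; it stabilizes the Gauss-Newton step
    on shot-noise-limited images.  ``rho_floor`` and ``det_range`` define the
    failure criterion: a solution below the floor or with a degenerate linear
    part is reported as not converged (callers fall back to identity).
    """

    max_iter: int = 50
    tol_rho: float = 1e-6
    tol_p: float = 1e-8
    rho_floor: float = 0.3
    grad_sigma: float = 1.0
    det_min: float = 0.2
    det_max: float = 5.0
    min_support: int = 16
    min_support_frac: float = 0.25  # of the template area; blocks the
    # degenerate "solution" of shrinking the overlap to a spuriously
    # well-correlated sliver


@dataclass
class EccResult:
    """Outcome of one ECC maximization."""

    transform: Transform
    rho: float
    iterations: int
    converged: bool
    rho_trace: list[float] = field(default_factory=list)


def _params_to_transform(model: Model, p: np.ndarray) -> Transform:
    if model == "affine":
        return AffineMatrix.from_params(p)
    return EuclideanMatrix(p[0], p[1], p[2])


def _transform_to_params(model: Model, t: Transform) -> np.ndarray:
    if model == "affine":
        if isinstance(t, EuclideanMatrix):
            t = t.as_affine()
        return t.params.copy()
    if isinstance(t, AffineMatrix):
        # project onto the Euclidean manifold via the rotation angle
        theta = float(np.arctan2(t.matrix[1, 0], t.matrix[0, 0]))
        return np.array([theta, t.matrix[0, 2], t.matrix[1, 2]])
    return t.params.copy()


def _det_ok(transform: Transform, config: EccConfig) -> bool:
    if isinstance(transform, EuclideanMatrix):
        return True
    d = transform.linear_det
    return config.det_min <= d <= config.det_max


def ecc_maximize(
    template: np.ndarray,
    target: np.ndarray,
    model: Model = "affine",
    init: Transform | None = None,
    config: EccConfig | None = None,
) -> EccResult:
    """Estimate the transform maximizing the ECC of ``target`` against
    ``template`` by a forward-additive gradient ascent.

    Each iteration warps the target (and its pre-smoothed spatial gradients)
    with the current transform, builds the Jacobian of warped pixel values
    with respect to the 6 affine or 3 Euclidean parameters on the in-bounds
    support, solves the ECC normal equations for the parameter update, and
    re-evaluates rho.  Steps that decrease rho cause a revert to the best
    iterate.  The inputs are expected to be locally normalized by the caller;
    the score itself is additionally invariant to gain and bias.
    """
    config = config or EccConfig()
    template = np.asarray(template, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if init is None:
        init = AffineMatrix.identity() if model == "affine" else EuclideanMatrix.identity()
    p = _transform_to_params(model, init)

    h_out, w_out = template.shape
    h_in, w_in = target.shape
    yy, xx = np.mgrid[0:h_out, 0:w_out].astype(np.float64)
    smoothed = gaussian_filter(target, config.grad_sigma) if config.grad_sigma > 0 else target
    gy_full, gx_full = np.gradient(smoothed)

    def evaluate(p_vec: np.ndarray):
        if model == "affine":
            a1, a2, a3, a4, a5, a6 = p_vec
            xs = a1 * xx + a2 * yy + a3
            ys = a4 * xx + a5 * yy + a6
        else:
            th, e1, e2 = p_vec
            c, s = np.cos(th), np.sin(th)
            xs = c * xx - s * yy + e1
            ys = s * xx + c * yy + e2
        sup = (xs >= 0) & (xs <= w_in - 1) & (ys >= 0) & (ys <= h_in - 1)
        if sup.sum() < max(config.min_support,
                           config.min_support_frac * template.size):
            return None
        coords = [ys[sup], xs[sup]]
        iw = map_coordinates(target, coords, order=1, mode="nearest")
        gxw = map_coordinates(gx_full, coords, order=1, mode="nearest")
        gyw = map_coordinates(gy_full, coords, order=1, mode="nearest")
        tv = template[sup]
        rho = ecc_score(tv, iw)
        return sup, iw, gxw, gyw, tv, rho

    best_p = p.copy()
    state = evaluate(p)
    if state is None:
        return EccResult(_params_to_transform(model, p), -1.0, 0, False, [])
    best_rho = state[5]
    rho_trace = [best_rho]
    prev_rho = best_rho
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        sup, iw, gxw, gyw, tv, _ = state
        xs_s = xx[sup]
        ys_s = yy[sup]
        if model == "affine":
            g_cols = [gxw * xs_s, gxw * ys_s, gxw, gyw * xs_s, gyw * ys_s, gyw]
        else:
            th = p[0]
            c, s = np.cos(th), np.sin(th)
            dtheta = gxw * (-s * xs_s - c * ys_s) + gyw * (c * xs_s - s * ys_s)
            g_cols = [dtheta, gxw, gyw]
        g_mat = np.stack(g_cols, axis=1)
        g_mat = g_mat - g_mat.mean(axis=0, keepdims=True)
        tbar = tv - tv.mean()
        wbar = iw - iw.mean()
        hess = g_mat.T @ g_mat
        g_w = g_mat.T @ wbar
        g_t = g_mat.T @ tbar
        try:
            hinv_gw = np.linalg.solve(hess, g_w)
            hinv_gt = np.linalg.solve(hess, g_t)
        except np.linalg.LinAlgError:
            break
        num = float(wbar @ wbar - g_w @ hinv_gw)
        den = float(tbar @ wbar - g_t @ hinv_gw)
        if not np.isfinite(num) or not np.isfinite(den) or den <= 0:
            break
        lam = num / den
        err = lam * tbar - wbar
        try:
            dp = np.linalg.solve(hess, g_mat.T @ err)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(dp)):
            break
        if np.linalg.norm(dp) < config.tol_p:
            break
        # backtracking: a full Gauss-Newton step can overshoot near the
        # optimum; halve it until rho improves (or give up after 4 halvings)
        rho_current = state[5]
        accepted = None
        for _ in range(5):
            state_new = evaluate(p + dp)
            if state_new is not None and state_new[5] > rho_current:
                accepted = (p + dp, state_new)
                break
            dp = dp / 2.0
        if accepted is None:
            break  # no improving step along this direction; keep best iterate
        p, state = accepted
        rho_new = state[5]
        if rho_new > best_rho:
            best_rho = rho_new
            best_p = p.copy()
            rho_trace.append(rho_new)
        if abs(rho_new - prev_rho) < config.tol_rho:
            break
        prev_rho = rho_new

    final = _params_to_transform(model, best_p)
    converged = bool(
        best_rho >= config.rho_floor and np.isfinite(best_rho) and _det_ok(final, config)
    )
    return EccResult(final, best_rho, n_iter, converged, rho_trace)


# ---------------------------------------------------------------------------
# Pyramid wrapper
# ---------------------------------------------------------------------------


def downscale2x(image: np.ndarray) -> np.ndarray:
    """Halve both dimensions by 2x2 block averaging (odd edges cropped)."""
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    h2, w2 = h // 2, w // 2
    trimmed = image[: 2 * h2, : 2 * w2]
    return trimmed.reshape(h2, 2, w2, 2).mean(axis=(1, 3))


def build_pyramid(image: np.ndarray, levels: int, smooth: bool = False) -> list[np.ndarray]:
    """Pyramid from level 0 (full resolution) to ``levels`` (1/2**levels).

    With ``smooth`` a sigma-1 Gaussian is applied before each halving
    (antialiasing, which also widens the convergence basin of gradient-based
    alignment at the coarse levels).
    """
    pyr = [np.asarray(image, dtype=np.float64)]
    for _ in range(levels):
        prev = gaussian_filter(pyr[-1], 1.0) if smooth else pyr[-1]
        pyr.append(downscale2x(prev))
    return pyr


def _multistart_coarse(template: np.ndarray, target: np.ndarray, model: Model,
                       init: Transform, config: EccConfig) -> EccResult:
    """Coarsest-level fit with a sweep of translation (and rotation, for the
    Euclidean model) initializations around ``init``; the top candidates by
    initial ECC are optimized fully and the best final fit is returned."""
    p0 = _transform_to_params(model, init)
    h, w = template.shape
    step = max(2.0, min(h, w) / 8.0)
    offsets = [(-step, -step), (-step, 0), (-step, step), (0, -step), (0, 0),
               (0, step), (step, -step), (step, 0), (step, step)]
    thetas = [0.0]
    if model == "euclidean":
        thetas = [0.0, -0.35, -0.175, 0.175, 0.35]
    candidates: list[np.ndarray] = []
    for dth in thetas:
        for ox, oy in offsets:
            q = p0.copy()
            if model == "euclidean":
                q[0] += dth
                q[1] += ox
                q[2] += oy
            else:
                q[2] += ox
                q[5] += oy
            candidates.append(q)

    def initial_rho(q: np.ndarray) -> float:
        try:
            warped, sup = warp_image(target, _params_to_transform(model, q),
                                     out_shape=template.shape)
        except ValueError:
            return -2.0
        if sup.sum() < max(config.min_support,
                           config.min_support_frac * template.size):
            return -2.0
        return ecc_score(template[sup], warped[sup])

    scored = sorted(candidates, key=initial_rho, reverse=True)
    best: EccResult | None = None
    for q in scored[:5]:
        res = ecc_maximize(template, target, model,
                           _params_to_transform(model, q), config)
        if best is None or res.rho > best.rho:
            best = res
    assert best is not None
    return best


def ecc_maximize_pyramid(
    template: np.ndarray,
    target: np.ndarray,
    model: Model = "euclidean",
    levels: int = 3,
    init: Transform | None = None,
    config: EccConfig | None = None,
) -> EccResult:
    """Coarse-to-fine ECC maximization for large displacements.

    Runs :func:`ecc_maximize` from the coarsest pyramid level (1/2**levels
    downscaling) to full resolution, doubling the translation components of
    the estimate between levels (the rotation angle carries unchanged).
    At the coarsest level a small multi-start sweep over translation (and,
    for the Euclidean model, rotation) initializations guards against the
    narrow convergence basin of fine-textured images; the best-scoring fit
    seeds the finer levels.  Returns the full-resolution result.
    """
    config = config or EccConfig()
    if init is None:
        init = EuclideanMatrix.identity() if model == "euclidean" else AffineMatrix.identity()
    pyr_t = build_pyramid(template, levels, smooth=True)
    pyr_i = build_pyramid(target, levels, smooth=True)

    scale = float(2**levels)
    p = _transform_to_params(model, init)
    if model == "euclidean":
        p = np.array([p[0], p[1] / scale, p[2] / scale])
    else:
        p = np.array([p[0], p[1], p[2] / scale, p[3], p[4], p[5] / scale])
    current: Transform = _params_to_transform(model, p)

    result: EccResult | None = None
    any_ok = False
    for level in range(levels, -1, -1):
        if level == levels:
            result = _multistart_coarse(pyr_t[level], pyr_i[level], model,
                                        current, config)
        else:
            result = ecc_maximize(pyr_t[level], pyr_i[level], model, current, config)
        any_ok = any_ok or result.converged
        q = _transform_to_params(model, result.transform)
        if level > 0:
            if model == "euclidean":
                q = np.array([q[0], q[1] * 2, q[2] * 2])
            else:
                q = np.array([q[0], q[1], q[2] * 2, q[3], q[4], q[5] * 2])
            current = _params_to_transform(model, q)
    assert result is not None
    if not any_ok:
        return EccResult(result.transform, result.rho, result.iterations, False,
                         result.rho_trace)
    return result
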