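"""Ellipsoid geometry: representation, least-squares fitting, nearest-point projection.

The eggshell of the early C. elegans embryo is well approximated by an
ellipsoid (roughly 50 x 30 x 30 um outer dimensions).  The simulator confines
cell surfaces to a fitted ellipsoid with a one-sided constraint, so the two
workhorse operations here are fitting an ellipsoid to contour points extracted
from the eggshell channel and projecting points onto the ellipsoid surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq


@dataclass(frozen=True)
class Ellipsoid:
    """An arbitrarily oriented ellipsoid.

    Attributes
    ----------
    center : (3,) array, um
    semi_axes : (3,) array, um, sorted a >= b >= c, all positive
    rotation : (3, 3) proper rotation; column i is the world-frame direction
        of local axis i, so local axis 0 is the major axis.
    """

    center: np.ndarray
    semi_axes: np.ndarray
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "semi_axes", np.asarray(self.semi_axes, dtype=float))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        if self.center.shape != (3,) or self.semi_axes.shape != (3,):
            raise ValueError("center and semi_axes must be 3-vectors")
        if np.any(self.semi_axes <= 0):
            raise ValueError("semi-axes must be strictly positive")
        if np.any(np.diff(self.semi_axes) > 1e-12):
            raise ValueError("semi-axes must be sorted a >= b >= c")
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with determinant +1")

    @property
    def major_axis(self) -> np.ndarray:
        """Unit vector along the longest semi-axis (the AP axis of the embryo)."""
        return self.rotation[:, 0]

    @property
    def volume(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    def to_local(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return (points - self.center) @ self.rotation

    def to_world(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.center

    def implicit(self, points: np.ndarray) -> np.ndarray:
        """Level-set value sum((x_i/s_i)^2) - 1: negative inside, 0 on surface."""
        q = self.to_local(points) / self.semi_axes
        return np.sum(np.square(q), axis=-1) - 1.0

    def contains(self, points: np.ndarray, tol: float = 0.0) -> np.ndarray:
        return self.implicit(points) <= tol

    def surface_normal(self, points: np.ndarray) -> np.ndarray:
        """Outward unit normal of the level set at (near-)surface points."""
        local = self.to_local(points)
        g = 2.0 * local / np.square(self.semi_axes)
        g = g @ self.rotation.T
        n = np.linalg.norm(g, axis=-1, keepdims=True)
        return g / np.where(n == 0, 1.0, n)

    def to_dict(self) -> dict:
        return {
            "center": self.center.tolist(),
            "semi_axes": self.semi_axes.tolist(),
            "rotation": self.rotation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Ellipsoid":
        return cls(
            center=np.array(d["center"], dtype=float),
            semi_axes=np.array(d["semi_axes"], dtype=float),
            rotation=np.array(d["rotation"], dtype=float),
        )


def fit_ellipsoid(points: np.ndarray) -> tuple[Ellipsoid, float]:
    """Least-squares ellipsoid fit to a 3D point set.

    Fits the general quadric ``x^T A x + 2 b^T x + c = 0`` by algebraic least
    squares (smallest singular vector of the design matrix, uniform weights),
    then recovers center, semi-axes and orientation by completing the square
    and eigendecomposition.  All points are weighted equally.

    Parameters
    ----------
    points : (n, 3) array with n >= 9 non-degenerate points.

    Returns
    -------
    (ellipsoid, residual) where residual is the RMS of the normalized
    implicit values at the input points (0 for an exact fit).

    Raises
    ------
    ValueError if the point set is degenerate or the best quadric is not an
    ellipsoid (e.g. coplanar points).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    if pts.shape[0] < 9:
        raise ValueError("need at least 9 points to fit an ellipsoid")

    # Center and scale for conditioning.
    mu = pts.mean(axis=0)
    scale = pts.std(axis=0).mean()
    if scale <= 0:
        raise ValueError("degenerate point set (all points coincide)")
    q = (pts - mu) / scale

    x, y, z = q.T
    design = np.column_stack(
        [x * x, y * y, z * z, x * y, x * z, y * z, x, y, z, np.ones_like(x)]
    )
    _, _, vt = np.linalg.svd(design, full_matrices=False)
    w = vt[-1]

    A = np.array(
        [
            [w[0], w[3] / 2, w[4] / 2],
            [w[3] / 2, w[1], w[5] / 2],
            [w[4] / 2, w[5] / 2, w[2]],
        ]
    )
    b = w[6:9] / 2.0
    c = w[9]

    # Ellipsoid-ness: A must be definite. Flip overall sign so A is pos. def.
    eigval, eigvec = np.linalg.eigh(A)
    if np.all(eigval < 0):
        A, b, c = -A, -b, -c
        eigval, eigvec = -eigval[::-1], eigvec[:, ::-1]
    if np.any(eigval <= 0):
        raise ValueError("best-fit quadric is not an ellipsoid (degenerate points?)")

    center_local = np.linalg.solve(A, -b)
    k = b @ center_local + c  # value of the form at the center
    if k >= 0:
        raise ValueError("best-fit quadric is not an ellipsoid (degenerate points?)")
    # (x - x0)^T A (x - x0) = -k  ->  semi-axes sqrt(-k / eigval)
    axes_local = np.sqrt(-k / eigval)

    order = np.argsort(axes_local)[::-1]
    axes = axes_local[order] * scale
    rotation = eigvec[:, order]
    if np.linalg.det(rotation) < 0:
        rotation[:, 2] = -rotation[:, 2]
    center = mu + center_local * scale

    ell = Ellipsoid(center=center, semi_axes=axes, rotation=rotation)
    residual = float(np.sqrt(np.mean(np.square(ell.implicit(pts)))))
    return ell, residual


def _project_local(y: np.ndarray, axes: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Nearest point on the axis-aligned ellipsoid surface to a single point.

    Solves the Lagrange condition p_i = y_i / (1 + t / s_i^2) by bracketed
    1D root finding on f(t) = sum((s_i y_i / (s_i^2 + t))^2) - 1.
    """
    s2 = np.square(axes)
    y = np.asarray(y, dtype=float)
    # Handle exact center: project along the shortest axis.
    if np.all(np.abs(y) < 1e-300):
        p = np.zeros(3)
        p[np.argmin(axes)] = axes.min()
        return p

    def f(t: float) -> float:
        return float(np.sum(np.square(axes * y / (s2 + t))) - 1.0)

    lo = -s2.min()
    # f is strictly decreasing on (lo, inf); bracket the root.
    t_lo = lo + 1e-12 * s2.min()
    while f(t_lo) < 0 and t_lo > lo:
        t_lo = lo + (t_lo - lo) / 10.0
    hi = axes.max() * (np.linalg.norm(y) + axes.max())
    while f(hi) > 0:
        hi *= 2.0
    t = brentq(f, t_lo, hi, xtol=tol, rtol=4 * np.finfo(float).eps)
    return y / (1.0 + t / s2)


def project_to_ellipsoid(point: np.ndarray, e: Ellipsoid) -> np.ndarray:
    """Euclidean nearest point on the ellipsoid surface.

    Works for interior and exterior points; callers implementing a one-sided
    (confinement) constraint should test `e.contains` first and only project
    points that fall outside.
    """
    local = e.to_local(np.asarray(point, dtype=float))
    p = _project_local(local, e.semi_axes)
    return e.to_world(p)


def project_to_ellipsoid_many(points: np.ndarray, e: Ellipsoid, iters: int = 60) -> np.ndarray:
    """Vectorized nearest-point projection for many (near-surface) points.

    Newton iteration on the Lagrange parameter t of the nearest-point
    condition, started at t = 0.  For exterior points f(0) > 0 and f is
    strictly decreasing and convex on t > -min(s_i^2), so Newton from 0
    converges monotonically.  Intended for the simulator's shell constraint
    where points sit close to the surface; `project_to_ellipsoid` is the
    robust scalar fallback.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    local = e.to_local(pts)
    s2 = np.square(e.semi_axes)
    y2s2 = np.square(local) * s2  # (s_i y_i)^2
    t = np.zeros(len(local))
    for _ in range(iters):
        denom = s2 + t[:, None]
        f = np.sum(y2s2 / np.square(denom), axis=1) - 1.0
        fp = -2.0 * np.sum(y2s2 / denom**3, axis=1)
        step = f / fp
        t_new = t - step
        # Keep iterates inside the admissible half line.
        t_new = np.maximum(t_new, -s2.min() * (1 - 1e-12))
        if np.max(np.abs(t_new - t)) < 1e-14 * max(1.0, np.max(np.abs(t_new))):
            t = t_new
            break
        t = t_new
    proj = local / (1.0 + t[:, None] / s2)
    return e.to_world(proj)
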