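"""Tension-parameter fitting by grid search with ICP shape registration.

The contact-stability inequality |g_AB - g_P1| <= g_cnt <= g_AB + g_P1 prunes
the (gamma_AB, gamma_cnt) grid (gamma_P1 is the tension unit and fixed at 1);
for every admissible combination the two-cell equilibrium shape is computed,
rigidly registered onto the target membrane contour with the iterative
closest point algorithm, and scored by the RMSE of the remaining
point-to-point distances.  The combination with the smallest RMSE is the
fitted tension pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .ellipsoid import Ellipsoid
from .simulator import (
    EquilibriumShape,
    MinimizeOptions,
    TensionParams,
    mesh_curve_depth,
    minimize_shape,
)


@dataclass(frozen=True)
class GridSpec:
    """Regular tension grid: values min + k*step up to max (inclusive)."""

    min: float = 0.2
    max: float = 10.0
    step: float = 0.2
    gamma_p1: float = 1.0

    def __post_init__(self) -> None:
        if self.min <= 0 or self.step <= 0 or self.max < self.min:
            raise ValueError("grid requires min > 0, step > 0, max >= min")

    def values(self) -> list[Fraction]:
        """Grid values as exact rationals (endpoint-robust)."""
        lo, hi, st = (Fraction(str(x)) for x in (self.min, self.max, self.step))
        n = int((hi - lo) / st)
        return [lo + k * st for k in range(n + 1)]


def valid_tension_grid(g: GridSpec, g_cnt: GridSpec | None = None) -> list[tuple[float, float]]:
    """All (gamma_AB, gamma_cnt) grid pairs satisfying contact stability.

    `g` supplies the gamma_AB values (and gamma_P1); `g_cnt` the gamma_cnt
    values (defaults to the same grid).  The inequality
    |g_AB - g_P1| <= g_cnt <= g_AB + g_P1 is evaluated in exact rational
    arithmetic, since the admissible count is sensitive to endpoint ties (the
    full 0.2..10.0 step-0.2 grid admits exactly 514 pairs).  Pairs are
    returned in lexicographic order.
    """
    gp1 = Fraction(str(g.gamma_p1))
    vals_ab = g.values()
    vals_cnt = (g_cnt or g).values()
    out = []
    for ga in vals_ab:
        lo, hi = abs(ga - gp1), ga + gp1
        for gc in vals_cnt:
            if lo <= gc <= hi:
                out.append((float(ga), float(gc)))
    return out


# ---------------------------------------------------------------------------
# ICP


def _kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) mapping src onto dst."""
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    rot, _ = Rotation.align_vectors(dst - mu_d, src - mu_s)
    R = rot.as_matrix()
    return R, mu_d - R @ mu_s


def _principal_axes(points: np.ndarray) -> np.ndarray:
    _, _, vt = np.linalg.svd(points - points.mean(axis=0), full_matrices=False)
    R = vt.T
    if np.linalg.det(R) < 0:
        R[:, 2] = -R[:, 2]
    return R


def icp_align(
    source: np.ndarray,
    target: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Rigid ICP registration of source points onto a target point set.

    Correspondences are directional nearest neighbours from the (transformed)
    source to the target; each iteration re-estimates the least-squares rigid
    transform (no scaling).  Initialization is centroid alignment followed by
    principal-axes alignment, with the axis-sign ambiguity resolved by RMSE.

    Returns (rotation, translation, rmse): ``rotation @ source + translation``
    is the registered source, rmse the root mean square of the final
    nearest-neighbour distances (um).
    """
    src = np.asarray(source, dtype=float)
    dst = np.asarray(target, dtype=float)
    if src.ndim != 2 or src.shape[1] != 3 or len(src) < 3:
        raise ValueError("source must be an (n>=3, 3) array")
    if dst.ndim != 2 or dst.shape[1] != 3 or len(dst) < 3:
        raise ValueError("target must be an (n>=3, 3) array")
    if np.linalg.matrix_rank(src - src.mean(axis=0)) < 2:
        raise ValueError("source points are degenerate (collinear)")
    tree = cKDTree(dst)

    def rmse_of(R: np.ndarray, t: np.ndarray) -> float:
        d, _ = tree.query(src @ R.T + t)
        return float(np.sqrt(np.mean(d**2)))

    # initialization: principal axes with sign disambiguation
    A_s, A_d = _principal_axes(src), _principal_axes(dst)
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    best = None
    for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        S = np.diag([sx, sy, sx * sy])  # proper rotations only
        R0 = A_d @ S @ A_s.T
        t0 = mu_d - R0 @ mu_s
        r0 = rmse_of(R0, t0)
        if best is None or r0 < best[2]:
            best = (R0, t0, r0)
    R, t, rmse = best

    for _ in range(max_iter):
        moved = src @ R.T + t
        _, idx = tree.query(moved)
        R_new, t_new = _kabsch(src, dst[idx])
        new_rmse = rmse_of(R_new, t_new)
        if new_rmse > rmse:  # safeguard; NN + Kabsch is monotone in exact math
            break
        R, t = R_new, t_new
        if rmse - new_rmse < tol:
            rmse = new_rmse
            break
        rmse = new_rmse
    return R, t, rmse


# ---------------------------------------------------------------------------
# Grid-search fit


@dataclass
class FitResult:
    """Outcome of the tension grid search against one target shape."""

    table: pd.DataFrame  # gamma_ab, gamma_cnt, rmse_um, pressure_ratio, depth_um, converged
    best: tuple[float, float]
    rotation: np.ndarray
    translation: np.ndarray
    target_descriptor: dict = field(default_factory=dict)

    @property
    def best_row(self) -> pd.Series:
        m = self.table
        return m[(m.gamma_ab == self.best[0]) & (m.gamma_cnt == self.best[1])].iloc[0]


def grid_equilibria(
    pairs: list[tuple[float, float]],
    V_AB: float,
    V_P1: float,
    e: Ellipsoid | None,
    opts: MinimizeOptions | None = None,
) -> dict[tuple[float, float], EquilibriumShape | None]:
    """Minimize the model shape for every tension pair (None on failure).

    Exposed separately from `fit_tensions` so the (target-independent)
    equilibria can be reused across several target contours.
    """
    shapes: dict[tuple[float, float], EquilibriumShape | None] = {}
    for ga, gc in pairs:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                shapes[(ga, gc)] = minimize_shape(
                    TensionParams(ga, gc), V_AB, V_P1, e=e, opts=opts
                )
        except Exception as exc:  # noqa: BLE001 - record and continue the sweep
            warnings.warn(f"minimization failed at ({ga}, {gc}): {exc}", stacklevel=2)
            shapes[(ga, gc)] = None
    return shapes


def fit_tensions(
    target_contour: np.ndarray,
    V_AB: float,
    V_P1: float,
    e: Ellipsoid | None,
    g: GridSpec,
    g_cnt: GridSpec | None = None,
    opts: MinimizeOptions | None = None,
    shapes: dict | None = None,
) -> FitResult:
    """Grid search for the tensions whose equilibrium best matches a target.

    For every admissible (gamma_AB, gamma_cnt) pair the equilibrium shape is
    computed (or taken from a precomputed `shapes` cache), its mesh vertices
    are registered onto the target contour points by ICP, and the pair with
    the smallest registration RMSE wins.  Combinations whose minimization
    fails are recorded as unconverged and excluded from the argmin.
    """
    target = np.asarray(target_contour, dtype=float)
    pairs = valid_tension_grid(g, g_cnt)
    if shapes is None:
        shapes = grid_equilibria(pairs, V_AB, V_P1, e, opts)

    rows = []
    transforms = {}
    for ga, gc in pairs:
        shape = shapes.get((ga, gc))
        if shape is None or not shape.converged:
            rows.append((ga, gc, np.nan, np.nan, np.nan, False))
            continue
        R, t, rmse = icp_align(shape.mesh.vertices, target)
        transforms[(ga, gc)] = (R, t)
        rows.append((ga, gc, rmse, shape.pressure_ratio, mesh_curve_depth(shape), True))
    table = pd.DataFrame(
        rows,
        columns=["gamma_ab", "gamma_cnt", "rmse_um", "pressure_ratio", "depth_um", "converged"],
    )
    ok = table[table.converged]
    if ok.empty:
        raise RuntimeError("all tension combinations failed to converge")
    ib = ok.rmse_um.idxmin()
    best = (float(table.loc[ib, "gamma_ab"]), float(table.loc[ib, "gamma_cnt"]))
    R, t = transforms[best]
    return FitResult(
        table=table,
        best=best,
        rotation=R,
        translation=t,
        target_descriptor={
            "n_points": int(len(target)),
            "V_AB": float(V_AB),
            "V_P1": float(V_P1),
        },
    )
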