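"""Synthetic inputs for every pipeline stage.

Generates embryo-like geometries (eggshell ellipsoid plus cell volumes),
confocal-like two-channel stacks rendered from simulated equilibrium shapes,
kymographs with yolk-granule path lines, and cortical intensity traces — so
segmentation, fitting and measurement can be exercised end to end without any
recorded data.  All generators are pure functions of (config, seed).

An analytic double-bubble solver (two spherical caps and a spherical contact
cap satisfying Laplace's law and the Young tangent balance at the triple
circle) is included as a simulator-independent reference for free two-cell
shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .ellipsoid import Ellipsoid
from .imaging import (
    LABEL_AB,
    LABEL_EXTERIOR,
    LABEL_P1,
    ImageStack,
    Kymograph,
)
from .mesh import Body, Patch, TriSurfaceMesh, body_centroid, subdivide
from .simulator import EquilibriumShape


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic embryo.

    Geometry defaults emulate the two-cell C. elegans embryo: an eggshell of
    about 50 x 30 x 30 um with +-10% per-axis jitter, the AB:P1 volume split
    drawn from the known AB > P1 asymmetry (AB fraction 0.55-0.60), and the
    two cells jointly occupying 95% of the eggshell volume.  Rendering mimics
    a confocal stack: voxels 0.244 um in XY and 0.733 um in Z, a thin
    membrane shell blurred by an anisotropic PSF, Poisson photon noise plus
    Gaussian read noise.
    """

    seed: int = 0
    shell_axes: tuple[float, float, float] = (25.0, 15.0, 15.0)
    shell_jitter: float = 0.10
    ab_fraction_range: tuple[float, float] = (0.55, 0.60)
    packing: float = 0.95
    gamma_truth: tuple[float, float] = (3.4, 3.4)  # (gamma_AB, gamma_cnt)
    # rendering
    spacing: tuple[float, float, float] = (0.733, 0.244, 0.244)  # (dz, dy, dx) um
    margin: float = 2.0  # um of empty space around the shell
    membrane_sigma: float = 0.35  # um, membrane shell half-width
    psf_sigma: tuple[float, float, float] = (0.6, 0.2, 0.2)  # um (z, y, x)
    photon_scale: float = 200.0
    background: float = 5.0
    read_noise: float = 2.0
    # kymograph
    kymo_dt: float = 0.1  # s (100-ms frame interval)
    kymo_duration: float = 10.0  # s
    kymo_dx: float = 0.1  # um per column
    kymo_extent: float = 25.0  # um
    kymo_n_lines: int = 3
    kymo_noise: float = 0.3  # um positional jitter
    # intensity traces
    trace_t_max: float = 10.0  # min
    trace_dt: float = 0.5  # min
    trace_ab_base: float = 100.0
    trace_ab_ramp: float = 0.08  # fractional increase per minute in AB
    trace_p1_base: float = 100.0
    trace_noise: float = 0.0
    trace_gain: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.packing < 1):
            raise ValueError("packing fraction must lie in (0, 1)")
        lo, hi = self.ab_fraction_range
        if not (0 < lo <= hi < 1):
            raise ValueError("AB fraction range must lie in (0, 1)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacings must be positive")


# ---------------------------------------------------------------------------
# Geometry


def generate_embryo_geometry(c: SynthConfig) -> tuple[Ellipsoid, float, float]:
    """Jittered eggshell ellipsoid plus consistent cell volumes.

    V_AB + V_P1 equals the packing fraction of the shell volume exactly and
    the AB fraction is drawn uniformly from the configured range.
    """
    rng = np.random.default_rng(c.seed)
    axes = np.asarray(c.shell_axes, dtype=float)
    axes = axes * (1.0 + rng.uniform(-c.shell_jitter, c.shell_jitter, 3))
    axes = np.sort(axes)[::-1]
    e = Ellipsoid(center=np.zeros(3), semi_axes=axes)
    frac = rng.uniform(*c.ab_fraction_range)
    v_tot = c.packing * e.volume
    return e, frac * v_tot, (1.0 - frac) * v_tot


# ---------------------------------------------------------------------------
# Analytic double bubble (simulator-independent reference)


@dataclass
class AnalyticDoubleBubble:
    """Free two-cell equilibrium built from three spherical caps.

    The AB and P1 outer caps and the spherical contact cap share the triple
    circle (radius rho, in the plane x = 0, axis of symmetry x); sphere
    centres sit on the axis at a_AB, a_P1, a_cnt.  Pressures obey Laplace's
    law and the tangents the Young balance, so this is the exact equilibrium
    for given tensions and volumes — no eggshell.
    """

    gamma: tuple[float, float, float]  # (g_AB, g_P1, g_cnt)
    R_AB: float
    R_P1: float
    R_cnt: float
    rho: float
    a_AB: float
    a_P1: float
    a_cnt: float
    P_AB: float
    P_P1: float
    depth: float

    def sample_surface(self, n: int, seed: int = 0) -> np.ndarray:
        """Quasi-uniform surface point cloud (for registration targets)."""
        rng = np.random.default_rng(seed)
        pts = []
        specs = [
            (self.a_AB, self.R_AB, -1),   # AB outer cap occupies x <= 0 side
            (self.a_P1, self.R_P1, +1),
            (self.a_cnt, self.R_cnt, +1 if self.a_cnt < 0 else -1),
        ]
        for a, R, side in specs:
            m = 0
            take = max(n // 3, 8)
            while m < take:
                u = rng.normal(size=(4 * take, 3))
                u /= np.linalg.norm(u, axis=1, keepdims=True)
                p = u * R + np.array([a, 0.0, 0.0])
                p = p[np.sign(p[:, 0]) * side >= 0]
                pts.append(p[: take - m])
                m += len(p[: take - m])
        return np.vstack(pts)


def _halfspace_ball_volume(a: float, rho: float) -> float:
    """Volume of ball(center x=a, radius sqrt(a^2+rho^2)) with x <= 0."""
    R = np.sqrt(a * a + rho * rho)
    h = R + a  # cap height on the x > 0 side
    return 4.0 / 3.0 * np.pi * R**3 - np.pi * h * h * (3 * R - h) / 3.0


def analytic_double_bubble(
    gamma_ab: float, gamma_p1: float, gamma_cnt: float, V_AB: float, V_P1: float
) -> AnalyticDoubleBubble:
    """Solve the free double bubble for arbitrary admissible tensions.

    Unknowns are the axial sphere-centre offsets of the two outer caps, the
    (signed, inverse) contact offset and the triple-circle radius; equations
    are the two components of the Young tangent balance at the circle and the
    two volume constraints.  Laplace's law across the contact then holds
    identically and is verified on return.
    """
    if not abs(gamma_ab - gamma_p1) <= gamma_cnt <= gamma_ab + gamma_p1:
        raise ValueError("tensions violate the contact-stability inequality")

    def lens_volume(q: float, rho: float) -> float:
        # signed volume between the contact cap and the circle plane
        # (positive when the contact bulges toward P1, i.e. q > 0)
        a = -1.0 / q
        R = np.sqrt(a * a + rho * rho)
        if q > 0:
            return 4.0 / 3.0 * np.pi * R**3 - _halfspace_ball_volume(a, rho)
        return -_halfspace_ball_volume(a, rho)

    def tangent(a: float, rho: float, side: int) -> np.ndarray:
        R = np.sqrt(a * a + rho * rho)
        r = np.array([-a, rho]) / R
        t = np.array([-r[1], r[0]])
        if np.sign(t[0]) != side:
            t = -t
        return t

    def eqs(u):
        aA, aP, q, rho = u
        if rho <= 0 or q == 0:
            return [1e6] * 4
        ac = -1.0 / q
        tA = tangent(aA, rho, -1)
        tP = tangent(aP, rho, +1)
        tc = tangent(ac, rho, +1 if q > 0 else -1)
        bal = gamma_ab * tA + gamma_p1 * tP + gamma_cnt * tc
        vA = _halfspace_ball_volume(aA, rho) + lens_volume(q, rho)
        RP = np.sqrt(aP * aP + rho * rho)
        vP = (4.0 / 3.0 * np.pi * RP**3 - _halfspace_ball_volume(aP, rho)) - lens_volume(q, rho)
        return [bal[0], bal[1], (vA - V_AB) / V_AB, (vP - V_P1) / V_P1]

    R0 = (3 * V_AB / (4 * np.pi)) ** (1 / 3)
    R1 = (3 * V_P1 / (4 * np.pi)) ** (1 / 3)
    q0 = 0.05 if gamma_ab >= gamma_p1 else -0.05
    sol = least_squares(eqs, [-R0 / 2, R1 / 2, q0, 0.8 * R0],
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if sol.cost > 1e-16:
        raise RuntimeError(f"double-bubble solve did not close (cost={sol.cost:.2e})")
    aA, aP, q, rho = sol.x
    ac = -1.0 / q
    RA, RP = np.sqrt(aA**2 + rho**2), np.sqrt(aP**2 + rho**2)
    Rc = np.sqrt(ac**2 + rho**2)
    PA, PP = 2 * gamma_ab / RA, 2 * gamma_p1 / RP
    assert abs((PA - PP) - np.sign(q) * 2 * gamma_cnt / Rc) < 1e-8 * max(PA, PP)
    sag = Rc - np.sqrt(Rc**2 - rho**2)
    return AnalyticDoubleBubble(
        gamma=(gamma_ab, gamma_p1, gamma_cnt),
        R_AB=RA, R_P1=RP, R_cnt=Rc, rho=rho,
        a_AB=aA, a_P1=aP, a_cnt=ac,
        P_AB=PA, P_P1=PP,
        depth=float(np.sign(q) * sag),
    )


# ---------------------------------------------------------------------------
# Confocal-like rendering


def _body_trees(mesh: TriSurfaceMesh, extra_subdiv: int = 2):
    """KD-trees over oriented face centroids for point-in-body sign tests."""
    fine = mesh
    for _ in range(extra_subdiv):
        fine = subdivide(fine)
    out = {}
    for body in (Body.AB, Body.P1):
        tris, signs = fine.body_faces(body)
        v = fine.vertices[tris]
        centroids = v.mean(axis=1)
        normals = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]) * signs[:, None]
        nl = np.linalg.norm(normals, axis=1, keepdims=True)
        normals = normals / np.where(nl == 0, 1.0, nl)
        out[body] = (cKDTree(centroids), centroids, normals)
    all_v = fine.vertices[fine.triangles]
    all_c = all_v.mean(axis=1)
    return out, cKDTree(all_c)


def _render_grid(e: Ellipsoid, spacing: tuple[float, float, float], margin: float):
    """Voxel-centre physical coordinates covering the shell plus margin."""
    half = e.semi_axes.max() + margin
    lo = e.center - half
    hi = e.center + half
    sp = np.array(spacing)  # (dz, dy, dx)
    shape = np.ceil((hi - lo)[::-1] / sp).astype(int)  # (nz, ny, nx)
    zs = lo[2] + (np.arange(shape[0]) + 0.5) * sp[0]
    ys = lo[1] + (np.arange(shape[1]) + 0.5) * sp[1]
    xs = lo[0] + (np.arange(shape[2]) + 0.5) * sp[2]
    return shape, lo, (zs, ys, xs)


def _grid_points(zs, ys, xs) -> np.ndarray:
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])


def ground_truth_labels(
    shape: EquilibriumShape,
    e: Ellipsoid,
    spacing: float,
    margin: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelized body labels on a cubic grid (for segmentation scoring).

    Returns (labels, origin): labels use the segmentation conventions
    (LABEL_AB / LABEL_P1 / LABEL_EXTERIOR, no boundary class) on voxels of
    the given cubic pitch; origin is the physical coordinate of the grid
    corner.
    """
    grid_shape, lo, (zs, ys, xs) = _render_grid(e, (spacing,) * 3, margin)
    pts = _grid_points(zs, ys, xs)
    labels = np.full(len(pts), LABEL_EXTERIOR, dtype=np.int32)
    inside_shell = e.implicit(pts) <= 0
    trees, _ = _body_trees(shape.mesh)
    for body, lab in ((Body.AB, LABEL_AB), (Body.P1, LABEL_P1)):
        tree, cents, norms = trees[body]
        sel = np.where(inside_shell)[0]
        _, idx = tree.query(pts[sel])
        inside = np.einsum("ij,ij->i", pts[sel] - cents[idx], norms[idx]) < 0
        labels[sel[inside]] = lab
    return labels.reshape(grid_shape), lo


def render_stack(
    shape: EquilibriumShape,
    e: Ellipsoid,
    c: SynthConfig,
    noise: bool = True,
) -> tuple[ImageStack, ImageStack]:
    """Render membrane and eggshell channels of a simulated embryo.

    The membrane channel is a thin Gaussian shell around the cell surfaces
    (distance computed against a subdivided copy of the equilibrium mesh),
    convolved with an anisotropic Gaussian PSF; the eggshell channel is the
    analogous shell on the ellipsoid surface.  With noise=True, Poisson
    photon noise at the configured photon scale plus Gaussian read noise are
    applied (seeded by the config, so stacks are bit-reproducible).
    """
    if np.any(e.implicit(shape.mesh.vertices) > 1e-6):
        raise ValueError("equilibrium shape is not contained in the eggshell")
    grid_shape, lo, (zs, ys, xs) = _render_grid(e, c.spacing, c.margin)
    pts = _grid_points(zs, ys, xs)

    _, all_tree = _body_trees(shape.mesh)
    d_mem, _ = all_tree.query(pts)
    membrane = np.exp(-(d_mem**2) / (2 * c.membrane_sigma**2)).reshape(grid_shape)

    # first-order distance to the ellipsoid surface: phi / |grad phi|
    local = e.to_local(pts)
    q = local / e.semi_axes
    phi = np.sum(q * q, axis=1) - 1.0
    gnorm = 2.0 * np.linalg.norm(q / e.semi_axes, axis=1)
    d_shell = np.abs(phi) / np.maximum(gnorm, 1e-12)
    eggshell = np.exp(-(d_shell**2) / (2 * c.membrane_sigma**2)).reshape(grid_shape)

    sig_vox = np.asarray(c.psf_sigma) / np.asarray(c.spacing)
    membrane = ndimage.gaussian_filter(membrane, sig_vox, mode="nearest")
    eggshell = ndimage.gaussian_filter(eggshell, sig_vox, mode="nearest")

    if noise:
        rng = np.random.default_rng(c.seed)
        def noisy(img):
            counts = rng.poisson(c.photon_scale * img + c.background).astype(float)
            counts += rng.normal(0.0, c.read_noise, img.shape)
            return np.clip(counts, 0.0, None)
        membrane, eggshell = noisy(membrane), noisy(eggshell)
    else:
        membrane = c.photon_scale * membrane
        eggshell = c.photon_scale * eggshell

    return (
        ImageStack(membrane, tuple(c.spacing), channel="membrane"),
        ImageStack(eggshell, tuple(c.spacing), channel="eggshell"),
    )


def default_markers(
    shape: EquilibriumShape, e: Ellipsoid, spacing: float, margin: float = 2.0
) -> dict[int, tuple[int, int, int]]:
    """Seed voxels (AB centroid, P1 centroid, grid corner) on the cubic grid."""
    _, lo, _ = _render_grid(e, (spacing,) * 3, margin)
    out = {LABEL_EXTERIOR: (0, 0, 0)}
    for body, lab in ((Body.AB, LABEL_AB), (Body.P1, LABEL_P1)):
        cpt = body_centroid(shape.mesh, body)
        idx = np.floor((cpt - lo) / spacing).astype(int)[::-1]  # (z, y, x)
        out[lab] = tuple(int(i) for i in idx)
    return out


# ---------------------------------------------------------------------------
# Kymographs and intensity traces


def synth_kymograph(velocity: float, c: SynthConfig) -> Kymograph:
    """Kymograph with path lines of the given slope (um/s) plus jitter."""
    rng = np.random.default_rng(c.seed)
    times = np.arange(0.0, c.kymo_duration + 1e-9, c.kymo_dt)
    n_cols = int(round(c.kymo_extent / c.kymo_dx))
    img = np.zeros((len(times), n_cols))
    cols = (np.arange(n_cols) + 0.5) * c.kymo_dx
    lines = []
    span = velocity * c.kymo_duration
    x0s = np.linspace(0.15, 0.6, c.kymo_n_lines) * (c.kymo_extent - abs(span)) + max(-span, 0)
    for x0 in x0s:
        x = x0 + velocity * times + rng.normal(0.0, c.kymo_noise, len(times))
        lines.append(np.column_stack([times, x]))
        img += np.exp(-((cols[None, :] - x[:, None]) ** 2) / (2 * 0.4**2))
    return Kymograph(image=img, dt=c.kymo_dt, dx=c.kymo_dx, path_lines=lines)


@dataclass
class RawTraces:
    """Raw (unnormalized) cortical intensity inputs plus generation truth."""

    time: np.ndarray  # minutes
    I_AB: np.ndarray
    I_P1: np.ndarray
    area_AB: float
    area_P1: float
    truth_I_AB_norm: np.ndarray
    truth_I_P1_norm: np.ndarray


def synth_intensity_traces(c: SynthConfig, area_AB: float = 1.2, area_P1: float = 1.0) -> RawTraces:
    """Cortical NMY-2-like traces: AB ramps up, P1 stays flat.

    The configured gain multiplies both raw traces (normalization must cancel
    it); the returned truth traces are the noise-free normalized values.
    """
    rng = np.random.default_rng(c.seed)
    t = np.arange(0.0, c.trace_t_max + 1e-9, c.trace_dt)
    ab_clean = c.trace_ab_base * (1.0 + c.trace_ab_ramp * t)
    p1_clean = np.full_like(t, c.trace_p1_base)
    merged = (area_AB * ab_clean + area_P1 * p1_clean) / (area_AB + area_P1)
    div = merged.mean()
    ab = c.trace_gain * (ab_clean + rng.normal(0.0, c.trace_noise, t.shape))
    p1 = c.trace_gain * (p1_clean + rng.normal(0.0, c.trace_noise, t.shape))
    return RawTraces(
        time=t, I_AB=ab, I_P1=p1, area_AB=area_AB, area_P1=area_P1,
        truth_I_AB_norm=ab_clean / div, truth_I_P1_norm=p1_clean / div,
    )
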