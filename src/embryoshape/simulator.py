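"""Surface-energy minimization of the two-cell embryo.

The two blastomeres are modelled as fluid bodies bounded by three surface
patches (AB outer, P1 outer, contact), each carrying a uniform tension.  The
total mechanical energy is

    E = gamma_AB * A_AB + gamma_P1 * A_P1 + gamma_cnt * A_cnt

and the equilibrium shape minimizes E subject to (i) fixed body volumes and
(ii) one-sided confinement to the eggshell ellipsoid.  Minimization is
projected gradient descent on the vertex positions with backtracking line
search, interleaved with three rounds of triangle subdivision; each accepted
step restores both volume constraints exactly (to numerical tolerance) by a
minimal-norm Newton correction along the volume gradients, and clamps any
vertex that left the eggshell back onto its surface.

Intracellular pressures are the volume-constraint sensitivities dE/dV at the
optimum, extracted as least-squares Lagrange multipliers of the stationarity
condition (a finite-difference estimate is provided as an independent
cross-check).  Tensions are dimensionless (relative to gamma_P1), lengths in
um, so pressures come out in tension/um.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ellipsoid import Ellipsoid, project_to_ellipsoid_many
from .mesh import (
    Body,
    Patch,
    TriSurfaceMesh,
    area_gradient,
    body_centroid,
    enclosed_volume,
    equiangulate,
    make_two_cube_mesh,
    smooth_tangential,
    subdivide,
    surface_area,
    vertex_lumped_areas,
    volume_gradient,
)

#: side length of the initial cubes, um (20 voxels at 0.733 um)
INIT_CUBE_SIDE = 14.7


class ConvergenceError(RuntimeError):
    """Raised when the minimizer fails to reach its convergence criteria."""


@dataclass(frozen=True)
class TensionParams:
    """Surface tensions of the three patches, relative to gamma_P1 = 1."""

    gamma_ab: float
    gamma_cnt: float
    gamma_p1: float = 1.0

    def __post_init__(self) -> None:
        if min(self.gamma_ab, self.gamma_cnt, self.gamma_p1) <= 0:
            raise ValueError("surface tensions must be strictly positive")

    @property
    def is_valid(self) -> bool:
        """Contact stability: |g_AB - g_P1| <= g_cnt <= g_AB + g_P1."""
        lo = abs(self.gamma_ab - self.gamma_p1)
        hi = self.gamma_ab + self.gamma_p1
        eps = 1e-9 * max(1.0, hi)
        return lo - eps <= self.gamma_cnt <= hi + eps

    def patch_weights(self) -> np.ndarray:
        """Tension per patch label, indexable by Patch value."""
        w = np.empty(3)
        w[int(Patch.AB_OUTER)] = self.gamma_ab
        w[int(Patch.P1_OUTER)] = self.gamma_p1
        w[int(Patch.CONTACT)] = self.gamma_cnt
        return w


def check_tension_validity(t: TensionParams) -> bool:
    """True iff the tensions satisfy the contact-stability triangle inequality.

    Outside it, the energy favours complete detachment (contact tension too
    high) or engulfment of one cell by the other (too low), so no two-cell
    equilibrium with a stable contact exists.
    """
    return t.is_valid


def total_energy(mesh: TriSurfaceMesh, t: TensionParams) -> float:
    """Tension-weighted total patch area (tension * um^2)."""
    w = t.patch_weights()
    return float(sum(w[int(p)] * surface_area(mesh, p) for p in Patch))


@dataclass
class EquilibriumShape:
    """Result of a shape minimization."""

    mesh: TriSurfaceMesh
    tensions: TensionParams
    energy: float
    pressures: dict[Body, float]
    target_volumes: dict[Body, float]
    volume_residuals: dict[Body, float]
    converged: bool
    info: dict = field(default_factory=dict)

    @property
    def pressure_ratio(self) -> float:
        """P_AB / P_P1 (only meaningful for two-body shapes)."""
        return self.pressures[Body.AB] / self.pressures[Body.P1]


@dataclass
class MinimizeOptions:
    """Solver schedule and tolerances.

    The schedule is: minimize on the initial mesh, then three rounds of
    subdivision each followed by minimization, then a final polish phase
    without mesh-maintenance passes (so the stored state is stationary and
    clean Lagrange multipliers can be extracted).
    """

    faces_per_edge: int = 2           # initial cube-face resolution
    subdivisions: int = 3
    max_iters: tuple = (800, 500, 400, 350)   # per level (len = subdivisions + 1)
    polish_iters: int = 600
    rel_energy_tol: float = 1e-8      # level stop: relative drop per window
    polish_tol: float = 1e-5          # polish stop & convergence criterion
    stall_window: int = 30
    volume_tol: float = 1e-9          # relative volume residual after projection
    smooth_every: int = 30
    step_init: float = 0.5
    max_backtracks: int = 12
    shell_active_tol: float = 1e-9    # level-set value above which a vertex counts as on-shell


# ---------------------------------------------------------------------------
# Core solver


class _Solver:
    """Projected-gradient minimizer over one or two constrained bodies."""

    def __init__(
        self,
        mesh: TriSurfaceMesh,
        tri_weights_fn,
        targets: dict[Body, float],
        shell: Ellipsoid | None,
        opts: MinimizeOptions,
    ):
        self.mesh = mesh
        self._weights_fn = tri_weights_fn
        self.targets = dict(targets)
        # Working targets: the coarse initial mesh cannot always hold the full
        # target volume inside the shell (an inscribed polyhedron is smaller
        # than the smooth body), so targets are approached gradually and the
        # remainder deferred to finer levels.
        self.targets_now = dict(targets)
        self.shell = shell
        self.opts = opts
        self.step = opts.step_init
        self.n_iters = 0
        self.energy_history: list[float] = []

    # -- measures ---------------------------------------------------------

    def tri_weights(self) -> np.ndarray:
        return self._weights_fn(self.mesh)

    def energy(self) -> float:
        v = self.mesh.vertices[self.mesh.triangles]
        areas = 0.5 * np.linalg.norm(
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
        )
        return float(np.sum(self.tri_weights() * areas))

    def volumes(self) -> dict[Body, float]:
        return {b: enclosed_volume(self.mesh, b, check_closed=False) for b in self.targets}

    # -- constraints --------------------------------------------------------

    def shell_clamp(self) -> None:
        if self.shell is None:
            return
        phi = self.shell.implicit(self.mesh.vertices)
        out = phi > 0
        if np.any(out):
            self.mesh.vertices[out] = project_to_ellipsoid_many(
                self.mesh.vertices[out], self.shell
            )

    def active_shell(self) -> np.ndarray:
        if self.shell is None:
            return np.zeros(len(self.mesh.vertices), dtype=bool)
        return self.shell.implicit(self.mesh.vertices) >= -self.opts.shell_active_tol

    def enforce_volumes(self, targets: dict[Body, float] | None = None,
                        max_newton: int = 25) -> dict[Body, float]:
        """Restore volume constraints by minimal-norm correction along the
        volume gradients, re-clamping the shell after each Newton pass.

        At shell-active vertices the outward component of a growth correction
        is blocked by the clamp, so for a body that must grow the tangentially
        projected gradient is used (it reflects the achievable volume change);
        shrinking bodies use the raw gradient, since pulling off the shell is
        allowed.  Stops early when residuals stagnate (target infeasible at
        the current resolution).  Returns the final relative residuals.
        """
        targets = self.targets_now if targets is None else targets
        bodies = list(targets)
        scales = np.array([max(abs(targets[b]), 1e-12) for b in bodies])
        prev = None
        for _ in range(max_newton):
            vols = self.volumes()
            resid = np.array([targets[b] - vols[b] for b in bodies])
            rel = np.abs(resid) / scales
            if np.all(rel < self.opts.volume_tol):
                break
            if prev is not None and np.max(rel) > 0.98 * prev:
                break  # stagnated: infeasible at this resolution
            prev = np.max(rel)
            active = self.active_shell()
            normals = (
                self.shell.surface_normal(self.mesh.vertices[active])
                if self.shell is not None and np.any(active)
                else None
            )
            grads = []
            for b, r in zip(bodies, resid):
                g = volume_gradient(self.mesh, b)
                if r > 0 and normals is not None:
                    gn = np.sum(g[active] * normals, axis=1)
                    g[active] -= gn[:, None] * normals
                grads.append(g)
            gram = np.array([[np.sum(ga * gb) for gb in grads] for ga in grads])
            try:
                lam = np.linalg.solve(gram, resid)
            except np.linalg.LinAlgError:
                break
            dx = sum(l * g for l, g in zip(lam, grads))
            # damp very large corrections (early volume ramp)
            mx = np.max(np.linalg.norm(dx, axis=1))
            if mx > 2.0:
                dx *= 2.0 / mx
            self.mesh.vertices = self.mesh.vertices + dx
            self.shell_clamp()
        vols = self.volumes()
        return {b: (vols[b] - targets[b]) / max(abs(targets[b]), 1e-12) for b in bodies}

    def ramp_volumes(self, factor: float = 1.25, max_rounds: int = 100) -> bool:
        """Grow body volumes geometrically toward their final targets.

        The initial cubes hold far less volume than the measured cells, so the
        targets are approached in bounded multiplicative steps, letting the
        surfaces bulge outward smoothly instead of jumping in one Newton step.
        If growth stalls (the current mesh resolution cannot hold more volume
        inside the shell), the working targets are frozen at the achieved
        volumes and the remainder is deferred to the next subdivision level.
        Returns True when the full targets were reached.
        """
        for _ in range(max_rounds):
            vols = self.volumes()
            inter = {}
            at_target = True
            for b, tgt in self.targets.items():
                cur = vols[b]
                nxt = float(np.clip(tgt, cur / factor, cur * factor))
                if abs(nxt - tgt) > 1e-9 * abs(tgt):
                    at_target = False
                inter[b] = nxt
            rel = self.enforce_volumes(inter)
            achieved = self.volumes()
            stalled = any(abs(r) > 1e-6 for r in rel.values())
            if stalled:
                # freeze working targets at what the mesh can actually hold
                self.targets_now = {
                    b: min(achieved[b], self.targets[b]) for b in self.targets
                }
                self.enforce_volumes()
                return False
            self.targets_now = dict(inter)
            # a few descent steps keep the surface well-behaved during growth
            for _ in range(3):
                self.descent_step()
            if at_target:
                self.targets_now = dict(self.targets)
                self.enforce_volumes()
                return True
        self.targets_now = dict(self.targets)
        self.enforce_volumes()
        return False

    # -- descent ------------------------------------------------------------

    def _projected_direction(self) -> tuple[np.ndarray, np.ndarray, float]:
        """Constraint-tangent, preconditioned descent direction.

        Returns (direction, energy gradient, directional derivative).
        """
        gE = area_gradient(self.mesh, self.tri_weights())
        inv_m = 1.0 / np.maximum(vertex_lumped_areas(self.mesh)[:, None], 1e-12)
        grads_raw = [volume_gradient(self.mesh, b) for b in self.targets]

        # One-sided shell constraint, active-set treatment: an on-shell vertex
        # stays clamped (motion restricted to the shell tangent plane) only
        # where the shell actually pushes on the surface, i.e. where the
        # residual force -(gE - sum lambda_i gV_i) points outward.  Vertices
        # the shell is not pressing on are released and move freely.
        active = self.active_shell()
        clamped = active
        normals_all = None
        if np.any(active):
            normals_all = self.shell.surface_normal(self.mesh.vertices[active])
            lam0 = self._estimate_multipliers(gE, grads_raw, active, normals_all)
            resid = gE - sum(l * g for l, g in zip(lam0, grads_raw))
            rn = np.sum(resid[active] * normals_all, axis=1)
            keep = rn < 0  # shell reaction force positive
            clamped = np.zeros_like(active)
            clamped[np.where(active)[0][keep]] = True
            normals_all = normals_all[keep]

        def tangent(field: np.ndarray) -> np.ndarray:
            if normals_all is None or not np.any(clamped):
                return field
            out = field.copy()
            fn = np.sum(out[clamped] * normals_all, axis=1)
            out[clamped] -= fn[:, None] * normals_all
            return out

        gE_t = tangent(gE)
        grads = [tangent(g) for g in grads_raw]
        d = -gE_t * inv_m

        # Project out the volume-gradient components in the preconditioner
        # metric, so the step is first-order volume preserving and remains a
        # descent direction (the correction basis is M^-1 g, the Gram matrix
        # g_i^T M^-1 g_j).
        basis = [g * inv_m for g in grads]
        gram = np.array([[np.sum(ga * cb) for cb in basis] for ga in grads])
        rhs = np.array([np.sum(g * d) for g in grads])
        try:
            lam = np.linalg.solve(gram, rhs)
        except np.linalg.LinAlgError:
            lam = np.linalg.lstsq(gram, rhs, rcond=None)[0]
        for l, c in zip(lam, basis):
            d -= l * c
        return d, gE, float(np.sum(d * gE_t))

    @staticmethod
    def _estimate_multipliers(gE, grads, active, normals) -> np.ndarray:
        """Least-squares Lagrange multipliers with shell normals projected out."""
        gE_t = gE.copy()
        gn = np.sum(gE_t[active] * normals, axis=1)
        gE_t[active] -= gn[:, None] * normals
        gts = []
        for g in grads:
            gt = g.copy()
            gn = np.sum(gt[active] * normals, axis=1)
            gt[active] -= gn[:, None] * normals
            gts.append(gt)
        gram = np.array([[np.sum(ga * gb) for gb in gts] for ga in gts])
        rhs = np.array([np.sum(g * gE_t) for g in gts])
        try:
            return np.linalg.solve(gram, rhs)
        except np.linalg.LinAlgError:
            return np.linalg.lstsq(gram, rhs, rcond=None)[0]

    def descent_step(self) -> bool:
        """One line-searched descent step with exact constraint restoration.

        The trial scale both backtracks and expands: constraint restoration
        perturbs the energy by a small noise floor, so very small trial steps
        are uninformative and the step size must be able to recover after a
        sequence of failures.
        """
        E0 = self.energy()
        d, gE, slope = self._projected_direction()
        if slope >= 0:
            self.energy_history.append(E0)
            return False
        x0 = self.mesh.vertices.copy()

        def trial(t: float) -> float:
            self.mesh.vertices = x0 + t * d
            self.shell_clamp()
            self.enforce_volumes()
            return self.energy()

        accept_margin = 1e-13 * max(1.0, abs(E0))
        t = float(np.clip(self.step, 1e-4, 10.0))
        E1 = trial(t)
        if E1 < E0 - accept_margin:
            # expand while it keeps paying off
            best_t, best_E, best_x = t, E1, self.mesh.vertices.copy()
            for _ in range(4):
                t2 = best_t * 2.0
                if t2 > 10.0:
                    break
                E2 = trial(t2)
                if E2 < best_E - accept_margin:
                    best_t, best_E, best_x = t2, E2, self.mesh.vertices.copy()
                else:
                    break
            self.mesh.vertices = best_x
            self.step = best_t
            self.n_iters += 1
            self.energy_history.append(best_E)
            return True
        for _ in range(self.opts.max_backtracks):
            t *= 0.4
            if t < 1e-5:
                break
            E1 = trial(t)
            if E1 < E0 - accept_margin:
                self.step = t
                self.n_iters += 1
                self.energy_history.append(E1)
                return True
        self.mesh.vertices = x0
        self.enforce_volumes()
        self.step = max(self.step * 0.4, 1e-4)
        self.energy_history.append(E0)
        return False

    def maintain_mesh(self) -> None:
        equiangulate(self.mesh)
        smooth_tangential(self.mesh, relax=0.4)
        self.shell_clamp()
        self.enforce_volumes()

    def run_level(self, max_iter: int, smooth_every: int | None = None,
                  tol: float | None = None) -> None:
        window = self.opts.stall_window
        tol = self.opts.rel_energy_tol if tol is None else tol
        stalls = 0
        self.energy_history = []
        self.step = max(self.step, self.opts.step_init)
        for it in range(max_iter):
            ok = self.descent_step()
            if smooth_every and (it + 1) % smooth_every == 0:
                self.maintain_mesh()
            h = self.energy_history
            if len(h) > window:
                drop = (h[-window - 1] - h[-1]) / max(abs(h[-1]), 1e-12)
                if drop < tol:
                    return
            if not ok:
                stalls += 1
                if stalls > 6:
                    return
            else:
                stalls = 0

    def subdivide(self) -> None:
        self.mesh = subdivide(self.mesh)
        self.shell_clamp()
        self.enforce_volumes()
        self.step = self.opts.step_init


def _patch_weight_fn(t: TensionParams):
    def fn(mesh: TriSurfaceMesh) -> np.ndarray:
        return t.patch_weights()[mesh.patch]
    return fn


# ---------------------------------------------------------------------------
# Public operations


def init_configuration(e: Ellipsoid, V_AB: float, V_P1: float,
                       faces_per_edge: int = 2) -> TriSurfaceMesh:
    """Initial two-cube configuration.

    Two cubes of side 14.7 um sharing one (triangulated) face, centred in the
    eggshell and aligned along its major axis; the AB cube sits on the
    anterior (negative major-axis) side.  Volume constraints are enforced by
    the solver afterwards.
    """
    if V_AB <= 0 or V_P1 <= 0:
        raise ValueError("target volumes must be positive")
    if V_AB + V_P1 >= 0.995 * e.volume:
        raise ValueError(
            f"target volumes ({V_AB + V_P1:.1f} um^3) do not fit inside the "
            f"eggshell ({e.volume:.1f} um^3)"
        )
    mesh = make_two_cube_mesh(
        INIT_CUBE_SIDE, faces_per_edge=faces_per_edge,
        center=e.center, axis=e.major_axis,
    )
    # pre-scale about the centre so the cube pair starts inside the shell
    phi = e.implicit(mesh.vertices)
    if np.any(phi > 0):
        local = e.to_local(mesh.vertices) / e.semi_axes
        r = np.linalg.norm(local, axis=1).max()
        s = 0.98 / r
        if s < 0.2:
            raise ValueError("initial cubes cannot be scaled to fit inside the eggshell")
        mesh.vertices = (mesh.vertices - e.center) * s + e.center
    return mesh


def minimize_shape(
    t: TensionParams,
    V_AB: float,
    V_P1: float,
    e: Ellipsoid | None = None,
    opts: MinimizeOptions | None = None,
) -> EquilibriumShape:
    """Minimize the two-cell surface energy under volume and shell constraints.

    Parameters
    ----------
    t : tension parameters (must satisfy the contact-stability inequality)
    V_AB, V_P1 : target body volumes, um^3
    e : eggshell ellipsoid, or None for a free double bubble
    opts : solver schedule; defaults are suitable for embryo-scale problems

    Returns
    -------
    EquilibriumShape with the final mesh, energy, per-body pressures and
    convergence diagnostics.
    """
    if not t.is_valid:
        raise ValueError(
            "tensions violate the contact-stability inequality "
            "|g_AB - g_P1| <= g_cnt <= g_AB + g_P1"
        )
    opts = opts or MinimizeOptions()
    if e is not None:
        mesh = init_configuration(e, V_AB, V_P1, opts.faces_per_edge)
    else:
        mesh = make_two_cube_mesh(INIT_CUBE_SIDE, faces_per_edge=opts.faces_per_edge)
    targets = {Body.AB: float(V_AB), Body.P1: float(V_P1)}
    return _minimize_mesh(mesh, _patch_weight_fn(t), targets, e, opts, tensions=t)


def minimize_single_body(
    mesh: TriSurfaceMesh,
    gamma: float,
    V: float,
    e: Ellipsoid | None = None,
    opts: MinimizeOptions | None = None,
) -> EquilibriumShape:
    """Degenerate one-cell mode: minimize a single closed surface at fixed volume.

    Used for validation against the Laplace closed form P = 2*gamma/R.
    """
    opts = opts or MinimizeOptions(max_iters=(300, 200, 150, 120), polish_iters=100)
    t = TensionParams(gamma_ab=gamma, gamma_cnt=gamma, gamma_p1=gamma)
    targets = {Body.AB: float(V)}
    return _minimize_mesh(mesh.copy(), _patch_weight_fn(t), targets, e, opts, tensions=t)


def _minimize_mesh(mesh, weights_fn, targets, shell, opts, tensions) -> EquilibriumShape:
    solver = _Solver(mesh, weights_fn, targets, shell, opts)
    solver.shell_clamp()
    solver.targets_now = solver.volumes()

    levels = list(opts.max_iters[: opts.subdivisions + 1])
    while len(levels) < opts.subdivisions + 1:
        levels.append(levels[-1])
    for li, max_iter in enumerate(levels):
        solver.ramp_volumes()
        solver.run_level(max_iter, smooth_every=opts.smooth_every)
        if li < opts.subdivisions:
            solver.maintain_mesh()
            solver.subdivide()
    if solver.targets_now != solver.targets:
        solver.ramp_volumes()
    # final polish: no mesh maintenance, so the state is stationary
    solver.step = min(solver.step, opts.step_init)
    solver.run_level(opts.polish_iters, smooth_every=None, tol=opts.polish_tol)

    resid = solver.enforce_volumes(solver.targets)
    energy = solver.energy()
    converged = all(abs(r) < 1e-4 for r in resid.values())
    h = solver.energy_history
    if len(h) > opts.stall_window:
        drop = (h[-opts.stall_window - 1] - h[-1]) / max(abs(h[-1]), 1e-12)
        converged = converged and drop < 10 * opts.polish_tol
    shape = EquilibriumShape(
        mesh=solver.mesh,
        tensions=tensions,
        energy=energy,
        pressures={},
        target_volumes=dict(targets),
        volume_residuals=resid,
        converged=converged,
        info={
            "iterations": solver.n_iters,
            "final_step": solver.step,
            "n_triangles": len(solver.mesh.triangles),
            "energy_history_tail": h[-10:],
        },
    )
    shape.pressures = _multiplier_pressures(shape, shell, opts)
    if not converged:
        warnings.warn("shape minimization did not meet convergence criteria", stacklevel=2)
    return shape


# ---------------------------------------------------------------------------
# Pressures


def _multiplier_pressures(shape: EquilibriumShape, shell: Ellipsoid | None,
                          opts: MinimizeOptions) -> dict[Body, float]:
    mesh = shape.mesh
    t = shape.tensions
    gE = area_gradient(mesh, t.patch_weights()[mesh.patch])
    bodies = list(shape.target_volumes)
    grads = [volume_gradient(mesh, b) for b in bodies]
    if shell is not None:
        active = shell.implicit(mesh.vertices) >= -opts.shell_active_tol
        if np.any(active):
            normals = shell.surface_normal(mesh.vertices[active])
            gn = np.sum(gE[active] * normals, axis=1)
            gE = gE.copy()
            gE[active] -= gn[:, None] * normals
            for g in grads:
                gn = np.sum(g[active] * normals, axis=1)
                g[active] -= gn[:, None] * normals
    gram = np.array([[np.sum(ga * gb) for gb in grads] for ga in grads])
    rhs = np.array([np.sum(g * gE) for g in grads])
    lam = np.linalg.solve(gram, rhs)
    return {b: float(l) for b, l in zip(bodies, lam)}


def body_pressures(shape: EquilibriumShape, t: TensionParams | None = None) -> tuple[float, float]:
    """Per-body pressures relative to the exterior (tension/um).

    Computed as the least-squares Lagrange multipliers of the stationarity
    condition grad E = sum_i P_i grad V_i (shell reaction forces projected
    out), i.e. the sensitivities dE/dV of the constrained optimum.
    """
    if not shape.converged:
        raise ValueError("pressures are only defined for a converged shape")
    if t is not None and t != shape.tensions:
        scale = t.gamma_p1 / shape.tensions.gamma_p1
        return (shape.pressures[Body.AB] * scale, shape.pressures[Body.P1] * scale)
    return (shape.pressures[Body.AB], shape.pressures[Body.P1])


def body_pressures_fd(shape: EquilibriumShape, e: Ellipsoid | None = None,
                      rel: float = 0.005, polish_iters: int = 150) -> dict[Body, float]:
    """Finite-difference pressures dE/dV by re-minimizing at V*(1 +/- rel).

    Independent cross-check of the multiplier-based `body_pressures`; slower,
    intended for validation.
    """
    opts = MinimizeOptions(subdivisions=0, max_iters=(polish_iters,),
                           polish_iters=polish_iters)
    out = {}
    weights_fn = _patch_weight_fn(shape.tensions)
    for b, V in shape.target_volumes.items():
        energies = []
        for s in (1.0 + rel, 1.0 - rel):
            targets = dict(shape.target_volumes)
            targets[b] = V * s
            solver = _Solver(shape.mesh.copy(), weights_fn, targets, e, opts)
            solver.enforce_volumes()
            solver.run_level(polish_iters, smooth_every=None)
            solver.enforce_volumes()
            energies.append(solver.energy())
        out[b] = (energies[0] - energies[1]) / (2 * rel * V)
    return out


# ---------------------------------------------------------------------------
# Curve depth


def mesh_curve_depth(shape: EquilibriumShape) -> float:
    """Signed depth of the contact-surface bulge, um.

    A plane is fitted (total least squares) to the triple line — the boundary
    ring of the contact patch — and the depth is the signed distance of the
    farthest contact vertex from that plane, positive when the contact bulges
    from AB toward P1 and negative for the opposite direction.
    """
    mesh = shape.mesh
    ring = mesh.triple_line_vertices()
    if len(ring) < 3:
        raise ValueError("degenerate contact: fewer than 3 boundary vertices")
    pts = mesh.vertices[ring]
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    normal = vt[-1]
    # orient the normal from AB toward P1
    to_p1 = body_centroid(mesh, Body.P1) - centroid
    if np.dot(normal, to_p1) < 0:
        normal = -normal
    contact_vids = np.unique(mesh.triangles[mesh.patch_mask(Patch.CONTACT)])
    dists = (mesh.vertices[contact_vids] - centroid) @ normal
    return float(dists[np.argmax(np.abs(dists))])
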