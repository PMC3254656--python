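"""Physics of the energy minimizer: symmetry, Laplace law, covariances."""

import numpy as np
import pytest

from embryoshape.ellipsoid import Ellipsoid
from embryoshape.mesh import Body, Patch, make_icosphere, make_two_cube_mesh
from embryoshape.simulator import (
    INIT_CUBE_SIDE,
    MinimizeOptions,
    TensionParams,
    body_pressures,
    body_pressures_fd,
    check_tension_validity,
    init_configuration,
    mesh_curve_depth,
    minimize_single_body,
    total_energy,
)
from embryoshape.synth import analytic_double_bubble

from .conftest import (
    COARSE_OPTS,
    FAST_OPTS,
    V_AB_BUBBLE,
    V_P1_BUBBLE,
    quiet_minimize,
)


def fit_sphere(points):
    """Algebraic least-squares sphere fit -> (center, radius, rms residual)."""
    A = np.column_stack([2 * points, np.ones(len(points))])
    b = np.sum(points**2, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c = sol[:3]
    R = np.sqrt(sol[3] + c @ c)
    rms = np.sqrt(np.mean((np.linalg.norm(points - c, axis=1) - R) ** 2))
    return c, R, rms


def patch_vertices(mesh, label):
    return mesh.vertices[np.unique(mesh.triangles[mesh.patch_mask(label)])]


class TestTensionParams:
    @pytest.mark.parametrize(
        ("gab", "gcnt", "valid"),
        [
            (1.0, 1.0, True),     # equal tensions
            (3.4, 3.4, True),     # fitted heterogeneous values: 2.4 <= 3.4 <= 4.4
            (5.0, 0.2, False),    # detachment regime: 0.2 < |5 - 1|
            (1.0, 2.0, True),     # upper boundary inclusive
            (3.0, 2.0, True),     # lower boundary inclusive
            (1.0, 2.1, False),    # engulfment regime
        ],
    )
    def test_contact_stability(self, gab, gcnt, valid):
        assert check_tension_validity(TensionParams(gab, gcnt)) is valid

    def test_nonpositive_tension_rejected(self):
        with pytest.raises(ValueError):
            TensionParams(-1.0, 1.0)


class TestTotalEnergy:
    def test_unit_tensions_give_total_area(self):
        mesh = make_two_cube_mesh(INIT_CUBE_SIDE)
        expected = 11 * INIT_CUBE_SIDE**2  # 5 + 5 outer faces + 1 shared face
        assert total_energy(mesh, TensionParams(1.0, 1.0)) == pytest.approx(expected)

    def test_linearity_in_tensions(self):
        mesh = make_two_cube_mesh(INIT_CUBE_SIDE)
        e1 = total_energy(mesh, TensionParams(1.3, 0.7, gamma_p1=1.1))
        e2 = total_energy(mesh, TensionParams(2.6, 1.4, gamma_p1=2.2))
        assert e2 == pytest.approx(2 * e1)


class TestInitConfiguration:
    SHELL = Ellipsoid(center=np.array([2.0, 1.0, -1.0]),
                      semi_axes=np.array([25.0, 15.0, 15.0]))

    def test_construction(self):
        mesh = init_configuration(self.SHELL, 12000.0, 9000.0)
        assert mesh.is_body_closed(Body.AB) and mesh.is_body_closed(Body.P1)
        # both cubes congruent before constraint enforcement
        from embryoshape.mesh import enclosed_volume

        v_ab = enclosed_volume(mesh, Body.AB)
        assert v_ab == pytest.approx(enclosed_volume(mesh, Body.P1))
        # contact face normal along the shell's major axis
        tris = mesh.triangles[mesh.patch_mask(Patch.CONTACT)]
        v = mesh.vertices[tris]
        n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        assert np.abs(np.abs(n @ self.SHELL.major_axis) - 1).max() < 1e-8

    def test_infeasible_volumes_raise(self):
        with pytest.raises(ValueError, match="fit inside"):
            init_configuration(self.SHELL, 0.6 * self.SHELL.volume, 0.5 * self.SHELL.volume)


class TestSymmetricBubble:
    def test_contact_is_planar(self, symmetric_bubble):
        ring = patch_vertices(symmetric_bubble.mesh, Patch.CONTACT)
        centroid = ring.mean(axis=0)
        _, _, vt = np.linalg.svd(ring - centroid, full_matrices=False)
        dev = np.abs((ring - centroid) @ vt[-1]).max()
        diameter = 2 * np.linalg.norm(ring - centroid, axis=1).max()
        assert dev < 0.01 * diameter

    def test_pressures_equal(self, symmetric_bubble):
        p_ab, p_p1 = body_pressures(symmetric_bubble)
        assert p_ab == pytest.approx(p_p1, rel=0.01)

    def test_depth_is_zero(self, symmetric_bubble):
        assert abs(mesh_curve_depth(symmetric_bubble)) < 0.1


class TestFreeDoubleBubble:
    """60:40 free bubble vs the analytic spherical-cap equilibrium."""

    def test_outer_patches_are_spherical_caps(self, free_bubble_6040):
        for label in (Patch.AB_OUTER, Patch.P1_OUTER):
            pts = patch_vertices(free_bubble_6040.mesh, label)
            _, R, rms = fit_sphere(pts)
            assert rms < 0.01 * R

    def test_laplace_pressures(self, free_bubble_6040):
        shape = free_bubble_6040
        p = {
            Patch.AB_OUTER: shape.pressures[Body.AB],
            Patch.P1_OUTER: shape.pressures[Body.P1],
        }
        for label, pressure in p.items():
            _, R, _ = fit_sphere(patch_vertices(shape.mesh, label))
            assert pressure == pytest.approx(2.0 / R, rel=0.02)
        # pressure difference vs contact curvature
        _, Rc, _ = fit_sphere(patch_vertices(shape.mesh, Patch.CONTACT))
        dp = shape.pressures[Body.P1] - shape.pressures[Body.AB]
        assert abs(dp) == pytest.approx(2.0 / Rc, rel=0.02)

    def test_matches_analytic_solution(self, free_bubble_6040):
        ref = analytic_double_bubble(1.0, 1.0, 1.0, V_AB_BUBBLE, V_P1_BUBBLE)
        shape = free_bubble_6040
        _, RA, _ = fit_sphere(patch_vertices(shape.mesh, Patch.AB_OUTER))
        _, RP, _ = fit_sphere(patch_vertices(shape.mesh, Patch.P1_OUTER))
        assert RA == pytest.approx(ref.R_AB, rel=0.01)
        assert RP == pytest.approx(ref.R_P1, rel=0.01)
        assert shape.pressures[Body.AB] == pytest.approx(ref.P_AB, rel=0.02)
        assert shape.pressures[Body.P1] == pytest.approx(ref.P_P1, rel=0.02)
        # smaller cell has the higher pressure; contact bulges toward AB
        assert mesh_curve_depth(shape) == pytest.approx(ref.depth, abs=0.06)

    def test_equal_tension_films_meet_at_120_degrees(self, free_bubble_6040):
        # Tangents of the fitted spherical caps at the triple circle, oriented
        # away from the line along each film (AB film runs toward -x, P1
        # toward +x; the bubble axis is x by construction).
        mesh = free_bubble_6040.mesh
        ring = mesh.vertices[mesh.triple_line_vertices()]

        def film_tangents(label, away_sign):
            c, _, _ = fit_sphere(patch_vertices(mesh, label))
            r = ring - c
            radial = ring - ring.mean(axis=0)
            t = np.cross(np.cross(r, radial), r)
            t /= np.linalg.norm(t, axis=1, keepdims=True)
            flip = np.sign(t[:, 0]) != away_sign
            t[flip] = -t[flip]
            return t

        t_ab = film_tangents(Patch.AB_OUTER, -1)
        t_p1 = film_tangents(Patch.P1_OUTER, +1)
        cosang = np.einsum("ij,ij->i", t_ab, t_p1)
        mean_angle = np.degrees(np.arccos(np.clip(cosang.mean(), -1, 1)))
        assert mean_angle == pytest.approx(120.0, abs=2.0)

    def test_multiplier_pressures_match_finite_difference(self, free_bubble_6040):
        fd = body_pressures_fd(free_bubble_6040, e=None, polish_iters=120)
        for body in (Body.AB, Body.P1):
            assert free_bubble_6040.pressures[body] == pytest.approx(fd[body], rel=0.02)

    def test_energy_decreased_monotonically(self, free_bubble_6040):
        tail = free_bubble_6040.info["energy_history_tail"]
        assert all(b <= a + 1e-9 for a, b in zip(tail, tail[1:]))


class TestCovariances:
    def test_tension_scaling(self):
        s1 = quiet_minimize(TensionParams(1.0, 1.0), V_AB_BUBBLE, V_P1_BUBBLE,
                            e=None, opts=COARSE_OPTS)
        s2 = quiet_minimize(TensionParams(2.0, 2.0, gamma_p1=2.0),
                            V_AB_BUBBLE, V_P1_BUBBLE, e=None, opts=COARSE_OPTS)
        for body in (Body.AB, Body.P1):
            assert s2.pressures[body] == pytest.approx(2 * s1.pressures[body], rel=0.005)
        # equilibrium geometry unchanged by the scaling (vertices may slide
        # tangentially between runs, so compare shape summaries): cap radii
        # and curve depth within 0.5%
        for label in (Patch.AB_OUTER, Patch.P1_OUTER):
            _, r1, _ = fit_sphere(patch_vertices(s1.mesh, label))
            _, r2, _ = fit_sphere(patch_vertices(s2.mesh, label))
            assert r2 == pytest.approx(r1, rel=0.005)
        assert mesh_curve_depth(s2) == pytest.approx(
            mesh_curve_depth(s1), rel=0.005, abs=0.005
        )

    def test_body_swap_mirrors_depth(self):
        ga, gc = 1.6, 1.3
        fwd = quiet_minimize(TensionParams(ga, gc), V_AB_BUBBLE, V_P1_BUBBLE,
                             e=None, opts=COARSE_OPTS)
        # swapped system: relabel bodies and tensions, then rescale so the
        # P1 tension is again the unit
        swapped = quiet_minimize(
            TensionParams(1.0 / ga, gc / ga), V_P1_BUBBLE, V_AB_BUBBLE,
            e=None, opts=COARSE_OPTS,
        )
        d_fwd = mesh_curve_depth(fwd)
        d_swp = mesh_curve_depth(swapped)
        assert d_swp == pytest.approx(-d_fwd, abs=0.15)

    def test_one_extra_subdivision_leaves_result_invariant(self):
        base = quiet_minimize(TensionParams(1.0, 1.0), V_AB_BUBBLE, V_P1_BUBBLE,
                              e=None, opts=FAST_OPTS)
        finer_opts = MinimizeOptions(
            faces_per_edge=1, subdivisions=4,
            max_iters=(400, 300, 250, 200, 200), polish_iters=500,
        )
        fine = quiet_minimize(TensionParams(1.0, 1.0), V_AB_BUBBLE, V_P1_BUBBLE,
                              e=None, opts=finer_opts)
        assert fine.pressure_ratio == pytest.approx(base.pressure_ratio, rel=0.01)
        assert mesh_curve_depth(fine) == pytest.approx(
            mesh_curve_depth(base), abs=0.01 * abs(mesh_curve_depth(base)) + 0.02
        )


class TestSingleBody:
    def test_laplace_closed_form(self):
        R = 8.0
        sphere = make_icosphere(R * 1.08, 1)  # start off the equilibrium radius
        opts = MinimizeOptions(subdivisions=2, max_iters=(200, 150, 120),
                               polish_iters=200)
        shape = minimize_single_body(sphere, gamma=1.4, V=4 / 3 * np.pi * R**3,
                                     opts=opts)
        assert shape.pressures[Body.AB] == pytest.approx(2 * 1.4 / R, rel=0.02)

    def test_pressure_requires_convergence(self, symmetric_bubble):
        import dataclasses

        broken = dataclasses.replace(symmetric_bubble, converged=False)
        with pytest.raises(ValueError):
            body_pressures(broken)


class TestEmbryoShapes:
    def test_homogeneous_contact_bulges_toward_ab(self, homo_embryo):
        assert mesh_curve_depth(homo_embryo) < 0

    def test_heterogeneous_contact_bulges_toward_p1(self, hetero_embryo):
        assert mesh_curve_depth(hetero_embryo) > 0

    def test_shell_constraint_respected(self, homo_embryo, embryo_geometry):
        e, _, _ = embryo_geometry
        # implicit value -> distance via the gradient scale; semi-axes O(10 um)
        assert e.implicit(homo_embryo.mesh.vertices).max() < 1e-6

    def test_energy_equals_weighted_patch_areas(self, hetero_embryo):
        assert hetero_embryo.energy == pytest.approx(
            total_energy(hetero_embryo.mesh, hetero_embryo.tensions), rel=1e-12
        )

    def test_volume_constraints_met(self, homo_embryo):
        for body, resid in homo_embryo.volume_residuals.items():
            assert abs(resid) < 1e-4
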