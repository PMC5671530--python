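"""Finite-element core verification: patch test, tangent consistency,
stress post-processing conventions, and solver behaviour."""

import numpy as np
import pytest

from npwtox.fem import (
    ConvergenceError,
    NonlinearFE,
    pressure_stress,
    principal_stresses,
    von_mises,
)
from npwtox.geometry import LimbGeometryParams, MeshOptions, build_limb_geometry
from npwtox.macro import NPWTLoadCase, build_problem, max_deformation, solve_macro
from npwtox.materials import MUSCLE

from conftest import rect_axisym_mesh


class TestStressPostprocessing:
    def test_hydrostatic_pressure_sign_convention(self):
        """p = -tr(sigma)/3: a hydrostatic compression diag(-a,-a,-a) must
        give exactly +a (positive pressure stress in compression)."""
        a = 0.375  # binary-exact so the identity holds bit-for-bit
        sig2 = np.array([[[-a, 0.0], [0.0, -a]]])
        sig33 = np.array([-a])
        assert pressure_stress(sig2, sig33)[0] == a

    def test_principal_ordering(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = rng.standard_normal((2, 2))
            sig2 = (m + m.T)[None] / 2
            sig33 = rng.standard_normal(1)
            s1, s2, s3 = principal_stresses(sig2, sig33)
            assert s1 >= s2 >= s3
            # trace invariance
            tr = sig2[0, 0, 0] + sig2[0, 1, 1] + sig33[0]
            assert s1 + s2 + s3 == pytest.approx(tr, rel=1e-12, abs=1e-12)

    def test_von_mises_hydrostatic_is_zero(self):
        sig2 = np.array([[[-1.0, 0.0], [0.0, -1.0]]])
        assert von_mises(sig2, np.array([-1.0]))[0] == pytest.approx(0.0, abs=1e-12)


class TestPatchTest:
    def test_hydrostatic_external_pressure(self):
        """Uniform pressure on all external faces of a solid MR cylinder must
        reproduce a uniform hydrostatic state: p equals the applied pressure
        within 1% and the deviatoric (von Mises) stress is near zero."""
        mesh = rect_axisym_mesh(radius=0.02, height=0.02, nr=6, nz=6)
        fe = NonlinearFE(mesh, {"muscle": MUSCLE}, mode="axisymmetric")
        fe.fix(mesh.facet_nodes("axis"), 0)
        fe.fix(mesh.facet_nodes("bottom"), 1)  # symmetry plane of a 2H cylinder
        a = 0.01  # MPa
        fe.add_pressure(mesh.facets[mesh.facet_ids("outer")], a)
        fe.add_pressure(mesh.facets[mesh.facet_ids("top")], a)
        sol = fe.solve(n_steps=4)
        sig2, sig33 = fe.element_stress(sol.u)
        p = pressure_stress(sig2, sig33)
        assert np.abs(p - a).max() < 0.01 * a
        assert von_mises(sig2, sig33).max() < 0.02 * a

    def test_zero_load_zero_displacement(self, limb_mesh_coarse):
        res = solve_macro(limb_mesh_coarse, NPWTLoadCase(0.0))
        assert np.abs(res.u).max() == 0.0
        assert max_deformation(res) == 0.0


class TestTangent:
    def test_tangent_matches_residual_derivative(self, limb_mesh_coarse):
        """K * v must equal the directional derivative of the residual
        (including follower-pressure load stiffness)."""
        fe = build_problem(limb_mesh_coarse, NPWTLoadCase(50.0))
        rng = np.random.default_rng(5)
        u = 1e-4 * rng.standard_normal((len(limb_mesh_coarse.nodes), 2))
        u.reshape(-1)[fe.fixed] = 0.0
        v = rng.standard_normal(fe.ndof)
        v[fe.fixed] = 0.0
        v /= np.linalg.norm(v)
        K = fe.tangent(u, 1.0)
        eps = 1e-6
        rp = fe.residual(u + eps * v.reshape(-1, 2), 1.0)
        rm = fe.residual(u - eps * v.reshape(-1, 2), 1.0)
        dr_fd = (rp - rm) / (2 * eps)
        dr_K = K @ v
        mask = ~fe.fixed
        err = np.linalg.norm((dr_K - dr_fd)[mask]) / np.linalg.norm(dr_fd[mask])
        assert err < 1e-5


class TestSolver:
    def test_small_load_linearity(self, limb_mesh_coarse):
        """At 1-2 mmHg the response is in the linear regime: doubling the
        suction must double the displacement field to within 2%."""
        r1 = solve_macro(limb_mesh_coarse, NPWTLoadCase(1.0), n_steps=2)
        r2 = solve_macro(limb_mesh_coarse, NPWTLoadCase(2.0), n_steps=2)
        num = np.linalg.norm(r2.u - 2.0 * r1.u)
        assert num / np.linalg.norm(r2.u) < 0.02

    def test_equilibrium_residual_at_convergence(self, macro_125):
        steps = macro_125.solution.info["steps"]
        assert steps[-1][0] == pytest.approx(1.0)
        fe = build_problem(macro_125.mesh, macro_125.load)
        r = fe.residual(macro_125.u, 1.0)
        free = ~fe.fixed
        fext = fe.external_force(macro_125.u, 1.0)
        rel = np.linalg.norm(r[free]) / np.linalg.norm(fext[free])
        assert rel < 1e-8

    def test_mesh_convergence_of_max_deformation(self, limb_params):
        """One refinement level changes the reported maximum deformation by
        less than 3%."""
        coarse = build_limb_geometry(limb_params, MeshOptions(scale=0.7))
        fine = build_limb_geometry(limb_params, MeshOptions(scale=1.4))
        d = {}
        for name, mesh in (("c", coarse), ("f", fine)):
            d[name] = max_deformation(solve_macro(mesh, NPWTLoadCase(125.0)))
        assert abs(d["f"] - d["c"]) / d["f"] < 0.03

    def test_nonconvergence_raises_with_diagnostics(self):
        """A grossly overloaded foam-free problem must fail loudly, reporting
        the last load factor, not hang or return garbage."""
        mesh = rect_axisym_mesh(radius=0.02, height=0.02, nr=3, nz=3)
        fe = NonlinearFE(mesh, {"muscle": MUSCLE}, mode="axisymmetric")
        fe.fix(mesh.facet_nodes("axis"), 0)
        fe.fix(mesh.facet_nodes("bottom"), (0, 1))
        fe.add_pressure(mesh.facets[mesh.facet_ids("top")], 1e4)  # absurd load
        with pytest.raises(ConvergenceError) as exc:
            fe.solve(n_steps=2, max_iter=8, min_step=1.0 / 8.0)
        assert exc.value.load_factor is not None

    def test_inverted_mesh_rejected(self):
        mesh = rect_axisym_mesh(nr=2, nz=2)
        mesh.elements[0] = mesh.elements[0][::-1]  # flip orientation
        with pytest.raises(ValueError, match="[Ii]nverted"):
            NonlinearFE(mesh, {"muscle": MUSCLE})
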