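"""Oxygen diffusion tests: oracle comparison, conservation, coupling identities."""

from dataclasses import replace

import numpy as np
import pytest

from npwtox.capillary import CapillaryLoadCase, build_capillary_mesh, solve_capillary
from npwtox.diffusion import (
    ConcentrationField,
    DiffusionParams,
    DiffusionSystem,
    area_change,
    export_binary_mask,
    oxygenated_area,
    solve_diffusion,
)
from npwtox.units import UM


@pytest.fixture(scope="module")
def dsys(cap_mesh):
    return DiffusionSystem(cap_mesh, DiffusionParams())


@pytest.fixture(scope="module")
def baseline(dsys):
    return dsys.solve(None, 0.0)


@pytest.fixture(scope="module")
def coupled_setup(cap_mesh, dsys):
    res = solve_capillary(cap_mesh, CapillaryLoadCase(-0.005, -0.012, 0.5))
    return res.pressure()


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(d_tissue=-1.0),
            dict(threshold=0.0),
            dict(wall_concentration=5.0),  # below threshold
            dict(dtau=0.2),  # > tau_end
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            DiffusionParams(**kwargs)


class TestBaseline:
    def test_maximum_principle(self, baseline):
        """Pure diffusion stays within [initial, wall] values (small discrete
        tolerance for the lumped Q1 scheme)."""
        tol = 1e-3 * 40.32
        assert baseline.values.min() > -tol
        assert baseline.values.max() < 40.32 + tol

    def test_radially_monotone(self, dsys, baseline):
        """Baseline concentration decreases outward along every ray."""
        C = baseline.values.reshape(dsys.n_rings, dsys.n_theta)
        assert (np.diff(C, axis=0) <= 1e-9 * 40.32).all()

    def test_mass_balance(self, dsys, baseline):
        """Total mass gained equals the boundary influx (closure < 0.1%)."""
        m = baseline.info["mass_history"]
        influx = baseline.info["boundary_influx"].sum()
        assert abs((m[-1] - m[0]) - influx) < 1e-3 * abs(m[-1] - m[0])

    def test_1d_radial_oracle(self, cap_mesh):
        """The 2D FE baseline must match an independent 1D radial
        finite-difference solve to within 0.5% relative L2."""
        from conftest import radial_diffusion_oracle

        mesh = build_capillary_mesh(refine=2.0, h_tissue=1.5)
        params = DiffusionParams()
        sys2 = DiffusionSystem(mesh, params)
        fe = sys2.solve(None, 0.0)
        oracle = radial_diffusion_oracle(
            sys2.ring_r,
            params.d_wall * 1e-4,
            params.d_tissue * 1e-4,
            mesh.metadata["geometry"].wall_outer_radius * UM,
            params.wall_concentration,
            params.tau_end,
            params.dtau,
        )
        C = fe.values.reshape(sys2.n_rings, sys2.n_theta)[:, 0]
        ref = oracle(sys2.ring_r)
        err = np.linalg.norm(C - ref) / np.linalg.norm(ref)
        assert err < 0.005

    def test_long_time_uniform(self, cap_mesh):
        """K_P = 0, tau -> large: zero-flux outer boundary drives the field to
        the uniform wall concentration (the threshold-degenerate steady state)."""
        params = DiffusionParams(tau_end=8.0, dtau=0.05)
        c = solve_diffusion(cap_mesh, params)
        assert np.abs(c.values - 40.32).max() < 0.02 * 40.32


class TestCoupling:
    def test_kp_zero_identical_to_baseline(self, dsys, baseline, coupled_setup):
        again = dsys.solve(None, 0.0)
        assert np.array_equal(again.values, baseline.values)
        coupled0 = dsys.solve(coupled_setup, 0.0)
        assert np.array_equal(coupled0.values, baseline.values)

    def test_kp_without_pressure_field_raises(self, dsys):
        with pytest.raises(ValueError):
            dsys.solve(None, 1e-5)

    def test_superposition_matches_direct_solve(self, dsys, coupled_setup):
        """C_baseline + K_P * C_unit must equal the direct coupled solve."""
        k_p = 7.3e-6
        base, unit = dsys.baseline_and_unit_drift(coupled_setup)
        direct = dsys.solve(coupled_setup, k_p)
        combo = base.values + k_p * unit.values
        assert np.allclose(direct.values, combo, rtol=1e-9, atol=1e-9)

    def test_coupling_direction(self, dsys, baseline):
        """With p decaying radially outward (compressed capillary) and K_P>0
        the oxygenated area shrinks; flipping the sign of p reverses it."""
        cent = dsys.mesh.element_centroids()
        r = np.hypot(cent[:, 0], cent[:, 1])
        p_comp = 1e-3 * (5 * UM / np.maximum(r, 5 * UM)) ** 2  # decays outward
        f0 = dsys.oxygenated_area(baseline)
        dec = dsys.solve(p_comp, 2e-5)
        inc = dsys.solve(-p_comp, 2e-5)
        assert dsys.oxygenated_area(dec) < f0
        assert dsys.oxygenated_area(inc) > f0

    def test_steady_zero_flux_identity(self, dsys):
        """At steady state with a radius-only p field and zero-flux outer
        boundary the total flux vanishes, so within each region
        C - (s K_P / D) p is constant (the extended Fick's law rearranged)."""
        cent = dsys.mesh.element_centroids()
        r = np.hypot(cent[:, 0], cent[:, 1])
        g = 1e-3 / (40 * UM)
        p_lin = g * r  # MPa, linear in radius
        k_p = 5e-6
        params = replace(dsys.params, tau_end=8.0, dtau=0.05)
        sys2 = DiffusionSystem(dsys.mesh, params)
        c = sys2.solve(p_lin, k_p)
        p_node = sys2.project_pressure(p_lin)
        d_t = params.d_tissue  # cm^2/s; k_p in the same units
        phi = c.values - (params.drift_scale * k_p / d_t) * p_node
        # evaluate on tissue nodes away from the wall/tissue interface
        rn = np.hypot(sys2.nodes[:, 0], sys2.nodes[:, 1])
        sel = rn > 8 * UM
        spread = phi[sel].max() - phi[sel].min()
        rng = c.values.max() - c.values.min()
        assert spread < 0.02 * rng


class TestMetrics:
    def test_uniform_fields(self, dsys):
        ones = ConcentrationField(dsys.mesh, np.full(dsys.nn, 40.32), dsys.params, 0.1)
        fives = ConcentrationField(dsys.mesh, np.full(dsys.nn, 5.0), dsys.params, 0.1)
        assert dsys.oxygenated_area(ones) == 1.0
        assert dsys.oxygenated_area(fives) == 0.0

    def test_radial_step_profile(self, dsys):
        """C >= threshold only inside 20 µm: the fraction equals the annulus
        area ratio (20^2-5.5^2)/(40^2-5.5^2) ~= 0.2355."""
        rn = np.hypot(dsys.nodes[:, 0], dsys.nodes[:, 1])
        vals = np.where(rn < 20 * UM, 40.0, 0.0)
        f = dsys.oxygenated_area(ConcentrationField(dsys.mesh, vals, dsys.params, 0.1))
        analytic = (20**2 - 5.5**2) / (40**2 - 5.5**2)
        assert f == pytest.approx(analytic, abs=0.02)
        assert analytic == pytest.approx(0.2355, abs=1e-3)

    def test_area_change_arithmetic(self):
        assert area_change(0.5, 0.5) == 0.0
        assert area_change(0.25, 0.5) == -50.0
        assert area_change(0.675, 0.5) == pytest.approx(35.0)
        with pytest.raises(ZeroDivisionError):
            area_change(0.3, 0.0)

    def test_module_level_wrapper(self, baseline):
        assert oxygenated_area(baseline) == pytest.approx(
            DiffusionSystem(baseline.mesh, baseline.params).oxygenated_area(baseline)
        )


class TestMask:
    def test_uniform_above_threshold_is_white_annulus(self, dsys):
        ones = ConcentrationField(dsys.mesh, np.full(dsys.nn, 40.0), dsys.params, 0.1)
        img = export_binary_mask(ones, size=256)
        # white fraction equals annulus area / bounding-square area
        frac = (img == 255).mean()
        analytic = np.pi * (40**2 - 5**2) / 80**2
        assert frac == pytest.approx(analytic, abs=0.02)

    def test_baseline_rotational_symmetry(self, baseline):
        img = export_binary_mask(baseline, size=256)
        diff = (img != np.rot90(img)).mean()
        assert diff < 0.01

    def test_mask_area_agrees_with_quadrature(self, dsys, baseline):
        img = export_binary_mask(baseline, size=1024)
        # restrict to the tissue annulus (exclude wall ring and exterior)
        n = img.shape[0]
        ax = np.linspace(-40 * UM, 40 * UM, n)
        X, Y = np.meshgrid(ax, -ax)
        R = np.hypot(X, Y)
        tissue = (R >= 5.5 * UM) & (R <= 40 * UM)
        frac_pix = (img[tissue] == 255).mean()
        frac_fe = dsys.oxygenated_area(baseline)
        assert abs(frac_pix - frac_fe) < 0.01

    def test_png_written(self, baseline, tmp_path):
        path = tmp_path / "mask.png"
        export_binary_mask(baseline, size=64, path=path)
        assert path.exists() and path.stat().st_size > 0
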