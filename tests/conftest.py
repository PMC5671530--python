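"""Shared fixtures: meshes and solved states reused across the suite.

The expensive finite-element solves are session-scoped so each is run once;
tests that only need kinematic or geometric checks use the coarse mesh.
"""

from __future__ import annotations

import numpy as np
import pytest

from npwtox.capillary import (
    CapillaryLoadCase,
    build_capillary_mesh,
    solve_capillary,
)
from npwtox.geometry import (
    FILLER,
    MUSCLE,
    LimbGeometryParams,
    Mesh,
    MeshOptions,
    build_limb_geometry,
)
from npwtox.macro import NPWTLoadCase, solve_macro

SUCTION_LEVELS = (70.0, 125.0, 150.0)


@pytest.fixture(scope="session")
def limb_params():
    return LimbGeometryParams()


@pytest.fixture(scope="session")
def limb_mesh(limb_params):
    """Default-resolution limb mesh (the stated 1 mm / 5 mm grading)."""
    return build_limb_geometry(limb_params)


@pytest.fixture(scope="session")
def limb_mesh_coarse(limb_params):
    return build_limb_geometry(limb_params, MeshOptions(scale=0.6))


@pytest.fixture(scope="session")
def macro_sweep(limb_mesh):
    """Macro solutions at the three therapy suction levels (session cache)."""
    return {s: solve_macro(limb_mesh, NPWTLoadCase(s)) for s in SUCTION_LEVELS}


@pytest.fixture(scope="session")
def macro_125(macro_sweep):
    return macro_sweep[125.0]


@pytest.fixture(scope="session")
def cap_mesh():
    return build_capillary_mesh()


@pytest.fixture(scope="session")
def cap_mesh_annulus():
    """Bare annulus (no square frame), free outer boundary: Lame benchmark."""
    return build_capillary_mesh(frame=False, h_tissue=2.0)


@pytest.fixture(scope="session")
def lame_case(cap_mesh_annulus):
    """Luminal-only load at 0.05 kPa on the bare annulus (small-strain regime)."""
    return solve_capillary(
        cap_mesh_annulus, CapillaryLoadCase(0.0, 0.0, 0.05), n_steps=2
    )


@pytest.fixture(scope="session")
def pipeline_125():
    """Full pipeline run at 125 mmHg with the default ROI layers."""
    from npwtox.pipeline import PipelineConfig, run_pipeline

    return run_pipeline(PipelineConfig(suction_levels=(125.0,), classify=False))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def rect_axisym_mesh(radius=0.02, height=0.02, nr=8, nz=8, region=MUSCLE, name="muscle"):
    """Solid cylinder (axisymmetric rectangle) with tagged boundary facets."""
    r = np.linspace(0.0, radius, nr + 1)
    z = np.linspace(0.0, height, nz + 1)
    R, Z = np.meshgrid(r, z, indexing="ij")
    nid = np.arange((nr + 1) * (nz + 1)).reshape(nr + 1, nz + 1)
    quads = np.stack(
        [
            nid[:-1, :-1].ravel(),
            nid[1:, :-1].ravel(),
            nid[1:, 1:].ravel(),
            nid[:-1, 1:].ravel(),
        ],
        axis=1,
    )
    nodes = np.stack([R.ravel(), Z.ravel()], axis=1)
    facets, tags = [], []
    for j in range(nz):  # axis r=0 (normal -r) and outer r=R (+r)
        facets.append((nid[0, j + 1], nid[0, j]))
        tags.append(1)
        facets.append((nid[-1, j], nid[-1, j + 1]))
        tags.append(2)
    for i in range(nr):  # bottom z=0 (-z) and top z=H (+z)
        facets.append((nid[i, 0], nid[i + 1, 0]))
        tags.append(3)
        facets.append((nid[i + 1, -1], nid[i, -1]))
        tags.append(4)
    return Mesh(
        nodes=nodes,
        elements=quads,
        region=np.full(len(quads), region),
        region_names={region: name},
        facets=np.asarray(facets),
        facet_tags=np.asarray(tags),
        facet_tag_names={1: "axis", 2: "outer", 3: "bottom", 4: "top"},
        metadata={"kind": "rect"},
    )


def compound_lame_plane_strain(p_in, a, b, c, mat_wall, mat_tissue):
    """Analytic two-layer thick-wall cylinder under internal pressure.

    Plane-strain linear elasticity with u(r) = A r + B / r per layer;
    returns callables sigma_rr(r), sigma_tt(r). Independent oracle for the
    capillary structural solver (small-strain limit of Mooney-Rivlin with
    mu = 2(C1+C2) and the penalty bulk modulus).
    """

    def lame_consts(m):
        mu = m.mu0
        lam = m.kappa - 2.0 * mu / 3.0
        return mu, lam

    mu1, la1 = lame_consts(mat_wall)
    mu2, la2 = lame_consts(mat_tissue)

    def srr(mu, la, A, B, r):
        return 2.0 * (la + mu) * A - 2.0 * mu * B / r**2

    # unknowns [A1, B1, A2, B2]
    M = np.zeros((4, 4))
    rhs = np.zeros(4)
    # sigma_rr1(a) = -p_in
    M[0] = [2 * (la1 + mu1), -2 * mu1 / a**2, 0, 0]
    rhs[0] = -p_in
    # displacement continuity at b
    M[1] = [b, 1.0 / b, -b, -1.0 / b]
    # sigma_rr continuity at b
    M[2] = [2 * (la1 + mu1), -2 * mu1 / b**2, -2 * (la2 + mu2), 2 * mu2 / b**2]
    # sigma_rr2(c) = 0
    M[3] = [0, 0, 2 * (la2 + mu2), -2 * mu2 / c**2]
    A1, B1, A2, B2 = np.linalg.solve(M, rhs)

    def sigma_rr(r):
        r = np.asarray(r, dtype=float)
        inner = r < b
        out = np.where(
            inner,
            2 * (la1 + mu1) * A1 - 2 * mu1 * B1 / r**2,
            2 * (la2 + mu2) * A2 - 2 * mu2 * B2 / r**2,
        )
        return out

    def sigma_tt(r):
        r = np.asarray(r, dtype=float)
        inner = r < b
        return np.where(
            inner,
            2 * (la1 + mu1) * A1 + 2 * mu1 * B1 / r**2,
            2 * (la2 + mu2) * A2 + 2 * mu2 * B2 / r**2,
        )

    return sigma_rr, sigma_tt


def radial_diffusion_oracle(ring_radii, d_wall, d_tissue, wall_r, c_wall, tau_end, dtau, n=1500):
    """Independent 1D radial finite-difference solve of the baseline problem.

    Conservative implicit-Euler discretisation of (1/r) d/dr(r D dC/dr) on a
    fine grid, Dirichlet at the lumen surface, zero flux at the Krogh radius.
    Returns an interpolant C(r).
    """
    import scipy.sparse as sp
    import scipy.sparse.linalg as spla

    r0, r1 = ring_radii[0], ring_radii[-1]
    r = np.linspace(r0, r1, n)
    h = r[1] - r[0]
    rf = 0.5 * (r[:-1] + r[1:])  # face radii
    Df = np.where(rf < wall_r, d_wall, d_tissue)
    # flux F_{i+1/2} = -Df * rf * (C_{i+1}-C_i)/h ; dC/dt = -(1/r_i) dF/dr
    main = np.zeros(n)
    lower = np.zeros(n - 1)
    upper = np.zeros(n - 1)
    w = Df * rf / h
    main[1:-1] = (w[:-1] + w[1:]) / (r[1:-1] * h)
    lower[:-1] = -w[:-1] / (r[1:-1] * h)
    upper[1:] = -w[1:] / (r[1:-1] * h)
    # outer node: zero flux
    main[-1] = w[-1] / (r[-1] * h)
    lower[-1] = -w[-1] / (r[-1] * h)
    A = sp.diags([lower, main, upper], [-1, 0, 1]).tocsc()
    # time scale identical to the FE solver
    t_scale = r1**2 / d_tissue
    dt = dtau * t_scale
    nsteps = int(round(tau_end / dtau))
    eye = sp.identity(n, format="csc")
    lhs = (eye / dt + A).tolil()
    lhs.rows[0] = [0]
    lhs.data[0] = [1.0]
    lhs = lhs.tocsc()
    lu = spla.splu(lhs)
    c = np.zeros(n)
    c[0] = c_wall
    for _ in range(nsteps):
        rhs = c / dt
        rhs[0] = c_wall
        c = lu.solve(rhs)
    from scipy.interpolate import interp1d

    return interp1d(r, c, kind="cubic")
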