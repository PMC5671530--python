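"""Oxygen mass diffusion around one capillary, coupled to pressure stress.

Transient diffusion of oxygen over the capillary wall + tissue annulus
(the Krogh cross-section) with the extended Fick's law

    J = -D dC/dx + s K_P dp/dx,

so the solute flux has a Fickian part and a drift part driven by the gradient
of the equivalent pressure stress p from the structural sub-model. Boundary
conditions follow the source set-up: the lumen surface is held at the wall
concentration delivered by the axial Krogh balance (40.32 µM by default), the
outer boundary of the Krogh cylinder has zero total flux, and the tissue
starts at zero concentration.

Because the true steady state with zero-flux outer boundary and no tissue
consumption is uniform (threshold-degenerate), oxygenated-area metrics are
evaluated at a fixed dimensionless time tau = D_tissue * t / R_out^2
(default 0.1), identically for the uncoupled baseline and the coupled run.

Units: concentrations in µM, p in MPa, diffusivities and the pressure stress
factor K_P in cm²/s; the drift term's unit bridge (solubility x mmHg-per-MPa
x µM-per-ml-O2) is exact and lives in :mod:`npwtox.units`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import Mesh
from .units import solubility_drift_scale

__all__ = [
    "DiffusionParams",
    "ConcentrationField",
    "DiffusionSystem",
    "solve_diffusion",
    "oxygenated_area",
    "area_change",
    "export_binary_mask",
]


@dataclass(frozen=True)
class DiffusionParams:
    """Diffusion constants and evaluation settings.

    ``k_p`` is the pressure stress factor of the extended Fick's law, in
    diffusivity units (cm²/s); it has no printed literature value and is
    normally calibrated by the pipeline. ``tau_end``/``dtau`` control the
    dimensionless evaluation time and implicit-Euler step.
    """

    d_tissue: float = 2.0e-5
    d_wall: float = 1.0e-5
    solubility: float = 3.89e-5
    k_p: float = 0.0
    wall_concentration: float = 40.32
    threshold: float = 10.0
    tau_end: float = 0.1
    dtau: float = 1.0e-3

    def __post_init__(self) -> None:
        if self.d_tissue <= 0 or self.d_wall <= 0:
            raise ValueError("diffusivities must be positive")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.wall_concentration <= self.threshold:
            raise ValueError("wall concentration must exceed the threshold at baseline")
        if self.tau_end <= 0 or self.dtau <= 0 or self.dtau > self.tau_end:
            raise ValueError("need 0 < dtau <= tau_end")

    @property
    def drift_scale(self) -> float:
        """µM-per-MPa concentration equivalent of s*p (unit bridge)."""
        return solubility_drift_scale(self.solubility)


@dataclass
class ConcentrationField:
    """Nodal oxygen concentration (µM) on the annulus sub-mesh."""

    mesh: Mesh  # full capillary mesh (metadata carries the structure)
    values: np.ndarray  # (n_annulus_nodes,)
    params: DiffusionParams
    tau: float
    info: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.values)


class DiffusionSystem:
    """Assembled FE operators for the annulus diffusion problem.

    Precomputes the stiffness/mass matrices and factorisations once per mesh;
    provides plain solves and the baseline/unit-drift pair used for fast
    K_P calibration (the PDE is linear, so the coupled solution is
    ``C_baseline + K_P * C_drift_unit``).
    """

    def __init__(self, mesh: Mesh, params: DiffusionParams):
        md = mesh.metadata
        if md.get("kind") != "capillary":
            raise ValueError("diffusion runs on a capillary mesh")
        self.mesh = mesh
        self.params = params
        self.n_theta = md["n_theta"]
        self.ring_r = np.asarray(md["ring_radii_um"], dtype=float) * 1.0e-6
        self.n_rings = md["n_annulus_rings"]
        self.nn = self.n_rings * self.n_theta
        self.ne = (self.n_rings - 1) * self.n_theta
        self.elements = mesh.elements[: self.ne]
        self.nodes = mesh.nodes[: self.nn]
        self.region = mesh.region[: self.ne]
        self.wall_code = {v: k for k, v in mesh.region_names.items()}["wall"]
        self.tissue_ids = np.flatnonzero(self.region != self.wall_code)

        self._assemble()
        self.dirichlet = np.arange(self.n_theta)  # lumen-surface nodes (ring 0)
        self.free = np.ones(self.nn, dtype=bool)
        self.free[self.dirichlet] = False

        rt = self.ring_r[-1]
        self.t_scale = rt**2 / (params.d_tissue * 1.0e-4)  # tau -> seconds
        self._factor = None

    # -- assembly -----------------------------------------------------------

    def _quad_data(self):
        X = self.nodes[self.elements]  # (E,4,2)
        gp = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]]) / np.sqrt(3.0)
        Ns, dNs = [], []
        for xi, eta in gp:
            N = 0.25 * np.array(
                [(1 - xi) * (1 - eta), (1 + xi) * (1 - eta), (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)]
            )
            dN = 0.25 * np.array(
                [
                    [-(1 - eta), -(1 - xi)],
                    [(1 - eta), -(1 + xi)],
                    [(1 + eta), (1 + xi)],
                    [-(1 + eta), (1 - xi)],
                ]
            )
            Ns.append(N)
            dNs.append(dN)
        return X, Ns, dNs

    def _assemble(self):
        p = self.params
        D_el = np.where(self.region == self.wall_code, p.d_wall, p.d_tissue) * 1.0e-4
        X, Ns, dNs = self._quad_data()
        E = len(self.elements)
        Ke = np.zeros((E, 4, 4))
        Me = np.zeros((E, 4))
        self._grad_ops = []  # per-GP (dNdX (E,4,2), w (E,))
        for N, dN in zip(Ns, dNs):
            J = np.einsum("eai,aj->eij", X, dN)
            detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
            inv = np.empty_like(J)
            inv[:, 0, 0] = J[:, 1, 1] / detJ
            inv[:, 1, 1] = J[:, 0, 0] / detJ
            inv[:, 0, 1] = -J[:, 0, 1] / detJ
            inv[:, 1, 0] = -J[:, 1, 0] / detJ
            dNdX = np.einsum("ak,ekj->eaj", dN, inv)
            Ke += D_el[:, None, None] * np.einsum("eaj,ebj,e->eab", dNdX, dNdX, detJ)
            Me += N[None, :] * detJ[:, None]
            self._grad_ops.append((dNdX, detJ.copy()))
        rows = np.repeat(self.elements, 4, axis=1).ravel()
        cols = np.tile(self.elements, (1, 4)).ravel()
        self.A = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(self.nn, self.nn)).tocsr()
        mass = np.zeros(self.nn)
        np.add.at(mass, self.elements.ravel(), Me.ravel())
        self.M = mass  # lumped
        self.element_area = np.zeros(E)
        for _, detJ in self._grad_ops:
            self.element_area += detJ

    def project_pressure(self, p_elem: np.ndarray) -> np.ndarray:
        """Area-weighted projection of element p values onto annulus nodes."""
        p_elem = np.asarray(p_elem, dtype=float)[: self.ne]
        num = np.zeros(self.nn)
        den = np.zeros(self.nn)
        w = self.element_area
        for a in range(4):
            np.add.at(num, self.elements[:, a], w * p_elem)
            np.add.at(den, self.elements[:, a], w)
        return num / den

    def drift_source(self, p_nodal: np.ndarray, k_p_cm2s: float) -> np.ndarray:
        """b_a = ∫ s K_P ∇p · ∇N_a dA  (µM m²/s units)."""
        coef = self.params.drift_scale * k_p_cm2s * 1.0e-4
        b = np.zeros(self.nn)
        pe = p_nodal[self.elements]  # (E,4)
        for dNdX, detJ in self._grad_ops:
            gradp = np.einsum("ea,eaj->ej", pe, dNdX)  # MPa/m
            contrib = coef * np.einsum("ej,eaj,e->ea", gradp, dNdX, detJ)
            np.add.at(b, self.elements.ravel(), contrib.ravel())
        return b

    # -- time stepping ------------------------------------------------------

    def _march(self, c0, b, wall_value, tau_end, dtau):
        dt = dtau * self.t_scale
        n_steps = int(round(tau_end / dtau))
        lhs = sp.diags(self.M / dt) + self.A
        lhs = lhs.tolil()
        for i in self.dirichlet:
            lhs.rows[i] = [i]
            lhs.data[i] = [1.0]
        lhs = lhs.tocsc()
        factor = spla.splu(lhs)
        c = c0.copy()
        c[self.dirichlet] = wall_value
        mass_hist = [float(np.dot(self.M, c))]
        flux_hist = []
        for _ in range(n_steps):
            rhs = self.M / dt * c + b
            rhs[self.dirichlet] = wall_value
            c_new = factor.solve(rhs)
            # reaction flux at the Dirichlet nodes closes the mass budget
            # at the Dirichlet rows the residual of the free-node equation
            # equals the boundary reaction flux into the domain
            r = self.M / dt * (c_new - c) + self.A @ c_new - b
            flux_hist.append(float(r[self.dirichlet].sum()) * dt)
            c = c_new
            mass_hist.append(float(np.dot(self.M, c)))
        return c, np.asarray(mass_hist), np.asarray(flux_hist)

    def solve(
        self,
        p_field: np.ndarray | None = None,
        k_p: float | None = None,
        tau_end: float | None = None,
    ) -> ConcentrationField:
        """Transient solve to ``tau_end``; ``p_field=None`` is the baseline.

        ``p_field`` is the per-element equivalent pressure stress of the
        structural solve (MPa, on the same capillary mesh). A nonzero ``k_p``
        without a pressure field is an error.
        """
        p = self.params
        k_p = p.k_p if k_p is None else float(k_p)
        tau_end = p.tau_end if tau_end is None else float(tau_end)
        if p_field is None and k_p != 0.0:
            raise ValueError("nonzero K_P requires a pressure field")
        b = np.zeros(self.nn)
        if p_field is not None and k_p != 0.0:
            b = self.drift_source(self.project_pressure(p_field), k_p)
        c0 = np.zeros(self.nn)
        c, mass, flux = self._march(c0, b, p.wall_concentration, tau_end, p.dtau)
        if not np.all(np.isfinite(c)):
            raise FloatingPointError("diffusion time stepping diverged")
        # drift source adds/removes interior mass; include it in the budget
        source = float(b[self.free].sum()) * p.dtau * self.t_scale * len(flux)
        return ConcentrationField(
            self.mesh,
            c,
            p,
            tau_end,
            info={
                "mass_history": mass,
                "boundary_influx": flux,
                "source_total": source,
                "k_p": k_p,
            },
        )

    def baseline_and_unit_drift(self, p_field: np.ndarray, tau_end: float | None = None):
        """(baseline, unit-drift) pair: coupled C = baseline + K_P * unit.

        The unit-drift field solves the same transient with zero wall value
        and the drift source at K_P = 1 cm²/s; linearity of the PDE makes the
        superposition exact for any K_P on the same mesh and stepping.
        """
        p = self.params
        tau_end = p.tau_end if tau_end is None else float(tau_end)
        base = self.solve(None, 0.0, tau_end)
        b = self.drift_source(self.project_pressure(p_field), 1.0)
        cu, _, _ = self._march(np.zeros(self.nn), b, 0.0, tau_end, p.dtau)
        unit = ConcentrationField(self.mesh, cu, p, tau_end, info={"unit_drift": True})
        return base, unit

    # -- metrics ------------------------------------------------------------

    def oxygenated_area(self, conc: ConcentrationField, threshold: float | None = None) -> float:
        """Fraction of the tissue annulus with element-mean C >= threshold."""
        thr = self.params.threshold if threshold is None else float(threshold)
        ce = conc.values[self.elements].mean(axis=1)
        a = self.element_area[self.tissue_ids]
        above = ce[self.tissue_ids] >= thr
        return float(a[above].sum() / a.sum())


def solve_diffusion(mesh, params, p_field=None, k_p=None, tau_end=None) -> ConcentrationField:
    """One-shot convenience wrapper around :class:`DiffusionSystem`."""
    return DiffusionSystem(mesh, params).solve(p_field, k_p, tau_end)


def oxygenated_area(conc: ConcentrationField, threshold: float | None = None) -> float:
    """Oxygenated tissue-area fraction of a solved concentration field."""
    return DiffusionSystem(conc.mesh, conc.params).oxygenated_area(conc, threshold)


def area_change(coupled: float, baseline: float) -> float:
    """Signed relative change 100*(coupled - baseline)/baseline, percent."""
    if baseline == 0:
        raise ZeroDivisionError("baseline oxygenated area is zero")
    return 100.0 * (coupled - baseline) / baseline


def export_binary_mask(
    conc: ConcentrationField,
    threshold: float | None = None,
    size: int = 512,
    path=None,
) -> np.ndarray:
    """Black/white raster of the oxygenated region (white = C >= threshold).

    Pixels outside the annulus are black; the image spans the bounding square
    of the Krogh circle. Interpolation is bilinear on the structured
    (ring, sector) grid. Returns a uint8 array; optionally saves a PNG.
    """
    md = conc.mesh.metadata
    thr = conc.params.threshold if threshold is None else float(threshold)
    ring_r = np.asarray(md["ring_radii_um"], dtype=float) * 1.0e-6
    n_theta = md["n_theta"]
    n_rings = md["n_annulus_rings"]
    C = conc.values.reshape(n_rings, n_theta)

    rt = ring_r[-1]
    ax = np.linspace(-rt, rt, size)
    Xp, Yp = np.meshgrid(ax, -ax)  # image row 0 at top
    R = np.hypot(Xp, Yp)
    TH = np.mod(np.arctan2(Yp, Xp), 2.0 * np.pi)

    i = np.clip(np.searchsorted(ring_r, R) - 1, 0, n_rings - 2)
    fr = (R - ring_r[i]) / (ring_r[i + 1] - ring_r[i])
    dth = 2.0 * np.pi / n_theta
    j = np.floor(TH / dth).astype(int) % n_theta
    ft = TH / dth - np.floor(TH / dth)
    j1 = (j + 1) % n_theta
    vals = (
        C[i, j] * (1 - fr) * (1 - ft)
        + C[i, j1] * (1 - fr) * ft
        + C[i + 1, j] * fr * (1 - ft)
        + C[i + 1, j1] * fr * ft
    )
    inside = (R >= ring_r[0]) & (R <= rt)
    img = np.where(inside & (vals >= thr), 255, 0).astype(np.uint8)
    if path is not None:
        from PIL import Image

        Image.fromarray(img, mode="L").save(path)
    return img
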