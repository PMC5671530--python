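"""Nonlinear finite-element core: bilinear quads, axisymmetric or plane strain.

Total-Lagrangian displacement formulation with:

* 2x2 Gauss quadrature for the isochoric response and a single centroid point
  for the volumetric penalty of nearly incompressible materials (selective
  reduced integration, which prevents volumetric locking of Q1 elements);
* follower pressure loads integrated on the deformed surface;
* element tangents by central finite differencing of the (analytic) internal
  and surface force vectors — robust for any material and verified against
  directional derivatives of the residual in the test suite;
* Newton iteration with backtracking line search, uniform load incrementation
  and adaptive step cut-back.

Sign conventions: tension-positive Cauchy stress; a positive pressure-load
magnitude pushes against the outward surface normal (compression), a negative
magnitude (suction) pulls the surface outward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import Mesh

__all__ = [
    "NonlinearFE",
    "FESolution",
    "ConvergenceError",
    "PressureLoad",
    "principal_stresses",
    "pressure_stress",
]

log = logging.getLogger(__name__)

_GP = np.array(
    [
        [-1.0, -1.0],
        [1.0, -1.0],
        [1.0, 1.0],
        [-1.0, 1.0],
    ]
) / np.sqrt(3.0)
_GW = np.ones(4)
_GP_C = np.zeros((1, 2))
_GW_C = np.array([4.0])


def _shape(xi):
    """Bilinear shape functions and derivatives at (n, 2) points."""
    x, e = xi[:, 0], xi[:, 1]
    N = 0.25 * np.stack(
        [(1 - x) * (1 - e), (1 + x) * (1 - e), (1 + x) * (1 + e), (1 - x) * (1 + e)],
        axis=1,
    )
    dN = np.empty((len(xi), 4, 2))
    dN[:, :, 0] = 0.25 * np.stack([-(1 - e), (1 - e), (1 + e), -(1 + e)], axis=1)
    dN[:, :, 1] = 0.25 * np.stack([-(1 - x), -(1 + x), (1 + x), (1 - x)], axis=1)
    return N, dN


class ConvergenceError(RuntimeError):
    """Newton iteration failed; carries the last residual and load factor."""

    def __init__(self, msg, residual=None, load_factor=None):
        super().__init__(msg)
        self.residual = residual
        self.load_factor = load_factor


@dataclass
class PressureLoad:
    """Uniform pressure on a set of oriented facets (positive = compressive)."""

    facets: np.ndarray
    magnitude: float
    follower: bool = True


@dataclass
class FESolution:
    """Converged displacement field plus solver diagnostics."""

    mesh: Mesh
    u: np.ndarray  # (N, 2) displacements, metres
    info: dict = field(default_factory=dict)

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.u, axis=1)


class _Group:
    """Per-material element batch with precomputed quadrature data."""

    def __init__(self, mesh: Mesh, ids: np.ndarray, material, axisym: bool):
        self.ids = ids
        self.material = material
        self.conn = mesh.elements[ids]
        self.X = mesh.nodes[self.conn]  # (E, 4, 2)
        self.axisym = axisym
        self.full = self._precompute(_GP, _GW)
        self.centroid = self._precompute(_GP_C, _GW_C)
        dof = np.empty((len(ids), 8), dtype=int)
        dof[:, 0::2] = 2 * self.conn
        dof[:, 1::2] = 2 * self.conn + 1
        self.dof = dof
        area = np.abs(
            0.5
            * np.sum(
                self.X[:, :, 0] * np.roll(self.X[:, :, 1], -1, axis=1)
                - np.roll(self.X[:, :, 0], -1, axis=1) * self.X[:, :, 1],
                axis=1,
            )
        )
        self.h_fd = 1.0e-7 * float(np.sqrt(np.median(area)))

    def _precompute(self, gp, gw):
        N, dN = _shape(gp)  # (G,4), (G,4,2)
        # Jacobian J[e,g,i,j] = sum_a X[e,a,i] * dN[g,a,j]
        J = np.einsum("eai,gaj->egij", self.X, dN)
        detJ = J[..., 0, 0] * J[..., 1, 1] - J[..., 0, 1] * J[..., 1, 0]
        if np.any(detJ <= 0):
            raise ValueError("non-positive element Jacobian (inverted element)")
        inv = np.empty_like(J)
        inv[..., 0, 0] = J[..., 1, 1] / detJ
        inv[..., 1, 1] = J[..., 0, 0] / detJ
        inv[..., 0, 1] = -J[..., 0, 1] / detJ
        inv[..., 1, 0] = -J[..., 1, 0] / detJ
        # dN/dX[e,g,a,j] = dN[g,a,k] * inv[e,g,k,j]
        dNdX = np.einsum("gak,egkj->egaj", dN, inv)
        w = gw[None, :] * detJ
        R = np.einsum("ga,ea->eg", N, self.X[..., 0])
        if self.axisym:
            w = w * 2.0 * np.pi * R
        return {"N": N, "dNdX": dNdX, "w": w, "R": R}

    # -- kinematics & forces ------------------------------------------------

    def _kinematics(self, ue, q):
        """Deformation gradient blocks at the quadrature points of batch ``q``."""
        H = np.einsum("eai,egaj->egij", ue, q["dNdX"])
        F2 = H.copy()
        F2[..., 0, 0] += 1.0
        F2[..., 1, 1] += 1.0
        if self.axisym:
            ur = np.einsum("ga,ea->eg", q["N"], ue[..., 0])
            lam3 = 1.0 + ur / q["R"]
        else:
            lam3 = np.ones(F2.shape[:2])
        return F2, lam3

    def _accumulate(self, ue, q, part, out):
        F2, lam3 = self._kinematics(ue, q)
        P2, P3 = self.material.piola(F2, lam3, part)
        w = q["w"]
        # volume term: f[e,a,i] += w * P2[i,j] dNdX[a,j]
        out += np.einsum("eg,egij,egaj->eai", w, P2, q["dNdX"])
        if self.axisym:
            out[..., 0] += np.einsum("eg,ga->ea", w * P3 / q["R"], q["N"])
        return out

    def _mean_dilatation(self, ue, q):
        """Element-average volume ratio and the kinematic data to use it."""
        F2, lam3 = self._kinematics(ue, q)
        J2 = F2[..., 0, 0] * F2[..., 1, 1] - F2[..., 0, 1] * F2[..., 1, 0]
        J = J2 * lam3
        w = q["w"]
        Jbar = np.sum(w * J, axis=1) / np.sum(w, axis=1)
        return F2, lam3, J2, Jbar

    def _vol_force(self, ue, q, out):
        """Mean-dilatation volumetric force: a single element pressure
        pbar = kappa*(Jbar - 1) acting through the pointwise J F^{-T}, with
        full quadrature (integration-consistent; passes the patch test and
        avoids Q1 volumetric locking)."""
        F2, lam3, J2, Jbar = self._mean_dilatation(ue, q)
        pbar = self.material.kappa * (Jbar - 1.0)
        w = q["w"]
        # J * F^{-T} (2x2 block) = lam3 * adj(F2)^T
        P2 = np.empty_like(F2)
        P2[..., 0, 0] = F2[..., 1, 1]
        P2[..., 0, 1] = -F2[..., 1, 0]
        P2[..., 1, 0] = -F2[..., 0, 1]
        P2[..., 1, 1] = F2[..., 0, 0]
        P2 = P2 * (lam3 * pbar[:, None])[..., None, None]
        out += np.einsum("eg,egij,egaj->eai", w, P2, q["dNdX"])
        if self.axisym:
            P3 = pbar[:, None] * J2  # pbar * J / lam3
            out[..., 0] += np.einsum("eg,ga->ea", w * P3 / q["R"], q["N"])
        return out

    def force(self, ue):
        """Element internal force vectors (E, 8)."""
        out = np.zeros_like(ue)
        if self.material.split_volumetric:
            self._accumulate(ue, self.full, "iso", out)
            self._vol_force(ue, self.full, out)
        else:
            self._accumulate(ue, self.full, "both", out)
        return out.reshape(len(ue), 8)

    def energy(self, ue):
        total = 0.0
        if self.material.split_volumetric:
            from .materials import _mr_energy_parts

            F2, lam3 = self._kinematics(ue, self.full)
            Wi, _ = _mr_energy_parts(F2, lam3, self.material)
            total += float(np.sum(self.full["w"] * Wi))
            _, _, _, Jbar = self._mean_dilatation(ue, self.full)
            vol = np.sum(self.full["w"], axis=1)
            total += float(np.sum(vol * 0.5 * self.material.kappa * (Jbar - 1.0) ** 2))
        else:
            F2, lam3 = self._kinematics(ue, self.full)
            total += float(np.sum(self.full["w"] * self.material.energy(F2, lam3)))
        return total

    def stiffness(self, ue):
        """Element tangents (E, 8, 8) by central finite differences."""
        E = len(ue)
        K = np.empty((E, 8, 8))
        h = self.h_fd
        flat = ue.reshape(E, 8)
        for k in range(8):
            up = flat.copy()
            up[:, k] += h
            um = flat.copy()
            um[:, k] -= h
            fp = self.force(up.reshape(E, 4, 2))
            fm = self.force(um.reshape(E, 4, 2))
            K[:, :, k] = (fp - fm) / (2.0 * h)
        return K

    def stress(self, ue):
        """Cauchy stress at the element centroid: (E,2,2) block and (E,) hoop."""
        F2, lam3 = self._kinematics(ue, self.centroid)
        sig2, sig33 = self.material.cauchy(F2, lam3)
        return sig2[:, 0], sig33[:, 0]


class NonlinearFE:
    """Static nonlinear FE problem on a tagged quad mesh.

    Parameters
    ----------
    mesh : Mesh
    materials : dict mapping region name -> constitutive object
    mode : 'axisymmetric' or 'plane_strain'
    """

    def __init__(self, mesh: Mesh, materials: dict, mode: str = "axisymmetric"):
        if mode not in ("axisymmetric", "plane_strain"):
            raise ValueError("mode must be 'axisymmetric' or 'plane_strain'")
        self.mesh = mesh
        self.mode = mode
        self.axisym = mode == "axisymmetric"
        self.ndof = 2 * len(mesh.nodes)
        self.groups = []
        for code, name in mesh.region_names.items():
            ids = np.flatnonzero(mesh.region == code)
            if ids.size == 0:
                continue
            if name not in materials:
                raise KeyError(f"no material given for region '{name}'")
            self.groups.append(_Group(mesh, ids, materials[name], self.axisym))
        self.fixed = np.zeros(self.ndof, dtype=bool)
        self.loads: list[PressureLoad] = []

    # -- boundary conditions ------------------------------------------------

    def fix(self, node_ids, dofs=(0, 1)) -> None:
        """Constrain the given displacement components to zero."""
        for d in np.atleast_1d(dofs):
            self.fixed[2 * np.asarray(node_ids, dtype=int) + int(d)] = True

    def add_pressure(self, facets, magnitude: float, follower: bool = True) -> None:
        """Uniform pressure on oriented facets; negative magnitude = suction."""
        facets = np.asarray(facets, dtype=int)
        if facets.size:
            self.loads.append(PressureLoad(facets, float(magnitude), follower))

    # -- force assembly -----------------------------------------------------

    def internal_force(self, u: np.ndarray) -> np.ndarray:
        f = np.zeros(self.ndof)
        for g in self.groups:
            fe = g.force(u[g.conn])
            np.add.at(f, g.dof.ravel(), fe.ravel())
        return f

    def _facet_force(self, load: PressureLoad, x: np.ndarray) -> np.ndarray:
        """Nodal forces (Fc, 4) of a pressure load on coordinates ``x``."""
        xa, xb = x[load.facets[:, 0]], x[load.facets[:, 1]]
        gp = np.array([-1.0, 1.0]) / np.sqrt(3.0)
        out = np.zeros((len(load.facets), 4))
        for xi in gp:
            Na, Nb = 0.5 * (1 - xi), 0.5 * (1 + xi)
            mid = Na * xa + Nb * xb
            d = 0.5 * (xb - xa)  # dx/dxi
            nvec = np.stack([d[:, 1], -d[:, 0]], axis=1)  # outward normal * |J|
            wgt = 2.0 * np.pi * mid[:, 0] if self.axisym else 1.0
            t = -load.magnitude * nvec * np.atleast_1d(wgt)[:, None]
            out[:, 0:2] += Na * t
            out[:, 2:4] += Nb * t
        return out

    def external_force(self, u: np.ndarray, scale: float = 1.0) -> np.ndarray:
        f = np.zeros(self.ndof)
        for load in self.loads:
            x = self.mesh.nodes + (u if load.follower else 0.0)
            fe = scale * self._facet_force(load, x)
            dof = np.empty((len(load.facets), 4), dtype=int)
            dof[:, 0] = 2 * load.facets[:, 0]
            dof[:, 1] = 2 * load.facets[:, 0] + 1
            dof[:, 2] = 2 * load.facets[:, 1]
            dof[:, 3] = 2 * load.facets[:, 1] + 1
            np.add.at(f, dof.ravel(), fe.ravel())
        return f

    def residual(self, u: np.ndarray, scale: float = 1.0) -> np.ndarray:
        return self.internal_force(u) - self.external_force(u, scale)

    def tangent(self, u: np.ndarray, scale: float = 1.0) -> sp.csr_matrix:
        rows, cols, vals = [], [], []
        for g in self.groups:
            Ke = g.stiffness(u[g.conn])
            dof = g.dof
            rows.append(np.repeat(dof, 8, axis=1).ravel())
            cols.append(np.tile(dof, (1, 8)).ravel())
            vals.append(Ke.ravel())
        # follower-load stiffness by FD on facet dofs
        h = 1.0e-9 * max(float(np.abs(self.mesh.nodes).max()), 1.0e-6)
        for load in self.loads:
            if not load.follower:
                continue
            dof = np.empty((len(load.facets), 4), dtype=int)
            dof[:, 0] = 2 * load.facets[:, 0]
            dof[:, 1] = 2 * load.facets[:, 0] + 1
            dof[:, 2] = 2 * load.facets[:, 1]
            dof[:, 3] = 2 * load.facets[:, 1] + 1
            Kf = np.empty((len(load.facets), 4, 4))
            for k in range(4):
                for sgn, store in ((1.0, 0), (-1.0, 1)):
                    xp = self.mesh.nodes + u
                    pert = np.zeros((len(load.facets), 4))
                    pert[:, k] = sgn * h
                    # build perturbed coordinates facet-locally
                    xa = xp[load.facets[:, 0]] + pert[:, 0:2]
                    xb = xp[load.facets[:, 1]] + pert[:, 2:4]
                    fe = self._facet_force_local(load, xa, xb)
                    if store == 0:
                        fplus = fe
                    else:
                        fminus = fe
                Kf[:, :, k] = -scale * (fplus - fminus) / (2.0 * h)
            rows.append(np.repeat(dof, 4, axis=1).ravel())
            cols.append(np.tile(dof, (1, 4)).ravel())
            vals.append(Kf.ravel())
        K = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.ndof, self.ndof),
        ).tocsr()
        return K

    def _facet_force_local(self, load: PressureLoad, xa, xb) -> np.ndarray:
        gp = np.array([-1.0, 1.0]) / np.sqrt(3.0)
        out = np.zeros((len(xa), 4))
        for xi in gp:
            Na, Nb = 0.5 * (1 - xi), 0.5 * (1 + xi)
            mid = Na * xa + Nb * xb
            d = 0.5 * (xb - xa)
            nvec = np.stack([d[:, 1], -d[:, 0]], axis=1)
            wgt = 2.0 * np.pi * mid[:, 0] if self.axisym else 1.0
            t = -load.magnitude * nvec * np.atleast_1d(wgt)[:, None]
            out[:, 0:2] += Na * t
            out[:, 2:4] += Nb * t
        return out

    # -- solver -------------------------------------------------------------

    def solve(
        self,
        n_steps: int = 10,
        tol: float = 1.0e-8,
        max_iter: int = 25,
        min_step: float = 1.0 / 160.0,
    ) -> FESolution:
        """Incremental-iterative solve to full load; returns the solution.

        The convergence test is on the free-dof residual norm relative to the
        external force norm (absolute when the load is zero). On Newton
        failure the load increment is halved down to ``min_step``.
        """
        free = ~self.fixed
        u = np.zeros((len(self.mesh.nodes), 2))
        lam, dlam = 0.0, 1.0 / n_steps
        newton_log = []
        while lam < 1.0 - 1.0e-12:
            target = min(lam + dlam, 1.0)
            ok, u_trial, iters, res = self._newton(u, target, free, tol, max_iter)
            if ok:
                u = u_trial
                lam = target
                newton_log.append((target, iters, res))
                log.debug("load %.3f converged in %d iterations (res=%.2e)", lam, iters, res)
            else:
                dlam /= 2.0
                log.debug("cutting load increment to %.4f", dlam)
                if dlam < min_step:
                    raise ConvergenceError(
                        f"Newton failed at load factor {target:.4f} "
                        f"(residual {res:.3e} after {iters} iterations)",
                        residual=res,
                        load_factor=target,
                    )
        return FESolution(self.mesh, u, info={"steps": newton_log, "tol": tol})

    def _newton(self, u0, scale, free, tol, max_iter):
        u = u0.copy()
        fext = self.external_force(u, scale)
        ref = np.linalg.norm(fext[free])
        res_prev = None
        for it in range(max_iter):
            r = self.residual(u, scale)
            rn = np.linalg.norm(r.ravel()[free])
            ref = max(np.linalg.norm(self.external_force(u, scale)[free]), 1.0e-300)
            if rn <= tol * ref or rn < 1.0e-16:
                return True, u, it, rn
            K = self.tangent(u, scale)
            Kff = K[free][:, free]
            du = spla.spsolve(Kff.tocsc(), -r.ravel()[free])
            if not np.all(np.isfinite(du)):
                return False, u, it, rn
            # backtracking line search
            step = 1.0
            for _ in range(6):
                u_new = u.copy()
                u_new.reshape(-1)[free] += step * du
                try:
                    rn_new = np.linalg.norm(self.residual(u_new, scale).ravel()[free])
                except FloatingPointError:
                    rn_new = np.inf
                if np.isfinite(rn_new) and (rn_new < rn or rn_new <= tol * ref):
                    break
                step /= 2.0
            else:
                return False, u, it, rn
            u = u_new
            res_prev = rn
        r = self.residual(u, scale)
        rn = np.linalg.norm(r.ravel()[free])
        return rn <= tol * ref, u, max_iter, rn

    # -- post-processing ----------------------------------------------------

    def element_stress(self, u: np.ndarray):
        """Centroid Cauchy stress per element: (E,2,2) in-plane and (E,) out-of-plane."""
        E = len(self.mesh.elements)
        sig2 = np.zeros((E, 2, 2))
        sig33 = np.zeros(E)
        for g in self.groups:
            s2, s3 = g.stress(u[g.conn])
            sig2[g.ids] = s2
            sig33[g.ids] = s3
        return sig2, sig33

    def strain_energy(self, u: np.ndarray) -> float:
        return sum(g.energy(u[g.conn]) for g in self.groups)


# ---------------------------------------------------------------------------
# Stress post-processing helpers
# ---------------------------------------------------------------------------


def principal_stresses(sig2: np.ndarray, sig33: np.ndarray):
    """Sorted principal stresses (s_max >= s_mid >= s_min) of the 3D tensor
    blockdiag(sig2, sig33)."""
    a = sig2[..., 0, 0]
    b = sig2[..., 1, 1]
    c = sig2[..., 0, 1]
    mean = 0.5 * (a + b)
    rad = np.sqrt(0.25 * (a - b) ** 2 + c**2)
    p1 = mean + rad
    p2 = mean - rad
    allp = np.stack([p1, p2, sig33], axis=-1)
    allp.sort(axis=-1)
    return allp[..., 2], allp[..., 1], allp[..., 0]


def pressure_stress(sig2: np.ndarray, sig33: np.ndarray) -> np.ndarray:
    """Equivalent pressure stress p = -tr(sigma)/3 (positive in compression)."""
    return -(sig2[..., 0, 0] + sig2[..., 1, 1] + sig33) / 3.0


def von_mises(sig2: np.ndarray, sig33: np.ndarray) -> np.ndarray:
    s1, s2, s3 = principal_stresses(sig2, sig33)
    return np.sqrt(0.5 * ((s1 - s2) ** 2 + (s2 - s3) ** 2 + (s3 - s1) ** 2))
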