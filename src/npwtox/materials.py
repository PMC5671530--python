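"""Hyperelastic constitutive models for soft tissue and polyurethane foam.

Two strain-energy densities are implemented, both in total-Lagrangian form
specialised to the two solver kinematics used in this package:

* axisymmetric: deformation gradient ``F = blockdiag(F2, lam3)`` where ``F2``
  is the in-plane (r,z) 2x2 block and ``lam3 = 1 + u_r/R`` the hoop stretch;
* plane strain: same block structure with ``lam3 = 1`` frozen.

Muscle tissue and capillary wall use a Mooney-Rivlin energy with an
isochoric/volumetric split,

    W = C1*(I1b - 3) + C2*(I2b - 3) + kappa/2*(J - 1)^2,

where ``I1b = J^(-2/3) I1`` and ``I2b = J^(-4/3) I2`` are the deviatoric
invariants. The incompressibility parameter D of the source table maps to the
bulk modulus as ``kappa = 2/D``, capped at ``kappa_ratio * mu0`` (default
1000) because D = 0 (exactly incompressible muscle) is ill-posed for a
displacement formulation.

The foam filler uses a single-term compressible Ogden hyperfoam energy

    U = (2 mu / alpha^2) * [l1^a + l2^a + l3^a - 3 + (J^(-a*b) - 1)/b],

whose initial shear modulus is ``mu`` and initial Poisson ratio
``beta/(1+2*beta)``. All stresses are in MPa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MooneyRivlinParams",
    "HyperfoamParams",
    "mr_energy",
    "mr_uniaxial_stress",
    "MUSCLE",
    "CAPILLARY_WALL",
    "PU_FOAM",
]


@dataclass(frozen=True)
class MooneyRivlinParams:
    """Mooney-Rivlin constants (MPa) with Abaqus-style volumetric parameter D.

    ``d_vol`` is in 1/MPa; 0 means incompressible and is realised as a
    near-incompressible penalty with bulk modulus ``kappa_ratio * mu0``.
    """

    c1: float
    c2: float
    d_vol: float = 0.0
    kappa_ratio: float = 1.0e3

    def __post_init__(self) -> None:
        if self.c1 < 0 or self.c2 < 0 or self.c1 + self.c2 <= 0:
            raise ValueError("require C1 >= 0, C2 >= 0 and C1 + C2 > 0")
        if self.d_vol < 0:
            raise ValueError("D must be >= 0")

    @property
    def mu0(self) -> float:
        """Initial shear modulus 2*(C1 + C2)."""
        return 2.0 * (self.c1 + self.c2)

    @property
    def kappa(self) -> float:
        """Bulk modulus used by the penalty term (MPa)."""
        cap = self.kappa_ratio * self.mu0
        if self.d_vol == 0.0:
            return cap
        return min(2.0 / self.d_vol, cap)

    # -- solver interface ---------------------------------------------------

    split_volumetric = True

    def energy(self, F2: np.ndarray, lam3: np.ndarray) -> np.ndarray:
        Wi, Wv = _mr_energy_parts(F2, lam3, self)
        return Wi + Wv

    def piola(self, F2: np.ndarray, lam3: np.ndarray, part: str = "both"):
        """First Piola-Kirchhoff stress blocks d W / d F.

        Returns ``(P2, P3)`` with ``P2`` shaped like ``F2`` and ``P3`` the
        hoop (or out-of-plane) component. ``part`` selects the isochoric or
        volumetric contribution for selective reduced integration.
        """
        return _mr_piola(F2, lam3, self, part)

    def cauchy(self, F2: np.ndarray, lam3: np.ndarray):
        """Cauchy stress: in-plane 2x2 block and out-of-plane normal component."""
        P2, P3 = self.piola(F2, lam3, "both")
        return _piola_to_cauchy(F2, lam3, P2, P3)


@dataclass(frozen=True)
class HyperfoamParams:
    """Single-term Ogden hyperfoam constants (mu in MPa)."""

    mu: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.alpha == 0:
            raise ValueError("alpha must be nonzero")

    @property
    def mu0(self) -> float:
        return self.mu

    @property
    def poisson0(self) -> float:
        """Initial Poisson ratio beta/(1+2*beta)."""
        return self.beta / (1.0 + 2.0 * self.beta)

    split_volumetric = False

    def energy(self, F2: np.ndarray, lam3: np.ndarray) -> np.ndarray:
        l1, l2, _ = _principal_stretches(F2, lam3)
        return _foam_energy(l1, l2, lam3, self)

    def piola(self, F2: np.ndarray, lam3: np.ndarray, part: str = "both"):
        if part == "vol":
            P2 = np.zeros_like(F2)
            return P2, np.zeros_like(lam3)
        return _foam_piola(F2, lam3, self)

    def cauchy(self, F2: np.ndarray, lam3: np.ndarray):
        P2, P3 = self.piola(F2, lam3, "both")
        return _piola_to_cauchy(F2, lam3, P2, P3)


# ---------------------------------------------------------------------------
# Mooney-Rivlin internals (vectorised over leading axes)
# ---------------------------------------------------------------------------


def _invariants(F2, lam3):
    """Right Cauchy-Green blocks and invariants for blockdiag(F2, lam3)."""
    c11 = F2[..., 0, 0] ** 2 + F2[..., 1, 0] ** 2
    c22 = F2[..., 0, 1] ** 2 + F2[..., 1, 1] ** 2
    c12 = F2[..., 0, 0] * F2[..., 0, 1] + F2[..., 1, 0] * F2[..., 1, 1]
    c33 = lam3**2
    J2 = F2[..., 0, 0] * F2[..., 1, 1] - F2[..., 0, 1] * F2[..., 1, 0]
    J = J2 * lam3
    I1 = c11 + c22 + c33
    trC2 = c11**2 + 2.0 * c12**2 + c22**2 + c33**2
    I2 = 0.5 * (I1**2 - trC2)
    return c11, c12, c22, c33, J, I1, I2


def _mr_energy_parts(F2, lam3, m: MooneyRivlinParams):
    *_, J, I1, I2 = _invariants(F2, lam3)
    if np.any(J <= 0):
        raise FloatingPointError("non-positive Jacobian in Mooney-Rivlin energy")
    Wi = m.c1 * (J ** (-2.0 / 3.0) * I1 - 3.0) + m.c2 * (J ** (-4.0 / 3.0) * I2 - 3.0)
    Wv = 0.5 * m.kappa * (J - 1.0) ** 2
    return Wi, Wv


def _mr_piola(F2, lam3, m: MooneyRivlinParams, part: str):
    c11, c12, c22, c33, J, I1, I2 = _invariants(F2, lam3)
    if np.any(J <= 0):
        raise FloatingPointError("non-positive Jacobian in Mooney-Rivlin stress")
    # inverse of C blocks
    det2 = c11 * c22 - c12**2
    i11 = c22 / det2
    i22 = c11 / det2
    i12 = -c12 / det2
    i33 = 1.0 / c33

    Jm23 = J ** (-2.0 / 3.0)
    Jm43 = J ** (-4.0 / 3.0)

    def zero():
        return np.zeros_like(c11)

    s11 = s12 = s22 = s33 = None
    if part in ("iso", "both"):
        a1 = 2.0 * m.c1 * Jm23
        a2 = 2.0 * m.c2 * Jm43
        s11 = a1 * (1.0 - I1 / 3.0 * i11) + a2 * (I1 - c11 - 2.0 * I2 / 3.0 * i11)
        s22 = a1 * (1.0 - I1 / 3.0 * i22) + a2 * (I1 - c22 - 2.0 * I2 / 3.0 * i22)
        s12 = a1 * (-I1 / 3.0 * i12) + a2 * (-c12 - 2.0 * I2 / 3.0 * i12)
        s33 = a1 * (1.0 - I1 / 3.0 * i33) + a2 * (I1 - c33 - 2.0 * I2 / 3.0 * i33)
    else:
        s11, s12, s22, s33 = zero(), zero(), zero(), zero()
    if part in ("vol", "both"):
        kv = m.kappa * (J - 1.0) * J
        s11 = s11 + kv * i11
        s22 = s22 + kv * i22
        s12 = s12 + kv * i12
        s33 = s33 + kv * i33

    # P2 = F2 @ S2 (2nd PK block), P3 = lam3 * S33
    P2 = np.empty_like(F2)
    P2[..., 0, 0] = F2[..., 0, 0] * s11 + F2[..., 0, 1] * s12
    P2[..., 0, 1] = F2[..., 0, 0] * s12 + F2[..., 0, 1] * s22
    P2[..., 1, 0] = F2[..., 1, 0] * s11 + F2[..., 1, 1] * s12
    P2[..., 1, 1] = F2[..., 1, 0] * s12 + F2[..., 1, 1] * s22
    P3 = lam3 * s33
    return P2, P3


def _piola_to_cauchy(F2, lam3, P2, P3):
    """sigma = (1/J) P F^T for the block-diagonal kinematics."""
    J2 = F2[..., 0, 0] * F2[..., 1, 1] - F2[..., 0, 1] * F2[..., 1, 0]
    J = J2 * lam3
    sig = np.empty_like(P2)
    sig[..., 0, 0] = P2[..., 0, 0] * F2[..., 0, 0] + P2[..., 0, 1] * F2[..., 0, 1]
    sig[..., 0, 1] = P2[..., 0, 0] * F2[..., 1, 0] + P2[..., 0, 1] * F2[..., 1, 1]
    sig[..., 1, 0] = P2[..., 1, 0] * F2[..., 0, 0] + P2[..., 1, 1] * F2[..., 0, 1]
    sig[..., 1, 1] = P2[..., 1, 0] * F2[..., 1, 0] + P2[..., 1, 1] * F2[..., 1, 1]
    sig = sig / J[..., None, None]
    # symmetrise (exact up to roundoff)
    s01 = 0.5 * (sig[..., 0, 1] + sig[..., 1, 0])
    sig[..., 0, 1] = s01
    sig[..., 1, 0] = s01
    sig33 = P3 * lam3 / J
    return sig, sig33


# ---------------------------------------------------------------------------
# Hyperfoam internals
# ---------------------------------------------------------------------------


def _principal_stretches(F2, lam3):
    """Principal stretches of the in-plane block (plus the out-of-plane one).

    Returns (l1, l2, lam3) with l1 >= l2, and also caches the spectral data
    needed to rotate principal stresses back (handled in _foam_piola).
    """
    c11 = F2[..., 0, 0] ** 2 + F2[..., 1, 0] ** 2
    c22 = F2[..., 0, 1] ** 2 + F2[..., 1, 1] ** 2
    c12 = F2[..., 0, 0] * F2[..., 0, 1] + F2[..., 1, 0] * F2[..., 1, 1]
    tr = c11 + c22
    disc = np.sqrt(np.maximum((c11 - c22) ** 2 / 4.0 + c12**2, 0.0))
    e1 = tr / 2.0 + disc
    e2 = tr / 2.0 - disc
    return np.sqrt(np.maximum(e1, 0.0)), np.sqrt(np.maximum(e2, 0.0)), lam3


def _foam_energy(l1, l2, l3, f: HyperfoamParams):
    # expm1/log formulation: with the printed alpha ~ 2e-3 the energy is an
    # O(alpha^2) residue of O(1) terms and the naive power form loses ~8
    # digits to cancellation (which breaks finite-difference consistency).
    a, b = f.alpha, f.beta
    lnJ = np.log(l1) + np.log(l2) + np.log(l3)
    bracket = (
        np.expm1(a * np.log(l1))
        + np.expm1(a * np.log(l2))
        + np.expm1(a * np.log(l3))
        + np.expm1(-a * b * lnJ) / b
    )
    return (2.0 * f.mu / a**2) * bracket


def _foam_principal_kirchhoff(l1, l2, l3, f: HyperfoamParams):
    """tau_i = l_i * dU/dl_i (principal Kirchhoff stresses)."""
    a, b = f.alpha, f.beta
    lnJ = np.log(l1) + np.log(l2) + np.log(l3)
    jb = np.expm1(-a * b * lnJ)
    c = 2.0 * f.mu / a
    return (
        c * (np.expm1(a * np.log(l1)) - jb),
        c * (np.expm1(a * np.log(l2)) - jb),
        c * (np.expm1(a * np.log(l3)) - jb),
    )


def _foam_piola(F2, lam3, f: HyperfoamParams):
    c11 = F2[..., 0, 0] ** 2 + F2[..., 1, 0] ** 2
    c22 = F2[..., 0, 1] ** 2 + F2[..., 1, 1] ** 2
    c12 = F2[..., 0, 0] * F2[..., 0, 1] + F2[..., 1, 0] * F2[..., 1, 1]
    tr = c11 + c22
    disc = np.sqrt(np.maximum((c11 - c22) ** 2 / 4.0 + c12**2, 0.0))
    e1 = tr / 2.0 + disc
    e2 = tr / 2.0 - disc
    l1 = np.sqrt(np.maximum(e1, 1.0e-30))
    l2 = np.sqrt(np.maximum(e2, 1.0e-30))
    t1, t2, t3 = _foam_principal_kirchhoff(l1, l2, lam3, f)
    # 2nd PK principal values S_i = tau_i / l_i^2
    S1 = t1 / e1
    S2 = t2 / e2
    S3 = t3 / lam3**2
    # rotate S back: S = S2_avg*I + dS*(N1 ox N1 - ...). Use spectral projection:
    # for a 2x2 symmetric C with eigenvalues e1 != e2:
    #   P1 = (C - e2 I)/(e1 - e2),  P2 = I - P1
    de = e1 - e2
    small = np.abs(de) < 1.0e-12 * np.maximum(np.abs(e1), 1.0)
    inv = np.where(small, 0.0, 1.0 / np.where(small, 1.0, de))
    # S(2x2) = S2*I + (S1-S2) * P1
    p1_11 = (c11 - e2) * inv
    p1_22 = (c22 - e2) * inv
    p1_12 = c12 * inv
    dS = S1 - S2
    s11 = S2 + dS * p1_11
    s22 = S2 + dS * p1_22
    s12 = dS * p1_12
    # degenerate (equal eigenvalue) case: isotropic in-plane stress
    s11 = np.where(small, S1, s11)
    s22 = np.where(small, S1, s22)
    s12 = np.where(small, 0.0, s12)

    P2 = np.empty_like(F2)
    P2[..., 0, 0] = F2[..., 0, 0] * s11 + F2[..., 0, 1] * s12
    P2[..., 0, 1] = F2[..., 0, 0] * s12 + F2[..., 0, 1] * s22
    P2[..., 1, 0] = F2[..., 1, 0] * s11 + F2[..., 1, 1] * s12
    P2[..., 1, 1] = F2[..., 1, 0] * s12 + F2[..., 1, 1] * s22
    P3 = lam3 * S3
    return P2, P3


# ---------------------------------------------------------------------------
# Convenience closed forms
# ---------------------------------------------------------------------------


def mr_energy(i1, i2, params: MooneyRivlinParams, j=1.0):
    """Mooney-Rivlin energy density from invariants (volumetric term for J != 1).

    For ``j = 1`` this is exactly ``C1*(I1-3) + C2*(I2-3)``.
    """
    i1 = np.asarray(i1, dtype=float)
    i2 = np.asarray(i2, dtype=float)
    j = np.asarray(j, dtype=float)
    w = params.c1 * (i1 - 3.0) + params.c2 * (i2 - 3.0)
    w = w + 0.5 * params.kappa * (j - 1.0) ** 2
    return w[()] if w.ndim == 0 else w


def mr_uniaxial_stress(lam, params: MooneyRivlinParams):
    """Uniaxial Cauchy stress of an incompressible Mooney-Rivlin solid.

    sigma(lambda) = 2*(lambda^2 - 1/lambda)*(C1 + C2/lambda).
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    s = 2.0 * (lam**2 - 1.0 / lam) * (params.c1 + params.c2 / lam)
    return s[()] if s.ndim == 0 else s


#: Muscle tissue (macro and capillary-surrounding), Mooney-Rivlin, MPa.
MUSCLE = MooneyRivlinParams(c1=0.0094, c2=0.082, d_vol=0.0)

#: Capillary wall, Mooney-Rivlin, MPa.
CAPILLARY_WALL = MooneyRivlinParams(c1=0.257, c2=0.00257, d_vol=1.0e-6)

#: Polyurethane wound filler, single-term hyperfoam.
PU_FOAM = HyperfoamParams(mu=0.907e-2, alpha=0.213e-2, beta=0.844e-2)
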