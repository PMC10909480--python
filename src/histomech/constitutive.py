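"""Hyperelastic constituent models under a plane-stress kinematic contract.

Two strain energies are implemented, in kPa throughout:

* neo-Hookean (isotropic matrix):

      Psi_NH = C10 * (Ibar1 - 3) + (1/D1) * (J - 1)^2

* Holzapfel-Gasser-Ogden (HGO) with a single collagen-fibre family:

      Psi = Psi_NH + k1/(2 k2) * (exp(k2 * E^2) - 1),
      E   = kappa * (Ibar1 - 3) + (1 - 3 kappa) * (Ibar4 - 1),

  where Ibar1 = J^(-2/3) tr(C) is the first distortional invariant,
  Ibar4 = J^(-2/3) a0.C.a0 the squared distortional stretch along the
  (in-plane, axial) fibre direction a0, kappa in [0, 1/3] the fibre
  dispersion (0 = perfectly aligned, 1/3 = isotropic).  The fibre term
  is included only while E > 0: collagen carries no load when the
  matrix is compressed along the fibre direction, which is the source
  of the tissue's tension-compression asymmetry.  The energy stays C^1
  across E = 0 because the fibre term is O(E^2).

Kinematics are plane stress: the material point carries an in-plane
deformation gradient F (2x2) plus an out-of-plane stretch lambda3; the
full deformation gradient is blkdiag(F, lambda3) and lambda3 is
condensed locally from sigma_33 = 0.

All kernels are vectorized over leading batch axes so the finite
element assembly can evaluate every quadrature point in one call; the
dataclass API wraps the batched kernels for single states.  Stresses
are second Piola-Kirchhoff S = 2 dPsi/dC (and Cauchy via push-forward);
the material tangent is the referential elasticity CC = 2 dS/dC, both
closed-form.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LAMBDA3_BRACKET = (0.05, 20.0)
_EYE3 = np.eye(3)


def d1_from_poisson(C10: float, nu: float = 0.49) -> float:
    """Incompressibility parameter D1 for a target small-strain Poisson ratio.

    From the small-strain identities mu0 = 2*C10, K0 = 2/D1 and
    K0 = 2 mu0 (1 + nu) / (3 (1 - 2 nu)):
    D1 = 3 (1 - 2 nu) / (2 C10 (1 + nu)).
    """
    if not (0 <= nu < 0.5):
        raise ValueError("nu must lie in [0, 0.5)")
    return 3.0 * (1.0 - 2.0 * nu) / (2.0 * C10 * (1.0 + nu))


def c10_from_youngs(E_kpa: float, nu: float = 0.49) -> float:
    """C10 from a Young's modulus via mu = E/(2(1+nu)) and mu = 2*C10."""
    return E_kpa / (4.0 * (1.0 + nu))


@dataclass
class NeoHookeanParams:
    C10: float          # kPa
    D1: float           # 1/kPa

    def __post_init__(self):
        if not (self.C10 > 0 and self.D1 > 0):
            raise ValueError("C10 and D1 must be positive")

    @classmethod
    def from_poisson(cls, C10: float, nu: float = 0.49):
        return cls(C10, d1_from_poisson(C10, nu))


@dataclass
class HGOParams:
    base: NeoHookeanParams
    k1: float           # kPa, fibre stiffness
    k2: float           # dimensionless fibre nonlinearity
    kappa: float = 0.0  # dispersion in [0, 1/3]

    def __post_init__(self):
        if self.k1 < 0:
            raise ValueError("k1 must be nonnegative")
        if not (self.k2 > 0):
            raise ValueError("k2 must be positive")
        if not (0.0 <= self.kappa <= 1.0 / 3.0 + 1e-15):
            raise ValueError("kappa must lie in [0, 1/3]")


@dataclass
class DeformationState:
    """In-plane deformation gradient + out-of-plane stretch (+ fibre angle)."""

    F_inplane: np.ndarray
    lambda3: float
    fiber_angle_deg: float = np.nan

    def __post_init__(self):
        self.F_inplane = np.asarray(self.F_inplane, dtype=float)
        if self.F_inplane.shape != (2, 2):
            raise ValueError("F_inplane must be 2x2")
        if np.linalg.det(self.F_inplane) <= 0:
            raise ValueError("det(F_inplane) must be positive")
        if not (self.lambda3 > 0):
            raise ValueError("lambda3 must be positive")

    def _kin(self):
        return kinematics(self.F_inplane, self.lambda3,
                          self.fiber_angle_deg)

    @property
    def J(self) -> float:
        """Volume ratio det(F_inplane) * lambda3."""
        return float(self._kin()[2])

    @property
    def Ibar1(self) -> float:
        """First distortional invariant J^(-2/3) tr(C)."""
        _, _, J, I1, _, _ = self._kin()
        return float(J ** (-2.0 / 3.0) * I1)

    @property
    def Ibar4(self) -> float:
        """Squared distortional stretch along the fibre direction."""
        _, _, J, _, I4, _ = self._kin()
        return float(J ** (-2.0 / 3.0) * I4)


def _params_arrays(material):
    """(C10, D1, k1, k2, kappa) scalars for either parameter type."""
    if isinstance(material, HGOParams):
        return (material.base.C10, material.base.D1, material.k1,
                material.k2, material.kappa)
    if isinstance(material, NeoHookeanParams):
        return (material.C10, material.D1, 0.0, 1.0, 0.0)
    raise TypeError(f"unsupported material {type(material).__name__}")


# ---------------------------------------------------------------------------
# batched kernels: leading axes are batch, F is (..., 2, 2), scalars (...,)
# ---------------------------------------------------------------------------

def kinematics(F2d, lam3, angle_deg):
    """Invariants of blkdiag(F, lambda3) and the structural tensor a0 x a0."""
    F2d = np.asarray(F2d, dtype=float)
    lam3 = np.asarray(lam3, dtype=float)
    detF2 = F2d[..., 0, 0] * F2d[..., 1, 1] - F2d[..., 0, 1] * F2d[..., 1, 0]
    J = detF2 * lam3
    if np.any(J <= 0):
        raise ValueError("non-positive volume ratio J")
    C2 = np.einsum("...ki,...kj->...ij", F2d, F2d)
    C = np.zeros(F2d.shape[:-2] + (3, 3))
    C[..., :2, :2] = C2
    C[..., 2, 2] = lam3**2
    Cinv = np.zeros_like(C)
    det2 = C2[..., 0, 0] * C2[..., 1, 1] - C2[..., 0, 1] * C2[..., 1, 0]
    Cinv[..., 0, 0] = C2[..., 1, 1] / det2
    Cinv[..., 1, 1] = C2[..., 0, 0] / det2
    Cinv[..., 0, 1] = -C2[..., 0, 1] / det2
    Cinv[..., 1, 0] = -C2[..., 1, 0] / det2
    Cinv[..., 2, 2] = lam3**-2
    I1 = C[..., 0, 0] + C[..., 1, 1] + C[..., 2, 2]
    ang = np.nan_to_num(np.asarray(angle_deg, dtype=float), nan=0.0)
    t = np.deg2rad(ang)
    a0 = np.zeros(F2d.shape[:-2] + (3,))
    a0[..., 0] = np.cos(t)
    a0[..., 1] = np.sin(t)
    A = np.einsum("...i,...j->...ij", a0, a0)
    I4 = np.einsum("...i,...ij,...j->...", a0, C, a0)
    return C, Cinv, J, I1, I4, A


def _psi_derivatives(J, I1, I4, C10, D1, k1, k2, kappa):
    """First/second derivatives of Psi w.r.t. (Ibar1, Ibar4, J)."""
    Jm23 = J ** (-2.0 / 3.0)
    Ib1 = Jm23 * I1
    Ib4 = Jm23 * I4
    E = kappa * (Ib1 - 3.0) + (1.0 - 3.0 * kappa) * (Ib4 - 1.0)
    act = (E > 0.0) & (np.asarray(k1) > 0.0)
    # cap keeps the tangent finite; reachable only far outside the
    # <= 5% strain working range of the model
    ex = np.exp(np.minimum(k2 * E * E, 200.0))
    fp = np.where(act, k1 * E * ex, 0.0)                  # dPsi_f/dE
    fpp = np.where(act, k1 * (1.0 + 2.0 * k2 * E * E) * ex, 0.0)
    psi1 = C10 + fp * kappa
    psi4 = fp * (1.0 - 3.0 * kappa)
    psiJ = (2.0 / D1) * (J - 1.0)
    psi11 = fpp * kappa**2
    psi14 = fpp * kappa * (1.0 - 3.0 * kappa)
    psi44 = fpp * (1.0 - 3.0 * kappa) ** 2
    psiJJ = 2.0 / D1
    energy = (C10 * (Ib1 - 3.0) + (1.0 / D1) * (J - 1.0) ** 2
              + np.where(act, k1 / (2.0 * k2) * (ex - 1.0), 0.0))
    return Jm23, energy, psi1, psi4, psiJ, psi11, psi14, psi44, psiJJ


def energy_batch(F2d, lam3, angle_deg, C10, D1, k1, k2, kappa):
    _, _, J, I1, I4, _ = kinematics(F2d, lam3, angle_deg)
    _, energy, *_ = _psi_derivatives(J, I1, I4, C10, D1, k1, k2, kappa)
    return energy


def _pk2_from_parts(kin, psis):
    Cinv, J, I1, I4, A = kin[1], kin[2], kin[3], kin[4], kin[5]
    Jm23, psi1, psi4, psiJ = psis[0], psis[2], psis[3], psis[4]
    G1 = Jm23[..., None, None] * (_EYE3 - (I1 / 3.0)[..., None, None] * Cinv)
    G4 = Jm23[..., None, None] * (A - (I4 / 3.0)[..., None, None] * Cinv)
    S = (2.0 * psi1[..., None, None] * G1
         + 2.0 * psi4[..., None, None] * G4
         + (psiJ * J)[..., None, None] * Cinv)
    return S


def pk2_batch(F2d, lam3, angle_deg, C10, D1, k1, k2, kappa):
    """Second Piola-Kirchhoff stress S = 2 dPsi/dC, (..., 3, 3)."""
    kin = kinematics(F2d, lam3, angle_deg)
    psis = _psi_derivatives(kin[2], kin[3], kin[4], C10, D1, k1, k2, kappa)
    return _pk2_from_parts(kin, psis)


def _elasticity_from_parts(kin, psis):
    C, Cinv, J, I1, I4, A = kin
    (Jm23, _, psi1, psi4, psiJ, psi11, psi14, psi44, psiJJ) = psis
    G1 = Jm23[..., None, None] * (_EYE3 - (I1 / 3.0)[..., None, None] * Cinv)
    G4 = Jm23[..., None, None] * (A - (I4 / 3.0)[..., None, None] * Cinv)
    # dCinv_MJ/dC_NL, symmetrised
    Dinv = -0.5 * (np.einsum("...mn,...jl->...mjnl", Cinv, Cinv)
                   + np.einsum("...ml,...jn->...mjnl", Cinv, Cinv))
    eye = np.broadcast_to(_EYE3, Cinv.shape)

    def second_deriv(B, Ib):
        """d/dC of Jm23 * (B - (Ib/3) Cinv) for constant structural B."""
        t1 = -(1.0 / 3.0) * (np.einsum("...mj,...nl->...mjnl", B, Cinv)
                             + np.einsum("...mj,...nl->...mjnl", Cinv, B))
        t2 = (Ib / 9.0)[..., None, None, None, None] * np.einsum(
            "...mj,...nl->...mjnl", Cinv, Cinv)
        t3 = -(Ib / 3.0)[..., None, None, None, None] * Dinv
        return Jm23[..., None, None, None, None] * (t1 + t2 + t3)

    H1 = second_deriv(eye, I1)
    H4 = second_deriv(A, I4)
    CC = 4.0 * (psi11[..., None, None, None, None]
                * np.einsum("...mj,...nl->...mjnl", G1, G1)
                + psi14[..., None, None, None, None]
                * (np.einsum("...mj,...nl->...mjnl", G1, G4)
                   + np.einsum("...mj,...nl->...mjnl", G4, G1))
                + psi44[..., None, None, None, None]
                * np.einsum("...mj,...nl->...mjnl", G4, G4))
    CC = CC + 4.0 * psi1[..., None, None, None, None] * H1
    CC = CC + 4.0 * psi4[..., None, None, None, None] * H4
    CC = CC + ((psiJJ * J + psiJ) * J)[..., None, None, None, None] \
        * np.einsum("...mj,...nl->...mjnl", Cinv, Cinv)
    CC = CC + (2.0 * psiJ * J)[..., None, None, None, None] * Dinv
    return CC


def elasticity_batch(F2d, lam3, angle_deg, C10, D1, k1, k2, kappa):
    """Referential elasticity CC = 2 dS/dC, (..., 3, 3, 3, 3)."""
    kin = kinematics(F2d, lam3, angle_deg)
    psis = _psi_derivatives(kin[2], kin[3], kin[4], C10, D1, k1, k2, kappa)
    return _elasticity_from_parts(kin, psis)


def _p33_and_derivative(F2d, lam3, angle_deg, C10, D1, k1, k2, kappa):
    """P_33 and dP_33/dlambda3 = S_33 + lambda3^2 * CC_3333, closed form.

    Scalar specialization used by the plane-stress root solve; avoids
    building the full fourth-order tangent per iteration.  The fibre
    direction is in-plane, so the structural tensor has no 33 component.
    """
    C, Cinv, J, I1, I4, A = kinematics(F2d, lam3, angle_deg)
    Jm23, _, psi1, psi4, psiJ, psi11, psi14, psi44, psiJJ = \
        _psi_derivatives(J, I1, I4, C10, D1, k1, k2, kappa)
    c33 = Cinv[..., 2, 2]
    G1_33 = Jm23 * (1.0 - I1 / 3.0 * c33)
    G4_33 = Jm23 * (-I4 / 3.0 * c33)
    S33 = 2.0 * psi1 * G1_33 + 2.0 * psi4 * G4_33 + psiJ * J * c33
    H1_3333 = Jm23 * (-(2.0 / 3.0) * c33 + (4.0 * I1 / 9.0) * c33**2)
    H4_3333 = Jm23 * (4.0 * I4 / 9.0) * c33**2
    CC3333 = (4.0 * (psi11 * G1_33**2 + 2.0 * psi14 * G1_33 * G4_33
                     + psi44 * G4_33**2)
              + 4.0 * psi1 * H1_3333 + 4.0 * psi4 * H4_3333
              + (psiJJ * J + psiJ) * J * c33**2 - 2.0 * psiJ * J * c33**2)
    return lam3 * S33, S33 + lam3**2 * CC3333


def _full_F(F2d, lam3):
    F = np.zeros(np.asarray(F2d).shape[:-2] + (3, 3))
    F[..., :2, :2] = F2d
    F[..., 2, 2] = lam3
    return F


def pk1_and_tangent_batch(F2d, lam3, angle_deg, C10, D1, k1, k2, kappa):
    """First Piola-Kirchhoff stress P = F S and A_iJkL = dP_iJ/dF_kL."""
    kin = kinematics(F2d, lam3, angle_deg)
    psis = _psi_derivatives(kin[2], kin[3], kin[4], C10, D1, k1, k2, kappa)
    S = _pk2_from_parts(kin, psis)
    CC = _elasticity_from_parts(kin, psis)
    F = _full_F(F2d, lam3)
    P = np.einsum("...im,...mj->...ij", F, S)
    geo = np.einsum("ik,...jl->...ijkl", _EYE3, S)
    mat = np.einsum("...im,...mjnl,...kn->...ijkl", F, CC, F, optimize=True)
    return P, geo + mat


def solve_plane_stress_lambda3(F2d, angle_deg, C10, D1, k1, k2, kappa,
                               lam3_init=None, max_iter: int = 80):
    """Out-of-plane stretch from sigma_33 = 0, batched safeguarded Newton.

    Since sigma_33 = lam3 * P_33 / J and lam3, J > 0, the root of P_33
    is used; Newton steps use A_3333 and fall back to bisection on the
    bracket lam3 in [0.05, 20].
    """
    F2d = np.asarray(F2d, dtype=float)
    shape = F2d.shape[:-2]
    lam3 = np.full(shape, 1.0) if lam3_init is None else np.array(
        lam3_init, dtype=float, copy=True)
    lo = np.full(shape, LAMBDA3_BRACKET[0])
    hi = np.full(shape, LAMBDA3_BRACKET[1])

    def p33(l3):
        return _p33_and_derivative(F2d, l3, angle_deg,
                                   C10, D1, k1, k2, kappa)[0]

    r_lo, r_hi = p33(lo), p33(hi)
    if np.any(r_lo > 0) or np.any(r_hi < 0):
        raise RuntimeError(
            "plane-stress condensation: no sigma_33 root bracketed in "
            f"lambda3 in {list(LAMBDA3_BRACKET)}")
    lam3 = np.clip(lam3, lo + 1e-6, hi - 1e-6)
    detF2 = F2d[..., 0, 0] * F2d[..., 1, 1] - F2d[..., 0, 1] * F2d[..., 1, 0]
    scale0 = np.maximum(1.0, np.abs(C10) * 4.0)  # reference stress scale
    for _ in range(max_iter):
        r, dr = _p33_and_derivative(F2d, lam3, angle_deg,
                                    C10, D1, k1, k2, kappa)
        # convergence on the physical stress: |sigma_33| << stress scale
        J = detF2 * lam3
        sig33 = lam3 * r / J
        if np.all(np.abs(sig33) <= 1e-12 * scale0):
            return lam3
        hi = np.where(r > 0, lam3, hi)
        lo = np.where(r <= 0, lam3, lo)
        with np.errstate(divide="ignore", invalid="ignore"):
            cand = lam3 - r / dr
        bad = ~np.isfinite(cand) | (cand < lo) | (cand > hi) | (dr <= 0)
        new = np.where(bad, 0.5 * (lo + hi), cand)
        # float64 floor: lambda3 cannot be resolved further; accept if the
        # residual stress is already negligible against the stress scale
        if np.all(np.abs(new - lam3) <= 1e-14 * np.abs(lam3)):
            if np.all(np.abs(sig33) <= 1e-7 * scale0):
                return new
        lam3 = new
    raise RuntimeError("plane-stress lambda3 iteration did not converge")


def condensed_response_batch(F2d, angle_deg, C10, D1, k1, k2, kappa,
                             lam3_init=None, need_tangent=True,
                             need_energy=False):
    """Plane-stress condensed in-plane PK1 stress and tangent.

    Solves sigma_33 = 0 for lambda3 at every point, then statically
    condenses the out-of-plane component out of the full tangent:
    Ahat = A_inplane - A_(iJ33) A_(33kL) / A_3333.

    Returns (lambda3, P_inplane (...,2,2), Ahat (...,2,2,2,2) or None,
    energy).  ``need_tangent=False`` skips the fourth-order tensor (for
    residual-only evaluations).
    """
    lam3 = solve_plane_stress_lambda3(F2d, angle_deg, C10, D1, k1, k2,
                                      kappa, lam3_init)
    if not need_tangent:
        S = pk2_batch(F2d, lam3, angle_deg, C10, D1, k1, k2, kappa)
        F = _full_F(F2d, lam3)
        P = np.einsum("...im,...mj->...ij", F, S)
        W = energy_batch(F2d, lam3, angle_deg, C10, D1, k1, k2, kappa) \
            if need_energy else None
        return lam3, P[..., :2, :2], None, W
    P, Atan = pk1_and_tangent_batch(F2d, lam3, angle_deg,
                                    C10, D1, k1, k2, kappa)
    A33 = Atan[..., 2, 2, 2, 2]
    Ahat = (Atan[..., :2, :2, :2, :2]
            - np.einsum("...ij,...kl->...ijkl",
                        Atan[..., :2, :2, 2, 2],
                        Atan[..., 2, 2, :2, :2]) / A33[..., None, None,
                                                       None, None])
    W = energy_batch(F2d, lam3, angle_deg, C10, D1, k1, k2, kappa) \
        if need_energy else None
    return lam3, P[..., :2, :2], Ahat, W


# ---------------------------------------------------------------------------
# single-state API
# ---------------------------------------------------------------------------

def neo_hookean_energy(state: DeformationState, p: NeoHookeanParams) -> float:
    """Psi_NH = C10 (Ibar1 - 3) + (1/D1)(J - 1)^2, in kPa."""
    return float(energy_batch(state.F_inplane, state.lambda3,
                              state.fiber_angle_deg, p.C10, p.D1,
                              0.0, 1.0, 0.0))


def hgo_energy(state: DeformationState, p: HGOParams) -> float:
    """HGO energy with the tension-only fibre term (active only for E > 0)."""
    if not np.isfinite(state.fiber_angle_deg) and p.k1 > 0:
        raise ValueError("HGO material requires a defined fibre angle")
    return float(energy_batch(state.F_inplane, state.lambda3,
                              state.fiber_angle_deg, p.base.C10, p.base.D1,
                              p.k1, p.k2, p.kappa))


def pk2_stress(state: DeformationState, material) -> np.ndarray:
    """Second Piola-Kirchhoff stress S = 2 dPsi/dC (3x3, kPa)."""
    C10, D1, k1, k2, kappa = _params_arrays(material)
    return pk2_batch(state.F_inplane, state.lambda3, state.fiber_angle_deg,
                     C10, D1, k1, k2, kappa)


def cauchy_stress(state: DeformationState, material) -> np.ndarray:
    """Cauchy stress sigma = (1/J) F S F^T (3x3 symmetric, kPa)."""
    C10, D1, k1, k2, kappa = _params_arrays(material)
    S = pk2_batch(state.F_inplane, state.lambda3, state.fiber_angle_deg,
                  C10, D1, k1, k2, kappa)
    F = _full_F(state.F_inplane, state.lambda3)
    J = np.linalg.det(F)
    return np.einsum("im,mn,jn->ij", F, S, F) / J


def material_tangent(state: DeformationState, material) -> np.ndarray:
    """Referential elasticity CC = 2 dS/dC (3x3x3x3, kPa).

    The consistent linearization of the stress: dS = CC : dC / 2.
    """
    C10, D1, k1, k2, kappa = _params_arrays(material)
    return elasticity_batch(state.F_inplane, state.lambda3,
                            state.fiber_angle_deg, C10, D1, k1, k2, kappa)


def plane_stress_condense(F_inplane, material, fiber_angle_deg=np.nan):
    """Solve sigma_33 = 0 and return (lambda3, in-plane Cauchy stress,
    condensed in-plane PK1 tangent)."""
    F_inplane = np.asarray(F_inplane, dtype=float)
    if np.linalg.det(F_inplane) <= 0:
        raise ValueError("det(F_inplane) must be positive")
    C10, D1, k1, k2, kappa = _params_arrays(material)
    lam3, P2, Ahat, _ = condensed_response_batch(
        F_inplane, fiber_angle_deg, C10, D1, k1, k2, kappa)
    state = DeformationState(F_inplane, float(lam3), fiber_angle_deg)
    sig = cauchy_stress(state, material)
    return float(lam3), sig[:2, :2], Ahat
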