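"""Guccione transversely isotropic law, active stress and incompressibility.

Strain energy (fibre-frame Green-Lagrange strain components E_ij, fibres
along e1):

    W = C_mat/2 (exp(Q) - 1),
    Q = b_f E11^2 + b_t (E22^2 + E33^2 + E23^2 + E32^2)
      + b_fs (E12^2 + E21^2 + E13^2 + E31^2),

with the off-diagonal components counted separately, so the componentwise
derivative dW/dE_ij = C_mat exp(Q) B_ij E_ij (B the coefficient matrix) is
symmetric without an extra factor of two.  The total second Piola-Kirchhoff
stress adds a constant active fibre tension and the exact incompressibility
multiplier term:

    T = T_p + T_a f f^T - p J C^{-1},      C = F^T F,

with the sign convention that p > 0 is a compressive hydrostatic Cauchy
stress (-p I at F = I).  An optional volumetric-deviatoric split evaluates
the passive law on the isochoric strain built from J^(-1/3) F; at an
incompressible solution (J = 1) the split changes nothing, but it
stabilises the inflation problems on the way there.

All functions broadcast over leading axes and accept complex input (for
complex-step differentiation in the solver).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EYE = np.eye(3)


@dataclass(frozen=True)
class MaterialParams:
    """Guccione parameters: C_mat in kPa, exponents dimensionless.

    The material constant of the energy is stored as ``C_mat`` to avoid a
    symbol collision with the right Cauchy-Green tensor.
    """

    C_mat: float
    b_f: float
    b_t: float
    b_fs: float

    def __post_init__(self):
        if self.C_mat <= 0:
            raise ValueError("C_mat must be > 0")
        if min(self.b_f, self.b_t, self.b_fs) < 0:
            raise ValueError("exponents must be >= 0")

    @property
    def b_matrix(self) -> np.ndarray:
        bf, bt, bfs = self.b_f, self.b_t, self.b_fs
        return np.array([[bf, bfs, bfs], [bfs, bt, bt], [bfs, bt, bt]])


@dataclass(frozen=True)
class ActiveParams:
    """Constant active fibre tension T_a in kPa."""

    T_a: float = 0.0

    def __post_init__(self):
        if self.T_a < 0:
            raise ValueError("T_a must be >= 0")


@dataclass
class KinematicState:
    """Deformation gradient plus the local fibre frame.

    F : (..., 3, 3); basis Q : (..., 3, 3) with columns (e1=f, e2, e3).
    """

    F: np.ndarray
    basis: np.ndarray

    @property
    def J(self):
        return np.linalg.det(self.F)

    @property
    def C(self):
        return np.swapaxes(self.F, -1, -2) @ self.F

    @property
    def E(self):
        return 0.5 * (self.C - _EYE)


@dataclass
class StressState:
    """Second Piola-Kirchhoff and Cauchy stress (kPa) with the multiplier."""

    T: np.ndarray
    sigma: np.ndarray
    p: np.ndarray


def _Q_exponent(E_fib, m: MaterialParams):
    B = m.b_matrix
    return np.sum(B * E_fib * E_fib, axis=(-2, -1))


def strain_energy(E_fib, m: MaterialParams):
    """W(E) in kPa for fibre-frame strain components."""
    Q = _Q_exponent(np.asarray(E_fib), m)
    return 0.5 * m.C_mat * (np.exp(Q) - 1.0)


def passive_second_pk(E_fib, m: MaterialParams):
    """Componentwise dW/dE in the fibre frame: C_mat e^Q B_ij E_ij."""
    E_fib = np.asarray(E_fib)
    Q = _Q_exponent(E_fib, m)
    return m.C_mat * np.exp(Q)[..., None, None] * m.b_matrix * E_fib


def _rotate_to_fibre(A, basis):
    return np.swapaxes(basis, -1, -2) @ A @ basis


def _rotate_from_fibre(A, basis):
    return basis @ A @ np.swapaxes(basis, -1, -2)


def total_second_pk_from_E(E, basis, m: MaterialParams, a: ActiveParams, p, *, split=False):
    """Total second Piola-Kirchhoff stress as a function of E (and p).

    E may be any (...,3,3) array (components treated independently, as in
    the energy); C = 2E + I and J = sqrt(det C) are derived from it, which
    keeps the function meaningful for finite-difference and complex-step
    probes of single strain components.
    """
    E = np.asarray(E)
    C = 2.0 * E + _EYE
    Cinv = np.linalg.inv(C)
    J = np.sqrt(np.linalg.det(C))
    if split:
        Jm23 = J ** (-2.0 / 3.0)
        Ebar = 0.5 * (Jm23[..., None, None] * C - _EYE)
        Sbar = _rotate_from_fibre(
            passive_second_pk(_rotate_to_fibre(Ebar, basis), m), basis
        )
        trace = np.einsum("...ij,...ij->...", Sbar, C)
        Tp = Jm23[..., None, None] * (
            Sbar - (trace / 3.0)[..., None, None] * Cinv
        )
    else:
        Tp = _rotate_from_fibre(passive_second_pk(_rotate_to_fibre(E, basis), m), basis)
    f = basis[..., 0]
    active = np.asarray(a.T_a) * f[..., :, None] * f[..., None, :]
    vol = -np.asarray(p)[..., None, None] * J[..., None, None] * Cinv
    return Tp + active + vol


def total_second_pk(k: KinematicState, m: MaterialParams, a: ActiveParams, p, *, split=False):
    """Total second Piola-Kirchhoff stress at a kinematic state (kPa)."""
    return total_second_pk_from_E(k.E, k.basis, m, a, np.asarray(p, dtype=float), split=split)


def cauchy_stress(k: KinematicState, T):
    """sigma = J^-1 F T F^T.  Raises on non-positive J (inverted element)."""
    J = k.J
    if np.any(np.real(J) <= 0.0):
        raise ValueError("non-positive J: inverted element")
    Ft = np.swapaxes(k.F, -1, -2)
    return (k.F @ np.asarray(T) @ Ft) / J[..., None, None]


def material_tangent(k: KinematicState, m: MaterialParams, a: ActiveParams, p, *, split=False):
    """Analytic dT/dE (componentwise, 9 independent slots) and dT/dp.

    Returns ``(dT_dE, dT_dp)`` with shapes (...,3,3,3,3) and (...,3,3).
    The passive block carries major symmetry (second derivative of W); the
    active stress is strain independent; the volumetric block follows from
    d(J C^-1)/dC with C = 2E + I.  With ``split=True`` the passive part is
    differentiated by complex step (machine precision) instead.
    """
    E = np.asarray(k.E, dtype=float)
    basis = k.basis
    p = np.asarray(p, dtype=float)
    C = 2.0 * E + _EYE
    Cinv = np.linalg.inv(C)
    J = np.sqrt(np.linalg.det(C))

    if split:
        dTdE = np.zeros(E.shape + (3, 3), dtype=float)
        h = 1e-200
        base_vol = lambda Ec: -p[..., None, None] * np.sqrt(
            np.linalg.det(2.0 * Ec + _EYE)
        )[..., None, None] * np.linalg.inv(2.0 * Ec + _EYE)
        for kk in range(3):
            for ll in range(3):
                Ec = E.astype(complex).copy()
                Ec[..., kk, ll] += 1j * h
                T_pert = total_second_pk_from_E(Ec, basis, m, a, p, split=True)
                dTdE[..., kk, ll] = np.imag(T_pert) / h
        dTdp = -J[..., None, None] * Cinv
        return dTdE, dTdp

    E_fib = _rotate_to_fibre(E, basis)
    B = m.b_matrix
    Q = _Q_exponent(E_fib, m)
    ceQ = m.C_mat * np.exp(Q)
    BE = B * E_fib
    # fibre-frame passive tangent: ceQ (B_ij d_ik d_jl + 2 B_ij E_ij B_kl E_kl)
    diag = np.einsum("ij,ik,jl->ijkl", B, _EYE, _EYE)
    outer = 2.0 * np.einsum("...ij,...kl->...ijkl", BE, BE)
    C_fib = ceQ[..., None, None, None, None] * (diag + outer)
    # rotate all four legs back to the reference frame
    dTp = np.einsum("...im,...jn,...kp,...lq,...mnpq->...ijkl", basis, basis, basis, basis, C_fib)
    # volumetric: -p J (Cinv_ij Cinv_kl - 2 Cinv_ik Cinv_lj)
    pj = p * J
    dTvol = -pj[..., None, None, None, None] * (
        np.einsum("...ij,...kl->...ijkl", Cinv, Cinv)
        - 2.0 * np.einsum("...ik,...lj->...ijkl", Cinv, Cinv)
    )
    dTdp = -J[..., None, None] * Cinv
    return dTp + dTvol, dTdp
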