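"""Mixture free energy and stresses for the collagen/matrix constrained mixture.

The Helmholtz free energy per unit reference volume is

    Psi = rho_0^c W^c(Ie) + rho_0^m W^m(I1_bar) + rho_0 W^L(J)

with mass-specific strain energies: an exponential fiber law for collagen
(active only in tension through a Macaulay bracket), an isochoric Neo-Hookean
matrix, and a quadratic growth penalty W^L = kappa/2 (J - rho_0/rho_0(0))^2
that constrains the volume change to the accumulated net mass change
(incompressible growth).  Stresses are obtained as S = 2 dPsi/dC at frozen
internal variables; the derivative is implemented analytically through the
chain rule, with a finite-difference fallback retained for testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import (
    DecomposedDeformation,
    DegenerateDeformationError,
    ElasticInvariants,
    FiberFrame,
    elastic_invariants,
)
from .params import MaterialParams

__all__ = [
    "MixtureComposition",
    "collagen_energy",
    "matrix_energy",
    "penalty_energy",
    "mixture_free_energy",
    "second_pk_stress",
    "second_pk_stress_fd",
    "cauchy_stress",
]

_EYE = np.eye(3)


@dataclass(frozen=True)
class MixtureComposition:
    """Reference mass densities of the constituents (per total tissue volume).

    The total density is their sum; mass fractions follow.  The matrix
    density is constant in time, collagen evolves with healing.
    """

    rho_c: float
    rho_m: float

    def __post_init__(self):
        if self.rho_c < 0 or self.rho_m < 0:
            raise ValueError("constituent densities must be non-negative")

    @property
    def rho_0(self) -> float:
        return self.rho_c + self.rho_m

    @property
    def phi_c(self) -> float:
        return self.rho_c / self.rho_0

    @property
    def phi_m(self) -> float:
        return self.rho_m / self.rho_0


def collagen_energy(Ie_c: float, params: MaterialParams) -> float:
    """Exponential fiber strain energy, J/kg.  Zero in compression
    (squared elastic stretch at or below one)."""
    if not Ie_c > 0:
        raise ValueError("Ie_c must be positive")
    x = max(Ie_c - 1.0, 0.0)
    return params.k1 / (2.0 * params.k2) * np.expm1(params.k2 * x * x)


def _collagen_energy_d(Ie_c: float, params: MaterialParams) -> float:
    """dW^c/dIe_c."""
    x = max(Ie_c - 1.0, 0.0)
    return params.k1 * x * np.exp(params.k2 * x * x)


def matrix_energy(I1_bar: float, params: MaterialParams) -> float:
    """Isochoric Neo-Hookean matrix energy, J/kg; insensitive to volume
    change by construction."""
    return 0.5 * params.mu * (I1_bar - 3.0)


def penalty_energy(vol: float, rho_0: float, params: MaterialParams) -> float:
    """Growth-constraint penalty, J/kg; zero exactly at vol = rho_0/rho_0(0).

    ``vol`` is the kinematic J at a material point, or the independent
    dilatation field in the mixed finite-element setting.
    """
    if not vol > 0:
        raise ValueError("vol must be positive")
    target = rho_0 / params.rho0_init
    return 0.5 * params.kappa * (vol - target) ** 2


def mixture_free_energy(
    inv: ElasticInvariants, comp: MixtureComposition, params: MaterialParams
) -> float:
    """Free energy per unit reference volume (J/m^3 = Pa)."""
    return (
        comp.rho_c * collagen_energy(inv.Ie_c, params)
        + comp.rho_m * matrix_energy(inv.I1_bar, params)
        + comp.rho_0 * penalty_energy(inv.J, comp.rho_0, params)
    )


def _collagen_pk2(
    defo: DecomposedDeformation, frame: FiberFrame, params: MaterialParams
) -> np.ndarray:
    """2 dW^c/dC for the full volume filled with collagen (unit density).

    Ie = C : (A M_r A^T) with A = F_p^-1 F_r^-1, so the derivative is the
    pulled-back structural tensor scaled by the fiber-law slope.
    """
    A = np.linalg.inv(defo.F_p) @ np.linalg.inv(defo.F_r)
    w = A @ frame.a_r
    C = defo.F.T @ defo.F
    Ie = float(w @ C @ w)
    return 2.0 * _collagen_energy_d(Ie, params) * np.outer(w, w)


def _matrix_pk2(F: np.ndarray, params: MaterialParams) -> np.ndarray:
    """2 dW^m/dC (unit density): deviatoric projection of mu*I."""
    C = F.T @ F
    J2 = np.linalg.det(C)
    if J2 <= 0:
        raise DegenerateDeformationError("det(C) <= 0")
    C_inv = np.linalg.inv(C)
    return params.mu * J2 ** (-1.0 / 3.0) * (_EYE - (np.trace(C) / 3.0) * C_inv)


def second_pk_stress(
    defo: DecomposedDeformation,
    frame: FiberFrame,
    comp: MixtureComposition,
    params: MaterialParams,
    *,
    pressure: float | None = None,
) -> np.ndarray:
    """Second Piola-Kirchhoff stress S = 2 dPsi/dC at frozen internal state.

    With ``pressure=None`` the volumetric term is the penalty evaluated at
    the kinematic J (material-point setting).  In the mixed finite-element
    setting the penalty acts on the independent dilatation and the stress
    carries the Lagrange-multiplier term ``rho_0 p J C^-1`` instead; pass
    the element pressure ``p`` for that case.
    """
    F = defo.F
    J = np.linalg.det(F)
    if J <= 0:
        raise DegenerateDeformationError("det(F) <= 0")
    C_inv = np.linalg.inv(F.T @ F)

    S = comp.rho_c * _collagen_pk2(defo, frame, params)
    S = S + comp.rho_m * _matrix_pk2(F, params)
    if pressure is None:
        target = comp.rho_0 / params.rho0_init
        p_eff = params.kappa * (J - target)
    else:
        p_eff = pressure
    S = S + comp.rho_0 * p_eff * J * C_inv
    return 0.5 * (S + S.T)


def second_pk_stress_fd(
    defo: DecomposedDeformation,
    frame: FiberFrame,
    comp: MixtureComposition,
    params: MaterialParams,
    h: float = 1e-6,
) -> np.ndarray:
    """Central finite difference of the free energy w.r.t. C (testing only).

    Perturbs C symmetrically and recomputes the invariants at fixed
    F_p, F_r and fiber frame, i.e., at frozen internal state.
    """
    C0 = defo.F.T @ defo.F

    def psi_of_C(C: np.ndarray) -> float:
        # any F with F^T F = C works; use the symmetric square root
        w, V = np.linalg.eigh(0.5 * (C + C.T))
        F = V @ np.diag(np.sqrt(w)) @ V.T
        inv = elastic_invariants(F, defo.F_p, defo.F_r, frame)
        return mixture_free_energy(inv, comp, params)

    S = np.zeros((3, 3))
    for i in range(3):
        for j in range(i, 3):
            dC = np.zeros((3, 3))
            dC[i, j] += 0.5
            dC[j, i] += 0.5
            f_plus = psi_of_C(C0 + h * dC)
            f_minus = psi_of_C(C0 - h * dC)
            S[i, j] = S[j, i] = (f_plus - f_minus) / h
    return S  # already 2 dPsi/dC: symmetric perturbation counts both entries


def cauchy_stress(F: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Push-forward sigma = (1/J) F S F^T."""
    J = np.linalg.det(F)
    if J <= 0:
        raise DegenerateDeformationError("det(F) <= 0")
    sig = (F @ S @ F.T) / J
    return 0.5 * (sig + sig.T)
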