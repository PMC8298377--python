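"""Material-point (Gauss-point) driver: staggered phase logic and stress.

The internal variables are split into three sets that evolve in disjoint
phases of the simulated history:

* prestretch (t < t0): remodeling only, toward the deposition pre-stretch;
* damage (t0 <= t < t*): maximum-stretch tracking, damage and plastic flow
  (remodeling optionally left active; its effect over the seconds-long
  damage phase is negligible), species and densities frozen;
* healing (t >= t*): species/turnover dynamics and remodeling, plastic set
  frozen.  On entry the damaged/intact collagen pools are initialized from
  the accumulated damage.

``local_update`` is a pure function: it consumes a committed state and a
(right Cauchy-Green) deformation and returns the new state and the second
Piola-Kirchhoff stress, which makes the finite-difference consistent
tangent (including internal-variable sensitivity) straightforward.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import sqrt

import numpy as np

from .biology import BioState, init_pools, step_biology
from .constitutive import MixtureComposition
from .evolution import (
    PlasticState,
    plastic_increment,
    prestretch_remodeling,
    remodeling_increment,
    update_max_stretch,
)
from .params import MaterialParams

__all__ = [
    "PhaseSchedule",
    "GaussPointState",
    "phase_of",
    "initial_state",
    "local_update",
    "local_update_with_tangent",
    "pk2_stress",
]

_EYE = np.eye(3)


@dataclass(frozen=True)
class PhaseSchedule:
    """Phase boundaries: prestretch ends at t0, damage at t_star, healing
    at t_end.  Boundaries belong to the later phase."""

    t0: float
    t_star: float
    t_end: float

    def __post_init__(self):
        if not self.t0 < self.t_star < self.t_end:
            raise ValueError("schedule must satisfy t0 < t_star < t_end")


def phase_of(t: float, schedule: PhaseSchedule) -> str:
    if t < schedule.t0:
        return "prestretch"
    if t < schedule.t_star:
        return "damage"
    return "healing"


@dataclass(frozen=True)
class GaussPointState:
    """Complete internal state at a quadrature point."""

    a_0: tuple[float, float, float]
    plastic: PlasticState
    lambda_r: float
    lambda_hist: float  # history maximum of the tissue stretch along a_0
    rho_c: float
    rho_m: float
    bio: BioState | None = None

    @property
    def composition(self) -> MixtureComposition:
        return MixtureComposition(rho_c=self.rho_c, rho_m=self.rho_m)

    @property
    def rho_0(self) -> float:
        return self.rho_c + self.rho_m


def initial_state(params: MaterialParams, a_0=(1.0, 0.0, 0.0)) -> GaussPointState:
    a = np.asarray(a_0, dtype=float)
    a = a / np.linalg.norm(a)
    return GaussPointState(
        a_0=tuple(a),
        plastic=PlasticState(),
        lambda_r=1.0,
        lambda_hist=1.0,
        rho_c=params.rho_c0,
        rho_m=params.rho_m,
        bio=None,
    )


def fiber_stretch(C: np.ndarray, a_0) -> float:
    a = np.asarray(a_0, dtype=float)
    return sqrt(float(a @ C @ a))


def pk2_stress(
    C: np.ndarray,
    state: GaussPointState,
    params: MaterialParams,
    pressure: float | None = None,
) -> np.ndarray:
    """Second Piola-Kirchhoff stress at frozen internal state, from C alone.

    Specialization of the mixture stress to fiber frames generated by the
    unimodular inelastic stretches (all frame directions coincide with a_0,
    and the inelastic pull-back reduces to a 1/(lambda_p lambda_r) scaling
    of the structural tensor).
    """
    # hand-coded 3x3 algebra: this routine dominates the finite-element
    # runtime (hundreds of thousands of calls per solve)
    c00 = C[0, 0]; c01 = C[0, 1]; c02 = C[0, 2]
    c11 = C[1, 1]; c12 = C[1, 2]; c22 = C[2, 2]
    a0 = c11 * c22 - c12 * c12
    a1 = c02 * c12 - c01 * c22
    a2 = c01 * c12 - c02 * c11
    detC = c00 * a0 + c01 * a1 + c02 * a2
    if detC <= 0.0:
        raise FloatingPointError("det(C) <= 0: inverted deformation")
    C_inv = np.array([
        [a0, a1, a2],
        [a1, c00 * c22 - c02 * c02, c02 * c01 - c00 * c12],
        [a2, c02 * c01 - c00 * c12, c00 * c11 - c01 * c01],
    ]) / detC
    J = sqrt(detC)
    trC = c00 + c11 + c22

    ax, ay, az = state.a_0
    lam_pr = state.plastic.lambda_p * state.lambda_r

    # volumetric (growth penalty or mixed-element pressure) atop the
    # isochoric Neo-Hookean matrix
    rho_0 = state.rho_c + state.rho_m
    if pressure is None:
        p_eff = params.kappa * (J - rho_0 / params.rho0_init)
    else:
        p_eff = pressure
    cm = state.rho_m * params.mu * detC ** (-1.0 / 3.0)
    S = (rho_0 * p_eff * J - cm * trC / 3.0) * C_inv
    S[0, 0] += cm
    S[1, 1] += cm
    S[2, 2] += cm

    # collagen (tension only)
    Ca0 = C @ (ax, ay, az)
    Ie = (ax * Ca0[0] + ay * Ca0[1] + az * Ca0[2]) / (lam_pr * lam_pr)
    x = Ie - 1.0
    if x > 0.0:
        cc = (2.0 * state.rho_c / (lam_pr * lam_pr)
              * params.k1 * x * np.exp(params.k2 * x * x))
        a = np.array((ax, ay, az))
        S = S + cc * np.outer(a, a)
    return S


def advance_biology(
    state: GaussPointState,
    t: float,
    params: MaterialParams,
    schedule: PhaseSchedule,
    bio_substep: float | None,
) -> GaussPointState:
    """Bring the biological set up to time t (C-independent, so this can be
    done once per step and reused across Newton iterations)."""
    bio = state.bio
    if bio is None:
        rho_cd, rho_ci = init_pools(state.plastic.d, state.rho_c)
        bio = BioState(
            M=params.bio.M0,
            G=params.bio.G0,
            i_M=0.0,
            t=schedule.t_star,
            t_star=schedule.t_star,
            rho_cd=rho_cd,
            rho_ci=rho_ci,
            rho_c_star=state.rho_c,
        )
    remaining = t - bio.t
    if remaining <= 0:
        return replace(state, bio=bio, rho_c=bio.rho_c)
    h_max = bio_substep if bio_substep is not None else remaining
    n_sub = max(1, int(np.ceil(remaining / h_max - 1e-12)))
    h = remaining / n_sub
    for _ in range(n_sub):
        bio = step_biology(bio, h, params.bio)
    return replace(state, bio=bio, rho_c=bio.rho_c)


def local_update(
    C: np.ndarray,
    t: float,
    dt: float,
    state: GaussPointState,
    params: MaterialParams,
    schedule: PhaseSchedule,
    *,
    pressure: float | None = None,
    bio_substep: float | None = None,
    remodel_during_damage: bool = True,
) -> tuple[GaussPointState, np.ndarray]:
    """Advance the internal variables over (t - dt, t] at deformation C and
    return the updated state with the stress at the step end.

    ``t`` is the end time of the step and selects the phase.  Phase
    freezing is exact: fields not owned by the active phase are returned
    bitwise unchanged.
    """
    phase = phase_of(t, schedule)
    lam = fiber_stretch(C, state.a_0)

    if phase == "prestretch":
        lam_r = remodeling_increment(
            state.lambda_r, lam, state.plastic.lambda_p, dt, params
        )
        new = GaussPointState(
            a_0=state.a_0, plastic=state.plastic, lambda_r=lam_r,
            lambda_hist=state.lambda_hist, rho_c=state.rho_c,
            rho_m=state.rho_m, bio=state.bio,
        )

    elif phase == "damage":
        hist, lam_max = update_max_stretch(state.lambda_hist, lam, state.lambda_r)
        delta = max(lam_max - state.plastic.lambda_max, 0.0)
        plastic = plastic_increment(state.plastic, delta, lam, state.lambda_r, params)
        lam_r = state.lambda_r
        if remodel_during_damage:
            lam_r = remodeling_increment(lam_r, lam, plastic.lambda_p, dt, params)
        new = GaussPointState(
            a_0=state.a_0, plastic=plastic, lambda_r=lam_r,
            lambda_hist=hist, rho_c=state.rho_c,
            rho_m=state.rho_m, bio=state.bio,
        )

    else:  # healing
        adv = advance_biology(state, t, params, schedule, bio_substep)
        lam_r = remodeling_increment(
            adv.lambda_r, lam, adv.plastic.lambda_p, dt, params
        )
        new = GaussPointState(
            a_0=adv.a_0, plastic=adv.plastic, lambda_r=lam_r,
            lambda_hist=adv.lambda_hist, rho_c=adv.rho_c,
            rho_m=adv.rho_m, bio=adv.bio,
        )

    S = pk2_stress(C, new, params, pressure=pressure)
    return new, S


def local_update_with_tangent(
    C: np.ndarray,
    t: float,
    dt: float,
    state: GaussPointState,
    params: MaterialParams,
    schedule: PhaseSchedule,
    *,
    pressure: float | None = None,
    bio_substep: float | None = None,
    remodel_during_damage: bool = True,
    fd_step: float = 1e-6,
) -> tuple[GaussPointState, np.ndarray, np.ndarray]:
    """Like :func:`local_update` but also returns the algorithmically
    consistent material tangent CC with  dS = CC : dC  for symmetric dC.

    Central differences of the full local update, so the sensitivity of the
    internal variables to the deformation is included.  The biological set
    does not depend on C and is advanced once, then reused.
    """
    if phase_of(t, schedule) == "healing":
        state = advance_biology(state, t, params, schedule, bio_substep)

    # FD differentiates only the bounded collagen + matrix response (with
    # its internal-variable sensitivity); the very stiff volumetric term is
    # differentiated analytically so its magnitude cannot drown the soft
    # modes in finite-difference noise.
    def stress_at(Cp: np.ndarray) -> np.ndarray:
        _, Sp = local_update(
            Cp, t, dt, state, params, schedule,
            pressure=0.0, bio_substep=bio_substep,
            remodel_during_damage=remodel_during_damage,
        )
        return Sp

    new, S_iso = local_update(
        C, t, dt, state, params, schedule,
        pressure=0.0, bio_substep=bio_substep,
        remodel_during_damage=remodel_during_damage,
    )

    h = fd_step * max(1.0, float(np.abs(C).max()))
    CC = np.zeros((3, 3, 3, 3))
    for k in range(3):
        for l in range(k, 3):
            dC = np.zeros((3, 3))
            dC[k, l] += 1.0
            dC[l, k] += 1.0
            dS = (stress_at(C + h * dC) - S_iso) / h
            # dS/deps = CC : dC = 2 CC[..., k, l]  (minor symmetry)
            CC[:, :, k, l] = 0.5 * dS
            CC[:, :, l, k] = 0.5 * dS

    S_vol, CC_vol = _volumetric_stress_tangent(C, new, params, pressure)
    return new, S_vol + S_iso, CC + CC_vol


def _volumetric_stress_tangent(
    C: np.ndarray,
    state: GaussPointState,
    params: MaterialParams,
    pressure: float | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stress and exact tangent of the volumetric term rho_0 p_eff J C^-1,
    with p_eff the penalty slope (point setting) or the element pressure."""
    C_inv = np.linalg.inv(C)
    J = sqrt(float(np.linalg.det(C)))
    rho_0 = state.rho_0
    if pressure is None:
        p_eff = params.kappa * (J - rho_0 / params.rho0_init)
        dp_dC = params.kappa * 0.5 * J * C_inv  # dJ/dC
    else:
        p_eff = pressure
        dp_dC = None
    S = (rho_0 * p_eff * J) * C_inv

    # d(J C^-1)/dC = J [ (1/2) C^-1 x C^-1 - C^-1 (.) C^-1 ]
    CiCi = np.einsum("IJ,KL->IJKL", C_inv, C_inv)
    Codot = 0.5 * (
        np.einsum("IK,JL->IJKL", C_inv, C_inv)
        + np.einsum("IL,JK->IJKL", C_inv, C_inv)
    )
    CC = rho_0 * p_eff * J * (0.5 * CiCi - Codot)
    if dp_dC is not None:
        CC = CC + rho_0 * J * np.einsum("IJ,KL->IJKL", C_inv, dp_dC)
    return S, CC


def equilibrated_prestretch_state(
    state: GaussPointState, C: np.ndarray, params: MaterialParams
) -> GaussPointState:
    """Closed-form pre-stretch initialization: remodeling stretch set to its
    steady state so the elastic collagen stretch equals the pre-stretch."""
    lam = fiber_stretch(C, state.a_0)
    lam_r = prestretch_remodeling(lam, state.plastic.lambda_p, params)
    return replace(state, lambda_r=lam_r)
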