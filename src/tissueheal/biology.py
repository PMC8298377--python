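"""Damage-stimulated biochemistry: MMP and growth-factor dynamics driving
collagen turnover, and the resulting growth target.

Damaged collagen stimulates matrix-metalloproteinase (MMP) production; the
time-averaged MMP excess (with a saturating exponential memory) stimulates
growth-factor (GF) production; MMP degrades the damaged collagen pool while
GF deposits new intact collagen.  The net change of the collagen reference
density sets the target dilatation of incompressible volumetric growth.
All rates vanish identically at homeostasis (M = M0, G = G0, no damaged
collagen), which is therefore an exact fixed point.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

from .evolution import LocalSolverError
from .params import BioParams

__all__ = [
    "BioState",
    "init_pools",
    "mmp_rate",
    "accumulated_mmp",
    "gf_rate",
    "degradation_rate",
    "production_rate",
    "step_biology",
    "growth_target",
]

_FP_TOL = 1e-14
_FP_MAXIT = 200


@dataclass(frozen=True)
class BioState:
    """Biological state at a material point during healing.

    M, G      MMP / GF concentrations                [kg/m^3]
    i_M       running integral of M since t_star     [kg s/m^3]
    t         time of this state                     [s]
    t_star    healing start time                     [s]
    rho_cd    damaged collagen reference density     [kg/m^3]
    rho_ci    intact collagen reference density      [kg/m^3]
    rho_c_star collagen density at end of damage     [kg/m^3]
    """

    M: float
    G: float
    i_M: float
    t: float
    t_star: float
    rho_cd: float
    rho_ci: float
    rho_c_star: float

    def __post_init__(self):
        if self.M <= 0 or self.G <= 0:
            raise ValueError("species concentrations must be positive")
        if self.rho_cd < 0 or self.rho_ci < 0:
            raise ValueError("collagen pools cannot be negative")

    @property
    def rho_c(self) -> float:
        return self.rho_cd + self.rho_ci


def init_pools(d_star: float, rho_c_star: float) -> tuple[float, float]:
    """Split the collagen density at the end of the damage phase into
    damaged and intact pools proportionally to the damage variable."""
    if not 0.0 <= d_star <= 1.0:
        raise ValueError("d_star must lie in [0, 1]")
    if not rho_c_star > 0:
        raise ValueError("rho_c_star must be positive")
    rho_cd = d_star * rho_c_star
    return rho_cd, rho_c_star - rho_cd


def mmp_rate(state: BioState, params: BioParams) -> float:
    """MMP rate: production proportional to the damaged-collagen fraction,
    linear decay toward the homeostatic concentration."""
    return (
        params.m1 * state.rho_cd / state.rho_c_star
        - params.m2 * (state.M - params.M0)
    )


def accumulated_mmp(state: BioState, t: float, params: BioParams) -> float:
    """Saturating accumulated-MMP signal driving GF production.

    The time average of M over the healing window, less the homeostatic
    level, damped by exp(-(t-t*)/t_decay).  At the start of healing the
    0/0 average is defined by its right limit, M(t*) - M0.
    """
    dt_heal = t - state.t_star
    if dt_heal < 0:
        raise ValueError("accumulated MMP requested before healing start")
    if dt_heal == 0.0:
        return state.M - params.M0
    avg_excess = state.i_M / dt_heal - params.M0
    return avg_excess * math.exp(-dt_heal / params.t_decay)


def gf_rate(state: BioState, I_M: float, params: BioParams) -> float:
    """GF rate: production from the accumulated MMP signal, linear decay."""
    return params.g1 * I_M - params.g2 * (state.G - params.G0)


def degradation_rate(M: float, params: BioParams) -> float:
    """Rate of damaged-collagen removal (non-positive), active only for
    MMP above homeostatic; saturates at -kd1 for large MMP excess."""
    if not M > 0:
        raise ValueError("M must be positive")
    if M <= params.M0:
        return 0.0
    return params.kd1 * math.expm1(-params.kd2 * (M - params.M0) / params.M0)


def production_rate(G: float, params: BioParams) -> float:
    """Rate of intact-collagen deposition, saturating at ki1.

    The formula is negative for G below homeostatic; the dynamics never
    produce that regime, but it is left unclamped (a warning is emitted
    by the stepper if it ever occurs)."""
    if not G > 0:
        raise ValueError("G must be positive")
    return params.ki1 * -math.expm1(-params.ki2 * (G - params.G0) / params.G0)


def step_biology(
    state: BioState,
    dt: float,
    params: BioParams,
    *,
    freeze_pools: bool = False,
) -> BioState:
    """One backward-Euler step of the coupled species/turnover system.

    M and the damaged pool are mutually implicit and solved by fixed-point
    iteration (the coupling is weak); the accumulator, GF and intact pool
    then follow, each implicit in its own variable.  The damaged pool is
    clamped at zero, after which degradation stops.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    t_new = state.t + dt

    # --- implicit (M, rho_cd): eliminate the pool and solve the resulting
    # monotone scalar equation for M by safeguarded Newton
    def pool_of(M):
        if freeze_pools:
            return state.rho_cd
        return max(state.rho_cd + dt * degradation_rate(M, params), 0.0)

    denom = 1.0 + dt * params.m2

    def resid(M):
        return M * denom - state.M - dt * (
            params.m1 * pool_of(M) / state.rho_c_star + params.m2 * params.M0)

    lo = (state.M + dt * params.m2 * params.M0) / denom  # empty pool
    hi = (state.M + dt * (params.m1 * state.rho_cd / state.rho_c_star
                          + params.m2 * params.M0)) / denom  # full pool
    M_new = min(max(state.M, lo), hi)
    for _ in range(_FP_MAXIT):
        r = resid(M_new)
        if abs(r) <= _FP_TOL * max(params.M0, abs(M_new)):
            break
        # derivative of the pool term (zero when clamped or below M0)
        dpool = 0.0
        if not freeze_pools and M_new > params.M0 and pool_of(M_new) > 0.0:
            dpool = dt * (-params.kd1 * params.kd2 / params.M0
                          * math.exp(-params.kd2 * (M_new - params.M0)
                                     / params.M0))
        slope = denom - dt * params.m1 * dpool / state.rho_c_star
        step = -r / slope
        M_try = M_new + step
        if not lo <= M_try <= hi:  # bisection fallback on the bracket
            if r > 0:
                hi = M_new
            else:
                lo = M_new
            M_try = 0.5 * (lo + hi)
        if abs(M_try - M_new) <= 1e-17 * max(params.M0, abs(M_new)):
            M_new = M_try
            break
        M_new = M_try
    else:
        raise LocalSolverError("biology step: implicit MMP solve stalled")
    rcd_new = pool_of(M_new)

    # --- accumulator and GF (implicit in G)
    i_M_new = state.i_M + dt * M_new
    probe = replace(state, M=M_new, i_M=i_M_new)
    I_M = accumulated_mmp(probe, t_new, params)
    G_new = (state.G + dt * (params.g1 * I_M + params.g2 * params.G0)) / (
        1.0 + dt * params.g2
    )
    if G_new < params.G0 * (1.0 - 1e-9):  # tolerate accumulator round-off
        warnings.warn("GF concentration dropped below homeostatic level",
                      RuntimeWarning, stacklevel=2)

    # --- intact collagen deposition
    if freeze_pools:
        rci_new = state.rho_ci
    else:
        rci_new = state.rho_ci + dt * production_rate(G_new, params)

    return BioState(
        M=M_new,
        G=G_new,
        i_M=i_M_new,
        t=t_new,
        t_star=state.t_star,
        rho_cd=rcd_new,
        rho_ci=rci_new,
        rho_c_star=state.rho_c_star,
    )


def growth_target(rho_0: float, rho0_init: float) -> float:
    """Target dilatation of incompressible growth: current over initial
    total reference density."""
    if rho_0 <= 0 or rho0_init <= 0:
        raise ValueError("densities must be positive")
    return rho_0 / rho0_init
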