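"""Internal-variable evolution: collagen damage (plastic stretch) and remodeling.

Damage is driven by the maximum collagen stretch, the history maximum of the
tissue stretch along the fiber divided by the current remodeling stretch.
Above a threshold the damage variable grows linearly with that maximum and the
plastic stretch flows at rate d * (rate of maximum stretch) / (elastic
stretch), until at most the elastic stretch reaches one.  Remodeling drives
the elastic collagen stretch toward the deposition pre-stretch at a gain
k_rem.  All updates are backward Euler; the plastic update has a closed-form
solution of its implicit equation, the remodeling update is solved by a
safeguarded scalar Newton.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import MaterialParams

__all__ = [
    "PlasticState",
    "RemodelingState",
    "update_max_stretch",
    "damage_value",
    "plastic_increment",
    "remodeling_increment",
    "prestretch_remodeling",
    "LocalSolverError",
]

_NEWTON_TOL = 1e-12
_NEWTON_MAXIT = 50


class LocalSolverError(RuntimeError):
    """Local (Gauss-point level) Newton iteration failed to converge."""


@dataclass(frozen=True)
class PlasticState:
    """Damage set h_p: damage d, maximum collagen stretch, plastic stretch.

    All three are monotone non-decreasing along any admissible history
    (damage irreversibility)."""

    d: float = 0.0
    lambda_max: float = 1.0
    lambda_p: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.d <= 1.0:
            raise ValueError("damage must lie in [0, 1]")
        if self.lambda_p < 1.0:
            raise ValueError("plastic stretch cannot be below 1")


@dataclass(frozen=True)
class RemodelingState:
    lambda_r: float = 1.0

    def __post_init__(self):
        if not self.lambda_r > 0:
            raise ValueError("remodeling stretch must be positive")


def update_max_stretch(
    lambda_hist_prev: float, lambda_total: float, lambda_r: float
) -> tuple[float, float]:
    """Advance the history maximum of the tissue stretch and return it with
    the maximum collagen stretch (history maximum over the current
    remodeling stretch)."""
    hist = max(lambda_hist_prev, lambda_total)
    return hist, hist / lambda_r


def damage_value(lambda_max: float, params: MaterialParams) -> float:
    """Damage from the maximum collagen stretch: zero below the threshold,
    linear above, capped at one (held monotone by the caller)."""
    if not lambda_max > 0:
        raise ValueError("lambda_max must be positive")
    excess = lambda_max - params.lambda_bar_p
    if excess <= 0.0:
        return 0.0
    return min(1.0, params.m_p * excess)


def plastic_increment(
    state: PlasticState,
    delta_lambda_max: float,
    lambda_total: float,
    lambda_r: float,
    params: MaterialParams,
) -> PlasticState:
    """Backward-Euler update of the plastic flow over one step.

    The implicit equation  dlam_p = d * dlam_max / lam_e  with
    lam_e = lam / (lam_r lam_p) evaluated at the step end is linear in the
    end-of-step plastic stretch and solved in closed form; the flow is then
    clamped so the elastic stretch never drops below one, and plasticity is
    inactive when the trial elastic stretch is at or below one.
    """
    if delta_lambda_max < 0:
        raise ValueError("delta_lambda_max must be non-negative")
    lam_max_new = state.lambda_max + delta_lambda_max
    d_new = max(state.d, damage_value(lam_max_new, params))
    if delta_lambda_max == 0.0:
        return PlasticState(d=d_new, lambda_max=lam_max_new,
                            lambda_p=state.lambda_p)

    lam_e_trial = lambda_total / (lambda_r * state.lambda_p)
    if lam_e_trial <= 1.0 or d_new == 0.0:
        return PlasticState(d=d_new, lambda_max=lam_max_new,
                            lambda_p=state.lambda_p)

    denom = 1.0 - d_new * delta_lambda_max * lambda_r / lambda_total
    if denom <= 0.0:
        # flow would overshoot within the step; land on the lam_e = 1 cap
        lam_p_new = lambda_total / lambda_r
    else:
        lam_p_new = state.lambda_p / denom
    lam_p_new = min(lam_p_new, lambda_total / lambda_r)  # keep lam_e >= 1
    lam_p_new = max(lam_p_new, state.lambda_p)  # irreversible
    return PlasticState(d=d_new, lambda_max=lam_max_new, lambda_p=lam_p_new)


def remodeling_increment(
    lambda_r_prev: float,
    lambda_total: float,
    lambda_p: float,
    dt: float,
    params: MaterialParams,
) -> float:
    """Backward-Euler update of the remodeling stretch.

    Solves  lam_r = lam_r_n + dt k_rem (lam_e - lam_pre)/(lam_pre - 1)
    with lam_e = lam/(lam_r lam_p) at the step end.  The residual is
    strictly monotone in lam_r, so Newton with a bisection safeguard
    always converges.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if dt == 0.0:
        return lambda_r_prev
    c = dt * params.k_rem / (params.lambda_pre - 1.0)
    ratio = lambda_total / lambda_p

    def resid(x: float) -> float:
        return x - lambda_r_prev - c * (ratio / x - params.lambda_pre)

    def dresid(x: float) -> float:
        return 1.0 + c * ratio / (x * x)

    # bracket: the fixed point lies between lam_r_prev and lam/(lam_p lam_pre)
    lo = min(lambda_r_prev, ratio / params.lambda_pre) * 0.5
    hi = max(lambda_r_prev, ratio / params.lambda_pre) * 2.0
    x = lambda_r_prev
    for _ in range(_NEWTON_MAXIT):
        r = resid(x)
        if abs(r) <= _NEWTON_TOL * max(1.0, abs(x)):
            return x
        step = r / dresid(x)
        x_new = x - step
        if not (lo < x_new < hi):  # bisection fallback
            if r > 0:
                hi = x
            else:
                lo = x
            x_new = 0.5 * (lo + hi)
        x = x_new
    raise LocalSolverError(
        f"remodeling update did not converge: residual {resid(x):.3e}"
    )


def prestretch_remodeling(
    lambda_total: float, lambda_p: float, params: MaterialParams
) -> float:
    """Steady-state remodeling stretch under constant total stretch: the
    closed-form fixed point lam_e = lam_pre, i.e. lam_r = lam/(lam_p lam_pre).

    Equivalent to integrating the remodeling rate to stationarity; used as
    the default pre-stretch initialization.
    """
    return lambda_total / (lambda_p * params.lambda_pre)
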