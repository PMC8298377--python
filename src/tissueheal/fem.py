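"""Mixed three-field (u, theta, p) finite elements on hexahedral meshes.

Each H1-P0 element carries trilinear displacements at its eight nodes and an
element-wise constant dilatation/pressure pair enforcing, in the sense of a
Hu-Washizu functional, the equivalence of the volume map J and the
independent dilatation controlled by the growth penalty.  Since theta and p
are constant per element they are condensed analytically:

    theta_e = <J>_e,   p_e = kappa (theta_e - <rho_0/rho_0(0)>_e),

with rho_0-weighted element averages <.>_e, leaving a displacement-only
global Newton iteration.  Gauss-point internal variables are advanced by the
staggered material driver; they are committed only when the global iteration
has converged, so the local and global solves are properly nested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .driver import (
    GaussPointState,
    PhaseSchedule,
    advance_biology,
    initial_state,
    phase_of,
)
from .evolution import PlasticState
from .params import MaterialParams

__all__ = [
    "HexMesh",
    "LoadCase",
    "FemModel",
    "GlobalSolverError",
    "cone_pressure_profile",
]

_EYE = np.eye(3)

# 2x2x2 Gauss quadrature on the bi-unit cube
_G = 1.0 / np.sqrt(3.0)
_GAUSS_PTS = np.array(
    [(sx * _G, sy * _G, sz * _G) for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)]
)
_GAUSS_W = np.ones(8)

# node ordering of the trilinear hexahedron (VTK convention)
_XI_NODES = np.array(
    [
        (-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
        (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1),
    ],
    dtype=float,
)

# quadrature on a bilinear quadrilateral facet
_GAUSS2D = np.array([(sx * _G, sy * _G) for sy in (-1, 1) for sx in (-1, 1)])
_XI_QUAD = np.array([(-1, -1), (1, -1), (1, 1), (-1, 1)], dtype=float)


class GlobalSolverError(RuntimeError):
    """Global Newton iteration failed (after step bisection)."""


def _shape_gradients(xi: np.ndarray) -> np.ndarray:
    """d N_a / d xi at a quadrature point, shape (8, 3)."""
    out = np.empty((8, 3))
    for a, (xa, ya, za) in enumerate(_XI_NODES):
        out[a, 0] = 0.125 * xa * (1 + ya * xi[1]) * (1 + za * xi[2])
        out[a, 1] = 0.125 * ya * (1 + xa * xi[0]) * (1 + za * xi[2])
        out[a, 2] = 0.125 * za * (1 + xa * xi[0]) * (1 + ya * xi[1])
    return out


_DN_XI = np.array([_shape_gradients(xi) for xi in _GAUSS_PTS])  # (8 gp, 8, 3)


@dataclass
class HexMesh:
    """Hexahedral mesh with per-element fiber directions and boundary sets.

    ``node_sets`` maps names to node index arrays; ``top_facets`` lists
    (element index, 4 global node ids) of the loaded top surface.
    """

    nodes: np.ndarray
    elems: np.ndarray
    fiber: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    top_facets: list[tuple[int, np.ndarray]] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]


def cone_pressure_profile(r: float, r_p: float) -> float:
    """Spatial profile of the indentation pressure: linear cone, peaking at
    the center and vanishing at radius r_p and beyond."""
    return max(1.0 - r / r_p, 0.0)


@dataclass
class LoadCase:
    """Boundary conditions for one analysis.

    dirichlet: list of (node indices, component, value(t)) prescribed
    displacement specifications.  nodal_forces: optional callable t ->
    global force vector.  pressure: optional (pbar(t), r_p) dead surface
    pressure on the mesh's top facets, with the cone profile in the
    reference radius about the z axis.
    """

    dirichlet: list[tuple[np.ndarray, int, object]] = field(default_factory=list)
    nodal_forces: object | None = None
    pressure: tuple[object, float] | None = None



# --------------------------------------------------------------------------
# Vectorized Gauss-point kernels.  These mirror the scalar material driver
# (driver.local_update / driver.pk2_stress) over all quadrature points at
# once; agreement with the scalar path is asserted in the test suite.

def _batch_det_inv(C: np.ndarray):
    """Determinant, inverse and J = sqrt(det) of a batch of 3x3 tensors,
    via the adjugate (faster than np.linalg for this shape and raises on
    non-positive determinants)."""
    c00 = C[:, 0, 0]; c01 = C[:, 0, 1]; c02 = C[:, 0, 2]
    c11 = C[:, 1, 1]; c12 = C[:, 1, 2]; c22 = C[:, 2, 2]
    a0 = c11 * c22 - c12 * c12
    a1 = c02 * c12 - c01 * c22
    a2 = c01 * c12 - c02 * c11
    det = c00 * a0 + c01 * a1 + c02 * a2
    if np.any(det <= 0.0):
        raise FloatingPointError("det(C) <= 0: inverted element")
    C_inv = np.empty_like(C)
    C_inv[:, 0, 0] = a0
    C_inv[:, 0, 1] = C_inv[:, 1, 0] = a1
    C_inv[:, 0, 2] = C_inv[:, 2, 0] = a2
    C_inv[:, 1, 1] = c00 * c22 - c02 * c02
    C_inv[:, 1, 2] = C_inv[:, 2, 1] = c02 * c01 - c00 * c12
    C_inv[:, 2, 2] = c00 * c11 - c01 * c01
    C_inv /= det[:, None, None]
    return det, C_inv, np.sqrt(det)


def _batch_remodel(lam_r_prev, lam, lam_p, dt, params):
    """Vectorized backward-Euler remodeling update (Newton, the residual is
    strictly monotone in the remodeling stretch)."""
    if dt == 0.0:
        return lam_r_prev.copy()
    c = dt * params.k_rem / (params.lambda_pre - 1.0)
    ratio = lam / lam_p
    x = lam_r_prev.copy()
    for _ in range(60):
        r = x - lam_r_prev - c * (ratio / x - params.lambda_pre)
        if np.all(np.abs(r) <= 1e-12 * np.maximum(1.0, np.abs(x))):
            break
        x = x - r / (1.0 + c * ratio / (x * x))
        np.maximum(x, 1e-8, out=x)
    return x


def _batch_update(C, t, dt, arrs, params, schedule, remodel_during_damage):
    """Vectorized internal-variable update over all Gauss points; the
    deformation-independent biology is advanced beforehand (its result is
    already contained in arrs['rho_c'])."""
    a0 = arrs["a0"]
    lam = np.sqrt(np.einsum("ni,nij,nj->n", a0, C, a0))
    phase = phase_of(t, schedule)
    out = dict(arrs)
    if phase == "prestretch" or phase == "healing":
        out["lam_r"] = _batch_remodel(arrs["lam_r"], lam, arrs["lam_p"],
                                      dt, params)
        return out

    # damage phase
    lam_p, lam_r = arrs["lam_p"], arrs["lam_r"]
    hist_n = np.maximum(arrs["lam_hist"], lam)
    lmax_n = np.maximum(hist_n / lam_r, arrs["lam_max"])
    delta = lmax_n - arrs["lam_max"]
    d_n = np.maximum(arrs["d"], np.minimum(
        1.0, params.m_p * np.maximum(lmax_n - params.lambda_bar_p, 0.0)))
    lam_e_trial = lam / (lam_r * lam_p)
    denom = 1.0 - d_n * delta * lam_r / lam
    lam_p_flow = np.where(denom > 0.0,
                          lam_p / np.where(denom > 0.0, denom, 1.0),
                          lam / lam_r)
    lam_p_flow = np.minimum(lam_p_flow, lam / lam_r)  # keep lam_e >= 1
    lam_p_flow = np.maximum(lam_p_flow, lam_p)        # irreversible
    active = (delta > 0.0) & (lam_e_trial > 1.0) & (d_n > 0.0)
    out["lam_p"] = np.where(active, lam_p_flow, lam_p)
    out["d"] = d_n
    out["lam_hist"] = hist_n
    out["lam_max"] = lmax_n
    out["lam_r"] = (_batch_remodel(lam_r, lam, out["lam_p"], dt, params)
                    if remodel_during_damage else lam_r.copy())
    return out


def _batch_stress(C, det, C_inv, J, arrs, params, pressure):
    """Vectorized second Piola-Kirchhoff stress at the given internal state.

    ``pressure`` is an array (mixed-element mode) or None (growth-penalty
    mode at the kinematic J)."""
    rho_c, rho_m = arrs["rho_c"], arrs["rho_m"]
    rho0 = rho_c + rho_m
    if pressure is None:
        p_eff = params.kappa * (J - rho0 / params.rho0_init)
    else:
        p_eff = pressure
    trC = C[:, 0, 0] + C[:, 1, 1] + C[:, 2, 2]
    cm = rho_m * params.mu * det ** (-1.0 / 3.0)
    S = (rho0 * p_eff * J - cm * trC / 3.0)[:, None, None] * C_inv
    S[:, [0, 1, 2], [0, 1, 2]] += cm[:, None]

    a0 = arrs["a0"]
    lam_pr2 = (arrs["lam_p"] * arrs["lam_r"]) ** 2
    Ie = np.einsum("ni,nij,nj->n", a0, C, a0) / lam_pr2
    x = Ie - 1.0
    with np.errstate(over="ignore"):
        cc = np.where(
            x > 0.0,
            2.0 * rho_c / lam_pr2 * params.k1 * x
            * np.exp(params.k2 * x * x),
            0.0,
        )
    S += np.einsum("n,ni,nj->nij", cc, a0, a0)
    return S


def _batch_vol_tangent(C_inv, J, rho0, params, pressure):
    """Exact tangent of the volumetric stress rho0 p_eff J C^-1 (vectorized;
    the stiff term is never finite-differenced)."""
    if pressure is None:
        p_eff = params.kappa * (J - rho0 / params.rho0_init)
    else:
        p_eff = pressure
    CiCi = np.einsum("nIJ,nKL->nIJKL", C_inv, C_inv)
    Codot = 0.5 * (np.einsum("nIK,nJL->nIJKL", C_inv, C_inv)
                   + np.einsum("nIL,nJK->nIJKL", C_inv, C_inv))
    CC = (rho0 * p_eff * J)[:, None, None, None, None] * (0.5 * CiCi - Codot)
    if pressure is None:
        CC += (rho0 * params.kappa * 0.5 * J * J)[:, None, None, None, None] \
            * CiCi
    return CC


class FemModel:
    """Displacement-driven nonlinear quasi-static model with condensed
    element dilatation/pressure and staggered Gauss-point internal state."""

    def __init__(
        self,
        mesh: HexMesh,
        params: MaterialParams,
        schedule: PhaseSchedule,
        *,
        remodel_during_damage: bool = True,
        bio_substep: float | None = None,
        newton_rtol: float = 1e-8,
        newton_atol: float = 1e-9,
        stall_rtol: float = 1e-6,
        max_newton: int = 40,
    ):
        self.mesh = mesh
        self.params = params
        self.schedule = schedule
        self.remodel_during_damage = remodel_during_damage
        self.bio_substep = bio_substep
        self.newton_rtol = newton_rtol
        self.newton_atol = newton_atol
        self.stall_rtol = stall_rtol
        self.max_newton = max_newton

        self.ndof = 3 * mesh.n_nodes
        self.u = np.zeros(self.ndof)
        self.t = 0.0
        self.states: list[list[GaussPointState]] = [
            [initial_state(params, mesh.fiber[e]) for _ in range(8)]
            for e in range(mesh.n_elems)
        ]
        self.theta = np.ones(mesh.n_elems)
        self.p = np.zeros(mesh.n_elems)
        self.loadcase = LoadCase()
        self.log: list[dict] = []

        # reference-configuration shape gradients and weights
        self._gradN = np.empty((mesh.n_elems, 8, 8, 3))  # (elem, gp, node, dim)
        self._wdet = np.empty((mesh.n_elems, 8))
        for e in range(mesh.n_elems):
            Xe = mesh.nodes[mesh.elems[e]]
            for g in range(8):
                Jmat = _DN_XI[g].T @ Xe  # dX/dxi, (3,3)
                det = np.linalg.det(Jmat)
                if det <= 0:
                    raise ValueError(f"element {e} has non-positive Jacobian")
                # Jmat[k, J] = dX_J/dxi_k, so dN/dX = dN/dxi . (Jmat^-1)^T
                self._gradN[e, g] = _DN_XI[g] @ np.linalg.inv(Jmat).T
                self._wdet[e, g] = _GAUSS_W[g] * det

        # flattened Gauss-point views and assembly index maps
        n_gp = 8 * mesh.n_elems
        self._gradN_n = self._gradN.reshape(n_gp, 8, 3)
        self._w_n = self._wdet.reshape(n_gp)
        self._edofs = (3 * mesh.elems[:, :, None]
                       + np.arange(3)[None, None, :]).reshape(-1, 24)
        self._K_rows = np.repeat(self._edofs, 24, axis=1).ravel()
        self._K_cols = np.tile(self._edofs, (1, 24)).ravel()
        self._state_version = 0
        self._base_cache = (None, None)

    # ------------------------------------------------------------------ loads

    def _dirichlet_dofs_values(self, t: float):
        dofs, vals = [], []
        for nodes, comp, fn in self.loadcase.dirichlet:
            v = fn(t) if callable(fn) else float(fn)
            dofs.append(3 * np.asarray(nodes) + comp)
            vals.append(np.full(len(nodes), v))
        if dofs:
            return np.concatenate(dofs), np.concatenate(vals)
        return np.array([], dtype=int), np.array([])

    def external_forces(self, t: float) -> np.ndarray:
        f = np.zeros(self.ndof)
        if self.loadcase.nodal_forces is not None:
            f += self.loadcase.nodal_forces(t)
        if self.loadcase.pressure is not None:
            f += self.surface_pressure_forces(t)
        return f

    def surface_pressure_forces(self, t: float) -> np.ndarray:
        """Dead pressure load on the top facets: traction -pbar f(r) e_z per
        unit reference area, with the cone profile in the reference radius."""
        pbar_fn, r_p = self.loadcase.pressure
        pbar = pbar_fn(t) if callable(pbar_fn) else float(pbar_fn)
        f = np.zeros(self.ndof)
        if pbar == 0.0:
            return f
        for _, conn in self.mesh.top_facets:
            X = self.mesh.nodes[conn]  # (4, 3)
            for xi in _GAUSS2D:
                N = 0.25 * (1 + _XI_QUAD[:, 0] * xi[0]) * (1 + _XI_QUAD[:, 1] * xi[1])
                dN = np.stack(
                    [
                        0.25 * _XI_QUAD[:, 0] * (1 + _XI_QUAD[:, 1] * xi[1]),
                        0.25 * _XI_QUAD[:, 1] * (1 + _XI_QUAD[:, 0] * xi[0]),
                    ],
                    axis=1,
                )  # (4, 2)
                t1 = dN[:, 0] @ X
                t2 = dN[:, 1] @ X
                n_dA = np.cross(t1, t2)  # outward normal times area Jacobian
                xg = N @ X
                r = np.hypot(xg[0], xg[1])
                traction = -pbar * cone_pressure_profile(r, r_p) * n_dA
                for a, node in enumerate(conn):
                    f[3 * node : 3 * node + 3] += N[a] * traction
        return f

    # --------------------------------------------------------------- assembly

    def _base_states(self, t: float):
        """Committed states with the deformation-independent biology advanced
        to the step end, plus their flat internal-variable arrays (cached
        per step, reused across Newton iterations and perturbations)."""
        key = (t, self._state_version)
        if self._base_cache[0] == key:
            return self._base_cache[1]
        if t >= self.schedule.t_star:
            base = [
                [advance_biology(s, t, self.params, self.schedule,
                                 self.bio_substep) for s in row]
                for row in self.states
            ]
        else:
            base = self.states
        flat = [s for row in base for s in row]
        arrs = {
            "a0": np.array([s.a_0 for s in flat]),
            "lam_p": np.array([s.plastic.lambda_p for s in flat]),
            "d": np.array([s.plastic.d for s in flat]),
            "lam_max": np.array([s.plastic.lambda_max for s in flat]),
            "lam_hist": np.array([s.lambda_hist for s in flat]),
            "lam_r": np.array([s.lambda_r for s in flat]),
            "rho_c": np.array([s.rho_c for s in flat]),
            "rho_m": np.array([s.rho_m for s in flat]),
        }
        self._base_cache = (key, (base, arrs))
        return base, arrs

    def _materialize(self, base, upd) -> list[list[GaussPointState]]:
        """Gauss-point state objects from updated internal arrays (commit)."""
        E = self.mesh.n_elems
        d = upd["d"].reshape(E, 8)
        lam_max = upd["lam_max"].reshape(E, 8)
        lam_p = upd["lam_p"].reshape(E, 8)
        lam_r = upd["lam_r"].reshape(E, 8)
        hist = upd["lam_hist"].reshape(E, 8)
        states = []
        for e in range(E):
            row = []
            for g in range(8):
                b = base[e][g]
                row.append(GaussPointState(
                    a_0=b.a_0,
                    plastic=PlasticState(
                        d=float(d[e, g]),
                        lambda_max=float(lam_max[e, g]),
                        lambda_p=float(lam_p[e, g])),
                    lambda_r=float(lam_r[e, g]),
                    lambda_hist=float(hist[e, g]),
                    rho_c=b.rho_c,
                    rho_m=b.rho_m,
                    bio=b.bio,
                ))
            states.append(row)
        return states

    def assemble(self, u: np.ndarray, t: float, dt: float,
                 want_tangent: bool = True):
        """Internal forces (and consistent tangent) over the whole mesh,
        vectorized over Gauss points.  Returns
        (f_int, K, (base, updated arrays), theta, p)."""
        E = self.mesh.n_elems
        n = 8 * E
        base, arrs = self._base_states(t)
        kappa = self.params.kappa

        ue = u.reshape(-1, 3)[self.mesh.elems]           # (E, 8, 3)
        F = np.einsum("eai,egaJ->egiJ", ue, self._gradN).reshape(n, 3, 3)
        F[:, 0, 0] += 1.0
        F[:, 1, 1] += 1.0
        F[:, 2, 2] += 1.0
        C = np.einsum("nkI,nkJ->nIJ", F, F)
        det, C_inv, J = _batch_det_inv(C)

        # condensed element dilatation and pressure
        rho0 = arrs["rho_c"] + arrs["rho_m"]
        w_r = (self._w_n * rho0).reshape(E, 8)
        m_e = w_r.sum(axis=1)
        theta = (w_r * J.reshape(E, 8)).sum(axis=1) / m_e
        gbar = (w_r * (rho0 / self.params.rho0_init).reshape(E, 8)
                ).sum(axis=1) / m_e
        p_e = kappa * (theta - gbar)
        p_gp = np.repeat(p_e, 8)

        upd = _batch_update(C, t, dt, arrs, self.params, self.schedule,
                            self.remodel_during_damage)
        S = _batch_stress(C, det, C_inv, J, upd, self.params, p_gp)

        P = F @ S                                        # (n, 3, 3)
        f_gp = np.einsum("n,naJ,niJ->nai", self._w_n, self._gradN_n, P)
        f_e = f_gp.reshape(E, 8, 8, 3).sum(axis=1)       # (E, node, dim)
        f_int = np.bincount(self._edofs.ravel(),
                            weights=f_e.reshape(-1), minlength=self.ndof)

        K = None
        if want_tangent:
            # bounded part by forward differences of the full local update
            def iso_stress(Cp):
                up = _batch_update(Cp, t, dt, arrs, self.params,
                                   self.schedule, self.remodel_during_damage)
                dp, ip, jp = _batch_det_inv(Cp)
                return _batch_stress(Cp, dp, ip, jp, up, self.params,
                                     np.zeros(n))

            S0 = _batch_stress(C, det, C_inv, J, upd, self.params,
                               np.zeros(n))
            h = 1e-6 * np.maximum(1.0, np.abs(C).max(axis=(1, 2)))
            CC = np.zeros((n, 3, 3, 3, 3))
            for k in range(3):
                for l in range(k, 3):
                    Cp = C.copy()
                    Cp[:, k, l] += h
                    Cp[:, l, k] += h
                    dS = (iso_stress(Cp) - S0) / (2.0 * h)[:, None, None]
                    CC[:, :, :, k, l] = dS
                    CC[:, :, :, l, k] = dS
            CC += _batch_vol_tangent(C_inv, J, rho0, self.params, p_gp)

            # K_mat[a,i,b,m] = 2 w gradN_aJ (F CC F)_iJmL gradN_bL
            t1 = np.einsum("niI,nIJKL->niJKL", F, CC)
            t2 = np.einsum("niJKL,nmK->niJmL", t1, F)
            K_gp = 2.0 * np.einsum("n,naJ,niJmL,nbL->naibm",
                                   self._w_n, self._gradN_n, t2,
                                   self._gradN_n, optimize=True)
            geo = np.einsum("n,naJ,nJK,nbK->nab",
                            self._w_n, self._gradN_n, S, self._gradN_n)
            for i in range(3):
                K_gp[:, :, i, :, i] += geo
            K_e = K_gp.reshape(E, 8, 24, 24).sum(axis=1)

            # condensation coupling: rank-one kappa/m_e v v^T per element
            F_inv = np.linalg.inv(F)
            v_gp = np.einsum("n,naJ,nJi->nai",
                             self._w_n * rho0 * J, self._gradN_n, F_inv)
            v_e = v_gp.reshape(E, 8, 24).sum(axis=1)
            K_e += (kappa / m_e)[:, None, None] \
                * np.einsum("ea,eb->eab", v_e, v_e)

            K = sp.csr_matrix(
                (K_e.reshape(-1), (self._K_rows, self._K_cols)),
                shape=(self.ndof, self.ndof))
        return f_int, K, (base, upd), theta, p_e

    # ----------------------------------------------------------------- newton

    def _kappa_continuation(self, u0: np.ndarray, t: float, dt: float,
                            free: np.ndarray, f_ext: np.ndarray):
        """Continuation in the penalty stiffness: solve the step with a
        softened volumetric constraint and ramp kappa back up with warm
        starts.  A short ladder is tried first (cheap when the state is
        close), then a gradual one."""
        import dataclasses

        params0 = self.params
        try:
            for ladder in ((1e-4, 1e-2, 1.0),
                           (1e-4, 1e-3, 1e-2, 1e-1, 0.3, 1.0)):
                u = u0.copy()
                out = None
                for scale in ladder:
                    self.params = dataclasses.replace(
                        params0, kappa=params0.kappa * scale)
                    self._lm_mu = 0.0
                    out = self._damped_newton(u, t, dt, free, f_ext,
                                              min(self.max_newton, 15))
                    if out is not None:
                        u = out[0].copy()
                    elif scale == 1.0:
                        break
                    if getattr(self, "verbose", False):
                        ok = "ok" if out is not None else "FAIL"
                        print(f"    continuation kappa x{scale:g}: {ok}")
                if out is not None:
                    return out
        finally:
            self.params = params0
        self._lm_mu = 0.0
        return self._damped_newton(u0.copy(), t, dt, free, f_ext,
                                   self.max_newton)

    def _damped_newton(self, u: np.ndarray, t: float, dt: float,
                       free: np.ndarray, f_ext: np.ndarray, max_iter: int):
        """Levenberg-Marquardt damped Newton with backtracking; returns the
        converged solution tuple or None (no descent / iteration cap)."""
        ref = None
        prev = np.inf
        mu = getattr(self, "_lm_mu", 0.0)
        rnorm = np.inf
        for it in range(max_iter):
            f_int, K, handle, thetas, ps = self.assemble(u, t, dt,
                                                         want_tangent=True)
            R = f_int - f_ext
            rnorm = np.linalg.norm(R[free]) if free.size else 0.0
            if ref is None:
                ref = rnorm
            fscale = max(1.0, np.linalg.norm(f_int))
            floor = self.newton_atol * fscale
            # stagnation at round-off level of the stiff penalty counts as
            # converged provided the relative residual is already tiny
            stalled = rnorm > 0.5 * prev and rnorm <= self.stall_rtol * fscale
            if getattr(self, "verbose", False):
                print(f"    newton t={t:.6g} it={it} |R|={rnorm:.4e} "
                      f"mu={mu:.2e} fscale={fscale:.2e}")
            if rnorm <= max(self.newton_rtol * ref, floor) or stalled:
                self._lm_mu = mu
                states = self._materialize(*handle)
                return u, states, thetas, ps, R, it + 1
            prev = rnorm
            if not np.isfinite(rnorm) or rnorm > 1e6 * max(ref, 1.0):
                return None
            Kff = K[free][:, free].tocsc()
            mu_ref = 1e-4 * float(np.median(np.abs(Kff.diagonal())))

            def try_alpha(du, alpha):
                u_try = u.copy()
                u_try[free] += alpha * du
                try:
                    f_try, _, _, _, _ = self.assemble(u_try, t, dt,
                                                      want_tangent=False)
                    return np.linalg.norm((f_try - f_ext)[free]), u_try
                except FloatingPointError:
                    return np.inf, u_try

            accepted = False
            for _ in range(7):
                A = Kff if mu == 0.0 else (
                    Kff + mu * sp.identity(len(free), format="csc"))
                du = spla.spsolve(A, -R[free])
                r_full, u_full = try_alpha(du, 1.0)
                if r_full < 0.5 * rnorm:
                    u, accepted = u_full, True
                    mu *= 0.3
                    break
                best_r, best_u = r_full, u_full
                alpha = 0.5
                for _ in range(6):
                    r_a, u_a = try_alpha(du, alpha)
                    if r_a < best_r:
                        best_r, best_u = r_a, u_a
                    if r_a < (1.0 - 0.25 * alpha) * rnorm:
                        break
                    alpha *= 0.5
                if np.isfinite(best_r) and best_r < rnorm:
                    u, accepted = best_u, True
                    if best_r < 0.5 * rnorm:
                        mu *= 0.3
                    break
                mu = max(10.0 * mu, mu_ref)
            self._lm_mu = mu
            if not accepted:
                return None
        return None

    def _newton(self, t: float, dt: float):
        u = self.u.copy()
        bc_dofs, bc_vals = self._dirichlet_dofs_values(t)
        u[bc_dofs] = bc_vals
        free = np.setdiff1d(np.arange(self.ndof), bc_dofs)
        f_ext = self.external_forces(t)

        budget = getattr(self, "_fast_budget", 12)
        out = self._damped_newton(u, t, dt, free, f_ext, budget)
        if out is not None:
            self._fast_budget = 12
        if out is None:
            self._fast_budget = 2  # this regime likely needs continuation again

            # continuation in the penalty stiffness: solve the step with a
            # softened volumetric constraint, then ramp kappa back up with
            # warm starts (each intermediate problem is well conditioned)
            out = self._kappa_continuation(u, t, dt, free, f_ext)
        if out is None:
            raise GlobalSolverError(
                f"Newton failed at t={t:.6g}, dt={dt:.3g}")
        return out

    def solve_step(self, t: float, dt: float, max_bisect: int = 4):
        """Advance the committed solution from self.t to t, bisecting the
        step on divergence (up to ``max_bisect`` times)."""
        t_start, u_start = self.t, self.u.copy()
        targets = [t]
        level = 0
        while targets:
            t_i = targets[-1]
            dt_i = t_i - self.t
            try:
                u, states, thetas, ps, R, iters = self._newton(t_i, dt_i)
            except (GlobalSolverError, FloatingPointError):
                level += 1
                if level > max_bisect:
                    self.t, self.u = t_start, u_start
                    raise GlobalSolverError(
                        f"step to t={t:.6g} failed after {max_bisect} bisections"
                    )
                targets.append(0.5 * (self.t + t_i))
                continue
            # commit
            self.u, self.t = u, t_i
            self.states = states
            self._state_version += 1
            self.theta, self.p = thetas, ps
            self._last_residual = R
            self.log.append({"t": t_i, "dt": dt_i, "iters": iters})
            targets.pop()
        return self

    def advance_to(self, t_target: float, dt: float):
        while self.t < t_target - 1e-9 * max(1.0, abs(t_target)):
            t_next = min(self.t + dt, t_target)
            self.solve_step(t_next, t_next - self.t)
        return self

    # ------------------------------------------------------------ post/helpers

    def reactions(self, nodes: np.ndarray, comp: int) -> float:
        """Sum of reaction forces at the given nodes/component, from the
        residual of the last converged step."""
        R = self._last_residual
        return float(sum(R[3 * n + comp] for n in np.asarray(nodes)))

    def reaction_vector(self) -> np.ndarray:
        return self._last_residual.copy()

    def equilibrate_prestretch(self):
        """Closed-form pre-stretch initialization: after an equilibrium solve
        under the prestretch boundary conditions, set every Gauss point's
        remodeling stretch to its steady state and re-solve."""
        from .driver import equilibrated_prestretch_state

        for e in range(self.mesh.n_elems):
            conn = self.mesh.elems[e]
            ue = self.u.reshape(-1, 3)[conn]
            for g in range(8):
                F = _EYE + ue.T @ self._gradN[e, g]
                self.states[e][g] = equilibrated_prestretch_state(
                    self.states[e][g], F.T @ F, self.params
                )
        return self

    def gauss_values(self, fn) -> np.ndarray:
        """Evaluate fn(state) at every Gauss point, shape (n_elems, 8)."""
        return np.array([[fn(s) for s in row] for row in self.states])

    def element_values(self, fn) -> np.ndarray:
        return self.gauss_values(fn).mean(axis=1)

    def deformation_gradient(self, e: int, g: int) -> np.ndarray:
        conn = self.mesh.elems[e]
        ue = self.u.reshape(-1, 3)[conn]
        return _EYE + ue.T @ self._gradN[e, g]
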