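"""End-to-end studies: species response, parameter sensitivity, biaxial
tension with healing growth, and the indentation test.

Each runner builds its inputs programmatically (meshes, loading protocols,
parameter tables), executes the model and returns plain dictionaries /
DataFrames; ``write_outputs`` serializes them to CSV, VTK and a JSON summary.
The model is deterministic, so re-running with an identical configuration is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .biology import BioState, accumulated_mmp, init_pools, step_biology
from .constitutive import cauchy_stress
from .driver import (
    PhaseSchedule,
    equilibrated_prestretch_state,
    initial_state,
    local_update,
)
from .fem import FemModel, HexMesh, LoadCase
from .params import (
    DAY,
    YEAR,
    BioParams,
    MaterialParams,
    biaxial_params,
    indentation_params,
    species_study_params,
)
from .vtkio import write_vtk

__all__ = [
    "make_plate_mesh",
    "run_species_study",
    "run_sensitivity",
    "run_biaxial",
    "material_point_biaxial",
    "run_indentation",
    "biaxial_stretch_history",
    "write_outputs",
]


# --------------------------------------------------------------------- meshes

def _graded_coords(length: float, n: int, ratio: float | None) -> np.ndarray:
    """1D node coordinates on [0, length]; with a grading ratio the element
    sizes grow geometrically away from 0 (smallest at the origin)."""
    if ratio is None or ratio == 1.0:
        return np.linspace(0.0, length, n + 1)
    sizes = (1.0 / ratio) ** np.arange(n)
    sizes *= length / sizes.sum()
    return np.concatenate([[0.0], np.cumsum(sizes)])


def make_plate_mesh(
    lx: float,
    ly: float,
    lz: float,
    nx: int,
    ny: int,
    nz: int,
    grading: float | None = None,
    fiber=(1.0, 0.0, 0.0),
) -> HexMesh:
    """Structured hexahedral quarter-plate mesh with tagged boundary sets.

    With ``grading`` the in-plane element sizes shrink geometrically toward
    the x = y = 0 corner (where the indentation pressure is applied); the
    through-thickness direction stays uniform.
    """
    xs = _graded_coords(lx, nx, grading)
    ys = _graded_coords(ly, ny, grading)
    zs = np.linspace(0.0, lz, nz + 1)

    nnx, nny = nx + 1, ny + 1
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    order = np.arange(nnx * nny * (nz + 1)).reshape(nnx, nny, nz + 1)
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(i, j, k):
        return order[i, j, k]

    elems = []
    top_facets = []
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                conn = [
                    nid(i, j, k), nid(i + 1, j, k),
                    nid(i + 1, j + 1, k), nid(i, j + 1, k),
                    nid(i, j, k + 1), nid(i + 1, j, k + 1),
                    nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
                ]
                if k == nz - 1:
                    top_facets.append(
                        (len(elems), np.array(conn[4:8]))
                    )
                elems.append(conn)
    elems = np.asarray(elems, dtype=int)

    tol = 1e-12 * max(lx, ly, lz)
    node_sets = {
        "x0": np.where(np.abs(nodes[:, 0]) < tol)[0],
        "xl": np.where(np.abs(nodes[:, 0] - lx) < tol)[0],
        "y0": np.where(np.abs(nodes[:, 1]) < tol)[0],
        "yl": np.where(np.abs(nodes[:, 1] - ly) < tol)[0],
        "z0": np.where(np.abs(nodes[:, 2]) < tol)[0],
        "top": np.where(np.abs(nodes[:, 2] - lz) < tol)[0],
    }
    a = np.asarray(fiber, dtype=float)
    a = a / np.linalg.norm(a)
    fiber_arr = np.tile(a, (len(elems), 1))
    return HexMesh(
        nodes=nodes, elems=elems, fiber=fiber_arr,
        node_sets=node_sets, top_facets=top_facets,
    )


# ------------------------------------------------------------ species / sweep

def run_species_study(
    params: MaterialParams | None = None,
    d_values=(0.0, 0.1, 0.4, 0.7, 1.0),
    dt: float = 0.1 * DAY,
    t_end: float = YEAR,
) -> dict[float, pd.DataFrame]:
    """Single-material-point species response for fixed damage values.

    Damage is treated as a prescribed constant; the pools are initialized
    from it and the coupled MMP/GF/turnover system is integrated by
    backward Euler over one year.
    """
    params = params or species_study_params()
    out = {}
    for d in d_values:
        out[float(d)] = _integrate_bio(d, params.bio, params.rho_c0,
                                       params.rho_m, dt, t_end)
    return out


def _integrate_bio(
    d_star: float,
    bio_params: BioParams,
    rho_c0: float,
    rho_m: float,
    dt: float,
    t_end: float,
) -> pd.DataFrame:
    rho_cd, rho_ci = init_pools(d_star, rho_c0)
    state = BioState(
        M=bio_params.M0, G=bio_params.G0, i_M=0.0, t=0.0, t_star=0.0,
        rho_cd=rho_cd, rho_ci=rho_ci, rho_c_star=rho_c0,
    )
    rows = [_bio_row(state, bio_params, rho_m)]
    n = int(round(t_end / dt))
    for _ in range(n):
        state = step_biology(state, dt, bio_params)
        rows.append(_bio_row(state, bio_params, rho_m))
    return pd.DataFrame(rows)


def _bio_row(state: BioState, bp: BioParams, rho_m: float) -> dict:
    return {
        "t": state.t,
        "M": state.M,
        "G": state.G,
        "I_M": accumulated_mmp(state, state.t, bp),
        "rho_cd": state.rho_cd,
        "rho_ci": state.rho_ci,
        "rho_c": state.rho_c,
        "rho_0": state.rho_c + rho_m,
    }


_SWEEP_PARAMS = ("m1", "m2", "g1", "g2", "kd1", "kd2", "ki1", "ki2")


def run_sensitivity(
    params: MaterialParams | None = None,
    factors=(0.25, 0.5, 1.0, 2.0, 4.0),
    d: float = 0.5,
    dt: float = 0.1 * DAY,
    t_end: float = YEAR,
    keep_trajectories: bool = False,
):
    """One-at-a-time sweep of the eight species parameters at fixed damage.

    Returns a DataFrame of summary scalars (peak M, peak G, final collagen
    density) per (parameter, factor); optionally also the trajectories.
    """
    params = params or species_study_params()
    rows, trajs = [], {}
    for name in _SWEEP_PARAMS:
        for f in factors:
            bp = dataclasses.replace(
                params.bio, **{name: getattr(params.bio, name) * f}
            )
            df = _integrate_bio(d, bp, params.rho_c0, params.rho_m, dt, t_end)
            rows.append(
                {
                    "param": name,
                    "factor": f,
                    "peak_M": df["M"].max(),
                    "peak_G": df["G"].max(),
                    "final_rho_c": df["rho_c"].iloc[-1],
                }
            )
            if keep_trajectories:
                trajs[(name, f)] = df
    summary = pd.DataFrame(rows)
    return (summary, trajs) if keep_trajectories else summary


# ------------------------------------------------------------------- biaxial

def biaxial_stretch_history(t: float, heal_config: str = "prestretched") -> float:
    """Fiber-direction tissue stretch during the 60 s damage phase: two
    cycles with maxima 1.83 and 1.93 in four 15 s ramps; the last segment
    returns to the prestretch (``prestretched``) or holds the maximum
    (``max``)."""
    if t <= 0:
        return 1.34
    if t < 15:
        return 1.34 + (1.83 - 1.34) * t / 15
    if t < 30:
        return 1.83 - (1.83 - 1.34) * (t - 15) / 15
    if t < 45:
        return 1.34 + (1.93 - 1.34) * (t - 30) / 15
    if t < 60:
        if heal_config == "max":
            return 1.93
        return 1.93 - (1.93 - 1.34) * (t - 45) / 15
    return 1.93 if heal_config == "max" else 1.34


def _biaxial_model(params: MaterialParams, schedule: PhaseSchedule,
                   heal_config: str, dt_heal: float) -> FemModel:
    lx, ly, lz = 6e-3, 3e-3, 0.225e-3  # quarter sample
    mesh = make_plate_mesh(lx, ly, lz, 1, 1, 1)
    model = FemModel(mesh, params, schedule, bio_substep=dt_heal)
    ns = mesh.node_sets
    model.loadcase = LoadCase(
        dirichlet=[
            (ns["x0"], 0, 0.0),
            (ns["y0"], 1, 0.0),
            (ns["z0"], 2, 0.0),
            (ns["xl"], 0,
             lambda t: (_prestretch_ramp(t) if t < 0
                        else biaxial_stretch_history(t, heal_config) - 1.0) * lx),
            (ns["yl"], 1, lambda t: (min(1.25, 1.0 + 0.25 * (t + 2)) - 1.0) * ly),
        ]
    )
    return model


def _prestretch_ramp(t: float) -> float:
    # stretch 1 -> 1.34 over t in [-2, -1], held afterwards
    return min(1.34, 1.0 + 0.34 * (t + 2.0)) - 1.0


def run_biaxial(
    params: MaterialParams | None = None,
    heal_config: str = "prestretched",
    dt_damage: float = 0.25,
    dt_heal: float = 0.1 * DAY,
    t_end: float = YEAR,
    kappa: float | None = None,
    n_heal_records: int = 60,
) -> dict:
    """Biaxial tension test on a single mixed element: prestretch with
    remodeling to the collagen pre-stretch, two damaging stretch cycles,
    then one year of healing in the chosen held configuration.

    Returns a report with the per-cycle maximum collagen stretches, the
    damage at the end of the damage phase, the healing thickness change,
    the growth-constraint error and the recorded trajectories.
    """
    if heal_config not in ("prestretched", "max"):
        raise ValueError("heal_config must be 'prestretched' or 'max'")
    params = params or biaxial_params()
    if kappa is not None:
        params = dataclasses.replace(params, kappa=kappa)
    schedule = PhaseSchedule(t0=0.0, t_star=60.0, t_end=t_end)
    model = _biaxial_model(params, schedule, heal_config, dt_heal)
    lz = 0.225e-3

    # prestretch phase (t < 0): ramp on, remodel (closed form), re-solve
    model.t = -2.0
    model.advance_to(-1.0, 0.25)
    model.equilibrate_prestretch()
    model.solve_step(-0.5, 0.5)

    lam_z = lambda: 1.0 + model.u.reshape(-1, 3)[
        model.mesh.node_sets["top"], 2].mean() / lz
    lam_e = lambda s: (
        biaxial_stretch_history(model.t, heal_config)
        / (s.lambda_r * s.plastic.lambda_p))

    # damage phase
    cycle_max = {1: 0.0, 2: 0.0}
    damage_traj = []
    n_dmg = int(round(60.0 / dt_damage))
    for i in range(n_dmg):
        t = (i + 1) * dt_damage
        model.solve_step(t, dt_damage)
        lmax = model.gauss_values(lambda s: s.plastic.lambda_max).max()
        cyc = 1 if t <= 30.0 else 2
        cycle_max[cyc] = max(cycle_max[cyc], lmax)
        damage_traj.append(
            {"t": t,
             "lambda_x": biaxial_stretch_history(t, heal_config),
             "lambda_max": lmax,
             "d": model.gauss_values(lambda s: s.plastic.d).max(),
             "sigma_xx": _fiber_cauchy(model)}
        )
    d_star = model.gauss_values(lambda s: s.plastic.d).max()
    lam_z_star = lam_z()
    J_star = float(model.theta.mean())

    # healing phase
    heal_traj = []
    record_every = max(1, int(round(t_end / dt_heal / n_heal_records)))
    n_heal = int(round((t_end - 60.0) / dt_heal))
    for i in range(n_heal):
        t = 60.0 + (i + 1) * dt_heal
        model.solve_step(t, dt_heal)
        if (i + 1) % record_every == 0 or i == n_heal - 1:
            s = model.states[0][0]
            heal_traj.append(
                {"t": t,
                 "lambda_z": lam_z(),
                 "theta": float(model.theta[0]),
                 "rho_c": s.rho_c,
                 "rho_0": s.rho_0,
                 "lambda_r": s.lambda_r,
                 "lambda_e": lam_e(s),
                 "M": s.bio.M, "G": s.bio.G,
                 "sigma_xx": _fiber_cauchy(model)}
            )

    s = model.states[0][0]
    J_end = float(model.theta[0])
    target = s.rho_0 / params.rho0_init
    return {
        "heal_config": heal_config,
        "cycle1_lambda_max": cycle_max[1],
        "cycle2_lambda_max": cycle_max[2],
        "d_star": d_star,
        "lambda_z_star": lam_z_star,
        "J_star": J_star,
        "lambda_z_end": lam_z(),
        "thickness_increase_percent": 100.0 * (lam_z() / lam_z_star - 1.0),
        "J_end": J_end,
        "growth_target_end": target,
        "kappa_error": abs(J_end - target),
        "lambda_e_end": lam_e(s),
        "rho_c_end": s.rho_c,
        "damage_trajectory": pd.DataFrame(damage_traj),
        "healing_trajectory": pd.DataFrame(heal_traj),
    }


def _fiber_cauchy(model: FemModel) -> float:
    from .driver import pk2_stress

    F = model.deformation_gradient(0, 0)
    S = pk2_stress(F.T @ F, model.states[0][0], model.params,
                   pressure=float(model.p[0]))
    return float(cauchy_stress(F, S)[0, 0])


def material_point_biaxial(
    params: MaterialParams | None = None,
    heal_config: str = "prestretched",
    dt_damage: float = 0.25,
    dt_heal: float = 0.1 * DAY,
    t_end: float = YEAR,
    record=None,
) -> dict:
    """Homogeneous (material-point) version of the biaxial test: the
    through-thickness stretch is found from vanishing transverse Cauchy
    stress with the growth penalty at the kinematic J.  Cross-checks the
    single-element mixed finite-element solution."""
    params = params or biaxial_params()
    schedule = PhaseSchedule(t0=0.0, t_star=60.0, t_end=t_end)
    state = initial_state(params)
    lam_y = 1.25

    def solve_lz(lx, st, t, dt, lz0):
        lz = lz0
        for _ in range(80):
            def res(z):
                C = np.diag([lx**2, lam_y**2, z**2])
                s_new, S = local_update(C, t, dt, st, params, schedule,
                                        bio_substep=dt_heal)
                F = np.diag([lx, lam_y, z])
                return cauchy_stress(F, S)[2, 2], s_new
            r, s_new = res(lz)
            h = 1e-7 * lz
            r2, _ = res(lz + h)
            step = -r / ((r2 - r) / h)
            step = np.clip(step, -0.2 * lz, 0.2 * lz)
            lz += step
            if abs(step) <= 1e-13 * lz:
                break
        return lz, s_new

    # prestretch
    lz, st = solve_lz(1.34, state, -1.0, 1.0, 1.0 / (1.34 * lam_y))
    state = equilibrated_prestretch_state(
        st, np.diag([1.34**2, lam_y**2, lz**2]), params)
    lz, state = solve_lz(1.34, state, -0.5, 0.5, lz)

    cycle_max = {1: 0.0, 2: 0.0}
    for i in range(int(round(60.0 / dt_damage))):
        t = (i + 1) * dt_damage
        lz, state = solve_lz(biaxial_stretch_history(t, heal_config),
                             state, t, dt_damage, lz)
        cyc = 1 if t <= 30.0 else 2
        cycle_max[cyc] = max(cycle_max[cyc], state.plastic.lambda_max)
        if record is not None:
            record(t, lz, state)
    d_star = state.plastic.d
    lz_star = lz

    lx_hold = 1.93 if heal_config == "max" else 1.34
    for i in range(int(round((t_end - 60.0) / dt_heal))):
        t = 60.0 + (i + 1) * dt_heal
        lz, state = solve_lz(lx_hold, state, t, dt_heal, lz)
        if record is not None:
            record(t, lz, state)

    J_end = lx_hold * lam_y * lz
    target = state.rho_0 / params.rho0_init
    return {
        "heal_config": heal_config,
        "cycle1_lambda_max": cycle_max[1],
        "cycle2_lambda_max": cycle_max[2],
        "d_star": d_star,
        "lambda_z_star": lz_star,
        "lambda_z_end": lz,
        "thickness_increase_percent": 100.0 * (lz / lz_star - 1.0),
        "J_end": J_end,
        "growth_target_end": target,
        "kappa_error": abs(J_end - target),
        "rho_c_end": state.rho_c,
        "state": state,
    }


def _homogeneous_thickness_stretch(
    params: MaterialParams, lam_x: float, lam_y: float
) -> float:
    """Thickness stretch of a virgin homogeneous biaxial state with zero
    transverse stress (used as a Newton predictor)."""
    schedule = PhaseSchedule(t0=0.0, t_star=60.0, t_end=YEAR)
    state = initial_state(params)
    lz = 1.0 / (lam_x * lam_y)
    for _ in range(60):
        def res(z):
            C = np.diag([lam_x**2, lam_y**2, z**2])
            _, S = local_update(C, -1.0, 1.0, state, params, schedule)
            return cauchy_stress(np.diag([lam_x, lam_y, z]), S)[2, 2]
        r = res(lz)
        h = 1e-7 * lz
        step = -r / ((res(lz + h) - r) / h)
        lz += float(np.clip(step, -0.2 * lz, 0.2 * lz))
        if abs(step) <= 1e-12 * lz:
            break
    return lz


# ---------------------------------------------------------------- indentation

def run_indentation(
    params: MaterialParams | None = None,
    nx: int = 22,
    ny: int = 22,
    nz: int = 8,
    grading: float = 0.7,
    dt_damage: float = 2.5,
    dt_heal: float = 5.0 * DAY,
    bio_substep: float = 0.5 * DAY,
    t_end: float = YEAR,
    pbar_peak: float = 36e3,
    r_p: float = 0.01,
    output_days=(0.0, 50.0, 150.0, 300.0, 365.0),
    vtk_dir: str | Path | None = None,
    probe_coords: dict | None = None,
) -> dict:
    """Indentation of a prestretched quarter plate by a conical pressure.

    Prestretch is applied by essential boundary conditions, remodeled to the
    collagen pre-stretch, then the face conditions are swapped for the
    equivalent tractions so the plate can grow in all directions.  A
    triangular pressure ramp (peak at mid damage phase) injures a circular
    region; the species field then heals the plate over one year.
    Probe strains are nominal, referenced to the end-of-damage configuration.
    """
    params = params or indentation_params()
    lx = ly = 0.06
    lz = 0.012
    schedule = PhaseSchedule(t0=0.0, t_star=60.0, t_end=t_end)
    mesh = make_plate_mesh(lx, ly, lz, nx, ny, nz, grading=grading)
    model = FemModel(mesh, params, schedule, bio_substep=bio_substep)
    ns = mesh.node_sets

    # --- prestretch with essential BCs; the prestretched plate is an exactly
    # homogeneous biaxial state, so seed Newton with it
    model.loadcase = LoadCase(
        dirichlet=[
            (ns["x0"], 0, 0.0),
            (ns["y0"], 1, 0.0),
            (ns["z0"], 2, 0.0),
            (ns["xl"], 0, 0.34 * lx),
            (ns["yl"], 1, 0.25 * ly),
        ]
    )
    lam_z0 = _homogeneous_thickness_stretch(params, 1.34, 1.25)
    U = model.mesh.nodes * (np.array([1.34, 1.25, lam_z0]) - 1.0)
    model.u = U.reshape(-1)
    model.t = -2.0
    model.solve_step(-1.0, 1.0)
    model.equilibrate_prestretch()
    model.solve_step(-0.5, 0.5)

    # --- replace the face conditions by the equivalent tractions
    release = prestretch_and_release(model)

    def pbar(t):
        if t < 0:
            return 0.0
        half = 0.5 * (schedule.t0 + schedule.t_star)
        if t <= half:
            return pbar_peak * t / half
        if t <= schedule.t_star:
            return pbar_peak * (schedule.t_star - t) / (schedule.t_star - half)
        return 0.0

    model.loadcase.pressure = (pbar, r_p)

    probes = _probe_nodes(mesh, lx, ly, lz, probe_coords)

    # --- damage phase
    n_dmg = int(round(60.0 / dt_damage))
    damage_log = []
    for i in range(n_dmg):
        t = (i + 1) * dt_damage
        model.solve_step(t, dt_damage)
        damage_log.append({"t": t, "pbar": pbar(t),
                           "max_d": model.gauss_values(
                               lambda s: s.plastic.d).max()})
    x_star = mesh.nodes + model.u.reshape(-1, 3)
    damage_elem = model.element_values(lambda s: s.plastic.d)

    if vtk_dir is not None:
        _write_indentation_vtk(model, Path(vtk_dir) / "state_tstar.vtk")

    # --- healing phase with probe recording
    heal_rows = []
    out_times = sorted(60.0 + d * DAY for d in output_days)
    snapshots = {}
    n_heal = int(round((t_end - 60.0) / dt_heal))
    for i in range(n_heal):
        t = 60.0 + (i + 1) * dt_heal
        model.solve_step(t, dt_heal)
        x_now = mesh.nodes + model.u.reshape(-1, 3)
        row = {"t_days": (t - 60.0) / DAY}
        for name, (node, comp) in probes.items():
            row[name] = (x_now[node, comp] - x_star[node, comp]) / x_star[node, comp]
        heal_rows.append(row)
        for t_out in out_times:
            if abs(t - t_out) < 0.51 * dt_heal and t_out not in snapshots:
                snapshots[t_out] = _field_snapshot(model)
                if vtk_dir is not None:
                    _write_indentation_vtk(
                        model,
                        Path(vtk_dir) / f"state_{(t_out-60)/DAY:.0f}d.vtk")

    strains = pd.DataFrame(heal_rows)
    return {
        "mesh": {"nx": nx, "ny": ny, "nz": nz,
                 "n_nodes": mesh.n_nodes, "n_elems": mesh.n_elems},
        "damage_log": pd.DataFrame(damage_log),
        "damage_elem": damage_elem,
        "release_residual": release["residual_norm"],
        "probe_strains": strains,
        "snapshots": snapshots,
        "model": model,
    }


def _probe_nodes(mesh: HexMesh, lx, ly, lz, probe_coords=None):
    """Probe points: A on the x face, B on the y face, C at the loaded
    center, all on the top surface; the tracked component is the direction
    of anisotropic growth reported at each point."""
    coords = probe_coords or {
        "A_x": ((lx, 0.0, lz), 0),
        "B_y": ((0.0, ly, lz), 1),
        "C_z": ((0.0, 0.0, lz), 2),
    }
    out = {}
    for name, (xyz, comp) in coords.items():
        node = int(np.argmin(np.linalg.norm(mesh.nodes - np.asarray(xyz), axis=1)))
        out[name] = (node, comp)
    return out


def prestretch_and_release(model: FemModel) -> dict:
    """Swap the prestretch essential boundary conditions on the loaded faces
    for the equivalent nodal tractions (natural conditions), leaving the
    deformation state in equilibrium."""
    R = model.reaction_vector()
    ns = model.mesh.node_sets
    forces = np.zeros(model.ndof)
    for set_name, comp in (("xl", 0), ("yl", 1)):
        for n in ns[set_name]:
            forces[3 * n + comp] = R[3 * n + comp]
    u_before = model.u.copy()
    model.loadcase = LoadCase(
        dirichlet=[
            (ns["x0"], 0, 0.0),
            (ns["y0"], 1, 0.0),
            (ns["z0"], 2, 0.0),
        ],
        nodal_forces=lambda t: forces,
    )
    # equilibrium identity: re-solving must leave the displacements unchanged
    model.solve_step(model.t + 0.25, 0.25)
    drift = float(np.max(np.abs(model.u - u_before)))
    f_int, _, _, _, _ = model.assemble(model.u, model.t, 0.25, want_tangent=False)
    R = f_int - model.external_forces(model.t)
    bc_dofs, _ = model._dirichlet_dofs_values(model.t)
    free = np.setdiff1d(np.arange(model.ndof), bc_dofs)
    return {"forces": forces, "displacement_drift": drift,
            "residual_norm": float(np.linalg.norm(R[free]))}


def _field_snapshot(model: FemModel) -> dict:
    sn = {
        "d": model.element_values(lambda s: s.plastic.d),
        "lambda_p": model.element_values(lambda s: s.plastic.lambda_p),
        "lambda_r": model.element_values(lambda s: s.lambda_r),
        "rho_c": model.element_values(lambda s: s.rho_c),
        "theta": model.theta.copy(),
        "u": model.u.copy(),
    }
    if model.states[0][0].bio is not None:
        sn["M"] = model.element_values(lambda s: s.bio.M)
        sn["G"] = model.element_values(lambda s: s.bio.G)
    return sn


def _write_indentation_vtk(model: FemModel, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    cell_data = {
        "theta": model.theta,
        "p": model.p,
        "d": model.element_values(lambda s: s.plastic.d),
        "lambda_p": model.element_values(lambda s: s.plastic.lambda_p),
        "lambda_r": model.element_values(lambda s: s.lambda_r),
        "rho_c": model.element_values(lambda s: s.rho_c),
    }
    if model.states[0][0].bio is not None:
        cell_data["M"] = model.element_values(lambda s: s.bio.M)
        cell_data["G"] = model.element_values(lambda s: s.bio.G)
    write_vtk(path, model.mesh.nodes, model.mesh.elems,
              point_vectors={"u": model.u.reshape(-1, 3)},
              cell_scalars=cell_data)


# ------------------------------------------------------------------- outputs

def write_outputs(report: dict, out_dir: str | Path) -> dict:
    """Serialize a runner's report: DataFrames to CSV, arrays to CSV, scalar
    entries to a JSON summary with stable keys.  Returns the summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {}
    for key, val in report.items():
        if isinstance(val, pd.DataFrame):
            val.to_csv(out / f"{key}.csv", index=False)
        elif isinstance(val, np.ndarray):
            np.savetxt(out / f"{key}.csv", val, delimiter=",")
        elif isinstance(val, (int, float, str, bool)):
            summary[key] = val
        elif isinstance(val, dict) and all(
            isinstance(v, (int, float, str, bool)) for v in val.values()
        ):
            summary[key] = val
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
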