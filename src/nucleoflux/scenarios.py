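"""End-to-end numerical experiments on the two-phase cell.

A scenario couples one boundary-displacement program (calibrated so the
deformed nucleus matches prescribed in-plane semi-axes), the quasi-static
mechanics ramp, and the transient diffusion problem driven by the resulting
Jacobian field, then extracts the observables: the normalized diffusive
flux trace at the nucleus-cytoplasm interface, the maximum nuclear
volumetric strain and its location, the maximum strain-dependent
diffusivity, and volume-averaged nuclear stresses.

Scenarios
---------
roundish_ref     undeformed reference (diffusion only)
uniform_spread   axisymmetric-equivalent uniform radial equatorial pull
azimuthal_spread fully 3D radial program varying with azimuth, matching
                 distinct X and Y nucleus semi-axis targets

Coupling modes: ``simultaneous`` starts deformation and diffusion together
at t0 (the working hypothesis); ``sequential`` freezes the final Jacobian
field into D(J) before any diffusion occurs (deform-then-diffuse).
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np

from . import diffusion as dif
from . import mechanics as mech
from .meshing import NUCLEUS, build_axisymmetric_mesh, build_octant_mesh

A_STAR_DEFAULT = 4.0             # equatorial boundary displacement a*, µm
B_OVER_A_DEFAULT = 0.9           # spread-group elongation index b/a
VOLUME_FACTOR_DEFAULT = 1.3      # cell-volume scale of the boundary map


@dataclasses.dataclass
class ScenarioConfig:
    """Deterministic configuration of one coupled run."""

    scenario: str = "azimuthal_spread"   # roundish_ref | uniform_spread | azimuthal_spread
    coupling: str = "simultaneous"       # simultaneous | sequential
    t_f: float = 1.0                     # ramp duration, s
    t_end: float = 5.0                   # total simulated time, s
    a_star: float = A_STAR_DEFAULT       # equatorial boundary amplitude, µm
    b_over_a: float = B_OVER_A_DEFAULT   # deformed-nucleus in-plane aspect target
    volume_factor: float = VOLUME_FACTOR_DEFAULT
    r_nucleus: float = 5.0
    r_cell: float = 10.0
    band_halfwidth: float = 5.0          # degrees
    h3d: float = 1.4                     # octant target edge, µm
    h2d: float = 0.35                    # axisymmetric target edge, µm
    n_load_steps: int = 10
    material: mech.MaterialParams = dataclasses.field(default_factory=mech.MaterialParams)
    diffusion: dif.DiffusionParams = dataclasses.field(default_factory=dif.DiffusionParams)
    out_dir: str | None = None

    def __post_init__(self):
        if self.scenario not in ("roundish_ref", "uniform_spread", "azimuthal_spread"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.coupling not in ("simultaneous", "sequential"):
            raise ValueError(f"unknown coupling mode {self.coupling!r}")
        if self.a_star < 0 or not (0 < self.b_over_a <= 1):
            raise ValueError("need a_star >= 0 and 0 < b_over_a <= 1")


@dataclasses.dataclass
class ScenarioResult:
    config: ScenarioConfig
    mesh: object
    mech_traj: object            # None for roundish_ref
    conc: object                 # deformed-run ConcentrationState
    conc_ref: object             # roundish reference ConcentrationState
    trace: object                # FluxTrace (vs itself for roundish_ref)
    summary: dict


def _build_mesh(cfg: ScenarioConfig, force_3d: bool = False):
    if cfg.scenario == "azimuthal_spread" or force_3d:
        return build_octant_mesh(cfg.r_nucleus, cfg.r_cell, h=cfg.h3d,
                                 band_halfwidth=cfg.band_halfwidth)
    return build_axisymmetric_mesh(cfg.r_nucleus, cfg.r_cell, h=cfg.h2d,
                                   band_halfwidth=cfg.band_halfwidth)


def calibrate_azimuthal_split(mesh, cfg: ScenarioConfig, tol: float = 0.01,
                              max_iter: int = 6, coarse: bool = True):
    """Split the mean boundary amplitude a* between the X and Y axes.

    The azimuthal program keeps (ux + uy)/2 = a_star (so its azimuthal mean
    matches the uniform program) and secant-iterates the split until the
    deformed nucleus in-plane aspect ratio b_ext/a_ext matches ``b_over_a``
    within ``tol``.  The secant solves run on a coarsened octant (the aspect
    ratio is a mild global quantity, insensitive to resolution); the final
    extents are re-measured on the production mesh by the caller.  Returns
    (program, (a_ext, b_ext), n_solves).
    """
    cal_mesh = mesh
    if coarse:
        cal_mesh = build_octant_mesh(cfg.r_nucleus, cfg.r_cell,
                                     h=1.45 * cfg.h3d,
                                     band_halfwidth=cfg.band_halfwidth)
    prob = mech.MechanicsProblem(cal_mesh, cfg.material)

    def make(ux):
        uy = max(2.0 * cfg.a_star - ux, 0.0)
        return mech.BoundaryProgram("azimuthal", cfg.t_f, amplitude_x=ux,
                                    amplitude_y=uy,
                                    volume_factor=cfg.volume_factor)

    def ratio(ux):
        traj = mech.solve_quasistatic(prob, program=make(ux), n_steps=5)
        a_ext = mech.nucleus_extent(prob, traj.u_final, axis=0)
        b_ext = mech.nucleus_extent(prob, traj.u_final, axis=1)
        return b_ext / a_ext, (a_ext, b_ext)

    target = cfg.b_over_a
    ux0 = cfg.a_star * (1.0 + (1.0 - target))
    r0, ext0 = ratio(ux0)
    n = 1
    ux1 = min(ux0 * 1.3, 2 * cfg.a_star)
    for _ in range(max_iter):
        if abs(r0 - target) < tol:
            return make(ux0), ext0, n
        r1, ext1 = ratio(ux1)
        n += 1
        if abs(r1 - target) < tol:
            return make(ux1), ext1, n
        slope = (r1 - r0) / (ux1 - ux0)
        ux_next = ux1 + (target - r1) / slope
        ux_next = min(max(ux_next, 0.0), 2 * cfg.a_star)
        ux0, r0, ext0 = ux1, r1, ext1
        ux1 = ux_next
    raise mech.NewtonError(
        f"azimuthal split calibration did not converge: ratio {r0:.4f} "
        f"vs target {target:.4f}")


def run_scenario(cfg: ScenarioConfig, mesh=None, force_3d: bool = False) -> ScenarioResult:
    """Calibrate, deform, diffuse and probe one scenario."""
    if mesh is None:
        mesh = _build_mesh(cfg, force_3d=force_3d)
    solver = dif.DiffusionSolver(mesh, cfg.diffusion)

    if cfg.scenario == "roundish_ref":
        conc = dif.solve_diffusion(solver, None, t_end=cfg.t_end)
        trace = dif.flux_probe(solver, conc, None, conc)
        summary = _summarize(cfg, mesh, None, solver, conc, conc, trace)
        result = ScenarioResult(cfg, mesh, None, conc, conc, trace, summary)
        _write_outputs(result, solver)
        return result

    if cfg.scenario == "azimuthal_spread":
        if mesh.dim != 3:
            raise ValueError("azimuthal_spread requires the 3D octant mesh")
        program, extents, n_cal = calibrate_azimuthal_split(mesh, cfg)
    else:
        program = mech.BoundaryProgram("uniform_radial", cfg.t_f,
                                       amplitude_x=cfg.a_star,
                                       volume_factor=cfg.volume_factor)
        extents, n_cal = None, 0
    traj = mech.solve_quasistatic(mesh, cfg.material, program,
                                  n_steps=cfg.n_load_steps)
    if extents is None:
        prob = traj.problem
        extents = [mech.nucleus_extent(prob, traj.u_final, axis=0)]

    if cfg.coupling == "simultaneous":
        J_of_t, ramp_end = traj.J_at_time, cfg.t_f
    else:
        J_final = traj.J_steps[-1]
        J_of_t, ramp_end = (lambda t: J_final), 0.0
    conc = dif.solve_diffusion(solver, J_of_t, t_end=cfg.t_end,
                               ramp_end=ramp_end)
    conc_ref = dif.solve_diffusion(solver, None, t_end=cfg.t_end,
                                   time_grid=conc.times)
    trace = dif.flux_probe(solver, conc, J_of_t, conc_ref, t_select=cfg.t_f)

    summary = _summarize(cfg, mesh, traj, solver, conc, conc_ref, trace,
                         extents=extents, n_calibration_solves=n_cal,
                         program=program)
    result = ScenarioResult(cfg, mesh, traj, conc, conc_ref, trace, summary)
    _write_outputs(result, solver)
    return result


def _nucleus_amount_vector(solver: dif.DiffusionSolver) -> np.ndarray:
    """Nodal weights integrating a field over the nucleus subdomain."""
    sp = solver.space_mass
    mesh = solver.mesh
    nuc = mesh.phase == NUCLEUS
    w = sp.w[nuc]
    if solver.axisym:
        w = w * sp.xq[nuc][:, :, 0]
    en = np.einsum("eq,qn->en", w, sp.N)
    out = np.zeros(mesh.nnodes)
    np.add.at(out, mesh.conn[nuc].ravel(), en.ravel())
    return out


def trace_characteristic_time(solver: dif.DiffusionSolver,
                              conc: dif.ConcentrationState,
                              t_start: float) -> float:
    """Late-time exponential time constant of nuclear filling (s).

    Fits ln(y_inf - y(t)) over [t_start, t_start + 3] where y is the total
    amount inside the nucleus and y_inf its equilibration value (uniform
    concentration limit).
    """
    wn = _nucleus_amount_vector(solver)
    y = conc.c @ wn
    vol_n = wn.sum()
    vol_tot = solver._amount_vec.sum()
    y_inf = conc.total_amount[0] / vol_tot * vol_n
    t = conc.times
    sel = (t >= t_start) & (t <= t_start + 3.0)
    resid = y_inf - y[sel]
    ok = resid > 1e-12 * max(y_inf, 1e-300)
    if ok.sum() < 3:
        return float("nan")
    slope = np.polyfit(t[sel][ok], np.log(resid[ok]), 1)[0]
    return float(-1.0 / slope)


def _summarize(cfg, mesh, traj, solver, conc, conc_ref, trace,
               extents=None, n_calibration_solves=0, program=None) -> dict:
    out = {
        "scenario": cfg.scenario,
        "coupling": cfg.coupling,
        "t_f_s": cfg.t_f,
        "mesh_dim": mesh.dim,
        "n_elements": int(mesh.nelements),
        "n_nodes": int(mesh.nnodes),
        "peak_normalized_flux": trace.peak,
        "peak_time_s": trace.peak_time,
        "probe_latitude_deg": trace.latitude_deg,
        "probe_location_um": [float(x) for x in trace.location],
        "conservation_error": conc.conservation_error(),
        "characteristic_time_s": trace_characteristic_time(
            solver, conc, t_start=cfg.t_f if traj is not None else 0.5),
    }
    if traj is None:
        out.update({"max_eps_V": 0.0, "max_D_um2_s": float(
            max(cfg.diffusion.D0_cytoplasm, cfg.diffusion.D0_nucleus))})
        return out
    eV, loc, lat = mech.max_volumetric_strain(traj)
    D_field = dif.strain_dependent_D(traj.J_steps[-1], solver.D0[:, None])
    e_d, q_d = np.unravel_index(np.argmax(D_field), D_field.shape)
    xq_d = traj.problem.space.xq[e_d, q_d]
    r_d = float(np.linalg.norm(xq_d))
    nuc = mesh.phase == NUCLEUS
    e_n, q_n = np.unravel_index(np.argmax(D_field[nuc]), D_field[nuc].shape)
    xq_n = traj.problem.space.xq[nuc][e_n, q_n]
    r_n = float(np.linalg.norm(xq_n))
    lat_n = math.degrees(math.asin(min(max(xq_n[-1] / r_n, -1), 1)))
    out.update({
        "max_eps_V": float(eV),
        "max_eps_V_percent": float(100 * eV),
        "max_eps_V_location_um": [float(x) for x in loc],
        "max_eps_V_latitude_deg": float(lat),
        "max_D_um2_s": float(D_field[e_d, q_d]),
        "max_D_location_um": [float(x) for x in xq_d],
        "max_D_radius_um": r_d,
        "max_D_nucleus_um2_s": float(D_field[nuc][e_n, q_n]),
        "max_D_nucleus_latitude_deg": float(lat_n),
        "max_D_nucleus_radius_um": r_n,
        "amplitudes_um": [program.amplitude_x, program.amplitude_y],
        "nucleus_extents_um": [float(x) for x in np.atleast_1d(extents)],
        "n_calibration_solves": int(n_calibration_solves),
    })
    out.update(mech.nuclear_stress_summary(traj))
    return out


def _write_outputs(result: ScenarioResult, solver) -> None:
    cfg = result.config
    if cfg.out_dir is None:
        return
    import pandas as pd

    from .vtkio import write_vtk

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "summary.json").write_text(json.dumps(result.summary, indent=2))
    tr = result.trace
    pd.DataFrame({
        "time_s": tr.times, "flux": tr.flux, "flux_ref": tr.flux_ref,
        "normalized": tr.normalized,
    }).to_csv(out / "flux_trace.csv", index=False)
    point_data = {"c_final": result.conc.c[-1]}
    cell_data = {"phase": result.mesh.phase.astype(float)}
    if result.mech_traj is not None:
        u = result.mech_traj.u_final.reshape(result.mesh.nnodes, -1)
        point_data["u"] = u
        cell_data["J_mean"] = result.mech_traj.J_steps[-1].mean(axis=1)
        cell_data["eps_V_mean"] = cell_data["J_mean"] - 1.0
    write_vtk(out / "final_state.vtk", result.mesh, point_data, cell_data)


# ---------------------------------------------------------------------------


def ramp_study(cfg: ScenarioConfig, durations=(0.75, 1.0, 1.25),
               include_sequential: bool = False) -> dict:
    """Run the uniform-radial scenario at several ramp durations.

    Returns per-duration summaries plus the pairwise relative spread of the
    late-time diffusion characteristic times, which the model predicts to be
    approximately rate-independent.  Optionally adds a sequential-coupling
    run at the base duration for the deform-then-diffuse comparison.
    """
    mesh = build_axisymmetric_mesh(cfg.r_nucleus, cfg.r_cell, h=cfg.h2d,
                                   band_halfwidth=cfg.band_halfwidth)
    rows = []
    for t_f in durations:
        sub = dataclasses.replace(cfg, scenario="uniform_spread", t_f=t_f,
                                  coupling="simultaneous", out_dir=None)
        res = run_scenario(sub, mesh=mesh)
        rows.append(res.summary)
    taus = np.array([r["characteristic_time_s"] for r in rows])
    spread = float((taus.max() - taus.min()) / taus.mean())
    out = {"runs": rows, "characteristic_times_s": taus.tolist(),
           "char_time_rel_spread": spread,
           "peak_normalized_flux_max": float(
               max(r["peak_normalized_flux"] for r in rows))}
    if include_sequential:
        sub = dataclasses.replace(cfg, scenario="uniform_spread",
                                  coupling="sequential", out_dir=None)
        out["sequential"] = run_scenario(sub, mesh=mesh).summary
    return out
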