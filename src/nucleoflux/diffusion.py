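"""Transient passive diffusion with strain-dependent diffusivity.

Fick's second law, dc/dt = div(D grad c), is solved on the reference mesh
with the Jacobian-coupled diffusivity

    D(J) = D0 * (exp(J) - 1) / (e - 1),

which vanishes at full densification (J = 0) and recovers the phase
baseline D0 at J = 1.  The formulation deliberately keeps the equation on
the reference domain with D(J) as a spatially varying coefficient and omits
the pull-back metric terms of a fully Lagrangian transport law; see the
methods note for why this simplification is part of the model definition.

The outer boundary is insulated (zero flux), which the Galerkin form
enforces naturally; concentration and normal flux are continuous across the
conforming nucleus-cytoplasm interface by construction.  Time integration
is implicit, variable-step BDF (order 1 startup, order 2 after), with steps
bounded to resolve the loading ramp.  Because the stiffness matrix has zero
row sums, the scheme conserves the total amount exactly up to linear-solver
roundoff.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.sparse.linalg import factorized

from .fem import FESpace
from .meshing import CYTOPLASM, NUCLEUS, Mesh

E_MINUS_1 = math.e - 1.0


@dataclasses.dataclass(frozen=True)
class DiffusionParams:
    """Baseline diffusivities (µm²/s) and initial concentrations (µmol/ml).

    At t = 0 the transcription factors sit entirely in the cytoplasm;
    interface nodes take the cytoplasm value by default (config switch).
    """

    D0_cytoplasm: float = 30.0
    D0_nucleus: float = 29.2
    c0_cytoplasm: float = 0.2
    c0_nucleus: float = 0.0
    interface_value: str = "cytoplasm"   # cytoplasm | nucleus | mean

    def __post_init__(self):
        if self.D0_cytoplasm <= 0 or self.D0_nucleus <= 0:
            raise ValueError("baseline diffusivities must be positive")
        if self.c0_cytoplasm < 0 or self.c0_nucleus < 0:
            raise ValueError("initial concentrations must be non-negative")


def strain_dependent_D(J, D0):
    """Jacobian-coupled diffusivity D = D0 (e^J - 1)/(e - 1).

    Monotone increasing in J; D(0) = 0 and D(1) = D0.  Negative J is
    unphysical and rejected.
    """
    J = np.asarray(J, float)
    if np.any(J < 0):
        raise ValueError("negative Jacobian: unphysical volume ratio")
    return np.asarray(D0, float) * (np.expm1(J)) / E_MINUS_1


def characteristic_time(R: float, D: float) -> float:
    """One-dimensional diffusion time scale R^2 / D (s)."""
    if R <= 0 or D <= 0:
        raise ValueError("R and D must be positive")
    return R * R / D


# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ConcentrationState:
    """Time-resolved nodal concentration on the reference mesh."""

    mesh: Mesh
    times: np.ndarray            # (nt,)
    c: np.ndarray                # (nt, nnodes) µmol/ml
    total_amount: np.ndarray     # (nt,) integral of c over the domain

    def conservation_error(self) -> float:
        a0 = self.total_amount[0]
        return float(np.max(np.abs(self.total_amount - a0)) / abs(a0))


@dataclasses.dataclass
class FluxTrace:
    """Flux magnitude at one tracked material point vs its roundish twin."""

    times: np.ndarray
    flux: np.ndarray             # ||phi|| at the tracked point
    flux_ref: np.ndarray         # ||phi_0|| at the same point, roundish run
    normalized: np.ndarray       # flux / flux_ref (NaN where ref ~ 0)
    location: np.ndarray         # reference coordinates of the point, µm
    latitude_deg: float

    @property
    def peak(self) -> float:
        ok = np.isfinite(self.normalized)
        return float(np.nanmax(self.normalized[ok]))

    @property
    def peak_time(self) -> float:
        ok = np.isfinite(self.normalized)
        idx = np.flatnonzero(ok)[int(np.nanargmax(self.normalized[ok]))]
        return float(self.times[idx])


class DiffusionSolver:
    """Assembled diffusion operator on one mesh (shared by runs)."""

    def __init__(self, mesh: Mesh, params: DiffusionParams,
                 degree_mass: int = 4):
        self.mesh = mesh
        self.params = params
        self.space = FESpace(mesh, degree=2)          # stiffness + flux qps
        self.space_mass = FESpace(mesh, degree=degree_mass)
        self.axisym = mesh.dim == 2
        if self.axisym:
            self._wstiff = self.space.xq[:, :, 0]
            self._wmass = self.space_mass.xq[:, :, 0]
        else:
            self._wstiff = None
            self._wmass = None
        self.M = self.space_mass.mass_matrix(self._wmass)
        nel = mesh.nelements
        self.D0 = np.where(mesh.phase == NUCLEUS,
                           params.D0_nucleus, params.D0_cytoplasm)
        # lumped integration vector for total amount
        ones = np.ones(mesh.nnodes)
        self._amount_vec = self.M @ ones

    def initial_condition(self) -> np.ndarray:
        """Phase-wise nodal assignment of the discontinuous initial field."""
        mesh, p = self.mesh, self.params
        c = np.full(mesh.nnodes, np.nan)
        # nodes of nucleus elements then cytoplasm elements; interface nodes
        # are members of both and get the configured value
        c[np.unique(mesh.conn[mesh.phase == NUCLEUS])] = p.c0_nucleus
        c[np.unique(mesh.conn[mesh.phase == CYTOPLASM])] = p.c0_cytoplasm
        iface = mesh.node_sets["interface"]
        if p.interface_value == "cytoplasm":
            c[iface] = p.c0_cytoplasm
        elif p.interface_value == "nucleus":
            c[iface] = p.c0_nucleus
        elif p.interface_value == "mean":
            c[iface] = 0.5 * (p.c0_cytoplasm + p.c0_nucleus)
        else:
            raise ValueError(f"unknown interface_value {p.interface_value!r}")
        assert not np.isnan(c).any()
        return c

    def stiffness(self, J_qp) -> "sparse matrix":
        """K for a Jacobian field at the stiffness quadrature points
        (scalar 1.0 for the undeformed reference)."""
        D = strain_dependent_D(J_qp, self.D0[:, None])
        coeff = D if self._wstiff is None else D * self._wstiff
        return self.space.stiffness_matrix(coeff)

    def amount(self, c) -> float:
        return float(self._amount_vec @ c)

    def flux_at_qp(self, c, J_qp):
        """phi = -D grad c at the stiffness quadrature points."""
        D = strain_dependent_D(J_qp, self.D0[:, None])
        return -D[..., None] * self.space.gradient(c)

    def flux_at_qp_subset(self, c, J_qp, elems):
        """phi = -D grad c restricted to a subset of elements."""
        D = strain_dependent_D(J_qp, self.D0[elems][:, None])
        grad = np.einsum("eqnd,en->eqd", self.space.dNdX[elems],
                         c[self.mesh.conn[elems]])
        return -D[..., None] * grad


def solve_diffusion(solver: DiffusionSolver, J_of_t=None, t_end: float = 5.0,
                    ramp_end: float = 0.0, dt_init: float = 2.5e-3,
                    dt_ramp_max: float = 0.02, dt_growth: float = 1.15,
                    dt_max: float = 0.25, c_init=None,
                    time_grid=None) -> ConcentrationState:
    """Variable-step implicit BDF integration of the diffusion problem.

    ``J_of_t`` maps a time to the Jacobian field at the stiffness
    quadrature points (None means the undeformed J = 1 reference run).
    During the ramp ([0, ramp_end]) the stiffness is reassembled every step
    and the step size is capped at ``dt_ramp_max``; afterwards the operator
    is frozen and the step grows geometrically.  BDF1 starts the run, BDF2
    (variable-step coefficients) continues it.
    """
    M = solver.M
    c_prev = solver.initial_condition() if c_init is None else np.asarray(c_init, float)
    times = [0.0]
    cs = [c_prev.copy()]
    amounts = [solver.amount(c_prev)]

    if J_of_t is None:
        K_frozen = solver.stiffness(1.0)
    else:
        K_frozen = None

    t = 0.0
    dt = dt_init
    dt_prev = None
    c_prev2 = None
    solve_cache = {}
    if time_grid is not None:
        # replay an existing run's step sequence exactly (used so the
        # roundish reference shares the deformed run's time grid)
        grid = list(np.asarray(time_grid, float))
        if grid and grid[0] == 0.0:
            grid = grid[1:]

    def get_K(t_new):
        nonlocal K_frozen
        if J_of_t is None:
            return K_frozen, True
        if t_new >= ramp_end:
            if K_frozen is None:
                K_frozen = solver.stiffness(J_of_t(ramp_end))
            return K_frozen, True
        return solver.stiffness(J_of_t(t_new)), False

    while t < t_end - 1e-12:
        if time_grid is not None:
            if not grid:
                break
            t_new = grid.pop(0)
            dt = t_new - t
        else:
            dt = min(dt, t_end - t)
            if t < ramp_end:
                dt = min(dt, dt_ramp_max, ramp_end - t + 1e-12)
            t_new = t + dt
        K, frozen = get_K(t_new)
        if c_prev2 is None:
            A = M + dt * K
            rhs = M @ c_prev
            key = ("bdf1", round(math.log(dt, 1.0001)))
        else:
            rho = dt / dt_prev
            a0 = (1 + 2 * rho) / (1 + rho) / dt
            a1 = (1 + rho) / dt
            a2 = -rho * rho / (1 + rho) / dt
            A = a0 * M + K
            rhs = M @ (a1 * c_prev + a2 * c_prev2)
            key = ("bdf2", round(math.log(dt, 1.0001)),
                   round(math.log(dt_prev, 1.0001)))
        if frozen and key in solve_cache:
            solve = solve_cache[key]
        else:
            solve = factorized(A.tocsc())
            if frozen:
                solve_cache[key] = solve
        c_new = solve(rhs)

        c_prev2, c_prev = c_prev, c_new
        dt_prev = dt
        t = t_new
        times.append(t)
        cs.append(c_new.copy())
        amounts.append(solver.amount(c_new))
        dt = min(dt * dt_growth, dt_max)

    return ConcentrationState(solver.mesh, np.array(times), np.array(cs),
                              np.array(amounts))


# ---------------------------------------------------------------------------


def interface_probe_candidates(solver: DiffusionSolver) -> np.ndarray:
    """Element indices of nucleus elements touching the interface."""
    mesh = solver.mesh
    iface = set(mesh.node_sets["interface"].tolist())
    ncorner = 4 if mesh.dim == 3 else 3
    out = []
    for e in np.flatnonzero(mesh.phase == NUCLEUS):
        if sum(1 for n in mesh.conn[e, :ncorner] if n in iface) >= mesh.dim:
            out.append(e)
    return np.array(out, int)


def flux_probe(solver: DiffusionSolver, state: ConcentrationState,
               traj_J_of_t, reference: ConcentrationState,
               floor_rel: float = 1e-3, t_select: float | None = None) -> FluxTrace:
    """Normalized flux trace at the interface point of maximum flux.

    The tracked material point is the interface-adjacent quadrature point
    (nucleus side) where the deformed run's flux magnitude is largest at
    ``t_select`` -- the instant the spread configuration is attained (end of
    ramp); with ``t_select=None`` the global space-time maximum is used.
    The trace is that point's flux history divided by its time-matched
    counterpart in the roundish reference run (linear interpolation onto the
    deformed run's time grid).  Reference values below ``floor_rel`` times
    the reference maximum yield masked (NaN) samples rather than silent
    division.
    """
    cand = interface_probe_candidates(solver)
    nt = len(state.times)
    mags = np.empty((nt, len(cand), solver.space.qw.size))
    for k, t in enumerate(state.times):
        J = traj_J_of_t(t) if traj_J_of_t is not None else 1.0
        J_qp = J[cand] if np.ndim(J) > 0 else J
        phi = solver.flux_at_qp_subset(state.c[k], J_qp, cand)
        mags[k] = np.linalg.norm(phi, axis=-1)
    if t_select is None:
        k_sel, e_loc, q_loc = np.unravel_index(np.argmax(mags), mags.shape)
    else:
        k_sel = int(np.argmin(np.abs(state.times - t_select)))
        e_loc, q_loc = np.unravel_index(np.argmax(mags[k_sel]),
                                        mags.shape[1:])
    flux = mags[:, e_loc, q_loc]
    e_glob = cand[e_loc]
    loc = solver.space.xq[e_glob, q_loc]

    # reference flux at the same material point, interpolated in time
    ref_mags = np.empty(len(reference.times))
    for k in range(len(reference.times)):
        phi = solver.flux_at_qp_subset(reference.c[k], 1.0,
                                       np.array([e_glob]))
        ref_mags[k] = np.linalg.norm(phi[0, q_loc])
    flux_ref = np.interp(state.times, reference.times, ref_mags)

    floor = floor_rel * max(flux_ref.max(), 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(flux_ref > floor, flux / flux_ref, np.nan)
    r = float(np.linalg.norm(loc))
    lat = math.degrees(math.asin(min(max(loc[-1] / r, -1.0), 1.0)))
    return FluxTrace(state.times.copy(), flux, flux_ref, normalized,
                     np.array(loc), lat)
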