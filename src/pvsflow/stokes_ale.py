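"""Time-dependent Stokes flow on a moving PVS domain (ALE formulation).

Each time step performs, in order:

1. evaluate the prescribed inner-wall displacement d|_Lambda(X, t) =
   A(X,t) n + B(X,t) r on the *reference* wall nodes;
2. extend it harmonically into the volume (Laplace solve per component,
   zero on the rigid outer wall, natural condition on inlet/outlet faces)
   and move the mesh to Omega_t;
3. form the discrete mesh velocity w = (d^k - d^{k-1}) / dt;
4. solve one implicit-Euler step of the Stokes system on Omega_t with the
   ALE advection correction -rho div(w x v), traction (pressure) conditions
   on inlet/outlets, v = w on the inner wall and v = 0 on the outer wall;
5. record boundary fluxes, average normal velocities and pressures.

Discretization: Taylor-Hood P2/P2/P1 (see :mod:`pvsflow.fem`), sparse
direct linear solves, first-order implicit Euler in time; the momentum mass
term of the previous step is integrated over the previous domain. The
global mass balance sum_b int_b v.n ds + dV/dt = 0 is monitored every step
and reported on the resulting :class:`~pvsflow.metrics.FlowRecord`.

Internally everything is in SI units; geometry enters in mm and reported
velocities leave in um/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import fem
from .errors import ParameterError
from .forcing import (PressureBCSpec, RigidMotionSpec, WallWaveSpec,
                      WindkesselSpec, boundary_displacement)
from .geometry import PVSGeometry3D
from .metrics import FlowRecord
from .units import MIN_S, UL_M3

__all__ = ["FluidParams", "ForcingSpec", "StokesALESolver", "run_cycles",
           "solve_steady", "mesh_velocity", "extend_displacement"]


@dataclass
class FluidParams:
    """CSF fluid parameters: density (kg/m^3), dynamic viscosity (Pa s),
    time step (s)."""

    rho: float = 1e3
    mu: float = 0.697e-3
    dt: float = 1e-3

    def __post_init__(self):
        if self.rho <= 0 or self.mu <= 0 or self.dt <= 0:
            raise ParameterError("rho, mu and dt must be positive")


@dataclass
class ForcingSpec:
    """Bundle of all driving mechanisms for one model run."""

    wall: WallWaveSpec | None = None
    rigid: RigidMotionSpec | None = None
    pressure: PressureBCSpec = field(default_factory=PressureBCSpec)
    windkessel: tuple | None = None  # one WindkesselSpec per outlet

    @property
    def frequency(self) -> float:
        if self.wall is not None:
            return self.wall.waveform.f
        return self.pressure.f


def mesh_velocity(d_now, d_prev, dt: float) -> np.ndarray:
    """First-order mesh velocity (m/s) from displacements in mm."""
    if dt <= 0:
        raise ParameterError("dt must be positive")
    return (np.asarray(d_now, dtype=float) - np.asarray(d_prev, dtype=float)) * 1e-3 / dt


def extend_displacement(geometry: PVSGeometry3D, inner_disp: np.ndarray,
                        outer_disp: np.ndarray | None = None) -> np.ndarray:
    """Harmonic extension of a wall displacement to all mesh vertices.

    ``inner_disp``: (n_inner_verts, 3) displacement prescribed on the inner
    wall vertices (ordered as ``mesh.verts_with_tag(TAG_INNER_WALL)``), in
    the same units as the mesh. The outer wall is held fixed unless
    ``outer_disp`` prescribes it (used e.g. to verify that a rigid
    translation of both walls extends exactly).
    """
    mesh = geometry.mesh
    inner = mesh.verts_with_tag(fem.TAG_INNER_WALL)
    outer = np.setdiff1d(mesh.verts_with_tag(fem.TAG_OUTER_WALL), inner)
    dirichlet = np.concatenate([inner, outer])
    ext = fem.HarmonicExtension(mesh.verts, mesh.cells, dirichlet)
    vals = np.zeros((dirichlet.size, 3))
    vals[: inner.size] = inner_disp
    if outer_disp is not None:
        vals[inner.size:] = outer_disp
    return ext.extend(vals)


class StokesALESolver:
    """Implicit-Euler ALE Stokes stepper on a :class:`PVSGeometry3D`."""

    def __init__(self, geometry: PVSGeometry3D, params: FluidParams,
                 ale_form: str = "conservative"):
        if ale_form not in ("conservative", "nonconservative", "off"):
            raise ParameterError("ale_form must be conservative/nonconservative/off")
        self.geometry = geometry
        self.params = params
        self.ale_form = ale_form
        mesh = geometry.mesh
        self.mesh = mesh
        self.X_ref = mesh.coords_p2 * 1e-3  # m
        self.n_p2 = mesh.n_p2
        self.n_verts = mesh.n_verts

        self.inner_p2 = mesh.p2_nodes_with_tag(fem.TAG_INNER_WALL)
        outer_p2 = mesh.p2_nodes_with_tag(fem.TAG_OUTER_WALL)
        self.outer_p2 = np.setdiff1d(outer_p2, self.inner_p2)
        self.dir_nodes = np.concatenate([self.inner_p2, self.outer_p2])
        self.dir_dofs = (3 * self.dir_nodes[:, None] + np.arange(3)).ravel()

        self.inner_verts = mesh.verts_with_tag(fem.TAG_INNER_WALL)
        outer_verts = np.setdiff1d(mesh.verts_with_tag(fem.TAG_OUTER_WALL),
                                   self.inner_verts)
        self._ext_dirichlet = np.concatenate([self.inner_verts, outer_verts])
        self._n_inner_verts = self.inner_verts.size
        self.extension = fem.HarmonicExtension(
            mesh.verts * 1e-3, mesh.cells, self._ext_dirichlet)

        # outward (fluid) unit normals at the reference inner-wall nodes
        if geometry.normal_fn is not None:
            self.inner_normals = np.asarray(
                geometry.normal_fn(mesh.coords_p2[self.inner_p2]))
        else:
            nn = fem.nodal_normals(mesh.coords_p2,
                                   mesh.faces_with_tag(fem.TAG_INNER_WALL),
                                   mesh.n_p2)
            self.inner_normals = nn[self.inner_p2]

        self.boundary_tags = [t for t in (fem.TAG_INNER_WALL, fem.TAG_OUTER_WALL,
                                          fem.TAG_INLET, *geometry.outlet_tags)]
        self.faces_by_tag = {t: mesh.faces_with_tag(t) for t in self.boundary_tags}

    # -- displacement handling -------------------------------------------

    def wall_displacement_m(self, forcing: ForcingSpec, t: float) -> np.ndarray:
        """Prescribed displacement (m) at the reference inner-wall P2 nodes."""
        if forcing.wall is None:
            return np.zeros((self.inner_p2.size, 3))
        X_mm = self.mesh.coords_p2[self.inner_p2]
        d_mm = boundary_displacement(forcing.wall, forcing.rigid, X_mm,
                                     self.inner_normals, t)
        return d_mm * 1e-3

    def full_displacement(self, wall_disp_m: np.ndarray) -> np.ndarray:
        """Extend a wall displacement to every P2 node (m)."""
        vals = np.zeros((self._ext_dirichlet.size, 3))
        # prescribed values on inner-wall vertices (leading block of the
        # inner-wall P2 node list is exactly the vertex subset)
        vert_rows = np.searchsorted(self.inner_p2, self.inner_verts)
        vals[: self._n_inner_verts] = wall_disp_m[vert_rows]
        d_verts = self.extension.extend(vals)
        d = np.zeros((self.n_p2, 3))
        d[: self.n_verts] = d_verts
        e = self.mesh.edges
        d[self.n_verts:] = 0.5 * (d_verts[e[:, 0]] + d_verts[e[:, 1]])
        d[self.inner_p2] = wall_disp_m  # exact values on the moving wall
        d[self.outer_p2] = 0.0
        return d

    # -- single solves ----------------------------------------------------

    def _stokes_system(self, X, w_nodal, dt):
        p = self.params
        Msc, Ksc, geom = fem.assemble_scalar_operators(X, self.mesh.cells_p2,
                                                       self.n_p2)
        A_s = Ksc * p.mu
        if dt is not None:
            A_s = A_s + Msc * (p.rho / dt)
        if w_nodal is not None and self.ale_form != "off":
            C = fem.assemble_ale_advection(
                X, self.mesh.cells_p2, self.n_p2, w_nodal, geom,
                conservative=(self.ale_form == "conservative"))
            A_s = A_s - p.rho * C
        A_vv = sp.kron(A_s, sp.eye(3), format="csr")
        B = fem.assemble_divergence(X, self.mesh.cells_p2, self.mesh.cells,
                                    self.n_p2, self.n_verts, geom)
        K = sp.bmat([[A_vv, -B.T], [B, None]], format="csr")
        return K, Msc

    def _traction_rhs(self, X, tractions: dict) -> np.ndarray:
        rhs = np.zeros(3 * self.n_p2)
        for tag, value in tractions.items():
            if value == 0.0:
                continue
            rhs += fem.traction_rhs(X, self.faces_by_tag[tag], value, self.n_p2)
        return rhs

    def solve_step(self, X, w_nodal, v_old, Msc_prev, tractions, dt):
        """One implicit-Euler ALE step; returns (v (n_p2,3), p (n_verts))."""
        K, Msc = self._stokes_system(X, w_nodal, dt)
        rhs_v = (self.params.rho / dt) * (Msc_prev @ v_old)
        rhs = np.concatenate([(rhs_v.ravel()
                               + self._traction_rhs(X, tractions)),
                              np.zeros(self.n_verts)])
        dir_vals = np.zeros((self.dir_nodes.size, 3))
        if w_nodal is not None:
            dir_vals[: self.inner_p2.size] = w_nodal[self.inner_p2]
        x = fem.solve_dirichlet(K, rhs, self.dir_dofs, dir_vals.ravel())
        v = x[: 3 * self.n_p2].reshape(self.n_p2, 3)
        p = x[3 * self.n_p2:]
        return v, p, Msc

    def solve_steady(self, tractions: dict):
        """Steady Stokes flow on the reference domain with rigid walls."""
        K, _ = self._stokes_system(self.X_ref, None, None)
        rhs = np.concatenate([self._traction_rhs(self.X_ref, tractions),
                              np.zeros(self.n_verts)])
        x = fem.solve_dirichlet(K, rhs, self.dir_dofs,
                                np.zeros(self.dir_dofs.size))
        return x[: 3 * self.n_p2].reshape(self.n_p2, 3), x[3 * self.n_p2:]

    def flux(self, X, v, tag) -> float:
        return fem.boundary_flux(X, self.faces_by_tag[tag], v)

    def area(self, X, tag) -> float:
        return fem.surface_area(X, self.faces_by_tag[tag])


def solve_steady(geometry: PVSGeometry3D, params: FluidParams,
                 tractions: dict):
    """Convenience wrapper: steady Stokes with per-tag traction values (Pa).

    Returns (v, p, solver); boundary fluxes can then be measured with
    ``solver.flux(solver.X_ref, v, tag)``.
    """
    solver = StokesALESolver(geometry, params)
    v, p = solver.solve_steady(tractions)
    return v, p, solver


def run_cycles(geometry: PVSGeometry3D, forcing: ForcingSpec,
               params: FluidParams, n_cycles: int = 4,
               convergence_rtol: float | None = None,
               ale_form: str = "conservative") -> FlowRecord:
    """March the ALE Stokes model from rest through forcing cycles.

    Stops after ``n_cycles`` or earlier if ``convergence_rtol`` is given and
    the cycle-over-cycle change of the peak particle position drops below
    it. Records per-boundary flow rates and average normal velocities, the
    running peak pressure, and the worst-step global mass-balance residual
    (relative to the peak boundary flux).
    """
    solver = StokesALESolver(geometry, params, ale_form=ale_form)
    mesh = geometry.mesh
    f = forcing.frequency
    dt = params.dt
    n_steps_cycle = max(1, int(round(1.0 / (f * dt))))
    bc = forcing.pressure
    outlet_tags = geometry.outlet_tags
    wk_states = None
    if bc.mode == "windkessel":
        wk_states = list(forcing.windkessel or
                         [WindkesselSpec() for _ in outlet_tags])

    d_prev = np.zeros((solver.n_p2, 3))
    v = np.zeros((solver.n_p2, 3))
    Msc_prev = fem.assemble_scalar_operators(solver.X_ref, mesh.cells_p2,
                                             solver.n_p2)[0]
    V_prev = fem.mesh_volume(solver.X_ref, mesh.cells_p2)
    Q_prev = {t: 0.0 for t in outlet_tags}

    names = {fem.TAG_INLET: "in", fem.TAG_OUTLET_1: "out1", fem.TAG_OUTLET_2: "out2"}
    ts = [0.0]
    Q_rec = {names[t]: [0.0] for t in (fem.TAG_INLET, *outlet_tags)}
    v_rec = {names[t]: [0.0] for t in (fem.TAG_INLET, *outlet_tags)}
    p_peak = 0.0
    peak_flux = 0.0
    mass_res = 0.0
    peak_snapshot = None
    peak_vavg = -1.0
    x_cycle_peaks = []

    k = 0
    for cycle in range(n_cycles):
        for _ in range(n_steps_cycle):
            k += 1
            t = k * dt
            wall_d = solver.wall_displacement_m(forcing, t)
            d = solver.full_displacement(wall_d)
            X = solver.X_ref + d
            w = (d - d_prev) / dt

            if bc.mode == "windkessel":
                tr_in, tr_out = bc.traction_values(
                    t, outlet_rates=[Q_prev[tg] / UL_M3 * MIN_S
                                     for tg in outlet_tags],
                    wk_states=wk_states, dt=dt)
            else:
                tr_in, tr_out = bc.traction_values(t)
            tractions = {fem.TAG_INLET: tr_in}
            for tg, val in zip(outlet_tags, tr_out):
                tractions[tg] = val

            v, p, Msc_prev = solver.solve_step(X, w, v, Msc_prev, tractions, dt)

            V = fem.mesh_volume(X, mesh.cells_p2)
            end_flux = 0.0
            for tg in (fem.TAG_INLET, *outlet_tags):
                q = solver.flux(X, v, tg)
                end_flux += q
                Q_rec[names[tg]].append(q)
                a = solver.area(X, tg)
                v_rec[names[tg]].append(q / a * 1e6)
                if tg in Q_prev:
                    Q_prev[tg] = q
            end_fluxes = [Q_rec[names[tg]][-1] for tg in (fem.TAG_INLET, *outlet_tags)]
            peak_flux = max(peak_flux, *(abs(q) for q in end_fluxes))
            # fluid leaving through the ends balances the domain volume change
            if peak_flux > 0:
                mass_res = max(mass_res,
                               abs(end_flux + (V - V_prev) / dt) / peak_flux)
            p_peak = max(p_peak, float(np.abs(p).max()))
            if abs(v_rec["in"][-1]) > peak_vavg:
                peak_vavg = abs(v_rec["in"][-1])
                peak_snapshot = (X.copy(), p.copy(), t)
            ts.append(t)
            d_prev = d
            V_prev = V

        if convergence_rtol is not None:
            from .metrics import particle_position
            x = particle_position(-np.asarray(v_rec["in"]), np.asarray(ts))
            x_cycle_peaks.append(np.abs(x).max())
            if (len(x_cycle_peaks) >= 2 and x_cycle_peaks[-2] > 0 and
                    abs(x_cycle_peaks[-1] - x_cycle_peaks[-2])
                    < convergence_rtol * x_cycle_peaks[-2]):
                break

    rec = FlowRecord(
        t=np.array(ts), f=f,
        Q={kk: np.array(vv) for kk, vv in Q_rec.items()},
        v_avg={kk: np.array(vv) for kk, vv in v_rec.items()},
        pressure_peak=p_peak,
        mass_residual=mass_res,
        extra={"model": "stokes_ale", "n_cells": mesh.n_cells,
               "dt": dt, "n_steps": k},
    )
    rec.extra["peak_snapshot"] = peak_snapshot
    return rec
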