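"""Quasi-static lubrication model of an idealized annular PVS.

The axisymmetric annulus (inner radius R1 = arterial wall, outer radius R2
rigid) under a travelling wall wave is reduced to a 1D problem for the
cross-section-averaged pressure p(z, t) and axial flow rate Q(z, t):

    a_t + Q_z = 0,        Q = -(pi K(R1, R2) / 8 mu) p_z,

where a = pi (R2^2 - R1^2) is the cross-section area and K the annular
Poiseuille conductance

    K(R1, R2) = R2^4 - R1^4 - (R2^2 - R1^2)^2 / ln(R2/R1).

The quasi-static (zero Womersley) closure is justified by the small
Womersley number of the application (alpha < 0.2 at cardiac frequencies and
a 40 um gap); an explicit unsteady inertia correction is available behind a
flag for checking that assumption. The wall radius follows the same
travelling-wave amplitude rule as the 3D model: R1(z, t) = R1_0 +
0.5 delta(t - z/c) R_PVS, so a positive diameter pulsation narrows the gap.

Discretization: vertex-centred finite volumes on the 1D axial mesh of
:class:`~pvsflow.geometry.IdealizedPVS` with implicit time stepping — face
fluxes from the instantaneous (or optionally frozen-at-rest) conductance,
cell sources from the backward-difference area rate. Discrete mass is
conserved to round-off by construction. End conditions: prescribed
pressures (from the static/pulsatile/Windkessel traction model) or a
symmetry (zero-flux) condition at the far end.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ParameterError, PhysicalRegimeError
from .forcing import (PressureBCSpec, WallWaveSpec, WindkesselSpec,
                      eval_waveform, windkessel_step)
from .geometry import IdealizedPVS, make_idealized_annulus
from .metrics import FlowRecord
from .units import MIN_S, MMHG_PA, UL_M3

__all__ = ["annular_conductance", "solve_reduced", "length_for_amplitude"]


def _conductance_m4(R1_m, R2_m):
    r = R2_m / R1_m
    return R2_m ** 4 - R1_m ** 4 - (R2_m ** 2 - R1_m ** 2) ** 2 / np.log(r)


def annular_conductance(R1: float, R2: float) -> float:
    """Annular Poiseuille conductance K (m^4) for radii in um.

    Q = pi dp K / (8 mu L); K -> R2^4 as R1 -> 0 (Hagen-Poiseuille limit)
    and decreases monotonically with R1 at fixed R2.
    """
    if not (R2 > R1 > 0):
        raise ParameterError("need R2 > R1 > 0")
    return float(_conductance_m4(R1 * 1e-6, R2 * 1e-6))


def solve_reduced(pvs: IdealizedPVS, wall: WallWaveSpec | None,
                  bc: PressureBCSpec, params, n_cycles: int = 4,
                  frozen_conductance: bool = False,
                  end_condition: str = "pressure",
                  windkessel: WindkesselSpec | None = None,
                  inertia_correction: bool = False,
                  record_profiles: bool = False) -> FlowRecord:
    """March the lubrication model through ``n_cycles`` forcing cycles.

    ``wall`` may be None (frozen wall, pressure-driven flow only). ``bc``
    carries the end-pressure model; in "windkessel" mode a
    :class:`WindkesselSpec` state is attached to the far end. Frequency is
    taken from the wall waveform if present, else from ``bc.f``.
    """
    if end_condition not in ("pressure", "symmetry"):
        raise ParameterError("end_condition must be 'pressure' or 'symmetry'")
    f = wall.waveform.f if wall is not None else bc.f
    dt = params.dt
    n_steps_cycle = max(1, int(round(1.0 / (f * dt))))
    n_steps = n_steps_cycle * n_cycles

    z = pvs.z * 1e-3  # m
    L = pvs.L * 1e-3
    R1_0 = pvs.R_in * 1e-6
    R2 = pvs.R_out * 1e-6
    n = z.size
    dz = np.diff(z)
    h = np.empty(n)  # control volume widths
    h[0] = dz[0] / 2
    h[-1] = dz[-1] / 2
    h[1:-1] = 0.5 * (dz[:-1] + dz[1:])
    zf = 0.5 * (z[:-1] + z[1:])  # face midpoints

    def wall_radius(zz, t):
        if wall is None:
            return np.full_like(zz, R1_0)
        lag = zz / wall.c  # m / (m/s)
        delta = eval_waveform(wall.waveform, t - lag)
        return R1_0 + 0.5 * delta * (wall.R_PVS * 1e-3)

    mu = params.mu
    wk = windkessel
    if bc.mode == "windkessel" and wk is None:
        wk = WindkesselSpec()

    a_prev = np.pi * (R2 ** 2 - wall_radius(z, 0.0) ** 2)
    V_prev = float(np.sum(a_prev * h))
    Q_out_prev = 0.0

    ts = [0.0]
    Q_in_rec, Q_out_rec = [0.0], [0.0]
    v_in_rec, v_out_rec = [0.0], [0.0]
    p_peak = 0.0
    mass_res = 0.0
    peak_flux = 0.0
    profiles = []
    Qf_prev = np.zeros(n - 1)
    Qf_prev2 = np.zeros(n - 1)

    for k in range(1, n_steps + 1):
        t = k * dt
        R1 = wall_radius(z, t)
        if np.any(R1 >= R2):
            raise PhysicalRegimeError("arterial wall reached the outer PVS "
                                      "boundary (gap closure)")
        a = np.pi * (R2 ** 2 - R1 ** 2)
        adot = (a - a_prev) / dt

        R1_face = wall_radius(zf, t) if not frozen_conductance else np.full(n - 1, R1_0)
        if frozen_conductance:
            a_face = np.pi * (R2 ** 2 - R1_0 ** 2) * np.ones(n - 1)
        else:
            a_face = np.pi * (R2 ** 2 - R1_face ** 2)
        k_face = np.pi * _conductance_m4(R1_face, R2) / (8.0 * mu)  # m^4/(Pa s)*m^2...
        c_face = k_face / dz  # flux per unit pressure difference

        # assemble tridiagonal system for p
        main = np.zeros(n)
        lower = np.zeros(n - 1)
        upper = np.zeros(n - 1)
        rhs = -adot * h
        main[:-1] += c_face
        main[1:] += c_face
        lower[:] = -c_face
        upper[:] = -c_face

        if bc.mode == "windkessel":
            p_in_val = 0.0
            wk.p = windkessel_step(wk, Q_out_prev / UL_M3 * MIN_S, dt)
            p_out_val = wk.p * MMHG_PA
        else:
            p_in_val, outs = bc.traction_values(t)
            p_out_val = outs[0]

        # Dirichlet at inlet
        main[0] = 1.0
        upper[0] = 0.0
        rhs[0] = p_in_val
        rhs[1] -= lower[0] * p_in_val
        lower[0] = 0.0
        if end_condition == "pressure":
            main[-1] = 1.0
            lower[-1] = 0.0
            rhs[-1] = p_out_val
            rhs[-2] -= upper[-1] * p_out_val
            upper[-1] = 0.0
        # symmetry: natural zero-flux at the far end, nothing to modify

        if inertia_correction:
            rhs_extra = np.zeros(n)
            corr = c_face * dz * (1.0 / a_face) * (Qf_prev - Qf_prev2) / dt * params.rho
            # Q_face = -c(p_j+1 - p_j) - corr  ->  moves to rhs of the balance
            rhs_extra[:-1] += corr
            rhs_extra[1:] -= corr
            rhs_extra[0] = 0.0
            if end_condition == "pressure":
                rhs_extra[-1] = 0.0
            rhs = rhs + rhs_extra

        A = sp.diags([lower, main, upper], [-1, 0, 1], format="csc")
        p = spla.spsolve(A, rhs)

        Qf = -c_face * (p[1:] - p[:-1])
        if inertia_correction:
            Qf = Qf - c_face * dz * (params.rho / a_face) * (Qf_prev - Qf_prev2) / dt
        # boundary fluxes from the half-cell balances (exact discrete mass)
        Q0 = Qf[0] + h[0] * adot[0]
        QN = Qf[-1] - h[-1] * adot[-1] if end_condition == "pressure" else 0.0

        V = float(np.sum(a * h))
        out_total = -Q0 + QN
        peak_flux = max(peak_flux, abs(Q0), abs(QN))
        if peak_flux > 0:
            mass_res = max(mass_res, abs(out_total + (V - V_prev) / dt) / peak_flux)

        ts.append(t)
        Q_in_rec.append(-Q0)        # outflow positive at z=0
        Q_out_rec.append(QN)        # outflow positive at z=L
        # frozen mode linearizes fully, including the v_avg normalization
        a_in = np.pi * (R2 ** 2 - R1_0 ** 2) if frozen_conductance else a[0]
        a_out = np.pi * (R2 ** 2 - R1_0 ** 2) if frozen_conductance else a[-1]
        v_in_rec.append(-Q0 / a_in * 1e6)
        v_out_rec.append(QN / a_out * 1e6)
        p_peak = max(p_peak, float(np.abs(p).max()))
        if record_profiles:
            profiles.append((t, p.copy(), np.concatenate([[Q0], Qf, [QN]])))

        a_prev = a
        V_prev = V
        Q_out_prev = QN
        Qf_prev2 = Qf_prev
        Qf_prev = Qf

    rec = FlowRecord(
        t=np.array(ts), f=f,
        Q={"in": np.array(Q_in_rec), "out1": np.array(Q_out_rec)},
        v_avg={"in": np.array(v_in_rec), "out1": np.array(v_out_rec)},
        pressure_peak=p_peak,
        mass_residual=mass_res,
        extra={"L_mm": pvs.L, "model": "reduced_axisym"},
    )
    if record_profiles:
        rec.extra["profiles"] = profiles
        rec.extra["z_m"] = z
    return rec


def length_for_amplitude(target_p2p: float, wall: WallWaveSpec,
                         bc: PressureBCSpec, params, bracket=(0.02, 2.0),
                         R_in: float = 20.0, R_out: float = 60.0,
                         tol_mm: float = 0.005, n_cycles: int = 3) -> float:
    """PVS length (mm) whose inlet peak-to-peak velocity equals the target.

    Bisection over ``bracket`` (mm) on the monotone length -> amplitude map
    of :func:`solve_reduced`; target in um/s.
    """
    if target_p2p < 0:
        raise ParameterError("target amplitude must be >= 0")
    if target_p2p == 0.0:
        return float(bracket[0])

    def amp(L):
        pvs = make_idealized_annulus(L, R_in, R_out, mesh_size=min(0.1, L / 10))
        rec = solve_reduced(pvs, wall, bc, params, n_cycles=n_cycles)
        return rec.p2p_amplitude("in")

    lo, hi = float(bracket[0]), float(bracket[1])
    f_lo, f_hi = amp(lo) - target_p2p, amp(hi) - target_p2p
    if f_lo * f_hi > 0:
        raise ParameterError(
            f"bracket {bracket} mm does not straddle the target amplitude "
            f"({f_lo + target_p2p:.3g} .. {f_hi + target_p2p:.3g} um/s)")
    while hi - lo > tol_mm:
        mid = 0.5 * (lo + hi)
        if (amp(mid) - target_p2p) * f_lo <= 0:
            hi = mid
        else:
            lo = mid
            f_lo = amp(mid) - target_p2p
    return 0.5 * (lo + hi)
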