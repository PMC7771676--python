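"""Derived flow quantities.

All model outputs funnel through :class:`FlowRecord`: per-boundary flow
rates Q_b(t) (m^3/s, outflow positive), average normal velocities
v_avg = Q/A (um/s), the particle position x(t) = int_0^t v(tau) dtau
tracked with the downstream-positive velocity at the inlet, and scalars
derived from them (net-flow velocity from the slope between the particle
position peaks of the two last cycles, peak-to-peak amplitude over the last
cycle, peak pressure).

Sign conventions: each boundary's outward normal defines positive v_avg
(outflow). The tracked particle uses the *into-the-domain* velocity at the
inlet so that steady downstream transport gives a positive net-flow
velocity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .errors import ParameterError
from .units import MMHG_PA, convert_units

__all__ = [
    "FlowRecord",
    "particle_position",
    "net_flow_velocity",
    "nondimensional_numbers",
    "pressure_gradient_stats",
    "convert_units",
]


def particle_position(v_avg, t) -> np.ndarray:
    """Cumulative trapezoidal integral of a velocity trace.

    v_avg in um/s on the (monotone) time grid t in s; returns x(t) in um
    with x(0) = 0.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v_avg, dtype=float)
    if t.ndim != 1 or t.size != v.size:
        raise ParameterError("t and v_avg must be 1D arrays of equal length")
    if np.any(np.diff(t) <= 0):
        raise ParameterError("time grid must be strictly increasing")
    return cumulative_trapezoid(v, t, initial=0.0)


def net_flow_velocity(x, t, f: float) -> float:
    """Net-flow velocity (um/s) as the slope between per-cycle position peaks.

    Locates the maximum of x(t) within each of the two last complete cycles
    (windows of length 1/f aligned to the end of the record) and returns
    (x_peak2 - x_peak1) * f. A flat trace returns 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    T = 1.0 / f
    if t[-1] - t[0] < 3 * T - 1e-9:
        raise ParameterError("record must span at least 3 cycles")
    peaks = []
    for k in (2, 1):
        lo, hi = t[-1] - k * T, t[-1] - (k - 1) * T
        m = (t >= lo - 1e-12) & (t <= hi + 1e-12)
        xm = x[m]
        if xm.max() - xm.min() < 1e-300:
            warnings.warn("flat particle trace; net flow set to 0")
            return 0.0
        peaks.append(xm[np.argmax(xm)])  # earliest index on ties (argmax)
    return float((peaks[1] - peaks[0]) * f)


def nondimensional_numbers(record, gap_um: float, f: float,
                           rho: float = 1e3, mu: float = 0.697e-3):
    """(Reynolds, Womersley) numbers of a record (or a peak |v_avg| in um/s).

    The characteristic length is the gap *half*-width h = gap/2 (the only
    choice consistent with the reported regime bounds at the reported
    velocities): Re = rho U h / mu with U the peak |v_avg|, and
    alpha = h sqrt(2 pi f rho / mu).
    """
    peak = record.peak_v_avg() if hasattr(record, "peak_v_avg") else record
    h = 0.5 * gap_um * 1e-6
    U = abs(peak) * 1e-6
    Re = rho * U * h / mu
    alpha = h * np.sqrt(2 * np.pi * f * rho / mu)
    return float(Re), float(alpha)


def pressure_gradient_stats(p_nodal, coords_p2, cells, cells_p2) -> tuple[float, float]:
    """(volume-weighted mean, max) |grad p| in mmHg/m from a P1 pressure field.

    ``p_nodal`` is defined on the mesh vertices; coordinates in metres,
    pressure in Pa.
    """
    from . import fem

    if p_nodal is None:
        raise ParameterError("missing pressure snapshot")
    detJ, _, G4 = fem.element_geometry(coords_p2, cells_p2)
    pe = p_nodal[cells]  # (T, 4)
    grad = np.einsum("tqia,ti->tqa", G4, pe)  # (T, nq, 3) Pa/m
    mag = np.linalg.norm(grad, axis=2)
    w = fem._WTET[None, :] * detJ
    mean = float((w * mag).sum() / w.sum())
    return mean / MMHG_PA, float(mag.max()) / MMHG_PA


@dataclass
class FlowRecord:
    """Time series of boundary quantities from one simulation.

    ``Q`` and ``v_avg`` map a boundary name ("in", "out1", "out2") to the
    outflow-positive flow rate (m^3/s) and average normal velocity (um/s).
    ``x`` is the tracked particle position at the inlet (um, downstream
    positive). ``pressure_peak`` is max |p| over the run (Pa).
    """

    t: np.ndarray
    f: float
    Q: dict = field(default_factory=dict)
    v_avg: dict = field(default_factory=dict)
    x: np.ndarray | None = None
    pressure_peak: float = 0.0
    mass_residual: float = 0.0  # max |sum Q_b + dV/dt| / peak flux
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if self.x is None and "in" in self.v_avg:
            self.x = particle_position(-np.asarray(self.v_avg["in"]), self.t)

    # -- scalars ----------------------------------------------------------

    def p2p_amplitude(self, boundary: str = "in") -> float:
        """Peak-to-peak v_avg amplitude (um/s) over the last full cycle."""
        T = 1.0 / self.f
        m = self.t >= self.t[-1] - T - 1e-12
        v = np.asarray(self.v_avg[boundary])[m]
        return float(v.max() - v.min())

    def peak_v_avg(self, boundary: str = "in") -> float:
        v = np.asarray(self.v_avg[boundary])
        return float(np.abs(v).max())

    def net_flow_velocity(self) -> float:
        return net_flow_velocity(self.x, self.t, self.f)

    # -- export -----------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        data = {"t": self.t}
        for k, v in self.Q.items():
            data[f"Q_{k}"] = v
        for k, v in self.v_avg.items():
            data[f"v_avg_{k}"] = v
        if self.x is not None:
            data["x"] = self.x
        for k, v in self.extra.items():
            if np.ndim(v) == 1 and len(v) == len(self.t):
                data[k] = v
        return pd.DataFrame(data)

    def summary(self) -> dict:
        out = {
            "p2p_amplitude_um_s": self.p2p_amplitude(),
            "peak_v_avg_um_s": self.peak_v_avg(),
            "peak_pressure_Pa": self.pressure_peak,
            "mass_residual": self.mass_residual,
        }
        try:
            out["net_flow_velocity_um_s"] = self.net_flow_velocity()
        except ParameterError:
            pass
        return out

    def summary_json(self) -> str:
        return json.dumps({k: float(v) for k, v in self.summary().items()},
                          sort_keys=True, indent=2)
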