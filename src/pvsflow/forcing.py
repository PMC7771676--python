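"""Driving mechanisms for perivascular CSF flow.

Four forcings act on the PVS model, alone or combined:

* a travelling wall wave — the arterial diameter pulsation ``delta(s)``
  (relative diameter change over one cardiac cycle) propagating along the
  vessel at wave speed ``c``, displacing the inner PVS wall along its normal
  with amplitude ``A(X, t) = -0.5 * delta(t - |X - X0|/c) * R_PVS``;
* a rigid pulsatile motion of the artery, a signed translation along a fixed
  direction ``r`` pivoting about a point ``Xc`` near the bifurcation,
  ``B(X, t) = gamma * (|Xc-X0| - |X-X0|)/|Xc-X0| * delta(t)/(dmax - dmin)``;
* static or sinusoidal pressure differences between inlet and outlets,
  applied as traction boundary values and weighted by branch length so the
  average gradient along every inlet->outlet path is identical;
* a lumped Windkessel (compliance C, resistance R) outlet model
  ``C dp/dt = Q - p/R`` representing the downstream CSF compartment.

Conventions: points and lengths in mm, wave speed in m/s, tractions in Pa,
time in s. ``delta`` is a fraction (0.01 x percentage diameter change).
At the inner wall the outward normal of the *fluid* domain points toward the
artery axis, so the negative sign in ``A`` makes ``delta > 0`` move the wall
into the PVS (arterial expansion narrows the gap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .units import MMHG_PA, MIN_S

__all__ = [
    "Waveform",
    "WallWaveSpec",
    "RigidMotionSpec",
    "PressureBCSpec",
    "WindkesselSpec",
    "eval_waveform",
    "wall_amplitude",
    "rigid_amplitude",
    "boundary_displacement",
    "static_traction_values",
    "pulsatile_traction",
    "windkessel_step",
    "default_rigid_direction",
]


@dataclass
class Waveform:
    """Periodic relative-diameter-change curve over one cardiac cycle.

    ``samples`` is an (N, 2) array of (cycle fraction s in [0, 1),
    dimensionless delta). Evaluation wraps periodically with linear
    interpolation between samples.
    """

    samples: np.ndarray
    f: float  # Hz

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2 or s.shape[1] != 2 or s.shape[0] < 2:
            raise ParameterError("waveform needs >= 2 (s, delta) samples")
        if np.any(s[:, 0] < 0.0) or np.any(s[:, 0] >= 1.0):
            raise ParameterError("cycle fractions must lie in [0, 1)")
        order = np.argsort(s[:, 0], kind="stable")
        s = s[order]
        if np.any(np.diff(s[:, 0]) <= 0.0):
            raise ParameterError("duplicate cycle-fraction samples")
        if self.f <= 0.0:
            raise ParameterError("frequency must be positive")
        self.samples = s

    @property
    def delta_min(self) -> float:
        return float(self.samples[:, 1].min())

    @property
    def delta_max(self) -> float:
        return float(self.samples[:, 1].max())

    def __call__(self, t):
        return eval_waveform(self, t)


def eval_waveform(w: Waveform, t):
    """Evaluate delta at time ``t`` (scalar or array), wrapping s = (t f) mod 1.

    Negative times wrap mathematically into [0, 1).
    """
    s = np.mod(np.asarray(t, dtype=float) * w.f, 1.0)
    xs = np.concatenate([w.samples[:, 0], [w.samples[0, 0] + 1.0]])
    ys = np.concatenate([w.samples[:, 1], [w.samples[0, 1]]])
    # shift so the table covers [s0, s0+1] and wrap the query into it
    s = np.where(s < xs[0], s + 1.0, s)
    out = np.interp(s, xs, ys)
    return out if out.ndim else float(out)


@dataclass
class WallWaveSpec:
    """Travelling-wave wall forcing.

    ``R_PVS`` is the average PVS width (mm; default 4.4e-2 mm) entering the
    displacement amplitude; ``X0`` is the reference point near the inlet
    center from which the retardation |X - X0|/c is measured.
    """

    waveform: Waveform
    c: float = 1.0  # wave speed, m/s
    R_PVS: float = 4.4e-2  # mm
    X0: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.c <= 0.0:
            raise ParameterError("wave speed must be positive")
        if self.R_PVS <= 0.0:
            raise ParameterError("R_PVS must be positive")
        self.X0 = np.asarray(self.X0, dtype=float)

    @property
    def wavelength_mm(self) -> float:
        """lambda = c / f, in mm."""
        return self.c / self.waveform.f * 1e3


def wall_amplitude(spec: WallWaveSpec, X, t):
    """Signed normal displacement amplitude A(X, t) in mm.

    ``X`` may be a single point (3,) or an array (n, 3) of points in mm;
    the retardation along the wave is |X - X0| [mm] / c [m/s].
    """
    X = np.asarray(X, dtype=float)
    dist_mm = np.linalg.norm(X - spec.X0, axis=-1)
    lag = dist_mm * 1e-3 / spec.c  # s
    delta = eval_waveform(spec.waveform, np.asarray(t) - lag)
    return -0.5 * delta * spec.R_PVS


@dataclass
class RigidMotionSpec:
    """Rigid pulsatile translation of the artery.

    ``gamma`` is the peak amplitude in um; ``r`` the unit direction, which
    must be orthogonal to the main axis Xc - X0.
    """

    gamma: float  # um
    Xc: np.ndarray  # mm
    X0: np.ndarray  # mm
    r: np.ndarray
    waveform: Waveform

    def __post_init__(self) -> None:
        self.Xc = np.asarray(self.Xc, dtype=float)
        self.X0 = np.asarray(self.X0, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if abs(np.linalg.norm(self.r) - 1.0) > 1e-9:
            raise ParameterError("rigid-motion direction r must be a unit vector")
        axis = self.Xc - self.X0
        naxis = np.linalg.norm(axis)
        if naxis == 0.0:
            raise ParameterError("Xc must differ from X0")
        if abs(float(self.r @ axis)) / naxis > 1e-9:
            raise ParameterError("r must be orthogonal to Xc - X0")
        if self.waveform.delta_max <= self.waveform.delta_min:
            raise ParameterError("waveform must have delta_max > delta_min")


def default_rigid_direction(X0, Xc) -> np.ndarray:
    """A canonical unit direction normal to the axis Xc - X0.

    The axis only pins the direction down to a one-parameter family; we take
    the global coordinate axis least aligned with it, projected orthogonal to
    it, and normalized.
    """
    a = np.asarray(Xc, dtype=float) - np.asarray(X0, dtype=float)
    a = a / np.linalg.norm(a)
    e = np.zeros(3)
    e[int(np.argmin(np.abs(a)))] = 1.0
    r = e - (e @ a) * a
    return r / np.linalg.norm(r)


def rigid_amplitude(spec: RigidMotionSpec, X, t):
    """Signed rigid-motion amplitude B(X, t) in mm.

    Vanishes at the pivot Xc and changes sign for points beyond it.
    """
    X = np.asarray(X, dtype=float)
    l_c = np.linalg.norm(spec.Xc - spec.X0)
    l_x = np.linalg.norm(X - spec.X0, axis=-1)
    w = spec.waveform
    delta = eval_waveform(w, t)
    gamma_mm = spec.gamma * 1e-3
    return gamma_mm * (l_c - l_x) / l_c * delta / (w.delta_max - w.delta_min)


def boundary_displacement(wall: WallWaveSpec, rigid: RigidMotionSpec | None, X, n, t):
    """Inner-wall displacement vector d|_Lambda = A n (+ B r), in mm.

    ``n`` is the unit outward normal of the fluid domain at ``X`` (pointing
    into the artery). Shapes: X, n either (3,) or (npts, 3).
    """
    X = np.asarray(X, dtype=float)
    n = np.asarray(n, dtype=float)
    if not np.allclose(np.linalg.norm(n, axis=-1), 1.0, atol=1e-8):
        raise ParameterError("normals must be unit vectors")
    A = np.asarray(wall_amplitude(wall, X, t))
    d = A[..., None] * n
    if rigid is not None:
        B = np.asarray(rigid_amplitude(rigid, X, t))
        d = d + B[..., None] * rigid.r
    return d


@dataclass
class PressureBCSpec:
    """Inlet/outlet pressure (traction) boundary condition.

    ``mode``: "zero", "static", "pulsatile" or "windkessel".
    ``g`` static gradient magnitude (mmHg/m), ``a`` pulsatile peak amplitude
    (mmHg/m), ``theta`` phase shift as a cycle fraction, ``f`` frequency (Hz).
    The inlet traction is gauged to zero; outlet values are derived from the
    branch lengths so every inlet->outlet path sees the same average gradient.
    """

    mode: str = "zero"
    g: float = 0.0
    a: float = 0.0
    theta: float = 0.0
    f: float = 1.0
    branch_lengths: tuple = (1.0,)  # mm

    def __post_init__(self) -> None:
        if self.mode not in ("zero", "static", "pulsatile", "windkessel"):
            raise ParameterError(f"unknown pressure mode {self.mode!r}")
        if len(self.branch_lengths) == 0:
            raise ParameterError("at least one branch length required")
        if any(L <= 0 for L in self.branch_lengths):
            raise ParameterError("branch lengths must be positive")
        if not (0.0 <= self.theta < 1.0):
            raise ParameterError("theta is a cycle fraction in [0, 1)")

    def traction_values(self, t: float, outlet_rates=None, wk_states=None, dt=None):
        """(inlet Pa, tuple of outlet Pa) at time t.

        For windkessel mode, ``wk_states`` (one :class:`WindkesselSpec` per
        outlet) are advanced with the previous step's outflow rates
        ``outlet_rates`` (uL/min) over ``dt``.
        """
        if self.mode == "zero":
            return 0.0, tuple(0.0 for _ in self.branch_lengths)
        if self.mode == "static":
            return static_traction_values(self.g, self.branch_lengths)
        if self.mode == "pulsatile":
            return pulsatile_traction(self.a, self.f, self.theta, t, self.branch_lengths)
        # windkessel
        outs = []
        for spec, Q in zip(wk_states, outlet_rates):
            spec.p = windkessel_step(spec, Q, dt)
            outs.append(spec.p * MMHG_PA)
        return 0.0, tuple(outs)


def static_traction_values(g: float, branch_lengths) -> tuple[float, tuple[float, ...]]:
    """Traction values (Pa) realizing a uniform average gradient g (mmHg/m).

    Gauge: inlet 0; outlet_i = -g * L_i, so (c1 - c2_i)/L_i == g exactly for
    every branch.
    """
    if g < 0.0:
        raise ParameterError("gradient magnitude must be >= 0")
    if len(branch_lengths) == 0:
        raise ParameterError("at least one branch length required")
    g_pa_per_m = g * MMHG_PA
    outs = tuple(-g_pa_per_m * (L * 1e-3) for L in branch_lengths)
    return 0.0, outs


def pulsatile_traction(a: float, f: float, theta: float, t: float, branch_lengths):
    """Instantaneous tractions for the gradient a sin(2 pi (f t + theta))."""
    g_t = a * np.sin(2.0 * np.pi * (f * t + theta))
    g_pa_per_m = g_t * MMHG_PA
    outs = tuple(-g_pa_per_m * (L * 1e-3) for L in branch_lengths)
    return 0.0, outs


@dataclass
class WindkesselSpec:
    """Lumped outlet impedance: compliance C (uL/mmHg), resistance R
    (mmHg/(uL/min)), and the current boundary pressure state p (mmHg)."""

    C: float = 1.798
    R: float = 1.097
    p: float = 0.0

    def __post_init__(self) -> None:
        if self.C <= 0.0 or self.R <= 0.0:
            raise ParameterError("C and R must be positive")


def windkessel_step(spec: WindkesselSpec, Q: float, dt: float) -> float:
    """One implicit-Euler update of C dp/dt = Q - p/R.

    ``Q`` is the outflow rate in uL/min, ``dt`` in seconds; returns the new
    pressure in mmHg. Implicit Euler is unconditionally stable, so for Q = 0
    the pressure decays monotonically for any dt > 0.
    """
    if dt <= 0.0:
        raise ParameterError("dt must be positive")
    q_per_s = Q / MIN_S  # uL/s
    r_per_s = spec.R * MIN_S  # mmHg/(uL/s)
    return (spec.C * spec.p + dt * q_per_s) / (spec.C + dt / r_per_s)
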