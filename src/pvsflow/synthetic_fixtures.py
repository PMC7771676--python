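"""Synthetic stand-ins for external measurement inputs.

The measured arterial waveform (digitized from in vivo two-photon imaging)
and the image-based artery surface are external inputs that cannot be
shipped; this module generates parametric surrogates that reproduce their
stated summary characteristics:

* ``surrogate_sine`` — a single-harmonic diameter pulsation with
  configurable half-amplitude (default 0.7 %, the value used in the
  peristaltic-pumping comparison);
* ``surrogate_cardiac`` — an asymmetric cardiac-like pulse: fast systolic
  upstroke over the first 20 % of the cycle, slow smooth decay, diastolic
  baseline at zero (delta_min = 0, delta_max = twice the half-amplitude);
* ``csv`` — a user-supplied digitized waveform (two columns
  ``cycle_fraction, delta_fraction`` with a header row).

It also provides the configuration matrix of the seven canonical models
(A "Pulsatile", B "Static", C "Systemic", D "Rigid", E "Reduced HR",
F "Resistance", G "Idealized") as self-validating, serializable
:class:`ModelConfig` objects.
"""

from __future__ import annotations

import io
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .errors import FormatError, ParameterError
from .forcing import Waveform

__all__ = ["ModelConfig", "make_waveform", "make_model_config",
           "MODEL_IDS", "MODEL_MATRIX", "config_to_yaml", "config_from_yaml"]

MODEL_IDS = ("A", "B", "C", "D", "E", "F", "G")

# model matrix: short name, frequency (Hz), forcing flags
MODEL_MATRIX = {
    "A": {"short_name": "Pulsatile", "f": 8.67, "wall": True, "rigid": False,
          "pressure_mode": "zero"},
    "B": {"short_name": "Static", "f": 8.67, "wall": True, "rigid": False,
          "pressure_mode": "static"},
    "C": {"short_name": "Systemic", "f": 8.67, "wall": True, "rigid": False,
          "pressure_mode": "pulsatile"},
    "D": {"short_name": "Rigid", "f": 8.67, "wall": True, "rigid": True,
          "pressure_mode": "zero"},
    "E": {"short_name": "Reduced HR", "f": 2.2, "wall": True, "rigid": True,
          "pressure_mode": "static"},
    "F": {"short_name": "Resistance", "f": 2.2, "wall": True, "rigid": False,
          "pressure_mode": "windkessel"},
    "G": {"short_name": "Idealized", "f": 10.0, "wall": True, "rigid": False,
          "pressure_mode": "zero"},
}

# static gradient presets (mmHg/m): third circulation, respiration, cardiac,
# infusion upper bound
STATIC_GRADIENTS = {"third_circulation": 0.01, "respiratory": 0.52,
                    "cardiac": 1.46, "infusion": 12.0}


def make_waveform(kind: str, half_amplitude: float = 0.007, f: float = 10.0,
                  path=None, n_samples: int = 100) -> Waveform:
    """Build a diameter-pulsation waveform.

    ``half_amplitude`` is the relative diameter change fraction h in
    (0, 0.1); the sine surrogate spans [-h, h], the cardiac surrogate
    [0, 2h]. ``csv`` loads and validates ``path``.
    """
    if kind == "csv":
        return _load_waveform_csv(path, f)
    if not (0.0 < half_amplitude < 0.1):
        raise ParameterError("half_amplitude must lie in (0, 0.1)")
    s = np.arange(n_samples) / n_samples
    if kind == "surrogate_sine":
        delta = half_amplitude * np.sin(2 * np.pi * s)
    elif kind == "surrogate_cardiac":
        s_sys = 0.2  # systolic upstroke fraction of the cycle
        delta = np.where(
            s < s_sys,
            half_amplitude * (1.0 - np.cos(np.pi * s / s_sys)),
            half_amplitude * (1.0 + np.cos(np.pi * (s - s_sys) / (1.0 - s_sys))),
        )
    else:
        raise ParameterError(f"unknown waveform kind {kind!r}")
    return Waveform(np.column_stack([s, delta]), f=f)


def _load_waveform_csv(path, f: float) -> Waveform:
    if path is None:
        raise ParameterError("csv waveform needs a path")
    try:
        with open(path) as fh:
            header = fh.readline()
            body = fh.read()
    except OSError as exc:
        raise FormatError(f"cannot read waveform CSV {path}: {exc}") from exc
    if any(ch.isdigit() for ch in header.split(",")[0].strip()):
        raise FormatError("waveform CSV must start with a header row "
                          "(cycle_fraction,delta_fraction)")
    try:
        data = np.loadtxt(io.StringIO(body), delimiter=",", ndmin=2)
    except Exception as exc:
        raise FormatError(f"malformed waveform CSV: {exc}") from exc
    if data.shape[1] != 2:
        raise FormatError("waveform CSV needs exactly two columns")
    bad = np.nonzero((data[:, 0] < 0) | (data[:, 0] >= 1)
                     | (np.abs(data[:, 1]) >= 1))[0]
    if bad.size:
        rows = ", ".join(str(i + 2) for i in bad[:10])  # 1-based + header
        raise FormatError(
            f"waveform CSV rows out of range (s in [0,1), |delta| < 1): "
            f"lines {rows}")
    return Waveform(data, f=f)


@dataclass
class ModelConfig:
    """Fully populated configuration for one model run.

    Geometry kinds: "bifurcation" (3D synthetic Y), "annulus3d" (straight
    3D annulus) or "idealized" (1D reduced model). ``seed`` is reserved for
    randomized mesh perturbations (none by default — the pipeline is
    deterministic).
    """

    model_id: str
    short_name: str
    f: float
    wall: bool
    rigid: bool
    pressure_mode: str
    g: float = 0.0                      # static gradient, mmHg/m
    a: float = 0.0                      # pulsatile amplitude, mmHg/m
    theta: float = 0.0                  # phase shift, cycle fraction
    wk_C: float = 1.798                 # compliance, uL/mmHg
    wk_R: float = 1.097                 # resistance, mmHg/(uL/min)
    gamma: float = 6.0                  # rigid-motion peak amplitude, um
    c: float = 1.0                      # wall wave speed, m/s
    R_PVS: float = 4.4e-2               # average PVS width, mm
    waveform_kind: str = "surrogate_cardiac"
    half_amplitude: float = 0.007
    waveform_path: str | None = None
    geometry: dict = field(default_factory=dict)
    rho: float = 1e3
    mu: float = 0.697e-3
    dt: float = 1e-3
    n_cycles: int = 4
    seed: int | None = None

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ParameterError(f"unknown model id {self.model_id!r}")
        row = MODEL_MATRIX[self.model_id]
        for key in ("wall", "rigid", "pressure_mode"):
            if getattr(self, key) != row[key]:
                raise ParameterError(
                    f"model {self.model_id}: field {key}={getattr(self, key)!r} "
                    f"contradicts the model matrix ({row[key]!r})")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def make_model_config(model_id: str, **overrides) -> ModelConfig:
    """Instantiate one row of the model matrix with canonical defaults.

    Defaults: cardiac static gradient 1.46 mmHg/m for the static models,
    pulsatile amplitude 1.46 mmHg/m for the systemic model, Windkessel
    C = 1.798 uL/mmHg and R = 1.097 mmHg/(uL/min) for the resistance model
    (pass ``wk_C=0.001798`` for the low-compliance variant), and the
    synthetic bifurcation geometry for A-F / an idealized L = 1 mm annulus
    for G. Overrides replace any field, e.g. ``make_model_config("G",
    geometry={"kind": "idealized", "L": 100.0})``.
    """
    if model_id not in MODEL_IDS:
        raise ParameterError(f"unknown model id {model_id!r}")
    row = MODEL_MATRIX[model_id]
    cfg = {
        "model_id": model_id,
        "short_name": row["short_name"],
        "f": row["f"],
        "wall": row["wall"],
        "rigid": row["rigid"],
        "pressure_mode": row["pressure_mode"],
    }
    if row["pressure_mode"] == "static":
        cfg["g"] = STATIC_GRADIENTS["cardiac"]
    if row["pressure_mode"] == "pulsatile":
        cfg["a"] = STATIC_GRADIENTS["cardiac"]
    if model_id == "G":
        cfg["geometry"] = {"kind": "idealized", "L": 1.0, "R_in": 20.0,
                           "R_out": 60.0, "mesh_size": 0.1}
    else:
        cfg["geometry"] = {"kind": "bifurcation", "parent_diameter": 40.0,
                           "daughter_diameters": [36.0, 32.0],
                           "branch_lengths": [0.5, 0.45, 0.5],
                           "pvs_width_ratio": 0.9}
    geometry_override = overrides.pop("geometry", None)
    cfg.update(overrides)
    if geometry_override is not None:
        merged = dict(cfg["geometry"])
        merged.update(geometry_override)
        cfg["geometry"] = merged
    return ModelConfig(**cfg)


def config_to_yaml(cfg: ModelConfig) -> str:
    return yaml.safe_dump(cfg.to_dict(), sort_keys=True)


def config_from_yaml(text: str) -> ModelConfig:
    try:
        d = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise FormatError(f"invalid config YAML: {exc}") from exc
    if not isinstance(d, dict):
        raise FormatError("config YAML must contain a mapping")
    try:
        return ModelConfig.from_dict(d)
    except TypeError as exc:
        raise FormatError(f"config fields do not match the schema: {exc}") from exc
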