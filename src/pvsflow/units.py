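"""Unit conversion helpers.

The PVS literature mixes mmHg, Pa, mm, um, uL and minutes; geometry in this
package is expressed in mm, solver internals in SI, and reported velocities
in um/s. All conversion factors are centralized here.

``convert_units`` handles simple units and single-slash compound units
("mmHg/m", "uL/min", "Pa/mm"). Unicode mu is accepted as an alias for "u".
"""

from __future__ import annotations

from .errors import ParameterError

# 1 mmHg in Pa (conventional value used throughout)
MMHG_PA = 133.322
# metres per mm / um
MM_M = 1e-3
UM_M = 1e-6
# 1 uL in m^3
UL_M3 = 1e-9
MIN_S = 60.0

# unit -> (factor to SI, dimension signature)
_UNITS: dict[str, tuple[float, str]] = {
    "m": (1.0, "L"),
    "mm": (MM_M, "L"),
    "um": (UM_M, "L"),
    "cm": (1e-2, "L"),
    "s": (1.0, "T"),
    "ms": (1e-3, "T"),
    "min": (MIN_S, "T"),
    "Pa": (1.0, "P"),
    "mmHg": (MMHG_PA, "P"),
    "kPa": (1e3, "P"),
    "m3": (1.0, "V"),
    "uL": (UL_M3, "V"),
    "mL": (1e-6, "V"),
    "L": (1e-3, "V"),
    "Hz": (1.0, "F"),
}


def _lookup(unit: str) -> tuple[float, str]:
    unit = unit.strip().replace("μ", "u").replace("µ", "u")
    if "/" in unit:
        num, _, den = unit.partition("/")
        fn, dn = _lookup(num)
        fd, dd = _lookup(den)
        return fn / fd, f"{dn}/{dd}"
    if unit not in _UNITS:
        raise ParameterError(f"unknown unit {unit!r}")
    return _UNITS[unit]


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` from ``from_unit`` to ``to_unit``.

    Raises :class:`ParameterError` for unknown units or dimension mismatch.

    >>> round(convert_units(1.46, "mmHg/m", "Pa/mm"), 3)
    0.195
    """
    f_from, d_from = _lookup(from_unit)
    f_to, d_to = _lookup(to_unit)
    if d_from != d_to:
        raise ParameterError(
            f"incompatible units: {from_unit!r} ({d_from}) vs {to_unit!r} ({d_to})"
        )
    return value * f_from / f_to
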