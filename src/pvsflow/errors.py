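"""Exception hierarchy for pvsflow.

All user-facing failures derive from :class:`PVSFlowError` so callers can
catch one base class at CLI level.
"""


class PVSFlowError(Exception):
    """Base class for all pvsflow errors."""


class ParameterError(PVSFlowError, ValueError):
    """Invalid physical or numerical parameter (non-positive length, etc.)."""


class GeometryError(PVSFlowError):
    """Mesh generation or mesh quality failure."""


class FormatError(PVSFlowError):
    """Malformed input file (waveform CSV, surface mesh, centerline)."""


class SolverError(PVSFlowError):
    """Linear solver failure or non-convergence."""


class PhysicalRegimeError(PVSFlowError):
    """The requested state leaves the model's validity region (e.g. the
    arterial wall touching the outer PVS boundary)."""
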