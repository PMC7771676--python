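"""Shared fixtures.

The 3D solver fixtures are session-scoped because a moving-mesh run costs
tens of seconds; several tests interrogate the same run (mass balance,
frequency content, cross-validation against the reduced model).
"""

import numpy as np
import pytest

import pvsflow as pf
from pvsflow.forcing import PressureBCSpec, WallWaveSpec
from pvsflow.stokes_ale import FluidParams, ForcingSpec, run_cycles


@pytest.fixture(scope="session")
def cardiac_wave():
    return pf.make_waveform("surrogate_cardiac", 0.007, 10.0)


@pytest.fixture(scope="session")
def sine_wave():
    return pf.make_waveform("surrogate_sine", 0.007, 10.0)


@pytest.fixture(scope="session")
def params():
    return FluidParams()  # rho 1e3, mu 0.697e-3, dt 1 ms


@pytest.fixture(scope="session")
def idealized_1mm():
    return pf.make_idealized_annulus(1.0, 20.0, 60.0, 0.1)


@pytest.fixture(scope="session")
def annulus3d_coarse():
    """Short straight annulus for time-dependent 3D runs."""
    return pf.make_annulus_mesh_3d(0.4, 20.0, 60.0, n_theta=12, n_r=2, n_z=8)


@pytest.fixture(scope="session")
def wave_run_3d(annulus3d_coarse, cardiac_wave):
    """Two forcing cycles of the travelling wall wave on the 3D annulus."""
    wall = WallWaveSpec(waveform=cardiac_wave, c=1.0, R_PVS=4.4e-2,
                        X0=annulus3d_coarse.X0)
    bc = PressureBCSpec(mode="zero", f=10.0, branch_lengths=(0.4,))
    prm = FluidParams(dt=2.5e-3)
    rec = run_cycles(annulus3d_coarse, ForcingSpec(wall=wall, pressure=bc), prm,
                     n_cycles=2)
    return rec, prm


@pytest.fixture(scope="session")
def reduced_run_matched(cardiac_wave):
    """Reduced model on the annulus matching :func:`wave_run_3d`."""
    pvs = pf.make_idealized_annulus(0.4, 20.0, 60.0, 0.05)
    wall = WallWaveSpec(waveform=cardiac_wave, c=1.0, R_PVS=4.4e-2,
                        X0=np.zeros(3))
    bc = PressureBCSpec(mode="zero", f=10.0, branch_lengths=(0.4,))
    return pf.solve_reduced(pvs, wall, bc, FluidParams(dt=2.5e-3), n_cycles=2)
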