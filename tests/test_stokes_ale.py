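"""Moving-domain Stokes solver: harmonic extension, steady verification,
and time-dependent travelling-wave runs."""

import numpy as np
import pytest

import pvsflow as pf
from pvsflow import fem
from pvsflow.errors import ParameterError
from pvsflow.forcing import PressureBCSpec, WallWaveSpec
from pvsflow.stokes_ale import (FluidParams, ForcingSpec, extend_displacement,
                                mesh_velocity, run_cycles, solve_steady)


class TestExtension:
    def test_zero_boundary_displacement_extends_to_zero(self, annulus3d_coarse):
        inner = annulus3d_coarse.mesh.verts_with_tag(fem.TAG_INNER_WALL)
        d = extend_displacement(annulus3d_coarse, np.zeros((inner.size, 3)))
        assert np.abs(d).max() == 0.0

    def test_rigid_translation_extends_exactly(self, annulus3d_coarse):
        # harmonic extension of linear (constant) data is exact
        m = annulus3d_coarse.mesh
        inner = m.verts_with_tag(fem.TAG_INNER_WALL)
        outer = np.setdiff1d(m.verts_with_tag(fem.TAG_OUTER_WALL), inner)
        u = np.array([1e-4, -2e-4, 3e-4])
        d = extend_displacement(annulus3d_coarse,
                                np.tile(u, (inner.size, 1)),
                                np.tile(u, (outer.size, 1)))
        assert np.abs(d - u).max() < 1e-16

    def test_interior_bounded_by_boundary(self, annulus3d_coarse):
        # discrete maximum principle per component
        m = annulus3d_coarse.mesh
        inner = m.verts_with_tag(fem.TAG_INNER_WALL)
        vals = np.zeros((inner.size, 3))
        vals[:, 0] = 1e-4 * np.sin(m.verts[inner, 2] * 20.0)
        d = extend_displacement(annulus3d_coarse, vals)
        assert np.abs(d).max() <= np.abs(vals).max() * (1 + 1e-9)


class TestMeshVelocity:
    def test_stationary_and_linear_motion(self):
        d = np.random.default_rng(0).normal(size=(10, 3))
        assert np.abs(mesh_velocity(d, d, 1e-3)).max() == 0.0
        u = np.array([1.0, 2.0, -3.0])  # mm per second
        w = mesh_velocity(d + u * 1e-3, d, 1e-3)
        assert np.allclose(w, u * 1e-3)  # mm -> m conversion

    def test_invalid_dt(self):
        with pytest.raises(ParameterError):
            mesh_velocity(np.zeros((2, 3)), np.zeros((2, 3)), 0.0)


class TestSteadyStokes:
    def test_quiescent_without_forcing(self, annulus3d_coarse, params):
        v, p, _ = solve_steady(annulus3d_coarse, params,
                               {fem.TAG_INLET: 0.0, fem.TAG_OUTLET_1: 0.0})
        assert np.abs(v).max() == 0.0
        assert np.abs(p).max() == 0.0

    def test_linearity_in_tractions(self, annulus3d_coarse, params):
        tr = {fem.TAG_INLET: 0.1, fem.TAG_OUTLET_1: 0.0}
        v1, p1, _ = solve_steady(annulus3d_coarse, params, tr)
        v2, p2, _ = solve_steady(annulus3d_coarse, params,
                                 {k: 2 * x for k, x in tr.items()})
        assert np.abs(v2 - 2 * v1).max() <= 1e-10 * np.abs(v1).max()
        assert np.abs(p2 - 2 * p1).max() <= 1e-10 * max(np.abs(p1).max(), 1e-30)

    def test_annular_poiseuille_within_two_percent(self, params):
        # 1.46 mmHg/m over 1 mm on the 20/60 um annulus
        geom = pf.make_annulus_mesh_3d(1.0, 20.0, 60.0, n_theta=24, n_r=3,
                                       n_z=10)
        dp = 1.46e-3 * 133.322
        v, p, solver = solve_steady(geom, params,
                                    {fem.TAG_INLET: dp, fem.TAG_OUTLET_1: 0.0})
        Q = solver.flux(solver.X_ref, v, fem.TAG_OUTLET_1)
        K = pf.annular_conductance(20.0, 60.0)
        Q_exact = np.pi * dp * K / (8 * params.mu * 1e-3)
        assert Q == pytest.approx(Q_exact, rel=0.02)
        # mean axial velocity ~ 38 um/s
        assert Q / solver.area(solver.X_ref, fem.TAG_OUTLET_1) * 1e6 == \
            pytest.approx(38.0, rel=0.02)


class TestTravellingWaveRun:
    def test_zero_forcing_run_is_identically_zero(self, annulus3d_coarse):
        bc = PressureBCSpec(mode="zero", f=10.0, branch_lengths=(0.4,))
        rec = run_cycles(annulus3d_coarse, ForcingSpec(pressure=bc),
                         FluidParams(dt=0.02), n_cycles=1)
        assert np.abs(rec.v_avg["in"]).max() == 0.0
        assert rec.pressure_peak == 0.0

    def test_global_mass_balance_within_one_percent(self, wave_run_3d):
        rec, _ = wave_run_3d
        assert rec.mass_residual < 0.01

    def test_velocity_oscillates_at_forcing_frequency(self, wave_run_3d):
        rec, prm = wave_run_3d
        v = rec.v_avg["in"][1:]
        spec = np.abs(np.fft.rfft(v - v.mean()))
        freqs = np.fft.rfftfreq(v.size, d=prm.dt)
        assert freqs[np.argmax(spec)] == pytest.approx(10.0, abs=freqs[1] / 2)

    def test_agrees_with_reduced_model_within_ten_percent(self, wave_run_3d,
                                                          reduced_run_matched):
        rec3, prm = wave_run_3d
        rec1 = reduced_run_matched
        q3, q1 = np.abs(rec3.Q["in"]).max(), np.abs(rec1.Q["in"]).max()
        assert q3 == pytest.approx(q1, rel=0.10)
        # phase: peak times within a tenth of the cycle
        t3 = rec3.t[np.argmax(np.abs(rec3.Q["in"]))]
        t1 = rec1.t[np.argmax(np.abs(rec1.Q["in"]))]
        T = 1.0 / rec3.f
        assert abs(((t3 - t1 + T / 2) % T) - T / 2) <= 0.1 * T

    def test_outflow_during_systole(self, wave_run_3d):
        # expanding artery pushes fluid out of the domain at both ends
        rec, _ = wave_run_3d
        i_peak = int(np.argmax(rec.v_avg["in"]))
        assert rec.v_avg["out1"][i_peak] > 0.0


@pytest.fixture(scope="module")
def bifurcation_run(cardiac_wave):
    geom = pf.make_synthetic_bifurcation(
        40.0, (36.0, 32.0), (0.10, 0.10, 0.10), 0.9,
        half_angle_deg=45.0, lattice_spacing=0.016)
    wall = WallWaveSpec(waveform=cardiac_wave, X0=geom.X0)
    bc = PressureBCSpec(mode="zero", f=10.0,
                        branch_lengths=geom.branch_lengths)
    rec = run_cycles(geom, ForcingSpec(wall=wall, pressure=bc),
                     FluidParams(dt=5e-3), n_cycles=1)
    return geom, rec


class TestBifurcationRun:
    def test_oscillates_at_forcing_frequency(self, bifurcation_run):
        _, rec = bifurcation_run
        v = rec.v_avg["in"][1:]
        spec = np.abs(np.fft.rfft(v - v.mean()))
        freqs = np.fft.rfftfreq(v.size, d=5e-3)
        assert freqs[np.argmax(spec)] == pytest.approx(10.0, abs=freqs[1] / 2)

    def test_flow_leaves_through_both_outlets_in_systole(self, bifurcation_run):
        _, rec = bifurcation_run
        i_peak = int(np.argmax(rec.v_avg["in"]))
        assert rec.v_avg["out1"][i_peak] > 0.0
        assert rec.v_avg["out2"][i_peak] > 0.0

    def test_pressure_maximum_is_interior(self, bifurcation_run):
        # with zero end tractions the pressure peaks inside the domain
        _, rec = bifurcation_run
        assert rec.pressure_peak > 0.0
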