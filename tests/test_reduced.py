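"""Reduced axisymmetric lubrication model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pvsflow as pf
from pvsflow.errors import ParameterError, PhysicalRegimeError
from pvsflow.forcing import PressureBCSpec, WallWaveSpec
from pvsflow.reduced_axisym import annular_conductance, length_for_amplitude
from pvsflow.stokes_ale import FluidParams


class TestConductance:
    def test_direct_value(self):
        assert annular_conductance(20.0, 60.0) == pytest.approx(3.48e-18, rel=5e-3)

    def test_hagen_poiseuille_limit(self):
        K = annular_conductance(1e-4, 60.0)
        assert K == pytest.approx((60e-6) ** 4, rel=1e-3)

    @given(st.floats(1.0, 55.0), st.floats(1.0, 55.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_monotone_in_inner_radius(self, r1a, r1b):
        lo, hi = sorted((r1a, r1b))
        if hi - lo < 1e-9:
            return
        assert annular_conductance(hi, 60.0) < annular_conductance(lo, 60.0)

    def test_inverted_radii_rejected(self):
        with pytest.raises(ParameterError):
            annular_conductance(60.0, 20.0)


class TestSolveReduced:
    def test_frozen_wall_no_gradient_is_quiescent(self, idealized_1mm, params):
        bc = PressureBCSpec(mode="zero", f=10.0, branch_lengths=(1.0,))
        rec = pf.solve_reduced(idealized_1mm, None, bc, params, n_cycles=3)
        assert np.abs(rec.Q["in"]).max() == 0.0
        assert np.abs(rec.v_avg["out1"]).max() == 0.0

    def test_static_gradient_matches_poiseuille(self, idealized_1mm, params):
        bc = PressureBCSpec(mode="static", g=1.46, f=10.0, branch_lengths=(1.0,))
        rec = pf.solve_reduced(idealized_1mm, None, bc, params, n_cycles=2)
        dp = 1.46e-3 * 133.322  # Pa over 1 mm
        K = annular_conductance(20.0, 60.0)
        Q_exact = np.pi * dp * K / (8 * params.mu * 1e-3)
        assert rec.Q["out1"][-1] == pytest.approx(Q_exact, rel=1e-3)

    def test_mass_conservation_to_roundoff(self, idealized_1mm, params,
                                           cardiac_wave):
        wall = WallWaveSpec(waveform=cardiac_wave)
        bc = PressureBCSpec(mode="zero", f=10.0, branch_lengths=(1.0,))
        rec = pf.solve_reduced(idealized_1mm, wall, bc, params, n_cycles=2)
        assert rec.mass_residual < 1e-10

    def test_superposition_in_frozen_conductance_mode(self, idealized_1mm,
                                                      params, cardiac_wave):
        wall = WallWaveSpec(waveform=cardiac_wave)
        bc0 = PressureBCSpec(mode="zero", f=10.0, branch_lengths=(1.0,))
        bcs = PressureBCSpec(mode="static", g=1.46, f=10.0, branch_lengths=(1.0,))
        kw = dict(n_cycles=2, frozen_conductance=True)
        r_wall = pf.solve_reduced(idealized_1mm, wall, bc0, params, **kw)
        r_grad = pf.solve_reduced(idealized_1mm, None, bcs, params, **kw)
        r_both = pf.solve_reduced(idealized_1mm, wall, bcs, params, **kw)
        combined = r_wall.v_avg["in"] + r_grad.v_avg["in"]
        scale = np.abs(r_both.v_avg["in"]).max()
        assert np.abs(r_both.v_avg["in"] - combined).max() < 1e-12 * scale

    def test_peak_amplitude_grows_with_length_below_wavelength(self, params,
                                                               cardiac_wave):
        # lambda = c/f = 100 mm; amplitudes grow monotonically up to it
        wall = WallWaveSpec(waveform=cardiac_wave)
        p2p = []
        for L in (1.0, 5.0, 10.0, 50.0):
            pvs = pf.make_idealized_annulus(L, 20.0, 60.0, 0.1)
            bc = PressureBCSpec(mode="zero", f=10.0, branch_lengths=(L,))
            rec = pf.solve_reduced(pvs, wall, bc, params, n_cycles=3)
            p2p.append(rec.p2p_amplitude("in"))
        assert all(b > a for a, b in zip(p2p, p2p[1:]))

    def test_net_flow_small_for_short_domains(self, params, cardiac_wave):
        # zero end-pressure difference, L <= 10 mm: net drift below 1 um/s
        wall = WallWaveSpec(waveform=cardiac_wave)
        for L in (1.0, 5.0, 10.0):
            pvs = pf.make_idealized_annulus(L, 20.0, 60.0, 0.1)
            bc = PressureBCSpec(mode="zero", f=10.0, branch_lengths=(L,))
            rec = pf.solve_reduced(pvs, wall, bc, params, n_cycles=4)
            assert abs(rec.net_flow_velocity()) < 1.0

    def test_symmetry_end_condition_closes_far_end(self, idealized_1mm, params,
                                                   cardiac_wave):
        wall = WallWaveSpec(waveform=cardiac_wave)
        bc = PressureBCSpec(mode="zero", f=10.0, branch_lengths=(1.0,))
        rec = pf.solve_reduced(idealized_1mm, wall, bc, params, n_cycles=2,
                               end_condition="symmetry")
        assert np.abs(rec.Q["out1"]).max() == 0.0
        assert np.abs(rec.Q["in"]).max() > 0.0

    def test_gap_closure_raises_physical_regime_error(self, params):
        # a pulsation large enough to slam the wall into the outer boundary
        wave = pf.Waveform(np.array([[0.0, 0.0], [0.5, 2.0 * 0.9]]), f=10.0)
        wall = WallWaveSpec(waveform=wave, R_PVS=0.1)  # 0.5*1.8*100 um > gap
        pvs = pf.make_idealized_annulus(1.0, 20.0, 60.0, 0.1)
        bc = PressureBCSpec(mode="zero", f=10.0, branch_lengths=(1.0,))
        with pytest.raises(PhysicalRegimeError):
            pf.solve_reduced(pvs, wall, bc, params, n_cycles=1)

    def test_windkessel_outlet_limits_outflow(self, idealized_1mm, params,
                                              cardiac_wave):
        from pvsflow.forcing import WindkesselSpec
        wall = WallWaveSpec(waveform=cardiac_wave)
        bc0 = PressureBCSpec(mode="zero", f=10.0, branch_lengths=(1.0,))
        bcw = PressureBCSpec(mode="windkessel", f=10.0, branch_lengths=(1.0,))
        free = pf.solve_reduced(idealized_1mm, wall, bc0, params, n_cycles=2)
        wk = pf.solve_reduced(idealized_1mm, wall, bcw, params, n_cycles=2,
                              windkessel=WindkesselSpec(C=0.001798, R=1.097))
        assert wk.p2p_amplitude("out1") < free.p2p_amplitude("out1")


class TestLengthForAmplitude:
    def test_returned_length_reproduces_target(self, params, cardiac_wave):
        wall = WallWaveSpec(waveform=cardiac_wave)
        bc = PressureBCSpec(mode="zero", f=10.0, branch_lengths=(1.0,))
        target = 20.0
        L = length_for_amplitude(target, wall, bc, params, bracket=(0.02, 1.0))
        pvs = pf.make_idealized_annulus(L, 20.0, 60.0, mesh_size=min(0.1, L / 10))
        rec = pf.solve_reduced(pvs, wall, bc, params, n_cycles=3)
        assert rec.p2p_amplitude("in") == pytest.approx(target, rel=0.05)

    def test_doubling_amplitude_roughly_halves_required_length(self, params):
        bc = PressureBCSpec(mode="zero", f=10.0, branch_lengths=(1.0,))
        w1 = WallWaveSpec(waveform=pf.make_waveform("surrogate_cardiac", 0.004, 10.0))
        w2 = WallWaveSpec(waveform=pf.make_waveform("surrogate_cardiac", 0.008, 10.0))
        L1 = length_for_amplitude(20.0, w1, bc, params, bracket=(0.02, 2.0))
        L2 = length_for_amplitude(20.0, w2, bc, params, bracket=(0.02, 2.0))
        assert L1 / L2 == pytest.approx(2.0, rel=0.15)

    def test_degenerate_target_returns_lower_bracket(self, params, cardiac_wave):
        wall = WallWaveSpec(waveform=cardiac_wave)
        bc = PressureBCSpec(mode="zero", f=10.0, branch_lengths=(1.0,))
        assert length_for_amplitude(0.0, wall, bc, params, bracket=(0.05, 1.0)) == 0.05

    def test_unstraddled_bracket_rejected(self, params, cardiac_wave):
        wall = WallWaveSpec(waveform=cardiac_wave)
        bc = PressureBCSpec(mode="zero", f=10.0, branch_lengths=(1.0,))
        with pytest.raises(ParameterError):
            length_for_amplitude(1e6, wall, bc, params, bracket=(0.02, 0.2))
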