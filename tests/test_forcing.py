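"""Forcing mechanisms: waveforms, wall wave, rigid motion, tractions,
Windkessel."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pvsflow as pf
from pvsflow.errors import ParameterError
from pvsflow.forcing import (PressureBCSpec, RigidMotionSpec, WallWaveSpec,
                             WindkesselSpec, boundary_displacement,
                             default_rigid_direction, eval_waveform,
                             pulsatile_traction, rigid_amplitude,
                             static_traction_values, wall_amplitude,
                             windkessel_step)
from pvsflow.units import MMHG_PA


class TestWaveform:
    def test_sine_surrogate_closed_form(self, sine_wave):
        # delta(s) = h sin(2 pi s): quarter cycle hits the half-amplitude
        assert eval_waveform(sine_wave, 0.025) == pytest.approx(0.007, abs=1e-15)
        assert sine_wave.delta_max == pytest.approx(0.007)
        assert sine_wave.delta_min == pytest.approx(-0.007)

    def test_periodicity_at_cycle_multiples(self, cardiac_wave):
        f = cardiac_wave.f
        for t in (0.0, 0.013, 0.0713):
            for k in (1, 3, -2):
                assert eval_waveform(cardiac_wave, t) == pytest.approx(
                    eval_waveform(cardiac_wave, t + k / f), rel=1e-9, abs=1e-12)

    def test_negative_time_wraps(self, cardiac_wave):
        f = cardiac_wave.f
        assert eval_waveform(cardiac_wave, -0.1 / f) == pytest.approx(
            eval_waveform(cardiac_wave, 0.9 / f), rel=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ParameterError):
            pf.Waveform(np.array([[0.0, 0.0]]), f=10.0)

    @given(st.floats(-5.0, 5.0), st.integers(-3, 3))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_periodicity_property(self, t, k):
        w = pf.make_waveform("surrogate_cardiac", 0.007, 4.0)
        assert eval_waveform(w, t) == pytest.approx(
            eval_waveform(w, t + k / w.f), rel=1e-9, abs=1e-12)


class TestWallWave:
    def test_zero_waveform_gives_zero_amplitude(self):
        w = pf.Waveform(np.array([[0.0, 0.0], [0.5, 0.0]]), f=10.0)
        spec = WallWaveSpec(waveform=w)
        assert wall_amplitude(spec, np.array([0.1, 0.0, 0.0]), 0.3) == 0.0

    def test_amplitude_arithmetic(self):
        # constant delta = 0.014, R_PVS = 4.4e-2 mm -> A = -3.08e-4 mm
        w = pf.Waveform(np.array([[0.0, 0.014], [0.5, 0.014]]), f=10.0)
        spec = WallWaveSpec(waveform=w, R_PVS=4.4e-2)
        A = wall_amplitude(spec, np.zeros(3), 0.123)
        assert A == pytest.approx(-3.08e-4, rel=1e-12)

    def test_retardation_lag(self, sine_wave):
        # 0.5 mm at c = 1 m/s lags the origin signal by 5e-4 s
        spec = WallWaveSpec(waveform=sine_wave, c=1.0)
        X = np.array([0.0, 0.0, 0.5])
        for t in (0.0, 0.0213, 0.05):
            assert wall_amplitude(spec, X, t) == pytest.approx(
                wall_amplitude(spec, np.zeros(3), t - 5e-4), rel=1e-12, abs=1e-18)

    def test_wavelength(self, sine_wave):
        spec = WallWaveSpec(waveform=sine_wave, c=1.0)
        assert spec.wavelength_mm == pytest.approx(100.0)


class TestRigidMotion:
    @pytest.fixture
    def spec(self, cardiac_wave):
        X0, Xc = np.zeros(3), np.array([0.0, 0.0, 0.4])
        return RigidMotionSpec(gamma=6.0, Xc=Xc, X0=X0,
                               r=default_rigid_direction(X0, Xc),
                               waveform=cardiac_wave)

    def test_vanishes_at_pivot(self, spec):
        assert rigid_amplitude(spec, spec.Xc, 0.33) == 0.0

    def test_full_amplitude_at_origin(self, spec):
        # delta = delta_max and delta_min = 0 -> B(X0) = gamma (in mm)
        t_peak = 0.02  # cardiac surrogate peaks at s = 0.2
        assert rigid_amplitude(spec, spec.X0, t_peak) == pytest.approx(
            6.0e-3, rel=1e-12)

    def test_sign_flips_beyond_pivot(self, spec):
        X = np.array([0.0, 0.0, 0.8])  # |X - X0| = 2 |Xc - X0|
        assert rigid_amplitude(spec, X, 0.02) == pytest.approx(-6.0e-3, rel=1e-12)

    def test_non_unit_direction_rejected(self, cardiac_wave):
        with pytest.raises(ParameterError):
            RigidMotionSpec(gamma=6.0, Xc=np.array([0, 0, 0.4]), X0=np.zeros(3),
                            r=np.array([2.0, 0, 0]), waveform=cardiac_wave)

    def test_direction_orthogonality_enforced(self, cardiac_wave):
        with pytest.raises(ParameterError):
            RigidMotionSpec(gamma=6.0, Xc=np.array([0, 0, 0.4]), X0=np.zeros(3),
                            r=np.array([0.0, 0, 1.0]), waveform=cardiac_wave)


class TestBoundaryDisplacement:
    def test_reduces_to_normal_motion_without_rigid(self, sine_wave):
        spec = WallWaveSpec(waveform=sine_wave)
        X = np.array([[0.02, 0.0, 0.1]])
        n = np.array([[-1.0, 0.0, 0.0]])
        d = boundary_displacement(spec, None, X, n, 0.033)
        A = wall_amplitude(spec, X[0], 0.033)
        assert np.allclose(d, A * n)

    def test_rigid_component_along_r_independent_of_n(self, cardiac_wave):
        X0, Xc = np.zeros(3), np.array([0.0, 0.0, 0.4])
        rigid = RigidMotionSpec(gamma=6.0, Xc=Xc, X0=X0,
                                r=default_rigid_direction(X0, Xc),
                                waveform=cardiac_wave)
        wall = WallWaveSpec(waveform=cardiac_wave)
        X = np.array([0.0, 0.02, 0.1])
        B = rigid_amplitude(rigid, X, 0.02)
        for n in (np.array([0.0, -1.0, 0.0]), np.array([0.0, 0.0, 1.0])):
            d = boundary_displacement(wall, rigid, X, n, 0.02)
            assert float(d @ rigid.r) == pytest.approx(B, rel=1e-12)

    def test_non_unit_normal_rejected(self, sine_wave):
        with pytest.raises(ParameterError):
            boundary_displacement(WallWaveSpec(waveform=sine_wave), None,
                                  np.zeros(3), np.array([0.0, 0.0, 2.0]), 0.0)


class TestPressureTractions:
    def test_static_single_path_value(self):
        # 1.46 mmHg/m over 1 mm -> -0.1947 Pa at the outlet
        c1, outs = static_traction_values(1.46, [1.0])
        assert c1 == 0.0
        assert outs[0] == pytest.approx(-1.46e-3 * MMHG_PA, rel=1e-12)
        assert outs[0] == pytest.approx(-0.1947, rel=1e-3)

    def test_zero_gradient(self):
        c1, outs = static_traction_values(0.0, [0.9, 1.1])
        assert c1 == 0.0 and outs == (0.0, 0.0)

    def test_branch_length_weighting(self):
        _, outs = static_traction_values(1.0, [0.9, 1.0])
        assert outs[0] / outs[1] == pytest.approx(0.9, rel=1e-12)

    @given(st.lists(st.floats(0.1, 10.0), min_size=1, max_size=4),
           st.floats(0.0, 20.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_per_path_average_gradient_exact(self, lengths, g):
        c1, outs = static_traction_values(g, lengths)
        for L, c2 in zip(lengths, outs):
            # back to mmHg/m: (c1 - c2) / L
            grad = (c1 - c2) / MMHG_PA / (L * 1e-3)
            assert grad == pytest.approx(g, rel=1e-9, abs=1e-12)

    def test_pulsatile_zero_crossings_and_peak(self):
        _, outs = pulsatile_traction(1.46, 10.0, 0.0, 0.1, [1.0])
        assert outs[0] == pytest.approx(0.0, abs=1e-12)
        _, outs = pulsatile_traction(1.46, 10.0, 0.25, 0.0, [1.0])
        assert outs[0] == pytest.approx(-1.46e-3 * MMHG_PA, rel=1e-12)

    def test_empty_branch_list_rejected(self):
        with pytest.raises(ParameterError):
            static_traction_values(1.0, [])


class TestWindkessel:
    def test_rest_state_stays_at_rest(self):
        spec = WindkesselSpec()
        assert windkessel_step(spec, 0.0, 1e-3) == 0.0

    def test_steady_state_is_QR(self):
        # constant inflow relaxes to p = Q R = 1.097 mmHg
        spec = WindkesselSpec(C=1.798, R=1.097)
        p = 0.0
        for _ in range(400):
            spec.p = p = windkessel_step(spec, 1.0, 50.0)
        assert p == pytest.approx(1.097, rel=1e-6)

    @given(st.floats(1e-5, 1e3), st.floats(0.01, 10.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_unconditional_decay(self, dt, p0):
        # implicit Euler: |p| decays monotonically for Q = 0 at any dt
        spec = WindkesselSpec(p=p0)
        p1 = windkessel_step(spec, 0.0, dt)
        spec.p = p1
        p2 = windkessel_step(spec, 0.0, dt)
        assert 0 <= p2 <= p1 <= p0

    def test_time_constant_scales_with_compliance(self):
        # reducing C by 1e3 reaches half the steady state ~1e3 times faster
        def steps_to_half(C):
            spec = WindkesselSpec(C=C, R=1.097)
            target = 0.5 * 1.097
            for k in range(1, 400_000):
                spec.p = windkessel_step(spec, 1.0, 1e-3)
                if spec.p >= target:
                    return k
            raise AssertionError("did not reach half steady state")

        ratio = steps_to_half(1.798) / steps_to_half(0.001798)
        assert 300 < ratio < 3000

    def test_invalid_dt_rejected(self):
        with pytest.raises(ParameterError):
            windkessel_step(WindkesselSpec(), 1.0, 0.0)


def test_pressure_bc_validation():
    with pytest.raises(ParameterError):
        PressureBCSpec(mode="nonsense")
    with pytest.raises(ParameterError):
        PressureBCSpec(branch_lengths=())
    with pytest.raises(ParameterError):
        PressureBCSpec(theta=1.0)
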