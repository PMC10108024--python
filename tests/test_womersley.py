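"""Velocity-driven Womersley solution: profiles, flow, wall shear stress."""

import numpy as np
import pytest

import pulsewss as pw
from pulsewss.womersley import I_3_2, harmonic_factors


class TestAlpha:
    def test_reference_value(self):
        spec = pw.VesselFluidSpec(radius=2e-3, omega=2 * np.pi * 70 / 60)
        assert pw.womersley_alpha(spec) == pytest.approx(2.628, abs=2e-3)

    def test_small_omega_limit(self):
        spec = pw.VesselFluidSpec(radius=2e-3, omega=1e-9)
        assert pw.womersley_alpha(spec) < 1e-3

    def test_linear_in_radius(self):
        a = pw.womersley_alpha(pw.VesselFluidSpec(radius=2e-3, omega=7.0))
        b = pw.womersley_alpha(pw.VesselFluidSpec(radius=4e-3, omega=7.0))
        assert b == pytest.approx(2 * a)

    def test_branch_of_i_three_halves(self):
        assert np.angle(I_3_2) == pytest.approx(3 * np.pi / 4)
        spec = pw.VesselFluidSpec(radius=3e-3, omega=7.0)
        assert harmonic_factors(spec, 1).Lambda_n.imag > 0


class TestHarmonicFactors:
    def test_parabolic_small_alpha_limit(self):
        """As alpha -> 0 the harmonic shape tends to the parabola 2(1 - x^2)."""
        spec = pw.VesselFluidSpec(radius=1e-5, omega=1e-3)  # alpha ~ 5e-3
        hf = harmonic_factors(spec, 1)
        x = np.linspace(0, 1, 21)
        assert np.real(hf.shape(x)) == pytest.approx(2 * (1 - x**2), abs=1e-4)

    def test_no_slip_identity(self):
        spec = pw.VesselFluidSpec(radius=3e-3, omega=7.0)
        for n in (1, 5, 20):
            assert abs(harmonic_factors(spec, n).shape(np.array([1.0]))[0]) < 1e-14

    def test_physiological_alpha_finite(self):
        omega = 7.33
        R = 4.2 * np.sqrt(4.5e-3 / (omega * 1060.0))
        spec = pw.VesselFluidSpec(radius=R, omega=omega)
        hf = harmonic_factors(spec, 1)
        assert np.isfinite(hf.shape_denominator)
        assert 0 < abs(hf.shape_denominator) < 2

    def test_large_alpha_does_not_overflow(self):
        """Scaled Bessel ratios stay finite far beyond the physiological range."""
        spec = pw.VesselFluidSpec(radius=2e-2, omega=50.0)  # alpha ~ 97
        hf = harmonic_factors(spec, 20)
        vals = hf.shape(np.linspace(0, 1, 11))
        assert np.all(np.isfinite(vals))
        # high-alpha harmonics are plug-like in the core: shape -> 1
        assert abs(vals[0] - 1.0) < 0.05

    def test_invalid_index(self):
        spec = pw.VesselFluidSpec(radius=3e-3, omega=7.0)
        with pytest.raises(ValueError):
            harmonic_factors(spec, 0)


class TestVelocityProfile:
    def test_constant_input_is_poiseuille(self, vessel):
        s = pw.FourierSpectrum(B0=0.2, B=np.zeros(5, complex), omega=vessel.omega)
        prof = pw.velocity_profile(s, vessel)
        expected = pw.poiseuille_profile(0.2, vessel, r_grid=prof.r_grid,
                                         t_grid=prof.t_grid)
        assert np.max(np.abs(prof.U - expected.U)) < 1e-12

    def test_no_slip(self, cosine_spectrum, vessel):
        prof = pw.velocity_profile(cosine_spectrum, vessel)
        assert np.max(np.abs(prof.U[-1])) < 1e-10 * np.max(np.abs(prof.U))

    def test_mean_recovery(self, cosine_spectrum, vessel, fine_r):
        """Area-mean of the profile reproduces the input waveform at every t."""
        prof = pw.velocity_profile(cosine_spectrum, vessel, r_grid=fine_r)
        mean = pw.numeric_flow(prof) / (np.pi * vessel.radius**2)
        u1d = pw.reconstruct_1d(cosine_spectrum, prof.t_grid)
        assert np.max(np.abs(mean - u1d)) < 1e-3 * np.max(np.abs(u1d))

    def test_linearity(self, vessel):
        rng = np.random.default_rng(3)
        B1 = rng.normal(size=4) + 1j * rng.normal(size=4)
        B2 = rng.normal(size=4) + 1j * rng.normal(size=4)
        om = vessel.omega
        t = np.linspace(0, 0.5, 7)
        p1 = pw.velocity_profile(pw.FourierSpectrum(0.1, 0.05 * B1, om), vessel, t_grid=t)
        p2 = pw.velocity_profile(pw.FourierSpectrum(0.05, 0.05 * B2, om), vessel, t_grid=t)
        p12 = pw.velocity_profile(
            pw.FourierSpectrum(0.15, 0.05 * (B1 + B2), om), vessel, t_grid=t
        )
        assert np.max(np.abs(p12.U - (p1.U + p2.U))) < 1e-12

    def test_rejects_centerline_spectrum(self, vessel):
        s = pw.FourierSpectrum(B0=0.4, B=np.zeros(2, complex), omega=vessel.omega,
                               mode="centerline")
        with pytest.raises(ValueError, match="centerline"):
            pw.velocity_profile(s, vessel)

    def test_rejects_r_outside_vessel(self, cosine_spectrum, vessel):
        with pytest.raises(ValueError, match="\\[0, R\\]"):
            pw.velocity_profile(cosine_spectrum, vessel,
                                r_grid=np.array([0.0, 2 * vessel.radius]))


class TestCenterlineRescale:
    def test_steady_halving(self, vessel):
        s = pw.FourierSpectrum(B0=0.4, B=np.zeros(2, complex), omega=vessel.omega,
                               mode="centerline")
        assert pw.centerline_rescale(s, vessel).B0 == pytest.approx(0.2)

    def test_centerline_recovery(self, vessel):
        """After rescaling, U(0, t) reproduces the measured centerline trace."""
        B = np.array([0.1 + 0.05j, -0.03 + 0.02j, 0.01 - 0.01j])
        s_c = pw.FourierSpectrum(B0=0.4, B=B, omega=vessel.omega, mode="centerline")
        s_m = pw.centerline_rescale(s_c, vessel)
        prof = pw.velocity_profile(s_m, vessel)
        target = pw.reconstruct_1d(
            pw.FourierSpectrum(B0=0.4, B=B, omega=vessel.omega), prof.t_grid
        )
        err = np.max(np.abs(prof.centerline() - target))
        assert err < 1e-8 * np.max(np.abs(target))

    def test_small_alpha_factor_is_two(self):
        """alpha -> 0: each harmonic's centerline-to-mean factor tends to 2."""
        spec = pw.VesselFluidSpec(radius=1e-5, omega=1e-3)
        s_c = pw.FourierSpectrum(B0=0.0, B=np.array([0.1 + 0j]), omega=spec.omega,
                                 mode="centerline")
        s_m = pw.centerline_rescale(s_c, spec)
        assert s_m.harmonic(1) == pytest.approx(0.05 + 0j, rel=1e-3)


class TestFlowRate:
    def test_constant_value(self, vessel):
        s = pw.FourierSpectrum(B0=0.2, B=np.zeros(1, complex), omega=vessel.omega)
        q = pw.flow_rate(s, vessel, np.array([0.0]))
        assert q[0] == pytest.approx(np.pi * (2e-3) ** 2 * 0.2, rel=1e-12)
        assert q[0] == pytest.approx(2.513e-6, rel=1e-3)

    def test_zero_spectrum(self, vessel):
        s = pw.FourierSpectrum(B0=0.0, B=np.zeros(3, complex), omega=vessel.omega)
        assert np.all(pw.flow_rate(s, vessel) == 0)

    def test_matches_quadrature(self, cosine_spectrum, vessel, fine_r):
        prof = pw.velocity_profile(cosine_spectrum, vessel, r_grid=fine_r)
        q_quad = pw.numeric_flow(prof)
        q_analytic = pw.flow_rate(cosine_spectrum, vessel, prof.t_grid)
        assert np.max(np.abs(q_quad - q_analytic)) < 1e-3 * np.max(np.abs(q_analytic))


class TestWallShearStress:
    def test_constant_value(self, vessel):
        s = pw.FourierSpectrum(B0=0.2, B=np.zeros(1, complex), omega=vessel.omega)
        tau = pw.wall_shear_stress(s, vessel)
        assert tau.tau_w == pytest.approx(1.8, rel=1e-12)

    def test_quasi_steady_limit(self):
        """At alpha = 0.1 the Womersley WSS reduces to 4 mu U(t) / R."""
        omega = 2 * np.pi
        R = 0.1 * np.sqrt(4.5e-3 / (omega * 1060.0))
        spec = pw.VesselFluidSpec(radius=R, omega=omega)
        s = pw.FourierSpectrum(B0=0.2, B=np.array([0.05 + 0j]), omega=omega)
        t = pw.default_t_grid(1.0)
        tau = pw.wall_shear_stress(s, spec, t)
        u1d = pw.reconstruct_1d(s, t)
        quasi = 4 * spec.viscosity * u1d / R
        assert np.max(np.abs(tau.tau_w - quasi)) < 0.01 * np.max(np.abs(quasi))

    def test_matches_wall_finite_difference(self, cosine_spectrum, vessel, fine_r):
        prof = pw.velocity_profile(cosine_spectrum, vessel, r_grid=fine_r)
        tau_fd = pw.numeric_wss(prof, vessel)
        tau = pw.wall_shear_stress(cosine_spectrum, vessel, prof.t_grid)
        peak = np.max(np.abs(tau.tau_w))
        assert np.max(np.abs(tau.tau_w - tau_fd.tau_w)) < 5e-3 * peak

    def test_periodic(self, cosine_spectrum, vessel):
        tau = pw.wall_shear_stress(cosine_spectrum, vessel,
                                   np.array([0.0, cosine_spectrum.period]))
        assert tau.tau_w[0] == pytest.approx(tau.tau_w[1], rel=1e-9)


class TestPressureDriven:
    def test_steady_gradient_is_poiseuille(self, vessel):
        G0 = 250.0  # Pa/m
        s = pw.FourierSpectrum(B0=G0, B=np.zeros(1, complex), omega=vessel.omega)
        prof = pw.pressure_driven_profile(s, vessel)
        u_mean = G0 * vessel.radius**2 / (8 * vessel.viscosity)
        expected = pw.poiseuille_profile(u_mean, vessel, r_grid=prof.r_grid,
                                         t_grid=prof.t_grid)
        assert np.max(np.abs(prof.U - expected.U)) < 1e-12 * np.max(np.abs(prof.U))

    def test_zero_gradient(self, vessel):
        s = pw.FourierSpectrum(B0=0.0, B=np.zeros(2, complex), omega=vessel.omega)
        prof = pw.pressure_driven_profile(s, vessel)
        assert np.max(np.abs(prof.U)) == 0.0

    def test_round_trip_with_velocity_driven(self, vessel, fine_r):
        """Pressure-driven profile -> area-mean -> velocity-driven reproduces it."""
        G = pw.FourierSpectrum(B0=120.0, B=np.array([90 + 40j]), omega=vessel.omega)
        t = pw.default_t_grid(1.0, 100)
        prof_p = pw.pressure_driven_profile(G, vessel, r_grid=fine_r, t_grid=t)
        u_mean = pw.numeric_flow(prof_p) / (np.pi * vessel.radius**2)
        w = pw.VelocityWaveform(t, u_mean, period=1.0)
        s = pw.fourier_decompose(w, N=5)
        prof_v = pw.velocity_profile(s, vessel, r_grid=fine_r, t_grid=t)
        peak = np.max(np.abs(prof_p.U))
        assert np.max(np.abs(prof_v.U - prof_p.U)) < 5e-3 * peak
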