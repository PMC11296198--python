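"""Forward model: loading program, Ogden stress, QLV integration, loops."""

import math

import numpy as np
import pytest
import sympy

import pronyfit as pf
from pronyfit.simulator import (InsufficientCyclesError, LoadingProfile,
                                NonPhysicalParameterError, OgdenModel,
                                extract_hysteresis, instantaneous_stress,
                                load_factor, simulate, simulate_stress_history,
                                suggested_dt)


class TestLoadFactor:
    def test_zero_at_start(self):
        assert load_factor(0.0, LoadingProfile()) == 0.0

    def test_ramp_endpoint(self):
        p = LoadingProfile()
        assert load_factor(p.ramp_duration_s - 1e-12, p) == pytest.approx(
            1.225, rel=1e-9)

    def test_sine_extremes_over_one_cycle(self):
        p = LoadingProfile()
        t = p.stage_start_time_s + np.linspace(0.0, 1.0, 200001)
        a = load_factor(t, p)
        assert round(float(a.max()), 3) == 1.718
        assert round(float(a.min()), 3) == 0.732

    def test_phase_continuous_option_removes_jump(self):
        p = LoadingProfile(phase_continuous=True)
        before = load_factor(p.stage_start_time_s - 1e-9, p)
        after = load_factor(p.stage_start_time_s, p)
        assert after == pytest.approx(before, abs=1e-6)

    def test_literal_phase_starts_at_maximum(self):
        p = LoadingProfile()
        assert load_factor(p.stage_start_time_s, p) == pytest.approx(
            1.225 + 0.493, rel=1e-12)

    def test_tensile_sinusoid_rejected(self):
        with pytest.raises(ValueError):
            LoadingProfile(sine_mean_mpa=0.4, sine_amplitude_mpa=0.5)


class TestOgdenStress:
    def test_zero_at_undeformed(self, ogden):
        assert instantaneous_stress(1.0, ogden) == 0.0

    def test_monotone_in_compression(self, ogden):
        lam = np.linspace(0.5, 1.0, 50)
        s = instantaneous_stress(lam, ogden)
        assert np.all(np.diff(s) < 0)  # stress grows as stretch decreases

    def test_energy_consistency_finite_differences(self, ogden):
        """Cauchy stress equals lam * dU/dlam along the incompressible path."""
        mu = np.asarray(ogden.mu_pa) / 1e6
        al = np.asarray(ogden.alpha)

        def energy(lam):
            return float(np.sum(2 * mu / al**2
                                * (lam**al + 2 * lam**(-al / 2) - 3.0)))

        h = 1e-6
        for lam in (0.8, 0.9, 0.95, 0.99):
            dU = (energy(lam + h) - energy(lam - h)) / (2 * h)
            assert instantaneous_stress(lam, ogden) == pytest.approx(
                abs(lam * dU), rel=1e-6)

    def test_symbolic_evaluation_at_table_coefficients(self, ogden):
        """Independent sympy differentiation of the strain energy, lam=0.95."""
        lam_s = sympy.Symbol("lam", positive=True)
        U = sum(2 * sympy.Rational(1) * m / 1e6 / a**2
                * (lam_s**a + 2 * lam_s**(-a / 2) - 3)
                for m, a in zip(ogden.mu_pa, ogden.alpha))
        sigma = sympy.simplify(lam_s * sympy.diff(U, lam_s))
        expected = abs(float(sigma.subs(lam_s, 0.95)))
        assert instantaneous_stress(0.95, ogden) == pytest.approx(expected,
                                                                  rel=1e-9)

    def test_small_strain_slope_is_three_shear(self, ogden):
        eps = 1e-6
        slope = instantaneous_stress(1.0 - eps, ogden) / eps
        assert slope == pytest.approx(ogden.e_inst_mpa, rel=1e-4)


class TestSimulate:
    def test_pure_elastic_matches_direct_inversion(self, ogden):
        prony = pf.PronySeries(g=[0.0], tau=[1.0], g_inf=1.0)
        prof = LoadingProfile()
        resp = simulate(prony, ogden, prof, dt=0.005)
        # invert sigma0 independently on a few samples
        from scipy.optimize import brentq
        for i in range(0, resp.time_s.size, 97):
            target = resp.stress_mpa[i]
            lam = brentq(lambda x: instantaneous_stress(x, ogden) - target,
                         0.2, 1.0) if target > 0 else 1.0
            assert resp.stretch[i] == pytest.approx(lam, abs=1e-8)

    def test_zero_stress_history_stays_undeformed(self, ogden):
        prony = pf.PronySeries(g=[0.4], tau=[0.1])
        t = np.arange(0.0, 1.0, 0.01)
        resp = simulate_stress_history(prony, ogden, t, np.zeros_like(t))
        assert np.all(resp.stretch == 1.0)
        assert np.all(resp.disp_mm == 0.0)

    def test_small_amplitude_loop_matches_prony_forms(self, ogden):
        prony = pf.PronySeries(g=[0.4], tau=[0.1])
        w = 10.0  # omega tau = 1
        e1, e2 = pf.measure_dynamic_moduli(prony, ogden, w)
        scale = ogden.e_inst_mpa
        assert e1 / scale == pytest.approx(pf.storage_modulus(prony, w), rel=0.01)
        assert e2 / scale == pytest.approx(pf.loss_modulus(prony, w), rel=0.01)

    def test_overload_scored_as_non_physical(self, ogden):
        soft = OgdenModel(mu_pa=(100.0,), alpha=(2.0,))  # ~300 Pa stiffness
        prony = pf.PronySeries(g=[0.4], tau=[0.1])
        with pytest.raises(NonPhysicalParameterError):
            simulate(prony, soft, LoadingProfile(), dt=0.005)

    def test_time_step_convergence(self, ogden, truth_n1):
        """Richardson check: halving dt changes the final cycle < 0.1%."""
        prof = LoadingProfile()
        dt = suggested_dt(truth_n1.prony, prof)
        r1 = simulate(truth_n1.prony, ogden, prof, dt=dt)
        r2 = simulate(truth_n1.prony, ogden, prof, dt=dt / 2)
        d1 = np.interp(np.linspace(1.0, 2.0, 300), r1.time_s, r1.disp_mm)
        d2 = np.interp(np.linspace(1.0, 2.0, 300), r2.time_s, r2.disp_mm)
        assert np.max(np.abs(d1 - d2) / np.max(d2)) < 1e-3

    def test_long_hold_relaxes_to_equilibrium(self, ogden):
        """Constant stress at t >> max tau approaches g_inf * sigma0 inversion."""
        prony = pf.PronySeries(g=[0.4], tau=[0.05])
        hold = 20 * 0.05
        t = np.arange(0.0, hold + 2.0, 0.005)
        stress = np.full_like(t, 1.0)
        resp = simulate_stress_history(prony, ogden, t, stress)
        lam_end = resp.stretch[-1]
        # equilibrium: g_inf * sigma0(lam) = 1.0
        assert prony.g_inf * instantaneous_stress(lam_end, ogden) == pytest.approx(
            1.0, rel=1e-3)

    def test_dt_preconditions_enforced(self, ogden):
        prony = pf.PronySeries(g=[0.4], tau=[0.1])
        with pytest.raises(ValueError):
            simulate(prony, ogden, LoadingProfile(), dt=0.1)  # > tau/5


class TestHysteresis:
    def test_elastic_loop_has_zero_area(self, ogden):
        prony = pf.PronySeries(g=[1e-9], tau=[0.1], g_inf=1.0 - 1e-9)
        prof = LoadingProfile()
        resp = simulate(prony, ogden, prof, dt=0.005)
        loop = extract_hysteresis(resp, prof)
        assert abs(loop.area) < 1e-7

    def test_viscoelastic_area_equals_dissipated_energy(self, ogden, truth_n1):
        """Loop area equals the independent trapezoid cyclic work integral."""
        prof = LoadingProfile()
        resp = simulate(truth_n1.prony, ogden, prof,
                        dt=suggested_dt(truth_n1.prony, prof))
        loop = extract_hysteresis(resp, prof)
        period = 1.0 / prof.sine_frequency_hz
        m = resp.time_s >= resp.time_s[-1] - period - 1e-12
        work = np.trapezoid(resp.stress_mpa[m], resp.disp_mm[m])
        assert loop.area == pytest.approx(work, rel=1e-9)
        assert loop.area > 0.0

    def test_minimum_displacement_normalized_to_zero(self, ogden, truth_n1):
        prof = LoadingProfile()
        resp = simulate(truth_n1.prony, ogden, prof,
                        dt=suggested_dt(truth_n1.prony, prof))
        loop = extract_hysteresis(resp, prof)
        assert min(loop.upper_disp_mm.min(), loop.lower_disp_mm.min()) == 0.0

    def test_insufficient_cycles_rejected(self, ogden, truth_n1):
        prof = LoadingProfile(sine_duration_s=0.4)
        resp = simulate(truth_n1.prony, ogden, prof, dt=0.005)
        with pytest.raises(InsufficientCyclesError):
            extract_hysteresis(resp, prof)


def test_dynamic_moduli_sweep_consistency(ogden, truth_n3):
    """Time-domain loops reproduce the frequency-domain forms over a decade."""
    prony = truth_n3.prony
    scale = ogden.e_inst_mpa
    for wt in np.geomspace(0.1, 10.0, 5):
        w = wt / 0.05  # reference the middle relaxation time
        e1, e2 = pf.measure_dynamic_moduli(prony, ogden, w)
        assert e1 / scale == pytest.approx(pf.storage_modulus(prony, w), rel=0.02)
        assert e2 / scale == pytest.approx(pf.loss_modulus(prony, w), rel=0.02)
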