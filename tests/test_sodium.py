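"""Sodium-current analysis: peak extraction, reversal, conductance,
Boltzmann fits, and the translation-equivariance invariants."""

import numpy as np
import pytest
from dataclasses import replace

from cmquant.errors import DegenerateDataError, NoReversalError
from cmquant.presets import GatingPreset, VClampProtocol
from cmquant.records import GVCurve, IVCurve, SweepFamily
from cmquant.sodium import (analyze_inact_family, analyze_na_family,
                            availability_curve, conductance_curve,
                            estimate_reversal, fit_boltzmann_activation,
                            fit_boltzmann_inactivation, peak_currents,
                            peak_density)
from cmquant.synth import simulate_inactivation_family, simulate_vclamp_family

from oracles import euler_vclamp_peak


def _manual_family(sweeps, voltages, capacitance=25.0, fs=20.0):
    proto = VClampProtocol(step_start=voltages[0], step_stop=voltages[-1],
                           step_increment=voltages[1] - voltages[0],
                           step_duration=40.0, sampling_rate=fs)
    n = sweeps.shape[0]
    t = np.arange(n) / fs
    return SweepFamily(time_ms=t, sweeps=sweeps,
                       step_voltages=np.asarray(voltages, float),
                       capacitance=capacitance, protocol=proto,
                       step_onset=5.0)


class TestPeakCurrents:
    def test_all_zero_sweep(self):
        sweeps = np.zeros((901, 2))
        fam = _manual_family(sweeps, [-20.0, -15.0])
        iv = peak_currents(fam)
        assert iv.peak_current[0] == 0.0
        assert iv.density[0] == 0.0

    def test_rectangular_pulse_density(self):
        fs = 20.0
        t = np.arange(901) / fs
        sweeps = np.zeros((901, 2))
        sweeps[(t >= 10) & (t < 20), 0] = -500.0
        fam = _manual_family(sweeps, [-20.0, -15.0], capacitance=25.0)
        iv = peak_currents(fam)
        assert iv.peak_current[0] == -500.0
        assert iv.density[0] == pytest.approx(-20.0)

    def test_matches_brute_force_scan(self, donor):
        fam = simulate_vclamp_family(donor, noise_sd=0.05, seed=2)
        iv = peak_currents(fam)
        lo, hi = fam.step_window
        sel = (fam.time_ms >= lo) & (fam.time_ms <= hi)
        pre = (fam.time_ms >= lo - 5.0) & (fam.time_ms < lo)
        for j in range(fam.step_voltages.size):
            sweep = fam.sweeps[:, j] - fam.sweeps[pre, j].mean()
            best = 0.0
            for sample in sweep[sel]:
                if abs(sample) > abs(best):
                    best = sample
            assert iv.peak_current[j] == pytest.approx(best, abs=1e-12)

    def test_noiseless_densities_match_euler_oracle(self, donor):
        fam = simulate_vclamp_family(donor)
        iv = peak_currents(fam)
        for v in (-30.0, -10.0, 10.0):
            j = int(np.where(iv.voltages == v)[0][0])
            expected = euler_vclamp_peak(
                v, v_half_act=donor.v_half_act, k_act=donor.k_act,
                v_half_inact=donor.v_half_inact, k_inact=donor.k_inact,
                g_max=donor.g_max, v_rev=donor.v_rev,
                tau_m_max=donor.tau_m_max,
                tau_h_max=donor.tau_h_max) / donor.capacitance
            assert iv.density[j] == pytest.approx(expected, rel=5e-3)


class TestReversal:
    def test_midpoint_interpolation(self):
        iv = IVCurve(voltages=np.array([45.0, 55.0, 65.0]),
                     peak_current=np.array([-80.0, -50.0, 50.0]),
                     capacitance=30.0)
        assert estimate_reversal(iv) == pytest.approx(60.0)

    def test_noiseless_simulation_recovers_v_rev(self, donor):
        iv = peak_currents(simulate_vclamp_family(donor))
        assert estimate_reversal(iv, extrapolate=True) == pytest.approx(
            donor.v_rev, abs=2.5)

    def test_monotone_negative_curve_raises(self):
        iv = IVCurve(voltages=np.array([0.0, 10.0, 20.0]),
                     peak_current=np.array([-10.0, -20.0, -30.0]),
                     capacitance=30.0)
        with pytest.raises(NoReversalError):
            estimate_reversal(iv, extrapolate=True)


class TestConductance:
    def test_chord_conductance_arithmetic(self):
        iv = IVCurve(voltages=np.array([-25.0, -20.0, -15.0]),
                     peak_current=np.array([-800.0, -900.0, -850.0]),
                     capacitance=30.0)
        gv = conductance_curve(iv, v_rev=70.0)
        j = int(np.where(gv.voltages == -20.0)[0][0])
        assert gv.conductance[j] == pytest.approx(10.0)

    def test_all_zero_currents_flagged(self):
        iv = IVCurve(voltages=np.array([-20.0, -10.0, 0.0]),
                     peak_current=np.zeros(3), capacitance=30.0)
        with pytest.raises(DegenerateDataError):
            conductance_curve(iv, v_rev=65.0)

    def test_near_reversal_points_excluded(self):
        iv = IVCurve(voltages=np.arange(-20.0, 75.0, 5.0),
                     peak_current=np.arange(-20.0, 75.0, 5.0) - 65.0,
                     capacitance=30.0)
        gv = conductance_curve(iv, v_rev=65.0)
        assert 65.0 not in gv.voltages
        assert np.all(np.abs(gv.voltages - 65.0) >= 2.5)
        assert 65.0 in gv.excluded_voltages

    def test_noiseless_gv_is_boltzmann_shaped(self, donor):
        fam = simulate_vclamp_family(donor)
        iv = peak_currents(fam)
        gv = conductance_curve(iv, v_rev=donor.v_rev)
        assert np.all(gv.conductance >= -1e-9)
        fit = fit_boltzmann_activation(gv)
        # the apparent G-V of an m^3*h family deviates from a pure
        # Boltzmann by ~1.5% rms (cubed-gate shape); see decisions ledger
        assert fit.rss < 0.02
        assert fit.rss / fit.n_points < 5e-4


class TestBoltzmannFits:
    @staticmethod
    def _exact_gv(v_half, k, lo=-80.0, hi=0.0):
        v = np.arange(lo, hi + 1e-9, 5.0)
        y = 1.0 / (1.0 + np.exp((v_half - v) / k))
        return GVCurve(voltages=v, conductance=y, normalized=y)

    def test_recovers_exact_activation_samples(self):
        fit = fit_boltzmann_activation(self._exact_gv(-35.0, 6.0))
        assert fit.v_half == pytest.approx(-35.0, abs=1e-6)
        assert fit.k == pytest.approx(6.0, abs=1e-6)
        assert float(fit.predict(fit.v_half)) == pytest.approx(0.5)

    def test_translation_is_exact(self):
        f0 = fit_boltzmann_activation(self._exact_gv(-35.0, 6.0))
        f1 = fit_boltzmann_activation(self._exact_gv(-30.0, 6.0))
        assert f1.v_half - f0.v_half == pytest.approx(5.0, abs=1e-7)
        assert f1.k == pytest.approx(f0.k, abs=1e-7)

    def test_translation_equivariance_on_shifted_data(self):
        gv = self._exact_gv(-35.0, 6.0)
        shifted = GVCurve(voltages=gv.voltages + 12.5,
                          conductance=gv.conductance,
                          normalized=gv.normalized)
        f0 = fit_boltzmann_activation(gv)
        f1 = fit_boltzmann_activation(shifted)
        assert f1.v_half - f0.v_half == pytest.approx(12.5, abs=1e-8)
        assert f1.k == pytest.approx(f0.k, abs=1e-8)

    def test_recovers_exact_inactivation_samples(self):
        v = np.arange(-120.0, 1e-9, 5.0)
        y = 1.0 / (1.0 + np.exp((v - (-78.0)) / 6.0))
        fit = fit_boltzmann_inactivation(
            GVCurve(voltages=v, conductance=y, normalized=y))
        assert fit.v_half == pytest.approx(-78.0, abs=1e-6)
        assert fit.k == pytest.approx(6.0, abs=1e-6)

    def test_inactivation_translation(self):
        v = np.arange(-120.0, 1e-9, 5.0)
        fits = []
        for vh in (-78.0, -89.0):
            y = 1.0 / (1.0 + np.exp((v - vh) / 6.0))
            fits.append(fit_boltzmann_inactivation(
                GVCurve(voltages=v, conductance=y, normalized=y)))
        assert fits[1].v_half - fits[0].v_half == pytest.approx(-11.0,
                                                               abs=1e-7)


class TestAvailability:
    def test_anchor_and_midpoint(self, donor):
        fam = simulate_inactivation_family(donor)
        avail = availability_curve(fam)
        assert avail.normalized[0] == pytest.approx(1.0)
        # midpoint prepulse (on-grid preset)
        preset = GatingPreset(v_half_inact=-80.0)
        fam = simulate_inactivation_family(preset)
        avail = availability_curve(fam)
        j = int(np.where(avail.voltages == -80.0)[0][0])
        assert avail.normalized[j] == pytest.approx(0.5, abs=0.01)

    def test_all_equal_peaks_flat(self):
        sweeps = np.full((501, 6), -100.0)
        voltages = np.arange(-120.0, -95.0 + 1e-9, 5.0)
        fam = _manual_family(sweeps, list(voltages))
        # constant sweeps: baseline correction zeroes them -> degenerate
        with pytest.raises(DegenerateDataError):
            availability_curve(fam)
        # equal pulses above a zero baseline -> flat availability at 1
        sweeps = np.zeros((901, 6))
        sweeps[200:400, :] = -100.0
        fam = _manual_family(sweeps, list(voltages))
        avail = availability_curve(fam)
        np.testing.assert_allclose(avail.normalized, 1.0)


class TestPeakDensity:
    def test_examples(self):
        iv = IVCurve(voltages=np.array([-30.0, -20.0, -10.0]),
                     peak_current=np.array([-10.0, -50.0, -20.0]),
                     capacitance=1.0)
        assert peak_density(iv) == -50.0
        zero = IVCurve(voltages=np.array([-30.0, -20.0]),
                       peak_current=np.zeros(2), capacitance=1.0)
        assert peak_density(zero) == 0.0


class TestEndToEndTranslation:
    def test_noiseless_activation_shift_recovered_exactly(self, donor,
                                                          r1267q):
        a0 = analyze_na_family(simulate_vclamp_family(donor))
        a1 = analyze_na_family(simulate_vclamp_family(r1267q))
        assert a1["v_half_act"] - a0["v_half_act"] == pytest.approx(5.0,
                                                                    abs=0.1)

    def test_noiseless_inactivation_shift_recovered_exactly(self, donor,
                                                            v2264m):
        i0 = analyze_inact_family(simulate_inactivation_family(donor))
        i1 = analyze_inact_family(simulate_inactivation_family(v2264m))
        assert i1["v_half_inact"] - i0["v_half_inact"] == pytest.approx(
            -11.0, abs=0.1)

    def test_g_max_scaling_reduces_peak_density(self, donor, r1267q):
        d0 = analyze_na_family(simulate_vclamp_family(donor))
        d1 = analyze_na_family(simulate_vclamp_family(r1267q))
        assert abs(d1["peak_density"]) < abs(d0["peak_density"])
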