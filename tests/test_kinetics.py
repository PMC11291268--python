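"""Trace generation and rate-constant fitting."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gnao1kit.kinetics import (
    Activity,
    FitMethod,
    FluorescenceTrace,
    InactiveTraceError,
    KineticParams,
    KineticsError,
    Ligand,
    bateman_curve,
    bateman_peak_time,
    classify_activity,
    fit_binding_rate,
    fit_gtp_kinetics,
    fold_change,
)
from gnao1kit.synthetic import (
    NoiseModel,
    SamplingSchedule,
    simulate_gtp_trace,
    simulate_gtpgs_trace,
)


class TestTraceGenerators:
    def test_binding_curve_matches_closed_form(self):
        params = KineticParams(k_bind=0.01, amplitude=100.0, baseline=50.0)
        trace = simulate_gtpgs_trace(params, SamplingSchedule(0, 600, 61))
        expected = 50.0 + 100.0 * (1.0 - math.exp(-6.0))
        assert trace.values[-1] == pytest.approx(expected, rel=1e-12)
        full = 50.0 + 100.0 * (1.0 - np.exp(-0.01 * trace.times))
        np.testing.assert_allclose(trace.values, full, rtol=1e-12)

    def test_zero_amplitude_gives_flat_trace(self):
        params = KineticParams(k_bind=0.05, amplitude=0.0, baseline=20.0)
        trace = simulate_gtpgs_trace(params, noise=NoiseModel(sigma_rel=0.1, seed=3))
        assert np.all(trace.values == 20.0)

    def test_same_seed_reproduces_noisy_trace_bitwise(self):
        params = KineticParams(k_bind=0.01, amplitude=100.0, baseline=50.0)
        noise = NoiseModel(sigma_rel=0.02, seed=7)
        a = simulate_gtpgs_trace(params, noise=noise)
        b = simulate_gtpgs_trace(params, noise=noise)
        assert np.array_equal(a.values, b.values)

    def test_gtp_trace_peaks_at_analytic_time(self):
        params = KineticParams(k_bind=0.02, k_hydr=0.002, amplitude=100.0)
        t_peak = bateman_peak_time(0.02, 0.002)
        assert t_peak == pytest.approx(math.log(10.0) / 0.018, rel=1e-12)
        sched = SamplingSchedule(0, 2500, 25001)
        trace = simulate_gtp_trace(params, sched)
        assert sched.times[np.argmax(trace.values)] == pytest.approx(t_peak, abs=0.1)

    def test_equal_rate_limit(self):
        value = bateman_curve(np.array([100.0]), 0.01, 0.01, 100.0, 0.0)[0]
        assert value == pytest.approx(100.0 * math.exp(-1.0), rel=1e-12)

    def test_no_hydrolysis_reduces_to_binding_trace_bitwise(self):
        params = KineticParams(k_bind=0.01, k_hydr=0.0, amplitude=80.0, baseline=5.0)
        noise = NoiseModel(sigma_rel=0.02, seed=11)
        gtp = simulate_gtp_trace(params, noise=noise)
        gtpgs = simulate_gtpgs_trace(params, noise=noise)
        assert np.array_equal(gtp.values, gtpgs.values)
        assert gtp.ligand is Ligand.GTP and gtpgs.ligand is Ligand.GTPGS

    def test_invalid_inputs_rejected(self):
        with pytest.raises(KineticsError):
            KineticParams(k_bind=0.0)
        with pytest.raises(KineticsError):
            KineticParams(k_bind=0.01, k_hydr=-1e-3)
        with pytest.raises(KineticsError):
            SamplingSchedule(10.0, 10.0, 5)
        with pytest.raises(KineticsError):
            SamplingSchedule(0.0, 100.0, 1)
        with pytest.raises(KineticsError):
            NoiseModel(sigma_rel=-0.1)


class TestBindingFit:
    def test_noiseless_round_trip(self):
        params = KineticParams(k_bind=0.010, amplitude=120.0, baseline=40.0)
        trace = simulate_gtpgs_trace(params, SamplingSchedule(0, 600, 121))
        fit = fit_binding_rate(trace)
        assert fit.converged
        assert fit.params.k_bind == pytest.approx(0.010, rel=1e-6)
        assert fit.params.amplitude == pytest.approx(120.0, rel=1e-6)
        assert fit.method is FitMethod.DIRECT

    def test_fold_change_between_variants_recovered(self):
        # uptake constants differing 34-fold should fit back to a 34-fold ratio
        sched = SamplingSchedule(0, 600, 121)
        slow = fit_binding_rate(
            simulate_gtpgs_trace(KineticParams(k_bind=0.01, amplitude=100.0), sched)
        )
        fast = fit_binding_rate(
            simulate_gtpgs_trace(KineticParams(k_bind=0.34, amplitude=100.0), sched)
        )
        fc = fold_change(fast.params.k_bind, slow.params.k_bind)
        assert fc.factor == pytest.approx(34.0, rel=1e-4)
        assert fc.direction == "increase"

    def test_rejects_gtp_ligand_and_inactive_trace(self):
        params = KineticParams(k_bind=0.01, amplitude=100.0)
        gtp = simulate_gtp_trace(params)
        with pytest.raises(KineticsError):
            fit_binding_rate(gtp)
        flat = FluorescenceTrace(
            times=np.arange(10.0), values=np.full(10, 50.0), ligand=Ligand.GTPGS
        )
        with pytest.raises(InactiveTraceError):
            fit_binding_rate(flat, sigma_noise=1.0)


class TestGtpFit:
    def test_noiseless_round_trip_direct(self):
        params = KineticParams(k_bind=0.02, k_hydr=0.002, amplitude=100.0, baseline=10.0)
        trace = simulate_gtp_trace(params, SamplingSchedule(0, 2500, 501))
        fit = fit_gtp_kinetics(trace)
        assert fit.method is FitMethod.DIRECT
        assert fit.params.k_bind == pytest.approx(0.02, rel=1e-4)
        assert fit.params.k_hydr == pytest.approx(0.002, rel=1e-4)

    def test_truncated_window_uses_projected_baseline(self):
        params = KineticParams(k_bind=0.02, k_hydr=0.002, amplitude=100.0, baseline=10.0)
        trace = simulate_gtp_trace(params, SamplingSchedule(0, 500, 101))
        fit = fit_gtp_kinetics(trace)
        assert fit.method is FitMethod.EXTRAPOLATED
        assert fit.params.baseline == trace.values[0]
        assert fit.params.k_hydr == pytest.approx(0.002, rel=0.10)

    def test_zero_hydrolysis_flagged_and_matches_binding_fit(self):
        params = KineticParams(k_bind=0.015, k_hydr=0.0, amplitude=100.0, baseline=30.0)
        gtp = simulate_gtp_trace(params, SamplingSchedule(0, 600, 121))
        fit = fit_gtp_kinetics(gtp)
        assert fit.params.k_hydr <= 1e-6
        assert fit.k_hydr_uncertain
        gtpgs = simulate_gtpgs_trace(params, SamplingSchedule(0, 600, 121))
        ref = fit_binding_rate(gtpgs)
        assert fit.params.k_bind == pytest.approx(ref.params.k_bind, rel=1e-4)


class TestActivityClassification:
    def _trace(self, amplitude, sigma=1.0, seed=0):
        params = KineticParams(k_bind=0.01, amplitude=max(amplitude, 1e-12), baseline=50.0)
        sched = SamplingSchedule(0, 600, 121)
        clean = 50.0 + amplitude * (1.0 - np.exp(-0.01 * sched.times))
        return FluorescenceTrace(times=sched.times, values=clean, ligand=Ligand.GTPGS)

    def test_flat_trace_is_inactive(self):
        trace = FluorescenceTrace(
            times=np.arange(20.0), values=np.full(20, 50.0), ligand=Ligand.GTPGS
        )
        assert classify_activity(trace, sigma_noise=1.0) is Activity.INACTIVE

    def test_clear_amplitude_is_active(self):
        assert classify_activity(self._trace(10.0), sigma_noise=1.0) is Activity.ACTIVE

    def test_boundary_amplitude_counts_as_active(self):
        # excursion of exactly k*sigma resolves to active (tie rule)
        times = np.array([0.0, 1.0, 2.0])
        values = np.array([0.0, 3.0, 3.0])
        trace = FluorescenceTrace(times=times, values=values, ligand=Ligand.GTPGS)
        assert classify_activity(trace, sigma_noise=1.0, k=3.0) is Activity.ACTIVE
        assert classify_activity(trace, sigma_noise=1.0001, k=3.0) is Activity.INACTIVE

    @given(st.floats(min_value=0.0, max_value=20.0))
    def test_monotone_in_amplitude(self, amplitude):
        trace = self._trace(amplitude)
        verdict = classify_activity(trace, sigma_noise=1.0)
        threshold_excursion = 3.0 * 1.0
        expected = (
            Activity.ACTIVE
            if trace.empirical_amplitude >= threshold_excursion
            else Activity.INACTIVE
        )
        assert verdict is expected


class TestFoldChange:
    def test_printed_style_examples(self):
        up = fold_change(0.34, 0.01)
        assert up.factor == pytest.approx(34.0) and up.direction == "increase"
        down = fold_change(0.005, 0.01)
        assert down.factor == pytest.approx(2.0) and down.direction == "decrease"
        same = fold_change(0.3, 0.3)
        assert same.factor == 1.0 and same.direction == "none"

    def test_bad_reference_rejected(self):
        with pytest.raises(KineticsError):
            fold_change(1.0, 0.0)
        with pytest.raises(KineticsError):
            fold_change(1.0, -2.0)
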