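import itertools

import numpy as np
import pytest

from is3sim.solver import CurrentStep, SolverConfig, VoltageTrace
from is3sim.trace_metrics import (
    IvlAssessment,
    TraceMeasurements,
    detect_and_cut_spikes,
    input_resistance,
    isi_cv,
    ivl_metric,
    measure_input_resistance,
    spike_psd,
    summarize,
)
from test_solver import single_compartment


def make_trace(vm, dt=0.025, t0=0.0):
    vm = np.asarray(vm, dtype=float)
    return VoltageTrace(t0 + dt * np.arange(len(vm)), vm)


def trace_with_triangles(peak_times, baseline=-70.0, peak=10.0, half_width_ms=1.5,
                         duration=10_000.0, dt=0.025):
    t = np.arange(0, duration, dt)
    v = np.full_like(t, baseline)
    for tp in peak_times:
        rise = (t >= tp - half_width_ms) & (t <= tp)
        fall = (t > tp) & (t <= tp + half_width_ms)
        v[rise] = baseline + (peak - baseline) * (1 - (tp - t[rise]) / half_width_ms)
        v[fall] = baseline + (peak - baseline) * (1 - (t[fall] - tp) / half_width_ms)
    return VoltageTrace(t, v)


class TestSpikeDetectionAndCutting:
    def test_flat_trace_has_no_spikes(self):
        trace = make_trace(np.full(4000, -70.0))
        cut = detect_and_cut_spikes(trace)
        assert len(cut.spike_times) == 0
        assert np.array_equal(cut.sub_vm, trace.vm)

    def test_triangular_spikes_are_found_cut_and_measured(self):
        trace = trace_with_triangles([3000.0, 6000.0])
        cut = detect_and_cut_spikes(trace)
        assert len(cut.spike_times) == 2
        assert np.allclose(cut.spike_times, [3000.0, 6000.0], atol=0.05)
        assert np.allclose(cut.amplitudes, 80.0, atol=1.0)
        assert np.mean(cut.sub_vm) == pytest.approx(-70.0, abs=0.01)

    def test_small_spike_amplitude_measured_from_spike_begin(self):
        # a shrunken spike peaking at -15 mV from a -52 mV baseline:
        # amplitude ~37 mV, below the 40 mV depolarization-block cutoff
        trace = trace_with_triangles([5000.0], baseline=-52.0, peak=-15.0,
                                     half_width_ms=0.5)
        cut = detect_and_cut_spikes(trace)
        assert len(cut.spike_times) == 1
        assert cut.amplitudes[0] == pytest.approx(37.0, abs=1.5)
        assert cut.amplitudes[0] < 40.0

    def test_subthreshold_bump_below_detection_threshold_is_not_a_spike(self):
        trace = trace_with_triangles([5000.0], baseline=-60.0, peak=-35.0)
        cut = detect_and_cut_spikes(trace)
        assert len(cut.spike_times) == 0


class TestSummarize:
    def test_constant_trace(self):
        m = summarize(make_trace(np.full(400_001, -70.0)))
        assert m.mean_sub_vm == -70.0
        assert m.sigma_sub_vm == 0.0
        assert m.isi_cv == 0.0
        assert m.n_spikes == 0

    def test_sinusoid_sigma_is_rms(self):
        t = np.arange(0, 10_000, 0.025)
        v = -65.0 + 2.0 * np.sin(2 * np.pi * 5.0 * t / 1000.0)
        m = summarize(VoltageTrace(t, v))
        assert m.sigma_sub_vm == pytest.approx(2.0 / np.sqrt(2), rel=1e-3)
        assert m.mean_sub_vm == pytest.approx(-65.0, abs=1e-3)

    def test_periodic_spikes_have_zero_isi_cv(self):
        assert isi_cv(np.arange(1000, 10_000, 100.0)) == 0.0

    def test_poisson_like_isis_have_unit_cv(self):
        rng = np.random.default_rng(0)
        st = np.cumsum(rng.exponential(10.0, size=1000))
        assert isi_cv(st) == pytest.approx(1.0, abs=0.1)

    def test_fewer_than_three_spikes_define_cv_zero(self):
        assert isi_cv(np.array([100.0, 200.0])) == 0.0

    def test_window_restriction(self):
        # spikes before 1 s are excluded from the analysis window
        trace = trace_with_triangles([500.0, 3000.0, 5000.0, 7000.0])
        m = summarize(trace)
        assert m.n_spikes == 3


class TestIvlMetric:
    @pytest.mark.parametrize(
        "vm, sigma, cv, amp, expected_metric, expected_state",
        [
            (-60.0, 3.0, 1.0, 55.0, 3, "IVL"),
            (-70.0, 1.0, 0.3, 55.0, 0, "NIVL"),
            (-55.0, 4.0, 1.2, 30.0, -1, "DB"),
        ],
    )
    def test_printed_anchor_cases(self, vm, sigma, cv, amp, expected_metric, expected_state):
        meas = TraceMeasurements(vm, sigma, cv, amp, 100, np.empty(0))
        out = ivl_metric(meas)
        assert out.ivl_metric == expected_metric
        assert out.state == expected_state

    def test_exhaustive_truth_table(self):
        # one value on each side of every threshold, all 16 combinations
        sides = {
            "vm": (-70.0, -60.0),      # threshold -66.7
            "sigma": (1.0, 3.0),       # threshold 2.2
            "cv": (0.3, 1.0),          # threshold 0.8
            "amp": (30.0, 55.0),       # threshold 40 (below -> DB term)
        }
        for vm, sigma, cv, amp in itertools.product(*sides.values()):
            meas = TraceMeasurements(vm, sigma, cv, amp, 50, np.empty(0))
            expected = (
                int(vm > -66.7) + int(sigma > 2.2) + int(cv > 0.8)
                - 4 * int(amp < 40.0)
            )
            out = ivl_metric(meas)
            assert out.ivl_metric == expected
            if expected == 3:
                assert out.state == "IVL"
            elif expected == 0:
                assert out.state == "NIVL"
            elif expected < 0:
                assert out.state == "DB"
            else:
                assert out.state == "PARTIAL"

    def test_spikeless_trace_is_never_ivl_and_never_db(self):
        meas = TraceMeasurements(-60.0, 3.0, 0.0, float("nan"), 0, np.empty(0))
        out = ivl_metric(meas)
        assert out.ivl_metric == 2
        assert out.state == "PARTIAL"


class TestInputResistance:
    def test_passive_compartment_matches_analytic(self):
        # 10x10 um soma at 0.7957747 mS/cm^2 -> 2.5 nS -> 400 MOhm
        model = single_compartment(g_leak=0.7957747)
        res = input_resistance(model)
        assert res.r_in == pytest.approx(400.0, rel=0.01)

    def test_linearity_in_injected_current(self):
        model = single_compartment(g_leak=0.7957747)
        a = input_resistance(model, i_inj=-0.1)
        b = input_resistance(model, i_inj=-0.2)
        assert a.r_in == pytest.approx(b.r_in, rel=1e-6)

    def test_zero_injection_rejected(self):
        trace = make_trace(np.full(400_001, -70.0))
        with pytest.raises(ValueError):
            measure_input_resistance(trace, 0.0)


class TestSpikePsd:
    def test_empty_train_has_zero_power(self):
        res = spike_psd(np.empty(0))
        assert np.all(res.power == 0)
        assert res.value_at_8hz == 0.0

    def test_frequency_grid_resolves_8hz(self):
        res = spike_psd(np.array([2000.0, 3000.0]))
        assert np.min(np.abs(res.frequencies - 8.0)) < 0.5

    def test_periodic_8hz_train_peaks_at_8hz(self):
        # a delta comb has equal-power harmonics at multiples of 8 Hz, so the
        # fundamental must dominate every *non-harmonic* frequency in 1-50 Hz
        st = 1000.0 + 125.0 * np.arange(72)
        res = spike_psd(st)
        band = (res.frequencies >= 1.0) & (res.frequencies <= 50.0)
        harmonic = np.min(
            np.abs(res.frequencies[:, None] - 8.0 * np.arange(1, 8)[None, :]), axis=1
        ) < 1.0
        assert res.value_at_8hz > 50.0
        assert res.value_at_8hz >= res.power[band & ~harmonic].max() * 50

    def test_homogeneous_train_is_spectrally_flat_at_8hz(self):
        # 8 Hz should not stand out of the 1-50 Hz band for random trains
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            st = np.sort(rng.uniform(1000.0, 10_000.0, size=180))
            res = spike_psd(st)
            band = (res.frequencies >= 1.0) & (res.frequencies <= 50.0)
            if res.value_at_8hz <= 3.0 * np.median(res.power[band]):
                hits += 1
        assert hits >= 95
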