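import numpy as np
import pytest

from is3sim.clamp_theta import (
    ConductanceTraces,
    ei_ratio,
    isolate_conductance,
    minimal_count_search,
    theta_cycle_average,
    theta_response,
)
from is3sim.input_gen import InputScenario, ThetaPopulation, ThetaProtocol
from is3sim.solver import SolverConfig, SynapticEvents, VoltageClamp
from is3sim.synapses import (
    CLASS_E_REV,
    CLASS_TAU_D,
    CLASS_TAU_R,
    SynapseSpec,
    conductance_kernel,
    peak_factor,
)
from test_solver import single_compartment


def _one_synapse_events(cls, weight_ns, spike_times):
    n = len(spike_times)
    amt = weight_ns * 1e-3 * peak_factor(CLASS_TAU_R[cls], CLASS_TAU_D[cls])
    return SynapticEvents(
        np.asarray(spike_times, float), np.zeros(n, np.int64),
        np.full(n, cls, np.int64), np.full(n, amt),
        CLASS_TAU_R.copy(), CLASS_TAU_D.copy(), CLASS_E_REV.copy(),
    )


class TestClampRecovery:
    def test_single_compartment_recovers_the_known_kernel(self):
        # ideal clamp at the synapse's compartment: recovered conductance
        # must equal the analytic two-exponential kernel
        model = single_compartment()
        events = _one_synapse_events(cls=0, weight_ns=0.5, spike_times=[50.0])
        trace = model.run(
            SolverConfig(duration=200.0), events=events,
            clamp=VoltageClamp(-70.0), e_leak_override=-70.0, v_init=-70.0,
        )
        g_rec = trace.clamp_current / (-70.0 - 0.0) * 1e3  # nS
        spec = SynapseSpec(0, 0, "excitatory", "proximal", 10.0, 0.5,
                           CLASS_TAU_R[0], CLASS_TAU_D[0], 0.0)
        g_true = conductance_kernel(spec, [50.0], trace.times)
        assert g_rec.max() == pytest.approx(0.5, rel=0.02)
        assert np.max(np.abs(g_rec - g_true)) < 0.02 * 0.5

    def test_no_inputs_give_zero_conductance(self):
        model = single_compartment()
        trace = model.run(
            SolverConfig(duration=100.0),
            clamp=VoltageClamp(-70.0), e_leak_override=-70.0, v_init=-70.0,
        )
        assert np.max(np.abs(trace.clamp_current)) < 1e-12

    def test_method1_equals_method2_without_a_cable(self):
        # with soma-only geometry there is no space-clamp artifact: an
        # inhibitory synapse adds no current at its own reversal, so removing
        # it (method 1) or keeping it (method 2) gives the same excitatory g
        model = single_compartment()
        exc = _one_synapse_events(0, 0.5, [50.0])
        inh = _one_synapse_events(2, 0.8, [40.0, 55.0])
        both = SynapticEvents(
            np.concatenate([exc.times, inh.times]),
            np.concatenate([exc.compartments, inh.compartments]),
            np.concatenate([exc.classes, inh.classes]),
            np.concatenate([exc.amounts, inh.amounts]),
            CLASS_TAU_R.copy(), CLASS_TAU_D.copy(), CLASS_E_REV.copy(),
        )
        kw = dict(clamp=VoltageClamp(-70.0), e_leak_override=-70.0, v_init=-70.0)
        cfg = SolverConfig(duration=200.0)
        t1 = model.run(cfg, events=exc, **kw)
        t2 = model.run(cfg, events=both, **kw)
        assert np.allclose(t1.clamp_current, t2.clamp_current, atol=1e-12)


class TestEiRatio:
    def _traces(self, g_e, g_i):
        t = np.arange(1000.0, 10_000.0, 1.0)
        return ConductanceTraces(t, np.broadcast_to(g_e, t.shape).copy(),
                                 np.broadcast_to(g_i, t.shape).copy())

    def test_equal_traces_give_unity(self):
        assert ei_ratio(self._traces(2.0, 2.0)) == pytest.approx(1.0)

    def test_zero_excitation_gives_zero(self):
        assert ei_ratio(self._traces(0.0, 1.5)) == pytest.approx(0.0)

    def test_elementwise_doubling(self):
        t = np.arange(1000.0, 10_000.0, 1.0)
        g_i = 1.0 + 0.5 * np.sin(t / 300.0)
        tr = ConductanceTraces(t, 2.0 * g_i, g_i)
        assert ei_ratio(tr) == pytest.approx(2.0, rel=1e-9)

    def test_scale_equivariance(self):
        t = np.arange(1000.0, 10_000.0, 1.0)
        g_i = 1.0 + 0.5 * np.cos(t / 100.0)
        g_e = 0.7 + 0.2 * np.sin(t / 170.0)
        base = ei_ratio(ConductanceTraces(t, g_e, g_i))
        scaled = ei_ratio(ConductanceTraces(t, 3.0 * g_e, g_i))
        assert scaled == pytest.approx(3.0 * base, rel=1e-9)

    def test_undefined_when_inhibition_below_floor(self):
        assert np.isnan(ei_ratio(self._traces(1.0, 0.0)))


class TestThetaCycleAverage:
    def test_analysis_window_holds_72_cycles(self):
        t = np.arange(0.0, 10_000.0, 0.5)
        avg = theta_cycle_average(t, np.sin(2 * np.pi * 8.0 * t / 1000.0))
        assert avg.n_cycles == 72

    def test_pure_8hz_sinusoid_has_zero_cycle_variance(self):
        t = np.arange(0.0, 10_000.0, 0.5)
        v = np.sin(2 * np.pi * 8.0 * t / 1000.0)
        avg = theta_cycle_average(t, v)
        assert np.max(avg.sd) < 1e-9
        assert np.max(np.abs(avg.mean - np.sin(2 * np.pi * avg.times / 125.0))) < 1e-9

    def test_constant_trace_is_flat_with_zero_sd(self):
        t = np.arange(0.0, 10_000.0, 0.5)
        avg = theta_cycle_average(t, np.full_like(t, 3.3))
        assert np.allclose(avg.mean, 3.3) and np.max(avg.sd) < 1e-12

    def test_bad_window_rejected(self):
        t = np.arange(0.0, 10_000.0, 0.5)
        with pytest.raises(ValueError, match="multiple"):
            theta_cycle_average(t, t, window=(1000.0, 9_980.0))


class TestMinimalCountSearch:
    def test_returns_smallest_satisfying_count(self):
        assert minimal_count_search(lambda c: c >= 7, cap=20) == 7

    def test_count_below_returned_one_fails(self):
        threshold = 5
        found = minimal_count_search(lambda c: c >= threshold, cap=20)
        assert found == threshold
        assert not (found - 1 >= threshold)

    def test_cap_raises(self):
        with pytest.raises(RuntimeError, match="up to 3"):
            minimal_count_search(lambda c: False, cap=3)


class TestOnCalibratedCell:
    def test_method2_space_clamp_depresses_excitatory_conductance(self, cell_plus):
        # strong dendritic inhibition reduces the apparent excitatory
        # conductance when it is left active during the clamp (method 2)
        sc = InputScenario(5.0, 80.0, 144, 300, k_e=9, k_i=4, seed=5)
        g1 = isolate_conductance(cell_plus, sc, method="method1")
        g2 = isolate_conductance(cell_plus, sc, method="method2")
        m = g1.times >= 1000.0
        assert np.mean(g2.g_e[m]) < np.mean(g1.g_e[m])

    def test_minimal_theta_count_satisfies_the_stopping_rule(self, cell_plus):
        from is3sim.clamp_theta import EXC_MIN_SPIKES, EXC_PSD_THRESHOLD, estimate_theta_inputs
        from is3sim.trace_metrics import spike_psd

        n = estimate_theta_inputs(cell_plus, "proximal", "excitatory", cap=40)

        def criteria(count):
            proto = ThetaProtocol(
                [ThetaPopulation("probe", "excitatory", "proximal", 0.0, count)]
            )
            res = cell_plus.run_scenario(InputScenario(0, 0, 0, 0, seed=2), theta=proto)
            psd8 = spike_psd(res.measurements.spike_times).value_at_8hz
            return psd8 > EXC_PSD_THRESHOLD and res.measurements.n_spikes > EXC_MIN_SPIKES

        assert 1 <= n <= 40
        assert criteria(n)
        assert not criteria(n - 1)

    def test_empty_theta_protocol_changes_nothing(self, cell_plus):
        sc = InputScenario(5.0, 30.0, 90, 40, k_e=9, k_i=4, seed=6)
        (before, after), = theta_response(cell_plus, sc, ThetaProtocol([]))
        assert before.value_at_8hz == after.value_at_8hz
        assert np.array_equal(before.power, after.power)
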