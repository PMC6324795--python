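"""Conductance isolation, E/I conductance ratios, theta-cycle analyses.

Isolation replicates the simulated voltage-clamp protocol: all active
channel conductances are removed, every compartment's leak reversal is set
to the holding potential (so leak current vanishes at the clamp), and an
ideal somatic clamp records the current needed to hold -70 mV (for
excitatory currents) or 0 mV (for inhibitory). The recorded current converts
to a conductance via G = I / (V_hold - E_R).

Method 1 removes the opposite input class's spike trains entirely; Method 2
("experiment-like") leaves both classes active, so dendritic inhibition can
depress the apparent excitatory conductance - the space-clamp artifact the
comparison is designed to expose.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cell import CellModel
from .input_gen import (
    InputScenario,
    ThetaPopulation,
    ThetaProtocol,
    events_from_assignment,
    realize_scenario,
)
from .solver import CableModel, CurrentStep, SynapticEvents, VoltageClamp, VoltageTrace
from .synapses import CLS_INH, E_REV_EXC, E_REV_INH
from .trace_metrics import ANALYSIS_WINDOW_MS, PsdResult, spike_psd

__all__ = [
    "ClampConfig", "ConductanceTraces", "CycleAverage",
    "isolate_conductance", "ei_ratio", "theta_cycle_average",
    "estimate_theta_inputs", "theta_response",
]

#: holding potentials per recorded class
V_HOLD = {"excitatory": E_REV_INH, "inhibitory": E_REV_EXC}
#: reversal of the *recorded* class (the denominator's E_R)
E_REV = {"excitatory": E_REV_EXC, "inhibitory": E_REV_INH}

G_I_FLOOR_NS = 1e-3  # samples with g_I below this are excluded from ratios


@dataclass(frozen=True)
class ClampConfig:
    """Voltage-clamp conductance-isolation settings."""

    method: str = "method1"        # method1 | method2
    target: str = "excitatory"     # class being recorded
    v_hold: float | None = None    # defaults to the opposite class's reversal

    def __post_init__(self) -> None:
        if self.method not in ("method1", "method2"):
            raise ValueError("method must be 'method1' or 'method2'")
        if self.target not in ("excitatory", "inhibitory"):
            raise ValueError("target must be 'excitatory' or 'inhibitory'")

    @property
    def hold(self) -> float:
        return V_HOLD[self.target] if self.v_hold is None else self.v_hold


@dataclass
class ConductanceTraces:
    """Isolated conductances (nS) on the recording time grid."""

    times: np.ndarray
    g_e: np.ndarray | None = None
    g_i: np.ndarray | None = None


@dataclass
class CycleAverage:
    """Mean and SD over stacked theta cycles."""

    times: np.ndarray  # within-cycle time, ms
    mean: np.ndarray
    sd: np.ndarray
    n_cycles: int


def _clamp_run(
    cell: CellModel, events: SynapticEvents, v_hold: float, duration: float
) -> VoltageTrace:
    passive = CableModel(cell.morphology, cell.channels.passive_copy())
    cfg = replace(cell.solver, duration=duration)
    return passive.run(
        solver=cfg,
        events=events,
        clamp=VoltageClamp(v_hold),
        e_leak_override=v_hold,
        v_init=v_hold,
    )


def _isolate_one(
    cell: CellModel, scenario: InputScenario, config: ClampConfig, duration: float
) -> tuple[np.ndarray, np.ndarray]:
    v_hold = config.hold
    e_rev = E_REV[config.target]
    if abs(v_hold - e_rev) < 1e-9:
        raise ValueError(
            f"holding potential {v_hold} mV equals the recorded class's "
            "reversal (zero driving force)"
        )
    assignment = realize_scenario(cell.bank, scenario, duration)
    events = events_from_assignment(assignment, cell.bank)
    if config.method == "method1":
        if config.target == "excitatory":
            keep = events.classes != CLS_INH
        else:
            keep = events.classes == CLS_INH
        events = SynapticEvents(
            events.times[keep], events.compartments[keep],
            events.classes[keep], events.amounts[keep],
            events.tau_r, events.tau_d, events.e_rev,
        )
    trace = _clamp_run(cell, events, v_hold, duration)
    g_nS = trace.clamp_current / (v_hold - e_rev) * 1e3  # nA/mV = uS -> nS
    return trace.times, g_nS


def isolate_conductance(
    cell: CellModel,
    scenario: InputScenario,
    method: str = "method1",
    duration: float = 10_000.0,
) -> ConductanceTraces:
    """Record both isolated conductance traces for one scenario.

    Runs the clamp twice (once per holding potential). Intrinsic noise is off
    during clamp runs; the background drive reuses the scenario's seeds, so
    method 1 and method 2 see identical spike trains.
    """
    t, g_e = _isolate_one(cell, scenario, ClampConfig(method, "excitatory"), duration)
    _, g_i = _isolate_one(cell, scenario, ClampConfig(method, "inhibitory"), duration)
    return ConductanceTraces(times=t, g_e=g_e, g_i=g_i)


def ei_ratio(
    g: ConductanceTraces,
    window: tuple[float, float] = ANALYSIS_WINDOW_MS,
    floor: float = G_I_FLOOR_NS,
) -> float:
    """Temporal mean of the element-wise ratio g_E(t)/g_I(t).

    Samples where g_I is below ``floor`` (nS) are excluded; returns nan if
    every sample is excluded (the ratio is then undefined).
    """
    m = (g.times >= window[0]) & (g.times <= window[1])
    ge, gi = g.g_e[m], g.g_i[m]
    ok = gi > floor
    if not np.any(ok):
        return float("nan")
    return float(np.mean(ge[ok] / gi[ok]))


def theta_cycle_average(
    times: np.ndarray,
    values: np.ndarray,
    period: float = 125.0,
    window: tuple[float, float] = ANALYSIS_WINDOW_MS,
) -> CycleAverage:
    """Stack the analysis window into consecutive theta cycles.

    The 1,000-10,000 ms window at the 125 ms theta period gives 72 cycles.
    Raises if the window is not a whole number of periods or the sampling
    interval does not divide the period.
    """
    t0, t1 = window
    n_cycles = (t1 - t0) / period
    if abs(n_cycles - round(n_cycles)) > 1e-9:
        raise ValueError("window length must be a multiple of the theta period")
    n_cycles = int(round(n_cycles))
    dt = float(times[1] - times[0])
    per = period / dt
    if abs(per - round(per)) > 1e-9:
        raise ValueError("sampling interval must divide the theta period")
    per = int(round(per))
    m = (times >= t0) & (times < t1)
    stack = np.asarray(values)[m][: n_cycles * per].reshape(n_cycles, per)
    return CycleAverage(
        times=np.arange(per) * dt,
        mean=stack.mean(axis=0),
        sd=stack.std(axis=0),
        n_cycles=n_cycles,
    )


# ---------------------------------------------------------------------------
# Theta-timed synapse-number estimation
# ---------------------------------------------------------------------------

#: minimal-count stopping criteria
EXC_PSD_THRESHOLD = 50.0   # spikes^2/Hz at 8 Hz
EXC_MIN_SPIKES = 10
INH_PSD_THRESHOLD = 80.0
INH_MAX_SPIKES = 240
HOLD_TARGET_SPIKES = 350   # >= 35 Hz over 10 s before inhibitory estimation


def minimal_count_search(evaluate, cap: int = 100) -> int:
    """Smallest count >= 1 whose evaluation satisfies its criteria.

    ``evaluate(count) -> bool``; raises ``RuntimeError`` at the cap.
    """
    for count in range(1, cap + 1):
        if evaluate(count):
            return count
    raise RuntimeError(f"criteria not met for any count up to {cap}")


def calibrate_holding_current(
    cell: CellModel,
    start_pa: float = 10.0,
    step_pa: float = 2.5,
    cap_pa: float = 200.0,
    duration: float = 10_000.0,
) -> float:
    """Smallest depolarizing current (pA) driving >= 350 spikes in 10 s."""
    amp = start_pa
    while amp <= cap_pa:
        inj = CurrentStep(0.0, duration, amp * 1e-3)
        res = cell.run_scenario(
            InputScenario(0, 0, 0, 0, seed=1), duration=duration, injections=(inj,)
        )
        if res.measurements.n_spikes >= HOLD_TARGET_SPIKES:
            return amp
        amp += step_pa
    raise RuntimeError(f"no holding current up to {cap_pa} pA reached "
                       f"{HOLD_TARGET_SPIKES} spikes")


def estimate_theta_inputs(
    cell: CellModel,
    zone: str,
    kind: str,
    cap: int = 100,
    duration: float = 10_000.0,
    holding_pa: float | None = None,
) -> int:
    """Minimal theta-timed synapse count recruiting 8 Hz output spiking.

    The cell starts from its quiescent ("in vitro") condition. One population
    of ``count`` synapses of the given kind/zone fires once per 125 ms cycle.
    Excitatory criterion: spike-train PSD at 8 Hz > 50 spikes^2/Hz and more
    than 10 spikes. Inhibitory criterion (with a depolarizing holding current
    first calibrated to >= 35 Hz firing): PSD at 8 Hz > 80 spikes^2/Hz and
    fewer than 240 spikes. Raises ``RuntimeError`` naming the unmet criterion
    when the cap is reached.
    """
    injections: tuple[CurrentStep, ...] = ()
    if kind == "inhibitory":
        amp = calibrate_holding_current(cell) if holding_pa is None else holding_pa
        injections = (CurrentStep(0.0, duration, amp * 1e-3),)

    def evaluate(count: int) -> bool:
        protocol = ThetaProtocol([ThetaPopulation("probe", kind, zone, 0.0, count)])
        res = cell.run_scenario(
            InputScenario(0, 0, 0, 0, seed=2),
            duration=duration, theta=protocol, injections=injections,
        )
        psd8 = spike_psd(res.measurements.spike_times).value_at_8hz
        n = res.measurements.n_spikes
        if kind == "excitatory":
            return psd8 > EXC_PSD_THRESHOLD and n > EXC_MIN_SPIKES
        return psd8 > INH_PSD_THRESHOLD and n < INH_MAX_SPIKES

    try:
        return minimal_count_search(evaluate, cap)
    except RuntimeError:
        crit = ("PSD@8Hz > 50 and > 10 spikes" if kind == "excitatory"
                else "PSD@8Hz > 80 and < 240 spikes")
        raise RuntimeError(
            f"{zone} {kind}: criterion not met up to {cap} synapses ({crit})"
        ) from None


def theta_response(
    cell: CellModel,
    scenario: InputScenario,
    protocol: ThetaProtocol,
    n_reseeds: int = 0,
) -> list[tuple[PsdResult, PsdResult]]:
    """Output-spike PSDs before and after adding theta-timed inputs.

    The background drive uses identical seeds in both runs, so with an empty
    protocol the two PSDs are exactly equal. With ``n_reseeds`` > 0 the pair
    is repeated over fresh background seeds (scenario seed + r) to assess
    consistency; returns one (before, after) pair per seed.
    """
    pairs = []
    for r in range(max(1, n_reseeds)):
        sc = replace(scenario, seed=(scenario.seed + r) % (2**31))
        before = cell.run_scenario(sc)
        after = cell.run_scenario(sc, theta=protocol)
        pairs.append((
            spike_psd(before.measurements.spike_times),
            spike_psd(after.measurements.spike_times),
        ))
    return pairs
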