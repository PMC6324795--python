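"""Feature extraction from voltage traces and spike trains.

A 10 s simulation is analyzed over its last 9 seconds (1,000-10,000 ms).
Spikes are detected by an upward threshold crossing, their begin/end located
by derivative criteria, and the samples they span are removed before
computing subthreshold statistics. The four resulting measurements - mean
subthreshold Vm, its standard deviation, the inter-spike-interval coefficient
of variation (ISICV) and the mean spike amplitude - feed a conditional
"in-vivo-like" (IVL) score:

    IVL = (Vm > -66.7 mV) + (sigma_Vm > 2.2 mV) + (ISICV > 0.8)
          - 4 * (mean spike amplitude < 40 mV)

A score of 3 is an in-vivo-like (IVL) state, 0 is non-in-vivo-like (NIVL),
and any negative score flags proximity to depolarization block (DB), where
spikes shrink below 40 mV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .solver import CableModel, CurrentStep, NoiseConfig, SolverConfig, SynapticEvents, VoltageTrace

__all__ = [
    "ANALYSIS_WINDOW_MS",
    "SpikeCut",
    "TraceMeasurements",
    "IvlAssessment",
    "InputResistanceResult",
    "PsdResult",
    "detect_and_cut_spikes",
    "summarize",
    "ivl_metric",
    "measure_input_resistance",
    "input_resistance",
    "spike_psd",
]

ANALYSIS_WINDOW_MS = (1_000.0, 10_000.0)

SPIKE_THRESHOLD_MV = -20.0     # upward crossing arms detection
SPIKE_DVDT_MV_PER_MS = 20.0    # spike begin: last upward dV/dt crossing
MAX_SPIKE_SPAN_MS = 10.0       # cap on the cut after the peak (DB plateaus)

IVL_VM_MV = -66.7
IVL_SIGMA_MV = 2.2
IVL_ISICV = 0.8
IVL_AMP_MV = 40.0


@dataclass
class SpikeCut:
    """Detected spikes plus the trace with their spans removed."""

    spike_times: np.ndarray   # ms (peak times)
    amplitudes: np.ndarray    # mV (peak - Vm at spike begin)
    sub_times: np.ndarray
    sub_vm: np.ndarray


@dataclass
class TraceMeasurements:
    """Per-simulation features over the analysis window."""

    mean_sub_vm: float
    sigma_sub_vm: float
    isi_cv: float
    mean_spike_amp: float  # nan when there are no spikes
    n_spikes: int
    spike_times: np.ndarray


@dataclass(frozen=True)
class IvlAssessment:
    ivl_metric: int
    state: str  # IVL | NIVL | DB | PARTIAL


@dataclass(frozen=True)
class InputResistanceResult:
    r_in: float       # MOhm
    v_baseline: float
    v_hyper: float
    i_inj: float      # nA


@dataclass
class PsdResult:
    frequencies: np.ndarray  # Hz
    power: np.ndarray        # spikes^2/Hz
    value_at_8hz: float


def detect_and_cut_spikes(trace: VoltageTrace) -> SpikeCut:
    """Find spikes and remove their spans from the trace.

    Detection arms on an upward crossing of -20 mV. The spike begin is the
    last upward crossing of dV/dt >= 20 mV/ms before the peak; the end is the
    return of Vm below the begin voltage, capped at 10 ms past the peak so
    depolarization-block plateaus are not swallowed. Amplitude is peak minus
    begin voltage. Zero spikes is a valid outcome.
    """
    v = np.asarray(trace.vm, dtype=float)
    t = np.asarray(trace.times, dtype=float)
    n = len(v)
    if n < 3:
        return SpikeCut(np.empty(0), np.empty(0), t, v)
    dt = trace.dt
    dvdt = np.empty(n)
    dvdt[1:] = np.diff(v) / dt
    dvdt[0] = dvdt[1]

    above = v >= SPIKE_THRESHOLD_MV
    ups = np.flatnonzero(~above[:-1] & above[1:]) + 1

    keep = np.ones(n, dtype=bool)
    peaks, amps = [], []
    max_span = round(MAX_SPIKE_SPAN_MS / dt)
    last_end = -1
    for u in ups:
        if u <= last_end:
            continue
        # peak: maximum until v drops back below threshold (or span cap)
        stop = u
        while stop < n - 1 and v[stop] >= SPIKE_THRESHOLD_MV and stop - u < max_span:
            stop += 1
        p = u + int(np.argmax(v[u : stop + 1]))
        # spike begin: last upward dV/dt crossing before the peak
        b = None
        i = p
        lo = max(0, p - max_span)
        while i > lo:
            if dvdt[i] >= SPIKE_DVDT_MV_PER_MS and dvdt[i - 1] < SPIKE_DVDT_MV_PER_MS:
                b = i - 1
                break
            i -= 1
        if b is None:
            b = int(np.flatnonzero(dvdt[lo : p + 1] >= SPIKE_DVDT_MV_PER_MS)[0] + lo) \
                if np.any(dvdt[lo : p + 1] >= SPIKE_DVDT_MV_PER_MS) else max(0, u - 1)
        # spike end: Vm back below the begin voltage (capped)
        e = p
        hi = min(n - 1, p + max_span)
        while e < hi and v[e] >= v[b]:
            e += 1
        keep[b : e + 1] = False
        peaks.append(t[p])
        amps.append(v[p] - v[b])
        last_end = e

    return SpikeCut(np.asarray(peaks), np.asarray(amps), t[keep], v[keep])


def isi_cv(spike_times: np.ndarray) -> float:
    """Coefficient of variation of inter-spike intervals.

    Defined as 0 with fewer than 3 spikes (an almost-silent trace cannot
    count as irregular); ~1 for Poisson-like firing.
    """
    if len(spike_times) < 3:
        return 0.0
    isi = np.diff(np.asarray(spike_times, dtype=float))
    return float(np.std(isi) / np.mean(isi))


def summarize(
    trace: VoltageTrace, window: tuple[float, float] = ANALYSIS_WINDOW_MS
) -> TraceMeasurements:
    """Subthreshold mean/SD, ISICV and mean spike amplitude over ``window``.

    ISICV = sd(ISI)/mean(ISI); with fewer than 3 spikes it is defined as 0
    (an almost-silent trace cannot count as irregular). The mean spike
    amplitude is nan when there are no spikes.
    """
    cut = detect_and_cut_spikes(trace)
    t0, t1 = window
    m = (cut.sub_times >= t0) & (cut.sub_times <= t1)
    sub = cut.sub_vm[m]
    in_win = (cut.spike_times >= t0) & (cut.spike_times <= t1)
    st = cut.spike_times[in_win]
    amps = cut.amplitudes[in_win]

    cv = isi_cv(st)
    return TraceMeasurements(
        mean_sub_vm=float(np.mean(sub)) if len(sub) else float("nan"),
        sigma_sub_vm=float(np.std(sub)) if len(sub) else 0.0,
        isi_cv=cv,
        mean_spike_amp=float(np.mean(amps)) if len(amps) else float("nan"),
        n_spikes=int(len(st)),
        spike_times=st,
    )


def ivl_metric(meas: TraceMeasurements) -> IvlAssessment:
    """Score the four measurements with the IVL conditional.

    A spikeless trace can never be IVL (the ISICV term fails) and is never
    counted as DB (no spikes is not depolarization block), so its amplitude
    term contributes 0 by convention.
    """
    score = int(meas.mean_sub_vm > IVL_VM_MV)
    score += int(meas.sigma_sub_vm > IVL_SIGMA_MV)
    score += int(meas.isi_cv > IVL_ISICV)
    if meas.n_spikes > 0 and np.isfinite(meas.mean_spike_amp):
        score -= 4 * int(meas.mean_spike_amp < IVL_AMP_MV)
    if score == 3:
        state = "IVL"
    elif score == 0:
        state = "NIVL"
    elif score < 0:
        state = "DB"
    else:
        state = "PARTIAL"
    return IvlAssessment(score, state)


# ---------------------------------------------------------------------------
# Input resistance protocol: -100 pA over 4.5-5.5 s of a 10 s run
# ---------------------------------------------------------------------------

RI_STEP_START_MS = 4_500.0
RI_STEP_END_MS = 5_500.0
RI_STEP_AMPLITUDE_NA = -0.1
RI_SETTLE_MS = 200.0  # skipped at hyperpolarization onset


def measure_input_resistance(trace: VoltageTrace, i_inj: float) -> InputResistanceResult:
    """Ri from a recorded step-protocol trace.

    Baseline Vm averages 0-4.5 s and 5.5-10 s with spikes cut; the
    hyperpolarized Vm averages 4.7-5.5 s (200 ms of settling skipped).
    """
    if i_inj == 0:
        raise ValueError("injected current must be nonzero")
    cut = detect_and_cut_spikes(trace)
    t, v = cut.sub_times, cut.sub_vm
    base = (t < RI_STEP_START_MS) | (t > RI_STEP_END_MS)
    hyper = (t >= RI_STEP_START_MS + RI_SETTLE_MS) & (t <= RI_STEP_END_MS)
    v_base = float(np.mean(v[base]))
    v_hyp = float(np.mean(v[hyper]))
    return InputResistanceResult(
        r_in=(v_hyp - v_base) / i_inj,  # mV/nA = MOhm
        v_baseline=v_base,
        v_hyper=v_hyp,
        i_inj=i_inj,
    )


def input_resistance(
    model: CableModel,
    events: SynapticEvents | None = None,
    noise: NoiseConfig | None = None,
    solver: SolverConfig | None = None,
    i_inj: float = RI_STEP_AMPLITUDE_NA,
) -> InputResistanceResult:
    """Run the 10 s step protocol on ``model`` and measure Ri."""
    cfg = solver or SolverConfig()
    step = CurrentStep(RI_STEP_START_MS, RI_STEP_END_MS, i_inj)
    trace = model.run(solver=cfg, events=events, injections=[step], noise=noise)
    return measure_input_resistance(trace, i_inj)


# ---------------------------------------------------------------------------
# Welch PSD of the model's output spike train
# ---------------------------------------------------------------------------

PSD_BIN_MS = 1.0
PSD_NPERSEG = 2048


def spike_psd(
    spike_times: np.ndarray,
    window: tuple[float, float] = ANALYSIS_WINDOW_MS,
) -> PsdResult:
    """Welch PSD of the binned spike train over ``window``.

    The train is binned at 1 ms (fs = 1 kHz) into an instantaneous rate
    signal (counts per bin / bin width, spikes/s) and estimated with
    Hann-windowed 2048-sample segments at 50% overlap (~0.49 Hz resolution);
    the 8 Hz value is read at the nearest frequency bin.
    """
    t0, t1 = window
    n_bins = int(round((t1 - t0) / PSD_BIN_MS))
    st = np.asarray(spike_times, dtype=float)
    st = st[(st >= t0) & (st < t1)]
    fs = 1000.0 / PSD_BIN_MS
    counts = np.bincount(
        np.floor((st - t0) / PSD_BIN_MS).astype(int), minlength=n_bins
    )[:n_bins].astype(float) * fs
    nper = min(PSD_NPERSEG, n_bins)
    freqs, power = signal.welch(
        counts, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2
    )
    idx = int(np.argmin(np.abs(freqs - 8.0)))
    return PsdResult(freqs, power, float(power[idx]))
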