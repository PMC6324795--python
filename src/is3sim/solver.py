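"""User-facing simulation layer over the compiled cable-equation engine.

Units throughout: mV, ms, nA, uS (nS where noted), um, MOhm; conductance
densities in mS/cm^2. Currents follow the convention positive = outward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import engine
from .channels import ChannelDensities
from .kinetics import E_K, E_NA
from .morphology import Morphology

__all__ = [
    "SolverConfig",
    "NoiseConfig",
    "CurrentStep",
    "VoltageClamp",
    "SynapticEvents",
    "VoltageTrace",
    "CableModel",
]


@dataclass(frozen=True)
class SolverConfig:
    """Time stepping: backward Euler at ``dt`` (ms) for ``duration`` (ms)."""

    dt: float = 0.025
    duration: float = 10_000.0
    record_dt: float = 0.025

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if abs(self.duration / self.dt - round(self.duration / self.dt)) > 1e-9:
            raise ValueError("duration must be a multiple of dt")

    @property
    def n_steps(self) -> int:
        return round(self.duration / self.dt)

    @property
    def record_every(self) -> int:
        k = round(self.record_dt / self.dt)
        return max(k, 1)


@dataclass(frozen=True)
class NoiseConfig:
    """Somatic Gaussian current noise.

    ``sigma_current`` (pA) sets the white-noise intensity; the per-step
    standard deviation is scaled by 1/sqrt(dt) so the voltage statistics are
    dt-invariant. Noise is injected at the soma only.
    """

    enabled: bool = True
    sigma_current: float = 10.0  # pA
    target_sigma_vm: float = 0.22  # mV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_current < 0:
            raise ValueError("sigma_current must be non-negative")


@dataclass(frozen=True)
class CurrentStep:
    """Constant current injection over [start, end) ms."""

    start: float
    end: float
    amplitude: float  # nA
    compartment: int = 0


@dataclass(frozen=True)
class VoltageClamp:
    """Ideal (zero series-resistance) somatic voltage clamp."""

    v_hold: float  # mV


@dataclass
class SynapticEvents:
    """Presynaptic events grouped into kinetic classes.

    Each class has one (tau_r, tau_d, e_rev) triple; an event delivers an
    increment ``amount`` (uS, already including the peak-normalization
    factor) to that class's two exponential states in one compartment.
    """

    times: np.ndarray        # ms
    compartments: np.ndarray
    classes: np.ndarray
    amounts: np.ndarray      # uS
    tau_r: np.ndarray        # per class, ms
    tau_d: np.ndarray        # per class, ms
    e_rev: np.ndarray        # per class, mV

    @classmethod
    def empty(cls) -> "SynapticEvents":
        z = np.zeros(0)
        return cls(z, z.astype(np.int64), z.astype(np.int64), z,
                   np.array([1.0]), np.array([2.0]), np.array([0.0]))

    def compiled(self, dt: float, n_steps: int):
        """Snap event times to the nearest solver step and sort."""
        steps = np.clip(np.rint(self.times / dt).astype(np.int64), 0, n_steps - 1)
        order = np.argsort(steps, kind="stable")
        return (
            steps[order],
            self.compartments[order].astype(np.int64),
            self.classes[order].astype(np.int64),
            self.amounts[order].astype(float),
        )


@dataclass
class VoltageTrace:
    """Recorded somatic voltage (and optionally clamp current, all-compartment V)."""

    times: np.ndarray  # ms
    vm: np.ndarray     # mV, somatic
    clamp_current: np.ndarray | None = None  # nA
    vm_all: np.ndarray | None = None         # (n_rec, n_comp)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.vm):
            raise ValueError("times and vm must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def window(self, t0: float, t1: float) -> "VoltageTrace":
        m = (self.times >= t0) & (self.times <= t1)
        return VoltageTrace(
            self.times[m], self.vm[m],
            None if self.clamp_current is None else self.clamp_current[m],
            None if self.vm_all is None else self.vm_all[m],
        )

    def to_csv(self, path) -> None:
        import pandas as pd

        cols = {"time_ms": self.times, "vm_mv": self.vm}
        if self.clamp_current is not None:
            cols["clamp_current_na"] = self.clamp_current
        pd.DataFrame(cols).to_csv(path, index=False)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("times", data=self.times)
            fh.create_dataset("vm", data=self.vm)
            if self.clamp_current is not None:
                fh.create_dataset("clamp_current", data=self.clamp_current)
            if self.vm_all is not None:
                fh.create_dataset("vm_all", data=self.vm_all)


class CableModel:
    """A morphology plus channel densities, ready to integrate.

    Axial coupling between a compartment and its parent is the series
    resistance of the two half-cylinders; geometry factors are precomputed at
    construction so repeated runs only pay for the step loop.
    """

    def __init__(self, morphology: Morphology, channels: ChannelDensities):
        self.morphology = morphology
        self.channels = channels
        m = morphology
        n = m.n
        area = m.area_cm2  # cm^2
        self._parent = m.parent
        self._cm_nF = channels.cm * area * 1e3  # uF -> nF
        self._g_leak_uS = np.full(n, channels.g_leak) * area * 1e3  # mS -> uS
        self._g_chan_uS = {
            "na_t": channels.g_na_t * area * 1e3,
            "na_p": channels.g_na_p * area * 1e3,
            "ka": channels.g_ka * area * 1e3,
            "kdrf": channels.g_kdrf * area * 1e3,
        }
        # axial conductance to parent, uS
        length_cm = m.length * 1e-4
        radius_cm = m.diameter * 1e-4 / 2.0
        r_half = channels.ra * (length_cm / 2.0) / (math.pi * radius_cm**2)  # Ohm
        g_ax = np.zeros(n)
        parent = self._parent
        for i in range(1, n):
            g_ax[i] = 1e6 / (r_half[i] + r_half[parent[i]])  # uS
        self._g_ax = g_ax
        child_gsum = np.zeros(n)
        for i in range(1, n):
            child_gsum[parent[i]] += g_ax[i]
        self._child_gsum = child_gsum

    @property
    def total_area_cm2(self) -> float:
        return float(np.sum(self.morphology.area_cm2))

    def run(
        self,
        solver: SolverConfig | None = None,
        events: SynapticEvents | None = None,
        injections: tuple[CurrentStep, ...] | list[CurrentStep] = (),
        noise: NoiseConfig | None = None,
        clamp: VoltageClamp | None = None,
        e_leak_override: float | None = None,
        v_init: float | None = None,
        record_all: bool = False,
    ) -> VoltageTrace:
        """Integrate and return the recorded trace.

        Identical arguments (including seeds) give bit-identical traces.
        Raises ``RuntimeError`` with the offending time and compartment if the
        state becomes non-finite.
        """
        cfg = solver or SolverConfig()
        n_steps = cfg.n_steps
        dt = cfg.dt
        ev = events or SynapticEvents.empty()
        ev_step, ev_comp, ev_cls, ev_amt = ev.compiled(dt, n_steps)
        if np.any(ev.tau_d <= ev.tau_r):
            raise ValueError("synaptic tau_d must exceed tau_r")
        syn_fr = np.exp(-dt / ev.tau_r)
        syn_fd = np.exp(-dt / ev.tau_d)

        if noise is not None and noise.enabled and noise.sigma_current > 0:
            rng = np.random.default_rng(noise.seed)
            amp_nA = noise.sigma_current * 1e-3 / math.sqrt(dt)
            noise_arr = amp_nA * rng.standard_normal(n_steps)
        else:
            noise_arr = np.zeros(0)

        inj_comp = np.array([j.compartment for j in injections], dtype=np.int64)
        inj_start = np.array([round(j.start / dt) for j in injections], dtype=np.int64)
        inj_end = np.array([round(j.end / dt) for j in injections], dtype=np.int64)
        inj_amp = np.array([j.amplitude for j in injections], dtype=float)

        e_leak = float(self.channels.e_leak if e_leak_override is None else e_leak_override)
        e_leak_arr = np.full(self.morphology.n, e_leak)
        v0 = float(e_leak if v_init is None else v_init)

        status, err_t, err_comp, rec_v, rec_ic, rec_all = engine.run_kernel(
            self._parent,
            self._g_ax,
            self._child_gsum,
            self._cm_nF / dt,
            self._g_leak_uS,
            e_leak_arr,
            self._g_chan_uS["na_t"],
            self._g_chan_uS["na_p"],
            self._g_chan_uS["ka"],
            self._g_chan_uS["kdrf"],
            E_NA,
            E_K,
            dt,
            n_steps,
            cfg.record_every,
            v0,
            noise_arr,
            inj_comp, inj_start, inj_end, inj_amp,
            ev_step, ev_comp, ev_cls, ev_amt,
            syn_fr, syn_fd, ev.e_rev.astype(float),
            clamp is not None,
            0.0 if clamp is None else float(clamp.v_hold),
            record_all,
        )
        if status == engine.STATUS_NONFINITE:
            raise RuntimeError(
                f"non-finite membrane state at t={err_t:.3f} ms, compartment {err_comp}"
            )
        times = np.arange(len(rec_v)) * cfg.record_every * dt
        return VoltageTrace(
            times,
            rec_v,
            clamp_current=rec_ic if clamp is not None else None,
            vm_all=rec_all if record_all else None,
        )
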