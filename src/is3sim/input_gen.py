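"""Synthetic presynaptic drive: spike trains, synapse selection, theta inputs.

Background trains emulate irregular in-vivo-like afferent activity: a train
of rate ``r`` over a ``T`` ms window is exactly ``round(r*T/1000)`` spike
times sampled uniformly on [0, T] and sorted (the sorted-uniform construction
whose inter-spike intervals are near-exponential). Active synapses are chosen
by unique uniform sampling with the excitatory actives split equally between
proximal and distal zones. Common inputs are groups of synapses sharing one
presynaptic train; grouping a vector of n actives with group size k yields
floor(n/k) full groups plus a remainder group of n mod k.

The theta protocol is fully deterministic: each population fires one spike
per 125 ms cycle (8 Hz) at a fixed quarter-cycle phase offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .solver import SynapticEvents
from .synapses import (
    CLASS_E_REV,
    CLASS_TAU_D,
    CLASS_TAU_R,
    SynapseBank,
    peak_factor,
)

__all__ = [
    "InputScenario",
    "InputAssignment",
    "ThetaPopulation",
    "ThetaProtocol",
    "THETA_COUNTS",
    "sample_spike_train",
    "select_active",
    "group_common",
    "realize_scenario",
    "events_from_assignment",
    "build_theta_protocol",
    "theta_events",
    "scenario_streams",
]

F_E_MAX = 30.0   # Hz
F_I_MAX = 100.0  # Hz
N_E_MAX = 1530
N_I_MAX = 344


@dataclass(frozen=True)
class InputScenario:
    """One point of the input parameter space."""

    f_e: float  # excitatory presynaptic rate, Hz
    f_i: float  # inhibitory presynaptic rate, Hz
    n_e: int    # active excitatory synapses (split equally proximal/distal)
    n_i: int    # active inhibitory synapses
    k_e: int = 1  # excitatory common-input group size (1 = independent)
    k_i: int = 1  # inhibitory common-input group size
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.f_e <= F_E_MAX):
            raise ValueError(f"f_e must be in [0, {F_E_MAX}] Hz")
        if not (0 <= self.f_i <= F_I_MAX):
            raise ValueError(f"f_i must be in [0, {F_I_MAX}] Hz")
        # n_e must additionally be even to realize the equal proximal/distal
        # split; that is enforced at selection time (select_active)
        if not (0 <= self.n_e <= N_E_MAX):
            raise ValueError(f"n_e must be in [0, {N_E_MAX}]")
        if not (0 <= self.n_i <= N_I_MAX):
            raise ValueError(f"n_i must be in [0, {N_I_MAX}]")
        if not (1 <= self.k_e <= 10 and 1 <= self.k_i <= 10):
            raise ValueError("common-input group sizes must be in [1, 10]")


def scenario_streams(seed: int) -> dict[str, np.random.Generator]:
    """Independent named random streams derived from one scenario seed.

    Placement, spike-time and noise streams are separate so protocols can
    re-seed one while holding the others fixed.
    """
    ss = np.random.SeedSequence(seed)
    placement, spikes, noise = ss.spawn(3)
    return {
        "placement": np.random.default_rng(placement),
        "spikes": np.random.default_rng(spikes),
        "noise_seed": int(noise.generate_state(1)[0] % (2**31)),
    }


def sample_spike_train(
    rate: float, duration: float, rng: np.random.Generator | int
) -> np.ndarray:
    """Exactly round(rate*duration/1000) sorted uniform spike times (ms)."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = round(rate * duration / 1000.0)
    return np.sort(rng.uniform(0.0, duration, size=n))


@dataclass
class InputAssignment:
    """Realized drive for one scenario: active slots, groups and trains."""

    scenario: InputScenario
    active_exc_prox: np.ndarray  # slot ids
    active_exc_dist: np.ndarray
    active_inh: np.ndarray
    #: groups of slot ids sharing one train, per stream vector
    groups: dict[str, list[np.ndarray]] = field(default_factory=dict)
    #: slot id -> spike-time array (group members reference the same array)
    trains: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def active_slots(self) -> np.ndarray:
        return np.concatenate(
            [self.active_exc_prox, self.active_exc_dist, self.active_inh]
        )

    def raster_to_csv(self, path) -> None:
        import pandas as pd

        rows = [
            (int(sid), float(t))
            for sid, train in sorted(self.trains.items())
            for t in train
        ]
        pd.DataFrame(rows, columns=["slot_id", "spike_time_ms"]).to_csv(
            path, index=False
        )


def select_active(
    bank: SynapseBank,
    n_e: int,
    n_i: int,
    rng: np.random.Generator | int,
    scenario: InputScenario | None = None,
) -> InputAssignment:
    """Choose active slots by unique uniform sampling.

    ``n_e`` must be even; half the excitatory actives come from each zone.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if n_e % 2:
        raise ValueError("n_e must be even (equal proximal/distal split)")
    prox = np.array([s.slot_id for s in bank.of("excitatory", "proximal")])
    dist = np.array([s.slot_id for s in bank.of("excitatory", "distal")])
    inh = np.array([s.slot_id for s in bank.of("inhibitory")])
    if n_e // 2 > len(prox) or n_e // 2 > len(dist):
        raise ValueError(f"n_e={n_e} exceeds per-zone excitatory capacity")
    if n_i > len(inh):
        raise ValueError(f"n_i={n_i} exceeds inhibitory capacity")
    sc = scenario or InputScenario(0.0, 0.0, n_e, n_i)
    return InputAssignment(
        scenario=sc,
        active_exc_prox=rng.choice(prox, size=n_e // 2, replace=False),
        active_exc_dist=rng.choice(dist, size=n_e // 2, replace=False),
        active_inh=rng.choice(inh, size=n_i, replace=False),
    )


def _partition(ids: np.ndarray, k: int) -> list[np.ndarray]:
    n = len(ids)
    cuts = list(range(0, n, k))
    return [ids[c : c + k] for c in cuts]


def group_common(
    assignment: InputAssignment,
    k_e: int,
    k_i: int,
    rng: np.random.Generator | int,
    duration: float = 10_000.0,
) -> InputAssignment:
    """Partition actives into common-input groups and sample their trains.

    Each kind's active vector splits into floor(n/k) groups of size k plus a
    remainder group (if n mod k > 0); every member of a group references the
    *same* freshly sampled train at the scenario's rate. k = 1 reduces to
    fully independent inputs; k > n leaves a single group of n.
    """
    if k_e < 1 or k_i < 1:
        raise ValueError("group sizes must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    sc = assignment.scenario
    groups: dict[str, list[np.ndarray]] = {}
    trains: dict[int, np.ndarray] = {}
    for name, ids, k, rate in (
        ("exc_prox", assignment.active_exc_prox, k_e, sc.f_e),
        ("exc_dist", assignment.active_exc_dist, k_e, sc.f_e),
        ("inh", assignment.active_inh, k_i, sc.f_i),
    ):
        parts = _partition(np.asarray(ids), k)
        groups[name] = parts
        for part in parts:
            train = sample_spike_train(rate, duration, rng)
            for sid in part:
                trains[int(sid)] = train
    return replace(assignment, groups=groups, trains=trains)


def realize_scenario(
    bank: SynapseBank, scenario: InputScenario, duration: float = 10_000.0
) -> InputAssignment:
    """Select actives and sample trains using the scenario's named streams."""
    streams = scenario_streams(scenario.seed)
    asg = select_active(
        bank, scenario.n_e, scenario.n_i, streams["placement"], scenario
    )
    return group_common(asg, scenario.k_e, scenario.k_i, streams["spikes"], duration)


def events_from_assignment(
    assignment: InputAssignment, bank: SynapseBank
) -> SynapticEvents:
    """Compile an assignment's trains into solver events (amounts in uS)."""
    by_id = {s.slot_id: s for s in bank.slots}
    times, comps, classes, amounts = [], [], [], []
    for sid, train in assignment.trains.items():
        if len(train) == 0:
            continue
        s = by_id[sid]
        amt = s.weight * 1e-3 * peak_factor(s.tau_r, s.tau_d)  # nS -> uS
        times.append(train)
        comps.append(np.full(len(train), s.compartment_id, dtype=np.int64))
        classes.append(np.full(len(train), s.cls, dtype=np.int64))
        amounts.append(np.full(len(train), amt))
    if not times:
        ev = SynapticEvents.empty()
        return replace_taus(ev)
    return SynapticEvents(
        np.concatenate(times),
        np.concatenate(comps),
        np.concatenate(classes),
        np.concatenate(amounts),
        CLASS_TAU_R.copy(),
        CLASS_TAU_D.copy(),
        CLASS_E_REV.copy(),
    )


def replace_taus(ev: SynapticEvents) -> SynapticEvents:
    ev.tau_r = CLASS_TAU_R.copy()
    ev.tau_d = CLASS_TAU_D.copy()
    ev.e_rev = CLASS_E_REV.copy()
    return ev


def merge_events(*event_sets: SynapticEvents) -> SynapticEvents:
    """Concatenate event sets sharing the standard three kinetic classes."""
    sets = [e for e in event_sets if len(e.times)]
    if not sets:
        return replace_taus(SynapticEvents.empty())
    return SynapticEvents(
        np.concatenate([e.times for e in sets]),
        np.concatenate([e.compartments for e in sets]),
        np.concatenate([e.classes for e in sets]),
        np.concatenate([e.amounts for e in sets]),
        CLASS_TAU_R.copy(),
        CLASS_TAU_D.copy(),
        CLASS_E_REV.copy(),
    )


# ---------------------------------------------------------------------------
# Theta protocol
# ---------------------------------------------------------------------------

THETA_FREQ_HZ = 8.0
THETA_PERIOD_MS = 125.0

#: theta-timed synapse counts per (variant, zone, kind)
THETA_COUNTS = {
    "AType+": {("proximal", "excitatory"): 27, ("proximal", "inhibitory"): 8,
               ("distal", "excitatory"): 27, ("distal", "inhibitory"): 8},
    "AType-": {("proximal", "excitatory"): 27, ("proximal", "inhibitory"): 4,
               ("distal", "excitatory"): 18, ("distal", "inhibitory"): 4},
}


@dataclass(frozen=True)
class ThetaPopulation:
    """One theta-locked afferent population firing once per cycle."""

    name: str
    kind: str       # excitatory | inhibitory
    zone: str       # proximal | distal
    phase_deg: float
    n_synapses: int

    def spike_times(self, duration: float) -> np.ndarray:
        offset = self.phase_deg / 360.0 * THETA_PERIOD_MS
        n_cycles = int(duration // THETA_PERIOD_MS)
        return offset + THETA_PERIOD_MS * np.arange(n_cycles)


@dataclass
class ThetaProtocol:
    """Deterministic 8 Hz population drive at quarter-cycle phase offsets.

    CA3 (proximal excitatory) anchors the cycle at 0 deg; CA3-driven
    inhibitory populations follow a quarter cycle later (90 deg); EC3 (distal
    excitatory) at 180 deg; EC3-driven inhibitory populations at 270 deg.
    """

    populations: list[ThetaPopulation]
    frequency: float = THETA_FREQ_HZ
    period: float = THETA_PERIOD_MS


def build_theta_protocol(
    variant: str = "AType+",
    counts: dict | None = None,
) -> ThetaProtocol:
    """Default populations with per-variant synapse counts.

    CA3-driven inhibitory populations (bistratified, IS1) target proximal
    dendrite; EC3-driven ones (neurogliaform, OLM, IS2) target distal.
    """
    c = counts or THETA_COUNTS[variant]
    pops = [
        ThetaPopulation("CA3", "excitatory", "proximal", 0.0,
                        c[("proximal", "excitatory")]),
        ThetaPopulation("bistratified", "inhibitory", "proximal", 90.0,
                        c[("proximal", "inhibitory")]),
        ThetaPopulation("IS1", "inhibitory", "proximal", 90.0,
                        c[("proximal", "inhibitory")]),
        ThetaPopulation("EC3", "excitatory", "distal", 180.0,
                        c[("distal", "excitatory")]),
        ThetaPopulation("neurogliaform", "inhibitory", "distal", 270.0,
                        c[("distal", "inhibitory")]),
        ThetaPopulation("OLM", "inhibitory", "distal", 270.0,
                        c[("distal", "inhibitory")]),
        ThetaPopulation("IS2", "inhibitory", "distal", 270.0,
                        c[("distal", "inhibitory")]),
    ]
    return ThetaProtocol(pops)


def theta_events(
    protocol: ThetaProtocol, bank: SynapseBank, duration: float = 10_000.0
) -> SynapticEvents:
    """Compile the protocol into solver events on deterministic bank slots.

    Theta synapses are chosen deterministically - evenly strided through the
    population's kind/zone slot list, so they spread over the dendritic tree
    rather than clustering on one branch - and hence the protocol adds no
    randomness beyond the background scenario. Raises if the duration is not
    a whole number of cycles or a population's zone has too few slots.
    """
    if abs(duration % THETA_PERIOD_MS) > 1e-9:
        raise ValueError("duration must be a multiple of the 125 ms theta period")
    times, comps, classes, amounts = [], [], [], []
    available: dict[tuple[str, str], list] = {}
    for pop in protocol.populations:
        key = (pop.kind, pop.zone)
        if key not in available:
            available[key] = sorted(bank.of(*key), key=lambda s: s.slot_id)
        pool = available[key]
        if len(pool) < pop.n_synapses:
            raise ValueError(f"not enough {pop.zone} {pop.kind} slots for {pop.name}")
        picks = [(j * len(pool)) // pop.n_synapses for j in range(pop.n_synapses)]
        chosen = [pool[j] for j in picks]
        available[key] = [s for i, s in enumerate(pool) if i not in set(picks)]
        train = pop.spike_times(duration)
        for s in chosen:
            amt = s.weight * 1e-3 * peak_factor(s.tau_r, s.tau_d)
            times.append(train)
            comps.append(np.full(len(train), s.compartment_id, dtype=np.int64))
            classes.append(np.full(len(train), s.cls, dtype=np.int64))
            amounts.append(np.full(len(train), amt))
    if not times:
        return replace_taus(SynapticEvents.empty())
    return SynapticEvents(
        np.concatenate(times),
        np.concatenate(comps),
        np.concatenate(classes),
        np.concatenate(amounts),
        CLASS_TAU_R.copy(),
        CLASS_TAU_D.copy(),
        CLASS_E_REV.copy(),
    )
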