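"""Two-exponential synapses: distance-dependent weights, kinetics, the bank.

Each synapse is a two-state kinetic scheme whose conductance after a spike at
t0 is

    g(t) = weight * factor * (exp(-(t-t0)/tau_d) - exp(-(t-t0)/tau_r))

with ``factor`` normalizing the single-event peak to ``weight``. Synaptic
current is i = g (V - E_R), positive outward. Weights grow linearly with path
distance from the soma (fits to layer-specific evoked EPSCs and spontaneous
IPSCs on IS3 cells); rise/decay time constants are fixed per class
(proximal-excitatory, distal-excitatory, inhibitory).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .morphology import Morphology, PROXIMAL_BOUNDARY_UM

__all__ = [
    "E_REV_EXC", "E_REV_INH",
    "CLS_EXC_PROX", "CLS_EXC_DIST", "CLS_INH",
    "CLASS_TAU_R", "CLASS_TAU_D", "CLASS_E_REV",
    "EXC_PER_COMPARTMENT",
    "excitatory_weight", "inhibitory_weight",
    "peak_time", "peak_factor", "conductance_kernel", "synaptic_current",
    "SynapseSpec", "SynapseBank", "build_synapse_bank",
]

E_REV_EXC = 0.0    # mV
E_REV_INH = -70.0  # mV

# kinetic class ids (fixed order used by the solver's event arrays)
CLS_EXC_PROX = 0
CLS_EXC_DIST = 1
CLS_INH = 2

#: optimized (tau_r, tau_d) per class, ms
CLASS_TAU_R = np.array([2.9936e-4, 6.1871e-4, 0.1013])
CLASS_TAU_D = np.array([2.4216, 3.1975, 4.8216])
CLASS_E_REV = np.array([E_REV_EXC, E_REV_EXC, E_REV_INH])

#: excitatory synapse slots per dendritic compartment
EXC_PER_COMPARTMENT = 9
#: total inhibitory slots on the default fixture (2 per compartment + remainder)
INH_TOTAL = 344

_EXC_SLOPE = 0.00230814   # nS/um
_EXC_INTERCEPT = 0.22016666  # nS
_INH_SLOPE = 0.00469125   # nS/um
_INH_INTERCEPT = 0.2695779   # nS


def excitatory_weight(path_distance: float) -> float:
    """Linear distance-dependent excitatory weight (nS)."""
    if np.any(np.asarray(path_distance) < 0):
        raise ValueError("path_distance must be non-negative")
    return _EXC_SLOPE * path_distance + _EXC_INTERCEPT


def inhibitory_weight(path_distance: float) -> float:
    """Linear distance-dependent inhibitory weight (nS)."""
    if np.any(np.asarray(path_distance) < 0):
        raise ValueError("path_distance must be non-negative")
    return _INH_SLOPE * path_distance + _INH_INTERCEPT


def peak_time(tau_r: float, tau_d: float) -> float:
    """Time to peak of a single two-exponential event (ms)."""
    return tau_r * tau_d / (tau_d - tau_r) * math.log(tau_d / tau_r)


def peak_factor(tau_r: float, tau_d: float) -> float:
    """Normalization so a single event peaks exactly at ``weight``."""
    if tau_d <= tau_r:
        raise ValueError("tau_d must exceed tau_r")
    tp = peak_time(tau_r, tau_d)
    return 1.0 / (math.exp(-tp / tau_d) - math.exp(-tp / tau_r))


def synaptic_current(g_nS: float, v: float, e_rev: float) -> float:
    """i = g (V - E_R) in nA for g in nS; positive = outward."""
    return g_nS * 1e-3 * (v - e_rev)


@dataclass(frozen=True)
class SynapseSpec:
    """One synapse slot: location, class, weight and kinetics."""

    slot_id: int
    compartment_id: int
    kind: str           # "excitatory" | "inhibitory"
    zone: str           # "proximal" | "distal" (by the 300 um boundary)
    distance: float     # um
    weight: float       # nS
    tau_r: float        # ms
    tau_d: float        # ms
    e_rev: float        # mV

    def __post_init__(self) -> None:
        if not (self.tau_d > self.tau_r > 0):
            raise ValueError("require tau_d > tau_r > 0")
        if self.weight <= 0:
            raise ValueError("weight must be positive")

    @property
    def cls(self) -> int:
        if self.kind == "inhibitory":
            return CLS_INH
        return CLS_EXC_PROX if self.zone == "proximal" else CLS_EXC_DIST


def assign_kinetics(spec: SynapseSpec) -> SynapseSpec:
    """Fix the slot's time constants to its class's optimized values."""
    c = CLS_INH if spec.kind == "inhibitory" else (
        CLS_EXC_PROX if spec.zone == "proximal" else CLS_EXC_DIST
    )
    return replace(spec, tau_r=float(CLASS_TAU_R[c]), tau_d=float(CLASS_TAU_D[c]))


def conductance_kernel(spec: SynapseSpec, spike_times, t_grid) -> np.ndarray:
    """Summed conductance (nS) of ``spec`` over ``t_grid`` for the given spikes."""
    t_grid = np.asarray(t_grid, dtype=float)
    g = np.zeros_like(t_grid)
    f = peak_factor(spec.tau_r, spec.tau_d)
    for t0 in np.asarray(spike_times, dtype=float):
        dt = t_grid - t0
        m = dt >= 0
        g[m] += spec.weight * f * (
            np.exp(-dt[m] / spec.tau_d) - np.exp(-dt[m] / spec.tau_r)
        )
    return g


@dataclass
class SynapseBank:
    """The cell's full synapse complement, indexed by slot id."""

    slots: list[SynapseSpec]

    def __len__(self) -> int:
        return len(self.slots)

    def of(self, kind: str, zone: str | None = None) -> list[SynapseSpec]:
        out = [s for s in self.slots if s.kind == kind]
        if zone is not None:
            out = [s for s in out if s.zone == zone]
        return out

    @property
    def n_excitatory(self) -> int:
        return len(self.of("excitatory"))

    @property
    def n_inhibitory(self) -> int:
        return len(self.of("inhibitory"))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "slot_id": s.slot_id,
                    "compartment_id": s.compartment_id,
                    "kind": s.kind,
                    "zone": s.zone,
                    "distance": s.distance,
                    "weight": s.weight,
                    "tau_r": s.tau_r,
                    "tau_d": s.tau_d,
                    "e_rev": s.e_rev,
                }
                for s in self.slots
            ]
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def build_synapse_bank(m: Morphology) -> SynapseBank:
    """Deterministically populate every synapse slot on the dendritic tree.

    Nine excitatory slots per dendritic compartment; 344 inhibitory slots
    spread round-robin (2 per compartment, the first compartments picking up
    the remainder). Weights follow the linear distance rules, kinetics the
    per-class optimized constants. Synapses sit at compartment midpoints, so
    their distance is the compartment's path distance.
    """
    dend = m.dendrite_ids
    if len(dend) == 0:
        raise ValueError("morphology has no dendritic compartments")
    path = m.path_distance
    slots: list[SynapseSpec] = []

    def zone_of(d: float) -> str:
        return "proximal" if d < PROXIMAL_BOUNDARY_UM else "distal"

    sid = 0
    for cid in dend:
        d = float(path[cid])
        z = zone_of(d)
        c = CLS_EXC_PROX if z == "proximal" else CLS_EXC_DIST
        for _ in range(EXC_PER_COMPARTMENT):
            slots.append(
                SynapseSpec(
                    sid, int(cid), "excitatory", z, d,
                    excitatory_weight(d),
                    float(CLASS_TAU_R[c]), float(CLASS_TAU_D[c]), E_REV_EXC,
                )
            )
            sid += 1

    n_dend = len(dend)
    base, extra = divmod(INH_TOTAL, n_dend)
    for j, cid in enumerate(dend):
        d = float(path[cid])
        count = base + (1 if j < extra else 0)
        for _ in range(count):
            slots.append(
                SynapseSpec(
                    sid, int(cid), "inhibitory", zone_of(d), d,
                    inhibitory_weight(d),
                    float(CLASS_TAU_R[CLS_INH]), float(CLASS_TAU_D[CLS_INH]),
                    E_REV_INH,
                )
            )
            sid += 1
    return SynapseBank(slots)
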