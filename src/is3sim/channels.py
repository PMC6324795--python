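"""Channel-density layouts for the two IS3 model variants.

Two variants are supported, differing in whether the A-type potassium
conductance extends into the dendrites:

* ``AType+``: G_Na,t, G_Ka and G_Kdrf uniform over the soma and the first
  70 um of dendrite; G_Na,p at the soma only.
* ``AType-``: G_Na,t and G_Kdrf uniform over the soma and the first 70 um of
  dendrite; G_Na,p *and* G_Ka at the soma only.

Active conductances are zero beyond 70 um of dendritic path distance and in
the axon initial segment. The leak conductance is uniform and is the knob the
passive calibration turns (see :mod:`is3sim.calibrate`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .morphology import Morphology, REGION_DEND, REGION_SOMA

__all__ = ["VARIANTS", "VariantDensities", "ChannelDensities", "assign_channels",
           "ACTIVE_DENDRITE_EXTENT_UM"]

#: Dendritic path distance (um) up to which active channels are inserted.
ACTIVE_DENDRITE_EXTENT_UM = 70.0


@dataclass(frozen=True)
class VariantDensities:
    """Maximal conductance densities (mS/cm^2) for one model variant."""

    g_na_t: float
    g_na_p: float
    g_ka: float
    g_kdrf: float
    ka_soma_only: bool


VARIANTS: dict[str, VariantDensities] = {
    "AType+": VariantDensities(70.0, 0.075, 70.0, 250.0, ka_soma_only=False),
    "AType-": VariantDensities(55.0, 0.15, 30.0, 295.0, ka_soma_only=True),
}


@dataclass
class ChannelDensities:
    """Per-compartment maximal conductances plus passive parameters.

    Conductance densities are in mS/cm^2 (as usually tabulated); membrane
    capacitance in uF/cm^2, axial resistivity in Ohm*cm.
    """

    g_na_t: np.ndarray
    g_na_p: np.ndarray
    g_ka: np.ndarray
    g_kdrf: np.ndarray
    g_leak: float = 0.02  # mS/cm^2, pre-calibration default
    e_leak: float = -70.0  # mV
    cm: float = 1.0  # uF/cm^2
    ra: float = 300.0  # Ohm*cm

    def __post_init__(self) -> None:
        for name in ("g_na_t", "g_na_p", "g_ka", "g_kdrf"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")
            setattr(self, name, arr)
        if self.g_leak < 0:
            raise ValueError("g_leak must be non-negative")

    def passive_copy(self) -> "ChannelDensities":
        """All active conductances zeroed (used by clamp protocols)."""
        z = np.zeros_like(self.g_na_t)
        return replace(self, g_na_t=z, g_na_p=z.copy(), g_ka=z.copy(), g_kdrf=z.copy())


def assign_channels(
    m: Morphology,
    variant: str,
    densities: VariantDensities | None = None,
) -> ChannelDensities:
    """Distribute the variant's maximal conductances over the tree.

    Raises ``ValueError`` for an unknown variant name.
    """
    if densities is None:
        try:
            densities = VARIANTS[variant]
        except KeyError:
            raise ValueError(
                f"unknown variant {variant!r}; expected one of {sorted(VARIANTS)}"
            ) from None

    n = m.n
    path = m.path_distance
    region = m.region
    soma = region == REGION_SOMA
    active_dend = (region == REGION_DEND) & (path <= ACTIVE_DENDRITE_EXTENT_UM)
    uniform = soma | active_dend

    g_na_t = np.where(uniform, densities.g_na_t, 0.0)
    g_kdrf = np.where(uniform, densities.g_kdrf, 0.0)
    g_na_p = np.where(soma, densities.g_na_p, 0.0)
    if densities.ka_soma_only:
        g_ka = np.where(soma, densities.g_ka, 0.0)
    else:
        g_ka = np.where(uniform, densities.g_ka, 0.0)
    return ChannelDensities(g_na_t=g_na_t, g_na_p=g_na_p, g_ka=g_ka, g_kdrf=g_kdrf)
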