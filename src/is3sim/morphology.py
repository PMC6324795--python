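"""Reduced IS3-like morphologies: compartment trees, the synthetic fixture, SWC I/O.

The package works on a rooted tree of cylindrical compartments. The default
*fixture* morphology is a synthetic stand-in for a reconstructed IS3 cell
(interneuron-specific type 3, hippocampal CA1): one somatic compartment, a
50-compartment axon initial segment (AIS), and ten unbranched dendrites whose
170 compartments split exactly 85/85 around the 300 um proximal/distal
boundary that separates stratum radiatum from stratum lacunosum-moleculare
input zones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PROXIMAL_BOUNDARY_UM",
    "Compartment",
    "Morphology",
    "FixtureConfig",
    "build_fixture_morphology",
    "write_swc",
    "read_swc",
]

#: Path distance (um) separating proximal from distal dendrite.
PROXIMAL_BOUNDARY_UM = 300.0

REGION_SOMA = "soma"
REGION_AIS = "AIS"
REGION_DEND = "dendrite"

_REGION_TO_SWC = {REGION_SOMA: 1, REGION_AIS: 2, REGION_DEND: 3}
_SWC_TO_REGION = {1: REGION_SOMA, 2: REGION_AIS, 3: REGION_DEND, 4: REGION_DEND}


@dataclass(frozen=True, slots=True)
class Compartment:
    """One cylindrical compartment.

    ``path_distance`` is measured from the soma center to the compartment
    midpoint along the tree (um); the soma itself sits at 0.
    """

    id: int
    parent_id: int | None
    length: float  # um
    diameter: float  # um
    path_distance: float  # um
    region: str

    @property
    def area_um2(self) -> float:
        """Lateral membrane area (um^2); the soma is treated as a cylinder."""
        return math.pi * self.diameter * self.length


@dataclass
class Morphology:
    """An ordered compartment tree with parent ids always below child ids."""

    compartments: list[Compartment]
    #: optional 3D anchor per compartment (distal endpoint), used for SWC I/O
    _xyz: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- array views ------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.compartments)

    @property
    def parent(self) -> np.ndarray:
        """Parent index per compartment; -1 for the root."""
        return np.array(
            [-1 if c.parent_id is None else c.parent_id for c in self.compartments],
            dtype=np.int64,
        )

    @property
    def length(self) -> np.ndarray:
        return np.array([c.length for c in self.compartments])

    @property
    def diameter(self) -> np.ndarray:
        return np.array([c.diameter for c in self.compartments])

    @property
    def path_distance(self) -> np.ndarray:
        return np.array([c.path_distance for c in self.compartments])

    @property
    def region(self) -> np.ndarray:
        return np.array([c.region for c in self.compartments], dtype=object)

    @property
    def area_cm2(self) -> np.ndarray:
        return np.array([c.area_um2 * 1e-8 for c in self.compartments])

    # -- classification ---------------------------------------------------
    def mask(self, region: str) -> np.ndarray:
        return self.region == region

    @property
    def dendrite_ids(self) -> np.ndarray:
        return np.flatnonzero(self.mask(REGION_DEND))

    @property
    def proximal_dendrite_ids(self) -> np.ndarray:
        m = self.mask(REGION_DEND) & (self.path_distance < PROXIMAL_BOUNDARY_UM)
        return np.flatnonzero(m)

    @property
    def distal_dendrite_ids(self) -> np.ndarray:
        m = self.mask(REGION_DEND) & (self.path_distance >= PROXIMAL_BOUNDARY_UM)
        return np.flatnonzero(m)

    def counts_by_region(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.compartments:
            out[c.region] = out.get(c.region, 0) + 1
        return out

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        comps = self.compartments
        if not comps:
            raise ValueError("morphology has no compartments")
        roots = [c for c in comps if c.parent_id is None]
        if len(roots) != 1 or roots[0].id != 0 or roots[0].region != REGION_SOMA:
            raise ValueError("exactly one root (the soma, id 0) is required")
        if roots[0].path_distance != 0.0:
            raise ValueError("soma path_distance must be 0")
        seen = set()
        for i, c in enumerate(comps):
            if c.id != i:
                raise ValueError(f"compartment ids must be 0..n-1 in order, got {c.id} at {i}")
            if c.parent_id is not None:
                if c.parent_id >= c.id or c.parent_id not in seen:
                    raise ValueError("parent ids must precede child ids")
                if c.path_distance <= comps[c.parent_id].path_distance:
                    raise ValueError(
                        f"path_distance must increase from parent to child (id {c.id})"
                    )
            seen.add(c.id)


@dataclass(frozen=True)
class FixtureConfig:
    """Geometry of the synthetic fixture morphology.

    The defaults give 1 + 50 + 170 = 221 compartments, with the 170 dendritic
    compartments split exactly 85 proximal / 85 distal around the 300 um
    boundary. Within each dendrite, compartment lengths are uniform within the
    proximal span [0, 300] um and within the distal span [300, L] um; half the
    dendrites carry 9 proximal + 8 distal compartments and half 8 + 9, which
    is what makes the global split exact.
    """

    n_dendrites: int = 10
    comps_per_dendrite: int = 17
    dendrite_length: float = 425.0  # um
    dendrite_diameter: float = 1.0  # um at the soma end
    dendrite_tip_diameter: float = 0.4  # um; linear taper along each dendrite
    n_ais: int = 50
    ais_length: float = 1.0  # um per compartment
    ais_diameter: float = 1.0  # um
    soma_length: float = 10.0  # um
    soma_diameter: float = 10.0  # um

    @property
    def total_compartments(self) -> int:
        return 1 + self.n_ais + self.n_dendrites * self.comps_per_dendrite


def build_fixture_morphology(config: FixtureConfig | None = None) -> Morphology:
    """Deterministically build the synthetic fixture tree.

    Raises ``ValueError`` if the configured dendrite length cannot reach past
    the 300 um proximal/distal boundary.
    """
    cfg = config or FixtureConfig()
    if cfg.dendrite_length <= PROXIMAL_BOUNDARY_UM:
        raise ValueError(
            f"dendrite_length {cfg.dendrite_length} um cannot reach beyond the "
            f"{PROXIMAL_BOUNDARY_UM} um proximal/distal boundary"
        )
    if cfg.comps_per_dendrite < 2:
        raise ValueError("need at least 2 compartments per dendrite")

    comps: list[Compartment] = []
    xyz: list[tuple[float, float, float]] = []
    comps.append(
        Compartment(0, None, cfg.soma_length, cfg.soma_diameter, 0.0, REGION_SOMA)
    )
    xyz.append((0.0, 0.0, 0.0))

    # AIS: straight chain along -z
    parent = 0
    dist = 0.0
    for _ in range(cfg.n_ais):
        cid = len(comps)
        comps.append(
            Compartment(
                cid, parent, cfg.ais_length, cfg.ais_diameter,
                dist + cfg.ais_length / 2.0, REGION_AIS,
            )
        )
        dist += cfg.ais_length
        xyz.append((0.0, 0.0, -dist))
        parent = cid

    # Dendrites: unbranched chains radiating in the xy plane
    for k in range(cfg.n_dendrites):
        n_prox = (cfg.comps_per_dendrite + (k % 2)) // 2
        n_dist = cfg.comps_per_dendrite - n_prox
        l_prox = PROXIMAL_BOUNDARY_UM / n_prox
        l_dist = (cfg.dendrite_length - PROXIMAL_BOUNDARY_UM) / n_dist
        theta = 2.0 * math.pi * k / cfg.n_dendrites
        ux, uy = math.cos(theta), math.sin(theta)
        parent = 0
        dist = 0.0
        for j in range(cfg.comps_per_dendrite):
            seg = l_prox if j < n_prox else l_dist
            cid = len(comps)
            mid = dist + seg / 2.0
            diam = cfg.dendrite_diameter + (
                cfg.dendrite_tip_diameter - cfg.dendrite_diameter
            ) * mid / cfg.dendrite_length
            comps.append(
                Compartment(cid, parent, seg, diam, mid, REGION_DEND)
            )
            dist += seg
            xyz.append((ux * dist, uy * dist, 0.0))
            parent = cid

    return Morphology(comps, _xyz=np.asarray(xyz))


# ---------------------------------------------------------------------------
# SWC serialization. Nodes are written at compartment *distal endpoints*
# (soma at the origin as a single node); lengths and path distances are
# recovered from inter-node euclidean distances on read, which is lossless
# for trees built from straight chains.
# ---------------------------------------------------------------------------

def write_swc(m: Morphology, path) -> None:
    if m._xyz is None:
        raise ValueError("morphology carries no 3D anchors; cannot write SWC")
    with open(path, "w") as fh:
        fh.write("# generated by is3sim (synthetic fixture morphology)\n")
        fh.write("# columns: id type x y z radius parent\n")
        for c in m.compartments:
            x, y, z = (float(v) for v in m._xyz[c.id])
            swc_type = _REGION_TO_SWC[c.region]
            parent = -1 if c.parent_id is None else c.parent_id + 1
            fh.write(
                f"{c.id + 1} {swc_type} {x!r} {y!r} {z!r} {c.diameter / 2.0!r} {parent}\n"
            )


def read_swc(path) -> Morphology:
    """Read an SWC file into a :class:`Morphology`.

    Nodes are re-indexed so parents precede children; the first (root) node
    becomes the soma. Each non-root node is interpreted as the distal endpoint
    of a cylindrical compartment extending from its parent node.
    """
    rows: dict[int, tuple[int, float, float, float, float, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            nid, ntype = int(parts[0]), int(parts[1])
            x, y, z, r = (float(p) for p in parts[2:6])
            parent = int(parts[6])
            rows[nid] = (ntype, x, y, z, r, parent)
    if not rows:
        raise ValueError(f"no SWC records in {path}")

    roots = [nid for nid, r in rows.items() if r[5] == -1]
    if len(roots) != 1:
        raise ValueError(f"expected exactly one SWC root, found {len(roots)}")

    # topological order (parents first)
    order: list[int] = []
    children: dict[int, list[int]] = {}
    for nid, r in rows.items():
        children.setdefault(r[5], []).append(nid)
    stack = [roots[0]]
    while stack:
        nid = stack.pop()
        order.append(nid)
        for ch in sorted(children.get(nid, []), reverse=True):
            stack.append(ch)
    if len(order) != len(rows):
        raise ValueError("SWC tree is not connected")
    new_id = {nid: i for i, nid in enumerate(order)}

    comps: list[Compartment] = []
    xyz = np.zeros((len(order), 3))
    path_dist = np.zeros(len(order))
    for i, nid in enumerate(order):
        ntype, x, y, z, r, parent = rows[nid]
        xyz[i] = (x, y, z)
        region = _SWC_TO_REGION.get(ntype, REGION_DEND)
        if i == 0:
            comps.append(Compartment(0, None, 2.0 * r, 2.0 * r, 0.0, REGION_SOMA))
            continue
        pi = new_id[parent]
        seg = float(np.linalg.norm(xyz[i] - xyz[pi]))
        if seg <= 0:
            raise ValueError(f"zero-length SWC segment at node {nid}")
        path_dist[i] = path_dist[pi] + seg
        comps.append(
            Compartment(i, pi, seg, 2.0 * r, path_dist[i] - seg / 2.0, region)
        )
    return Morphology(comps, _xyz=xyz)
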