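"""Geometrically embedded habitat networks: ring lattices and rewired variants.

Habitat patches (nodes) sit on a fixed ring; movement corridors (links) have
physical lengths set by the ring step between their endpoints, not by the
Euclidean chord.  A lattice connects every node to its four nearest ring
neighbours (steps 1 and 2).  Rewiring detaches one endpoint of a link and
reattaches it to a random node, trading regular spatial structure for random
structure while conserving the link count; because node positions are fixed,
rewiring changes link lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

__all__ = [
    "DEFAULT_STEP_LENGTHS",
    "StepLengthTable",
    "SpatialHabitatNetwork",
    "make_ring_coordinates",
    "step_distance",
    "build_lattice",
    "rewire",
    "generate_topology_set",
]

#: Tube length (mm) per ring step for the default 10-node geometry.  Steps 1,
#: 2 and 5 (15, 90, 190 mm) are the published corridor lengths of the arenas
#: this geometry mimics; steps 3 and 4 are not published and are calibrated
#: against the realized ring-step distribution of the rewiring generator so
#: that partially rewired (20%) networks average 65 mm of tube per link, the
#: published figure (see docs/methods.md for the calibration and its limits).
DEFAULT_STEP_LENGTHS = {1: 15, 2: 90, 3: 100, 4: 102, 5: 190}


class StepLengthTable:
    """Map from ring step k (1..n//2) to corridor tube length in mm.

    Lengths must be strictly increasing in the step: a corridor spanning a
    larger ring step is physically longer.
    """

    def __init__(self, lengths: dict[int, float] | None = None):
        lengths = dict(DEFAULT_STEP_LENGTHS if lengths is None else lengths)
        steps = sorted(lengths)
        if steps != list(range(1, len(steps) + 1)):
            raise ValueError(f"steps must be contiguous from 1, got {steps}")
        vals = [lengths[k] for k in steps]
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("step lengths must be strictly increasing in step")
        if any(v <= 0 for v in vals):
            raise ValueError("step lengths must be positive")
        self._lengths = {k: lengths[k] for k in steps}

    @property
    def max_step(self) -> int:
        return len(self._lengths)

    def __getitem__(self, step: int) -> float:
        return self._lengths[step]

    def __eq__(self, other) -> bool:
        return isinstance(other, StepLengthTable) and self._lengths == other._lengths

    def __repr__(self) -> str:
        return f"StepLengthTable({self._lengths})"

    def as_dict(self) -> dict[int, float]:
        return dict(self._lengths)


@dataclass(frozen=True)
class SpatialHabitatNetwork:
    """A habitat network with fixed ring geometry and physical link lengths."""

    n_nodes: int
    coords: np.ndarray = field(repr=False)  # (n, 2) positions in mm, presentational
    links: tuple[tuple[int, int], ...]  # sorted unordered pairs
    link_lengths: tuple[float, ...]  # mm, aligned with links
    config_label: str  # lattice | partial | random
    rewire_fraction: float
    topology_id: str
    step_table: StepLengthTable = field(repr=False, default_factory=StepLengthTable)
    #: number of links selected for rewiring when this network was generated
    #: (None for networks not produced by `rewire`)
    n_rewired: int | None = field(default=None, compare=False)

    def __post_init__(self):
        if len(self.links) != len(self.link_lengths):
            raise ValueError("links and link_lengths must align")
        for a, b in self.links:
            if a == b:
                raise ValueError(f"self-loop at node {a}")
            if not (0 <= a < self.n_nodes and 0 <= b < self.n_nodes):
                raise ValueError(f"link ({a},{b}) references unknown node")
            if a > b:
                raise ValueError("links must be stored as sorted pairs")
        if len(set(self.links)) != len(self.links):
            raise ValueError("duplicate links")

    @property
    def n_links(self) -> int:
        return len(self.links)

    @property
    def edge_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(self.links)

    @property
    def mean_link_length(self) -> float:
        return float(np.mean(self.link_lengths))

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for a, b in self.links:
            deg[a] += 1
            deg[b] += 1
        return deg

    def neighbor_lists(self) -> list[np.ndarray]:
        """Per-node arrays of neighbour ids (sorted), aligned with lengths_to()."""
        nbrs: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for a, b in self.links:
            nbrs[a].append(b)
            nbrs[b].append(a)
        return [np.array(sorted(x), dtype=np.int64) for x in nbrs]

    def length_of(self, a: int, b: int) -> float:
        key = (a, b) if a < b else (b, a)
        return self.link_lengths[self.links.index(key)]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(
            config_label=self.config_label,
            rewire_fraction=self.rewire_fraction,
            topology_id=self.topology_id,
        )
        for i in range(self.n_nodes):
            g.add_node(i, x_mm=float(self.coords[i, 0]), y_mm=float(self.coords[i, 1]))
        for (a, b), w in zip(self.links, self.link_lengths):
            g.add_edge(a, b, length_mm=float(w))
        return g

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx())


def make_ring_coordinates(n_nodes: int, spacing: float) -> np.ndarray:
    """Place ``n_nodes`` equally on a circle with ``spacing`` mm between ring
    neighbours.

    Node 0 sits at angle 0 and indices run counter-clockwise.  Coordinates are
    presentational (plots, serialisation); corridor lengths come from the
    :class:`StepLengthTable`, never from chord distances.
    """
    if n_nodes < 3:
        raise ValueError(f"need at least 3 nodes for a ring, got {n_nodes}")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    radius = spacing / (2.0 * np.sin(np.pi / n_nodes))
    theta = 2.0 * np.pi * np.arange(n_nodes) / n_nodes
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])


def ring_step(i: int, j: int, n: int) -> int:
    """Circular distance between node indices on an n-ring."""
    d = abs(i - j) % n
    return min(d, n - d)


def step_distance(i: int, j: int, table: StepLengthTable, n: int) -> float:
    """Corridor length (mm) between nodes i and j given the ring geometry."""
    if i == j:
        raise ValueError("distance from a node to itself is undefined")
    k = ring_step(i, j, n)
    if k > table.max_step:
        raise ValueError(f"step table covers steps 1..{table.max_step}, need {k}")
    return table[k]


def build_lattice(
    n_nodes: int = 10, table: StepLengthTable | None = None, spacing: float = 15.0
) -> SpatialHabitatNetwork:
    """Circulant ring lattice: every node linked to ring steps 1 and 2.

    Yields 2n links and uniform degree 4 (for n=5 the steps exhaust all pairs
    and the result is the complete graph K5 with 10 links).
    """
    if n_nodes < 5:
        raise ValueError("lattice needs n >= 5 so that steps 1 and 2 are distinct")
    table = table if table is not None else StepLengthTable()
    links: list[tuple[int, int]] = []
    for k in (1, 2):
        for i in range(n_nodes):
            j = (i + k) % n_nodes
            links.append((min(i, j), max(i, j)))
    links = sorted(set(links))
    lengths = tuple(step_distance(a, b, table, n_nodes) for a, b in links)
    return SpatialHabitatNetwork(
        n_nodes=n_nodes,
        coords=make_ring_coordinates(n_nodes, spacing),
        links=tuple(links),
        link_lengths=lengths,
        config_label="lattice",
        rewire_fraction=0.0,
        topology_id="lattice",
        step_table=table,
    )


def _label_for_fraction(fraction: float) -> str:
    if fraction == 0.0:
        return "lattice"
    if fraction == 1.0:
        return "random"
    return "partial"


def rewire(
    net: SpatialHabitatNetwork,
    fraction: float,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> SpatialHabitatNetwork:
    """Independently rewire each link with probability ``fraction``.

    A rewired link keeps one uniformly chosen endpoint; the other endpoint is
    reattached to a node drawn uniformly at random, resampling on self-loops,
    duplicate links and the original pair (a selected link always changes).  Lengths are recomputed from the ring geometry.  A
    draw that disconnects the network is discarded and the whole network is
    resampled, so the output is always connected with the same node and link
    counts.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if fraction == 0.0:
        return net
    n = net.n_nodes
    for _ in range(max_attempts):
        edge_set = set(net.links)
        links = list(net.links)
        selected = rng.random(len(links)) < fraction
        ok = True
        for idx in np.nonzero(selected)[0]:
            a, b = links[idx]
            keep = a if rng.random() < 0.5 else b
            edge_set.discard((a, b))
            new_edge = None
            for _try in range(200):
                target = int(rng.integers(n))
                if target == keep:
                    continue
                cand = (min(keep, target), max(keep, target))
                if cand == (a, b) or cand in edge_set:
                    continue
                new_edge = cand
                break
            if new_edge is None:  # pragma: no cover - cap exhaustion
                ok = False
                break
            edge_set.add(new_edge)
            links[idx] = new_edge
        if not ok:
            continue
        links_sorted = tuple(sorted(edge_set))
        g = nx.Graph(links_sorted)
        g.add_nodes_from(range(n))
        if not nx.is_connected(g):
            continue
        lengths = tuple(step_distance(a, b, net.step_table, n) for a, b in links_sorted)
        return replace(
            net,
            links=links_sorted,
            link_lengths=lengths,
            config_label=_label_for_fraction(fraction),
            rewire_fraction=fraction,
            topology_id=f"{_label_for_fraction(fraction)}",
            n_rewired=int(selected.sum()),
        )
    raise RuntimeError(f"could not generate a connected rewired network in {max_attempts} attempts")


def generate_topology_set(
    seed: int,
    n_nodes: int = 10,
    n_partial: int = 8,
    n_random: int = 8,
    partial_fraction: float = 0.2,
    table: StepLengthTable | None = None,
    max_attempts: int = 1000,
) -> list[SpatialHabitatNetwork]:
    """One lattice plus ``n_partial`` partially rewired and ``n_random`` fully
    rewired networks, all pairwise distinct as labelled edge sets.

    Deterministic given ``seed``; duplicates are resampled.
    """
    rng = np.random.default_rng(seed)
    lattice = build_lattice(n_nodes, table)
    nets = [lattice]
    seen = {lattice.edge_set}
    for label, fraction, count in (
        ("partial", partial_fraction, n_partial),
        ("random", 1.0, n_random),
    ):
        made = 0
        for _ in range(max_attempts):
            if made == count:
                break
            cand = rewire(lattice, fraction, rng)
            if cand.edge_set in seen:
                continue
            made += 1
            seen.add(cand.edge_set)
            nets.append(replace(cand, topology_id=f"{label}-{made}"))
        if made < count:  # pragma: no cover - cap exhaustion
            raise RuntimeError(f"could not generate {count} unique {label} networks")
    return nets
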