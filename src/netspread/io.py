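"""Reading and writing habitat networks (CSV pair and GraphML)."""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .networks import SpatialHabitatNetwork, StepLengthTable, make_ring_coordinates

__all__ = [
    "write_network_csv",
    "read_network_csv",
    "write_network_graphml",
    "read_network_graphml",
]


def write_network_csv(net: SpatialHabitatNetwork, nodes_path, edges_path) -> None:
    """Write the node table (node_id,x_mm,y_mm) and edge list
    (node_a,node_b,length_mm)."""
    nodes = pd.DataFrame(
        {
            "node_id": np.arange(net.n_nodes),
            "x_mm": net.coords[:, 0],
            "y_mm": net.coords[:, 1],
        }
    )
    edges = pd.DataFrame(
        {
            "node_a": [a for a, _ in net.links],
            "node_b": [b for _, b in net.links],
            "length_mm": [float(w) for w in net.link_lengths],
        }
    )
    nodes.to_csv(nodes_path, index=False, float_format="%.6f")
    edges.to_csv(edges_path, index=False, float_format="%.6f")


def read_network_csv(
    nodes_path,
    edges_path,
    config_label: str = "unknown",
    rewire_fraction: float = float("nan"),
    topology_id: str = "",
    step_table: StepLengthTable | None = None,
) -> SpatialHabitatNetwork:
    nodes = pd.read_csv(nodes_path).sort_values("node_id")
    edges = pd.read_csv(edges_path)
    pairs = sorted(
        (min(int(a), int(b)), max(int(a), int(b)))
        for a, b in zip(edges["node_a"], edges["node_b"])
    )
    lookup = {
        (min(int(a), int(b)), max(int(a), int(b))): float(w)
        for a, b, w in zip(edges["node_a"], edges["node_b"], edges["length_mm"])
    }
    return SpatialHabitatNetwork(
        n_nodes=len(nodes),
        coords=nodes[["x_mm", "y_mm"]].to_numpy(float),
        links=tuple(pairs),
        link_lengths=tuple(lookup[p] for p in pairs),
        config_label=config_label,
        rewire_fraction=rewire_fraction,
        topology_id=topology_id or Path(str(edges_path)).stem,
        step_table=step_table or StepLengthTable(),
    )


def write_network_graphml(net: SpatialHabitatNetwork, path, seed: int | None = None) -> None:
    g = net.to_networkx()
    if seed is not None:
        g.graph["seed"] = int(seed)
    nx.write_graphml(g, path)


def read_network_graphml(
    path, step_table: StepLengthTable | None = None
) -> SpatialHabitatNetwork:
    g = nx.read_graphml(path, node_type=int)
    n = g.number_of_nodes()
    coords = np.array([[g.nodes[i]["x_mm"], g.nodes[i]["y_mm"]] for i in range(n)])
    pairs = sorted((min(a, b), max(a, b)) for a, b in g.edges())
    lengths = tuple(float(g.edges[p]["length_mm"]) for p in pairs)
    return SpatialHabitatNetwork(
        n_nodes=n,
        coords=coords,
        links=tuple(pairs),
        link_lengths=lengths,
        config_label=str(g.graph.get("config_label", "unknown")),
        rewire_fraction=float(g.graph.get("rewire_fraction", float("nan"))),
        topology_id=str(g.graph.get("topology_id", Path(str(path)).stem)),
        step_table=step_table or StepLengthTable(),
    )
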