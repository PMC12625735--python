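"""Dense-subnetwork (module) detection within one omic layer.

Communities are found by Louvain modularity optimisation on the
layer-induced subgraph (seeded, since Louvain is order-sensitive), small
communities are discarded, and the survivors are ranked by internal edge
density 2e/(n(n−1)).  The algorithm is pluggable: any callable returning a
node partition can replace Louvain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx

from .exceptions import ValidationError
from .topology import SetCloseness, set_closeness

__all__ = ["Subnetwork", "detect_dense_subnetworks", "compartment_to_subnetwork_closeness"]


@dataclass
class Subnetwork:
    id: int
    members: frozenset
    n_nodes: int
    n_edges: int
    density: float  # 2e / (n(n-1))
    modularity_contribution: float

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density": self.density,
            "modularity_contribution": self.modularity_contribution,
            "members": sorted(self.members),
        }


def _density(n: int, e: int) -> float:
    return 2.0 * e / (n * (n - 1)) if n > 1 else 0.0


def detect_dense_subnetworks(
    graph: nx.Graph,
    layer: str,
    k: int = 2,
    min_size: int = 10,
    seed: int = 0,
    partition=None,
) -> list[Subnetwork]:
    """Top-``k`` densest communities of the layer-induced subgraph.

    ``partition`` may supply a pre-computed list of node sets (bypassing
    Louvain).  Fewer than ``k`` qualifying communities triggers a warning and
    returns what exists.
    """
    nodes = [n for n, d in graph.nodes(data=True) if d.get("layer") == layer]
    sub = graph.subgraph(nodes)
    if sub.number_of_nodes() < 2 * min_size:
        raise ValidationError(
            f"layer {layer!r} subgraph has {sub.number_of_nodes()} nodes; "
            f"need >= {2 * min_size}"
        )
    if partition is None:
        partition = nx.community.louvain_communities(sub, seed=seed)
    m = sub.number_of_edges()
    result: list[Subnetwork] = []
    for comm in partition:
        comm = set(comm)
        if len(comm) < min_size:
            continue
        cg = sub.subgraph(comm)
        e = cg.number_of_edges()
        deg_sum = sum(d for _, d in sub.degree(comm))
        mod = (e / m - (deg_sum / (2 * m)) ** 2) if m else 0.0
        result.append(
            Subnetwork(
                id=-1,
                members=frozenset(comm),
                n_nodes=len(comm),
                n_edges=e,
                density=_density(len(comm), e),
                modularity_contribution=mod,
            )
        )
    result.sort(key=lambda s: (-s.density, -s.n_nodes, sorted(s.members)[0]))
    if len(result) < k:
        warnings.warn(
            f"only {len(result)} communities of size >= {min_size} found (asked for {k})"
        )
    result = result[:k]
    for i, s in enumerate(result, start=1):
        s.id = i
    return result


def compartment_to_subnetwork_closeness(
    graph: nx.Graph, compartment_set, subnetwork: Subnetwork
) -> SetCloseness:
    """Shortest-path closeness of a compartment's microbes to a subnetwork's
    members, over the full network (paths may traverse any layer)."""
    return set_closeness(graph, compartment_set, subnetwork.members)
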