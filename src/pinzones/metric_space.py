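"""The metric-space model of a PIN: distances, centre, zones, zone metrics.

An undirected network is treated as a metric space under hop-count
shortest-path distance d(u, v).  The topological centre is the protein (or
proteins, under ties) minimising eccentricity ecc(v) = max_u d(v, u); the
minimum eccentricity is the radius.  Zone k collects the nodes at distance
exactly k from the centre (minimum over centres when tied), so zone 1 holds
the centre's direct interactors, zone 2 their interactors not already zoned,
and so on out to the radius.  Centre finding deliberately does not use node
degree: the centre is the eccentricity minimiser, which need not be a hub.

Eccentricity, centre and diameter are computed on the largest connected
component; nodes of smaller components are reported as unreachable rather
than zoned, since "distance from the centre" is undefined for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from pinzones._rounding import round_half_away


@dataclass(frozen=True)
class ZoneDecomposition:
    """A zone partition of a network around its topological centre(s).

    ``zone_of`` maps every node reachable from the centre set to its
    distance zone; centres are zone 0.  ``radius`` is the eccentricity of
    the centre set (the largest zone index); ``diameter`` is the diameter
    of the centre's connected component.  ``unreachable`` lists nodes with
    no path to any centre.
    """

    centres: frozenset[str]
    zone_of: Mapping[str, int]
    radius: int
    diameter: int
    unreachable: frozenset[str] = field(default_factory=frozenset)

    @property
    def max_zone(self) -> int:
        return self.radius

    def zones(self, include_centre: bool = False) -> dict[int, set[str]]:
        """Zone index -> node set, for zones >= 1 (optionally including zone 0)."""
        out: dict[int, set[str]] = {}
        for node, k in self.zone_of.items():
            if k == 0 and not include_centre:
                continue
            out.setdefault(k, set()).add(node)
        return dict(sorted(out.items()))

    def zone_sizes(self, include_centre: bool = False) -> dict[int, int]:
        return {k: len(v) for k, v in self.zones(include_centre=include_centre).items()}

    def validate(self, net: nx.Graph) -> None:
        """Assert the decomposition invariants against its network.

        Every zone-k node (k >= 1) must have a neighbour in zone k-1; zones
        partition the reachable set; radius <= diameter <= 2 * radius.
        """
        for centre in self.centres:
            if self.zone_of[centre] != 0:
                raise AssertionError(f"centre {centre!r} not in zone 0")
        for node, k in self.zone_of.items():
            if k == 0:
                continue
            if not any(self.zone_of.get(nbr) == k - 1 for nbr in net.neighbors(node)):
                raise AssertionError(f"zone-{k} node {node!r} has no zone-{k - 1} neighbour")
        if set(self.zone_of) | set(self.unreachable) != set(net.nodes):
            raise AssertionError("zoned + unreachable nodes do not cover the network")
        if max(self.zone_of.values()) != self.radius:
            raise AssertionError("largest zone index does not equal the radius")
        if self.radius > self.diameter:
            raise AssertionError("radius exceeds diameter")
        # diameter <= 2*radius needs the triangle inequality through a single
        # centre; with a tied centre set the decomposition radius can be
        # smaller than the graph radius (a 4-cycle has four centres, radius 0).
        if len(self.centres) == 1 and self.diameter > 2 * self.radius:
            raise AssertionError("diameter exceeds twice the radius")


def shortest_path_lengths(net: nx.Graph, source: str) -> dict[str, int]:
    """Breadth-first hop distances from ``source``; unreachable nodes absent."""
    if source not in net:
        raise KeyError(f"source {source!r} not in network")
    return dict(nx.single_source_shortest_path_length(net, source))


def eccentricity(net: nx.Graph, node: str) -> int:
    """Max hop distance from ``node`` to any node in its connected component."""
    return max(shortest_path_lengths(net, node).values())


def _largest_component(net: nx.Graph) -> set[str]:
    # deterministic tie-break on the smallest node label
    return max(nx.connected_components(net), key=lambda c: (len(c), min(c)))


def _component_eccentricities(component: nx.Graph) -> dict[str, int]:
    """All-pairs BFS eccentricities of a connected graph (sparse C BFS)."""
    nodes = list(component.nodes)
    if len(nodes) == 1:
        return {nodes[0]: 0}
    matrix = nx.to_scipy_sparse_array(component, nodelist=nodes, format="csr")
    dist = shortest_path(matrix, method="D", unweighted=True, directed=False)
    ecc = dist.max(axis=1)
    return {node: int(e) for node, e in zip(nodes, ecc)}


def find_centre(net: nx.Graph) -> tuple[set[str], int]:
    """Topological centre(s) and radius of the largest connected component.

    Returns all eccentricity minimisers (ties are real: a 4-cycle has four
    centres) and the minimum eccentricity.
    """
    if len(net) == 0:
        raise ValueError("cannot find the centre of an empty network")
    component = net.subgraph(_largest_component(net))
    ecc = _component_eccentricities(component)
    radius = min(ecc.values())
    return {v for v, e in ecc.items() if e == radius}, radius


def diameter(net: nx.Graph) -> int:
    """Diameter (max eccentricity) of the largest connected component."""
    if len(net) == 0:
        raise ValueError("cannot take the diameter of an empty network")
    component = net.subgraph(_largest_component(net))
    return max(_component_eccentricities(component).values())


def zone_partition(net: nx.Graph, centres: Iterable[str]) -> ZoneDecomposition:
    """Partition nodes into zones by minimum distance to the centre set.

    zone_of[v] = min over centres c of d(c, v), computed by multi-source BFS;
    nodes unreachable from every centre are listed, not zoned.  The reported
    diameter is that of the component holding the centres (of the largest
    such component if centres span several).
    """
    centre_set = frozenset(centres)
    if not centre_set:
        raise ValueError("centre set is empty")
    missing = centre_set - set(net.nodes)
    if missing:
        raise KeyError(f"centre(s) not in network: {sorted(missing)}")
    zone_of: dict[str, int] = {}
    for k, layer in enumerate(nx.bfs_layers(net, sorted(centre_set))):
        for node in layer:
            zone_of[node] = k
    unreachable = frozenset(set(net.nodes) - set(zone_of))
    reachable = net.subgraph(zone_of)
    component = reachable.subgraph(_largest_component(reachable))
    return ZoneDecomposition(
        centres=centre_set,
        zone_of=zone_of,
        radius=max(zone_of.values()),
        diameter=max(_component_eccentricities(component).values()),
        unreachable=unreachable,
    )


def decompose(net: nx.Graph) -> ZoneDecomposition:
    """Find the centre of the largest component and partition into zones."""
    centres, _ = find_centre(net)
    return zone_partition(net, centres)


def zone_metrics(
    net: nx.Graph,
    decomposition: ZoneDecomposition,
    include_centre: bool = False,
) -> pd.DataFrame:
    """Per-zone node count, average/min/max degree and quill count.

    Degrees are degrees in the full network, not the zone-induced subgraph;
    a quill is a node of degree 1.  Average degree is reported to one
    decimal, rounded half away from zero.  One row per non-empty zone >= 1
    (zone 0 — the centre row — only on request), indexed by zone.
    """
    columns = ["n_nodes", "avg_degree", "min_degree", "max_degree", "n_quills"]
    rows = []
    for k, members in decomposition.zones(include_centre=include_centre).items():
        degrees = [net.degree(v) for v in members]
        rows.append(
            {
                "zone": k,
                "n_nodes": len(members),
                "avg_degree": round_half_away(sum(degrees) / len(degrees), 1),
                "min_degree": min(degrees),
                "max_degree": max(degrees),
                "n_quills": sum(1 for d in degrees if d == 1),
            }
        )
    if not rows:  # every reachable node is a centre (e.g. complete graphs)
        return pd.DataFrame(columns=columns, index=pd.Index([], name="zone"))
    return pd.DataFrame(rows).set_index("zone")


def write_zone_metrics(
    net: nx.Graph,
    decomposition: ZoneDecomposition,
    path,
) -> pd.DataFrame:
    """Export the zone metrics table as TSV with a centre/radius/diameter header."""
    table = zone_metrics(net, decomposition)
    with open(path, "w") as handle:
        handle.write(f"# centre={','.join(sorted(decomposition.centres))}\n")
        handle.write(f"# radius={decomposition.radius}\n")
        handle.write(f"# diameter={decomposition.diameter}\n")
        table.to_csv(handle, sep="\t")
    return table
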