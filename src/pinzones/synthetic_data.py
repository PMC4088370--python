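"""Synthetic networks with planted core-periphery zone structure.

The generator plants a single centre node wired to every zone-1 node, then
grows shells outward: each zone-k node receives exactly one guaranteed edge
to a uniformly chosen zone-(k-1) node, plus random intra-zone and
adjacent-zone edges at per-zone probabilities that decay outward.  Outer
zones additionally receive "quills" — degree-1 nodes hung off the previous
shell — mirroring the quill-dominated peripheries of real human PINs.

Because every edge stays within a shell or crosses to an adjacent shell,
the planted zone index of a node equals its true hop distance from the
centre exactly; optional long-range noise edges break that guarantee in one
direction only (shortcuts can shrink distances, never grow them), so with
noise the computed zone index is <= the planted one.  Recoverability of the
planted centre as the *unique* eccentricity minimiser is a property of the
parameter regime, guaranteed for the shipped presets and asserted in tests,
not for arbitrary parameters.

All randomness flows from a single integer seed; outputs are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from pinzones.metric_space import ZoneDecomposition, zone_metrics
from pinzones.network_io import AnnotationSet, PresenceMatrix

CENTRE_ID = "CENTRE"


@dataclass(frozen=True)
class CorePeripheryParams:
    """Parameters of the planted core-periphery generator.

    ``zone_sizes[k-1]`` is the number of regular (non-quill) nodes planted
    in zone k; ``p_intra[k-1]`` the edge probability within zone k;
    ``p_adjacent[k-1]`` the extra edge probability between zones k and k+1
    (beyond the one guaranteed upward edge per node); ``quills`` maps a zone
    index to the number of degree-1 nodes hung off zone k-1 hosts.
    ``centre_degree``, if given, must equal ``zone_sizes[0]`` plus the
    anchor chain's zone-1 node: by the zone definition the centre is
    adjacent to exactly the zone-1 nodes.
    ``n_noise_edges`` uniformly random extra node pairs are added last.

    With ``anchor_chain`` a path centre-a1-...-aK (one extra node per zone)
    is planted whose nodes take part in no other wiring.  Its tip pins
    ecc(centre) = K while giving every other node eccentricity >= K + 1
    (any path from a non-spine node to the tip must pass the centre), so
    the planted centre is the unique eccentricity minimiser for *every*
    seed — even after noise edges, which never touch the spine.
    """

    zone_sizes: tuple[int, ...]
    p_intra: tuple[float, ...]
    p_adjacent: tuple[float, ...]
    quills: Mapping[int, int] = field(default_factory=dict)
    centre_degree: int | None = None
    n_noise_edges: int = 0
    anchor_chain: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.zone_sizes:
            raise ValueError("zone_sizes must be non-empty")
        if any(s <= 0 for s in self.zone_sizes):
            raise ValueError("every planted zone must be non-empty")
        if len(self.p_intra) != len(self.zone_sizes):
            raise ValueError("p_intra must give one probability per zone")
        if len(self.p_adjacent) != max(len(self.zone_sizes) - 1, 0):
            raise ValueError("p_adjacent must give one probability per adjacent zone pair")
        for p in (*self.p_intra, *self.p_adjacent):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"edge probability {p} outside [0, 1]")
        n_zones = len(self.zone_sizes)
        for k, count in self.quills.items():
            if not 1 <= k <= n_zones or count < 0:
                raise ValueError(f"invalid quill spec: zone {k} count {count}")
        zone1 = self.zone_sizes[0] + (1 if self.anchor_chain else 0)
        if self.centre_degree is not None and self.centre_degree != zone1:
            raise ValueError(
                "centre_degree must equal zone 1's size: the centre is adjacent "
                "to exactly the zone-1 nodes"
            )


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth recorded at generation time for recovery tests."""

    centre: str
    zone_of: Mapping[str, int]
    metrics: pd.DataFrame

    def zone_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for zone in self.zone_of.values():
            if zone > 0:
                sizes[zone] = sizes.get(zone, 0) + 1
        return dict(sorted(sizes.items()))


def _random_pairs(rng, left: Sequence[str], right: Sequence[str], p: float):
    """Each cross pair (or unordered within-pair if left is right) with prob p."""
    if p <= 0.0:
        return
    if left is right:
        n = len(left)
        iu, ju = np.triu_indices(n, k=1)
    else:
        iu, ju = np.meshgrid(np.arange(len(left)), np.arange(len(right)), indexing="ij")
        iu, ju = iu.ravel(), ju.ravel()
    keep = rng.random(len(iu)) < p
    for i, j in zip(iu[keep], ju[keep]):
        yield left[int(i)], right[int(j)]


def generate_core_periphery(params: CorePeripheryParams) -> tuple[nx.Graph, PlantedTruth]:
    """Generate a planted core-periphery network and its ground truth.

    The emitted graph is simple and undirected; every planted zone-k node is
    guaranteed an edge into zone k-1, so without noise edges the planted
    zone map is exactly the BFS distance map from the centre.
    """
    rng = np.random.default_rng(params.seed)
    net = nx.Graph()
    zone_nodes: dict[int, list[str]] = {0: [CENTRE_ID]}
    net.add_node(CENTRE_ID)
    zone_of: dict[str, int] = {CENTRE_ID: 0}

    for k, size in enumerate(params.zone_sizes, start=1):
        members = [f"Z{k}N{i:04d}" for i in range(size)]
        zone_nodes[k] = members
        hosts = zone_nodes[k - 1]
        for node in members:
            zone_of[node] = k
            net.add_edge(node, hosts[int(rng.integers(len(hosts)))])
        for u, v in _random_pairs(rng, members, members, params.p_intra[k - 1]):
            net.add_edge(u, v)
        if k >= 2:
            for u, v in _random_pairs(
                rng, zone_nodes[k - 1], members, params.p_adjacent[k - 2]
            ):
                net.add_edge(u, v)

    # quills: fresh degree-1 nodes on regular hosts of the previous shell
    for k in sorted(params.quills):
        hosts = zone_nodes[k - 1]
        for i in range(params.quills[k]):
            quill = f"Q{k}N{i:04d}"
            zone_of[quill] = k
            net.add_edge(quill, hosts[int(rng.integers(len(hosts)))])

    # anchor chain: an isolated spine pinning the centre's eccentricity
    if params.anchor_chain:
        previous = CENTRE_ID
        for k in range(1, len(params.zone_sizes) + 1):
            anchor = f"ANCH{k:02d}"
            zone_of[anchor] = k
            net.add_edge(previous, anchor)
            previous = anchor

    nodes = sorted(v for v in net.nodes if not v.startswith("ANCH"))
    added = 0
    while added < params.n_noise_edges:
        u, v = (nodes[int(i)] for i in rng.integers(len(nodes), size=2))
        if u != v and not net.has_edge(u, v):
            net.add_edge(u, v)
            added += 1

    decomposition = ZoneDecomposition(
        centres=frozenset({CENTRE_ID}),
        zone_of=zone_of,
        radius=max(zone_of.values()),
        diameter=0,  # placeholder; truth metrics do not use it
        unreachable=frozenset(),
    )
    truth = PlantedTruth(
        centre=CENTRE_ID,
        zone_of=zone_of,
        metrics=zone_metrics(net, decomposition),
    )
    return net, truth


def hfpin_like_params(seed: int = 0, n_noise_edges: int = 0) -> CorePeripheryParams:
    """The shipped ~500-node preset emulating a human functional PIN.

    Five zones with sizes and edge probabilities decaying outward, a dense
    zone 1 wired to the single centre, and quill-dominated outer shells —
    the qualitative structure of real PINs (most nodes within distance 3 of
    the centre, average degree falling with zone index) at a scale that
    keeps the test suite in seconds.
    """
    return CorePeripheryParams(
        zone_sizes=(40, 210, 175, 15, 5),
        p_intra=(0.12, 0.02, 0.012, 0.01, 0.0),
        p_adjacent=(0.015, 0.008, 0.004, 0.004),
        quills={3: 35, 4: 10, 5: 5},
        n_noise_edges=n_noise_edges,
        anchor_chain=True,
        seed=seed,
    )


def hfpin_like_large_params(seed: int = 0) -> CorePeripheryParams:
    """A ~5000-node variant of the preset (not exercised by the default suite)."""
    return CorePeripheryParams(
        zone_sizes=(300, 2100, 1750, 150, 50),
        p_intra=(0.05, 0.004, 0.002, 0.001, 0.0),
        p_adjacent=(0.004, 0.0015, 0.0008, 0.0008),
        quills={3: 350, 4: 100, 5: 50},
        anchor_chain=True,
        seed=seed,
    )


PRESETS = {
    "hfpin_like": hfpin_like_params,
    "hfpin_like_large": hfpin_like_large_params,
}


def preset_params(name: str, seed: int = 0, n_noise_edges: int = 0) -> CorePeripheryParams:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    params = PRESETS[name](seed=seed)
    if n_noise_edges:
        params = replace(params, n_noise_edges=n_noise_edges)
    return params


def generate_zone_biased_annotation(
    truth: PlantedTruth,
    prevalence: Mapping[int, float],
    seed: int = 0,
    name: str = "synthetic_annotation",
) -> AnnotationSet:
    """Include each zoned node independently with its zone's prevalence.

    Zones absent from ``prevalence`` get probability 0.  Deterministic per
    seed.  Emulates annotation classes (essential, disease, drug target)
    whose prevalence decreases monotonically away from the centre.
    """
    for k, p in prevalence.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"prevalence {p} for zone {k} outside [0, 1]")
    rng = np.random.default_rng(seed)
    nodes = sorted(truth.zone_of)
    probs = np.array([prevalence.get(truth.zone_of[v], 0.0) for v in nodes])
    keep = rng.random(len(nodes)) < probs
    return AnnotationSet(
        name=name, members=frozenset(v for v, k in zip(nodes, keep) if k)
    )


def generate_presence_matrix(
    genes: Sequence[str],
    n_samples: int,
    presence_prob: float | Mapping[str, float],
    seed: int = 0,
) -> PresenceMatrix:
    """I.i.d. Bernoulli presence/absence calls per gene; deterministic per seed."""
    if n_samples < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    if isinstance(presence_prob, Mapping):
        probs = np.array([presence_prob[g] for g in genes])
    else:
        probs = np.full(len(genes), float(presence_prob))
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("presence probabilities must lie in [0, 1]")
    calls = (rng.random((len(genes), n_samples)) < probs[:, None]).astype(np.int8)
    frame = pd.DataFrame(
        calls, index=list(genes), columns=[f"S{i:04d}" for i in range(n_samples)]
    )
    return PresenceMatrix(calls=frame)
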