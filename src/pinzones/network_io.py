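"""Readers, writers and merging for networks, gene sets and presence matrices.

Networks are plain :class:`networkx.Graph` objects over string node IDs
(gene symbols, matched exactly — no case folding or alias resolution, since
any symbol normalisation would silently change zone counts).  All readers
enforce the simple-graph invariants the zone metrics presuppose: no
self-loops, no duplicate or reversed-duplicate edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Zone colours used by the KEGG Mapper "Color objects in pathway maps" form.
DEFAULT_ZONE_COLOURS: dict[int, str] = {1: "red", 2: "orange", 3: "yellow", 4: "green"}


class EdgeListParseError(ValueError):
    """A malformed line in an edge-list file (reports the 1-based line number)."""


@dataclass(frozen=True)
class AnnotationSet:
    """A named gene set (GMT-style).

    Members may include IDs absent from any given network; they are ignored
    at mapping time with a logged count.
    """

    name: str
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class PresenceMatrix:
    """Binary gene x sample expression presence/absence calls.

    ``calls`` is a pandas DataFrame with unique gene IDs as the index,
    sample IDs as columns, and values restricted to {0, 1}.
    """

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        if self.calls.index.has_duplicates:
            dup = self.calls.index[self.calls.index.duplicated()][0]
            raise ValueError(f"duplicate gene ID {dup!r} in presence matrix")
        values = self.calls.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            r, c = np.argwhere(~np.isin(values, (0, 1)))[0]
            raise ValueError(
                f"non-binary call {values[r, c]!r} at gene {self.calls.index[r]!r}, "
                f"sample {self.calls.columns[c]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.calls.index)

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns)


def _add_edge(net: nx.Graph, u: str, v: str, counts: dict[str, int]) -> None:
    if u == v:
        counts["self_loops"] += 1
        net.add_node(u)
        return
    if net.has_edge(u, v):
        counts["duplicates"] += 1
        return
    net.add_edge(u, v)


def read_edge_list(path: str | Path, format: str = "tsv") -> nx.Graph:
    """Read an undirected network from a 2-column TSV or a SIF file.

    TSV lines are ``node<ws>node`` (extra columns ignored); SIF lines are
    ``node<ws>relation<ws>node[<ws>node...]`` with relation types ignored
    (interactions are treated as one undirected class).  Self-loops are
    dropped and duplicate/reversed edges collapsed, with counts logged.
    Blank lines and ``#`` comments are skipped.  An empty file yields an
    empty graph.
    """
    if format not in ("tsv", "sif"):
        raise ValueError(f"unknown edge list format {format!r}")
    net = nx.Graph()
    counts = {"self_loops": 0, "duplicates": 0}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if format == "tsv":
                if len(fields) < 2:
                    raise EdgeListParseError(
                        f"{path}: line {lineno}: expected 2 columns, got {len(fields)}"
                    )
                _add_edge(net, fields[0], fields[1], counts)
            else:  # sif
                if len(fields) < 3:
                    raise EdgeListParseError(
                        f"{path}: line {lineno}: SIF needs node, relation, node(s); "
                        f"got {len(fields)} field(s)"
                    )
                for target in fields[2:]:
                    _add_edge(net, fields[0], target, counts)
    if counts["self_loops"]:
        logger.warning("%s: dropped %d self-loop(s)", path, counts["self_loops"])
    if counts["duplicates"]:
        logger.info("%s: collapsed %d duplicate edge(s)", path, counts["duplicates"])
    return net


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    """Write a network as a sorted 2-column TSV (isolated nodes are dropped)."""
    isolated = sum(1 for v in net if net.degree(v) == 0)
    if isolated:
        logger.warning("%s: %d isolated node(s) cannot be written to an edge list", path, isolated)
    edges = sorted(tuple(sorted(e)) for e in net.edges())
    with open(path, "w") as handle:
        for u, v in edges:
            handle.write(f"{u}\t{v}\n")


def read_annotation_sets(path: str | Path) -> dict[str, AnnotationSet]:
    """Read GMT-format gene sets: ``name<TAB>description<TAB>member...``.

    Duplicate members within a line are collapsed; a duplicate set name is an
    error; an empty member list is retained (with a warning).
    """
    sets: dict[str, AnnotationSet] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                logger.warning("%s: line %d: set %r has no members", path, lineno, name)
            sets[name] = AnnotationSet(name=name, members=members)
    return sets


def write_annotation_sets(sets: Iterable[AnnotationSet], path: str | Path) -> None:
    """Write gene sets in GMT format, members sorted for determinism."""
    with open(path, "w") as handle:
        for aset in sets:
            members = "\t".join(sorted(aset.members))
            handle.write(f"{aset.name}\t-\t{members}\n" if members else f"{aset.name}\t-\n")


def read_presence_matrix(path: str | Path) -> PresenceMatrix:
    """Read a TSV presence matrix: header = sample IDs, first column = gene IDs."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return PresenceMatrix(calls=frame)


def write_presence_matrix(matrix: PresenceMatrix, path: str | Path) -> None:
    matrix.calls.to_csv(path, sep="\t", index_label="gene")


def merge_networks(a: nx.Graph, b: nx.Graph) -> nx.Graph:
    """Non-redundant merge: node set union, canonicalised edge set union.

    Commutative and idempotent; exact string identity on node IDs.
    """
    merged = nx.Graph()
    merged.add_nodes_from(a.nodes())
    merged.add_nodes_from(b.nodes())
    merged.add_edges_from(a.edges())
    merged.add_edges_from(b.edges())
    return merged


def export_kegg_mapper(
    zone_of: Mapping[str, int],
    path: str | Path,
    colour_scheme: Mapping[int, str] | None = None,
    skip_missing: bool = False,
) -> None:
    """Write a ``gene<TAB>colour`` file for KEGG Mapper pathway colouring.

    Each node is coloured by its zone; nodes whose zone has no colour in the
    scheme either raise (default) or are skipped with a logged count.
    Output is sorted by gene ID.
    """
    scheme = DEFAULT_ZONE_COLOURS if colour_scheme is None else colour_scheme
    skipped = 0
    lines = []
    for node in sorted(zone_of):
        zone = zone_of[node]
        if zone not in scheme:
            if skip_missing:
                skipped += 1
                continue
            raise KeyError(f"no colour for zone {zone} (node {node!r})")
        lines.append(f"{node}\t{scheme[zone]}\n")
    with open(path, "w") as handle:
        handle.writelines(lines)
    if skipped:
        logger.info("%s: skipped %d node(s) in uncoloured zones", path, skipped)


def write_zone_assignments(decomposition, path: str | Path) -> None:
    """Write ``node<TAB>zone`` TSV; centre node(s) get zone 0. Sorted by node."""
    with open(path, "w") as handle:
        handle.write("node\tzone\n")
        for node in sorted(decomposition.zone_of):
            handle.write(f"{node}\t{decomposition.zone_of[node]}\n")


def read_zone_assignments(path: str | Path) -> dict[str, int]:
    """Read a node -> zone map written by :func:`write_zone_assignments`."""
    zone_of: dict[str, int] = {}
    with open(path) as handle:
        header = handle.readline()
        if header and not header.startswith("node\t"):
            raise ValueError(f"{path}: expected 'node<TAB>zone' header")
        for lineno, raw in enumerate(handle, start=2):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            zone_of[fields[0]] = int(fields[1])
    return zone_of
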