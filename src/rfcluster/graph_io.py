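"""Plain-text I/O for networks and cluster families.

Networks are read from whitespace-separated edge lists (``u v`` or
``u v w``); cluster families (predicted or reference complexes) use the
MIPS-style dialect of one whitespace-separated cluster per line.  Node
identifiers are case-sensitive opaque strings and node order is
first-appearance order, so parsing is deterministic.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "ClusterSet",
    "EdgeListFormatError",
    "read_edge_list",
    "read_clusters",
    "write_clusters",
    "write_edge_list",
]


class EdgeListFormatError(ValueError):
    """Raised when an edge-list line cannot be parsed."""


class Network:
    """An undirected graph with optional strictly positive edge weights.

    Self-loops are rejected and each unordered node pair is stored once;
    adding a duplicate edge keeps the maximum weight (weights are
    interaction confidences, not counts).
    """

    def __init__(self) -> None:
        self._nodes: list[str] = []
        self._index: dict[str, int] = {}
        self._adj: dict[str, dict[str, float | None]] = {}
        self._n_edges = 0

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str] | tuple[str, str, float]],
        nodes: Iterable[str] = (),
    ) -> "Network":
        net = cls()
        for v in nodes:
            net.add_node(v)
        for e in edges:
            net.add_edge(*e)
        return net

    def add_node(self, v: str) -> None:
        if v not in self._index:
            self._index[v] = len(self._nodes)
            self._nodes.append(v)
            self._adj[v] = {}

    def add_edge(self, u: str, v: str, weight: float | None = None) -> None:
        if u == v:
            raise ValueError(f"self-loop edge on node {u!r}")
        if weight is not None and weight <= 0:
            raise ValueError(f"non-positive weight {weight} on edge ({u}, {v})")
        self.add_node(u)
        self.add_node(v)
        old = self._adj[u].get(v, _MISSING)
        if old is _MISSING:
            self._n_edges += 1
            w = weight
        else:
            # duplicate edge: keep the larger confidence
            if weight is None or old is None:
                w = weight if old is None else old
            else:
                w = max(old, weight)
        self._adj[u][v] = w
        self._adj[v][u] = w

    # -- queries ------------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self._nodes)

    @property
    def node_index(self) -> dict[str, int]:
        return dict(self._index)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return self._n_edges

    @property
    def density(self) -> float:
        """Edges per node, the summary statistic used for PPI datasets."""
        if not self._nodes:
            raise ValueError("density undefined for an empty network")
        return self._n_edges / len(self._nodes)

    @property
    def is_weighted(self) -> bool:
        return any(
            w is not None for nbrs in self._adj.values() for w in nbrs.values()
        )

    def __contains__(self, v: str) -> bool:
        return v in self._index

    def __len__(self) -> int:
        return len(self._nodes)

    def has_edge(self, u: str, v: str) -> bool:
        return v in self._adj.get(u, {})

    def weight(self, u: str, v: str) -> float | None:
        return self._adj[u][v]

    def neighbors(self, v: str) -> tuple[str, ...]:
        if v not in self._index:
            raise KeyError(f"unknown node {v!r}")
        return tuple(self._adj[v])

    def degree(self, v: str) -> int:
        return len(self._adj[v])

    def edges(self) -> Iterator[tuple[str, str, float | None]]:
        """Canonical edge iterator: endpoints ordered by node index."""
        idx = self._index
        for u in self._nodes:
            for v, w in self._adj[u].items():
                if idx[u] < idx[v]:
                    yield u, v, w

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self._nodes)
        for u, v, w in self.edges():
            if w is None:
                g.add_edge(u, v)
            else:
                g.add_edge(u, v, weight=w)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Network":
        net = cls()
        for v in g.nodes:
            net.add_node(str(v))
        for u, v, data in g.edges(data=True):
            if u == v:
                continue
            net.add_edge(str(u), str(v), data.get("weight"))
        return net

    def __repr__(self) -> str:  # pragma: no cover
        kind = "weighted" if self.is_weighted else "unweighted"
        return f"<Network {kind}: {self.n_nodes} nodes, {self.n_edges} edges>"


_MISSING = object()


class ClusterSet:
    """An ordered family of node sets, possibly overlapping.

    Carrier for both predicted complexes and reference (gold standard)
    complexes.  Clusters must be non-empty; order is preserved because
    text round-trips should be diffable.
    """

    def __init__(
        self, clusters: Iterable[Iterable[str]] = (), provenance: str = ""
    ) -> None:
        self.clusters: list[frozenset[str]] = []
        for c in clusters:
            fs = frozenset(c)
            if not fs:
                raise ValueError("clusters must be non-empty")
            self.clusters.append(fs)
        self.provenance = provenance

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(self.clusters)

    def __len__(self) -> int:
        return len(self.clusters)

    def __getitem__(self, i: int) -> frozenset[str]:
        return self.clusters[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClusterSet):
            return NotImplemented
        return sorted(map(sorted, self.clusters)) == sorted(
            map(sorted, other.clusters)
        )

    @property
    def node_universe(self) -> frozenset[str]:
        return frozenset().union(*self.clusters) if self.clusters else frozenset()

    @property
    def is_partition(self) -> bool:
        """True when no node appears in more than one cluster."""
        total = sum(len(c) for c in self.clusters)
        return total == len(self.node_universe)

    def overlapping_nodes(self) -> frozenset[str]:
        seen: set[str] = set()
        multi: set[str] = set()
        for c in self.clusters:
            multi.update(c & seen)
            seen.update(c)
        return frozenset(multi)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<ClusterSet: {len(self.clusters)} clusters>"


def read_edge_list(path: str | Path, weighted: bool = False) -> Network:
    """Parse a whitespace-separated edge list into a :class:`Network`.

    Lines starting with ``#`` are comments.  Self-loops are dropped (with
    a logged count); duplicate edges keep the maximum weight.  With
    ``weighted=True`` every data line must carry a third, strictly
    positive numeric field.
    """
    net = Network()
    n_loops = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if weighted:
                if len(fields) != 3:
                    raise EdgeListFormatError(
                        f"{path}:{lineno}: expected 'u v w', got {line!r}"
                    )
                u, v, ws = fields
                try:
                    w = float(ws)
                except ValueError as exc:
                    raise EdgeListFormatError(
                        f"{path}:{lineno}: non-numeric weight {ws!r}"
                    ) from exc
                if w <= 0:
                    raise ValueError(
                        f"{path}:{lineno}: non-positive weight {w}"
                    )
            else:
                if len(fields) not in (2, 3):
                    raise EdgeListFormatError(
                        f"{path}:{lineno}: expected 2 or 3 fields, got {line!r}"
                    )
                u, v = fields[0], fields[1]
                w = None
            if u == v:
                n_loops += 1
                net.add_node(u)
                continue
            net.add_edge(u, v, w)
    if n_loops:
        logger.info("dropped %d self-loop(s) while reading %s", n_loops, path)
    return net


def write_edge_list(net: Network, path: str | Path) -> None:
    """Write a TSV edge list; weights are emitted only when present."""
    with open(path, "w") as fh:
        for u, v, w in net.edges():
            if w is None:
                fh.write(f"{u}\t{v}\n")
            else:
                fh.write(f"{u}\t{v}\t{w:g}\n")


def read_clusters(path: str | Path) -> ClusterSet:
    """Read one whitespace-separated cluster per line; empty lines skipped."""
    clusters: list[frozenset[str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#"):
                continue
            if not line:
                logger.warning("%s:%d: empty cluster line skipped", path, lineno)
                continue
            clusters.append(frozenset(line.split()))
    return ClusterSet(clusters, provenance=str(path))


def write_clusters(cs: ClusterSet, path: str | Path) -> None:
    """Write one cluster per line, members sorted for determinism."""
    with open(path, "w") as fh:
        for c in cs:
            fh.write(" ".join(sorted(c)) + "\n")
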