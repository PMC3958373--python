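"""Planted-structure benchmark generators.

Two generators cover the two experimental regimes: a simple planted-
partition graph with designated shared nodes (communities wired at
independent intra/inter edge probabilities), and an LFR-style benchmark
with heterogeneous degrees, community sizes drawn from a stated range,
and a mixing parameter u — the fraction of a node's edges that leave its
own communities.  Both are fully seeded: the same seed reproduces the
same edge list byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .graph_io import ClusterSet, Network

__all__ = [
    "PlantedBenchmark",
    "planted_overlap_graph",
    "lfr_like",
    "two_community_fixture",
]


@dataclass(frozen=True)
class PlantedBenchmark:
    """A generated network together with its planted ground truth."""

    network: Network
    truth: ClusterSet
    params: dict = field(default_factory=dict)


def _node_name(i: int) -> str:
    return f"v{i}"


def planted_overlap_graph(
    sizes: Sequence[int],
    p_in: float,
    p_out: float,
    n_shared: int = 0,
    seed: int = 0,
) -> PlantedBenchmark:
    """Planted communities with independent intra/inter edge probabilities.

    Communities are laid out over ``sum(sizes) - n_shared`` nodes; the
    last ``n_shared`` members of the first community double as the first
    members of the second, so shared nodes are wired at rate ``p_in``
    into both.  Every pair sharing a community is connected with
    probability ``p_in``, every other pair with ``p_out``.
    """
    if not sizes or any(s < 3 for s in sizes):
        raise ValueError("each community must have size >= 3")
    if not p_in > p_out:
        raise ValueError(f"p_in must exceed p_out (got {p_in} <= {p_out})")
    if n_shared < 0:
        raise ValueError("n_shared must be >= 0")
    if n_shared > 0:
        if len(sizes) < 2:
            raise ValueError("shared nodes require at least two communities")
        if n_shared >= min(sizes[0], sizes[1]):
            raise ValueError("n_shared must be smaller than both host communities")

    n = sum(sizes) - n_shared
    nodes = [_node_name(i) for i in range(n)]
    communities: list[list[str]] = []
    start = 0
    for ci, size in enumerate(sizes):
        if ci == 1:
            start -= n_shared  # overlap with the tail of community 0
        communities.append(nodes[start : start + size])
        start += size
    membership: dict[str, set[int]] = {v: set() for v in nodes}
    for ci, comm in enumerate(communities):
        for v in comm:
            membership[v].add(ci)

    rng = np.random.default_rng(seed)
    net = Network()
    for v in nodes:
        net.add_node(v)
    for i in range(n):
        for j in range(i + 1, n):
            u, v = nodes[i], nodes[j]
            p = p_in if membership[u] & membership[v] else p_out
            if rng.random() < p:
                net.add_edge(u, v)
    truth = ClusterSet(communities, provenance="planted")
    params = {
        "sizes": tuple(sizes),
        "p_in": p_in,
        "p_out": p_out,
        "n_shared": n_shared,
        "seed": seed,
    }
    return PlantedBenchmark(net, truth, params)


def _powerlaw_degrees(
    n: int, avg_deg: float, max_deg: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample a truncated power-law degree sequence (exponent 2) whose
    minimum degree is chosen so the expected mean is closest to avg_deg."""
    best_dmin, best_gap = 1, float("inf")
    for dmin in range(1, max_deg + 1):
        d = np.arange(dmin, max_deg + 1, dtype=float)
        w = d ** -2.0
        mean = float((d * w).sum() / w.sum())
        gap = abs(mean - avg_deg)
        if gap < best_gap:
            best_dmin, best_gap = dmin, gap
    d = np.arange(best_dmin, max_deg + 1)
    w = d.astype(float) ** -2.0
    return rng.choice(d, size=n, p=w / w.sum())


def _sample_sizes(
    slots: int, size_min: int, size_max: int, rng: np.random.Generator
) -> list[int]:
    if size_min > size_max:
        raise ValueError("size_min must not exceed size_max")
    if slots < size_min:
        raise ValueError("fewer membership slots than the minimum community size")
    for _ in range(200):
        sizes: list[int] = []
        total = 0
        while total < slots:
            s = int(rng.integers(size_min, size_max + 1))
            sizes.append(s)
            total += s
        excess = total - slots
        if excess == 0:
            return sizes
        if sizes[-1] - excess >= size_min:
            sizes[-1] -= excess
            return sizes
    raise RuntimeError(
        "could not sample community sizes matching the node count; "
        "adjust size_min/size_max"
    )


def lfr_like(
    n: int,
    avg_deg: float = 20.0,
    max_deg: int = 50,
    size_min: int = 20,
    size_max: int = 50,
    mixing: float = 0.1,
    overlap_nodes: int = 0,
    memberships: int = 2,
    seed: int = 0,
) -> PlantedBenchmark:
    """LFR-style benchmark: power-law degrees, planted communities of
    sizes in [size_min, size_max], mixing fraction u of external edges.

    Each node splits its degree into an internal part (1-u, shared
    evenly among its communities) and an external part (u); edges are
    then realized Chung-Lu style, internally within each community and
    externally between nodes sharing no community.  ``overlap_nodes``
    designated nodes belong to ``memberships`` communities each.  This
    is an emulation of the published benchmark's statistics, not a
    reimplementation of its configuration-model internals.
    """
    if not 0.0 <= mixing < 1.0:
        raise ValueError(f"mixing must lie in [0, 1), got {mixing}")
    if overlap_nodes < 0 or (overlap_nodes > 0 and memberships < 2):
        raise ValueError("overlapping nodes need memberships >= 2")
    rng = np.random.default_rng(seed)

    degrees = _powerlaw_degrees(n, avg_deg, max_deg, rng)
    slots = n + overlap_nodes * (memberships - 1)
    sizes = _sample_sizes(slots, size_min, size_max, rng)
    k = len(sizes)
    if overlap_nodes > 0 and memberships > k:
        raise RuntimeError(
            f"memberships={memberships} exceeds the {k} sampled communities"
        )

    nodes = [_node_name(i) for i in range(n)]
    capacity = list(sizes)
    membership: dict[str, set[int]] = {}
    overlap_ids = rng.choice(n, size=overlap_nodes, replace=False) if overlap_nodes else []
    overlap_set = {int(i) for i in np.atleast_1d(overlap_ids)} if overlap_nodes else set()
    # overlapping nodes first, into the communities with most room
    for i in sorted(overlap_set):
        order = sorted(range(k), key=lambda c: (-capacity[c], c))
        chosen = order[:memberships]
        if capacity[chosen[-1]] <= 0:
            raise RuntimeError("insufficient community capacity for overlaps")
        for c in chosen:
            capacity[c] -= 1
        membership[nodes[i]] = set(chosen)
    labels = [c for c in range(k) for _ in range(capacity[c])]
    rng.shuffle(labels)
    rest = [i for i in range(n) if i not in overlap_set]
    for i, lab in zip(rest, labels):
        membership[nodes[i]] = {lab}

    communities: list[list[str]] = [[] for _ in range(k)]
    for i in range(n):
        for c in membership[nodes[i]]:
            communities[c].append(nodes[i])

    internal = np.array(
        [(1.0 - mixing) * degrees[i] / len(membership[nodes[i]]) for i in range(n)]
    )
    external = mixing * degrees.astype(float)

    net = Network()
    for v in nodes:
        net.add_node(v)
    index = {v: i for i, v in enumerate(nodes)}
    # internal edges, Chung-Lu per community
    for c in range(k):
        members = sorted(index[v] for v in communities[c])
        w = internal[members]
        total = w.sum()
        if total <= 0:
            continue
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                i, j = members[a], members[b]
                p = min(1.0, internal[i] * internal[j] / total)
                if rng.random() < p and not net.has_edge(nodes[i], nodes[j]):
                    net.add_edge(nodes[i], nodes[j])
    # external edges between nodes sharing no community
    total_ext = external.sum()
    if total_ext > 0:
        for i in range(n):
            if external[i] <= 0:
                continue
            mi = membership[nodes[i]]
            for j in range(i + 1, n):
                if external[j] <= 0 or (mi & membership[nodes[j]]):
                    continue
                p = min(1.0, external[i] * external[j] / total_ext)
                if rng.random() < p:
                    net.add_edge(nodes[i], nodes[j])

    realized = _realized_mixing(net, membership)
    truth = ClusterSet(communities, provenance="lfr-like")
    params = {
        "n": n,
        "avg_deg": avg_deg,
        "max_deg": max_deg,
        "size_min": size_min,
        "size_max": size_max,
        "mixing": mixing,
        "overlap_nodes": overlap_nodes,
        "memberships": memberships,
        "seed": seed,
        "realized_mixing": realized,
        "n_communities": k,
    }
    return PlantedBenchmark(net, truth, params)


def _realized_mixing(net: Network, membership: dict[str, set[int]]) -> float:
    """Mean over nodes of the fraction of their edges leaving all of
    their own communities."""
    fracs = []
    for v in net.nodes:
        nbrs = net.neighbors(v)
        if not nbrs:
            continue
        ext = sum(1 for u in nbrs if not (membership[v] & membership[u]))
        fracs.append(ext / len(nbrs))
    return float(np.mean(fracs)) if fracs else 0.0


def two_community_fixture() -> PlantedBenchmark:
    """Deterministic 9-node toy graph: two 4-cliques bridged by one node.

    Node ``d`` is adjacent to two members of each clique and is the
    planted overlapping node; the ground truth is each clique augmented
    with ``d``.
    """
    clique1 = ["a", "b", "c", "e"]
    clique2 = ["f", "g", "h", "i"]
    net = Network()
    for group in (clique1, clique2):
        for x in range(len(group)):
            for y in range(x + 1, len(group)):
                net.add_edge(group[x], group[y])
    for v in ("a", "b", "f", "g"):
        net.add_edge("d", v)
    truth = ClusterSet(
        [clique1 + ["d"], clique2 + ["d"]], provenance="two-community fixture"
    )
    return PlantedBenchmark(net, truth, {"overlap_node": "d"})
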