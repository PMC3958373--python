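"""Rough-set assignment of nodes to lower approximations and boundaries.

Each λ₁-cut class X is refined into a lower approximation (nodes that
certainly belong to X alone) and a boundary region (nodes shared with
other classes).  A node u is compared with every candidate class through
the node-to-set similarity S(u, X); the ratio of each S(u, Xᵢ) to the
maximum decides membership: ratios ≥ λ₂ for two or more classes place u
in all of their boundaries, otherwise u enters the lower approximation
of the best class.  The resulting cover satisfies the three rough-set
properties: a node lies in at most one lower approximation, every lower
approximation is contained in its upper approximation, and a node in no
lower approximation lies in at least two boundary regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fuzzy_core import CUT_TOL, Partition
from .graph_io import ClusterSet
from .similarity import FuzzyRelation

logger = logging.getLogger(__name__)

__all__ = ["RoughCover", "set_similarity", "rough_assign", "cover_to_clusters"]

SET_SIMILARITY_KINDS = ("mean", "max")


@dataclass(frozen=True)
class RoughCover:
    """Per-cluster lower approximation and boundary region.

    ``upper[i] = lower[i] | boundary[i]`` is the cluster read out by
    :func:`cover_to_clusters`; boundary members are the overlapping
    nodes.
    """

    lower: tuple[frozenset[str], ...]
    boundary: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if len(self.lower) != len(self.boundary):
            raise ValueError("lower and boundary must align cluster-wise")
        seen: set[str] = set()
        for lo in self.lower:
            if lo & seen:
                raise ValueError("a node may join at most one lower approximation")
            seen |= lo
        counts: dict[str, int] = {}
        for bd in self.boundary:
            for v in bd:
                counts[v] = counts.get(v, 0) + 1
        for v, k in counts.items():
            if v in seen:
                raise ValueError(
                    f"node {v!r} is in a lower approximation and a boundary"
                )
            if k < 2:
                raise ValueError(
                    f"boundary node {v!r} must lie in >= 2 boundary regions"
                )

    @property
    def upper(self) -> tuple[frozenset[str], ...]:
        return tuple(lo | bd for lo, bd in zip(self.lower, self.boundary))

    @property
    def n_clusters(self) -> int:
        return len(self.lower)

    def covered_nodes(self) -> frozenset[str]:
        out: set[str] = set()
        for up in self.upper:
            out |= up
        return frozenset(out)


def set_similarity(
    u: str, X: frozenset[str] | set[str], R: FuzzyRelation, kind: str = "mean"
) -> float:
    """Similarity S(u, X) between a node and a node set.

    Mean (default) or maximum of the pairwise grades to the members of
    X other than u itself; S(u, {u}) = 1 by convention.
    """
    if not X:
        raise ValueError("set similarity of an empty set is undefined")
    others = [v for v in X if v != u]
    if not others:
        return 1.0
    grades = [R[u, v] for v in others]
    if kind == "mean":
        return float(np.mean(grades))
    if kind == "max":
        return float(np.max(grades))
    raise ValueError(f"unknown set-similarity kind {kind!r}")


def rough_assign(
    part: Partition,
    R: FuzzyRelation,
    lam2: float = 0.7,
    kind: str = "mean",
) -> RoughCover:
    """Assign every node to lower approximations / boundary regions.

    For each node u the similarities sᵢ = S(u, Xᵢ) are computed for the
    candidate classes; with s* their maximum, the index set
    T(u) = {i : sᵢ / s* ≥ λ₂} holds all classes u plausibly belongs to.
    |T(u)| ≥ 2 puts u in the boundary of every class of T(u); |T(u)| = 1
    puts u in the lower approximation of the best class (which may
    differ from u's own cut class — the ratio rule overrides the cut).

    Singleton cut classes are unassigned nodes, not modules: they are
    excluded from the candidate classes for every node.  A node's own
    singleton {u} would otherwise always win the argmax (S(u, {u}) = 1
    by convention), stranding every bridge node, and a foreign
    singleton {w} would attract its neighbors through one strong
    pairwise grade that outweighs the mean grade to a genuine class.
    A node with zero similarity to every candidate class falls back to
    the lower approximation of its own cut class.
    """
    if not 0.0 < lam2 <= 1.0:
        raise ValueError(f"lambda2 must lie in (0, 1], got {lam2}")
    if kind not in SET_SIMILARITY_KINDS:
        raise ValueError(f"unknown set-similarity kind {kind!r}")
    if part.node_universe != frozenset(R.nodes):
        raise ValueError("partition does not cover the relation's node set")

    nodes = R.nodes
    idx = R.node_index
    k = len(part.classes)
    n = len(nodes)
    member = np.zeros((k, n), dtype=bool)
    for ci, cls in enumerate(part.classes):
        for v in cls:
            member[ci, idx[v]] = True
    sizes = member.sum(axis=1)

    g = R.grades.copy()
    np.fill_diagonal(g, 0.0)  # exclude self from node-to-set grades
    if kind == "mean":
        sums = member @ g.T  # (k, n): class-to-node grade sums, self excluded
        denom = sizes[:, None] - member.astype(float)  # |X \ {u}|
        with np.errstate(invalid="ignore", divide="ignore"):
            S = np.where(denom > 0, sums / denom, 1.0)
    else:
        S = np.empty((k, n))
        for ci in range(k):
            sub = g[member[ci]]
            S[ci] = sub.max(axis=0) if sub.shape[0] else 0.0
        # own singleton: no other members -> convention 1
        own_singleton = (sizes[:, None] == 1) & member
        S[own_singleton] = 1.0

    lower: list[set[str]] = [set() for _ in range(k)]
    boundary: list[set[str]] = [set() for _ in range(k)]
    candidates = sizes >= 2  # singleton cut classes are not modules
    for j, v in enumerate(nodes):
        own = part.class_of(v)
        s = S[:, j]
        s_cand = np.where(candidates, s, -np.inf)
        s_star = s_cand.max() if candidates.any() else -np.inf
        if not np.isfinite(s_star) or s_star <= CUT_TOL:
            lower[own].add(v)
            continue
        T = np.flatnonzero(candidates & (s >= lam2 * s_star - CUT_TOL))
        if T.size >= 2:
            for ci in T:
                boundary[ci].add(v)
        else:
            best = int(np.flatnonzero(s_cand == s_star)[0])
            lower[best].add(v)

    return RoughCover(
        tuple(frozenset(lo) for lo in lower),
        tuple(frozenset(bd) for bd in boundary),
    )


def cover_to_clusters(rc: RoughCover, min_size: int = 2) -> ClusterSet:
    """Read the upper approximations out as clusters, dropping those
    smaller than ``min_size`` (singletons are not complexes)."""
    kept: list[frozenset[str]] = []
    dropped = 0
    for up in rc.upper:
        if len(up) >= min_size:
            kept.append(up)
        elif up:
            dropped += 1
    if dropped:
        logger.info("dropped %d cluster(s) below min_size=%d", dropped, min_size)
    return ClusterSet(kept, provenance="rough cover")
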