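"""Overlap scoring and greedy merging of highly overlapping clusters.

Two clusters match to the degree ω(A, B) = |A∩B|² / (|A|·|B|): 0 when
disjoint, 1 when identical.  The default merging threshold 0.64
corresponds to an intersection of at least 80% of the size of two
equal-size sets; merging repeats greedily (highest ω first) until no
pair reaches the threshold.
"""

from __future__ import annotations

from .graph_io import ClusterSet

__all__ = ["overlap_score", "merge_overlapping", "sort_clusters"]


def overlap_score(A: frozenset[str] | set[str], B: frozenset[str] | set[str]) -> float:
    """Squared-intersection overlap ω(A, B) = |A∩B|² / (|A|·|B|)."""
    if not A or not B:
        raise ValueError("overlap score of an empty set is undefined")
    inter = len(set(A) & set(B))
    return inter * inter / (len(A) * len(B))


def sort_clusters(clusters, provenance: str = "") -> ClusterSet:
    """Deterministic output order: descending size, then lexicographic."""
    ordered = sorted(clusters, key=lambda c: (-len(c), sorted(c)))
    return ClusterSet(ordered, provenance=provenance)


def merge_overlapping(cs: ClusterSet, threshold: float = 0.64) -> ClusterSet:
    """Greedily merge the highest-ω pair while any pair has ω ≥ threshold.

    Ties on ω are broken toward the smaller combined size, then
    lexicographically, so the result is independent of input order.
    Each merge replaces two clusters by their union, so the loop
    terminates; on output every pairwise ω is < threshold.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"merge threshold must lie in (0, 1], got {threshold}")
    sets: list[frozenset[str]] = list(cs)
    while len(sets) > 1:
        best = None
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                w = overlap_score(sets[i], sets[j])
                if w < threshold - 1e-12:
                    continue
                union = sets[i] | sets[j]
                key = (-w, len(union), sorted(union))
                if best is None or key < best[0]:
                    best = (key, i, j, union)
        if best is None:
            break
        _, i, j, union = best
        sets = [s for k, s in enumerate(sets) if k not in (i, j)]
        sets.append(union)
    return sort_clusters(sets, provenance=cs.provenance)
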