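"""Fuzzy max-min algebra: transitive closure, λ-cut, automatic λ₁.

The transitive closure t(R) of a reflexive symmetric fuzzy relation is
the first fixpoint of repeated max-min squaring; its entry (u, v) equals
the max-min path capacity — the maximum over u–v paths of the minimum
grade along the path.  Cutting t(R) at level λ therefore yields exactly
the connected components of the graph that keeps raw-similarity edges
with grade ≥ λ, which is the fast path used on large networks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .similarity import FuzzyRelation

__all__ = [
    "Partition",
    "maxmin_compose",
    "transitive_closure",
    "lambda_cut",
    "auto_lambda1",
    "CUT_TOL",
]

#: absolute tolerance for grade comparisons at a cut
CUT_TOL = 1e-12


@dataclass(frozen=True)
class Partition:
    """Disjoint node classes covering the full node set."""

    classes: tuple[frozenset[str], ...]
    assignment: dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.classes:
            if not c:
                raise ValueError("partition classes must be non-empty")
            if c & seen:
                raise ValueError("partition classes must be disjoint")
            seen |= c
        if not self.assignment:
            object.__setattr__(
                self,
                "assignment",
                {v: i for i, c in enumerate(self.classes) for v in c},
            )
        elif set(self.assignment) != seen or any(
            v not in self.classes[i] for v, i in self.assignment.items()
        ):
            raise ValueError("assignment inconsistent with classes")

    def __len__(self) -> int:
        return len(self.classes)

    def __iter__(self):
        return iter(self.classes)

    @property
    def node_universe(self) -> frozenset[str]:
        return frozenset(self.assignment)

    def class_of(self, v: str) -> int:
        return self.assignment[v]


def _check_same_index(A: FuzzyRelation, B: FuzzyRelation) -> None:
    if A.nodes != B.nodes:
        raise ValueError("relations are defined over different node sets")


def maxmin_compose(A: FuzzyRelation, B: FuzzyRelation) -> FuzzyRelation:
    """Max-min composition: (A∘B)(u,v) = max_w min(A(u,w), B(w,v))."""
    _check_same_index(A, B)
    return FuzzyRelation(_compose_arrays(A.grades, B.grades), A.nodes, A.node_index)


def _compose_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.empty_like(a)
    # row-wise to keep the n×n×n broadcast out of memory
    for i in range(n):
        out[i] = np.minimum(a[i][:, None], b).max(axis=0)
    return out


def transitive_closure(R: FuzzyRelation) -> FuzzyRelation:
    """Smallest max-min transitive relation containing R, by repeated
    squaring; reached in at most ceil(log2(n-1)) squarings."""
    g = R.grades
    n = g.shape[0]
    if n <= 2:
        return R
    max_steps = math.ceil(math.log2(n - 1)) + 1
    cur = g
    for _ in range(max_steps):
        nxt = _compose_arrays(cur, cur)
        if np.array_equal(nxt, cur):
            break
        cur = nxt
    return FuzzyRelation(cur, R.nodes, R.node_index)


def lambda_cut(rel: FuzzyRelation, lam: float) -> Partition:
    """Partition nodes by the Boolean relation ``grade ≥ lam``.

    On a max-min transitive relation the cut is itself an equivalence
    relation; on a raw similarity relation the connected components of
    the thresholded graph coincide with the classes of the cut closure,
    so one component search serves both paths.  Classes are ordered by
    their first member in node order.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    mask = rel.grades >= lam - CUT_TOL
    np.fill_diagonal(mask, True)
    n_comp, labels = connected_components(csr_matrix(mask), directed=False)
    classes: list[set[str]] = [set() for _ in range(n_comp)]
    order: list[int] = []
    seen: set[int] = set()
    for v, lab in zip(rel.nodes, labels):
        classes[lab].add(v)
        if lab not in seen:
            seen.add(lab)
            order.append(lab)
    return Partition(tuple(frozenset(classes[lab]) for lab in order))


def auto_lambda1(R: FuzzyRelation) -> float:
    """Data-driven first threshold: the mean of the above-mean pairwise
    similarities.

    Only positive off-diagonal grades (adjacent pairs, each unordered
    pair once) enter; the mean over all n(n-1)/2 pairs of a sparse
    network would be ≈ 0 and give one giant class.  Falls back to the
    overall mean when no grade exceeds it (all grades equal).
    """
    off = R.off_diagonal()
    pos = off[off > 0]
    if pos.size == 0:
        raise ValueError(
            "no positive off-diagonal similarity: network has no edges"
        )
    mean = float(pos.mean())
    above = pos[pos > mean]
    if above.size == 0:
        return mean
    return float(above.mean())
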