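"""Fuzzy node-pair similarity: the relation R over the node set.

For an unweighted network the grade of an adjacent pair is a shared-
neighbor statistic on closed neighborhoods Γ(x) = N(x) ∪ {x}; the default
kernel is the structural cosine |Γ(u)∩Γ(v)| / sqrt(|Γ(u)|·|Γ(v)|), which
is 1 on the diagonal, 0 for non-adjacent pairs, and increases with the
number of shared neighbors at fixed degrees.  For a weighted network the
grade of an edge is its confidence weight, rescaled by the maximum weight
only when weights exceed 1 (confidence scores already in [0,1] pass
through unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_io import Network

__all__ = ["FuzzyRelation", "node_similarity", "similarity_matrix", "KERNELS"]

KERNELS = ("cosine", "jaccard", "min-overlap")


@dataclass(frozen=True)
class FuzzyRelation:
    """A reflexive symmetric matrix of membership grades in [0, 1]."""

    grades: np.ndarray
    nodes: tuple[str, ...]
    node_index: dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        g = np.asarray(self.grades, dtype=float)
        if g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ValueError("grades must be a square matrix")
        if g.shape[0] != len(self.nodes):
            raise ValueError("grade matrix order does not match node list")
        if np.any(g < -1e-12) or np.any(g > 1 + 1e-12):
            raise ValueError("grades must lie in [0, 1]")
        if not np.allclose(np.diag(g), 1.0, atol=1e-12):
            raise ValueError("relation must be reflexive (unit diagonal)")
        if not np.allclose(g, g.T, atol=1e-12):
            raise ValueError("relation must be symmetric")
        object.__setattr__(self, "grades", g)
        if not self.node_index:
            object.__setattr__(
                self, "node_index", {v: i for i, v in enumerate(self.nodes)}
            )

    @property
    def order(self) -> int:
        return len(self.nodes)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        u, v = pair
        return float(self.grades[self.node_index[u], self.node_index[v]])

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangle grades, each unordered pair once."""
        iu = np.triu_indices(self.order, k=1)
        return self.grades[iu]


def _closed_kernel(common: float, su: float, sv: float, kernel: str) -> float:
    if kernel == "cosine":
        return common / np.sqrt(su * sv)
    if kernel == "jaccard":
        return common / (su + sv - common)
    if kernel == "min-overlap":
        return common / min(su, sv)
    raise ValueError(f"unknown similarity kernel {kernel!r}")


def node_similarity(
    net: Network, u: str, v: str, kernel: str = "cosine"
) -> float:
    """Grade of a node pair: 1 if u = v, 0 if non-adjacent, else a
    shared-neighbor statistic on closed neighborhoods."""
    if u not in net or v not in net:
        missing = u if u not in net else v
        raise KeyError(f"unknown node {missing!r}")
    if u == v:
        return 1.0
    if not net.has_edge(u, v):
        return 0.0
    gu = set(net.neighbors(u)) | {u}
    gv = set(net.neighbors(v)) | {v}
    return float(_closed_kernel(len(gu & gv), len(gu), len(gv), kernel))


def similarity_matrix(
    net: Network, weighted: bool = False, kernel: str = "cosine"
) -> FuzzyRelation:
    """Build the fuzzy relation R for a whole network.

    Unweighted: entry (u, v) = node_similarity(u, v).  Weighted: entry
    (u, v) = w(u, v) / max(1, w_max) on edges, 0 off edges, 1 on the
    diagonal.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot build a similarity matrix for an empty network")
    if kernel not in KERNELS:
        raise ValueError(f"unknown similarity kernel {kernel!r}")
    n = net.n_nodes
    idx = {v: i for i, v in enumerate(net.nodes)}

    if weighted:
        if not net.is_weighted:
            raise ValueError(
                "weighted similarity requested for a network without weights"
            )
        grades = np.zeros((n, n))
        wmax = max(w for _, _, w in net.edges() if w is not None)
        scale = wmax if wmax > 1 else 1.0
        for u, v, w in net.edges():
            if w is None:
                raise ValueError(f"edge ({u}, {v}) has no weight")
            grades[idx[u], idx[v]] = grades[idx[v], idx[u]] = w / scale
        np.fill_diagonal(grades, 1.0)
        return FuzzyRelation(grades, net.nodes, idx)

    # closed adjacency B = A + I; B @ B counts shared closed neighbors
    adj = np.zeros((n, n))
    for u, v, _ in net.edges():
        adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = 1.0
    closed = adj + np.eye(n)
    common = closed @ closed
    sizes = closed.sum(axis=1)
    if kernel == "cosine":
        denom = np.sqrt(np.outer(sizes, sizes))
    elif kernel == "jaccard":
        denom = sizes[:, None] + sizes[None, :] - common
    else:  # min-overlap
        denom = np.minimum(sizes[:, None], sizes[None, :])
    with np.errstate(invalid="ignore"):
        grades = np.where(adj > 0, common / denom, 0.0)
    np.fill_diagonal(grades, 1.0)
    grades = np.clip(grades, 0.0, 1.0)
    return FuzzyRelation(grades, net.nodes, idx)
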