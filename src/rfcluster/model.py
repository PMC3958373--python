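"""Rough-fuzzy clustering model and results objects.

The pipeline composes five stages: (1) build the fuzzy similarity
relation R from topology or edge weights; (2) take its max-min
transitive closure t(R) (cut via the equivalent thresholded-components
fast path); (3) cut at λ₁ — chosen automatically as the mean of the
above-mean pairwise similarities unless fixed — into disjoint
equivalence classes; (4) refine each class with the rough-set ratio
rule at λ₂ into lower approximations and boundary regions, boundary
nodes being the overlapping members; (5) read the upper approximations
out as clusters and greedily merge pairs whose overlap score reaches
the merging threshold (default 0.64).

Usage follows the model/results convention::

    model = RoughFuzzyClustering.from_edgelist("network.tsv")
    res = model.fit()
    print(res.summary())
    res.clusters          # ClusterSet, possibly overlapping
    res.evaluate(truth)   # metric report against a reference family
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

from . import metrics as _metrics
from .fuzzy_core import Partition, auto_lambda1, lambda_cut
from .graph_io import ClusterSet, Network, read_edge_list
from .merge import merge_overlapping, sort_clusters
from .rough import RoughCover, cover_to_clusters, rough_assign, set_similarity
from .similarity import KERNELS, FuzzyRelation, similarity_matrix

logger = logging.getLogger(__name__)

__all__ = ["RFCConfig", "RoughFuzzyClustering", "RFCResults", "rfc_cluster"]


@dataclass(frozen=True)
class RFCConfig:
    """Tunable thresholds and kernels of the pipeline.

    lambda1: cut level for the fuzzy equivalence relation, or None for
        the automatic above-mean rule.
    lambda2: rough ratio threshold in (0, 1] deciding single versus
        multiple membership (lower values admit more overlap).
    merge_threshold: overlap score at or above which two clusters are
        merged; 0.64 corresponds to an 80% intersection of equal-size
        sets.
    min_size: smallest cluster reported.
    """

    weighted: bool = False
    lambda1: float | None = None
    lambda2: float = 0.7
    merge_threshold: float = 0.64
    min_size: int = 2
    similarity_kernel: str = "cosine"
    set_similarity: str = "mean"

    def __post_init__(self) -> None:
        if self.lambda1 is not None and not 0.0 <= self.lambda1 <= 1.0:
            raise ValueError("lambda1 must lie in [0, 1] or be None (auto)")
        if not 0.0 < self.lambda2 <= 1.0:
            raise ValueError("lambda2 must lie in (0, 1]")
        if not 0.0 < self.merge_threshold <= 1.0:
            raise ValueError("merge_threshold must lie in (0, 1]")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if self.similarity_kernel not in KERNELS:
            raise ValueError(f"unknown similarity kernel {self.similarity_kernel!r}")
        if self.set_similarity not in ("mean", "max"):
            raise ValueError(f"unknown set-similarity kind {self.set_similarity!r}")


class RoughFuzzyClustering:
    """Overlapping-cluster model for an undirected network."""

    def __init__(self, network: Network, config: RFCConfig | None = None, **overrides):
        if network.n_nodes == 0:
            raise ValueError("cannot cluster an empty network")
        self.network = network
        cfg = config or RFCConfig()
        if overrides:
            cfg = replace(cfg, **overrides)
        self.config = cfg

    @classmethod
    def from_edgelist(
        cls, path: str | Path, weighted: bool = False, **overrides
    ) -> "RoughFuzzyClustering":
        net = read_edge_list(path, weighted=weighted)
        return cls(net, weighted=weighted, **overrides)

    def fit(self) -> "RFCResults":
        cfg = self.config
        R = similarity_matrix(
            self.network, weighted=cfg.weighted, kernel=cfg.similarity_kernel
        )
        lam1 = cfg.lambda1 if cfg.lambda1 is not None else auto_lambda1(R)
        logger.info("lambda1 = %.4f (%s)", lam1, "fixed" if cfg.lambda1 else "auto")
        # cut the closure via its fast path: components of the graph
        # keeping raw-similarity edges with grade >= lambda1
        part = lambda_cut(R, lam1)
        logger.info("%d equivalence classes at the lambda1 cut", len(part))
        cover = rough_assign(part, R, lam2=cfg.lambda2, kind=cfg.set_similarity)
        clusters = cover_to_clusters(cover, min_size=cfg.min_size)
        logger.info("%d clusters before merging", len(clusters))
        merged = merge_overlapping(clusters, threshold=cfg.merge_threshold)
        logger.info("%d clusters after merging at %.2f", len(merged), cfg.merge_threshold)
        return RFCResults(
            model=self,
            relation=R,
            lambda1_=lam1,
            partition_=part,
            cover_=cover,
            pre_merge_clusters_=clusters,
            clusters=sort_clusters(merged, provenance="rfc"),
        )


@dataclass
class RFCResults:
    """Fitted clustering with per-stage diagnostics."""

    model: RoughFuzzyClustering
    relation: FuzzyRelation
    lambda1_: float
    partition_: Partition
    cover_: RoughCover
    pre_merge_clusters_: ClusterSet
    clusters: ClusterSet

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def overlapping_nodes(self) -> frozenset[str]:
        return self.clusters.overlapping_nodes()

    def to_partition(self) -> Partition:
        """Collapse the possibly overlapping clusters into a partition.

        Each node joins the final cluster to which its node-to-set
        similarity is highest (ties to the first cluster in output
        order); nodes in no reported cluster — dropped by the minimum
        size filter — keep their own singleton class.  This is the
        induced partition used for partition-level scores such as NMI.
        """
        best: dict[str, tuple[float, int]] = {}
        for ci, cluster in enumerate(self.clusters):
            for v in cluster:
                s = set_similarity(
                    v, cluster, self.relation, kind=self.model.config.set_similarity
                )
                if v not in best or s > best[v][0]:
                    best[v] = (s, ci)
        classes: list[set[str]] = [set() for _ in range(len(self.clusters))]
        for v, (_, ci) in best.items():
            classes[ci].add(v)
        out = [frozenset(c) for c in classes if c]
        for v in self.model.network.nodes:
            if v not in best:
                out.append(frozenset([v]))
        return Partition(tuple(out))

    def evaluate(
        self,
        reference: ClusterSet,
        omega: float = 0.25,
        restrict_universe: bool = True,
    ) -> dict[str, float]:
        """Score the fitted clusters against a reference family."""
        return _metrics.evaluate_clusters(
            reference, self.clusters, omega=omega, restrict_universe=restrict_universe
        )

    def summary(self) -> str:
        net, cfg = self.model.network, self.model.config
        sizes = sorted((len(c) for c in self.clusters), reverse=True)
        lines = [
            "Rough-Fuzzy Clustering Results",
            "==============================",
            f"Nodes:                  {net.n_nodes}",
            f"Edges:                  {net.n_edges}",
            f"Weighted:               {cfg.weighted}",
            f"Similarity kernel:      {cfg.similarity_kernel}",
            f"lambda1 (cut level):    {self.lambda1_:.4f}"
            + ("  [fixed]" if cfg.lambda1 is not None else "  [auto]"),
            f"lambda2 (ratio rule):   {cfg.lambda2:.2f}",
            f"Merge threshold:        {cfg.merge_threshold:.2f}",
            f"Equivalence classes:    {len(self.partition_)}",
            f"Clusters (pre-merge):   {len(self.pre_merge_clusters_)}",
            f"Clusters (final):       {self.n_clusters}",
            f"Overlapping nodes:      {len(self.overlapping_nodes)}",
        ]
        if sizes:
            lines.append(
                f"Cluster sizes:          max {sizes[0]}, median "
                f"{sizes[len(sizes) // 2]}, min {sizes[-1]}"
            )
        return "\n".join(lines)


def rfc_cluster(
    net: Network, config: RFCConfig | None = None, **overrides
) -> ClusterSet:
    """One-call pipeline: network in, (possibly overlapping) clusters out."""
    return RoughFuzzyClustering(net, config, **overrides).fit().clusters
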