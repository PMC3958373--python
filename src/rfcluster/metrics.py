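"""Evaluation criteria for predicted versus reference cluster families.

Implements the standard complex-prediction scores: partition NMI,
overlap-score matching (precision / recall / F1 at ω ≥ 0.25),
clustering-wise sensitivity Sn, positive predictive value PPV, geometric
accuracy Acc = sqrt(Sn·PPV), and the separation statistics rewarding
one-to-one correspondence.  All scores live in [0, 1].

The contingency table T has one row per known complex and one column per
predicted complex, with T_ij the number of members shared between known
complex i and predicted complex j.  By the usual evaluation convention
predicted complexes are first restricted to the universe of annotated
(known-complex) members, so PPV is not depressed by annotation gaps;
pass ``restrict_universe=False`` for the raw table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .fuzzy_core import Partition
from .graph_io import ClusterSet
from .merge import overlap_score

__all__ = [
    "ContingencyTable",
    "contingency",
    "nmi",
    "match_precision_recall_f1",
    "MatchScores",
    "sn_ppv_acc",
    "separation",
    "evaluate_clusters",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Known × predicted shared-member counts with known-complex sizes."""

    counts: np.ndarray
    known_sizes: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        s = np.asarray(self.known_sizes, dtype=int)
        if c.ndim != 2:
            raise ValueError("counts must be a matrix")
        if s.shape != (c.shape[0],):
            raise ValueError("one known size per row required")
        if np.any(c < 0) or np.any(s <= 0):
            raise ValueError("counts must be >= 0 and known sizes > 0")
        if np.any(c > s[:, None]):
            raise ValueError("T_ij cannot exceed the known complex size")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "known_sizes", s)

    @property
    def n_known(self) -> int:
        return self.counts.shape[0]

    @property
    def n_pred(self) -> int:
        return self.counts.shape[1]


def contingency(
    known: ClusterSet, predicted: ClusterSet, restrict_universe: bool = True
) -> ContingencyTable:
    """Build T_ij = |knownᵢ ∩ predictedⱼ|."""
    if len(known) == 0 or len(predicted) == 0:
        raise ValueError("both cluster families must be non-empty")
    universe = known.node_universe
    pred_sets = [set(p) for p in predicted]
    if restrict_universe:
        pred_sets = [p & universe for p in pred_sets]
    counts = np.array(
        [[len(set(k) & p) for p in pred_sets] for k in known], dtype=int
    )
    sizes = np.array([len(k) for k in known], dtype=int)
    return ContingencyTable(counts, sizes)


def _as_partition(p: Partition | ClusterSet) -> Partition:
    if isinstance(p, Partition):
        return p
    if not p.is_partition:
        raise ValueError(
            "NMI is defined for non-overlapping partitions only; "
            "overlapping cluster families are not supported"
        )
    return Partition(tuple(p.clusters))


def nmi(P: Partition | ClusterSet, Q: Partition | ClusterSet) -> float:
    """Partition NMI = 2·I(X;Y) / (H(X) + H(Y)), in [0, 1].

    Class probabilities are class sizes over n; the joint distribution
    comes from co-membership counts.  Conventions: 0·log 0 = 0; two
    trivial (single-class) partitions score 1; exactly one trivial
    partition scores 0.  Both inputs must cover the same node universe.
    """
    P = _as_partition(P)
    Q = _as_partition(Q)
    if P.node_universe != Q.node_universe:
        raise ValueError("partitions must cover the same node universe")
    n = len(P.node_universe)
    counts = np.zeros((len(P.classes), len(Q.classes)))
    for v in P.node_universe:
        counts[P.class_of(v), Q.class_of(v)] += 1
    pxy = counts / n
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)

    def entropy(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    hx, hy = entropy(px), entropy(py)
    if hx == 0.0 and hy == 0.0:
        return 1.0
    if hx == 0.0 or hy == 0.0:
        return 0.0
    nz = pxy > 0
    mi = float((pxy[nz] * np.log(pxy[nz] / np.outer(px, py)[nz])).sum())
    return max(0.0, min(1.0, 2.0 * mi / (hx + hy)))


class MatchScores(NamedTuple):
    precision: float
    recall: float
    f1: float
    n_matched_predicted: int
    n_matched_known: int


def match_precision_recall_f1(
    known: ClusterSet, predicted: ClusterSet, omega: float = 0.25
) -> MatchScores:
    """Overlap-score matching at threshold ω (default 0.25, i.e. two
    equal-size complexes sharing half their members).

    A predicted complex matches when some known complex reaches
    ω(p, k) ≥ omega and vice versa; precision and recall are the matched
    fractions of each family and F1 their harmonic mean.
    """
    if len(known) == 0 or len(predicted) == 0:
        raise ValueError("both cluster families must be non-empty")
    n_cp = sum(
        1 for p in predicted if any(overlap_score(p, k) >= omega for k in known)
    )
    n_ck = sum(
        1 for k in known if any(overlap_score(p, k) >= omega for p in predicted)
    )
    precision = n_cp / len(predicted)
    recall = n_ck / len(known)
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return MatchScores(precision, recall, f1, n_cp, n_ck)


def sn_ppv_acc(T: ContingencyTable) -> tuple[float, float, float]:
    """Clustering-wise sensitivity, positive predictive value, and their
    geometric mean.

    Sn = Σᵢ maxⱼ T_ij / Σᵢ Nᵢ ; PPV = Σⱼ maxᵢ T_ij / Σⱼ Σᵢ T_ij ;
    Acc = sqrt(Sn · PPV).
    """
    c = T.counts
    if c.sum() == 0:
        raise ValueError("all-zero contingency table: metrics undefined")
    sn = float(c.max(axis=1).sum() / T.known_sizes.sum())
    ppv = float(c.max(axis=0).sum() / c.sum())
    return sn, ppv, float(np.sqrt(sn * ppv))


def separation(T: ContingencyTable) -> tuple[float, float, float]:
    """Separation statistics rewarding one-to-one correspondence.

    sep_ij is the product of the row-wise and column-wise shares of
    T_ij; Sep_k averages the total over known complexes, Sep_p over
    predicted complexes, and Separation is their geometric mean.  Terms
    with a zero marginal contribute 0.
    """
    c = T.counts.astype(float)
    if c.sum() == 0:
        raise ValueError("all-zero contingency table: metrics undefined")
    row = c.sum(axis=1, keepdims=True)
    col = c.sum(axis=0, keepdims=True)
    # a zero marginal forces c = 0 on that line, so guarding the division
    # is enough to make those terms contribute 0
    sep = (c / np.where(row > 0, row, 1.0)) * (c / np.where(col > 0, col, 1.0))
    total = float(sep.sum())
    sep_k = total / T.n_known
    sep_p = total / T.n_pred
    return sep_k, sep_p, float(np.sqrt(sep_k * sep_p))


def evaluate_clusters(
    known: ClusterSet,
    predicted: ClusterSet,
    omega: float = 0.25,
    restrict_universe: bool = True,
) -> dict[str, float]:
    """All scores in one flat mapping; NMI included only when both
    families are partitions of the same universe."""
    ms = match_precision_recall_f1(known, predicted, omega)
    T = contingency(known, predicted, restrict_universe)
    sn, ppv, acc = sn_ppv_acc(T)
    sep_k, sep_p, sep = separation(T)
    report: dict[str, float] = {
        "precision": ms.precision,
        "recall": ms.recall,
        "f1": ms.f1,
        "ncp": float(ms.n_matched_predicted),
        "nck": float(ms.n_matched_known),
        "sn": sn,
        "ppv": ppv,
        "acc": acc,
        "sep_k": sep_k,
        "sep_p": sep_p,
        "separation": sep,
    }
    if (
        known.is_partition
        and predicted.is_partition
        and known.node_universe == predicted.node_universe
    ):
        report["nmi"] = nmi(known, predicted)
    return report
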