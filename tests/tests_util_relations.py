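"""Shared helper: build a small FuzzyRelation from sparse grade pairs."""

import numpy as np

from rfcluster import FuzzyRelation


def relation_from_grades(pairs, nodes):
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    g = np.eye(n)
    for (u, v), w in pairs.items():
        g[idx[u], idx[v]] = g[idx[v], idx[u]] = w
    return FuzzyRelation(g, tuple(nodes))
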