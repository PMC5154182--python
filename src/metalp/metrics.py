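"""Evaluation measures: modularity, normalized mutual information, sizes.

Both measures are always evaluated on the original (un-collapsed) graph, so
no self-loop convention enters here.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Dict, Hashable

from .graph import Graph, Partition

__all__ = ["modularity", "nmi", "size_distribution", "confusion_table"]


def modularity(graph: Graph, partition: Partition) -> float:
    """Newman-Girvan modularity Q = Σ_i (e_ii − a_i²).

    e_ii is the fraction of total edge weight internal to community i and
    a_i the fraction of edge-end weight attached to it. Weighted graphs use
    weight fractions; Q ∈ [−1, 1). The all-in-one partition scores exactly 0.
    """
    partition.require_covers(graph)
    if any(graph.self_loop(u) for u in graph.nodes()):
        raise ValueError("modularity is defined on the original graph "
                         "(no self-loops); got a collapsed graph")
    total = graph.total_edge_weight
    if total <= 0:
        raise ValueError("graph has no edges; modularity undefined")
    internal: Dict[Hashable, float] = {}
    strength: Dict[Hashable, float] = {}
    for u, v, w in graph.edges():
        cu, cv = partition[u], partition[v]
        strength[cu] = strength.get(cu, 0.0) + w
        strength[cv] = strength.get(cv, 0.0) + w
        if cu == cv:
            internal[cu] = internal.get(cu, 0.0) + w
    q = 0.0
    for c, s in strength.items():
        e_ii = internal.get(c, 0.0) / total
        a_i = s / (2.0 * total)
        q += e_ii - a_i * a_i
    return q


def confusion_table(real: Partition, detected: Partition):
    """Counts N_ij of nodes in real community i and detected community j,
    with row/column sums. Returns (N, row_labels, col_labels, N_i, N_j)."""
    if set(iter(real)) != set(iter(detected)):
        raise ValueError("partitions cover different node sets")
    counts: Counter = Counter((real[u], detected[u]) for u in real)
    rows = sorted({i for i, _ in counts}, key=str)
    cols = sorted({j for _, j in counts}, key=str)
    n_i = Counter(real[u] for u in real)
    n_j = Counter(detected[u] for u in detected)
    return counts, rows, cols, n_i, n_j


def nmi(real: Partition, detected: Partition) -> float:
    """Normalized mutual information between two partitions.

    I(A,B) = −2 Σ_ij N_ij ln(N_ij·N / (N_i·N_j))
             / [Σ_i N_i ln(N_i/N) + Σ_j N_j ln(N_j/N)]

    1 for identical partitions, 0 for independent ones. When both
    partitions are trivial (single community each, entropies vanish) the
    agreement is perfect and 1 is returned.
    """
    counts, rows, cols, n_i, n_j = confusion_table(real, detected)
    n = float(len(real))
    num = 0.0
    for (i, j), nij in counts.items():
        num += nij * math.log(nij * n / (n_i[i] * n_j[j]))
    den = sum(ni * math.log(ni / n) for ni in n_i.values())
    den += sum(nj * math.log(nj / n) for nj in n_j.values())
    if den == 0.0:
        return 1.0
    return -2.0 * num / den


def size_distribution(partition: Partition) -> Counter:
    """Histogram {community size: number of communities of that size}."""
    return Counter(partition.sizes().values())
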