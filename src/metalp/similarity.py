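"""Structural (cosine) similarity between adjacent nodes.

For adjacent nodes u, v the similarity compares their closed neighborhoods
N[u] = {u} ∪ neighbors(u):

    unweighted:  s(u,v) = |N[u] ∩ N[v]| / sqrt(|N[u]| · |N[v]|)

    weighted:    s(u,v) = Σ_{x ∈ N[u]∩N[v]} w(u,x)·w(v,x)
                          / sqrt(Σ_{x∈N[u]} w(u,x)² · Σ_{x∈N[v]} w(v,x)²)

with the self-term w(u,u) := 1, so on unit-weight graphs the weighted form
reduces exactly to the unweighted one. Since u and v are adjacent, the
intersection always contains both u and v, hence s(u,v) ∈ (0, 1]; s = 1
exactly when the closed neighborhoods coincide with proportional weights.
"""

from __future__ import annotations

import math
from typing import Dict, Iterator, Tuple

from .graph import Graph, Node

__all__ = ["SimilarityMap", "structural_similarity", "similarity_map"]


class SimilarityMap:
    """Per-edge similarity lookup, defined exactly for adjacent pairs."""

    __slots__ = ("_s",)

    def __init__(self, values: Dict[Tuple[Node, Node], float]) -> None:
        self._s = values

    def __call__(self, u: Node, v: Node) -> float:
        key = (u, v) if (u, v) in self._s else (v, u)
        try:
            return self._s[key]
        except KeyError:
            raise KeyError(f"no similarity for non-adjacent pair {u!r}, {v!r}") from None

    def __len__(self) -> int:
        return len(self._s)

    def __contains__(self, pair) -> bool:
        u, v = pair
        return (u, v) in self._s or (v, u) in self._s

    def items(self) -> Iterator[Tuple[Tuple[Node, Node], float]]:
        return iter(self._s.items())

    def values(self):
        return self._s.values()


def structural_similarity(graph: Graph, u: Node, v: Node) -> float:
    """Cosine similarity of the closed-neighborhood weight vectors of an
    adjacent pair. Raises ValueError for non-adjacent pairs."""
    if not graph.has_edge(u, v):
        raise ValueError(f"structural similarity is defined only for adjacent "
                         f"pairs; {u!r} and {v!r} are not adjacent")
    nu = graph.neighbors(u)
    nv = graph.neighbors(v)
    # closed-neighborhood weight vectors with w(u,u) = 1
    norm_u = 1.0 + sum(w * w for w in nu.values())
    norm_v = 1.0 + sum(w * w for w in nv.values())
    # common terms: x = u (w(u,u)*w(v,u)), x = v (w(u,v)*w(v,v)), shared neighbors
    dot = nv[u] + nu[v]
    small, other = (nu, nv) if len(nu) <= len(nv) else (nv, nu)
    for x, w in small.items():
        if x in other:
            dot += w * other[x]
    return dot / math.sqrt(norm_u * norm_v)


def similarity_map(graph: Graph) -> SimilarityMap:
    """Similarity for every edge of the graph; O(k·m) for max degree k.

    Computed once per graph and reused across resolution sweeps.
    """
    if graph.n == 0:
        raise ValueError("graph is empty")
    values: Dict[Tuple[Node, Node], float] = {}
    for u, v, _ in graph.edges():
        values[(u, v)] = structural_similarity(graph, u, v)
    return SimilarityMap(values)
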