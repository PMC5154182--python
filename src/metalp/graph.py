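"""Undirected weighted graph with self-loops, partitions, and graph collapse.

The graph model is deliberately minimal: community detection only needs
symmetric adjacency with positive edge weights, plus a per-node self-loop
weight that appears when a partitioned graph is collapsed (the self-loop of
a macro-node stores the total weight internal to its block).
"""

from __future__ import annotations

from collections import Counter
from typing import Any, Dict, Hashable, Iterable, Iterator, Mapping, Tuple

Node = Hashable

__all__ = ["Graph", "Partition", "collapse"]


class Graph:
    """Undirected weighted graph with optional per-node self-loop weights.

    Edge weights are strictly positive; self-loop weights are nonnegative
    and default to 0 (they arise only by collapsing a partitioned graph).
    Adding an edge that already exists accumulates its weight.
    """

    __slots__ = ("_adj", "_self")

    def __init__(self) -> None:
        self._adj: Dict[Node, Dict[Node, float]] = {}
        self._self: Dict[Node, float] = {}

    # -- construction -------------------------------------------------

    def add_node(self, u: Node) -> None:
        if u not in self._adj:
            self._adj[u] = {}
            self._self[u] = 0.0

    def add_edge(self, u: Node, v: Node, weight: float = 1.0) -> None:
        """Add (or accumulate onto) the undirected edge u-v."""
        if u == v:
            raise ValueError(f"self-referential edge {u!r}-{v!r} not allowed")
        if not weight > 0:
            raise ValueError(f"edge weight must be positive, got {weight!r}")
        self.add_node(u)
        self.add_node(v)
        w = self._adj[u].get(v, 0.0) + float(weight)
        self._adj[u][v] = w
        self._adj[v][u] = w

    def add_self_loop(self, u: Node, weight: float) -> None:
        if weight < 0:
            raise ValueError(f"self-loop weight must be nonnegative, got {weight!r}")
        self.add_node(u)
        self._self[u] += float(weight)

    # -- queries ------------------------------------------------------

    @property
    def n(self) -> int:
        """Number of nodes."""
        return len(self._adj)

    @property
    def m(self) -> int:
        """Number of edges (self-loops excluded)."""
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def __contains__(self, u: Node) -> bool:
        return u in self._adj

    def __len__(self) -> int:
        return len(self._adj)

    def nodes(self) -> Iterator[Node]:
        return iter(self._adj)

    def edges(self) -> Iterator[Tuple[Node, Node, float]]:
        """Yield each undirected edge once as (u, v, weight)."""
        seen = set()
        for u, nbrs in self._adj.items():
            for v, w in nbrs.items():
                if v not in seen:
                    yield u, v, w
            seen.add(u)

    def neighbors(self, u: Node) -> Mapping[Node, float]:
        """Neighbor -> edge-weight mapping for u (read-only view)."""
        return self._adj[u]

    def degree(self, u: Node) -> int:
        return len(self._adj[u])

    def weighted_degree(self, u: Node) -> float:
        return sum(self._adj[u].values())

    def has_edge(self, u: Node, v: Node) -> bool:
        return u in self._adj and v in self._adj[u]

    def weight(self, u: Node, v: Node) -> float:
        try:
            return self._adj[u][v]
        except KeyError:
            raise KeyError(f"no edge {u!r}-{v!r}") from None

    def self_loop(self, u: Node) -> float:
        return self._self[u]

    @property
    def total_edge_weight(self) -> float:
        return sum(w for _, _, w in self.edges())

    @property
    def total_self_loop_weight(self) -> float:
        return sum(self._self.values())

    @property
    def total_weight(self) -> float:
        """Total edge weight plus total self-loop weight (conserved by collapse)."""
        return self.total_edge_weight + self.total_self_loop_weight

    def max_degree(self) -> int:
        return max((len(n) for n in self._adj.values()), default=0)

    def connected_components(self) -> list[set]:
        comps = []
        unseen = set(self._adj)
        while unseen:
            root = unseen.pop()
            comp = {root}
            stack = [root]
            while stack:
                u = stack.pop()
                for v in self._adj[u]:
                    if v in unseen:
                        unseen.discard(v)
                        comp.add(v)
                        stack.append(v)
            comps.append(comp)
        return comps

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Graph n={self.n} m={self.m}>"

    # -- interop ------------------------------------------------------

    @classmethod
    def from_networkx(cls, nxg: Any, weighted: bool = False) -> "Graph":
        """Convert a networkx (multi)graph; parallel edges are summed,
        self-loops rejected."""
        g = cls()
        for u in nxg.nodes():
            g.add_node(u)
        for u, v, data in nxg.edges(data=True):
            if u == v:
                raise ValueError(f"input graph has a self-loop at {u!r}")
            w = float(data.get("weight", 1.0)) if weighted else 1.0
            g.add_edge(u, v, w)
        return g

    def to_networkx(self) -> Any:
        import networkx as nx

        nxg = nx.Graph()
        nxg.add_nodes_from(self.nodes())
        nxg.add_weighted_edges_from(self.edges())
        return nxg


class Partition:
    """Total assignment of nodes to opaque community labels."""

    __slots__ = ("_membership",)

    def __init__(self, membership: Mapping[Node, Hashable]) -> None:
        self._membership = dict(membership)
        if not self._membership:
            raise ValueError("partition must be nonempty")

    @classmethod
    def from_blocks(cls, blocks: Iterable[Iterable[Node]]) -> "Partition":
        membership: Dict[Node, Hashable] = {}
        for label, block in enumerate(blocks):
            block = list(block)
            if not block:
                raise ValueError("empty community block")
            for u in block:
                if u in membership:
                    raise ValueError(f"node {u!r} appears in two blocks")
                membership[u] = label
        return cls(membership)

    @classmethod
    def singletons(cls, nodes: Iterable[Node]) -> "Partition":
        return cls({u: u for u in nodes})

    def __getitem__(self, u: Node) -> Hashable:
        return self._membership[u]

    def __contains__(self, u: Node) -> bool:
        return u in self._membership

    def __len__(self) -> int:
        return len(self._membership)

    def __iter__(self) -> Iterator[Node]:
        return iter(self._membership)

    def items(self):
        return self._membership.items()

    def labels(self) -> set:
        return set(self._membership.values())

    @property
    def n_communities(self) -> int:
        return len(self.labels())

    def blocks(self) -> Dict[Hashable, set]:
        out: Dict[Hashable, set] = {}
        for u, lab in self._membership.items():
            out.setdefault(lab, set()).add(u)
        return out

    def sizes(self) -> Counter:
        return Counter(self._membership.values())

    def covers(self, graph: Graph) -> bool:
        return all(u in self._membership for u in graph.nodes())

    def require_covers(self, graph: Graph) -> None:
        for u in graph.nodes():
            if u not in self._membership:
                raise ValueError(f"partition does not cover node {u!r}")

    def same_block(self, u: Node, v: Node) -> bool:
        return self._membership[u] == self._membership[v]

    def relabel(self, mapping: Mapping[Hashable, Hashable]) -> "Partition":
        """Compose membership with a label -> new-label mapping."""
        return Partition({u: mapping[lab] for u, lab in self._membership.items()})

    def __eq__(self, other: object) -> bool:
        """Equality up to label renaming (same blocks)."""
        if not isinstance(other, Partition):
            return NotImplemented
        if set(self._membership) != set(other._membership):
            return False
        fwd: Dict[Hashable, Hashable] = {}
        bwd: Dict[Hashable, Hashable] = {}
        for u, a in self._membership.items():
            b = other._membership[u]
            if fwd.setdefault(a, b) != b or bwd.setdefault(b, a) != a:
                return False
        return True

    def __hash__(self):  # pragma: no cover
        raise TypeError("Partition is unhashable (equality is up to relabeling)")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Partition n={len(self)} communities={self.n_communities}>"


def collapse(graph: Graph, partition: Partition) -> Tuple[Graph, Dict[Node, Hashable]]:
    """Aggregate a partitioned graph into its quotient (macro) graph.

    One macro-node per community block. The weight of a macro-edge is the
    total weight of original edges crossing the two blocks; the self-loop of
    a macro-node is the total weight of edges internal to its block (each
    counted once) plus the pre-existing self-loops of the block's nodes.
    Total weight (edges + self-loops) is conserved exactly.

    Returns the collapsed graph and the original-node -> macro-node mapping.
    """
    partition.require_covers(graph)
    out = Graph()
    projection: Dict[Node, Hashable] = {}
    for u in graph.nodes():
        lab = partition[u]
        projection[u] = lab
        out.add_node(lab)
        s = graph.self_loop(u)
        if s:
            out.add_self_loop(lab, s)
    for u, v, w in graph.edges():
        cu, cv = projection[u], projection[v]
        if cu == cv:
            out.add_self_loop(cu, w)
        else:
            out.add_edge(cu, cv, w)
    return out, projection
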