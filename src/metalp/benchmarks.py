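"""Synthetic benchmark generators with planted partitions.

Each generator returns a :class:`BenchmarkInstance` bundling the graph,
the planted ground-truth partition, and the parameters (including the
seed) needed to regenerate it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Dict, Optional

import networkx as nx
import numpy as np

from .graph import Graph, Partition

__all__ = [
    "BenchmarkInstance",
    "gn_benchmark",
    "ring_of_cliques",
    "er_random",
    "sf_random",
    "lfr_benchmark",
]


@dataclass(frozen=True)
class BenchmarkInstance:
    graph: Graph
    planted: Partition
    params: Dict[str, Any]


def gn_benchmark(mu: float, seed: Optional[int] = None) -> BenchmarkInstance:
    """Planted-partition benchmark: 128 nodes in four groups of 32.

    Edges are placed independently with probability p_in inside groups and
    p_out between them, chosen so the expected degree of every node is 16:
    p_in = 16(1−μ)/31 and p_out = 16μ/96, where the mixing parameter μ is
    the expected fraction of a node's edges leaving its group.
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"mu must be in [0, 1], got {mu}")
    p_in = 16.0 * (1.0 - mu) / 31.0
    p_out = 16.0 * mu / 96.0
    nxg = nx.planted_partition_graph(4, 32, p_in, p_out, seed=seed)
    graph = Graph.from_networkx(nxg)
    planted = Partition({u: u // 32 for u in range(128)})
    return BenchmarkInstance(
        graph, planted, {"generator": "gn", "mu": mu, "p_in": p_in,
                         "p_out": p_out, "n": 128, "seed": seed}
    )


def ring_of_cliques(
    num_cliques: int,
    clique_size: int,
    seed: Optional[int] = None,
    topology: str = "ring",
) -> BenchmarkInstance:
    """Identical cliques joined by single edges, in a ring (default) or chain.

    The classic resolution-limit construction: cliques of at least three
    nodes, consecutive cliques connected by exactly one edge. The planted
    partition is the cliques themselves. Deterministic; the seed is kept
    only for interface uniformity.
    """
    if num_cliques < 2:
        raise ValueError(f"need at least 2 cliques, got {num_cliques}")
    if clique_size < 3:
        raise ValueError(f"clique_size must be >= 3, got {clique_size}")
    if topology not in ("ring", "chain"):
        raise ValueError(f"topology must be 'ring' or 'chain', got {topology!r}")
    g = Graph()
    for c in range(num_cliques):
        base = c * clique_size
        for i in range(clique_size):
            for j in range(i + 1, clique_size):
                g.add_edge(base + i, base + j)
    n_bridges = num_cliques if topology == "ring" else num_cliques - 1
    for c in range(n_bridges):
        nxt = (c + 1) % num_cliques
        g.add_edge(c * clique_size + 1, nxt * clique_size)
    planted = Partition({u: u // clique_size for u in range(num_cliques * clique_size)})
    return BenchmarkInstance(
        g, planted, {"generator": "cliques", "num_cliques": num_cliques,
                     "clique_size": clique_size, "topology": topology, "seed": seed}
    )


def er_random(n: int, avg_degree: float, seed: Optional[int] = None) -> BenchmarkInstance:
    """Erdős–Rényi G(n, p) with p = avg_degree/(n−1).

    A homogeneous random graph has no community structure, so the planted
    partition is a single community containing every node.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if not 0.0 <= avg_degree < n - 1:
        raise ValueError(f"avg_degree must be in [0, n-1), got {avg_degree}")
    p = avg_degree / (n - 1)
    nxg = nx.fast_gnp_random_graph(n, p, seed=seed)
    graph = Graph.from_networkx(nxg)
    planted = Partition({u: 0 for u in range(n)})
    return BenchmarkInstance(
        graph, planted, {"generator": "er", "n": n, "avg_degree": avg_degree,
                         "p": p, "seed": seed}
    )


def _power_law_degrees(
    n: int, avg_degree: float, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """Degree sequence from a truncated discrete power law k^exponent on
    [k_min, n−1], with k_min in 1..10 chosen so the expected mean is
    closest to avg_degree."""
    k_max = n - 1
    best_kmin, best_gap = 1, float("inf")
    for k_min in range(1, 11):
        ks = np.arange(k_min, k_max + 1, dtype=float)
        pmf = ks ** exponent
        pmf /= pmf.sum()
        gap = abs((ks * pmf).sum() - avg_degree)
        if gap < best_gap:
            best_kmin, best_gap = k_min, gap
    ks = np.arange(best_kmin, k_max + 1)
    pmf = ks.astype(float) ** exponent
    pmf /= pmf.sum()
    deg = rng.choice(ks, size=n, p=pmf)
    if deg.sum() % 2:  # configuration model needs an even degree sum
        deg[int(rng.integers(n))] += 1
    return deg


def sf_random(
    n: int,
    avg_degree: float,
    exponent: float = -2.0,
    seed: Optional[int] = None,
    max_tries: int = 10,
) -> BenchmarkInstance:
    """Scale-free random graph via the configuration model.

    Degrees are drawn from a power law with the given (negative) exponent,
    truncated so the realized mean approximates avg_degree; self-loops and
    multi-edges of the pairing are discarded. Planted partition: one
    community.
    """
    if exponent >= -1:
        raise ValueError(f"exponent must be < -1, got {exponent}")
    if n < 3:
        raise ValueError(f"n must be >= 3, got {n}")
    rng = np.random.default_rng(seed)
    last_err: Optional[Exception] = None
    for _ in range(max_tries):
        deg = _power_law_degrees(n, avg_degree, exponent, rng)
        try:
            multigraph = nx.configuration_model(
                deg.tolist(), seed=int(rng.integers(2**31))
            )
        except nx.NetworkXError as err:  # infeasible sequence
            last_err = err
            continue
        nxg = nx.Graph(multigraph)
        nxg.remove_edges_from(nx.selfloop_edges(nxg))
        graph = Graph.from_networkx(nxg)
        planted = Partition({u: 0 for u in range(n)})
        return BenchmarkInstance(
            graph, planted, {"generator": "sf", "n": n, "avg_degree": avg_degree,
                             "exponent": exponent, "seed": seed}
        )
    raise RuntimeError(
        f"could not realize a configuration-model graph after {max_tries} tries "
        f"(n={n}, avg_degree={avg_degree}, exponent={exponent}): {last_err}"
    )


_SIZE_RANGES = {"S": (10, 50), "B": (20, 100)}


def lfr_benchmark(
    n: int,
    mu: float,
    avg_degree: float = 20.0,
    max_degree: int = 50,
    tau_degree: float = 2.0,
    tau_size: float = 1.05,
    size_range: str = "S",
    seed: Optional[int] = None,
) -> BenchmarkInstance:
    """LFR benchmark with heterogeneous degrees and community sizes.

    Thin adapter over networkx's LFR generator (a published third-party
    benchmark, deliberately not reimplemented). tau_degree/tau_size are the
    magnitudes of the power-law exponents for degrees and community sizes;
    community sizes use 1.05 by default, the closest feasible value to an
    exponent of −1 for this generator. size_range presets: "S" = 10–50
    nodes per community, "B" = 20–100.
    """
    if size_range not in _SIZE_RANGES:
        raise ValueError(f"size_range must be one of {sorted(_SIZE_RANGES)}")
    min_c, max_c = _SIZE_RANGES[size_range]
    # Solve for the min degree whose truncated power-law mean hits
    # avg_degree; the generator's own average-degree search is unreliable
    # at steep exponents.
    ks = np.arange(1, max_degree + 1, dtype=float)
    weights = ks ** (-tau_degree)
    means = np.array([
        (ks[k0 - 1:] * weights[k0 - 1:]).sum() / weights[k0 - 1:].sum()
        for k0 in range(1, max_degree + 1)
    ])
    min_degree = int(np.argmin(np.abs(means - avg_degree))) + 1
    try:
        nxg = nx.LFR_benchmark_graph(
            n,
            tau1=tau_degree,
            tau2=tau_size,
            mu=mu,
            min_degree=min_degree,
            max_degree=max_degree,
            min_community=min_c,
            max_community=max_c,
            seed=seed,
        )
    except nx.ExceededMaxIterations as err:
        raise RuntimeError(
            f"LFR generation infeasible for n={n}, mu={mu}, "
            f"avg_degree={avg_degree}, max_degree={max_degree}, "
            f"size_range={size_range!r}, seed={seed}: {err}"
        ) from None
    nxg.remove_edges_from(nx.selfloop_edges(nxg))
    graph = Graph.from_networkx(nxg)
    communities = {frozenset(nxg.nodes[u]["community"]) for u in nxg}
    planted = Partition.from_blocks(sorted(communities, key=lambda b: min(b)))
    return BenchmarkInstance(
        graph, planted, {"generator": "lfr", "n": n, "mu": mu,
                         "avg_degree": avg_degree, "max_degree": max_degree,
                         "tau_degree": tau_degree, "tau_size": tau_size,
                         "size_range": size_range, "seed": seed}
    )
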