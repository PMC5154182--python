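"""Multi-resolution community detection by multilevel label propagation.

The algorithm has two stages:

1. **Initialization** — asynchronous label propagation on the input graph,
   with per-edge structural similarities as weights. Each node repeatedly
   adopts a label maximizing the summed similarity to the neighbors
   carrying it, until every node's label is among its locally most similar
   labels. This gathers similar nodes into meta-communities.

2. **Multilevel label propagation** — repeat: collapse the graph by the
   current meta-communities (internal weight becomes a macro-node
   self-loop, cross weight a macro-edge), then run weighted label
   propagation on the collapsed graph with each macro-node's self-loop
   rescaled by the resolution parameter λ. A macro-node keeps its own
   label only while its rescaled internal cohesion strictly exceeds its
   attraction to every competing label; otherwise it merges. Levels repeat
   until no merges occur, i.e. until every meta-community is a community:

       λ · w_internal(V_i)  >  w(V_i, V_j)   for every other community V_j.

λ controls the observation scale: large λ keeps communities small and
tight, λ → 0 merges everything into connected components. λ = 1 is the
default. Internal weight counts each internal edge once; values of λ above
1 are accepted and give a still finer resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Optional, Sequence

import numpy as np

from . import metrics
from .graph import Graph, Node, Partition, collapse
from .similarity import SimilarityMap, similarity_map

__all__ = [
    "ConvergenceWarning",
    "DetectorConfig",
    "LevelRecord",
    "DetectionResult",
    "initialize_labels",
    "satisfies_criterion",
    "propagate_labels",
    "detect_communities",
    "sweep_lambda",
]


class ConvergenceWarning(UserWarning):
    """Label propagation hit its sweep cap before reaching a fixed point."""


@dataclass(frozen=True)
class DetectorConfig:
    """Detector settings.

    lam: resolution parameter λ ≥ 0 (default 1, the natural-community
        scale); larger values yield smaller, tighter communities.
    seed: seed for the label-propagation node orders and tie-breaks.
    max_sweeps_per_lp: safety cap on sweeps within one propagation stage.
    max_levels: safety cap on collapse/propagate levels.
    """

    lam: float = 1.0
    seed: Optional[int] = None
    max_sweeps_per_lp: int = 100
    max_levels: int = 50

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if self.max_sweeps_per_lp < 1 or self.max_levels < 1:
            raise ValueError("sweep/level caps must be >= 1")


@dataclass(frozen=True)
class LevelRecord:
    """Per-level diagnostics: meta-community count and modularity of the
    projected partition on the original graph."""

    level: int
    n_meta: int
    modularity: float


@dataclass
class DetectionResult:
    """Outcome of a detection run on the original graph."""

    partition: Partition
    levels: int
    diagnostics: List[LevelRecord]
    lam: float
    seed: Optional[int]
    converged: bool = True
    criterion_satisfied: bool = True
    final_collapsed: Optional[Graph] = field(default=None, repr=False)

    @property
    def n_communities(self) -> int:
        return self.partition.n_communities


def _ordered_nodes(graph: Graph) -> list:
    return sorted(graph.nodes(), key=str)


def _lp_sweeps(
    graph: Graph,
    labels: Dict[Node, Hashable],
    affinity_weight,
    self_affinity,
    rng: np.random.Generator,
    max_sweeps: int,
) -> bool:
    """Generic asynchronous label propagation; mutates ``labels`` in place.

    affinity_weight(u, v) -> contribution of neighbor v to its label's
    affinity at u; self_affinity(u) -> contribution of u itself to its own
    current label (0 in the initialization stage, λ·self-loop on collapsed
    graphs). Keeps the current label on ties only when at least one
    neighbor supports it; an unsupported exact tie means the node's own
    cohesion does not strictly exceed the external attraction, so it
    merges. Returns True if a fixed point was reached within max_sweeps.
    """
    order = np.array(_ordered_nodes(graph), dtype=object)
    for _ in range(max_sweeps):
        rng.shuffle(order)
        changed = 0
        for u in order:
            nbrs = graph.neighbors(u)
            if not nbrs:
                continue
            aff: Dict[Hashable, float] = {}
            for v in nbrs:
                lab = labels[v]
                aff[lab] = aff.get(lab, 0.0) + affinity_weight(u, v)
            own = labels[u]
            supported = own in aff
            own_aff = aff.get(own, 0.0) + self_affinity(u)
            best_foreign = max(
                (a for lab, a in aff.items() if lab != own), default=None
            )
            if best_foreign is None:
                continue
            if own_aff > best_foreign or (own_aff == best_foreign and supported):
                continue
            candidates = sorted(
                (lab for lab, a in aff.items() if a == best_foreign and lab != own),
                key=str,
            )
            labels[u] = candidates[int(rng.integers(len(candidates)))]
            changed += 1
        if changed == 0:
            return True
    return False


def initialize_labels(
    graph: Graph,
    sims: SimilarityMap,
    config: DetectorConfig,
    rng: Optional[np.random.Generator] = None,
) -> Partition:
    """Similarity-weighted label propagation forming the meta-communities.

    Starts from singleton labels and sweeps asynchronously in a seeded
    random order until each node's label is one of the most similar labels
    in its neighborhood. Hitting the sweep cap emits a ConvergenceWarning
    and returns the current labels.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    labels: Dict[Node, Hashable] = {u: u for u in graph.nodes()}
    ok = _lp_sweeps(
        graph,
        labels,
        affinity_weight=lambda u, v: sims(u, v),
        self_affinity=lambda u: 0.0,
        rng=rng,
        max_sweeps=config.max_sweeps_per_lp,
    )
    if not ok:
        warnings.warn(
            "initialization label propagation hit the sweep cap",
            ConvergenceWarning,
            stacklevel=2,
        )
    return Partition(labels)


def satisfies_criterion(collapsed: Graph, i: Node, lam: float) -> bool:
    """Community criterion for macro-node i of a collapsed graph.

    True iff λ times the internal weight of i (its self-loop) strictly
    exceeds the weight shared with EVERY adjacent macro-node. Exact ties
    fail (the community would merge).
    """
    if i not in collapsed:
        raise KeyError(f"unknown macro-node {i!r}")
    cohesion = lam * collapsed.self_loop(i)
    return all(cohesion > w for w in collapsed.neighbors(i).values())


def propagate_labels(
    collapsed: Graph,
    config: DetectorConfig,
    rng: Optional[np.random.Generator] = None,
) -> Partition:
    """Weighted label propagation on a collapsed graph.

    Each macro-node starts with its own label. Its affinity to a label is
    the summed macro-edge weight to neighbors holding it, plus λ times its
    own self-loop for its current label. A macro-node whose label nobody
    else holds keeps it only under strict dominance — exactly the community
    criterion — so the retained singletons at the fixed point are the
    macro-nodes that already are communities.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lam = config.lam
    labels: Dict[Node, Hashable] = {u: u for u in collapsed.nodes()}
    ok = _lp_sweeps(
        collapsed,
        labels,
        affinity_weight=lambda u, v: collapsed.weight(u, v),
        self_affinity=lambda u: lam * collapsed.self_loop(u),
        rng=rng,
        max_sweeps=config.max_sweeps_per_lp,
    )
    if not ok:
        warnings.warn(
            "multilevel label propagation hit the sweep cap",
            ConvergenceWarning,
            stacklevel=2,
        )
    return Partition(labels)


def detect_communities(
    graph: Graph,
    config: Optional[DetectorConfig] = None,
    sims: Optional[SimilarityMap] = None,
    **kwargs,
) -> DetectionResult:
    """Run the full two-stage algorithm and return the final partition.

    Keyword arguments (lam, seed, ...) build a DetectorConfig when none is
    given. ``sims`` allows reuse of a precomputed similarity map across
    resolution sweeps. Isolated nodes end as singleton communities.
    """
    if config is None:
        config = DetectorConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a config or keyword settings, not both")
    if graph.n == 0:
        raise ValueError("graph is empty")
    if sims is None:
        sims = similarity_map(graph)
    rng = np.random.default_rng(config.seed)

    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        membership = dict(initialize_labels(graph, sims, config, rng=rng).items())
        converged &= not caught

    has_edges = graph.m > 0
    diagnostics: List[LevelRecord] = []

    def record(level: int, n_meta: int) -> None:
        q = metrics.modularity(graph, Partition(membership)) if has_edges else 0.0
        diagnostics.append(LevelRecord(level, n_meta, q))

    record(0, len(set(membership.values())))

    level = 0
    final_collapsed: Optional[Graph] = None
    while level < config.max_levels:
        level += 1
        collapsed, _ = collapse(graph, Partition(membership))
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            macro_labels = propagate_labels(collapsed, config, rng=rng)
            converged &= not caught
        n_before = collapsed.n
        n_after = macro_labels.n_communities
        if n_after >= n_before:
            final_collapsed = collapsed
            break
        membership = {u: macro_labels[membership[u]] for u in membership}
        record(level, n_after)
    else:
        converged = False
        warnings.warn(
            "detection hit the level cap before meta-communities stabilized",
            ConvergenceWarning,
            stacklevel=2,
        )
        final_collapsed, _ = collapse(graph, Partition(membership))

    criterion_ok = True
    if config.lam > 0 and final_collapsed is not None:
        criterion_ok = all(
            satisfies_criterion(final_collapsed, i, config.lam)
            for i in final_collapsed.nodes()
        )

    return DetectionResult(
        partition=Partition(membership),
        levels=level,
        diagnostics=diagnostics,
        lam=config.lam,
        seed=config.seed,
        converged=converged,
        criterion_satisfied=criterion_ok,
        final_collapsed=final_collapsed,
    )


def sweep_lambda(
    graph: Graph,
    lambdas: Sequence[float],
    seed: Optional[int] = None,
    **config_kwargs,
) -> List[DetectionResult]:
    """Detect at each λ in order, computing similarities only once.

    Every λ starts from the same seed, so repeated λ values give identical
    partitions.
    """
    if len(lambdas) == 0:
        raise ValueError("lambdas must be nonempty")
    sims = similarity_map(graph)
    results = []
    for lam in lambdas:
        cfg = DetectorConfig(lam=lam, seed=seed, **config_kwargs)
        results.append(detect_communities(graph, cfg, sims=sims))
    return results
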