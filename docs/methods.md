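# Methods

## Model and procedure

`metalp` treats community detection as a local comparison of cohesion and
attraction rather than the optimization of a global objective. A node
group V_i is a *community at resolution λ* when

    λ · w_in(V_i) > w(V_i, V_j)   for every other group V_j,

where w_in(V_i) is the total weight of edges internal to V_i (each edge
counted once) and w(V_i, V_j) the total weight shared between V_i and V_j.
The inequality is strict; an exact tie means the group merges. λ ≥ 0 sets
the observation scale: at λ = 0 attraction always wins and each connected
component collapses into one community; larger λ weights cohesion more
heavily and preserves smaller, tighter groups. λ = 1 is the default and
corresponds to the natural scale at which a group's internal weight must
beat each single external connection; values above 1 are accepted and
give finer partitions still.

The algorithm reaches a partition in which every community satisfies the
criterion through two stages:

1. **Initialization.** Per-edge structural similarities (cosine similarity
   of closed neighborhoods; see below) drive asynchronous label
   propagation from singleton labels: in a seeded random order, each node
   adopts a label maximizing the summed similarity to the neighbors
   currently holding it. The fixed point — every node's label is among its
   locally most similar labels — defines the initial meta-communities.
2. **Multilevel label propagation.** The graph is collapsed (macro-node
   per meta-community; internal weight → self-loop, cross weight →
   macro-edge; total weight conserved exactly), and weighted label
   propagation runs on the collapsed graph with each self-loop rescaled by
   λ *in the affinity scoring only* — stored weights stay unscaled so
   λ sweeps do not compound. A macro-node whose own label has no other
   supporter keeps it only under strict dominance, which makes "retained
   singleton" coincide exactly with "satisfies the criterion". Collapse
   and propagation alternate until a level produces no merges.

Because the final level is by construction a full sweep with no label
changes among singleton-labeled macro-nodes, the criterion holds for every
final community; the detector nevertheless re-checks it explicitly on the
final collapsed graph and records the result (`criterion_satisfied`).

## Structural similarity

For adjacent u, v with closed neighborhoods Γ(u) = {u} ∪ N(u):

    s(u,v) = Σ_{x ∈ Γ(u)∩Γ(v)} w(u,x)·w(v,x)
             / √( Σ_{x∈Γ(u)} w(u,x)² · Σ_{x∈Γ(v)} w(v,x)² ),

with the self-term defined as w(u,u) := 1. On unit-weight graphs this
reduces exactly to |Γ(u)∩Γ(v)| / √(|Γ(u)|·|Γ(v)|). Since adjacent closed
neighborhoods always share u and v, s ∈ (0, 1]. The self-term convention
matters only for weighted inputs (similarity is computed only on the
original graph, never on collapsed ones) and is chosen for exact
degeneration to the unweighted form. Similarities are computed once per
graph (O(k·m), maximum degree k) and cached across resolution sweeps.

## Conventions and numerical choices

- **Internal-weight counting.** The criterion counts each internal edge
  once. A twice-per-edge convention (summing over ordered node pairs)
  would only rescale λ by 2; one convention is used consistently
  everywhere. The once convention places the two-faction split of the
  karate network at λ = 0.6 and its three-community refinement at λ = 1.
- **Tie-breaking.** If a node's current label is supported by at least one
  neighbor and ties the best alternative, it is kept (damps oscillation);
  an *unsupported* tie merges, enforcing the criterion's strictness.
  Otherwise ties among foreign labels are broken uniformly at random with
  the seeded generator.
- **Update order.** A fresh seeded permutation per sweep, asynchronous
  updates; convergence is one full sweep with zero changes.
- **Safety caps.** `max_sweeps_per_lp` (default 100) and `max_levels`
  (default 50) convert any pathological oscillation into a
  `ConvergenceWarning` plus a `converged=False` flag, never an infinite
  loop or an exception. In practice the meta-community count drops
  sharply at every level and runs finish in a handful of levels.
- **Determinism.** One `numpy` generator seeded from `DetectorConfig.seed`
  drives all node orders and tie-breaks; identical graph + config + seed
  gives identical results, byte-for-byte through the CLI.
- **Degenerate inputs.** Isolated nodes never change label and end as
  singleton communities (the criterion is vacuously true without
  neighbors). Empty graphs are rejected. Metrics are always evaluated on
  the original graph, so no self-loop convention enters modularity.
- **Modularity diagnostics.** The modularity of the projected partition on
  the original graph is recorded at every level. It typically increases
  along the merge trajectory but this is monitored, not asserted — the
  algorithm does not optimize it.

## Evaluation measures

Modularity: Q = Σ_i (e_ii − a_i²) with weight fractions e_ij and attached
fractions a_i; the all-in-one partition scores exactly 0. NMI in the form

    I(A,B) = −2 Σ_ij N_ij ln(N_ij N / N_i N_j)
             / [ Σ_i N_i ln(N_i/N) + Σ_j N_j ln(N_j/N) ],

natural logarithms, 0·ln 0 = 0; 1 for identical partitions, 0 when the
detected partition is independent of (or uninformative about) the
reference; the doubly-trivial 0/0 case returns 1. This equals mutual
information normalized by the arithmetic mean of the entropies, which is
how the independent cross-check in the test suite (scikit-learn) is
configured.

## Synthetic benchmarks: what they emulate, what they do not

- **Planted-partition graphs** (`gn_benchmark`): 128 nodes, four groups of
  32, independent edges with p_in = 16(1−μ)/31, p_out = 16μ/96, so every
  node's expected degree is 16 and μ is the expected fraction of its edges
  leaving the group. Homogeneous degrees and equal group sizes — a clean
  accuracy dial, not a model of real networks.
- **Clique rings/chains** (`ring_of_cliques`): identical cliques (size
  ≥ 3) joined by single edges, the classic resolution-limit construction.
  The ring is the default minimal connected arrangement; a chain flag is
  provided since the published figures do not pin the topology down.
- **Random nulls** (`er_random`, `sf_random`): Erdős–Rényi and
  configuration-model graphs with a truncated power-law degree sequence
  (exponent −2 by default; minimum degree searched in 1..10 so the
  truncated mean matches the requested average; self-loops and multi-edges
  of the pairing discarded, which trims the realized mean below the target
  on heavy-tailed sequences). Their planted "partition" is a single
  community: the correct answer for a structureless graph.
- **LFR** (`lfr_benchmark`): delegated to networkx's generator — a
  published benchmark, not a contribution of this package. The adapter
  derives the minimum degree analytically from the requested average
  (the generator's own average-degree search is unreliable at steep
  exponents) and uses community-size exponent 1.05, the closest feasible
  value to 1 for this generator. Known limitations of the delegated
  implementation, inherited here: the realized mixing overshoots μ
  (≈ 0.17 at μ = 0.1), the nominal maximum degree can be slightly
  exceeded, μ = 0 and small n (≈ 250) are infeasible. LFR therefore
  serves as an exploratory benchmark only.

Passing on these generators shows scale separation, null behavior and
resolution-limit immunity under controlled conditions; it does not certify
accuracy on real networks with degree–community correlations, overlapping
groups, or weights with heavy-tailed noise.

## Problem sizes and stochastic outcomes

The validation suite uses the study conditions throughout: clique rings of
4–50 cliques of sizes 3–5 with 10 seeded runs each; random-graph nulls at
n = 1000, average degree 20, 20 seeded runs per model; planted-partition
accuracy over 20 realizations per μ ∈ {0.1, 0.3, 0.5}; mean-degree
calibration over 100 realizations; 1000 random collapse-conservation
trials (dyadic-rational weights, so floating-point sums are exact and
conservation is bit-exact). On the karate fixture the λ = 1 outcome is
genuinely bimodal across seeds (three communities in ≈ 57% of runs, two
otherwise); the reproduction script estimates the modal count over 100
seeds so the mode is stable, while the test suite asserts it over the 20
fixed seeds it documents.

## Known limitations

- Undirected graphs only; overlapping communities are out of scope.
- Label propagation is order-dependent: different seeds can give different
  (all criterion-satisfying) partitions, most visibly near resolution
  values where two scales compete (karate at λ = 1). Report distributions
  over seeds, not single runs, when this matters.
- The two-faction karate split found at λ = 0.6 is the modularity-optimal
  bipartition, which differs from the historically recorded membership of
  the two structurally ambiguous members (nodes 9 and 10); similarity-
  driven dynamics cannot recover a socially-determined assignment that
  contradicts the topology.
- On weighted inputs the w(u,u) = 1 self-term is a convention; similarity
  values (and hence the initialization) depend on the weight scale.
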