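# Methods

`cmcnet` implements a comparative centrality analysis for undirected,
connected networks: it computes a battery of 17 node-centrality
measures, summarizes how strongly the measures agree within and across
networks (centrality-measure correlations, CMCs), relates that agreement
to global topology, contrasts empirical networks with null-model
surrogates, and clusters nodes into topological roles from their
multivariate centrality profiles.

## Canonical network form

All analyses run on a symmetric, non-negative adjacency matrix **A**
with zero diagonal, restricted to the largest connected component
(components of fewer than 3 nodes are rejected: pairwise rank
correlations are undefined there). Directed inputs are symmetrized with
`A <- max(A, A^T)`, so a one-directional weighted edge keeps its weight;
this is a package choice among several defensible symmetrization rules.
The default analysis binarizes edge weights; a weighted analysis keeps
them and switches every measure to its standard weighted generalization
(below).

## The 17 measures

With `d_i` the degree, `s_i` the strength (row sum of A), `l_ij`
shortest-path lengths, `λ1, v` the leading eigenpair of A, `H` the mean
first-passage-time matrix of the unbiased random walk, `e^A` the matrix
exponential, `L` the Laplacian, `J` the all-ones matrix and
`C = (L + J)^{-1}`:

| id | definition |
|----|------------|
| DC | `Σ_j A_ij` |
| EC | leading eigenvector `v` (unit norm, non-negative) |
| KC | fixed point `x = αAx + β1`, `α = 0.85/λ1`, `β = 1` |
| PR | fixed point `x = αAD^{-1}x + β1`, `α = 0.85`, `β = (1-α)/N`, normalized to sum 1 |
| LC | mean over neighbours of `(d_i - d_j)/(d_i + d_j)` |
| HC | h-index of the neighbour degree sequence |
| LAPC | `d_i² + d_i + 2 Σ_{j∈N(i)} d_j` |
| CC | `N / Σ_j l_ij` |
| SC | `[e^A]_ii` |
| PC | `1 - Σ_m (d_i(m)/d_i)²` over the modules of a consensus partition |
| TCC | `Σ_j [e^A]_ji` |
| RWCC | `N / Σ_j H_ji` |
| IC | `(C_ii + (Σ_j C_jj - 2 Σ_j C_ij)/N)^{-1}` |
| BC | `Σ_{p≠i≠q} g_pq(i)/g_pq` over unordered pairs |
| CBC | `(1/Ć) Σ_{p≠i} Σ_{q≠i,p} ([e^A]_pq - [e^{A-E(i)}]_pq)/[e^A]_pq`, `Ć = (N-1)² - (N-1)` |
| RWBC | mean over pairs of the node's unit-current throughput (endpoints contribute 1) |
| BridC | `BC_i × Bc_i` with `Bc_i = d_i^{-1} / Σ_{j∈N(i)} d_j^{-1}` |

Notes and deliberate choices:

* **Closeness numerator.** CC uses `N`, not the conventional `N-1`; the
  two are rank-identical, and every downstream statistic is rank-based.
* **Katz/PageRank parameters.** Neither attenuation constant is forced
  by the method; the defaults (`α = 0.85/λ1` for Katz, damping 0.85 for
  PageRank) guarantee convergence of the fixed point and are
  configurable through `CentralityParams`.
* **MFPT.** `H` is computed from the fundamental matrix
  `Z = (I - P + Π)^{-1}` of the ergodic chain with `P = D^{-1}A` and
  stationary distribution proportional to strength; `H[j,i] =
  (Z_ii - Z_ji)/π_i`.
* **Current flow.** One inverse `C = (L+J)^{-1}` serves both IC and
  RWBC; pairwise potentials are `V = C(e_p - e_q)`. RWBC uses Newman's
  endpoint-inclusion convention (each endpoint contributes throughput
  1); endpoint exclusion is available via `CentralityParams`.
* **CBC cost cap.** CBC needs one matrix exponential per node; it
  refuses networks above `cbc_max_nodes` (default 2000) unless the cap
  is raised, and is skipped for surrogate ensembles by default (as is
  RWBC).
* **Weighted generalizations.** Degree terms become strengths (DC,
  LAPC, LC, PC, BridC); HC takes the h-index of neighbour strengths;
  CC/BC use path lengths `1/w`; EC/KC/SC/TCC/CBC use the weighted A
  directly; RWCC/RWBC/IC treat weights as transition rates /
  conductances. These are the standard generalizations, stated here
  because weighted conventions differ across toolboxes.
* **Missing-value policy.** A measure that fails on a network (e.g. PC
  without a partition) yields a logged NaN column; downstream means and
  correlations exclude missing pairs and report counts rather than
  imputing.

## Rank handling and numerical ties

Nodes exchangeable under a graph automorphism receive mathematically
identical scores on every measure, but eigensolvers and matrix
exponentials return them with jitter in the last floating-point bits.
Before any ranking (Spearman CMCs, rank-normalized profiles) scores are
therefore *tie-snapped*: after sorting, successive gaps below `1e-9 ×
max|score|` are merged to their group mean. Identical rank vectors
return a correlation of exactly 1 (and exactly −1 for reversed ranks).
The tolerance is far below any genuine score separation observed on
networks of the sizes analysed here, but merging genuinely distinct
scores closer than that is a known, accepted limitation.

A related substantive point: on threshold graphs every isolated-added
node's neighbourhood is a clique, so its shortest-path betweenness is
exactly zero. Betweenness thus ties nodes that degree or closeness
strictly order, and its Spearman correlation with those measures falls
below 1 even though there is never a strict rank inversion. Concordance
on threshold graphs is exact (CMC = 1.0) for the inclusion-preserving
measures other than betweenness, and holds as a weak order (zero strict
discordance) for betweenness.

## Global topology

Eight descriptors per network: density `2E/(N(N-1))`; degree
assortativity (Pearson over edge endpoints; NaN with a warning on
regular graphs); clustering as transitivity (the global closed-triangle
fraction — chosen over mean local clustering, which weights low-degree
nodes differently); global efficiency (mean `1/l_ij` over ordered
pairs); diffusion efficiency (mean `1/H_ij` over ordered pairs, always
≤ global efficiency on unweighted networks); modularity Q of a
consensus partition; majorization gap; spectral gap `λ1 - λ2`.

**Consensus modularity.** Louvain is run 50 times (igraph's C
implementation; per-run stochasticity comes from a seeded vertex
permutation, so results are bit-reproducible given a seed). The
co-assignment matrix across runs is thresholded at τ = 0.4 and
re-clustered with the same routine until all runs agree
(Lancichinetti–Fortunato consensus). Q is Newman's
`(1/2W) Σ_ij [A_ij - s_i s_j/2W] δ(c_i, c_j)` evaluated on the original
network.

**Majorization gap.** With the degree sequence sorted non-increasing,
the corrected conjugate is
`d*_k = |{i<k : d_i ≥ k-1}| + |{i>k : d_i ≥ k}|` and the gap is
`Σ_k max(d*_k - d_k, 0)` — zero exactly on threshold graphs, and
dependent only on the degree sequence (so degree-preserving surrogates
preserve it exactly). Weighted networks are binarized first.

## Surrogate ensembles

* **Unconstrained**: uniform simple graphs with the base N and E,
  conditioned on connectedness by rejection sampling (≤ 200 draws from
  G(n, m)), then a spanning-tree-plus-uniform-fill fallback for
  densities where rejection effectively never succeeds (near-tree
  densities). The fallback is connected by construction but no longer
  exactly uniform. Weighted bases have their weight multiset randomly
  permuted onto the new edges.
* **Constrained**: connectivity-preserving Maslov–Sneppen double-edge
  swaps, 10 per edge by default (common practice; enough for the edge
  set to decorrelate at the sizes analysed here). A graph admitting no
  valid swap (e.g. a star) is returned unchanged with a warning. For
  weighted bases the rewired binary structure receives the original
  weight multiset rank-matched to the product of endpoint strengths,
  which approximately preserves the strength distribution; this
  rank-matching is a package heuristic, validated only by the
  strength-correlation test.

Default ensembles have 100 members with sub-seeds `base_seed + k`.

## CMC analysis

Spearman's ρ between every pair of measure columns gives a per-network
CMC matrix (136 unique pairs for the full set). Summaries: the *within-
network mean* (mean over defined pairs of one network) and the
*between-network* per-pair mean/SD across a corpus. PCA runs on the
column-z-scored raw scores, with component signs fixed so each
component's mean loading is non-negative; note that because measure
relations are monotone but non-linear, a perfectly rank-concordant
network still has PC1 < 100%.

Mean within-network CMC is regressed (OLS, standardized variables) on
the descriptors, excluding density and diffusion efficiency (strongly
non-linear relations to CMCs) and fitting modularity and the
majorization gap in two separate models (they are strongly collinear
across realistic corpora). Per-pair CMC-vs-descriptor Spearman
correlations are Bonferroni-corrected by the number of measure pairs;
p-values use the large-sample approximation.

Empirical-vs-surrogate contrasts report the empirical value minus the
ensemble mean (positive = empirical larger), for the within-network
mean CMC and every descriptor, computed on a measure list that excludes
CBC and RWBC by default.

## Node-role profiling

Scores are converted per measure to normalized average ranks
`(rank-1)/(N-1)` (1 = most central; constant columns become 0.5 with a
warning). RWCC is dropped — it is rank-redundant with IC across
networks. Nodes are clustered by Ward's minimum-variance linkage on
Euclidean distances between rank profiles; the Davies-Bouldin index
(computed on the ranked matrix) is evaluated for horizontal cuts
k = 2..50 and the minimizing k chosen, ties to the smallest k. The
cluster with the highest mean rank is annotated "core", the lowest
"periphery", the rest "intermediate". Vertex-transitive inputs (all
profiles identical) return a single-cluster solution with a warning
instead of a spurious split.

## Synthetic generators and what they do (not) show

The generator families span the regimes that drive CMC variation:
threshold graphs (complete neighbourhood-inclusion preorder — the
perfectly concordant extreme), stars and bottleneck graphs (concordant
and discordant micro-examples), planted-partition SBMs (tunable
modularity; connectivity by regeneration so the stated edge
probabilities remain exact conditional on connectedness), connected
Erdős–Rényi graphs (tunable density), rings with tendrils, and i.i.d.
positive edge weights (uniform or lognormal). Defaults used in the
verification corpora: 4 blocks × 25 nodes for SBM sweeps, with `p_in`
set per sweep point so the expected mean degree stays at 16 — in a
modularity sweep with fixed `p_in`, density falls by more than half as
the blocks separate and confounds the modularity-CMC relation, so
constant expected degree is the design that isolates modularity;
100-node ER graphs for density sweeps; 10 sub-seeds per sweep point;
100-member surrogate ensembles (p_in = 0.3, p_out = 0.02 for the
surrogate base networks). Sizes were chosen so each sweep is a small
but adequately powered corpus.

Two caveats established by the verification corpora themselves: (i) in
a one-parameter SBM family, clustering and the spectral gap are
near-perfect linear proxies of Q (|r| > 0.9), so the multiple
regression cannot attribute unique variance to modularity there — the
negative modularity-CMC relation is a marginal statement on such
corpora, and the regression is only informative on corpora whose
descriptors vary independently; (ii) on homogeneous ER corpora the CMC
pairs involving the participation coefficient and bridging centrality
sit at a density-independent noise floor, so the density trend is
monotone for the 15 topology-sensitive measures but flat for the full
17-measure mean.

Synthetic corpora have independent edges, homogeneous blocks, and no
degree-distribution heavy tails, geometry, or measurement noise; tests
passing on them establish the *mechanics* and the *direction* of the
topology-CMC relationships (modularity down, density up,
surrogates ≥ empirical), not the effect sizes one should expect on real
corpora.

## Determinism

Every stochastic stage takes an explicit seed. The pipeline derives
stage seeds by CRC32-hashing (global seed, network content hash, stage,
repetition), so a run is bit-reproducible and identical input networks
receive identical analyses regardless of their file names.

## Known limitations

* Dense-matrix kernels (expm, matrix inverses, MFPT) scale as O(N³)
  memory/time; the package targets networks up to a few thousand nodes,
  with CBC capped by default.
* The consensus partition is one of many defensible community
  decompositions; PC and Q inherit its algorithmic degeneracies even
  after consensus.
* The unconstrained surrogate fallback and the weighted constrained
  rewiring are approximations, as flagged above.
* Hierarchical clustering cannot isolate single nodes with idiosyncratic
  profiles into their own roles; the DB-chosen k is a visualization
  heuristic, not a model-selection claim.
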