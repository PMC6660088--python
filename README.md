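# cmcnet

Comparative centrality analysis of undirected networks.

Many node-centrality measures exist — degree, closeness, betweenness,
eigenvector, Katz, PageRank, subgraph, current-flow variants, and so on
— and on many real networks they largely agree about which nodes are
central. How much they agree, and why, is itself a property of the
network. `cmcnet` is built for researchers who want to quantify that
property: it computes 17 centrality measures per node, measures the
Spearman correlation of every pair of measures within a network
(**centrality-measure correlations, CMCs**), relates CMC structure to
eight global topological descriptors (density, assortativity,
clustering, global and diffusion efficiency, consensus-Louvain
modularity *Q*, majorization gap, spectral gap), contrasts each network
with degree-preserving (Maslov–Sneppen) and density-matched
(connected Erdős–Rényi) surrogate ensembles, and clusters nodes into
topological roles (core / periphery / intermediates) from their
multivariate centrality profiles.

Two theoretical anchors organize the analysis:

* **Threshold graphs / majorization gap.** If node *i*'s neighbourhood
  contains node *j*'s, every reasonable measure ranks *i* ≥ *j*. In
  threshold graphs this dominance preorder is complete, so rankings
  coincide; the *majorization gap* — computed from the corrected
  conjugate of the degree sequence, `Σ_k max(d*_k − d_k, 0)` — measures
  how far a degree sequence is from that perfectly concordant extreme.
* **Modularity.** Modular networks decouple locally central nodes from
  globally central ones, lowering CMCs; the package quantifies this with
  consensus-Louvain *Q* (50 runs, co-assignment threshold τ = 0.4) and a
  descriptor regression.

## Worked example

A "bottleneck" network — two 4-cliques joined by a single bridge node —
is the canonical case where centrality measures disagree:

```python
from cmcnet.synthnet import bottleneck_graph
from cmcnet.centrality import NetworkKernels, centrality_profile
from cmcnet.topology import ConsensusConfig, topology_summary
from cmcnet.cmc import cmc_matrix, within_network_mean

net = bottleneck_graph(4)                      # 9 nodes, 14 edges
kernels = NetworkKernels(net)
summary, part = topology_summary(net, ConsensusConfig(seed=0), kernels=kernels)
prof = centrality_profile(net, partition=part, kernels=kernels)
m = cmc_matrix(prof)

print(prof.scores[["DC", "CC", "BC", "EC"]].round(3))
print("within-mean CMC:", round(within_network_mean(m), 3))
print("Q:", round(summary.modularity_q, 3),
      "majorization gap:", summary.majorization_gap)
```

```
    DC     CC    BC     EC
0  4.0  0.600  15.0  0.386
1  3.0  0.450   0.0  0.328
...
8  2.0  0.643  16.0  0.243
within-mean CMC: 0.47
Q: 0.426 majorization gap: 12.0
```

The bridge (node 8) has the *lowest* degree and eigenvector score but
the *highest* closeness and betweenness — degree and betweenness
correlate at only ρ = 0.14 here, and the mean within-network CMC (0.47)
is far below what a dense homogeneous network would show. The high
modularity and large majorization gap are exactly the descriptors that
predict such discordance.

Node-role profiling on the same network
(`cmcnet.profiling.profile_clusters`) rank-normalizes the 16 retained
measures (random-walk closeness is dropped as redundant with
information centrality), clusters nodes by Ward linkage, cuts the
dendrogram at the Davies-Bouldin optimum, and labels the clique-bridge
attachment points and the bridge as core/intermediate against a clique
periphery.

## Command line

```bash
cmcnet generate sbm --out net.txt --seed 1 \
    --params '{"block_sizes": [25,25,25,25], "p_in": 0.3, "p_out": 0.02}'
cmcnet analyze net.txt --out results/ --seed 1
cmcnet corpus nets/*.txt --out results/ --seed 1
cmcnet profile net.txt
cmcnet surrogate net.txt --model constrained -n 100 --out sur/
```

`analyze` writes per-network CSVs (profile, CMC matrix, topology row,
cluster assignments, DB curve); `corpus` adds between-network CMC
mean/SD matrices, the two-model topology regression, and the per-pair
CMC-vs-descriptor correlation table (Bonferroni-corrected over the 136
measure pairs).

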