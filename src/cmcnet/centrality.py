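"""The 17 node-centrality measures and their shared computational kernels.

Measure identifiers (fixed abbreviations used throughout):

========  ====================================================
DC        degree (strength on weighted networks)
EC        eigenvector centrality
KC        Katz centrality, x = alpha*A*x + beta*1
PR        PageRank, x = alpha*A*D^-1*x + beta*1, sum-normalized
LC        leverage centrality
HC        h-index centrality (h-index of neighbour degrees)
LAPC      Laplacian centrality, d^2 + d + 2*sum of neighbour degrees
CC        shortest-path closeness, N / sum_j l_ij
SC        subgraph centrality, [e^A]_ii
PC        participation coefficient (needs a module partition)
TCC       total communicability, sum_j [e^A]_ji
RWCC      random-walk closeness, N / sum_j H_ji (H = mean first-passage)
IC        information centrality (current-flow closeness)
BC        shortest-path betweenness (unnormalized pair sum)
CBC       communicability betweenness
RWBC      current-flow (random-walk) betweenness
BridC     bridging centrality, BC * bridging coefficient
========  ====================================================

Walk-based kernels (matrix exponential, mean first-passage times, the
current-flow matrix ``C = (L+J)^-1``) are cached per network in
:class:`NetworkKernels` so that measures sharing a kernel compute it once.

Weighted networks use standard weighted generalizations: degree terms
become strengths (row sums), path lengths are ``1/w``, walk kernels use
the weighted adjacency directly, and random-walk/current-flow measures
treat weights as transition rates / conductances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Sequence

import numpy as np
import networkx as nx
from scipy.linalg import expm
from scipy.sparse import csr_matrix
from scipy.sparse import csgraph

from .graphio import Network

logger = logging.getLogger(__name__)

ALL_MEASURES = (
    "DC", "EC", "KC", "PR", "LC", "HC", "LAPC", "CC", "SC", "PC",
    "TCC", "RWCC", "IC", "BC", "CBC", "RWBC", "BridC",
)

#: measures whose node ranking is provably concordant on threshold graphs
NEIGHBOURHOOD_INCLUSION_PRESERVING = (
    "DC", "EC", "KC", "CC", "SC", "TCC", "IC", "RWCC", "BC",
)

__all__ = [
    "ALL_MEASURES",
    "NEIGHBOURHOOD_INCLUSION_PRESERVING",
    "CentralityParams",
    "SpectralData",
    "WalkKernel",
    "NetworkKernels",
    "CentralityProfile",
    "shortest_path_distances",
    "spectral_data",
    "walk_kernel",
    "mfpt_matrix",
    "centrality_scores",
    "communicability_betweenness",
    "current_flow_betweenness",
    "participation_coefficient",
    "bridging_coefficient",
    "centrality_profile",
]


@dataclass(frozen=True)
class CentralityParams:
    """Tunable parameters of the parametric measures.

    katz_alpha_fraction
        Katz attenuation as a fraction of 1/lambda_1 (guarantees the fixed
        point converges for any value < 1).
    katz_beta
        Katz exogenous constant.
    pagerank_damping
        PageRank damping alpha.
    pagerank_beta
        PageRank exogenous constant; ``None`` means (1 - alpha)/N.
    cbc_max_nodes
        Size cap for the per-node deletion kernels of communicability
        betweenness (expensive: one matrix exponential per node).
    cf_endpoint_inclusion
        Current-flow betweenness endpoint convention: endpoints of each
        source-target pair contribute a throughput of 1 when True.
    """

    katz_alpha_fraction: float = 0.85
    katz_beta: float = 1.0
    pagerank_damping: float = 0.85
    pagerank_beta: float | None = None
    expm_tolerance: float = 1e-12
    measure_list: tuple[str, ...] = ALL_MEASURES
    cbc_max_nodes: int = 2000
    cf_endpoint_inclusion: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.katz_alpha_fraction < 1:
            raise ValueError("katz_alpha_fraction must lie in (0, 1)")
        if not 0 < self.pagerank_damping < 1:
            raise ValueError("pagerank_damping must lie in (0, 1)")
        unknown = set(self.measure_list) - set(ALL_MEASURES)
        if unknown:
            raise ValueError(f"unknown measure ids: {sorted(unknown)}")


@dataclass(frozen=True)
class SpectralData:
    lambda1: float
    lambda2: float
    leading_vector: np.ndarray


@dataclass(frozen=True)
class WalkKernel:
    expA: np.ndarray
    deleted_expA: np.ndarray | None  # (N, N, N): kernel with node i's edges zeroed
    norm_constant: float  # (N-1)^2 - (N-1)


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

def shortest_path_distances(net: Network) -> np.ndarray:
    """All-pairs shortest-path lengths l_ij.

    Unweighted networks use hop counts (BFS); weighted networks use
    minimum-sum paths over edge lengths 1/weight (strong edges are short).
    """
    if net.weighted:
        with np.errstate(divide="ignore"):
            lengths = np.where(net.adjacency > 0, 1.0 / net.adjacency, 0.0)
        D = csgraph.shortest_path(csr_matrix(lengths), directed=False)
    else:
        D = csgraph.shortest_path(
            csr_matrix(net.adjacency), directed=False, unweighted=True
        )
    if np.isinf(D).any():
        raise ValueError("network is disconnected: infinite distances")
    return D


def spectral_data(net: Network) -> SpectralData:
    """Leading and second adjacency eigenvalues plus the Perron vector."""
    vals, vecs = np.linalg.eigh(net.adjacency)
    v = vecs[:, -1]
    v = np.abs(v)  # Perron vector of a connected graph is strictly positive
    v /= np.linalg.norm(v)
    return SpectralData(float(vals[-1]), float(vals[-2]), v)


def walk_kernel(net: Network, with_deletions: bool = False,
                max_deletion_nodes: int = 2000) -> WalkKernel:
    """Matrix exponential of A, optionally with per-node deletion kernels.

    The deletion kernel for node i is ``expm(A - E(i))`` where E(i) zeroes
    row and column i (the node stays, its edges go) — the quantity needed
    for communicability betweenness.
    """
    n = net.n_nodes
    expA = expm(net.adjacency)
    deleted = None
    if with_deletions:
        if n > max_deletion_nodes:
            raise ValueError(
                f"N={n} exceeds the deletion-kernel cap {max_deletion_nodes}; "
                "disable with_deletions or raise the cap"
            )
        deleted = np.empty((n, n, n))
        for i in range(n):
            Ai = net.adjacency.copy()
            Ai[i, :] = 0.0
            Ai[:, i] = 0.0
            deleted[i] = expm(Ai)
    return WalkKernel(expA, deleted, float((n - 1) ** 2 - (n - 1)))


def mfpt_matrix(net: Network) -> np.ndarray:
    """Mean first-passage times H[j, i] of the unbiased random walk.

    The walk steps from j to a neighbour with probability A_jk / s_j.
    Computed from the fundamental matrix Z = (I - P + Pi)^-1 of the
    ergodic chain: H[j, i] = (Z_ii - Z_ji) / pi_i, with the stationary
    distribution pi proportional to node strength.
    """
    s = net.strengths
    if np.any(s <= 0):
        raise ValueError("MFPT undefined for isolated nodes")
    P = net.adjacency / s[:, None]
    pi = s / s.sum()
    n = net.n_nodes
    Z = np.linalg.inv(np.eye(n) - P + np.tile(pi, (n, 1)))
    H = (np.diag(Z)[None, :] - Z) / pi[None, :]
    np.fill_diagonal(H, 0.0)
    return H


class NetworkKernels:
    """Lazily computed, cached kernels shared across measures on one network."""

    def __init__(self, net: Network, params: CentralityParams | None = None):
        self.net = net
        self.params = params or CentralityParams()

    @cached_property
    def distances(self) -> np.ndarray:
        return shortest_path_distances(self.net)

    @cached_property
    def spectral(self) -> SpectralData:
        return spectral_data(self.net)

    @cached_property
    def expA(self) -> np.ndarray:
        return walk_kernel(self.net).expA

    @cached_property
    def mfpt(self) -> np.ndarray:
        return mfpt_matrix(self.net)

    @cached_property
    def current_flow_C(self) -> np.ndarray:
        """C = (L + J)^-1 with L the (weighted) Laplacian and J all-ones."""
        A = self.net.adjacency
        L = np.diag(A.sum(axis=1)) - A
        return np.linalg.inv(L + np.ones_like(L))

    @cached_property
    def graph(self) -> nx.Graph:
        G = self.net.to_networkx()
        if self.net.weighted:
            for u, v, d in G.edges(data=True):
                d["length"] = 1.0 / d["weight"]
        return G


# ---------------------------------------------------------------------------
# Individual measures
# ---------------------------------------------------------------------------

def _degree_variable(net: Network) -> np.ndarray:
    return net.strengths if net.weighted else net.degrees.astype(float)


def _dc(k: NetworkKernels) -> np.ndarray:
    return _degree_variable(k.net)


def _ec(k: NetworkKernels) -> np.ndarray:
    return k.spectral.leading_vector.copy()


def _kc(k: NetworkKernels) -> np.ndarray:
    p = k.params
    lam1 = k.spectral.lambda1
    alpha = p.katz_alpha_fraction / lam1
    if alpha >= 1.0 / lam1:
        raise ValueError("Katz alpha >= 1/lambda1: series diverges")
    n = k.net.n_nodes
    return np.linalg.solve(
        np.eye(n) - alpha * k.net.adjacency, np.full(n, p.katz_beta)
    )


def _pr(k: NetworkKernels) -> np.ndarray:
    p = k.params
    n = k.net.n_nodes
    alpha = p.pagerank_damping
    beta = (1.0 - alpha) / n if p.pagerank_beta is None else p.pagerank_beta
    s = k.net.strengths
    M = k.net.adjacency / s[None, :]  # A D^-1: column j scaled by 1/s_j
    x = np.linalg.solve(np.eye(n) - alpha * M, np.full(n, beta))
    return x / x.sum()


def _lc(k: NetworkKernels) -> np.ndarray:
    net = k.net
    d = _degree_variable(net)
    A = net.adjacency > 0
    out = np.empty(net.n_nodes)
    for i in range(net.n_nodes):
        nb = np.flatnonzero(A[i])
        out[i] = np.mean((d[i] - d[nb]) / (d[i] + d[nb]))
    return out


def _hc(k: NetworkKernels) -> np.ndarray:
    net = k.net
    d = _degree_variable(net)
    A = net.adjacency > 0
    out = np.empty(net.n_nodes)
    for i in range(net.n_nodes):
        nd = np.sort(d[np.flatnonzero(A[i])])[::-1]
        h = 0
        for rank, dv in enumerate(nd, start=1):
            if dv >= rank:
                h = rank
            else:
                break
        out[i] = h
    return out


def _lapc(k: NetworkKernels) -> np.ndarray:
    net = k.net
    d = _degree_variable(net)
    A = (net.adjacency > 0).astype(float)
    return d**2 + d + 2.0 * (A @ d)


def _cc(k: NetworkKernels) -> np.ndarray:
    D = k.distances
    return k.net.n_nodes / D.sum(axis=1)


def _sc(k: NetworkKernels) -> np.ndarray:
    return np.diag(k.expA).copy()


def _tcc(k: NetworkKernels) -> np.ndarray:
    return k.expA.sum(axis=0)


def _rwcc(k: NetworkKernels) -> np.ndarray:
    # H[j, i] is the passage time from j to i: sum over sources j
    return k.net.n_nodes / k.mfpt.sum(axis=0)


def _ic(k: NetworkKernels) -> np.ndarray:
    C = k.current_flow_C
    n = k.net.n_nodes
    T = np.trace(C)
    R = C.sum(axis=1)
    return 1.0 / (np.diag(C) + (T - 2.0 * R) / n)


def _bc(k: NetworkKernels) -> np.ndarray:
    weight = "length" if k.net.weighted else None
    bc = nx.betweenness_centrality(k.graph, normalized=False, weight=weight)
    return np.array([bc[i] for i in range(k.net.n_nodes)])


def bridging_coefficient(net: Network) -> np.ndarray:
    """Bc_i = d_i^-1 / sum over neighbours of d_j^-1."""
    d = _degree_variable(net)
    A = (net.adjacency > 0).astype(float)
    return (1.0 / d) / (A @ (1.0 / d))


def _bridc(k: NetworkKernels) -> np.ndarray:
    return _bc(k) * bridging_coefficient(k.net)


def communicability_betweenness(net: Network,
                                params: CentralityParams | None = None) -> np.ndarray:
    """CBC_i = (1/C') sum over ordered pairs (p, q), p != q != i, of
    ([e^A]_pq - [e^{A-E(i)}]_pq) / [e^A]_pq, with C' = (N-1)^2 - (N-1)."""
    params = params or CentralityParams()
    if net.n_nodes < 3:
        raise ValueError("communicability betweenness undefined for N < 3 (empty sum)")
    if net.n_nodes > params.cbc_max_nodes:
        raise ValueError(
            f"N={net.n_nodes} exceeds cbc_max_nodes={params.cbc_max_nodes}"
        )
    res = nx.communicability_betweenness_centrality(net.to_networkx())
    return np.array([res[i] for i in range(net.n_nodes)])


def current_flow_betweenness(net: Network,
                             params: CentralityParams | None = None,
                             kernels: NetworkKernels | None = None) -> np.ndarray:
    """Current-flow (random-walk) betweenness.

    For each unordered source-target pair a unit current is injected and
    drained; the throughput of an interior node is half the absolute flow
    over its incident edges, and each endpoint contributes 1 (endpoint
    inclusion, configurable).  Scores are normalized by N(N-1)/2.
    """
    params = params or CentralityParams()
    k = kernels or NetworkKernels(net, params)
    n = net.n_nodes
    C = k.current_flow_C
    ii, jj = np.nonzero(np.triu(net.adjacency, 1))
    w = net.adjacency[ii, jj]
    ps, qs = np.triu_indices(n, 1)
    # node potentials for every source-target pair (columns)
    V = C[:, ps] - C[:, qs]
    flow = w[:, None] * np.abs(V[ii, :] - V[jj, :])  # per edge per pair
    through = np.zeros((n, len(ps)))
    np.add.at(through, ii, flow)
    np.add.at(through, jj, flow)
    through *= 0.5
    endpoint = 1.0 if params.cf_endpoint_inclusion else 0.0
    through[ps, np.arange(len(ps))] = endpoint
    through[qs, np.arange(len(qs))] = endpoint
    return through.sum(axis=1) / (0.5 * n * (n - 1))


def participation_coefficient(net: Network, partition) -> np.ndarray:
    """PC_i = 1 - sum over modules m of (k_i(m) / k_i)^2.

    ``partition`` is a module-label array (or any object with a ``labels``
    attribute), one label per node.  Weighted networks use strengths.
    """
    labels = np.asarray(getattr(partition, "labels", partition))
    if labels.shape[0] != net.n_nodes:
        raise ValueError("partition does not cover all nodes")
    W = net.adjacency if net.weighted else (net.adjacency > 0).astype(float)
    k = W.sum(axis=1)
    if np.any(k == 0):
        raise ValueError("participation coefficient undefined for degree-0 nodes")
    pc = np.ones(net.n_nodes)
    for m in np.unique(labels):
        km = W[:, labels == m].sum(axis=1)
        pc -= (km / k) ** 2
    return pc


_DISPATCH = {
    "DC": _dc, "EC": _ec, "KC": _kc, "PR": _pr, "LC": _lc, "HC": _hc,
    "LAPC": _lapc, "CC": _cc, "SC": _sc, "TCC": _tcc, "RWCC": _rwcc,
    "IC": _ic, "BC": _bc, "BridC": _bridc,
}


def centrality_scores(net: Network, measure: str,
                      params: CentralityParams | None = None,
                      partition=None,
                      kernels: NetworkKernels | None = None) -> np.ndarray:
    """Compute one centrality measure; returns a per-node score vector."""
    params = params or CentralityParams()
    k = kernels or NetworkKernels(net, params)
    if measure in _DISPATCH:
        return _DISPATCH[measure](k)
    if measure == "PC":
        if partition is None:
            raise ValueError("participation coefficient requires a module partition")
        return participation_coefficient(net, partition)
    if measure == "CBC":
        return communicability_betweenness(net, params)
    if measure == "RWBC":
        return current_flow_betweenness(net, params, kernels=k)
    raise ValueError(f"unknown measure id {measure!r}")


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

@dataclass
class CentralityProfile:
    """Node x measure score matrix plus the configuration that produced it."""

    scores: "object"  # pandas.DataFrame, index = node labels, columns = measure ids
    params_used: CentralityParams
    partition_used: object | None = None

    @property
    def measure_ids(self) -> list[str]:
        return list(self.scores.columns)


def centrality_profile(net: Network,
                       params: CentralityParams | None = None,
                       partition=None,
                       kernels: NetworkKernels | None = None) -> CentralityProfile:
    """Assemble the requested measures into a node x measure score matrix.

    A measure that fails on the network yields a column of NaN with a logged
    warning rather than aborting the profile.
    """
    import pandas as pd

    params = params or CentralityParams()
    k = kernels or NetworkKernels(net, params)
    cols: dict[str, np.ndarray] = {}
    for m in params.measure_list:
        try:
            cols[m] = centrality_scores(net, m, params, partition=partition, kernels=k)
        except Exception as exc:  # noqa: BLE001 - contract: log and continue
            logger.warning("measure %s failed on network (N=%d): %s",
                           m, net.n_nodes, exc)
            cols[m] = np.full(net.n_nodes, np.nan)
    scores = pd.DataFrame(cols, index=list(net.node_labels),
                          columns=list(params.measure_list))
    return CentralityProfile(scores, params, partition)
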