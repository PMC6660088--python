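"""Null-model surrogate ensembles.

Two ensembles control for successively more structure of a base network:

* **unconstrained** — uniform simple connected graphs with the base
  network's node and edge counts (a connected Erdős–Rényi variant); for
  weighted networks the base weight multiset is randomly permuted onto
  the new edges.
* **constrained** — degree-preserving, connectivity-preserving
  Maslov–Sneppen double-edge swaps; for weighted networks the rewired
  binary structure receives weights rank-matched to the product of
  endpoint strengths, approximating the base strength distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import networkx as nx

from .graphio import Network
from .synthnet import er_connected

logger = logging.getLogger(__name__)

__all__ = [
    "SurrogateEnsemble",
    "unconstrained_surrogate",
    "constrained_surrogate",
    "build_ensemble",
]


@dataclass(frozen=True)
class SurrogateEnsemble:
    model: str  # "unconstrained" | "constrained"
    members: tuple[Network, ...]
    base_seed: int
    swaps_per_edge: int | None = None


def _permute_weights(net_bin: Network, weights: np.ndarray,
                     rng: np.random.Generator) -> Network:
    ii, jj = np.nonzero(np.triu(net_bin.adjacency, 1))
    w = rng.permutation(weights)
    A = np.zeros_like(net_bin.adjacency)
    A[ii, jj] = w
    A[jj, ii] = w
    return Network(A, net_bin.node_labels, weighted=True)


def unconstrained_surrogate(net: Network, seed: int | None = None) -> Network:
    """Connected uniform random graph with the base network's N and E."""
    if net.n_edges < net.n_nodes - 1:
        raise ValueError("fewer edges than N-1: no connected surrogate exists")
    ss = np.random.SeedSequence(seed)
    s_graph, s_weights = ss.spawn(2)
    sur = er_connected(net.n_nodes, net.n_edges,
                       seed=int(s_graph.generate_state(1)[0] & 0x7FFFFFFF))
    sur = Network(sur.adjacency, net.node_labels, weighted=False)
    if net.weighted:
        weights = net.adjacency[np.triu_indices(net.n_nodes, 1)]
        weights = weights[weights > 0]
        sur = _permute_weights(sur, weights, np.random.default_rng(s_weights))
    return sur


def constrained_surrogate(net: Network, swaps_per_edge: int = 10,
                          seed: int | None = None) -> Network:
    """Degree-preserving rewiring via connectivity-preserving double-edge swaps.

    A network admitting no valid swap (e.g. a star) is returned unchanged
    with a logged warning.
    """
    ss = np.random.SeedSequence(seed)
    s_swap, s_weights = ss.spawn(2)
    G = nx.Graph()
    G.add_nodes_from(range(net.n_nodes))
    ii, jj = np.nonzero(np.triu(net.adjacency, 1))
    G.add_edges_from(zip(ii.tolist(), jj.tolist()))
    nswap = swaps_per_edge * net.n_edges
    try:
        nx.connected_double_edge_swap(
            G, nswap=nswap, seed=int(s_swap.generate_state(1)[0] & 0x7FFFFFFF)
        )
    except nx.NetworkXError as exc:
        logger.warning("no valid degree-preserving swap (%s); returning input", exc)
        return net
    A = nx.to_numpy_array(G, nodelist=range(net.n_nodes))
    A = (A > 0).astype(float)
    sur = Network(A, net.node_labels, weighted=False)
    if net.weighted:
        # rank-match weights to the product of base endpoint strengths
        s = net.strengths
        si, sj = np.nonzero(np.triu(sur.adjacency, 1))
        score = s[si] * s[sj]
        weights = net.adjacency[np.triu_indices(net.n_nodes, 1)]
        weights = np.sort(weights[weights > 0])
        order = np.argsort(score, kind="stable")
        W = np.zeros_like(net.adjacency)
        W[si[order], sj[order]] = weights
        W = W + W.T
        sur = Network(W, net.node_labels, weighted=True)
    return sur


def build_ensemble(net: Network, model: str, n: int = 100,
                   base_seed: int = 0, swaps_per_edge: int = 10) -> SurrogateEnsemble:
    """Generate ``n`` surrogates with sub-seeds ``base_seed + k``."""
    if model not in ("unconstrained", "constrained"):
        raise ValueError(f"unknown surrogate model {model!r}")
    if n == 0:
        logger.warning("empty surrogate ensemble requested (n=0)")
    members = []
    for k in range(n):
        if model == "unconstrained":
            members.append(unconstrained_surrogate(net, seed=base_seed + k))
        else:
            members.append(
                constrained_surrogate(net, swaps_per_edge=swaps_per_edge,
                                      seed=base_seed + k)
            )
    return SurrogateEnsemble(
        model, tuple(members), base_seed,
        swaps_per_edge if model == "constrained" else None,
    )
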