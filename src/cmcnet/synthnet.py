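"""Synthetic network generators with known ground truth.

These families span the structural regimes that matter for centrality
concordance: threshold graphs (perfect neighbourhood-inclusion preorder,
hence perfectly concordant rankings), stars, bottleneck graphs (built to
be discordant), planted stochastic block models (tunable modularity),
connected Erdős–Rényi graphs (tunable density), and rings with tendrils.
Every generator is deterministic given its seed.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .graphio import Network

__all__ = [
    "threshold_graph",
    "star_graph",
    "bottleneck_graph",
    "sbm",
    "er_connected",
    "ring_with_tendrils",
    "assign_weights",
]


def threshold_graph(
    creation_sequence: str | list[int] | None = None,
    n: int | None = None,
    dominating_probability: float = 0.5,
    seed: int | None = None,
) -> Network:
    """Build a threshold graph from a creation sequence.

    Nodes are added one at a time: symbol 0 adds an isolated node, symbol 1
    adds a node connected to all existing nodes ("dominating").  With ``n``
    and ``dominating_probability`` a random sequence is drawn whose final
    symbol is forced to 1 so the result is connected.
    """
    if creation_sequence is None:
        if n is None or n < 2:
            raise ValueError("need a creation sequence or n >= 2")
        rng = np.random.default_rng(seed)
        seq = [0] + list((rng.random(n - 2) < dominating_probability).astype(int)) + [1]
    else:
        if isinstance(creation_sequence, str):
            seq = [int(c) for c in creation_sequence.replace(",", " ").split()]
        else:
            seq = [int(c) for c in creation_sequence]
        if not seq or seq[0] != 0:
            raise ValueError("creation sequence must begin with an isolated node (0)")
    if all(s == 0 for s in seq[1:]):
        raise ValueError("all-zeros creation sequence yields a disconnected graph")
    m = len(seq)
    A = np.zeros((m, m))
    for k, s in enumerate(seq):
        if s == 1:
            A[k, :k] = 1.0
            A[:k, k] = 1.0
    net = Network(A, tuple(str(i) for i in range(m)), weighted=False)
    if not net.is_connected():
        raise ValueError("creation sequence produced a disconnected graph "
                         "(last symbol must be dominating)")
    return net


def star_graph(n_leaves: int) -> Network:
    """Hub node 0 adjacent to ``n_leaves`` leaves, no other edges."""
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    A = np.zeros((n_leaves + 1, n_leaves + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    return Network(A, tuple(str(i) for i in range(n_leaves + 1)), weighted=False)


def bottleneck_graph(clique_size: int) -> Network:
    """Two complete graphs joined by a single degree-2 bridge node.

    The bridge (last node) touches exactly one member of each clique, so it
    has strictly maximal betweenness and closeness but minimal degree — a
    fixture on which centrality measures are discordant by construction.
    """
    if clique_size < 3:
        raise ValueError("clique_size must be >= 3")
    c = clique_size
    n = 2 * c + 1
    A = np.zeros((n, n))
    A[:c, :c] = 1.0
    A[c:2 * c, c:2 * c] = 1.0
    np.fill_diagonal(A, 0.0)
    bridge = 2 * c
    A[bridge, 0] = A[0, bridge] = 1.0
    A[bridge, c] = A[c, bridge] = 1.0
    return Network(A, tuple(str(i) for i in range(n)), weighted=False)


def sbm(
    block_sizes: list[int],
    p_in: float,
    p_out: float,
    seed: int | None = None,
    max_attempts: int = 100,
):
    """Planted-partition stochastic block model, conditioned on connectedness.

    Edges are drawn independently with probability ``p_in`` within blocks and
    ``p_out`` between blocks.  Disconnected draws are rejected and regenerated
    with a fresh sub-seed (keeping the stated probabilities exact conditional
    on connectedness), up to ``max_attempts``.

    Returns
    -------
    (Network, ndarray)
        The network and the planted block label (1-based) per node.
    """
    if not 0 <= p_out < p_in <= 1:
        raise ValueError("require 0 <= p_out < p_in <= 1")
    if p_out == 0 and len(block_sizes) > 1:
        raise ValueError("p_out = 0 with multiple blocks cannot be connected")
    n = int(sum(block_sizes))
    labels = np.concatenate(
        [np.full(sz, b + 1, dtype=int) for b, sz in enumerate(block_sizes)]
    )
    exp_deg = p_in * (np.array(block_sizes).max() - 1)
    if exp_deg < 1:
        import warnings

        warnings.warn("expected within-block degree < 1; connectivity unlikely")
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(max_attempts):
        rng = np.random.default_rng(child)
        same = labels[:, None] == labels[None, :]
        P = np.where(same, p_in, p_out)
        U = rng.random((n, n))
        A = (np.triu(U, 1) < np.triu(P, 1)).astype(float)
        A = A + A.T
        net = Network(A, tuple(str(i) for i in range(n)), weighted=False)
        if net.is_connected():
            return net, labels
    raise RuntimeError(f"no connected SBM draw in {max_attempts} attempts")


def er_connected(n: int, m_edges: int, seed: int | None = None) -> Network:
    """Uniform simple graph with exactly ``m_edges``, conditioned on connectedness.

    Rejection sampling from G(n, m) capped at 200 attempts; afterwards falls
    back to a uniform random labelled spanning tree plus uniform fill of the
    remaining edges (no longer exactly uniform, but always connected).
    """
    if m_edges < n - 1:
        raise ValueError("m_edges < n-1 cannot be connected")
    if m_edges > n * (n - 1) // 2:
        raise ValueError("m_edges exceeds the maximum for a simple graph")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(201)
    for child in children[:200]:
        rng = np.random.default_rng(child)
        G = nx.gnm_random_graph(n, m_edges, seed=int(rng.integers(2**31)))
        if nx.is_connected(G):
            return Network.from_networkx(G, labels=[str(i) for i in range(n)])
    # fallback: spanning tree seeding + uniform fill
    rng = np.random.default_rng(children[200])
    T = nx.random_labeled_tree(n, seed=int(rng.integers(2**31)))
    edges = set(frozenset(e) for e in T.edges())
    all_pairs = [
        frozenset((i, j)) for i in range(n) for j in range(i + 1, n)
        if frozenset((i, j)) not in edges
    ]
    extra = rng.choice(len(all_pairs), size=m_edges - (n - 1), replace=False)
    edges.update(all_pairs[k] for k in extra)
    A = np.zeros((n, n))
    for e in edges:
        i, j = sorted(e)
        A[i, j] = A[j, i] = 1.0
    return Network(A, tuple(str(i) for i in range(n)), weighted=False)


def ring_with_tendrils(
    ring_size: int, n_tendrils: int, tendril_length: int, seed: int | None = None
) -> Network:
    """A cycle with paths ("tendrils") attached at evenly spaced ring nodes."""
    if ring_size < 3:
        raise ValueError("ring_size must be >= 3")
    G = nx.cycle_graph(ring_size)
    nxt = ring_size
    if n_tendrils > 0:
        anchors = [round(k * ring_size / n_tendrils) % ring_size for k in range(n_tendrils)]
        for a in anchors:
            prev = a
            for _ in range(tendril_length):
                G.add_edge(prev, nxt)
                prev = nxt
                nxt += 1
    return Network.from_networkx(G, labels=[str(i) for i in range(G.number_of_nodes())])


def assign_weights(
    net: Network,
    distribution: str = "uniform",
    seed: int | None = None,
    **params: float,
) -> Network:
    """Draw i.i.d. positive weights onto the existing edges.

    ``distribution`` is ``"uniform"`` (params ``a``, ``b``; default 0.5..1.5)
    or ``"lognormal"`` (params ``mu``, ``sigma``; default 0, 0.5).
    """
    rng = np.random.default_rng(seed)
    ii, jj = np.nonzero(np.triu(net.adjacency, 1))
    m = len(ii)
    if distribution == "uniform":
        a = params.get("a", 0.5)
        b = params.get("b", 1.5)
        if a <= 0:
            raise ValueError("uniform weight lower bound must be positive")
        w = rng.uniform(a, b, size=m)
    elif distribution == "lognormal":
        mu = params.get("mu", 0.0)
        sigma = params.get("sigma", 0.5)
        w = rng.lognormal(mu, sigma, size=m)
    else:
        raise ValueError(f"unsupported weight distribution {distribution!r}")
    if np.any(w <= 0):
        raise ValueError("weight distribution produced non-positive weights")
    A = np.zeros_like(net.adjacency)
    A[ii, jj] = w
    A[jj, ii] = w
    weighted = not np.all(w == 1)
    return Network(A, net.node_labels, weighted=weighted)
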