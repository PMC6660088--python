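"""Global topological descriptors of a network.

Eight descriptors summarize each network: connection density, degree
assortativity, clustering (transitivity), global efficiency, diffusion
efficiency, modularity Q of a consensus-Louvain partition, the
majorization gap (degree-sequence distance from a threshold graph), and
the spectral gap lambda_1 - lambda_2 of the adjacency matrix.
"""

from __future__ import annotations

import logging
import random
import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
import igraph as ig

from .graphio import Network
from .centrality import NetworkKernels, SpectralData

logger = logging.getLogger(__name__)

__all__ = [
    "TopologySummary",
    "ModulePartition",
    "ConsensusConfig",
    "ConsensusError",
    "global_descriptors",
    "consensus_modularity",
    "modularity_q",
    "majorization_gap",
    "topology_summary",
]

DESCRIPTOR_NAMES = (
    "density", "assortativity", "clustering", "global_efficiency",
    "diffusion_efficiency", "modularity_q", "majorization_gap", "spectral_gap",
)


@dataclass(frozen=True)
class TopologySummary:
    density: float
    assortativity: float
    clustering: float
    global_efficiency: float
    diffusion_efficiency: float
    modularity_q: float
    majorization_gap: float
    spectral_gap: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in DESCRIPTOR_NAMES}


@dataclass(frozen=True)
class ModulePartition:
    """Node-to-module assignment with contiguous labels starting at 1."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", lab)
        uniq = np.unique(lab)
        if not np.array_equal(uniq, np.arange(1, len(uniq) + 1)):
            raise ValueError("module labels must be contiguous from 1")

    @property
    def n_modules(self) -> int:
        return int(self.labels.max())


@dataclass(frozen=True)
class ConsensusConfig:
    """Consensus-clustering settings: 50 Louvain repetitions, co-assignment
    threshold tau = 0.4, re-clustered until all repetitions agree."""

    n_runs: int = 50
    tau: float = 0.4
    max_consensus_rounds: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.tau < 1:
            raise ValueError("tau must lie in (0, 1)")
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")


class ConsensusError(RuntimeError):
    def __init__(self, msg: str, partition: "ModulePartition"):
        super().__init__(msg)
        self.partition = partition


# ---------------------------------------------------------------------------
# Descriptors
# ---------------------------------------------------------------------------

def global_descriptors(net: Network,
                       kernels: NetworkKernels | None = None) -> dict[str, float]:
    """The six non-community descriptors (density, assortativity, clustering,
    global/diffusion efficiency, spectral gap).

    Degenerate degree variance (regular graphs) yields NaN assortativity
    with a logged warning.
    """
    k = kernels or NetworkKernels(net)
    n = net.n_nodes
    density = 2.0 * net.n_edges / (n * (n - 1))
    G = k.graph
    weight = "weight" if net.weighted else None
    d = net.strengths if net.weighted else net.degrees
    if np.all(d == d[0]):
        logger.warning("regular graph: assortativity undefined, reported as NaN")
        assort = np.nan
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assort = float(
                nx.degree_pearson_correlation_coefficient(G, weight=weight)
            )
    if net.weighted:
        # geometric-mean triangle intensity, averaged over nodes
        cl = nx.clustering(G, weight="weight")
        clustering = float(np.mean(list(cl.values())))
    else:
        clustering = float(nx.transitivity(G))
    D = k.distances
    off = ~np.eye(n, dtype=bool)
    global_eff = float(np.mean(1.0 / D[off]))
    H = k.mfpt
    diffusion_eff = float(np.mean(1.0 / H[off]))
    spectral_gap = k.spectral.lambda1 - k.spectral.lambda2
    return {
        "density": density,
        "assortativity": assort,
        "clustering": clustering,
        "global_efficiency": global_eff,
        "diffusion_efficiency": diffusion_eff,
        "spectral_gap": spectral_gap,
    }


# ---------------------------------------------------------------------------
# Consensus Louvain modularity
# ---------------------------------------------------------------------------

def modularity_q(A: np.ndarray, labels: np.ndarray) -> float:
    """Newman modularity Q = (1/2W) sum_ij [A_ij - s_i s_j / 2W] delta(c_i, c_j)."""
    A = np.asarray(A, dtype=float)
    labels = np.asarray(labels)
    two_w = A.sum()
    s = A.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    B = A - np.outer(s, s) / two_w
    return float(B[same].sum() / two_w)


def _louvain_run(A: np.ndarray, seed: int) -> np.ndarray:
    """One Louvain run on a (possibly weighted) adjacency matrix.

    igraph's multilevel algorithm is deterministic given vertex order, so
    per-run stochasticity comes from a seeded vertex permutation.
    """
    n = A.shape[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    Ap = A[np.ix_(perm, perm)]
    src, dst = np.nonzero(np.triu(Ap, 1))
    g = ig.Graph(n=n, edges=list(zip(src.tolist(), dst.tolist())))
    w = Ap[src, dst].tolist()
    ig.set_random_number_generator(random.Random(int(seed) & 0x7FFFFFFF))
    memb = np.array(g.community_multilevel(weights=w).membership)
    out = np.empty(n, dtype=int)
    out[perm] = memb
    return out


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel modules 1..M by first occurrence, for comparability."""
    mapping: dict[int, int] = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def consensus_modularity(net: Network,
                         config: ConsensusConfig | None = None
                         ) -> tuple[ModulePartition, float]:
    """Consensus Louvain partition and its modularity Q on the original net.

    Louvain is run ``n_runs`` times with distinct sub-seeds; the co-assignment
    matrix is thresholded at tau and re-clustered with the same routine until
    every run returns the same partition (Lancichinetti-Fortunato scheme).
    """
    config = config or ConsensusConfig()
    A = net.adjacency
    n = net.n_nodes
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in
             ss.spawn(config.n_runs * (config.max_consensus_rounds + 1))]
    seed_iter = iter(seeds)
    current = A
    runs = [_canonical(_louvain_run(current, next(seed_iter)))
            for _ in range(config.n_runs)]
    for _ in range(config.max_consensus_rounds):
        if all(np.array_equal(runs[0], r) for r in runs[1:]):
            part = ModulePartition(runs[0])
            return part, modularity_q(A, part.labels)
        co = np.zeros((n, n))
        for r in runs:
            co += (r[:, None] == r[None, :])
        co /= config.n_runs
        co[co < config.tau] = 0.0
        np.fill_diagonal(co, 0.0)
        if not co.any():  # fully incoherent runs: fall back to best single run
            best = max(runs, key=lambda r: modularity_q(A, r))
            part = ModulePartition(best)
            return part, modularity_q(A, part.labels)
        current = co
        runs = [_canonical(_louvain_run(current, next(seed_iter)))
                for _ in range(config.n_runs)]
    last = ModulePartition(runs[0])
    raise ConsensusError(
        f"consensus did not converge in {config.max_consensus_rounds} rounds", last
    )


# ---------------------------------------------------------------------------
# Majorization gap
# ---------------------------------------------------------------------------

def majorization_gap(net: Network) -> int:
    """Degree-sequence distance from the nearest threshold graph.

    With the degree sequence d sorted non-increasing (1-based position k),
    the corrected conjugate is
    ``d*_k = |{i < k : d_i >= k - 1}| + |{i > k : d_i >= k}|`` and the gap
    is ``sum_k max(d*_k - d_k, 0)``.  Zero exactly on threshold graphs.
    Weighted networks are binarized first (the gap depends only on the
    degree sequence).
    """
    d = np.sort(net.degrees)[::-1].astype(int)
    n = len(d)
    gap = 0
    for k in range(1, n + 1):
        before = int(np.sum(d[: k - 1] >= k - 1))
        after = int(np.sum(d[k:] >= k))
        gap += max(before + after - d[k - 1], 0)
    return gap


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def topology_summary(net: Network,
                     config: ConsensusConfig | None = None,
                     kernels: NetworkKernels | None = None,
                     partition: ModulePartition | None = None,
                     ) -> tuple[TopologySummary, ModulePartition]:
    """All eight descriptors of one network, plus the consensus partition.

    A precomputed partition (with its Q recomputed here) can be passed to
    skip the consensus run.
    """
    k = kernels or NetworkKernels(net)
    desc = global_descriptors(net, k)
    if partition is None:
        partition, q = consensus_modularity(net, config)
    else:
        q = modularity_q(net.adjacency, partition.labels)
    summary = TopologySummary(
        density=desc["density"],
        assortativity=desc["assortativity"],
        clustering=desc["clustering"],
        global_efficiency=desc["global_efficiency"],
        diffusion_efficiency=desc["diffusion_efficiency"],
        modularity_q=q,
        majorization_gap=float(majorization_gap(net)),
        spectral_gap=desc["spectral_gap"],
    )
    return summary, partition
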