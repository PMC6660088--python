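"""Node-role profiling from multivariate centrality profiles.

Centrality scores are converted to normalized ranks in [0, 1] (1 = most
central; random-walk closeness dropped for its near-perfect redundancy
with information centrality), nodes are clustered with Ward's
minimum-variance method on Euclidean row distances, and the
Davies-Bouldin (DB) index selects a cut of the dendrogram.  The cluster
with the highest mean rank is annotated as the topological core, the
lowest as the periphery, and the rest as intermediates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, fcluster
from sklearn.metrics import davies_bouldin_score

from ._ranks import tied_ranks

logger = logging.getLogger(__name__)

__all__ = [
    "RankProfile",
    "ClusterSolution",
    "rank_normalize",
    "ward_linkage",
    "db_curve",
    "profile_clusters",
]

#: measure dropped from profiling (rank-redundant with IC across networks)
DROPPED_MEASURES = ("RWCC",)


@dataclass
class RankProfile:
    """Node x measure matrix of normalized ranks in [0, 1]."""

    normalized_ranks: pd.DataFrame

    @property
    def measure_ids(self) -> list[str]:
        return list(self.normalized_ranks.columns)


@dataclass
class ClusterSolution:
    linkage: np.ndarray               # scipy linkage matrix
    assignments: pd.DataFrame         # node x k (columns "k=2".."k=kmax")
    db_curve: pd.Series               # DB index per k
    chosen_k: int
    roles: pd.Series                  # node -> {"core", "periphery", "intermediate"}
    cluster_mean_ranks: pd.DataFrame  # cluster x measure, at chosen_k


def rank_normalize(profile, drop=DROPPED_MEASURES) -> RankProfile:
    """Per-column average ranks mapped to (rank - 1) / (N - 1).

    The highest score maps to 1.  Constant columns become all 0.5 with a
    warning.  Columns listed in ``drop`` are removed when present.
    """
    scores = getattr(profile, "scores", profile)
    scores = scores.drop(columns=[c for c in drop if c in scores.columns])
    if scores.shape[1] < 2:
        raise ValueError("need at least 2 measures after exclusions")
    n = scores.shape[0]
    out = {}
    for c in scores.columns:
        col = scores[c].to_numpy(dtype=float)
        if np.isnan(col).any():
            logger.warning("column %s has missing values; excluded from ranks", c)
            continue
        r = tied_ranks(col)
        if np.all(r == r[0]):
            logger.warning("constant column %s: all normalized ranks set to 0.5", c)
            out[c] = np.full(n, 0.5)
        else:
            out[c] = (r - 1.0) / (n - 1.0)
    if len(out) < 2:
        raise ValueError("fewer than 2 usable measure columns")
    return RankProfile(pd.DataFrame(out, index=scores.index))


def ward_linkage(rp: RankProfile) -> np.ndarray:
    """Agglomerative merge tree, Ward's minimum-variance on Euclidean rows."""
    X = rp.normalized_ranks.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 nodes")
    return linkage(X, method="ward")


def db_curve(rp: RankProfile, tree: np.ndarray, k_max: int = 50
             ) -> tuple[pd.Series, int]:
    """Davies-Bouldin index for each dendrogram cut k = 2..k_max.

    Lower is better; ``chosen_k`` is the argmin, ties resolved to the
    smallest k.  Singleton clusters contribute zero within-cluster scatter.
    """
    X = rp.normalized_ranks.to_numpy(dtype=float)
    n = X.shape[0]
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    k_max = min(k_max, n - 1)
    vals = {}
    for k in range(2, k_max + 1):
        labels = fcluster(tree, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            vals[k] = np.nan
            continue
        vals[k] = float(davies_bouldin_score(X, labels))
    curve = pd.Series(vals, name="davies_bouldin")
    chosen_k = int(curve.idxmin())
    return curve, chosen_k


def profile_clusters(net, params=None, consensus_config=None,
                     k_max: int = 50) -> ClusterSolution:
    """Full node-role pipeline: profile -> ranks -> Ward -> DB cut -> roles.

    Computes the 17-measure centrality profile (with a consensus partition
    for the participation coefficient), drops random-walk closeness, and
    clusters the ranked profiles.  On vertex-transitive inputs every
    profile row is identical; a warning is logged and all nodes share one
    role.
    """
    from .centrality import CentralityParams, centrality_profile, NetworkKernels
    from .topology import consensus_modularity, ConsensusConfig

    params = params or CentralityParams()
    consensus_config = consensus_config or ConsensusConfig()
    kernels = NetworkKernels(net, params)
    partition, _ = consensus_modularity(net, consensus_config)
    profile = centrality_profile(net, params, partition=partition, kernels=kernels)
    rp = rank_normalize(profile)
    X = rp.normalized_ranks.to_numpy(dtype=float)
    if np.allclose(X, X[0]):
        logger.warning("all centrality profiles identical (vertex-transitive "
                       "input?): no meaningful split")
        n = X.shape[0]
        assignments = pd.DataFrame({"k=1": np.ones(n, dtype=int)},
                                   index=rp.normalized_ranks.index)
        roles = pd.Series(["core"] * n, index=rp.normalized_ranks.index)
        return ClusterSolution(
            linkage=ward_linkage(rp), assignments=assignments,
            db_curve=pd.Series(dtype=float), chosen_k=1, roles=roles,
            cluster_mean_ranks=pd.DataFrame(
                [X.mean(axis=0)], index=[1], columns=rp.measure_ids),
        )
    tree = ward_linkage(rp)
    curve, chosen_k = db_curve(rp, tree, k_max=k_max)
    assignments = pd.DataFrame(
        {f"k={k}": fcluster(tree, t=k, criterion="maxclust")
         for k in curve.index},
        index=rp.normalized_ranks.index,
    )
    labels = assignments[f"k={chosen_k}"].to_numpy()
    means = pd.DataFrame(
        [X[labels == c].mean(axis=0) for c in np.unique(labels)],
        index=np.unique(labels), columns=rp.measure_ids,
    )
    overall = means.mean(axis=1)
    core = overall.idxmax()
    periphery = overall.idxmin()
    role_of = {c: "intermediate" for c in means.index}
    role_of[periphery] = "periphery"
    role_of[core] = "core"  # if core == periphery (k=1) core wins
    roles = pd.Series([role_of[c] for c in labels],
                      index=rp.normalized_ranks.index)
    return ClusterSolution(tree, assignments, curve, chosen_k, roles, means)
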