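"""Centrality-measure correlations (CMCs) and their topological drivers.

A CMC is the Spearman correlation between the node scores of two
centrality measures within one network.  This module computes per-network
CMC matrices, their within- and between-network summaries, the
dimensionality of centrality profiles (PCA), regressions of mean
within-network CMC on global topological descriptors, per-pair
CMC-vs-descriptor correlation tables, and empirical-vs-surrogate deltas.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from ._ranks import snap_ties, tied_ranks
from .topology import TopologySummary, DESCRIPTOR_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "CMCSummary",
    "PCAResult",
    "RegressionResult",
    "SurrogateDelta",
    "spearman",
    "cmc_matrix",
    "within_network_mean",
    "between_network_summary",
    "pca_dimensionality",
    "topology_regression",
    "cmc_property_correlations",
    "surrogate_delta",
]

#: descriptors excluded from the regression for their strongly non-linear
#: association with CMCs
REGRESSION_EXCLUDED = ("density", "diffusion_efficiency")


def spearman(x, y) -> float:
    """Spearman rho with average ranks; NaN for zero-variance input.

    Pairs where either value is missing are dropped first.  Scores
    separated only by floating-point jitter are treated as tied (see
    :func:`cmcnet._ranks.snap_ties`), so that exchangeable nodes receive
    identical ranks on every measure.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        return np.nan
    rx, ry = tied_ranks(x), tied_ranks(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return np.nan
    if np.array_equal(rx, ry):  # identical rankings: rho is 1 by definition
        return 1.0
    if np.array_equal(rx, len(rx) + 1 - ry):  # exactly reversed rankings
        return -1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.pearsonr(rx, ry).statistic
    return float(rho)


def cmc_matrix(profile) -> pd.DataFrame:
    """Measure x measure Spearman matrix of a centrality profile.

    Accepts a :class:`~cmcnet.centrality.CentralityProfile` or a DataFrame.
    Missing (all-NaN or constant) columns produce missing pairs, logged.
    """
    scores = getattr(profile, "scores", profile)
    if scores.shape[1] < 2 or scores.shape[0] < 3:
        raise ValueError("need >= 2 measures and >= 3 nodes")
    cols = list(scores.columns)
    m = len(cols)
    rho = np.full((m, m), np.nan)
    for a in range(m):
        rho[a, a] = 1.0
        for b in range(a + 1, m):
            r = spearman(scores.iloc[:, a].to_numpy(), scores.iloc[:, b].to_numpy())
            rho[a, b] = rho[b, a] = r
    out = pd.DataFrame(rho, index=cols, columns=cols)
    n_missing = int(np.isnan(rho[np.triu_indices(m, 1)]).sum())
    if n_missing:
        logger.warning("%d of %d measure pairs undefined (zero variance or NaN)",
                       n_missing, m * (m - 1) // 2)
    return out


def within_network_mean(m: pd.DataFrame) -> float:
    """Mean over the defined unique off-diagonal CMCs of one network."""
    vals = m.to_numpy()[np.triu_indices(len(m), 1)]
    defined = vals[~np.isnan(vals)]
    if defined.size == 0:
        raise ValueError("all CMC pairs are missing")
    excluded = vals.size - defined.size
    if excluded:
        logger.info("within-network mean excludes %d missing pairs", excluded)
    return float(defined.mean())


@dataclass
class CMCSummary:
    within_means: np.ndarray          # per network
    between_mean: pd.DataFrame        # per pair, mean across networks
    between_sd: pd.DataFrame          # per pair, SD across networks
    n_per_pair: pd.DataFrame          # defined-network count per pair


def between_network_summary(matrices: list[pd.DataFrame]) -> CMCSummary:
    """Per-pair mean/SD of CMCs across networks plus per-network means."""
    if len(matrices) < 2:
        raise ValueError("need at least 2 networks")
    cols = list(matrices[0].columns)
    for m in matrices[1:]:
        if list(m.columns) != cols:
            raise ValueError("networks have different measure sets")
    stack = np.stack([m.to_numpy() for m in matrices])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=0)
    n = np.sum(~np.isnan(stack), axis=0)
    within = []
    for m in matrices:
        try:
            within.append(within_network_mean(m))
        except ValueError:
            logger.warning("network with no defined CMC pairs: within-mean NaN")
            within.append(np.nan)
    within = np.array(within)
    return CMCSummary(
        within,
        pd.DataFrame(mean, index=cols, columns=cols),
        pd.DataFrame(sd, index=cols, columns=cols),
        pd.DataFrame(n, index=cols, columns=cols),
    )


@dataclass
class PCAResult:
    loadings: pd.DataFrame            # measure x component
    variance_explained: np.ndarray    # fraction per component, sums to 1


def pca_dimensionality(profile) -> PCAResult:
    """PCA of the column-z-scored centrality score matrix.

    Constant or all-NaN columns are dropped with a warning.  Component signs
    are fixed so each component's mean loading is non-negative.
    """
    from sklearn.decomposition import PCA

    scores = getattr(profile, "scores", profile)
    if scores.shape[0] < 3:
        raise ValueError("need at least 3 nodes")
    X = scores.to_numpy(dtype=float)
    keep = []
    for j, c in enumerate(scores.columns):
        col = X[:, j]
        if np.isnan(col).any() or np.all(col == col[0]):
            logger.warning("dropping constant/NaN measure column %s from PCA", c)
        else:
            keep.append(j)
    if len(keep) < 2:
        raise ValueError("fewer than 2 non-constant measure columns")
    X = X[:, keep]
    cols = [scores.columns[j] for j in keep]
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    pca = PCA()
    pca.fit(Z)
    load = pca.components_.T  # measure x component
    signs = np.where(load.mean(axis=0) < 0, -1.0, 1.0)
    load = load * signs
    return PCAResult(
        pd.DataFrame(load, index=cols,
                     columns=[f"PC{i + 1}" for i in range(load.shape[1])]),
        pca.explained_variance_ratio_.copy(),
    )


@dataclass
class RegressionResult:
    model_id: str                       # "modularity" | "majorization_gap"
    coefficients: pd.Series             # standardized betas
    standard_errors: pd.Series
    p_values: pd.Series
    r_squared: float
    n_networks: int


def _fit_one(table: pd.DataFrame, predictors: list[str], model_id: str
             ) -> RegressionResult:
    sub = table[["within_mean"] + predictors].dropna()
    y = sub["within_mean"].to_numpy(dtype=float)
    X = sub[predictors].to_numpy(dtype=float)
    sds = X.std(axis=0, ddof=0)
    if np.any(sds == 0):
        bad = [p for p, s in zip(predictors, sds) if s == 0]
        raise ValueError(f"constant predictor column(s): {bad}")
    Xz = (X - X.mean(axis=0)) / sds
    if np.linalg.matrix_rank(Xz) < Xz.shape[1]:
        raise ValueError(f"collinear predictor columns among {predictors}")
    yz = (y - y.mean()) / y.std(ddof=0)
    fit = sm.OLS(yz, sm.add_constant(Xz)).fit()
    names = ["const"] + predictors
    return RegressionResult(
        model_id,
        pd.Series(fit.params, index=names),
        pd.Series(fit.bse, index=names),
        pd.Series(fit.pvalues, index=names),
        float(fit.rsquared),
        int(len(sub)),
    )


def topology_regression(table: pd.DataFrame) -> dict[str, RegressionResult]:
    """OLS of mean within-network CMC on standardized topological descriptors.

    ``table`` holds one row per network with a ``within_mean`` column plus
    the eight descriptor columns.  Density and diffusion efficiency are
    excluded as predictors; modularity and the majorization gap are
    collinear across realistic corpora and therefore enter two separate
    models, returned under keys ``"modularity"`` and ``"majorization_gap"``.
    """
    if len(table) < 10:
        raise ValueError("need at least 10 networks for the regression")
    base = [d for d in DESCRIPTOR_NAMES
            if d not in REGRESSION_EXCLUDED + ("modularity_q", "majorization_gap")]
    return {
        "modularity": _fit_one(table, base + ["modularity_q"], "modularity"),
        "majorization_gap": _fit_one(table, base + ["majorization_gap"],
                                     "majorization_gap"),
    }


def cmc_property_correlations(matrices: list[pd.DataFrame],
                              summaries: list[TopologySummary],
                              alpha: float = 0.05) -> pd.DataFrame:
    """Spearman correlation of each measure-pair CMC with each descriptor.

    Returns a long-form table (pair, property, rho, p, p_bonferroni,
    significant); p-values use the large-sample approximation and are
    Bonferroni-corrected by the number of measure pairs (136 for the full
    17-measure set).
    """
    if len(matrices) < 10:
        raise ValueError("need at least 10 networks")
    if len(matrices) != len(summaries):
        raise ValueError("matrices and summaries must align")
    cols = list(matrices[0].columns)
    m = len(cols)
    n_pairs = m * (m - 1) // 2
    prop_table = pd.DataFrame([s.as_dict() for s in summaries])
    rows = []
    for a in range(m):
        for b in range(a + 1, m):
            cmcs = np.array([mat.iloc[a, b] for mat in matrices])
            for prop in DESCRIPTOR_NAMES:
                vals = prop_table[prop].to_numpy()
                ok = ~(np.isnan(cmcs) | np.isnan(vals))
                if ok.sum() < 3 or np.all(cmcs[ok] == cmcs[ok][0]) \
                        or np.all(vals[ok] == vals[ok][0]):
                    rho, p = np.nan, np.nan
                else:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = stats.spearmanr(cmcs[ok], vals[ok])
                    rho, p = float(res.statistic), float(res.pvalue)
                p_bonf = min(p * n_pairs, 1.0) if not np.isnan(p) else np.nan
                rows.append({
                    "pair": f"{cols[a]}-{cols[b]}",
                    "property": prop,
                    "rho": rho,
                    "p": p,
                    "p_bonferroni": p_bonf,
                    "significant": bool(p_bonf < alpha) if not np.isnan(p_bonf)
                    else False,
                    "n": int(ok.sum()),
                })
    return pd.DataFrame(rows)


@dataclass
class SurrogateDelta:
    """Empirical-minus-surrogate-ensemble-mean differences.

    Positive values mean the empirical network scores higher than the
    average surrogate.
    """

    delta_cmc: float
    delta_property: dict[str, float]


def surrogate_delta(net_within_mean: float,
                    net_summary: TopologySummary,
                    ensemble_within_means,
                    ensemble_summaries: list[TopologySummary]) -> SurrogateDelta:
    ens_w = np.asarray(ensemble_within_means, dtype=float)
    if ens_w.size == 0:
        raise ValueError("empty surrogate ensemble")

    def _delta(value: float, ens: np.ndarray) -> float:
        if np.all(ens == value):  # exact zero when every member matches
            return 0.0
        return float(value - np.nanmean(ens))

    delta_cmc = _delta(net_within_mean, ens_w)
    delta_prop = {}
    emp = net_summary.as_dict()
    ens = pd.DataFrame([s.as_dict() for s in ensemble_summaries])
    for prop in DESCRIPTOR_NAMES:
        delta_prop[prop] = _delta(emp[prop], ens[prop].to_numpy())
    return SurrogateDelta(delta_cmc, delta_prop)
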