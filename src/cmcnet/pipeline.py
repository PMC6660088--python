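"""End-to-end orchestration over single networks and corpora.

``run_network`` composes the stages in analysis order — preprocess ->
centrality profile -> topology summary -> CMC matrix -> surrogate
ensembles and deltas -> node-role profiling — and writes one CSV per
artifact.  ``run_corpus`` aggregates per-network results into
between-network CMC summaries, the two-variant topology regression, and
the per-pair CMC-vs-descriptor correlation table.

All randomness derives from a single global seed: each (network, stage,
repetition) gets a stable sub-seed via CRC32 hashing, so a run is
bit-reproducible given its configuration.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .graphio import Network, preprocess, read_network
from .centrality import (
    ALL_MEASURES, CentralityParams, NetworkKernels, centrality_profile,
)
from .topology import ConsensusConfig, TopologySummary, topology_summary
from .surrogates import build_ensemble
from .cmc import (
    cmc_matrix, within_network_mean, between_network_summary,
    topology_regression, cmc_property_correlations, surrogate_delta,
)
from .profiling import profile_clusters

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "NetworkResult", "run_network", "run_corpus", "sub_seed"]

#: measures skipped on surrogate ensembles by default (computationally heavy)
SURROGATE_SKIP = ("CBC", "RWBC")


def sub_seed(global_seed: int, *context) -> int:
    """Stable sub-seed below 2**31 derived from the global seed and context."""
    key = ":".join([str(global_seed)] + [str(c) for c in context])
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


@dataclass
class RunConfig:
    binarize: bool = True
    measures: tuple[str, ...] = ALL_MEASURES
    katz_alpha_fraction: float = 0.85
    pagerank_damping: float = 0.85
    consensus_runs: int = 50
    consensus_tau: float = 0.4
    surrogate_models: tuple[str, ...] = ()
    n_surrogates: int = 100
    swaps_per_edge: int = 10
    skip_expensive_for_surrogates: bool = True
    k_max: int = 50
    seed: int = 0
    output_dir: str = "cmcnet_out"

    def centrality_params(self) -> CentralityParams:
        return CentralityParams(
            katz_alpha_fraction=self.katz_alpha_fraction,
            pagerank_damping=self.pagerank_damping,
            measure_list=tuple(self.measures),
        )

    def consensus_config(self, seed: int) -> ConsensusConfig:
        return ConsensusConfig(n_runs=self.consensus_runs,
                               tau=self.consensus_tau, seed=seed)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for k in ("measures", "surrogate_models"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)


@dataclass
class NetworkResult:
    name: str
    net: Network
    profile: pd.DataFrame
    cmc: pd.DataFrame
    within_mean: float
    summary: TopologySummary
    deltas: dict[str, object]
    clusters: object | None


def analyse_network(net: Network, config: RunConfig, name: str = "net",
                    with_surrogates: bool | None = None,
                    with_profiling: bool = True) -> NetworkResult:
    """Run the full per-network analysis in memory."""
    net = preprocess(net, binarize=config.binarize)
    params = config.centrality_params()
    kernels = NetworkKernels(net, params)
    # sub-seeds derive from the network content, not its name, so identical
    # networks produce identical analyses under one global seed
    key = net.content_hash()
    summary, partition = topology_summary(
        net, config.consensus_config(sub_seed(config.seed, key, "consensus")),
        kernels=kernels,
    )
    profile = centrality_profile(net, params, partition=partition, kernels=kernels)
    cmc = cmc_matrix(profile)
    within = within_network_mean(cmc)

    deltas: dict[str, object] = {}
    if with_surrogates is None:
        with_surrogates = bool(config.surrogate_models) and config.n_surrogates > 0
    if with_surrogates:
        sur_measures = tuple(
            m for m in config.measures
            if not (config.skip_expensive_for_surrogates and m in SURROGATE_SKIP)
        )
        sur_params = CentralityParams(
            katz_alpha_fraction=config.katz_alpha_fraction,
            pagerank_damping=config.pagerank_damping,
            measure_list=sur_measures,
        )
        # compare empirical vs surrogates on the same measure list
        emp_cmc = cmc_matrix(profile.scores[list(sur_measures)])
        emp_within = within_network_mean(emp_cmc)
        for model in config.surrogate_models:
            ens = build_ensemble(
                net, model, n=config.n_surrogates,
                base_seed=sub_seed(config.seed, key, "surrogate", model),
                swaps_per_edge=config.swaps_per_edge,
            )
            withins, summaries = [], []
            for k, member in enumerate(ens.members):
                mk = NetworkKernels(member, sur_params)
                msum, mpart = topology_summary(
                    member,
                    config.consensus_config(
                        sub_seed(config.seed, key, "surrogate", model, k)),
                    kernels=mk,
                )
                mprof = centrality_profile(member, sur_params, partition=mpart,
                                           kernels=mk)
                withins.append(within_network_mean(cmc_matrix(mprof)))
                summaries.append(msum)
            deltas[model] = surrogate_delta(emp_within, summary, withins, summaries)
    clusters = None
    if with_profiling:
        clusters = profile_clusters(
            net, params,
            consensus_config=config.consensus_config(
                sub_seed(config.seed, key, "consensus")),
            k_max=config.k_max,
        )
    return NetworkResult(name, net, profile.scores, cmc, within, summary,
                         deltas, clusters)


def _write_network_result(res: NetworkResult, outdir: Path, config: RunConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    res.profile.to_csv(outdir / f"{res.name}_profile.csv", index_label="node")
    res.cmc.to_csv(outdir / f"{res.name}_cmc.csv", index_label="measure")
    pd.DataFrame([res.summary.as_dict()], index=[res.name]).to_csv(
        outdir / f"{res.name}_topology.csv", index_label="network")
    if res.deltas:
        rows = []
        for model, d in res.deltas.items():
            row = {"model": model, "delta_cmc": d.delta_cmc}
            row.update({f"delta_{k}": v for k, v in d.delta_property.items()})
            rows.append(row)
        pd.DataFrame(rows).to_csv(outdir / f"{res.name}_surrogate_deltas.csv",
                                  index=False)
    if res.clusters is not None:
        cs = res.clusters
        assign = cs.assignments.copy()
        assign["role"] = cs.roles
        assign.to_csv(outdir / f"{res.name}_clusters.csv", index_label="node")
        cs.db_curve.to_csv(outdir / f"{res.name}_db_curve.csv", index_label="k")
    manifest = {
        "network": res.name,
        "cmcnet_version": __version__,
        "seed": config.seed,
        "within_mean_cmc": res.within_mean,
        "n_nodes": res.net.n_nodes,
        "n_edges": res.net.n_edges,
    }
    with open(outdir / f"{res.name}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def run_network(source: Network | str | Path, config: RunConfig,
                name: str | None = None) -> NetworkResult:
    """Analyse one network and write all per-network artifacts."""
    if isinstance(source, (str, Path)):
        name = name or Path(source).stem
        net = read_network(source)
    else:
        net = source
        name = name or "net"
    res = analyse_network(net, config, name=name)
    _write_network_result(res, Path(config.output_dir), config)
    return res


def run_corpus(sources, config: RunConfig) -> dict[str, object]:
    """Analyse >= 2 networks and write corpus-level summaries.

    ``sources`` is an iterable of paths, Networks, or (name, Network) pairs.
    Per-network failures are logged and the network skipped.
    """
    results: list[NetworkResult] = []
    for k, src in enumerate(sources):
        if isinstance(src, tuple):
            name, net = src
        elif isinstance(src, (str, Path)):
            name, net = Path(src).stem, src
        else:
            name, net = f"net{k}", src
        try:
            results.append(run_network(net, config, name=name))
        except Exception as exc:  # noqa: BLE001 - corpus mode skips failures
            logger.warning("network %s failed and was skipped: %s", name, exc)
    if len(results) < 2:
        raise ValueError("corpus analysis needs at least 2 successful networks")
    outdir = Path(config.output_dir)
    summary = between_network_summary([r.cmc for r in results])
    summary.between_mean.to_csv(outdir / "between_mean.csv", index_label="measure")
    summary.between_sd.to_csv(outdir / "between_sd.csv", index_label="measure")
    pd.DataFrame({
        "network": [r.name for r in results],
        "within_mean": summary.within_means,
    }).to_csv(outdir / "within_means.csv", index=False)
    table = pd.DataFrame([r.summary.as_dict() for r in results],
                         index=[r.name for r in results])
    table["within_mean"] = summary.within_means
    table.to_csv(outdir / "topology_table.csv", index_label="network")
    out: dict[str, object] = {"results": results, "summary": summary,
                              "table": table}
    if len(results) >= 10:
        try:
            reg = topology_regression(table)
            coef_rows = []
            report_lines = []
            for model_id, r in reg.items():
                for term in r.coefficients.index:
                    coef_rows.append({
                        "model": model_id, "term": term,
                        "beta": r.coefficients[term],
                        "se": r.standard_errors[term],
                        "p": r.p_values[term],
                    })
                report_lines.append(
                    f"model [{model_id}]: R^2 = {r.r_squared:.4f}, "
                    f"n = {r.n_networks}"
                )
            pd.DataFrame(coef_rows).to_csv(outdir / "regression_coefficients.csv",
                                           index=False)
            (outdir / "regression_report.txt").write_text(
                "\n".join(report_lines) + "\n")
            out["regression"] = reg
        except ValueError as exc:
            logger.warning("regression skipped: %s", exc)
        corr = cmc_property_correlations(
            [r.cmc for r in results], [r.summary for r in results])
        corr.to_csv(outdir / "cmc_property_correlations.csv", index=False)
        out["property_correlations"] = corr
    else:
        logger.warning("fewer than 10 networks: regression and property "
                       "correlations skipped")
    return out
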