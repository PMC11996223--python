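"""End-to-end pipeline orchestration, configuration, and file I/O.

The pipeline runs: standardize -> SGTCCA (density-biased subsampling +
per-subsample GTCCA) -> global adjacency -> PageRank/summarization pruning
-> Pearson edge filtering, and writes the node table, edge list, GraphML
export, and a JSON run summary.  A single config (YAML) is the source of
truth; every CLI flag mirrors a config key.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import network as net
from .gtcca import StructureSpec, default_structures
from .subsampling import CanonicalWeightMatrices, SubsampleScheme, run_sgtcca
from .tensor_core import StandardizedBlock, read_block, standardize, validate_aligned

__all__ = [
    "OptimizerSettings",
    "PruneSettings",
    "PipelineSettings",
    "PipelineConfig",
    "PipelineResult",
    "run_arrays",
    "run_pipeline",
]

log = logging.getLogger("sgtcca")


@dataclass
class OptimizerSettings:
    init: str = "svd"
    max_iter: int = 500
    grad_tol: float = 1e-6


@dataclass
class PruneSettings:
    min_size: int = 30
    max_size: int = 300
    n_pcs: int = 3
    step: int = 10
    tolerance: float = 0.05
    edge_threshold: float = 0.2


@dataclass
class PipelineSettings:
    """Everything needed to run the pipeline on in-memory arrays."""

    common_fraction: float = 0.08
    distinct_fraction: float = 0.02
    n_subsamples: int = 10
    density_subsample_fraction: float = 0.1
    density_iterations: int = 50
    bias_power: float = 2.0
    structures: list[tuple[int, ...]] | None = None  # default: all with phenotype
    scalings: list[float] | None = None
    optimizer: OptimizerSettings = field(default_factory=OptimizerSettings)
    pruning: PruneSettings = field(default_factory=PruneSettings)
    run_prune: bool = True

    def scheme(self, seed: int) -> SubsampleScheme:
        return SubsampleScheme(
            common_fraction=self.common_fraction,
            distinct_fraction=self.distinct_fraction,
            n_subsamples=self.n_subsamples,
            density_subsample_fraction=self.density_subsample_fraction,
            density_iterations=self.density_iterations,
            bias_power=self.bias_power,
            seed=seed,
        )


@dataclass
class PipelineResult:
    weights: CanonicalWeightMatrices
    global_module: net.NetworkModule
    prune_result: net.PruneResult | None
    final_module: net.NetworkModule
    blocks: list[StandardizedBlock]
    phenotype: np.ndarray
    view_names: list[str]
    timings: dict[str, float]

    def node_data(self, module: net.NetworkModule) -> np.ndarray:
        cols = [self.blocks[v].values[:, c] for v, c in module.node_feature_index]
        return np.column_stack(cols)


def run_arrays(
    omics: list[np.ndarray],
    phenotype: np.ndarray,
    settings: PipelineSettings | None = None,
    seed: int = 0,
    view_names: list[str] | None = None,
    feature_ids: list[list[str]] | None = None,
) -> PipelineResult:
    """Run the full pipeline on in-memory matrices (samples x features)."""
    settings = settings or PipelineSettings()
    if view_names is None:
        view_names = [f"omics{j + 1}" for j in range(len(omics))] + ["phenotype"]
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    blocks = [standardize(x, feature_ids=feature_ids[j] if feature_ids else None)
              for j, x in enumerate(omics)]
    pheno_block = standardize(np.asarray(phenotype, float).reshape(-1, 1),
                              feature_ids=["phenotype"])
    blocks.append(pheno_block)
    timings["standardize"] = time.perf_counter() - t0

    k = len(blocks)
    phenotype_view = k - 1
    if settings.structures is None:
        spec = default_structures(k, phenotype_view)
    else:
        spec = StructureSpec([tuple(s) for s in settings.structures],
                             settings.scalings)

    t0 = time.perf_counter()
    scheme = settings.scheme(seed)
    weights = run_sgtcca(blocks, spec, scheme,
                         init=settings.optimizer.init,
                         max_iter=settings.optimizer.max_iter,
                         grad_tol=settings.optimizer.grad_tol)
    timings["sgtcca"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    fids = [b.feature_ids for b in blocks]
    global_module = net.build_adjacency(weights, view_names=view_names,
                                        feature_ids=fids)
    timings["adjacency"] = time.perf_counter() - t0

    result = PipelineResult(weights, global_module, None, global_module,
                            blocks, np.asarray(phenotype, float).ravel(),
                            view_names, timings)
    if settings.run_prune:
        t0 = time.perf_counter()
        data = result.node_data(global_module)
        pr = net.prune(global_module, data, result.phenotype,
                       min_size=settings.pruning.min_size,
                       max_size=settings.pruning.max_size,
                       n_pcs=settings.pruning.n_pcs,
                       step=settings.pruning.step,
                       tolerance=settings.pruning.tolerance)
        timings["prune"] = time.perf_counter() - t0
        t0 = time.perf_counter()
        sub_data = result.node_data(pr.module)
        final = net.filter_edges(pr.module, sub_data,
                                 threshold=settings.pruning.edge_threshold)
        timings["filter_edges"] = time.perf_counter() - t0
        result.prune_result = pr
        result.final_module = final
    return result


# --------------------------------------------------------------------------
# File-based configuration and artifacts
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    block_files: list[str]
    phenotype_file: str
    output_dir: str = "sgtcca_out"
    seed: int = 0
    settings: PipelineSettings = field(default_factory=PipelineSettings)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["settings"]["structures"] is not None:
            d["settings"]["structures"] = [list(s) for s in d["settings"]["structures"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        s = dict(d.get("settings", {}))
        opt = OptimizerSettings(**s.pop("optimizer", {}))
        pr = PruneSettings(**s.pop("pruning", {}))
        if s.get("structures") is not None:
            s["structures"] = [tuple(t) for t in s["structures"]]
        settings = PipelineSettings(optimizer=opt, pruning=pr, **s)
        return cls(block_files=list(d["block_files"]),
                   phenotype_file=d["phenotype_file"],
                   output_dir=d.get("output_dir", "sgtcca_out"),
                   seed=int(d.get("seed", 0)),
                   settings=settings)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based pipeline run writing all declared artifacts."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s", datefmt="%Y-%m-%dT%H:%M:%S"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("loading %d blocks + phenotype", len(config.block_files))
        frames = [read_block(p) for p in config.block_files]
        pheno_df = read_block(config.phenotype_file)
        sample_ids = [str(i) for i in frames[0].index]
        for j, f in enumerate(frames + [pheno_df]):
            if [str(i) for i in f.index] != sample_ids:
                raise ValueError(
                    f"stage=load: sample IDs of input {j} do not match the first block")
        omics = [f.to_numpy(dtype=float) for f in frames]
        feature_ids = [[str(c) for c in f.columns] for f in frames]
        phenotype = pheno_df.to_numpy(dtype=float).ravel()
        view_names = [Path(p).stem for p in config.block_files] + ["phenotype"]

        result = run_arrays(omics, phenotype, config.settings, config.seed,
                            view_names=view_names, feature_ids=feature_ids)
        validate_aligned(result.blocks[:-1])

        final = result.final_module
        data = result.node_data(final)
        pr_scores = (net.pagerank_scores(result.global_module)
                     if result.prune_result is None else result.prune_result.pagerank)
        sel = (result.prune_result.selected if result.prune_result is not None
               else np.arange(result.global_module.n_nodes))
        table = net.node_table(final, data, result.phenotype,
                               view_names=view_names, pagerank=pr_scores[sel])
        table.to_csv(out / "nodes.tsv", sep="\t", index=False)
        net.write_edge_list(final, out / "edges.tsv")
        import networkx as nx
        nx.write_graphml(net.to_networkx(final), out / "network.graphml")

        summary = {
            "n_samples": int(result.blocks[0].n_samples),
            "view_names": view_names,
            "global_network_size": int(result.global_module.n_nodes),
            "final_network_size": int(final.n_nodes),
            "prune_trace": (None if result.prune_result is None
                            else [[int(s), float(c)] for s, c in result.prune_result.trace]),
            "timings_s": {k: round(v, 4) for k, v in result.timings.items()},
            "seed": config.seed,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        config.to_yaml(out / "config.yaml")
        for stage, dt in result.timings.items():
            log.info("stage=%s elapsed=%.3fs", stage, dt)
        log.info("final network: %d nodes", final.n_nodes)
        return result
    finally:
        log.removeHandler(handler)
        handler.close()
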