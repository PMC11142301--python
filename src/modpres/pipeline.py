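"""End-to-end orchestration of the reference-vs-test comparison.

The pipeline mirrors the comparative workflow: QC filtering (cells first,
then genes), log-normalization, variable genes, scaling and PCA, optimal-
dimension selection, SNN-Louvain clustering, marker-based major-cell-type
assignment, stratified down-sampling to the base group's total, variable-gene
universe construction (intersection or reference-only), soft-threshold
selection and module detection on the reference network, preservation
statistics against the test network, non-preservation flagging, and
sub-network comparison of the flagged modules plus the most-preserved one.

A single global seed fans out to per-stage seeds through a
``numpy.random.SeedSequence`` spawn in a fixed order (PCA, clustering,
down-sampling, permutation), so later stages never perturb earlier ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from modpres import preprocess, sampling
from modpres.coexpression import (
    ModulePartition,
    NetworkParams,
    adjacency,
    detect_modules,
    pick_soft_threshold,
    topological_overlap,
    variable_gene_set,
)
from modpres.netcompare import SubnetworkComparison, compare_module, export_comparison
from modpres.preprocess import QCThresholds
from modpres.preservation import PreservationReport, preservation_report

__all__ = ["ComparisonConfig", "PipelineResult", "PipelineError", "run_pipeline",
           "stage_preset", "side_preset"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class ComparisonConfig:
    """Configuration of one reference-vs-test comparison."""

    reference_group: str
    group_key: str = "group"
    base_group: str | None = None  # defaults to the reference group
    condition_of: dict[str, str] | None = None  # group -> reference/test
    variable_gene_mode: str = "intersection"
    variable_fraction: float = 0.20
    hvg_flavor: str = "vst"
    qc: QCThresholds = field(default_factory=QCThresholds)
    npcs: int = 40
    cluster_resolution: float = 2.0
    snn_k: int = 20
    sampling_strategy: str = "space_filling"
    network: NetworkParams = field(default_factory=NetworkParams)
    pick_power: bool = True
    n_perm: int = 50
    rank_threshold: float = 10.0
    size_threshold: int = 100
    edge_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.variable_gene_mode not in ("intersection", "reference_only"):
            raise ValueError(f"unknown variable_gene_mode {self.variable_gene_mode!r}")
        if self.base_group is None:
            self.base_group = self.reference_group

    def stage_seeds(self) -> dict[str, int]:
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("pca", "cluster", "downsample", "permutation")
        return {n: int(s.generate_state(1)[0] % 2**31) for n, s in zip(names, children)}

    def param_hash(self) -> str:
        payload = repr(dataclasses.asdict(self)).encode()
        return hashlib.md5(payload).hexdigest()


def stage_preset(reference_group: str = "pT1", **kw) -> ComparisonConfig:
    """Stage-style comparison: the earliest (smallest) group is base and reference;
    the variable-gene universe is the intersection of both conditions' top lists."""
    return ComparisonConfig(reference_group=reference_group,
                            variable_gene_mode="intersection", **kw)


def side_preset(reference_group: str = "right", base_group: str = "left", **kw) -> ComparisonConfig:
    """Side-style comparison: the smaller group is the base, the other is the
    reference network, and the variable genes come from the reference alone."""
    return ComparisonConfig(reference_group=reference_group, base_group=base_group,
                            variable_gene_mode="reference_only", **kw)


@dataclass
class PipelineResult:
    qc: pd.DataFrame
    kept_cells: pd.Index
    kept_genes: pd.Index
    cluster_labels: np.ndarray | None
    cell_types: pd.Series | None
    quotas: pd.DataFrame
    downsampled_obs: pd.DataFrame
    universe: list[str]
    soft_threshold: pd.DataFrame
    beta: float
    partition: ModulePartition
    report: PreservationReport
    comparisons: dict[str, SubnetworkComparison]
    manifest: dict


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def _norm_frame(adata, genes) -> pd.DataFrame:
    import scipy.sparse as sp

    M = adata.layers["lognorm"]
    cols = list(genes)
    sub = adata[:, cols]
    X = sub.layers["lognorm"]
    arr = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
    return pd.DataFrame(arr, index=adata.obs_names, columns=cols)


def run_pipeline(adata, config: ComparisonConfig, out_dir: str | None = None,
                 markers: pd.DataFrame | None = None) -> PipelineResult:
    """Run the full comparison on a combined counts AnnData.

    ``adata`` holds raw counts for all groups with ``obs[config.group_key]``;
    the condition of each group comes from ``config.condition_of`` (default:
    the reference group is the reference condition, every other group is
    test).  ``markers`` (gene, cell_type) enables cluster-based cell-type
    assignment; without it an existing ``obs['cell_type']`` is used.
    """
    t0 = time.time()
    seeds = config.stage_seeds()
    gkey = config.group_key

    qc = _stage("cell_qc")(preprocess.compute_cell_qc)(adata)
    keep_cells = _stage("cell_filter")(preprocess.filter_cells)(qc, config.qc)
    adata = adata[keep_cells].copy()
    keep_genes = _stage("gene_filter")(preprocess.filter_genes)(adata, config.qc.min_cells_per_gene)
    adata = adata[:, keep_genes].copy()
    adata = _stage("normalize")(preprocess.log_normalize)(adata)

    hvg = _stage("variable_genes")(preprocess.select_variable_genes)(
        adata, fraction=config.variable_fraction, flavor=config.hvg_flavor)
    scaled = _stage("scale")(preprocess.scale_genes)(adata, genes=hvg)
    pca = _stage("pca")(preprocess.run_pca)(scaled, npcs=config.npcs, seed=seeds["pca"])
    dims = _stage("optimal_dims")(preprocess.select_optimal_dims)(pca.pv)
    adata.obsm["X_pca"] = pca.scores

    clusters = _stage("cluster")(preprocess.cluster_cells)(
        pca.scores, dims=dims, resolution=config.cluster_resolution,
        k=config.snn_k, seed=seeds["cluster"])
    if markers is not None:
        cell_types = _stage("cell_types")(preprocess.assign_cell_types)(clusters, adata, markers)
        adata.obs["cell_type"] = np.asarray(cell_types)
    elif "cell_type" not in adata.obs:
        raise PipelineError("stage 'cell_types' failed: no markers given and no "
                            "obs['cell_type'] present")

    counts_tab = pd.crosstab(adata.obs[gkey].astype(str), adata.obs["cell_type"].astype(str))
    quotas = _stage("quotas")(sampling.compute_quotas)(counts_tab, config.base_group)
    adata = _stage("downsample")(sampling.stratified_downsample)(
        adata, quotas, strategy=config.sampling_strategy, seed=seeds["downsample"],
        base_group=config.base_group, group_key=gkey)

    # post-down-sampling rescale/PCA, mirroring the upstream workflow
    scaled2 = _stage("rescale")(preprocess.scale_genes)(adata, genes=hvg)
    pca2 = _stage("re_pca")(preprocess.run_pca)(scaled2, npcs=config.npcs, seed=seeds["pca"])
    adata.obsm["X_pca"] = pca2.scores

    cond_of = config.condition_of or {}
    groups = np.asarray(adata.obs[gkey].astype(str))
    is_ref = np.array([
        cond_of.get(g, "reference" if g == config.reference_group else "test") == "reference"
        for g in groups
    ])
    ref_counts = adata[is_ref]
    test_counts = adata[~is_ref]
    if ref_counts.n_obs == 0 or test_counts.n_obs == 0:
        raise PipelineError("stage 'split' failed: empty reference or test condition")

    universe = _stage("variable_gene_set")(variable_gene_set)(
        ref_counts, test_counts, mode=config.variable_gene_mode,
        fraction=config.variable_fraction, flavor=config.hvg_flavor)
    ref_norm = _norm_frame(ref_counts, universe)
    test_norm = _norm_frame(test_counts, universe)

    params = dataclasses.replace(config.network)
    if config.pick_power:
        sft = _stage("soft_threshold")(pick_soft_threshold)(ref_norm, sign_mode=params.sign_mode)
        params.power = sft.power
        sft_table = sft.table
    else:
        sft_table = pd.DataFrame()
    adj = _stage("adjacency")(adjacency)(ref_norm, params)
    tom = _stage("tom")(topological_overlap)(adj)
    partition = _stage("detect_modules")(detect_modules)(tom, params, expr=ref_norm)
    if partition.n_modules == 0:
        raise PipelineError("stage 'detect_modules' failed: no modules found")

    report = _stage("preservation")(preservation_report)(
        ref_norm, test_norm, partition, n_perm=config.n_perm, seed=seeds["permutation"],
        beta=params.power, rank_threshold=config.rank_threshold,
        size_threshold=config.size_threshold)

    flagged = list(report.flags.index[report.flags["flagged"]])
    most_preserved = report.ranks["medianRank_pres"].idxmin()
    targets = list(dict.fromkeys(flagged + [most_preserved]))
    comparisons: dict[str, SubnetworkComparison] = {}
    if partition.n_modules >= 2:
        for mod in targets:
            try:
                comparisons[mod] = compare_module(
                    ref_norm, test_norm, partition, mod, beta=params.power,
                    edge_fraction=config.edge_fraction)
            except ValueError as exc:
                warnings.warn(f"comparison of module {mod} skipped: {exc}")

    manifest = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "param_hash": config.param_hash(),
        "n_cells_input": int(len(qc)),
        "n_cells_kept": int(keep_cells.sum()),
        "n_genes_kept": int(keep_genes.sum()),
        "optimal_dims": int(dims),
        "beta": float(params.power),
        "n_universe_genes": len(universe),
        "n_modules": partition.n_modules,
        "flagged_modules": flagged,
        "most_preserved": most_preserved,
        "started": t0,
        "elapsed_s": time.time() - t0,
    }
    result = PipelineResult(
        qc=qc, kept_cells=adata.obs_names, kept_genes=adata.var_names,
        cluster_labels=clusters, cell_types=adata.obs.get("cell_type"),
        quotas=quotas, downsampled_obs=adata.obs.copy(), universe=list(universe),
        soft_threshold=sft_table, beta=float(params.power), partition=partition,
        report=report, comparisons=comparisons, manifest=manifest,
    )
    if out_dir is not None:
        _write_products(result, out_dir)
    return result


def _write_products(result: PipelineResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    ff = "%.10g"
    result.qc.to_csv(os.path.join(out_dir, "qc_report.tsv"), sep="\t", float_format=ff)
    result.quotas.to_csv(os.path.join(out_dir, "quotas.tsv"), sep="\t", index=False)
    pd.Series(result.kept_cells).to_csv(os.path.join(out_dir, "kept_cells.txt"),
                                        index=False, header=False)
    result.partition.labels.rename("module").to_csv(
        os.path.join(out_dir, "partition.tsv"), sep="\t")
    result.report.to_frame().to_csv(os.path.join(out_dir, "preservation.tsv"),
                                    sep="\t", float_format=ff)
    result.report.flags.to_csv(os.path.join(out_dir, "flags.tsv"), sep="\t", float_format=ff)
    if len(result.soft_threshold):
        result.soft_threshold.to_csv(os.path.join(out_dir, "soft_threshold.tsv"),
                                     sep="\t", index=False, float_format=ff)
    for mod, comp in result.comparisons.items():
        export_comparison(comp, os.path.join(out_dir, "comparisons"))
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
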