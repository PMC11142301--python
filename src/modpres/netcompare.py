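"""Topological and statistical comparison of module sub-networks between conditions.

For a selected (typically non-preserved) module the workflow is: pick, per
condition, the cells whose mean normalized expression over the module's genes
strictly exceeds their mean over all other non-grey module genes; build the
soft-thresholded co-expression sub-network over those cells; extract the
top-fraction edges and mark the ones unique to each condition; compute node
connectivities, their Spearman rank correlation between conditions, and a
per-gene two-sample z-score (test minus reference) that drives the node
coloring of the circle plot (clamped to [-2, 2] on a blue-white-red scale).
A local hypergeometric over-representation analysis against GMT gene sets
replaces web-based enrichment services.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata
from statsmodels.stats.multitest import multipletests

from modpres.coexpression import ModulePartition

__all__ = [
    "ModuleCellSelection",
    "SubnetworkComparison",
    "select_module_cells",
    "module_subnetwork",
    "top_unique_edges",
    "connectivity_spearman",
    "gene_zscores",
    "compare_module",
    "export_comparison",
    "read_comparison_nodes",
    "ora",
]


@dataclass
class ModuleCellSelection:
    module: str
    cells: pd.Index


def select_module_cells(normalized: pd.DataFrame, partition: ModulePartition,
                        module: str) -> ModuleCellSelection:
    """Cells whose mean expression over module genes strictly exceeds their mean
    over the genes of all other non-grey modules."""
    if module == "grey":
        raise ValueError("grey is not a module")
    lab = partition.labels
    mod_genes = [g for g in lab.index[lab == module] if g in normalized.columns]
    other_genes = [g for g in lab.index[(lab != module) & (lab != "grey")]
                   if g in normalized.columns]
    if not mod_genes:
        raise ValueError(f"module {module!r} has no genes in the matrix")
    if not other_genes:
        raise ValueError("cell selection needs at least one other non-grey module")
    mean_mod = normalized[mod_genes].mean(axis=1)
    mean_other = normalized[other_genes].mean(axis=1)
    cells = normalized.index[mean_mod > mean_other]
    if len(cells) == 0:
        raise ValueError(f"no cells selected for module {module!r}")
    return ModuleCellSelection(module=module, cells=cells)


def module_subnetwork(normalized: pd.DataFrame, cells, genes, beta: float) -> pd.DataFrame:
    """Unsigned soft-thresholded adjacency over the selected cells (zero diagonal)."""
    cells = list(cells.cells if isinstance(cells, ModuleCellSelection) else cells)
    if len(cells) < 10:
        raise ValueError(f"only {len(cells)} selected cells; need at least 10")
    sub = normalized.loc[cells, list(genes)].to_numpy(dtype=float)
    sd = sub.std(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        C = np.corrcoef(sub, rowvar=False)
    C = np.nan_to_num(C, nan=0.0)
    if (sd == 0).any():
        warnings.warn(f"{int((sd == 0).sum())} constant genes in the sub-network")
    A = np.abs(np.clip(C, -1, 1)) ** beta
    np.fill_diagonal(A, 0.0)
    gi = pd.Index(genes)
    return pd.DataFrame(A, index=gi, columns=gi)


def _edge_table(adj: pd.DataFrame) -> pd.DataFrame:
    genes = adj.index
    iu, ju = np.triu_indices(len(genes), 1)
    df = pd.DataFrame(
        {"gene_i": np.asarray(genes)[iu], "gene_j": np.asarray(genes)[ju],
         "weight": adj.to_numpy()[iu, ju]}
    )
    return df.sort_values(["weight", "gene_i", "gene_j"],
                          ascending=[False, True, True], kind="stable").reset_index(drop=True)


def top_unique_edges(adj_ref: pd.DataFrame, adj_test: pd.DataFrame, fraction: float = 0.10,
                     order: str = "top_then_unique") -> dict[str, pd.DataFrame]:
    """Top-fraction edge tables per condition with uniqueness flags.

    ``top_then_unique`` (default): take the top ``ceil(fraction * E)`` edges
    of each condition by weight; an edge is unique to a condition when it is
    in that condition's top set but not the other's.  ``unique_then_top``:
    restrict first to edges whose weight favors the condition, then take the
    top fraction of those.
    """
    if list(adj_ref.index) != list(adj_test.index):
        raise ValueError("adjacency matrices must share the same gene set and order")
    ref_edges, test_edges = _edge_table(adj_ref), _edge_table(adj_test)
    n_edges = len(ref_edges)
    m = int(np.ceil(fraction * n_edges))
    out = {}
    if order == "top_then_unique":
        tops = {"reference": ref_edges.head(m).copy(), "test": test_edges.head(m).copy()}
        keys = {c: set(map(tuple, t[["gene_i", "gene_j"]].to_numpy())) for c, t in tops.items()}
        other = {"reference": "test", "test": "reference"}
        for c, t in tops.items():
            pairs = list(map(tuple, t[["gene_i", "gene_j"]].to_numpy()))
            t["unique"] = [p not in keys[other[c]] for p in pairs]
            out[c] = t.reset_index(drop=True)
    elif order == "unique_then_top":
        merged = ref_edges.merge(test_edges, on=["gene_i", "gene_j"], suffixes=("_ref", "_test"))
        for c, col, other_col in (("reference", "weight_ref", "weight_test"),
                                  ("test", "weight_test", "weight_ref")):
            fav = merged[merged[col] > merged[other_col]]
            fav = fav.sort_values([col, "gene_i", "gene_j"], ascending=[False, True, True])
            mf = int(np.ceil(fraction * len(fav))) if len(fav) else 0
            t = fav.head(mf)[["gene_i", "gene_j", col]].rename(columns={col: "weight"}).copy()
            t["unique"] = True
            out[c] = t.reset_index(drop=True)
    else:
        raise ValueError(f"unknown order {order!r}")
    return out


def connectivity_spearman(k_ref, k_test) -> float:
    """Spearman rank correlation of node connectivities between the two networks.

    Without ties the textbook closed form ``rho = 1 - 6 * sum(d^2) / (n(n^2-1))``
    is used; with ties, average ranks are correlated with the product-moment
    formula.  Returns NaN (with a warning) for constant input.
    """
    x = np.asarray(k_ref, dtype=float)
    y = np.asarray(k_test, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 genes for a rank correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("constant connectivity vector; Spearman undefined")
        return float("nan")
    rx, ry = rankdata(x, method="average"), rankdata(y, method="average")
    tie_free = len(np.unique(x)) == n and len(np.unique(y)) == n
    if tie_free:
        d = rx - ry
        return float(1.0 - 6.0 * float(d @ d) / (n * (n**2 - 1)))
    return float(np.corrcoef(rx, ry)[0, 1])


def gene_zscores(ref_vals: pd.DataFrame, test_vals: pd.DataFrame) -> pd.Series:
    """Two-sample z-score per gene, oriented test minus reference.

    ``z = (mean_test - mean_ref) / sqrt(s2_test/n_test + s2_ref/n_ref)`` with
    sample variances as plug-in estimates of the population variances.  If
    both variances are zero: z = 0 when the means agree, +/-inf (with a
    warning) when they differ.
    """
    common = [g for g in ref_vals.columns if g in test_vals.columns]
    r = ref_vals[common].to_numpy(dtype=float)
    t = test_vals[common].to_numpy(dtype=float)
    n1, n2 = r.shape[0], t.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 cells per condition")
    mr, mt = r.mean(axis=0), t.mean(axis=0)
    vr, vt = r.var(axis=0, ddof=1), t.var(axis=0, ddof=1)
    se = np.sqrt(vt / n2 + vr / n1)
    diff = mt - mr
    z = np.empty_like(diff)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, diff / np.where(se > 0, se, 1.0),
                     np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
    if np.isinf(z).any():
        warnings.warn("zero-variance genes with unequal means: infinite z-scores")
    return pd.Series(z, index=pd.Index(common, name="gene"), name="z_score")


@dataclass
class SubnetworkComparison:
    """Circle-plot-ready comparison of one module between conditions."""

    module: str
    nodes: pd.DataFrame  # gene, k_ref, k_test, z_score, color_value
    edges: dict[str, pd.DataFrame] = field(default_factory=dict)
    rho: float = float("nan")
    n_cells: dict[str, int] = field(default_factory=dict)


def compare_module(ref_norm: pd.DataFrame, test_norm: pd.DataFrame,
                   partition: ModulePartition, module: str, beta: float,
                   edge_fraction: float = 0.10) -> SubnetworkComparison:
    """Full module comparison: cell selection, sub-networks, edges, rho, z-scores."""
    genes = [g for g in partition.genes(module)
             if g in ref_norm.columns and g in test_norm.columns]
    sel_ref = select_module_cells(ref_norm, partition, module)
    sel_test = select_module_cells(test_norm, partition, module)
    adj_ref = module_subnetwork(ref_norm, sel_ref, genes, beta)
    adj_test = module_subnetwork(test_norm, sel_test, genes, beta)
    k_ref = adj_ref.sum(axis=1)
    k_test = adj_test.sum(axis=1)
    rho = connectivity_spearman(k_ref.to_numpy(), k_test.to_numpy())
    z = gene_zscores(ref_norm.loc[sel_ref.cells, genes], test_norm.loc[sel_test.cells, genes])
    nodes = pd.DataFrame(
        {"gene": genes, "k_ref": k_ref.to_numpy(), "k_test": k_test.to_numpy(),
         "z_score": z.reindex(genes).to_numpy()}
    )
    nodes["color_value"] = np.clip(nodes["z_score"], -2.0, 2.0)
    edges = top_unique_edges(adj_ref, adj_test, fraction=edge_fraction)
    return SubnetworkComparison(
        module=module, nodes=nodes, edges=edges, rho=rho,
        n_cells={"reference": len(sel_ref.cells), "test": len(sel_test.cells)},
    )


def _z_to_rgb(val: float) -> str:
    """Blue (-2) -> white (0) -> red (+2) gradient, hex-encoded."""
    t = float(np.clip(val, -2.0, 2.0)) / 2.0
    if t <= 0:
        r, g, b = 1.0 + t, 1.0 + t, 1.0
    else:
        r, g, b = 1.0, 1.0 - t, 1.0 - t
    return "#{:02x}{:02x}{:02x}".format(int(round(255 * r)), int(round(255 * g)), int(round(255 * b)))


def export_comparison(comparison: SubnetworkComparison, path: str | os.PathLike,
                      plot: bool = False) -> None:
    """Write node/edge TSVs (and optionally a circle plot) for one module."""
    path = os.fspath(path)
    os.makedirs(path, exist_ok=True)
    nodes = comparison.nodes.copy()
    nodes["color"] = [_z_to_rgb(v) for v in nodes["color_value"]]
    nodes.to_csv(os.path.join(path, f"{comparison.module}_nodes.tsv"), sep="\t",
                 index=False, float_format="%.10g")
    for cond, tab in comparison.edges.items():
        tab.to_csv(os.path.join(path, f"{comparison.module}_edges_{cond}.tsv"), sep="\t",
                   index=False, float_format="%.10g")
    with open(os.path.join(path, f"{comparison.module}_summary.tsv"), "w") as fh:
        fh.write("module\trho\tn_cells_reference\tn_cells_test\n")
        fh.write(f"{comparison.module}\t{comparison.rho:.10g}"
                 f"\t{comparison.n_cells.get('reference', 0)}\t{comparison.n_cells.get('test', 0)}\n")
    if plot:
        _circle_plot(comparison, os.path.join(path, f"{comparison.module}_circle.png"))


def read_comparison_nodes(path: str | os.PathLike, module: str) -> pd.DataFrame:
    return pd.read_csv(os.path.join(os.fspath(path), f"{module}_nodes.tsv"), sep="\t")


def _circle_plot(comparison: SubnetworkComparison, outfile: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genes = list(comparison.nodes["gene"])
    n = len(genes)
    angle = {g: 2 * np.pi * i / n for i, g in enumerate(genes)}
    fig, ax = plt.subplots(figsize=(7, 7))
    colors = {"reference": "#c8a800", "test": "#8b4513"}
    for cond, tab in comparison.edges.items():
        for _, e in tab[tab["unique"]].iterrows():
            x = [np.cos(angle[e["gene_i"]]), np.cos(angle[e["gene_j"]])]
            y = [np.sin(angle[e["gene_i"]]), np.sin(angle[e["gene_j"]])]
            ax.plot(x, y, color=colors.get(cond, "grey"),
                    lw=0.5 + 3 * float(e["weight"]), alpha=0.6)
    for _, row in comparison.nodes.iterrows():
        g = row["gene"]
        ax.scatter(1.08 * np.cos(angle[g]), 1.08 * np.sin(angle[g]),
                   color=_z_to_rgb(row["color_value"]), edgecolor="black", s=60, zorder=3)
        ax.text(1.18 * np.cos(angle[g]), 1.18 * np.sin(angle[g]), str(g), fontsize=5,
                ha="center", va="center")
    ax.set_title(f"{comparison.module}  (rho = {comparison.rho:.2f})")
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(outfile, dpi=150)
    plt.close(fig)


def ora(query, gene_sets: dict[str, list[str]], universe) -> pd.DataFrame:
    """Hypergeometric over-representation analysis with Benjamini-Hochberg correction.

    One-sided p-value per gene set for the overlap with ``query``, all sets
    restricted to ``universe``; rows sorted by ascending p.
    """
    query = set(query)
    universe = set(universe)
    if not query:
        raise ValueError("empty query gene list")
    if not query <= universe:
        raise ValueError("query genes must be contained in the universe")
    M, n = len(universe), len(query)
    rows = []
    for name, genes in gene_sets.items():
        members = set(genes) & universe
        K = len(members)
        k = len(members & query)
        p = float(hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append((name, k, K, p, ",".join(sorted(members & query))))
    df = pd.DataFrame(rows, columns=["gene_set", "overlap", "set_size", "p_value", "genes"])
    if len(df):
        df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    else:
        df["q_value"] = []
    return df.sort_values(["p_value", "gene_set"], kind="stable").reset_index(drop=True)
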