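"""Cell/gene QC, normalization, variable genes, scaling, PCA and clustering.

The QC rules follow conventional single-cell practice: cells are excluded for
more than 15% mitochondrial reads, fewer than 300 UMIs, fewer than 500
expressed genes or a library complexity (log10 genes / log10 UMIs) below 0.70;
genes expressed in fewer than 10 cells are dropped.  Threshold wording is
exclusive ("more than" / "fewer than"), so a cell sitting exactly on a
threshold is kept.  Normalization is ln(1 + 1e4 * x / total) per cell.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "QCThresholds",
    "PCAResult",
    "compute_cell_qc",
    "filter_cells",
    "filter_genes",
    "log_normalize",
    "select_variable_genes",
    "scale_genes",
    "run_pca",
    "select_optimal_dims",
    "build_snn_graph",
    "cluster_cells",
    "assign_cell_types",
]


def _counts_matrix(data) -> tuple[sp.csr_matrix, pd.Index | None, np.ndarray | None]:
    """Coerce AnnData / DataFrame / array into (csr counts, gene index, mt flags)."""
    mt = None
    genes = None
    if hasattr(data, "X"):  # AnnData
        X = data.X
        genes = data.var_names
        if "mt" in data.var:
            mt = np.asarray(data.var["mt"]).astype(bool)
    elif isinstance(data, pd.DataFrame):
        X = data.to_numpy()
        genes = data.columns
    else:
        X = data
    X = X.tocsr() if sp.issparse(X) else sp.csr_matrix(np.asarray(X))
    if mt is None and genes is not None:
        mt = np.array([str(g).startswith("MT-") for g in genes])
    return X, genes, mt


@dataclass
class QCThresholds:
    """Cell- and gene-level QC cutoffs (kept values are inclusive of the threshold)."""

    max_pct_mito: float = 0.15
    min_umi: int = 300
    min_genes: int = 500
    min_complexity: float = 0.70
    min_cells_per_gene: int = 10


def compute_cell_qc(data) -> pd.DataFrame:
    """Per-cell QC metrics: n_umi, n_genes, pct_mito and complexity.

    Complexity is log10(n_genes)/log10(n_umi); it is undefined (NaN) for
    cells with fewer than 2 UMIs or no expressed gene, and such cells always
    fail the filter.
    """
    X, genes, mt = _counts_matrix(data)
    n_umi = np.asarray(X.sum(axis=1)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    if mt is None or not mt.any():
        mito = np.zeros(X.shape[0])
    else:
        mito = np.asarray(X[:, mt].sum(axis=1)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_mito = np.where(n_umi > 0, mito / np.maximum(n_umi, 1), 0.0)
        complexity = np.where(
            (n_umi >= 2) & (n_genes >= 1), np.log10(n_genes) / np.log10(np.maximum(n_umi, 2)), np.nan
        )
    index = data.obs_names if hasattr(data, "obs_names") else pd.RangeIndex(X.shape[0])
    return pd.DataFrame(
        {"n_umi": n_umi.astype(int), "n_genes": n_genes.astype(int),
         "pct_mito": pct_mito, "complexity": complexity},
        index=index,
    )


def filter_cells(metrics: pd.DataFrame, thresholds: QCThresholds = QCThresholds()) -> np.ndarray:
    """Boolean keep-mask over cells. A cell is kept iff it violates no exclusion rule."""
    keep = (
        (metrics["pct_mito"].to_numpy() <= thresholds.max_pct_mito)
        & (metrics["n_umi"].to_numpy() >= thresholds.min_umi)
        & (metrics["n_genes"].to_numpy() >= thresholds.min_genes)
        & (metrics["complexity"].to_numpy() >= thresholds.min_complexity)  # NaN fails
    )
    return keep


def filter_genes(data, min_cells: int = 10) -> np.ndarray:
    """Boolean keep-mask over genes: expressed (nonzero) in at least ``min_cells`` cells."""
    X, _, _ = _counts_matrix(data)
    n_cells = np.asarray((X > 0).sum(axis=0)).ravel()
    return n_cells >= min_cells


def log_normalize(data, scale_factor: float = 1e4):
    """ln(1 + scale_factor * count / cell_total), the standard library-size normalization.

    Returns the same container kind as the input (AnnData gets a new
    ``layers['lognorm']`` entry and is returned; arrays/DataFrames return a
    dense array/DataFrame).  Cells with zero total counts are an error: they
    must be removed by QC first.
    """
    X, genes, _ = _counts_matrix(data)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise ValueError(f"{int((totals == 0).sum())} cells have zero total counts; filter first")
    Y = X.multiply(scale_factor / totals[:, None]).log1p().tocsr()
    if hasattr(data, "X"):
        data.layers["lognorm"] = Y
        return data
    dense = np.asarray(Y.todense())
    if isinstance(data, pd.DataFrame):
        return pd.DataFrame(dense, index=data.index, columns=data.columns)
    return dense


def _vst_scores(X: sp.csr_matrix, span: float = 0.3) -> np.ndarray:
    """Seurat-v3-style standardized variance of raw counts.

    Fits a lowess trend of log10(variance) on log10(mean), standardizes
    counts with the trend sd (clipped at sqrt(n_cells)) and scores genes by
    the variance of the standardized values.
    """
    n = X.shape[0]
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = (sq - mean**2) * n / max(n - 1, 1)
    score = np.zeros(X.shape[1])
    ok = (mean > 0) & (var > 0)
    if ok.sum() < 3:
        return var
    lx, ly = np.log10(mean[ok]), np.log10(var[ok])
    fit = lowess(ly, lx, frac=span, return_sorted=False)
    exp_sd = np.sqrt(10.0**fit)
    clip = np.sqrt(n)
    dense = np.asarray(X[:, ok].todense(), dtype=float)
    z = np.clip((dense - mean[ok]) / exp_sd, -clip, clip)
    score[ok] = z.var(axis=0, ddof=1)
    return score


def select_variable_genes(counts, fraction: float = 0.20, flavor: str = "vst"):
    """Top ``ceil(fraction * n_genes)`` variable genes, most variable first.

    ``flavor='vst'`` ranks genes by standardized variance after a
    mean-variance trend fit on raw counts; ``flavor='lognorm_var'`` ranks by
    plain variance of the log-normalized values.  Ties break by gene order.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    X, genes, _ = _counts_matrix(counts)
    if X.shape[1] < 10:
        raise ValueError("need at least 10 genes")
    if flavor == "vst":
        score = _vst_scores(X)
    elif flavor == "lognorm_var":
        Y = log_normalize(X)
        score = np.asarray(Y).var(axis=0, ddof=1) if not sp.issparse(Y) else None
        if score is None:
            m = np.asarray(Y.mean(axis=0)).ravel()
            sqm = np.asarray(Y.multiply(Y).mean(axis=0)).ravel()
            score = (sqm - m**2) * X.shape[0] / max(X.shape[0] - 1, 1)
    else:
        raise ValueError(f"unknown flavor {flavor!r}")
    n_top = int(np.ceil(fraction * X.shape[1]))
    order = np.lexsort((np.arange(len(score)), -score))[:n_top]
    if genes is not None:
        return list(np.asarray(genes)[order])
    return list(order)


def scale_genes(normalized, genes=None, max_value: float = 10.0) -> pd.DataFrame:
    """Z-score each gene across cells and clip at ±``max_value``; constant genes map to 0."""
    if hasattr(normalized, "X"):
        M = normalized.layers["lognorm"] if "lognorm" in normalized.layers else normalized.X
        df = pd.DataFrame(
            np.asarray(M.todense()) if sp.issparse(M) else np.asarray(M),
            index=normalized.obs_names, columns=normalized.var_names,
        )
    elif isinstance(normalized, pd.DataFrame):
        df = normalized
    else:
        df = pd.DataFrame(np.asarray(normalized))
    if genes is not None:
        df = df.loc[:, list(genes)]
    arr = df.to_numpy(dtype=float)
    mu = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (arr - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(np.clip(z, -max_value, max_value), index=df.index, columns=df.columns)


@dataclass
class PCAResult:
    """PCA scores plus percent variance (pv) and cumulative percent (cp) per component."""

    scores: np.ndarray
    pv: np.ndarray
    components: np.ndarray

    @property
    def cp(self) -> np.ndarray:
        return np.cumsum(self.pv)


def run_pca(scaled, npcs: int = 40, seed: int = 0) -> PCAResult:
    """PCA of the scaled matrix; pv_i = 100 * var_i / total variance.

    Exact SVD up to 3000 cells/genes, randomized (seeded) beyond that.
    Rank-deficient input yields fewer components with a warning.
    """
    arr = scaled.to_numpy(dtype=float) if isinstance(scaled, pd.DataFrame) else np.asarray(scaled, float)
    max_rank = min(arr.shape[0] - 1, arr.shape[1])
    k = min(npcs, max_rank)
    if k < npcs:
        warnings.warn(f"requested {npcs} components but rank allows only {k}")
    solver = "full" if min(arr.shape) <= 3000 else "randomized"
    p = PCA(n_components=k, svd_solver=solver, random_state=seed)
    scores = p.fit_transform(arr)
    return PCAResult(scores=scores, pv=100.0 * p.explained_variance_ratio_, components=p.components_)


def select_optimal_dims(pv, mode: str = "absolute") -> int:
    """Pick the clustering dimensionality from the percent-variance profile.

    Two candidate counts are formed: the first component index (1-based) at
    which the cumulative percent exceeds 90 while that component explains
    less than 5 percent; and the first index at which the drop to the next
    component's percent variance falls below 0.1 (absolute by default,
    relative change with ``mode='relative'``).  The smaller of the two is
    returned; if neither criterion is ever met the full length is returned
    with a warning.
    """
    pv = np.asarray(pv, dtype=float)
    if pv.size == 0:
        raise ValueError("empty percent-variance vector")
    cp = np.cumsum(pv)
    step2 = None
    for i in range(len(pv)):
        if cp[i] > 90.0 and pv[i] < 5.0:
            step2 = i + 1
            break
    step3 = None
    for i in range(len(pv) - 1):
        change = pv[i] - pv[i + 1]
        if mode == "relative" and pv[i] > 0:
            change = change / pv[i]
        if change < 0.1:
            step3 = i + 1
            break
    candidates = [s for s in (step2, step3) if s is not None]
    if not candidates:
        warnings.warn("no dimension-selection criterion met; using all components")
        return len(pv)
    return min(candidates)


def build_snn_graph(coords: np.ndarray, k: int = 20, prune: float = 1.0 / 15.0):
    """Shared-nearest-neighbor graph: Jaccard overlap of k-NN sets, pruned below ``prune``."""
    n = coords.shape[0]
    k_eff = min(k, n)
    if k_eff < k:
        warnings.warn(f"only {n} cells; using k={k_eff} neighbors")
    nn = NearestNeighbors(n_neighbors=k_eff).fit(coords)
    _, idx = nn.kneighbors(coords)  # row i includes i itself
    rows = np.repeat(np.arange(n), k_eff)
    A = sp.csr_matrix((np.ones(n * k_eff), (rows, idx.ravel())), shape=(n, n))
    shared = (A @ A.T).tocoo()  # |N(i) ∩ N(j)|
    jac = shared.data / (2 * k_eff - shared.data)
    keep = jac >= prune
    W = sp.csr_matrix((jac[keep], (shared.row[keep], shared.col[keep])), shape=(n, n))
    W.setdiag(0)
    W.eliminate_zeros()
    return W


def cluster_cells(scores: np.ndarray, dims: int | None = None, resolution: float = 2.0,
                  k: int = 20, prune: float = 1.0 / 15.0, seed: int = 0) -> np.ndarray:
    """Louvain community detection on the SNN graph of the first ``dims`` components."""
    coords = np.asarray(scores, dtype=float)
    if dims is not None:
        coords = coords[:, :dims]
    W = build_snn_graph(coords, k=k, prune=prune)
    W_ut = sp.triu(W.maximum(W.T), k=1).tocoo()
    g = igraph.Graph(
        n=W.shape[0],
        edges=list(zip(W_ut.row.tolist(), W_ut.col.tolist())),
        edge_attrs={"weight": W_ut.data.tolist()},
    )
    igraph.set_random_number_generator(random.Random(int(seed)))
    part = g.community_multilevel(weights="weight", resolution=resolution)
    return np.asarray(part.membership)


def assign_cell_types(clusters: np.ndarray, normalized, markers) -> pd.Series:
    """Assign each cluster the cell type whose markers are most highly expressed.

    ``markers`` is a (gene, cell_type) DataFrame or a dict type -> genes.
    Marker expression is z-scored per gene; a cluster's type is the argmax of
    the mean scaled marker expression, ties broken by type-name order (with a
    warning).  Types with no marker present in the matrix are never assigned.
    """
    if isinstance(markers, pd.DataFrame):
        marker_map = {t: list(sub["gene"]) for t, sub in markers.groupby("cell_type", observed=True)}
    else:
        marker_map = {t: list(g) for t, g in markers.items()}
    if hasattr(normalized, "X"):
        M = normalized.layers["lognorm"] if "lognorm" in normalized.layers else normalized.X
        df = pd.DataFrame(np.asarray(M.todense()) if sp.issparse(M) else np.asarray(M),
                          index=normalized.obs_names, columns=normalized.var_names)
    else:
        df = normalized if isinstance(normalized, pd.DataFrame) else pd.DataFrame(np.asarray(normalized))
    present = {t: [g for g in gs if g in df.columns] for t, gs in marker_map.items()}
    missing = sorted(t for t, gs in present.items() if not gs)
    if missing:
        warnings.warn(f"no markers found for types: {missing}; these types will not be assigned")
    present = {t: gs for t, gs in present.items() if gs}
    if not present:
        raise ValueError("none of the marker genes are present in the matrix")
    all_marker_genes = sorted({g for gs in present.values() for g in gs})
    z = scale_genes(df, genes=all_marker_genes)
    clusters = np.asarray(clusters)
    types = sorted(present)
    assignment: dict[int, str] = {}
    for c in np.unique(clusters):
        mean_by_type = {t: float(z.loc[clusters == c, present[t]].to_numpy().mean()) for t in types}
        best = max(mean_by_type.values())
        winners = [t for t in types if mean_by_type[t] == best]
        if len(winners) > 1:
            warnings.warn(f"cluster {c}: tie between {winners}; using {winners[0]}")
        assignment[int(c)] = winners[0]
    return pd.Series([assignment[int(c)] for c in clusters], index=df.index, name="cell_type")
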