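"""Weighted gene co-expression networks: soft threshold, adjacency, TOM, modules.

The network is built WGCNA-style: pairwise Pearson correlation over cells,
mapped to [0, 1] by soft thresholding (``|r|^beta`` unsigned,
``((1+r)/2)^beta`` signed), smoothed into a topological overlap matrix, and
clustered by average-linkage hierarchical clustering on ``1 - TOM``.  Every
sufficiently large dendrogram branch is a module candidate and is accepted
only if it looks like a genuine cluster (low core scatter, a clear gap to
the rest of the tree), a simplified form of the dynamic hybrid tree cut;
module eigengenes that correlate above ``1 - merge_height`` are merged.
Unassigned genes are labelled "grey"; module labels are assigned in ascending
size order (label 1 = smallest module).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "NetworkParams",
    "ModulePartition",
    "Eigengene",
    "SoftThresholdResult",
    "variable_gene_set",
    "pick_soft_threshold",
    "scale_free_fit",
    "adjacency",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
    "connectivity",
]

# deepSplit ladder of the hybrid tree cut: maximum allowed core scatter and
# the implied minimum cluster gap, both relative to the dendrogram height range
_MAX_CORE_SCATTER = (0.64, 0.73, 0.82, 0.91, 0.95)


@dataclass
class NetworkParams:
    """Tunable network-construction parameters (defaults follow common WGCNA practice)."""

    power: float = 6.0
    sign_mode: str = "unsigned"
    min_module_size: int = 20
    merge_height: float = 0.15
    deep_split: int = 2
    cut_height_frac: float = 0.99
    label_prefix: str = "E"

    def __post_init__(self):
        if self.sign_mode not in ("unsigned", "signed"):
            raise ValueError(f"unknown sign_mode {self.sign_mode!r}")
        if not 0 <= self.deep_split <= 4:
            raise ValueError("deep_split must be in 0..4")
        if not 0.0 < self.merge_height < 1.0:
            raise ValueError("merge_height must lie in (0, 1)")


@dataclass
class ModulePartition:
    """Gene -> module label map; "grey" marks unassigned genes.

    Non-grey labels are ``<prefix>1 ... <prefix>n`` in ascending size order.
    """

    labels: pd.Series

    @property
    def module_names(self) -> list[str]:
        sizes = self.sizes
        return list(sizes.index)

    @property
    def sizes(self) -> pd.Series:
        lab = self.labels[self.labels != "grey"]
        sizes = lab.value_counts()
        return sizes.sort_values(kind="stable")

    def genes(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    @property
    def n_modules(self) -> int:
        return int((self.labels[self.labels != "grey"]).nunique())


@dataclass
class Eigengene:
    """First principal component of a module's standardized expression."""

    scores: np.ndarray  # unit-norm, cell-indexed
    variance_explained: float
    index: pd.Index | None = None


def variable_gene_set(ref_counts, test_counts, mode: str = "intersection",
                      fraction: float = 0.20, flavor: str = "vst") -> list[str]:
    """Variable-gene universe for the two-network comparison.

    ``intersection`` takes genes in both conditions' top-``fraction`` lists
    (ordered by the reference ranking); ``reference_only`` takes the
    reference's top list.
    """
    from modpres.preprocess import select_variable_genes

    if mode not in ("intersection", "reference_only"):
        raise ValueError(f"unknown mode {mode!r}")
    ref_top = select_variable_genes(ref_counts, fraction=fraction, flavor=flavor)
    if mode == "reference_only":
        return ref_top
    test_top = set(select_variable_genes(test_counts, fraction=fraction, flavor=flavor))
    out = [g for g in ref_top if g in test_top]
    if not out:
        raise ValueError("empty intersection of variable-gene lists")
    return out


def _corr(expr) -> tuple[np.ndarray, pd.Index | None]:
    if isinstance(expr, pd.DataFrame):
        genes = expr.columns
        arr = expr.to_numpy(dtype=float)
    else:
        genes = None
        arr = np.asarray(expr, dtype=float)
    sd = arr.std(axis=0)
    const = sd == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        C = np.corrcoef(arr, rowvar=False)
    if const.any():
        warnings.warn(f"{int(const.sum())} constant genes; their correlations set to 0")
        C[const, :] = 0.0
        C[:, const] = 0.0
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0), genes


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free-topology fit of a connectivity vector.

    Bins ``k``, regresses log10 frequency on log10 mean connectivity per bin
    and returns ``(signed_r2, slope)`` where ``signed_r2 = -sign(slope) * R^2``
    (positive when the degree distribution decays, as a scale-free law does).
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < n_bins or np.allclose(k, k[0]):
        raise ValueError("degenerate connectivity: cannot assess scale-free fit")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins).astype(float)
    kmean = np.array([k[which == b].mean() if counts[b] else np.nan for b in range(n_bins)])
    ok = (counts > 0) & (kmean > 0)
    if ok.sum() < 3:
        raise ValueError("too few occupied bins for a scale-free fit")
    x = np.log10(kmean[ok])
    y = np.log10(counts[ok] / counts.sum())
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return -np.sign(slope) * r2, float(slope)


@dataclass
class SoftThresholdResult:
    power: float
    table: pd.DataFrame
    reached_target: bool


def pick_soft_threshold(expr, candidate_powers=tuple(range(1, 21)), target_r2: float = 0.8,
                        sign_mode: str = "unsigned", n_bins: int = 10) -> SoftThresholdResult:
    """Choose the soft-threshold power: the smallest candidate whose network
    shows a scale-free fit of at least ``target_r2``; otherwise the best-fitting
    power, with a warning."""
    C, _ = _corr(expr)
    if C.shape[0] < 50:
        warnings.warn("fewer than 50 genes; soft-threshold fit will be unstable")
    base = np.abs(C) if sign_mode == "unsigned" else (1.0 + C) / 2.0
    np.fill_diagonal(base, 0.0)
    rows = []
    for beta in candidate_powers:
        k = (base**beta).sum(axis=0)
        try:
            r2, slope = scale_free_fit(k, n_bins=n_bins)
        except ValueError:
            r2, slope = np.nan, np.nan
        rows.append((beta, r2, slope, k.mean(), np.median(k), k.max()))
    table = pd.DataFrame(rows, columns=["power", "sft_r2", "slope", "mean_k", "median_k", "max_k"])
    hit = table[table["sft_r2"] >= target_r2]
    if len(hit):
        return SoftThresholdResult(float(hit["power"].iloc[0]), table, True)
    warnings.warn(f"no candidate power reached R^2 >= {target_r2}; using the best fit")
    best = table["sft_r2"].idxmax()
    if np.isnan(table["sft_r2"]).all():
        raise ValueError("scale-free fit failed for every candidate power")
    return SoftThresholdResult(float(table.loc[best, "power"]), table, False)


def adjacency(expr, params: NetworkParams = NetworkParams()) -> pd.DataFrame:
    """Soft-thresholded co-expression adjacency (diagonal set to 1)."""
    C, genes = _corr(expr)
    if params.sign_mode == "unsigned":
        A = np.abs(C) ** params.power
    else:
        A = ((1.0 + C) / 2.0) ** params.power
    np.fill_diagonal(A, 1.0)
    if genes is None:
        genes = pd.RangeIndex(A.shape[0])
    return pd.DataFrame(A, index=genes, columns=genes)


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``k_i = sum_{u != i} a_iu`` and unit diagonal.
    """
    A = adj.to_numpy(dtype=float).copy() if isinstance(adj, pd.DataFrame) else np.array(adj, float)
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=0)
    num = A @ A + A
    den = np.minimum.outer(k, k) + 1.0 - A
    T = num / den
    T = np.clip((T + T.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(T, 1.0)
    idx = adj.index if isinstance(adj, pd.DataFrame) else pd.RangeIndex(T.shape[0])
    return pd.DataFrame(T, index=idx, columns=idx)


def _branch_table(Z: np.ndarray, D: np.ndarray):
    """Per-dendrogram-node members, mean within- and out-of-branch dissimilarity.

    Under average linkage the merge height equals the mean cross-cluster
    dissimilarity, so the within-branch sums build up in O(n) from the
    linkage itself; out-of-branch means come from precomputed row sums.
    """
    n = D.shape[0]
    rowsum = D.sum(axis=1)
    members: list[np.ndarray] = [np.array([i]) for i in range(n)]
    sum_in = np.zeros(2 * n - 1)  # sum of pairwise dissimilarities inside the branch
    sum_rows = np.concatenate([rowsum, np.zeros(n - 1)])
    nodes = []
    for step in range(n - 1):
        a, b, height, _ = Z[step]
        a, b = int(a), int(b)
        mem = np.concatenate([members[a], members[b]])
        members.append(mem)
        node = n + step
        cross = height * len(members[a]) * len(members[b])
        sum_in[node] = sum_in[a] + sum_in[b] + cross
        sum_rows[node] = sum_rows[a] + sum_rows[b]
        m = len(mem)
        d_in = sum_in[node] / (m * (m - 1) / 2.0)
        n_out = n - m
        d_out = (sum_rows[node] - 2.0 * sum_in[node]) / (m * n_out) if n_out else np.nan
        nodes.append({"node": node, "a": a, "b": b, "height": float(height),
                      "members": mem, "size": m, "d_in": float(d_in), "d_out": float(d_out)})
    return nodes


def detect_modules(tom: pd.DataFrame, params: NetworkParams = NetworkParams(),
                   expr: pd.DataFrame | None = None) -> ModulePartition:
    """Detect modules from a TOM by hierarchical clustering with a hybrid cut.

    Every dendrogram branch of at least ``min_module_size`` genes is a module
    candidate; a branch is accepted when its core scatter (mean within-branch
    dissimilarity, relative to the dendrogram height range) stays below the
    deep-split ceiling and the gap between its outside and inside mean
    dissimilarity exceeds the matching floor.  Maximal accepted branches win
    over nested ones.  When ``expr`` (cells x genes, log-normalized) is
    provided, modules whose eigengenes correlate above ``1 - merge_height``
    are merged; without it the merging step is skipped.
    """
    genes = tom.index if isinstance(tom, pd.DataFrame) else pd.RangeIndex(np.asarray(tom).shape[0])
    T = tom.to_numpy(dtype=float) if isinstance(tom, pd.DataFrame) else np.asarray(tom, float)
    n = T.shape[0]
    if n < params.min_module_size:
        raise ValueError(f"only {n} genes; below min_module_size={params.min_module_size}")
    D = 1.0 - T
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    h = Z[:, 2]
    h5, hmax = float(np.quantile(h, 0.05)), float(h.max())
    cut = h5 + params.cut_height_frac * (hmax - h5)
    span = max(cut - h5, 1e-12)
    max_scatter = _MAX_CORE_SCATTER[params.deep_split]
    min_gap = 0.75 * (1.0 - max_scatter)
    nodes = _branch_table(Z, D)
    passing = {}
    for nd in nodes:
        if nd["size"] < params.min_module_size or nd["size"] == n:
            continue
        scatter = (nd["d_in"] - h5) / span
        gap = (nd["d_out"] - nd["d_in"]) / span
        if scatter <= max_scatter and gap >= min_gap:
            passing[nd["node"]] = nd
    # keep maximal passing branches: drop any whose ancestor also passes
    parent = np.full(2 * n - 1, -1)
    for nd in nodes:
        parent[nd["a"]] = nd["node"]
        parent[nd["b"]] = nd["node"]
    modules: list[np.ndarray] = []
    for node, nd in passing.items():
        p = parent[node]
        shadowed = False
        while p != -1:
            if p in passing:
                shadowed = True
                break
            p = parent[p]
        if not shadowed:
            modules.append(np.sort(nd["members"]))
    if expr is not None and len(modules) > 1:
        modules = _merge_close_modules(expr, genes, modules, params.merge_height)
    labels = pd.Series("grey", index=genes, dtype=object)
    modules.sort(key=len)
    for i, members in enumerate(modules):
        labels.iloc[members] = f"{params.label_prefix}{i + 1}"
    return ModulePartition(labels=labels)


def _merge_close_modules(expr, genes, modules, merge_height):
    """Iteratively merge the closest module pair while eigengene cor > 1 - merge_height."""
    modules = [np.asarray(m) for m in modules]
    while len(modules) > 1:
        eigs = [module_eigengene(expr[list(np.asarray(genes)[m])]).scores for m in modules]
        E = np.corrcoef(np.vstack(eigs))
        np.fill_diagonal(E, -np.inf)
        i, j = np.unravel_index(int(np.argmax(E)), E.shape)
        if E[i, j] <= 1.0 - merge_height:
            break
        merged = np.sort(np.concatenate([modules[i], modules[j]]))
        modules = [m for idx, m in enumerate(modules) if idx not in (i, j)] + [merged]
    return modules


def module_eigengene(expr, genes=None) -> Eigengene:
    """First principal component of the standardized module submatrix.

    The returned score vector has unit norm and is oriented so its
    correlation with the module's mean expression is nonnegative.
    """
    df = expr if isinstance(expr, pd.DataFrame) else pd.DataFrame(np.asarray(expr, float))
    if genes is not None:
        df = df.loc[:, list(genes)]
    arr = df.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ValueError("a module eigengene needs at least 2 genes")
    sd = arr.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("constant module submatrix")
    Zm = (arr - arr.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    R = np.corrcoef(Zm, rowvar=False)
    R = np.nan_to_num(R, nan=0.0)
    np.fill_diagonal(R, 1.0)
    w, v = np.linalg.eigh(R)
    lead = v[:, -1]
    scores = Zm @ lead
    nrm = np.linalg.norm(scores)
    if nrm > 0:
        scores = scores / nrm
    mean_expr = Zm.mean(axis=1)
    if float(scores @ (mean_expr - mean_expr.mean())) < 0:
        scores = -scores
    return Eigengene(scores=scores, variance_explained=float(w[-1] / arr.shape[1]),
                     index=df.index)


def connectivity(adj: pd.DataFrame, partition: ModulePartition | None = None) -> pd.Series:
    """Weighted degree ``k_i = sum_{j != i} a_ij``, whole-network or intramodular.

    With a partition, each gene's sum runs over the other genes of its own
    module; grey genes get NaN.
    """
    A = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    idx = adj.index
    if partition is None:
        return pd.Series(A.sum(axis=1), index=idx, name="k")
    lab = partition.labels.reindex(idx)
    k = np.full(len(idx), np.nan)
    for m in lab.dropna().unique():
        if m == "grey":
            continue
        mask = (lab == m).to_numpy()
        k[mask] = A[np.ix_(mask, mask)].sum(axis=1)
    return pd.Series(k, index=idx, name="kIM")
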