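"""Stratified down-sampling that equalizes group totals while preserving type ratios.

Every non-base group is reduced to the base group's total cell count.  Within
a group, per-type quotas follow largest-remainder (Hamilton) apportionment of
the group's own type proportions, so totals are hit exactly and no stratum
deviates from exact proportionality by more than one cell.  Within each
stratum cells are chosen either uniformly at random or by greedy max-min
farthest-point sampling on PCA coordinates, a space-filling strategy that
keeps rare sub-populations represented.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["largest_remainder", "compute_quotas", "farthest_point_sample", "stratified_downsample"]


def largest_remainder(counts, total: int) -> np.ndarray:
    """Apportion ``total`` into integer quotas proportional to ``counts``.

    Floors the exact shares and hands the remaining units to the largest
    fractional remainders (ties to the lower index).  Quotas never exceed
    the original counts when ``total <= sum(counts)``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.sum() == 0:
        if total > 0:
            raise ValueError("cannot apportion a positive total over zero counts")
        return np.zeros(len(counts), dtype=int)
    shares = total * counts / counts.sum()
    quotas = np.floor(shares).astype(int)
    rem = int(total - quotas.sum())
    if rem > 0:
        order = np.lexsort((np.arange(len(counts)), -(shares - np.floor(shares))))
        quotas[order[:rem]] += 1
    return quotas


def compute_quotas(counts: pd.DataFrame, base_group: str) -> pd.DataFrame:
    """Per (group, cell_type) down-sampling quotas.

    ``counts`` is a group x cell-type table of cell counts.  Each non-base
    group's quotas apportion the base group's total over that group's own
    type counts; the base group keeps its original counts.
    """
    counts = counts.fillna(0).astype(int)
    if base_group not in counts.index:
        raise ValueError(f"base group {base_group!r} not present")
    totals = counts.sum(axis=1)
    n_base = int(totals[base_group])
    if n_base > totals.min():
        warnings.warn(
            f"base group {base_group!r} ({n_base} cells) is not the smallest group; "
            "larger groups will still be down-sampled to it"
        )
    rows = []
    for g in counts.index:
        orig = counts.loc[g].to_numpy()
        if g == base_group:
            quota = orig.copy()
        else:
            target = min(n_base, int(orig.sum()))
            if target < n_base:
                warnings.warn(f"group {g!r} has fewer cells than the base; keeping all")
            quota = largest_remainder(orig, target)
        for t, o, q in zip(counts.columns, orig, quota):
            rows.append((g, t, int(o), int(q)))
    return pd.DataFrame(rows, columns=["group", "cell_type", "original", "quota"])


def farthest_point_sample(coords: np.ndarray, k: int, seed: int | None = None) -> np.ndarray:
    """Greedy max-min (farthest-point) selection of ``k`` row indices.

    Starts from the point farthest from the centroid and repeatedly adds the
    point with the largest minimum Euclidean distance to the selected set.
    Fully deterministic: ties break to the lowest index (``seed`` is accepted
    for interface symmetry with the uniform sampler but unused).
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k > n:
        raise ValueError(f"cannot sample {k} points from {n}")
    if k == 0:
        return np.empty(0, dtype=int)
    centroid = coords.mean(axis=0)
    d0 = np.linalg.norm(coords - centroid, axis=1)
    selected = np.empty(k, dtype=int)
    selected[0] = int(np.argmax(d0))
    min_d = np.linalg.norm(coords - coords[selected[0]], axis=1)
    min_d[selected[0]] = -np.inf
    for i in range(1, k):
        nxt = int(np.argmax(min_d))
        selected[i] = nxt
        d = np.linalg.norm(coords - coords[nxt], axis=1)
        min_d = np.minimum(min_d, d)
        min_d[nxt] = -np.inf
    return selected


def stratified_downsample(adata, quotas: pd.DataFrame, strategy: str = "space_filling",
                          seed: int = 0, base_group: str | None = None,
                          group_key: str = "group", type_key: str = "cell_type",
                          use_rep: str = "X_pca"):
    """Subset ``adata`` so every non-base group meets its quota table.

    ``space_filling`` picks cells by farthest-point sampling on
    ``adata.obsm[use_rep]``; ``uniform`` picks uniformly at random (seeded).
    The base group is untouched.  Returns a copy in the original cell order.
    """
    if strategy not in ("space_filling", "uniform"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if strategy == "space_filling" and use_rep not in adata.obsm:
        raise ValueError(f"space_filling needs coordinates in adata.obsm[{use_rep!r}]")
    if base_group is None:
        totals = quotas.groupby("group")["quota"].sum()
        orig = quotas.groupby("group")["original"].sum()
        base_candidates = orig[orig == totals].index
        base_group = base_candidates[0] if len(base_candidates) else None
    rng = np.random.default_rng(seed)
    groups = np.asarray(adata.obs[group_key].astype(str))
    types = np.asarray(adata.obs[type_key].astype(str))
    keep = np.zeros(adata.n_obs, dtype=bool)
    keep[groups == str(base_group)] = True
    for _, row in quotas.iterrows():
        g, t, q = str(row["group"]), str(row["cell_type"]), int(row["quota"])
        if g == str(base_group):
            continue
        stratum = np.flatnonzero((groups == g) & (types == t))
        if q >= len(stratum):
            keep[stratum] = True
            continue
        if strategy == "space_filling":
            coords = np.asarray(adata.obsm[use_rep])[stratum]
            chosen = stratum[farthest_point_sample(coords, q)]
        else:
            chosen = rng.choice(stratum, size=q, replace=False)
        keep[chosen] = True
    return adata[keep].copy()
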