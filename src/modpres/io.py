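"""Reading and writing the package's on-disk formats.

Datasets travel as a MatrixMarket triple: ``matrix.mtx`` (cells x genes,
integer counts), ``genes.tsv`` (gene, mt flag) and ``cells.tsv``
(barcode, group, cell_type).  Gene sets use the GMT format.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

__all__ = ["write_dataset", "read_dataset", "read_gmt", "write_gmt"]


def write_dataset(adata: AnnData, path: str | os.PathLike) -> None:
    """Write ``adata`` to directory ``path`` as matrix.mtx + genes.tsv + cells.tsv."""
    path = os.fspath(path)
    os.makedirs(path, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), X.astype(np.int64))
    genes = pd.DataFrame({"gene": adata.var_names, "mt": adata.var.get("mt", False)})
    genes.to_csv(os.path.join(path, "genes.tsv"), sep="\t", index=False)
    cells = pd.DataFrame({"barcode": adata.obs_names})
    for col in ("group", "cell_type"):
        if col in adata.obs:
            cells[col] = np.asarray(adata.obs[col].astype(str))
    cells.to_csv(os.path.join(path, "cells.tsv"), sep="\t", index=False)


def read_dataset(path: str | os.PathLike) -> AnnData:
    """Read a dataset directory written by :func:`write_dataset`."""
    path = os.fspath(path)
    X = sp.csr_matrix(scipy.io.mmread(os.path.join(path, "matrix.mtx")))
    genes = pd.read_csv(os.path.join(path, "genes.tsv"), sep="\t", dtype={"gene": str})
    cells = pd.read_csv(os.path.join(path, "cells.tsv"), sep="\t", dtype={"barcode": str})
    if cells.empty:  # 0-cell matrix: mmread may collapse the shape
        X = sp.csr_matrix((0, len(genes)), dtype=X.dtype)
    var = pd.DataFrame(index=pd.Index(genes["gene"], name="gene"))
    var["mt"] = np.asarray(genes["mt"]).astype(bool) if "mt" in genes else False
    obs = pd.DataFrame(index=pd.Index(cells["barcode"].astype(str), name="barcode"))
    for col in ("group", "cell_type"):
        if col in cells:
            obs[col] = pd.Categorical(cells[col])
    return AnnData(X=X, obs=obs, var=var)


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a GMT gene-set file: one set per line (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")
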