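"""File-format helpers: GMT gene sets, Matrix Market / TSV matrices, annotation CSVs.

All matrices are exchanged as pandas DataFrames; counts are samples x genes
(or genes x cells for single-cell data, stated at each call site).
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


def read_gmt(path: str) -> dict[str, list[str]]:
    """Read a GMT file into ``{set_name: [genes...]}`` (description column dropped)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, list[str]], path: str, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_matrix_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t")


def read_matrix_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_mtx(counts: pd.DataFrame, prefix: str) -> None:
    """Write a counts DataFrame as ``<prefix>.mtx`` plus row/column TSVs."""
    spio.mmwrite(prefix + ".mtx", sparse.csr_matrix(counts.to_numpy()))
    pd.Series(counts.index).to_csv(prefix + ".rows.tsv", sep="\t", index=False, header=False)
    pd.Series(counts.columns).to_csv(prefix + ".cols.tsv", sep="\t", index=False, header=False)


def read_counts_mtx(prefix: str) -> pd.DataFrame:
    mat = spio.mmread(prefix + ".mtx")
    rows = pd.read_csv(prefix + ".rows.tsv", sep="\t", header=None)[0].tolist()
    cols = pd.read_csv(prefix + ".cols.tsv", sep="\t", header=None)[0].tolist()
    arr = mat.toarray() if sparse.issparse(mat) else np.asarray(mat)
    return pd.DataFrame(arr, index=rows, columns=cols)


def read_counts(path_or_prefix: str) -> pd.DataFrame:
    """Read counts from either a dense TSV or an MTX triple (``<prefix>.mtx``)."""
    if os.path.exists(path_or_prefix + ".mtx"):
        return read_counts_mtx(path_or_prefix)
    return read_matrix_tsv(path_or_prefix)


def read_target_db(path: str) -> dict[str, set[str]]:
    """miRNA target database: GMT, or two-column TSV (miRNA <tab> gene)."""
    if path.endswith(".gmt"):
        return {k: set(v) for k, v in read_gmt(path).items()}
    df = pd.read_csv(path, sep="\t", header=None, names=["mirna", "gene"])
    return {m: set(sub["gene"]) for m, sub in df.groupby("mirna")}
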