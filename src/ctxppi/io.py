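"""Readers and writers for the on-disk exchange formats.

Expression data travels as MatrixMarket (genes x cells) plus two TSV
sidecars (gene symbols; cell metadata with cell_id / cell_type / tissue
columns).  Networks, ontologies, ligand-receptor tables and target labels
are all plain TSVs.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

GENES_FILE = "genes.tsv"
MATRIX_FILE = "matrix.mtx"
CELLS_FILE = "cells.tsv"


def write_expression(outdir, matrix, gene_ids, cell_meta: pd.DataFrame) -> None:
    os.makedirs(outdir, exist_ok=True)
    scipy.io.mmwrite(os.path.join(outdir, MATRIX_FILE), sp.csr_matrix(matrix))
    pd.Series(gene_ids, name="gene").to_csv(
        os.path.join(outdir, GENES_FILE), sep="\t", index=False
    )
    cell_meta.to_csv(os.path.join(outdir, CELLS_FILE), sep="\t", index=False)


def read_expression(indir):
    matrix = sp.csr_matrix(scipy.io.mmread(os.path.join(indir, MATRIX_FILE)))
    genes = pd.read_csv(os.path.join(indir, GENES_FILE), sep="\t")["gene"].tolist()
    cells = pd.read_csv(os.path.join(indir, CELLS_FILE), sep="\t", dtype=str)
    return matrix, genes, cells


def write_edge_list(path, edges, columns=("protein_a", "protein_b")) -> None:
    pd.DataFrame(sorted(edges), columns=list(columns)).to_csv(path, sep="\t", index=False)


def read_edge_list(path, columns=("protein_a", "protein_b")):
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [tuple(row) for row in df[list(columns)].itertuples(index=False)]


def write_lr_table(path, rows) -> None:
    pd.DataFrame(rows, columns=["cell_type_a", "cell_type_b", "p_value"]).to_csv(
        path, sep="\t", index=False
    )


def read_lr_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"cell_type_a": str, "cell_type_b": str})


def write_labels(path, labels: dict) -> None:
    pd.DataFrame(
        sorted(labels.items()), columns=["protein", "label"]
    ).to_csv(path, sep="\t", index=False)


def read_labels(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype={"protein": str, "label": int})
    return dict(zip(df["protein"], df["label"]))


def write_embedding_tsv(path, names, vectors: np.ndarray, name_cols) -> None:
    d = vectors.shape[1]
    df = pd.DataFrame(names, columns=list(name_cols))
    for j in range(d):
        df[f"v{j + 1}"] = vectors[:, j]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_embedding_tsv(path, name_cols):
    df = pd.read_csv(path, sep="\t")
    vec_cols = [c for c in df.columns if c.startswith("v")]
    names = [tuple(str(v) for v in row) for row in df[list(name_cols)].itertuples(index=False)]
    return names, df[vec_cols].to_numpy(dtype=np.float64)
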