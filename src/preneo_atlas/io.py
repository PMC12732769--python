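"""Readers and writers for the pipeline's on-disk formats.

Single-cell matrices use the 10x-style MatrixMarket layout (matrix.mtx +
genes.tsv + barcodes.tsv, plain or gzip) with a separate cell-metadata TSV
joined on barcode.  Gene maps, ligand-receptor tables and bulk matrices
are plain CSV/TSV; gene sets use the GMT convention.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._utils import STAGES
from .errors import InputDataError


def _open_maybe_gz(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find(base: Path, stem: str) -> Path:
    for cand in (base / stem, base / f"{stem}.gz"):
        if cand.exists():
            return cand
    raise InputDataError(f"missing {stem}[.gz] under {base}")


def write_sc(adata: ad.AnnData, outdir) -> None:
    """Write counts in 10x layout plus metadata and gene map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    with open(outdir / "matrix.mtx", "wb") as fh:
        scipy.io.mmwrite(fh, X.T.tocoo())     # genes x cells, 10x orientation
    genes = pd.DataFrame({"gene_id": adata.var_names,
                          "gene_name": adata.var_names})
    genes.to_csv(outdir / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      header=False, index=False)
    adata.obs.to_csv(outdir / "metadata.tsv", sep="\t")
    if "chromosome" in adata.var:
        gm = adata.var[["chromosome", "start"]].copy()
        gm.index.name = "gene"
        gm.to_csv(outdir / "gene_map.csv")


def read_sc(indir) -> ad.AnnData:
    """Read a 10x-layout directory with its metadata TSV.

    Validates matrix/annotation dimensions, barcode uniqueness, metadata
    coverage and stage labels (must be within Normal/PRE/PDAC).
    """
    indir = Path(indir)
    with _open_maybe_gz(_find(indir, "matrix.mtx"), "rb") as fh:
        M = scipy.io.mmread(fh)
    X = sp.csr_matrix(M.T)                    # cells x genes
    genes = pd.read_csv(_find(indir, "genes.tsv"), sep="\t", header=None)
    barcodes = pd.read_csv(_find(indir, "barcodes.tsv"), sep="\t",
                           header=None)[0].astype(str)
    if X.shape[1] != len(genes):
        raise InputDataError(
            f"matrix has {X.shape[1]} genes but genes.tsv lists {len(genes)}")
    if X.shape[0] != len(barcodes):
        raise InputDataError(
            f"matrix has {X.shape[0]} cells but barcodes.tsv lists {len(barcodes)}")
    if barcodes.duplicated().any():
        dup = barcodes[barcodes.duplicated()].iloc[0]
        raise InputDataError(f"duplicate barcode {dup!r}")
    meta = pd.read_csv(_find(indir, "metadata.tsv"), sep="\t", index_col=0)
    missing = [b for b in barcodes if b not in meta.index]
    if missing:
        raise InputDataError(f"metadata missing barcode {missing[0]!r}")
    meta = meta.loc[barcodes]
    if "stage" in meta:
        bad = set(meta["stage"]) - set(STAGES)
        if bad:
            raise InputDataError(f"unknown stage label(s): {sorted(bad)}")
    var = pd.DataFrame(index=pd.Index(genes[0].astype(str), name="gene"))
    gm_path = indir / "gene_map.csv"
    if gm_path.exists():
        gm = pd.read_csv(gm_path, index_col=0)
        var = var.join(gm)
    return ad.AnnData(X=X, obs=meta, var=var)


def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets = {}
    with _open_maybe_gz(Path(path)) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = parts[2:]
    return sets


def read_gene_map(path) -> pd.DataFrame:
    gm = pd.read_csv(path, index_col=0)
    need = {"chromosome", "start"}
    if not need <= set(gm.columns):
        raise InputDataError(f"gene map needs columns {sorted(need)}")
    return gm


def read_lr_table(path) -> pd.DataFrame:
    tab = pd.read_csv(path)
    if not {"ligand", "receptor"} <= set(tab.columns):
        raise InputDataError("LR table needs ligand and receptor columns")
    if "pathway" not in tab:
        tab["pathway"] = ""
    return tab


def write_bulk(matrix: pd.DataFrame, meta: pd.DataFrame, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(outdir / "bulk_expression.tsv", sep="\t")
    meta.to_csv(outdir / "bulk_metadata.tsv", sep="\t")


def read_bulk(indir) -> tuple[pd.DataFrame, pd.DataFrame]:
    indir = Path(indir)
    matrix = pd.read_csv(indir / "bulk_expression.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(indir / "bulk_metadata.tsv", sep="\t", index_col=0)
    if not matrix.index.equals(meta.index):
        raise InputDataError("bulk matrix and metadata sample names differ")
    return matrix, meta
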