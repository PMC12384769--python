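"""Single-cell quality control and normalization.

Cell QC keeps cells with at least 300 expressed (nonzero) genes and a
mitochondrial-count fraction of at most 15%; both thresholds are strict
removal rules (<300 genes or >15% mito removes a cell, the boundary cell is
kept). Gene QC drops mitochondrial genes, ribosomal genes, genes expressed
in fewer than 3 cells and, when a protein-coding list is supplied,
non-coding genes. Normalization is per-cell library-size scaling to a fixed
total followed by natural-log log1p, with optional per-gene z-scaling.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import CellMatrix, GeneLists, QcReport

__all__ = ["qc_filter_cells", "qc_filter_genes", "normalize"]


def qc_filter_cells(
    m: CellMatrix,
    lists: GeneLists,
    min_genes: int = 300,
    max_mito: float = 0.15,
) -> tuple[CellMatrix, QcReport]:
    """Remove cells with <``min_genes`` expressed genes or >``max_mito``
    mitochondrial count fraction (both computed on raw counts, all genes)."""
    if max_mito < 1 and not lists.mito:
        raise ValueError("mitochondrial gene list required when max_mito < 1")
    expressed = (m.counts > 0).sum(axis=0)
    mito_mask = m.gene_ids.isin(lists.mito)
    totals = m.counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, m.counts[mito_mask].sum(axis=0) / np.maximum(totals, 1), 0.0)

    low_genes = expressed < min_genes
    high_mito = mito_frac > max_mito
    keep = ~(low_genes | high_mito)
    if not keep.any():
        raise ValueError("cell QC removed every cell")

    out = m.subset(cells=m.cell_ids[keep])
    report = QcReport(
        cells_in=m.n_cells,
        cells_out=out.n_cells,
        genes_in=m.n_genes,
        genes_out=m.n_genes,
        removed={
            "low_gene_count": int(low_genes.sum()),
            "high_mito_fraction": int(high_mito.sum()),
            "cells_removed": int((~keep).sum()),
        },
    )
    return out, report


def qc_filter_genes(
    m: CellMatrix,
    lists: GeneLists,
    min_cells: int = 3,
) -> tuple[CellMatrix, QcReport]:
    """Drop mito genes, ribo genes, genes expressed in <``min_cells`` cells,
    and genes outside the protein-coding list (when one is given)."""
    is_mito = m.gene_ids.isin(lists.mito)
    is_ribo = m.gene_ids.isin(lists.ribo)
    few = (m.counts > 0).sum(axis=1) < min_cells
    if lists.protein_coding is not None:
        non_coding = ~m.gene_ids.isin(lists.protein_coding)
    else:
        non_coding = np.zeros(m.n_genes, bool)

    drop = is_mito | is_ribo | few | non_coding
    if drop.all():
        raise ValueError("gene QC removed every gene")

    out = m.subset(genes=m.gene_ids[~drop])
    report = QcReport(
        cells_in=m.n_cells,
        cells_out=m.n_cells,
        genes_in=m.n_genes,
        genes_out=out.n_genes,
        removed={
            "mito": int(is_mito.sum()),
            "ribo": int(is_ribo.sum()),
            "few_cells": int(few.sum()),
            "non_coding": int(non_coding.sum()),
            "genes_removed": int(drop.sum()),
        },
    )
    return out, report


def normalize(
    m: CellMatrix,
    scale_factor: float = 1e4,
    zscale: bool = False,
) -> pd.DataFrame:
    """Library-size normalize and log-transform: ln(1 + c * sf / total).

    Returns a genes x cells float DataFrame. With ``zscale`` the log values
    are additionally centred and scaled per gene (zero-variance genes left
    at 0), matching the usual "scaled" variant.
    """
    totals = m.counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        bad = list(m.cell_ids[totals == 0][:5])
        raise ValueError(f"zero-count cells present (should have failed QC): {bad}")
    X = np.log1p(m.counts * (scale_factor / totals)[None, :])
    if zscale:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=0, keepdims=True)
        X = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(X, index=m.gene_ids, columns=m.cell_ids)
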