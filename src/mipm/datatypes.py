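"""Core in-memory containers shared across the pipeline.

Expression matrices are plain :class:`pandas.DataFrame` objects oriented
genes x samples (or genes x cells); containers below add the metadata and
invariants the pipeline relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

PRIMARY = "primary"
METASTATIC = "metastatic"
SITE_LABELS = (PRIMARY, METASTATIC)


@dataclass
class CellMatrix:
    """UMI count matrix, genes x cells, with identifier axes.

    ``counts`` is a dense non-negative integer array; at the scales this
    pipeline targets (a few thousand genes, a few thousand cells) dense
    storage is simpler and fast enough.
    """

    counts: np.ndarray
    gene_ids: pd.Index
    cell_ids: pd.Index

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_ids = pd.Index(self.cell_ids)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (genes x cells)")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.gene_ids.has_duplicates or self.cell_ids.has_duplicates:
            raise ValueError("gene and cell identifiers must be unique")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.cell_ids)

    def subset(self, genes: Optional[Sequence] = None, cells: Optional[Sequence] = None) -> "CellMatrix":
        gi = self.gene_ids.get_indexer(genes) if genes is not None else slice(None)
        ci = self.cell_ids.get_indexer(cells) if cells is not None else slice(None)
        return CellMatrix(
            self.counts[gi][:, ci] if genes is not None or cells is not None else self.counts.copy(),
            self.gene_ids[gi] if genes is not None else self.gene_ids,
            self.cell_ids[ci] if cells is not None else self.cell_ids,
        )


@dataclass
class CellAnnotation:
    """Per-cell metadata: patient of origin, tissue site, optional cell class."""

    table: pd.DataFrame  # index: cell_id; columns: patient_id, site[, cell_class]

    def __post_init__(self) -> None:
        required = {"patient_id", "site"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        bad = set(self.table["site"].dropna().unique()) - set(SITE_LABELS)
        if bad:
            raise ValueError(f"unknown site labels: {sorted(bad)}")

    def aligned_to(self, cell_ids: pd.Index) -> "CellAnnotation":
        return CellAnnotation(self.table.loc[cell_ids])

    @property
    def site(self) -> pd.Series:
        return self.table["site"]

    @property
    def patient_id(self) -> pd.Series:
        return self.table["patient_id"]


@dataclass
class GeneLists:
    """Gene-category sets used by QC: mitochondrial, ribosomal, protein-coding."""

    mito: frozenset = frozenset()
    ribo: frozenset = frozenset()
    protein_coding: Optional[frozenset] = None  # None = no coding restriction

    @classmethod
    def from_prefixes(cls, gene_ids: Iterable[str]) -> "GeneLists":
        """Convenience heuristic on human-style symbols: MT- mitochondrial,
        RPL/RPS ribosomal; every gene treated as protein-coding."""
        ids = list(gene_ids)
        mito = frozenset(g for g in ids if g.upper().startswith("MT-"))
        ribo = frozenset(g for g in ids if g.upper().startswith(("RPL", "RPS")))
        return cls(mito=mito, ribo=ribo, protein_coding=None)


@dataclass
class QcReport:
    """Bookkeeping for one QC pass; conservation: in - removed == out."""

    cells_in: int
    cells_out: int
    genes_in: int
    genes_out: int
    removed: dict = field(default_factory=dict)  # rule -> count

    def __post_init__(self) -> None:
        cell_rules = {"low_gene_count", "high_mito_fraction", "cells_removed"}
        gene_rules = {"mito", "ribo", "few_cells", "non_coding", "genes_removed"}
        if "cells_removed" in self.removed and self.cells_in - self.removed["cells_removed"] != self.cells_out:
            raise ValueError("cell conservation identity violated")
        if "genes_removed" in self.removed and self.genes_in - self.removed["genes_removed"] != self.genes_out:
            raise ValueError("gene conservation identity violated")
        _ = cell_rules, gene_rules

    def to_dict(self) -> dict:
        return {
            "cells_in": self.cells_in,
            "cells_out": self.cells_out,
            "genes_in": self.genes_in,
            "genes_out": self.genes_out,
            "removed": dict(self.removed),
        }


@dataclass
class SurvivalCohort:
    """Bulk cohort: clinical table plus an optional expression handle.

    ``clinical`` is indexed by sample id with columns ``os_time`` (months),
    ``os_event`` (0/1) and optionally ``dfs_time``, ``dfs_event``, ``age``,
    ``sex`` ('male'/'female'), ``stage`` (1-4), ``chemo`` (0/1).
    ``expression`` is genes x samples, log2 scale.
    """

    clinical: pd.DataFrame
    expression: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        for col in ("os_time", "os_event"):
            if col not in self.clinical.columns:
                raise ValueError(f"clinical table missing required column {col!r}")
        if (self.clinical["os_time"] < 0).any():
            raise ValueError("follow-up times must be non-negative")
        ev = self.clinical["os_event"].dropna()
        if not ev.isin([0, 1]).all():
            raise ValueError("os_event must be 0/1")
        if self.expression is not None:
            if not self.expression.columns.equals(self.clinical.index):
                self.expression = self.expression.loc[:, self.clinical.index]

    @property
    def sample_ids(self) -> pd.Index:
        return self.clinical.index

    @property
    def n_samples(self) -> int:
        return len(self.clinical)

    def endpoint(self, which: str = "os") -> tuple[pd.Series, pd.Series]:
        """Return (time, event) for endpoint 'os' or 'dfs'."""
        which = which.lower()
        if which not in ("os", "dfs"):
            raise ValueError("endpoint must be 'os' or 'dfs'")
        tcol, ecol = f"{which}_time", f"{which}_event"
        if tcol not in self.clinical.columns or ecol not in self.clinical.columns:
            raise ValueError(f"cohort has no {which.upper()} columns ({tcol}/{ecol})")
        t = self.clinical[tcol]
        e = self.clinical[ecol]
        if t.isna().all():
            raise ValueError(f"{which.upper()} times are all missing")
        return t.astype(float), e.astype(int)

    def subgroup(self, which: str = "all") -> "SurvivalCohort":
        """Restrict to a treatment subgroup: 'all', 'chemo' or 'chemo-naive'."""
        if which == "all":
            return self
        if which not in ("chemo", "chemo-naive"):
            raise ValueError("subgroup must be 'all', 'chemo' or 'chemo-naive'")
        if "chemo" not in self.clinical.columns:
            raise ValueError("cohort has no chemotherapy annotation")
        keep = self.clinical["chemo"] == (1 if which == "chemo" else 0)
        if not keep.any():
            raise ValueError(f"subgroup {which!r} is empty in this cohort")
        clin = self.clinical.loc[keep]
        expr = self.expression.loc[:, clin.index] if self.expression is not None else None
        return SurvivalCohort(clin, expr)
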