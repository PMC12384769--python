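"""Readers and writers for the plain-text formats the pipeline exchanges.

Single-cell counts travel as MatrixMarket (.mtx) plus genes.tsv /
barcodes.tsv (or one dense TSV); bulk expression and clinical tables as
TSV; gene sets as GMT; risk models and ground truth as JSON; signatures as
TSV with a JSON header sidecar.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse

from .datatypes import CellAnnotation, CellMatrix, SurvivalCohort
from .immune import GeneSet
from .model import RiskModel
from .signature import VotingSignature

PathLike = Union[str, Path]

CLINICAL_COLUMNS = [
    "os_time", "os_event", "dfs_time", "dfs_event", "age", "sex", "stage", "chemo",
]


def write_sc(matrix: CellMatrix, annotation: CellAnnotation, outdir: PathLike) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    scio.mmwrite(out / "matrix.mtx", sparse.csc_matrix(matrix.counts), field="integer")
    pd.Series(matrix.gene_ids).to_csv(out / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(matrix.cell_ids).to_csv(out / "barcodes.tsv", sep="\t", index=False, header=False)
    annotation.table.to_csv(out / "annotation.tsv", sep="\t", index_label="cell_id")


def read_sc(indir: PathLike) -> tuple[CellMatrix, CellAnnotation]:
    d = Path(indir)
    counts = np.asarray(scio.mmread(d / "matrix.mtx").todense())
    genes = pd.read_csv(d / "genes.tsv", sep="\t", header=None)[0]
    cells = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0]
    ann = pd.read_csv(d / "annotation.tsv", sep="\t", index_col="cell_id")
    return CellMatrix(counts.astype(np.int64), pd.Index(genes), pd.Index(cells)), CellAnnotation(ann)


def read_dense_counts(path: PathLike) -> CellMatrix:
    """Dense TSV alternative: genes x cells with header row of cell ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CellMatrix(df.to_numpy(np.int64), df.index, df.columns)


def write_expression(expr: pd.DataFrame, path: PathLike) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_expression(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_clinical(cohort: SurvivalCohort, path: PathLike) -> None:
    cohort.clinical.to_csv(path, sep="\t", index_label="sample_id")


def read_clinical(path: PathLike, expression: pd.DataFrame | None = None) -> SurvivalCohort:
    clin = pd.read_csv(path, sep="\t", index_col="sample_id")
    return SurvivalCohort(clin, expression)


def read_gmt(path: PathLike) -> dict[str, GeneSet]:
    """GMT: one set per line, tab-separated name, description, genes..."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        name, _desc, *genes = parts
        genes = [g for g in genes if g]
        sets[name] = GeneSet.from_iterable(name, genes)
    return sets


def write_gmt(sets: dict[str, GeneSet], path: PathLike, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *sorted(gs.genes)]) for name, gs in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_model(model: RiskModel, path: PathLike) -> None:
    d = model.to_dict()
    d["hash"] = hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]
    Path(path).write_text(json.dumps(d, indent=1, sort_keys=True) + "\n")


def read_model(path: PathLike) -> RiskModel:
    return RiskModel.from_dict(json.loads(Path(path).read_text()))


def write_signature(sig: VotingSignature, prefix: PathLike, training_hash: str | None = None) -> None:
    prefix = Path(prefix)
    sig.to_frame().to_csv(prefix.with_suffix(".tsv"), sep="\t", index_label="gene")
    header = {
        "boundary_mode": sig.boundary_mode,
        "ranking": sig.ranking,
        "size": sig.size,
        "training_hash": training_hash,
    }
    prefix.with_suffix(".json").write_text(json.dumps(header, indent=1, sort_keys=True) + "\n")


def read_signature(prefix: PathLike) -> VotingSignature:
    prefix = Path(prefix)
    tab = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t", index_col="gene")
    header = json.loads(prefix.with_suffix(".json").read_text())
    tab = tab.sort_values("rank")
    return VotingSignature(
        genes=tab.index,
        S=tab["S"].to_numpy(),
        b=tab["b"].to_numpy(),
        boundary_mode=header["boundary_mode"],
        ranking=header["ranking"],
    )


def matrix_hash(expr: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(expr.to_numpy(float)).tobytes())
    h.update("|".join(map(str, expr.index)).encode())
    h.update("|".join(map(str, expr.columns)).encode())
    return h.hexdigest()[:16]
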