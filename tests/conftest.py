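"""Shared fixtures: simulated datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from mipm import preprocess as pp
from mipm import signature as sg
from mipm.datatypes import GeneLists, SurvivalCohort
from mipm.simulate import BulkSimConfig, ScSimConfig, simulate_bulk, simulate_sc


@pytest.fixture(scope="session")
def sc_study():
    """Reference single-cell simulation (study-scale defaults, seed 1),
    QC-filtered and normalized, with aligned annotation and ground truth."""
    cfg = ScSimConfig(seed=1)
    matrix, ann, truth = simulate_sc(cfg)
    lists = GeneLists.from_prefixes(matrix.gene_ids)
    cells_ok, _ = pp.qc_filter_cells(matrix, lists)
    clean, _ = pp.qc_filter_genes(cells_ok, lists)
    norm = pp.normalize(clean)
    return {
        "config": cfg,
        "raw": matrix,
        "norm": norm,
        "annotation": ann.aligned_to(clean.cell_ids),
        "truth": truth,
    }


@pytest.fixture(scope="session")
def sc_small():
    """Small, fast single-cell simulation for structural tests."""
    cfg = ScSimConfig(
        n_patients=3,
        cells_per_patient_per_site=25,
        n_genes=400,
        n_de_genes=40,
        de_effect=2.0,
        lowq_cell_fraction=0.0,
        seed=7,
    )
    matrix, ann, truth = simulate_sc(cfg)
    norm = pp.normalize(matrix)
    return {"config": cfg, "norm": norm, "annotation": ann, "truth": truth}


@pytest.fixture(scope="session")
def bulk_planted():
    """Bulk cohort with one strongly prognostic gene (beta = 0.8, n = 500)."""
    cfg = BulkSimConfig(
        n_samples=500, n_genes=20, prognostic_genes={"G0001": 0.8}, seed=1
    )
    expr, cohort, truth = simulate_bulk(cfg)
    return {"config": cfg, "expr": expr, "cohort": cohort, "truth": truth}


def make_cohort(time, event, **cols) -> SurvivalCohort:
    """Minimal cohort from raw arrays (no expression)."""
    n = len(time)
    clin = pd.DataFrame(
        {"os_time": np.asarray(time, float), "os_event": np.asarray(event, int), **cols},
        index=pd.Index([f"S{i + 1:03d}" for i in range(n)]),
    )
    return SurvivalCohort(clin)
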