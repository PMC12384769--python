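"""Synthetic single-cell and bulk cohorts with planted, known structure.

The single-cell generator emulates a paired primary / liver-metastasis
colorectal design: negative-binomial UMI counts with patient blocks, a
configurable number of planted site markers (half up-, half down-regulated
in metastasis), mitochondrial tag genes, and a fraction of deliberately
low-quality cells that must fall to QC.

The bulk generator emulates a microarray-style cohort: Gaussian log2
expression, exponential survival times whose hazard follows a linear
predictor over planted prognostic genes (plus optional clinical covariate
effects), and independent exponential censoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import METASTATIC, PRIMARY, CellAnnotation, CellMatrix, SurvivalCohort

__all__ = [
    "ScSimConfig",
    "BulkSimConfig",
    "CovariateSpec",
    "GroundTruth",
    "simulate_sc",
    "simulate_bulk",
]


@dataclass(frozen=True)
class ScSimConfig:
    """Parameters of the paired-site single-cell simulation."""

    n_patients: int = 6
    cells_per_patient_per_site: int = 100
    n_genes: int = 2000
    n_de_genes: int = 200
    de_effect: float = 2.0          # |log2 fold change| of planted site markers
    patient_effect_sd: float = 0.2  # log-scale sd of per-patient gene-mean shifts
    mito_gene_fraction: float = 0.05
    lowq_cell_fraction: float = 0.05
    nb_dispersion: float = 0.4      # var = mu + dispersion * mu^2; 0 -> Poisson
    mean_log_mean: float = 0.5      # log-normal location of per-gene base means
    sd_log_mean: float = 1.0        # log-normal scale of per-gene base means
    gene_param_seed: Optional[int] = None  # share gene means / marker identity across datasets
    seed: int = 0

    def validate(self) -> None:
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes cannot exceed n_genes")
        for name in ("mito_gene_fraction", "lowq_cell_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.cells_per_patient_per_site < 1:
            raise ValueError("cells_per_patient_per_site must be >= 1")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if self.lowq_cell_fraction > 0 and self.n_genes < 300:
            raise ValueError(
                "cannot construct low-quality cells (<300 expressed genes) "
                "when n_genes < 300"
            )


@dataclass(frozen=True)
class CovariateSpec:
    """Clinical covariate generation and (optional) hazard effects.

    All ``*_beta`` values are log-hazard effects; defaults are zero so the
    covariates are generated but prognostically inert unless asked for.
    ``stage_beta`` applies per ordinal level above stage I.
    """

    age_mean: float = 67.0
    age_sd: float = 10.0
    age_range: tuple = (30.0, 90.0)
    male_p: float = 0.5
    stage_probs: tuple = (0.15, 0.35, 0.30, 0.20)
    chemo_p: float = 0.5
    age_beta: float = 0.0
    sex_beta: float = 0.0    # male vs female
    stage_beta: float = 0.0  # per level above I
    chemo_beta: float = 0.0


@dataclass(frozen=True)
class BulkSimConfig:
    """Parameters of the bulk survival-cohort simulation."""

    n_samples: int = 500
    n_genes: int = 1000
    prognostic_genes: Mapping[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.01    # events per month at the covariate mean
    censoring_rate: float = 0.008    # exponential censoring, events per month
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    gene_ids: Optional[Sequence[str]] = None  # overrides n_genes when given
    mean_log2: float = 8.0
    sd_log2: float = 2.0             # spread of per-gene mean levels
    gene_sd_range: tuple = (0.5, 1.5)
    program_genes: Sequence[str] = ()  # genes loading on a shared latent program
    program_strength: float = 0.0
    program_loadings: Optional[Mapping[str, float]] = None  # per-gene override
    program_beta: float = 0.0        # log-hazard effect of the latent program
    cluster_gap: float = 0.0         # bimodal split on the first prognostic gene
    gene_param_seed: Optional[int] = None  # share per-gene means/sds across cohorts
    with_dfs: bool = False
    dfs_baseline_hazard: Optional[float] = None
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.gene_sd_range[0] <= 0:
            raise ValueError("gene standard deviations must be positive")
        universe = set(self.resolved_gene_ids())
        missing = set(self.prognostic_genes) - universe
        if missing:
            raise ValueError(f"prognostic genes outside gene universe: {sorted(missing)}")
        missing_p = set(self.program_genes) - universe
        if missing_p:
            raise ValueError(f"program genes outside gene universe: {sorted(missing_p)}")

    def resolved_gene_ids(self) -> list:
        if self.gene_ids is not None:
            return list(self.gene_ids)
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset."""

    de_gene_ids: frozenset = frozenset()
    de_directions: dict = field(default_factory=dict)  # gene -> +1 (up in metastasis) / -1
    true_site_labels: Optional[pd.Series] = None
    lowq_cell_ids: frozenset = frozenset()
    true_beta: dict = field(default_factory=dict)      # gene -> log-hazard per unit log2 expr
    planted_cutpoint: Optional[float] = None

    def to_json(self) -> str:
        payload = {
            "de_gene_ids": sorted(self.de_gene_ids),
            "de_directions": dict(sorted(self.de_directions.items())),
            "true_site_labels": (
                self.true_site_labels.to_dict() if self.true_site_labels is not None else None
            ),
            "lowq_cell_ids": sorted(self.lowq_cell_ids),
            "true_beta": dict(sorted(self.true_beta.items())),
            "planted_cutpoint": self.planted_cutpoint,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _sub_rngs(seed: int, n: int) -> list:
    """Deterministic independent sub-streams derived from one config seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_sc(config: ScSimConfig) -> tuple[CellMatrix, CellAnnotation, GroundTruth]:
    """Simulate paired primary/metastatic single-cell UMI counts.

    Counts are gamma-Poisson (negative binomial) with per-gene log-normal
    base means, a multiplicative per-patient effect, and a multiplicative
    site effect of magnitude ``2**de_effect`` on the planted marker genes
    (half up, half down in metastasis). A ``lowq_cell_fraction`` of cells is
    corrupted post hoc to violate one of the two cell-QC rules.
    """
    config.validate()
    rng_genes, rng_patients, rng_counts, rng_lowq = _sub_rngs(config.seed, 4)
    if config.gene_param_seed is not None:
        # gene-level parameters (base means, marker identity/direction) come
        # from their own stream so independent datasets share the same biology
        rng_genes = np.random.default_rng(config.gene_param_seed)

    n_mito = int(round(config.mito_gene_fraction * config.n_genes))
    gene_ids = [f"MT-{i + 1:04d}" for i in range(n_mito)] + [
        f"G{i + 1:04d}" for i in range(config.n_genes - n_mito)
    ]
    gene_ids = pd.Index(gene_ids)
    non_mito = np.arange(n_mito, config.n_genes)

    # planted site markers live outside the mito set (mito genes fall to QC)
    if config.n_de_genes > len(non_mito):
        raise ValueError("not enough non-mitochondrial genes to plant markers in")
    de_idx = rng_genes.choice(non_mito, size=config.n_de_genes, replace=False)
    de_idx.sort()
    n_up = config.n_de_genes // 2
    up_idx = de_idx[:n_up]
    down_idx = de_idx[n_up:]

    base_mean = rng_genes.lognormal(config.mean_log_mean, config.sd_log_mean, config.n_genes)

    site_mult = np.ones(config.n_genes)
    site_mult[up_idx] = 2.0 ** config.de_effect      # up in metastasis
    site_mult[down_idx] = 2.0 ** (-config.de_effect)  # down in metastasis

    cps = config.cells_per_patient_per_site
    n_cells = config.n_patients * 2 * cps
    counts = np.empty((config.n_genes, n_cells), dtype=np.int64)
    cell_ids, patients, sites = [], [], []

    col = 0
    for p in range(config.n_patients):
        pid = f"P{p + 1:02d}"
        patient_mult = np.exp(rng_patients.normal(0.0, config.patient_effect_sd, config.n_genes))
        for site, mult in ((PRIMARY, np.ones(config.n_genes)), (METASTATIC, site_mult)):
            mu = base_mean * patient_mult * mult
            block = (config.n_genes, cps)
            if config.nb_dispersion > 0:
                shape = 1.0 / config.nb_dispersion
                lam = rng_counts.gamma(shape, np.broadcast_to((mu * config.nb_dispersion)[:, None], block))
                counts[:, col:col + cps] = rng_counts.poisson(lam)
            else:
                counts[:, col:col + cps] = rng_counts.poisson(np.broadcast_to(mu[:, None], block))
            tag = "pri" if site == PRIMARY else "met"
            cell_ids.extend(f"{pid}_{tag}_{i + 1:04d}" for i in range(cps))
            patients.extend([pid] * cps)
            sites.extend([site] * cps)
            col += cps

    cell_ids = pd.Index(cell_ids)

    # corrupt a fraction of cells so that they violate exactly one QC rule
    n_lowq = int(round(config.lowq_cell_fraction * n_cells))
    lowq_cols = rng_lowq.choice(n_cells, size=n_lowq, replace=False) if n_lowq else np.array([], int)
    for k, c in enumerate(np.sort(lowq_cols)):
        if n_mito > 0 and k % 2 == 0:
            # high mito content: inflate mito counts to ~30% of the library
            non_mito_total = counts[n_mito:, c].sum()
            target = max(int(np.ceil(non_mito_total * 0.30 / 0.70)), 5 * n_mito)
            counts[:n_mito, c] = rng_lowq.multinomial(target, np.full(n_mito, 1.0 / n_mito))
        else:
            # too few expressed genes: keep at most 250 random genes
            keep = rng_lowq.choice(config.n_genes, size=250, replace=False)
            mask = np.zeros(config.n_genes, bool)
            mask[keep] = True
            counts[~mask, c] = 0
            counts[keep[:50], c] += 1  # guarantee some library is left

    matrix = CellMatrix(counts, gene_ids, cell_ids)
    annotation = CellAnnotation(
        pd.DataFrame(
            {"patient_id": patients, "site": sites, "cell_class": "cancer"},
            index=cell_ids,
        )
    )
    truth = GroundTruth(
        de_gene_ids=frozenset(gene_ids[de_idx]),
        de_directions={gene_ids[i]: (+1 if i in set(up_idx) else -1) for i in de_idx},
        true_site_labels=pd.Series(sites, index=cell_ids, name="site"),
        lowq_cell_ids=frozenset(cell_ids[lowq_cols]),
    )
    return matrix, annotation, truth


def simulate_bulk(config: BulkSimConfig) -> tuple[pd.DataFrame, SurvivalCohort, GroundTruth]:
    """Simulate a bulk expression cohort with exponential survival.

    log2 expression is Gaussian per gene; the event hazard is
    ``baseline_hazard * exp(lp)`` where lp sums mean-centred planted gene
    effects and any covariate effects, so ``baseline_hazard`` is the hazard
    of an average sample. Censoring is independent exponential.
    """
    config.validate()
    rng_expr, rng_cov, rng_surv = _sub_rngs(config.seed, 3)

    gene_ids = pd.Index(config.resolved_gene_ids())
    n_genes, n = len(gene_ids), config.n_samples
    sample_ids = pd.Index([f"S{i + 1:04d}" for i in range(n)])

    rng_gene = (
        np.random.default_rng(config.gene_param_seed)
        if config.gene_param_seed is not None
        else rng_expr
    )
    gene_means = rng_gene.normal(config.mean_log2, config.sd_log2, n_genes)
    gene_sds = rng_gene.uniform(*config.gene_sd_range, n_genes)
    if np.any(gene_sds <= 0):
        raise ValueError("degenerate config: zero-variance expression")
    X = gene_means[:, None] + gene_sds[:, None] * rng_expr.standard_normal((n_genes, n))

    z = np.zeros(n)
    if len(config.program_genes) > 0 and (
        config.program_strength > 0 or config.program_loadings
    ):
        z = rng_expr.standard_normal(n)
        loadings = np.array(
            [
                (config.program_loadings or {}).get(g, config.program_strength)
                for g in config.program_genes
            ]
        )
        pg = gene_ids.get_indexer(list(config.program_genes))
        X[pg] += loadings[:, None] * z[None, :]

    planted_cut = None
    prognostic = dict(config.prognostic_genes)
    if config.cluster_gap > 0 and prognostic:
        g0 = next(iter(prognostic))
        i0 = gene_ids.get_loc(g0)
        half = rng_expr.permutation(n) < n // 2
        X[i0] = gene_means[i0] + np.where(half, -config.cluster_gap / 2, config.cluster_gap / 2)
        X[i0] += 0.1 * gene_sds[i0] * rng_expr.standard_normal(n)
        # cutpoint in true-score space: beta * midpoint of the two cluster centres
        planted_cut = 0.0  # centred contribution of g0 is +-beta*gap/2; midpoint 0

    expr = pd.DataFrame(X, index=gene_ids, columns=sample_ids)

    cov = config.covariates
    age = np.clip(rng_cov.normal(cov.age_mean, cov.age_sd, n), *cov.age_range)
    sex = np.where(rng_cov.random(n) < cov.male_p, "male", "female")
    stage = rng_cov.choice([1, 2, 3, 4], size=n, p=cov.stage_probs)
    chemo = (rng_cov.random(n) < cov.chemo_p).astype(int)

    lp = config.program_beta * z
    for g, beta in prognostic.items():
        xg = X[gene_ids.get_loc(g)]
        lp += beta * (xg - xg.mean())
    lp += cov.age_beta * (age - age.mean())
    lp += cov.sex_beta * (sex == "male")
    lp += cov.stage_beta * (stage - 1)
    lp += cov.chemo_beta * chemo

    def _draw_times(baseline: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        t_event = rng.exponential(1.0 / (baseline * np.exp(lp)))
        if config.censoring_rate > 0:
            t_cens = rng.exponential(1.0 / config.censoring_rate, n)
        else:
            t_cens = np.full(n, np.inf)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        return time, event

    os_time, os_event = _draw_times(config.baseline_hazard, rng_surv)
    clinical = pd.DataFrame(
        {
            "os_time": os_time,
            "os_event": os_event,
            "age": age,
            "sex": sex,
            "stage": stage,
            "chemo": chemo,
        },
        index=sample_ids,
    )
    if config.with_dfs:
        dfs_base = config.dfs_baseline_hazard or 1.5 * config.baseline_hazard
        dfs_time, dfs_event = _draw_times(dfs_base, rng_surv)
        clinical["dfs_time"] = dfs_time
        clinical["dfs_event"] = dfs_event

    cohort = SurvivalCohort(clinical, expr)
    truth = GroundTruth(true_beta=prognostic, planted_cutpoint=planted_cut)
    return expr, cohort, truth
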