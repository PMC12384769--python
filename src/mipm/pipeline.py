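"""End-to-end orchestration: simulate -> QC -> signature -> immune
selection -> risk model -> evaluation.

This is the programmatic equivalent of the study design: learn a
metastasis voting signature on single-cell data, restrict to
high-contribution immune genes in a bulk training cohort, build the
Lasso-Cox risk model there, and evaluate it on an independent cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import immune, model as rm, preprocess, signature as sg
from .datatypes import GeneLists, SurvivalCohort
from .immune import GeneSet
from .simulate import BulkSimConfig, ScSimConfig, simulate_bulk, simulate_sc


@dataclass
class PipelineResult:
    signature: sg.VotingSignature
    loocv: sg.CvResult
    lopo: sg.CvResult
    hirgs: pd.DataFrame
    intersection: list
    screen: rm.CoxScreenResult
    model: rm.RiskModel
    cutoff: float
    train_report: ev.EvalReport
    validation_report: ev.EvalReport
    sc_truth: object
    bulk_truth: object


def default_bulk_configs(
    signature_genes: Sequence[str],
    seed_train: int,
    seed_val: int,
    n_samples: int = 400,
    n_extra_genes: int = 500,
    n_immune: int = 200,
    n_prognostic: int = 4,
    beta: float = 0.6,
) -> tuple[BulkSimConfig, BulkSimConfig, GeneSet]:
    """Paired train/validation bulk configs sharing planted structure.

    The gene universe embeds the single-cell signature genes among
    ``n_extra_genes`` bystanders; an immune program (shared latent factor)
    loads on ``n_immune`` genes half drawn from the signature, and
    ``n_prognostic`` program-and-signature genes carry alternating +-beta
    log-hazard effects.
    """
    sig_genes = list(signature_genes)
    extra = [f"B{i + 1:04d}" for i in range(n_extra_genes)]
    universe = sig_genes + extra
    rng = np.random.default_rng(seed_train)
    half = min(n_immune // 2, len(sig_genes))
    immune_genes = list(rng.choice(sig_genes, half, replace=False)) + list(
        rng.choice(extra, n_immune - half, replace=False)
    )
    prognostic_pool = immune_genes[:half]
    chosen = list(rng.choice(prognostic_pool, n_prognostic, replace=False))
    betas = {g: beta * (1 if i % 2 == 0 else -1) for i, g in enumerate(chosen)}
    # heterogeneous program loadings: immune genes track the latent immune
    # activity to different degrees; the prognostic ones are strong trackers
    loadings = {g: float(rng.uniform(0.3, 1.0)) for g in immune_genes}
    for g in chosen:
        loadings[g] = 1.5

    def cfg(seed: int) -> BulkSimConfig:
        return BulkSimConfig(
            n_samples=n_samples,
            gene_ids=universe,
            prognostic_genes=betas,
            program_genes=immune_genes,
            program_loadings=loadings,
            program_beta=0.5,  # immune activity is itself prognostic
            baseline_hazard=0.01,
            censoring_rate=0.008,
            gene_param_seed=seed_train,  # cohorts share per-gene baselines
            seed=seed,
        )

    return cfg(seed_train), cfg(seed_val), GeneSet.from_iterable("immune", immune_genes)


def run_pipeline(
    sc_config: Optional[ScSimConfig] = None,
    seed: int = 1,
    signature_size: int = 200,
    loocv_sizes: Sequence[int] = (10, 25, 50, 100, 200, 400),
    boundary_mode: str = "paper",
    hirg_threshold: float = 1.0,
    cutoff_policy: str = "train",
) -> PipelineResult:
    """Run the full synthetic study; seeds derive deterministically from ``seed``.

    ``cutoff_policy``: 'train' freezes the training-cohort cutpoint into the
    model before validation; 'per-cohort' re-derives the cutpoint on the
    validation cohort.
    """
    ss = np.random.SeedSequence(seed)
    s_sc, s_train, s_val, s_rf, s_cv = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5))

    sc_config = sc_config or ScSimConfig(seed=s_sc)
    counts, ann, sc_truth = simulate_sc(sc_config)
    lists = GeneLists.from_prefixes(counts.gene_ids)
    cells_ok, _ = preprocess.qc_filter_cells(counts, lists)
    clean, _ = preprocess.qc_filter_genes(cells_ok, lists)
    norm = preprocess.normalize(clean)
    ann = ann.aligned_to(clean.cell_ids)

    cv = sg.loocv(norm, ann.site, sizes=loocv_sizes, boundary_mode=boundary_mode)
    size = signature_size or cv.chosen_size
    lopo = sg.lopo_cv(norm, ann.site, ann.patient_id, size=size, boundary_mode=boundary_mode)
    snr = sg.snr_rank(norm, ann.site)
    sig = sg.build_signature(snr, size=size, boundary_mode=boundary_mode)

    cfg_train, cfg_val, immune_set = default_bulk_configs(list(sig.genes), s_train, s_val)
    _, train_cohort, bulk_truth = simulate_bulk(cfg_train)
    _, val_cohort, _ = simulate_bulk(cfg_val)

    scores = immune.ssgsea(train_cohort.expression, immune_set)
    groups = immune.median_split(scores)
    sub = train_cohort.expression.loc[sorted(immune_set.genes)]
    gini = immune.select_hirgs(sub, groups, threshold=hirg_threshold, seed=s_rf)
    hirgs = list(gini.index[gini["selected"]])

    candidates = rm.intersect_genes(list(sig.genes), hirgs)
    screen = rm.cox_screen(train_cohort, candidates)
    if not screen.kept_genes:
        raise ValueError("univariate Cox screen kept no genes")
    path, risk_model = rm.lasso_cox(train_cohort, screen.kept_genes, seed=s_cv)

    train_scores = rm.risk_score(risk_model, train_cohort.expression)
    cutoff = rm.find_cutoff(train_scores, train_cohort)
    risk_model.cutoff = cutoff
    train_report = ev.evaluate(risk_model, train_cohort)
    if cutoff_policy == "per-cohort":
        val_report = ev.evaluate(risk_model, val_cohort, cutoff=None if risk_model.cutoff is None else rm.find_cutoff(rm.risk_score(risk_model, val_cohort.expression), val_cohort))
    else:
        val_report = ev.evaluate(risk_model, val_cohort)

    return PipelineResult(
        signature=sig,
        loocv=cv,
        lopo=lopo,
        hirgs=gini,
        intersection=candidates,
        screen=screen,
        model=risk_model,
        cutoff=cutoff,
        train_report=train_report,
        validation_report=val_report,
        sc_truth=sc_truth,
        bulk_truth=bulk_truth,
    )
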