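"""Construction of the metastasis-based immune prognostic model (MIPM).

The model is a linear risk score over log2 expression,

    risk = sum_i r_i * Exp_i ,

built by intersecting the metastasis voting signature with the
high-contribution immune genes, screening the intersection by univariate
Cox regression (Wald p < 0.05), and fitting an L1-penalized Cox model with
ten-fold cross-validated choice of the penalty. The published six-gene
model (C5AR1, CCR7, ICOS, IL2RB, NRP1, VIM; cutoff -0.17) ships frozen.
Risk groups are split at a cutoff chosen by the maximally selected
log-rank statistic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .datatypes import SurvivalCohort
from .stats import cox_partial_loglik, logrank_statistic

__all__ = [
    "RiskModel",
    "CoxScreenResult",
    "LassoPath",
    "intersect_genes",
    "cox_screen",
    "lasso_cox",
    "risk_score",
    "published_model",
    "find_cutoff",
    "assign_groups",
]

PUBLISHED_COEFFICIENTS = {
    "C5AR1": 0.077,
    "CCR7": -0.141,
    "ICOS": -0.359,
    "IL2RB": -0.191,
    "NRP1": 0.340,
    "VIM": 0.191,
}
PUBLISHED_CUTOFF = -0.17


@dataclass
class RiskModel:
    """Linear prognostic score: genes, per-gene coefficients, risk cutoff."""

    genes: list
    coefficients: np.ndarray
    cutoff: Optional[float] = None
    provenance: str = "fitted"

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, float)
        if len(self.genes) != len(self.coefficients):
            raise ValueError("genes and coefficients must align")
        if self.cutoff is not None and not math.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")

    def coefficient(self, gene: str) -> float:
        return float(self.coefficients[self.genes.index(gene)])

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "coefficients": [float(c) for c in self.coefficients],
            "cutoff": self.cutoff,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RiskModel":
        return cls(
            genes=list(d["genes"]),
            coefficients=np.asarray(d["coefficients"], float),
            cutoff=d.get("cutoff"),
            provenance=d.get("provenance", "fitted"),
        )


@dataclass
class CoxScreenResult:
    """Univariate Cox screen: per-gene coefficient, HR, Wald p, kept flag."""

    table: pd.DataFrame  # columns: coef, hr, se, p, kept
    alpha: float
    failed: list = field(default_factory=list)

    @property
    def kept_genes(self) -> list:
        return list(self.table.index[self.table["kept"]])


@dataclass
class LassoPath:
    """L1 Cox path with cross-validated deviance and the chosen penalty."""

    alphas: np.ndarray
    coefs: pd.DataFrame          # genes x alphas
    cv_deviance: pd.DataFrame    # alphas x folds, plus 'mean'
    chosen_alpha: float


def published_model() -> RiskModel:
    """The frozen six-gene model with its published cutoff."""
    genes = list(PUBLISHED_COEFFICIENTS)
    return RiskModel(
        genes=genes,
        coefficients=np.array([PUBLISHED_COEFFICIENTS[g] for g in genes]),
        cutoff=PUBLISHED_CUTOFF,
        provenance="published",
    )


def intersect_genes(signature_genes, hirgs) -> list:
    """Deterministic (lexicographic) intersection of two gene collections."""
    inter = sorted(set(signature_genes) & set(hirgs))
    if not inter:
        raise ValueError(
            f"empty intersection ({len(set(signature_genes))} signature genes, "
            f"{len(set(hirgs))} immune genes share no ids)"
        )
    return inter


def cox_screen(
    cohort: SurvivalCohort,
    genes: Sequence[str],
    alpha: float = 0.05,
    endpoint: str = "os",
) -> CoxScreenResult:
    """Univariate Cox proportional-hazards screen per gene.

    Each gene is fit alone (Efron ties); a gene is kept iff its Wald
    p-value is strictly below ``alpha``. Genes whose fit fails to converge
    are excluded and reported.
    """
    if cohort.expression is None:
        raise ValueError("cohort carries no expression matrix")
    time, event = cohort.endpoint(endpoint)
    if event.sum() < 2:
        raise ValueError("need at least 2 events for the Cox screen")
    missing = set(genes) - set(cohort.expression.index)
    if missing:
        raise ValueError(f"genes absent from expression matrix: {sorted(missing)[:10]}")

    rows, failed = [], []
    base = pd.DataFrame({"time": time.to_numpy(), "event": event.to_numpy()})
    for g in genes:
        df = base.copy()
        df["x"] = cohort.expression.loc[g].to_numpy(float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = CoxPHFitter()
                cph.fit(df, duration_col="time", event_col="event")
            s = cph.summary.loc["x"]
            rows.append((g, float(s["coef"]), float(np.exp(s["coef"])), float(s["se(coef)"]), float(s["p"])))
        except Exception:
            failed.append(g)
    table = pd.DataFrame(rows, columns=["gene", "coef", "hr", "se", "p"]).set_index("gene")
    table["kept"] = table["p"] < alpha
    return CoxScreenResult(table=table, alpha=alpha, failed=failed)


def lasso_cox(
    cohort: SurvivalCohort,
    genes: Sequence[str],
    nfolds: int = 10,
    seed: int = 0,
    alphas: Optional[Sequence[float]] = None,
    endpoint: str = "os",
) -> tuple[LassoPath, RiskModel]:
    """L1-penalized Cox fit with cross-validated penalty choice.

    The penalty grid is 100 log-spaced values spanning four decades below
    the smallest penalty that zeroes every coefficient (glmnet-style),
    unless ``alphas`` is given. Folds are stratified by event status with a
    fixed seed; the chosen penalty minimizes the mean out-of-fold partial-
    likelihood deviance. Expression is standardized internally; returned
    coefficients are on the original log2 scale. The model keeps only genes
    with nonzero coefficients; its cutoff is left unset.
    """
    if cohort.expression is None:
        raise ValueError("cohort carries no expression matrix")
    time, event = cohort.endpoint(endpoint)
    if event.sum() < nfolds:
        raise ValueError("need at least as many events as folds")
    genes = list(genes)
    X = cohort.expression.loc[genes].to_numpy(float).T  # samples x genes
    y = Surv.from_arrays(event.to_numpy().astype(bool), time.to_numpy())

    def _fit(a: Optional[Sequence[float]]) -> CoxnetSurvivalAnalysis:
        est = CoxnetSurvivalAnalysis(
            l1_ratio=1.0,
            n_alphas=100,
            alpha_min_ratio=1e-4,
            alphas=None if a is None else list(a),
            normalize=True,
            fit_baseline_model=False,
            tol=1e-9,
            max_iter=1000000,
        )
        est.fit(X, y)
        return est

    full = _fit(alphas)
    grid = np.asarray(full.alphas_)

    skf = StratifiedKFold(n_splits=nfolds, shuffle=True, random_state=int(seed) % (2**31))
    dev = np.full((len(grid), nfolds), np.nan)
    t_arr, e_arr = time.to_numpy(), event.to_numpy()
    for k, (tr, te) in enumerate(skf.split(X, e_arr)):
        est = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=list(grid), normalize=True,
            fit_baseline_model=False, tol=1e-9, max_iter=1000000,
        )
        est.fit(X[tr], y[tr])
        fold_alphas = list(est.alphas_)
        for i, a in enumerate(grid):
            if a not in fold_alphas:
                continue
            coef = est.coef_[:, fold_alphas.index(a)]
            lp = X[te] @ coef
            dev[i, k] = -2.0 * cox_partial_loglik(t_arr[te], e_arr[te], lp)
    cv = pd.DataFrame(dev, index=grid, columns=[f"fold{k}" for k in range(nfolds)])
    cv["mean"] = cv.mean(axis=1)
    chosen_alpha = float(cv["mean"].idxmin())
    idx = int(np.argmin(np.abs(grid - chosen_alpha)))

    coefs = pd.DataFrame(full.coef_, index=genes, columns=grid)
    chosen_coef = coefs.iloc[:, idx]
    nonzero = chosen_coef[chosen_coef != 0.0]
    if nonzero.empty:
        raise ValueError(
            "all coefficients zero at the chosen penalty; review the grid or seed"
        )
    path = LassoPath(alphas=grid, coefs=coefs, cv_deviance=cv, chosen_alpha=chosen_alpha)
    model = RiskModel(
        genes=list(nonzero.index),
        coefficients=nonzero.to_numpy(),
        cutoff=None,
        provenance="fitted",
    )
    return path, model


def risk_score(
    model: RiskModel,
    expr: pd.DataFrame,
    impute_missing: bool = False,
) -> pd.Series:
    """Per-sample linear risk score sum_i r_i * Exp_i (no intercept).

    Expression must be on the log2 scale the model was fit on; scoring does
    not re-normalize. Missing model genes are an error unless
    ``impute_missing`` is set, in which case each missing gene is imputed
    with the per-sample mean over all genes (with a warning).
    """
    missing = [g for g in model.genes if g not in expr.index]
    if missing and not impute_missing:
        raise ValueError(f"expression matrix missing model genes: {missing}")
    vals = expr.reindex(model.genes)
    if missing:
        warnings.warn(f"imputing {len(missing)} missing model genes with per-sample means")
        fill = expr.mean(axis=0)
        for g in missing:
            vals.loc[g] = fill
    scores = vals.to_numpy(float).T @ model.coefficients
    return pd.Series(scores, index=expr.columns, name="risk_score")


def find_cutoff(
    scores: pd.Series,
    cohort: SurvivalCohort,
    endpoint: str = "os",
    minprop: float = 0.10,
) -> float:
    """Maximally selected log-rank cutpoint on risk scores.

    Candidate cutpoints are the observed score values whose induced split
    (score > c vs <= c) leaves at least ``minprop`` of the cohort on each
    side; the returned cutpoint maximizes the absolute standardized
    log-rank statistic, ties resolved to the lower cutpoint.
    """
    time, event = cohort.endpoint(endpoint)
    scores = scores.reindex(cohort.sample_ids)
    n = len(scores)
    if n < 10:
        raise ValueError("cutpoint search needs at least 10 samples")
    if event.sum() < 2:
        raise ValueError("cutpoint search needs at least 2 events")
    s = scores.to_numpy(float)
    uniq = np.unique(s)
    min_side = max(1, int(np.ceil(minprop * n)))
    t_arr, e_arr = time.to_numpy(), event.to_numpy()

    best_z, best_cut = -np.inf, None
    for c in uniq[:-1]:  # last value would leave the high side empty
        high = s > c
        nh = int(high.sum())
        if nh < min_side or n - nh < min_side:
            continue
        z, _, _ = logrank_statistic(t_arr, e_arr, high)
        az = abs(z)
        if az > best_z:  # strict: first (lowest) cutpoint wins ties
            best_z, best_cut = az, float(c)
    if best_cut is None:
        raise ValueError("no admissible cutpoint under the minprop constraint")
    return best_cut


def assign_groups(scores: pd.Series, cutoff: float) -> pd.Series:
    """'high' for score strictly above the cutoff, 'low' otherwise."""
    if not math.isfinite(cutoff) and not np.isinf(cutoff):
        raise ValueError("cutoff must be finite or +-inf")
    return pd.Series(
        np.where(scores.to_numpy(float) > cutoff, "high", "low"),
        index=scores.index,
        name="risk_group",
    )
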