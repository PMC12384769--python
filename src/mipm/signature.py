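"""Signal-to-noise weighted-voting classifier for primary vs metastatic cells.

Per gene i the signal-to-noise statistic is

    S_i = (mu_p - mu_m) / (sigma_p + sigma_m)

with class means/SDs (population, ddof=0) of normalized expression in
primary (p) and metastatic (m) cells. A signature of the top-ranked genes
classifies a cell x by summing votes

    v_i = S_i * (g_ix - b_i)

against per-gene decision boundaries b_i; the sign of the vote sum decides
the class (positive -> primary). Two boundary conventions are supported:

* ``"paper"``: b_i = (mu_p - mu_m) / 2, the form printed alongside the
  statistic in the source method;
* ``"midpoint"``: b_i = (mu_p + mu_m) / 2, the classical weighted-voting
  boundary halfway between the class means.

Gene-set size is chosen by leave-one-out cross-validation (highest
accuracy, ties to the smaller set); patient-level (leave-one-patient-out)
cross-validation guards against patient-specific signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import METASTATIC, PRIMARY

__all__ = [
    "SnrTable",
    "VotingSignature",
    "VoteResult",
    "CvResult",
    "snr_rank",
    "build_signature",
    "vote",
    "vote_matrix",
    "loocv",
    "lopo_cv",
    "apply_signature",
    "rank_auc",
    "DEFAULT_SIZE_GRID",
]

DEFAULT_SIZE_GRID = (10, 25, 50, 100, 250, 500, 1000, 2000, 4000)


@dataclass
class SnrTable:
    """Per-gene SNR statistics; ``table`` columns: S, mu_p, mu_m, sigma_p,
    sigma_m, rankable (sigma_p + sigma_m > 0)."""

    table: pd.DataFrame

    @property
    def n_rankable(self) -> int:
        return int(self.table["rankable"].sum())


@dataclass
class VotingSignature:
    """Trained classifier: ordered genes with weights S_i and boundaries b_i."""

    genes: pd.Index
    S: np.ndarray
    b: np.ndarray
    boundary_mode: str
    ranking: str

    @property
    def size(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"S": self.S, "b": self.b, "rank": np.arange(1, self.size + 1)},
            index=self.genes,
        )


@dataclass
class VoteResult:
    """Votes for one sample: per-gene v_i, their sum, the call and margin."""

    votes: pd.Series
    vote_sum: float
    predicted: str
    margin: float
    tie: bool = False


@dataclass
class CvResult:
    """Cross-validation summary over candidate signature sizes (LOOCV) or
    patients (LOPO)."""

    by_size: pd.DataFrame          # index size; columns accuracy, auc
    chosen_size: Optional[int]
    scores: pd.DataFrame           # per cell: columns = sizes (or 'score'), vote sums
    predictions: pd.DataFrame      # per cell: predicted labels per size (or fold)
    per_patient: Optional[pd.DataFrame] = None
    skipped_folds: list = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        if self.chosen_size is not None:
            return float(self.by_size.loc[self.chosen_size, "accuracy"])
        return float(self.by_size["accuracy"].iloc[0])

    @property
    def auc(self) -> float:
        if self.chosen_size is not None:
            return float(self.by_size.loc[self.chosen_size, "auc"])
        return float(self.by_size["auc"].iloc[0])


def _check_labels(labels: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    labs = set(pd.unique(labels))
    if not labs <= {PRIMARY, METASTATIC}:
        raise ValueError(f"labels must be binary {PRIMARY}/{METASTATIC}, got {sorted(labs)}")
    lab = np.asarray(labels)
    return lab == PRIMARY, lab == METASTATIC


def _class_stats(X: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sub = X[:, mask]
    return sub.mean(axis=1), sub.std(axis=1, ddof=0)


def snr_rank(expr: pd.DataFrame, labels: pd.Series) -> SnrTable:
    """Signal-to-noise statistic per gene between primary and metastatic cells.

    ``expr`` is genes x cells (normalized); ``labels`` aligns to its columns.
    Genes with sigma_p + sigma_m == 0 get S = 0 and are flagged unrankable.
    """
    labels = pd.Series(labels).reindex(expr.columns) if not isinstance(labels, pd.Series) else labels.reindex(expr.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some cells")
    p_mask, m_mask = _check_labels(labels)
    if p_mask.sum() < 2 or m_mask.sum() < 2:
        raise ValueError("need at least 2 cells per class")
    X = expr.to_numpy(float)
    mu_p, sd_p = _class_stats(X, p_mask)
    mu_m, sd_m = _class_stats(X, m_mask)
    denom = sd_p + sd_m
    rankable = denom > 0
    S = np.where(rankable, (mu_p - mu_m) / np.where(rankable, denom, 1.0), 0.0)
    return SnrTable(
        pd.DataFrame(
            {"S": S, "mu_p": mu_p, "mu_m": mu_m, "sigma_p": sd_p, "sigma_m": sd_m, "rankable": rankable},
            index=expr.index,
        )
    )


def _boundaries(mu_p: np.ndarray, mu_m: np.ndarray, mode: str) -> np.ndarray:
    if mode == "paper":
        return (mu_p - mu_m) / 2.0
    if mode == "midpoint":
        return (mu_p + mu_m) / 2.0
    raise ValueError("boundary_mode must be 'paper' or 'midpoint'")


def _select_order(S: np.ndarray, rankable: np.ndarray, size: int, ranking: str) -> np.ndarray:
    """Indices of the `size` selected genes, in rank order (stable ties)."""
    idx = np.flatnonzero(rankable)
    if size > idx.size:
        raise ValueError(f"requested size {size} exceeds {idx.size} rankable genes")
    if ranking == "absolute":
        order = idx[np.argsort(-np.abs(S[idx]), kind="stable")]
        return order[:size]
    if ranking == "balanced":
        n_neg = size // 2
        n_pos = size - n_neg  # odd sizes take the extra gene from the positive side
        pos = idx[np.argsort(-S[idx], kind="stable")][:n_pos]
        neg = idx[np.argsort(S[idx], kind="stable")][:n_neg]
        return np.concatenate([pos, neg])
    raise ValueError("ranking must be 'absolute' or 'balanced'")


def build_signature(
    snr: SnrTable,
    size: int,
    ranking: str = "absolute",
    boundary_mode: str = "paper",
) -> VotingSignature:
    """Select the top ``size`` genes and attach decision boundaries."""
    t = snr.table
    order = _select_order(
        t["S"].to_numpy(), t["rankable"].to_numpy(), size, ranking
    )
    genes = t.index[order]
    S = t["S"].to_numpy()[order]
    b = _boundaries(t["mu_p"].to_numpy()[order], t["mu_m"].to_numpy()[order], boundary_mode)
    return VotingSignature(genes=genes, S=S, b=b, boundary_mode=boundary_mode, ranking=ranking)


def _call(total: float) -> tuple[str, bool]:
    if total > 0:
        return PRIMARY, False
    if total < 0:
        return METASTATIC, False
    return METASTATIC, True  # deterministic tie-break, flagged


def vote(sig: VotingSignature, sample_expr: pd.Series) -> VoteResult:
    """Cast weighted votes for one sample; positive vote sum -> primary."""
    missing = sig.genes.difference(sample_expr.index)
    if len(missing):
        raise ValueError(f"sample missing signature genes: {sorted(missing)[:10]}")
    g = sample_expr.reindex(sig.genes).to_numpy(float)
    v = sig.S * (g - sig.b)
    total = float(v.sum())
    denom = float(np.abs(v).sum())
    predicted, tie = _call(total)
    return VoteResult(
        votes=pd.Series(v, index=sig.genes),
        vote_sum=total,
        predicted=predicted,
        margin=abs(total) / denom if denom > 0 else 0.0,
        tie=tie,
    )


def vote_matrix(sig: VotingSignature, expr: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`vote` over the columns of a genes x samples matrix."""
    missing = sig.genes.difference(expr.index)
    if len(missing):
        raise ValueError(f"matrix missing signature genes: {sorted(missing)[:10]}")
    G = expr.reindex(sig.genes).to_numpy(float)
    V = sig.S[:, None] * (G - sig.b[:, None])
    totals = V.sum(axis=0)
    denoms = np.abs(V).sum(axis=0)
    preds = np.where(totals > 0, PRIMARY, METASTATIC)
    return pd.DataFrame(
        {
            "vote_sum": totals,
            "predicted": preds,
            "margin": np.where(denoms > 0, np.abs(totals) / np.where(denoms > 0, denoms, 1.0), 0.0),
            "tie": totals == 0,
        },
        index=expr.columns,
    )


def rank_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Mann-Whitney AUC of ``scores`` for the boolean positive class
    (ties counted 1/2). Equals U / (n1 * n0)."""
    positive = np.asarray(positive, bool)
    n1, n0 = positive.sum(), (~positive).sum()
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    r = rankdata(scores)
    u = r[positive].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _resolve_sizes(sizes: Optional[Sequence[int]], n_rankable: int) -> list[int]:
    if sizes is None:
        grid = [s for s in DEFAULT_SIZE_GRID if s < n_rankable] + [n_rankable]
    else:
        grid = sorted(set(int(s) for s in sizes))
        too_big = [s for s in grid if s > n_rankable]
        if too_big:
            raise ValueError(f"candidate sizes {too_big} exceed {n_rankable} rankable genes")
    if not grid or grid[0] < 1:
        raise ValueError("candidate sizes must be positive")
    return grid


def _loo_fold_stats(
    X: np.ndarray,
    p_mask: np.ndarray,
    m_mask: np.ndarray,
    j: int,
    sums: dict,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Leave-one-out class moments via downdate of precomputed totals."""
    x = X[:, j]
    out = {}
    for cls, mask in (("p", p_mask), ("m", m_mask)):
        n = mask.sum()
        if mask[j]:
            n -= 1
            s = sums[cls][0] - x
            q = sums[cls][1] - x * x
        else:
            s, q = sums[cls]
        mu = s / n
        var = np.maximum(q / n - mu * mu, 0.0)
        out[cls] = (mu, np.sqrt(var))
    return out["p"][0], out["p"][1], out["m"][0], out["m"][1]


def loocv(
    expr: pd.DataFrame,
    labels: pd.Series,
    sizes: Optional[Sequence[int]] = None,
    ranking: str = "absolute",
    boundary_mode: str = "paper",
    fast: bool = True,
) -> CvResult:
    """Leave-one-out CV of the weighted-voting classifier over a size grid.

    Each fold retrains the SNR ranking and boundaries on the remaining
    cells, rebuilds the signature at every candidate size and votes on the
    held-out cell. With ``fast=True`` the per-fold class moments come from
    downdating precomputed totals (algebraically identical to refitting);
    ``fast=False`` refits naively and exists as its own oracle.

    Accuracy is the fraction of correct calls; AUC is the rank-based AUC of
    vote sums with primary as the positive class. The chosen size maximizes
    accuracy, ties resolved to the smaller size.
    """
    labels = pd.Series(labels).reindex(expr.columns) if not isinstance(labels, pd.Series) else labels.reindex(expr.columns)
    p_mask, m_mask = _check_labels(labels)
    if p_mask.sum() < 3 or m_mask.sum() < 3:
        raise ValueError("LOOCV needs at least 3 cells per class")
    X = expr.to_numpy(float)
    n_genes, n_cells = X.shape

    # conservative rankable count: every fold keeps >=2 cells per class, so a
    # gene unrankable in some fold is rare; sizes are validated on full data
    full_rankable = (X.std(axis=1, ddof=0) > 0).sum()
    grid = _resolve_sizes(sizes, int(full_rankable))
    max_size = grid[-1]

    sums = {
        "p": (X[:, p_mask].sum(axis=1), (X[:, p_mask] ** 2).sum(axis=1)),
        "m": (X[:, m_mask].sum(axis=1), (X[:, m_mask] ** 2).sum(axis=1)),
    }

    score_mat = np.empty((n_cells, len(grid)))
    pred_mat = np.empty((n_cells, len(grid)), dtype=object)

    for j in range(n_cells):
        if fast:
            mu_p, sd_p, mu_m, sd_m = _loo_fold_stats(X, p_mask, m_mask, j, sums)
            denom = sd_p + sd_m
            rankable = denom > 0
            S = np.where(rankable, (mu_p - mu_m) / np.where(rankable, denom, 1.0), 0.0)
            b = _boundaries(mu_p, mu_m, boundary_mode)
            x = X[:, j]
            v = S * (x - b)
            n_rank = int(rankable.sum())
            order = _select_order(S, rankable, min(max_size, n_rank), ranking)
            if ranking == "absolute":
                csum = np.cumsum(v[order])
                for k, s in enumerate(grid):
                    tot = csum[min(s, len(order)) - 1] if len(order) else 0.0
                    score_mat[j, k] = tot
                    pred_mat[j, k] = _call(tot)[0]
            else:
                for k, s in enumerate(grid):
                    sel = _select_order(S, rankable, min(s, n_rank), ranking)
                    tot = v[sel].sum() if len(sel) else 0.0
                    score_mat[j, k] = tot
                    pred_mat[j, k] = _call(tot)[0]
        else:
            mask = np.ones(n_cells, bool)
            mask[j] = False
            snr = snr_rank(expr.iloc[:, mask], labels.iloc[mask])
            for k, s in enumerate(grid):
                sig = build_signature(snr, min(s, snr.n_rankable), ranking, boundary_mode)
                res = vote(sig, expr.iloc[:, j])
                score_mat[j, k] = res.vote_sum
                pred_mat[j, k] = res.predicted

    truth = np.asarray(labels)
    rows = []
    for k, s in enumerate(grid):
        acc = float((pred_mat[:, k] == truth).mean())
        auc = rank_auc(score_mat[:, k], p_mask)
        rows.append((s, acc, auc))
    by_size = pd.DataFrame(rows, columns=["size", "accuracy", "auc"]).set_index("size")
    chosen = int(by_size["accuracy"].idxmax())  # idxmax -> first max -> smallest size

    return CvResult(
        by_size=by_size,
        chosen_size=chosen,
        scores=pd.DataFrame(score_mat, index=expr.columns, columns=grid),
        predictions=pd.DataFrame(pred_mat, index=expr.columns, columns=grid),
    )


def lopo_cv(
    expr: pd.DataFrame,
    labels: pd.Series,
    patient_ids: pd.Series,
    size: int,
    ranking: str = "absolute",
    boundary_mode: str = "paper",
) -> CvResult:
    """Leave-one-patient-out CV at a fixed signature size.

    Each fold trains on all other patients' cells and votes on the held-out
    patient's cells; reports per-patient and pooled accuracy / AUC. Folds
    whose training set contains only one class are skipped with a warning.
    """
    labels = pd.Series(labels).reindex(expr.columns) if not isinstance(labels, pd.Series) else labels.reindex(expr.columns)
    patient_ids = pd.Series(patient_ids).reindex(expr.columns) if not isinstance(patient_ids, pd.Series) else patient_ids.reindex(expr.columns)
    _check_labels(labels)
    patients = pd.unique(patient_ids)
    if len(patients) < 2:
        raise ValueError("leave-one-patient-out needs at least 2 patients")

    all_scores, all_preds, all_truth, all_pmask = [], [], [], []
    per_patient_rows, skipped = [], []
    for pat in patients:
        test = (patient_ids == pat).to_numpy()
        train_labels = labels[~test]
        if train_labels.nunique() < 2:
            warnings.warn(f"fold {pat}: training set single-class, skipped")
            skipped.append(pat)
            continue
        snr = snr_rank(expr.loc[:, ~test], train_labels)
        sig = build_signature(snr, min(size, snr.n_rankable), ranking, boundary_mode)
        votes = vote_matrix(sig, expr.loc[:, test])
        truth = labels[test]
        pmask = (truth == PRIMARY).to_numpy()
        acc = float((votes["predicted"].to_numpy() == truth.to_numpy()).mean())
        auc = rank_auc(votes["vote_sum"].to_numpy(), pmask) if 0 < pmask.sum() < len(pmask) else np.nan
        per_patient_rows.append((pat, acc, auc, int(test.sum())))
        all_scores.append(votes["vote_sum"])
        all_preds.append(votes["predicted"])
        all_truth.append(truth)
        all_pmask.append(pmask)

    if not per_patient_rows:
        raise ValueError("every patient fold was skipped")
    scores = pd.concat(all_scores)
    preds = pd.concat(all_preds)
    truth = pd.concat(all_truth)
    pmask = np.concatenate(all_pmask)
    pooled_acc = float((preds.to_numpy() == truth.to_numpy()).mean())
    pooled_auc = (
        rank_auc(scores.to_numpy(), pmask) if 0 < pmask.sum() < len(pmask) else float("nan")
    )

    return CvResult(
        by_size=pd.DataFrame({"accuracy": [pooled_acc], "auc": [pooled_auc]}, index=pd.Index([size], name="size")),
        chosen_size=None,
        scores=scores.to_frame("score"),
        predictions=preds.to_frame("predicted"),
        per_patient=pd.DataFrame(per_patient_rows, columns=["patient", "accuracy", "auc", "n_cells"]).set_index("patient"),
        skipped_folds=skipped,
    )


def apply_signature(
    sig: VotingSignature,
    expr: pd.DataFrame,
    labels: Optional[pd.Series] = None,
    min_overlap: float = 0.8,
) -> tuple[pd.DataFrame, Optional[dict]]:
    """Apply a trained signature to an independent matrix.

    Signature genes missing from the matrix are dropped with a warning as
    long as the overlap stays at or above ``min_overlap``; margins are
    naturally renormalized because they divide by the retained votes.
    Returns per-cell predictions and, when labels are given, a metrics dict
    with accuracy and AUC (primary = positive class).
    """
    present = sig.genes.isin(expr.index)
    overlap = present.mean()
    if overlap < min_overlap:
        raise ValueError(
            f"gene overlap {overlap:.2%} below the {min_overlap:.0%} floor"
        )
    if not present.all():
        warnings.warn(
            f"{(~present).sum()} signature genes absent from matrix; dropped"
        )
        sig = VotingSignature(
            genes=sig.genes[present],
            S=sig.S[present],
            b=sig.b[present],
            boundary_mode=sig.boundary_mode,
            ranking=sig.ranking,
        )
    preds = vote_matrix(sig, expr)
    metrics = None
    if labels is not None:
        labels = labels.reindex(expr.columns)
        has = labels.notna()
        if has.any():
            truth = labels[has]
            pmask = (truth == PRIMARY).to_numpy()
            sub = preds.loc[has.to_numpy()]
            metrics = {
                "accuracy": float((sub["predicted"].to_numpy() == truth.to_numpy()).mean()),
                "auc": rank_auc(sub["vote_sum"].to_numpy(), pmask)
                if 0 < pmask.sum() < len(pmask)
                else float("nan"),
                "n_labeled": int(has.sum()),
            }
    return preds, metrics
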