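"""Immune stratification and high-contribution immune gene selection.

Samples are scored against an immune gene set with a single-sample GSEA
running-sum statistic, split at the cohort median into high/low-immunity
groups, and a random-forest classifier of that split then ranks immune
genes by mean decrease in Gini impurity; genes above a threshold (default
1, on the R-randomForest-like per-tree impurity-decrease scale) are the
high-contribution immune-related genes (HIRGs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

__all__ = ["GeneSet", "ssgsea", "median_split", "select_hirgs"]


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene set must be non-empty")

    @classmethod
    def from_iterable(cls, name: str, genes) -> "GeneSet":
        return cls(name, frozenset(genes))


def _ssgsea_one(values: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Running-sum enrichment of one sample.

    Genes are walked in decreasing expression order; in-set genes step the
    weighted ECDF P_in by rank^alpha (rank = within-sample expression rank,
    highest expression = largest rank, average ranks on ties), out-of-set
    genes step the unweighted ECDF P_out. Score = sum_i (P_in - P_out).
    """
    n = len(values)
    ranks = rankdata(values)  # 1..n, ascending, average ties
    order = np.lexsort((np.arange(n), -ranks))  # descending rank, stable
    in_ord = in_set[order]
    w = np.where(in_ord, ranks[order] ** alpha, 0.0)
    n_out = n - in_set.sum()
    if n_out == 0:
        return 0.0  # degenerate: every gene in the set; documented as 0
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~in_ord) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea(expr: pd.DataFrame, gs: GeneSet, alpha: float = 0.25) -> pd.Series:
    """Single-sample GSEA enrichment score per sample (column) of ``expr``.

    Scores are raw (unnormalized) running sums; the downstream median split
    is invariant to any monotone cross-sample normalization, so none is
    applied. Depends only on within-sample expression ranks.
    """
    members = expr.index.intersection(list(gs.genes))
    if len(members) == 0:
        raise ValueError(f"gene set {gs.name!r} shares no genes with the matrix")
    frac = len(members) / len(gs.genes)
    if frac < 0.5:
        warnings.warn(
            f"only {frac:.0%} of gene set {gs.name!r} present in the matrix"
        )
    in_set = expr.index.isin(members)
    X = expr.to_numpy(float)
    scores = [
        _ssgsea_one(X[:, j], in_set, alpha) for j in range(X.shape[1])
    ]
    return pd.Series(scores, index=expr.columns, name=f"ssgsea_{gs.name}")


def median_split(scores: pd.Series) -> pd.Series:
    """'high' for scores strictly above the median, 'low' otherwise."""
    if len(scores) < 2:
        raise ValueError("median split needs at least 2 samples")
    med = float(scores.median())
    if scores.nunique() == 1:
        raise ValueError("all scores identical; split is degenerate")
    return pd.Series(np.where(scores > med, "high", "low"), index=scores.index, name="immunity")


def select_hirgs(
    expr: pd.DataFrame,
    groups: pd.Series,
    threshold: float = 1.0,
    n_trees: int = 500,
    seed: int = 0,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Rank immune genes by random-forest mean decrease Gini.

    ``expr`` is the immune-gene submatrix (genes x samples); ``groups`` the
    high/low immunity labels. Importances are averaged per-tree impurity
    decreases rescaled by the sample count so the customary ``> 1``
    threshold is meaningful; ``top_k`` offers a scale-free alternative
    (select the k largest importances instead of thresholding).

    Returns a DataFrame indexed by gene with columns ``importance`` and
    ``selected``.
    """
    groups = groups.reindex(expr.columns)
    if groups.isna().any():
        raise ValueError("groups missing for some samples")
    if groups.nunique() < 2:
        raise ValueError("both immunity groups must be present")
    X = expr.to_numpy(float).T
    y = groups.to_numpy()
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    rf.fit(X, y)
    # per-tree unnormalized importances are impurity decrease per sample;
    # x n_samples puts them on the R randomForest MeanDecreaseGini scale
    per_tree = np.stack(
        [t.tree_.compute_feature_importances(normalize=False) for t in rf.estimators_]
    )
    importance = per_tree.mean(axis=0) * X.shape[0]
    out = pd.DataFrame({"importance": importance}, index=expr.index)
    if top_k is not None:
        sel = out["importance"].rank(ascending=False, method="first") <= top_k
    else:
        sel = out["importance"] > threshold
    out["selected"] = sel
    return out.sort_values("importance", ascending=False)
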