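"""Survival evaluation of a risk model on a cohort.

Covers Kaplan-Meier curves with the log-rank test, hazard ratios with Wald
confidence intervals from Cox proportional-hazards fits, horizon
(cumulative/dynamic) ROC and AUC, calibration against binned KM estimates,
decision-curve net benefit, and a points-based nomogram for 3-/5-year
survival. Endpoints are overall survival or disease-free survival, with
optional chemotherapy subgroups. Times are months throughout; the default
horizons are 36 and 60 months.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy.stats import mannwhitneyu

from .datatypes import SurvivalCohort
from .model import RiskModel, assign_groups, find_cutoff, risk_score
from .stats import km_estimate, km_survival_at, logrank_statistic

__all__ = [
    "KmCurve",
    "EvalReport",
    "Nomogram",
    "km_fit",
    "logrank",
    "cox_groups",
    "horizon_roc",
    "calibration",
    "decision_curve",
    "build_nomogram",
    "evaluate",
    "rank_sum_test",
]


@dataclass
class KmCurve:
    """Product-limit curve for one group: Ŝ(t), at-risk counts, Greenwood
    variance at each distinct event time."""

    group: str
    table: pd.DataFrame  # index time; columns at_risk, events, survival, variance
    n: int

    def survival_at(self, t: float) -> float:
        return km_survival_at(self.table, t)[0]


@dataclass
class Nomogram:
    """Points representation of a multivariable Cox model.

    Each covariate's linear-predictor contribution is mapped to a 0-100
    point scale (the covariate with the widest contribution range spans the
    full 100 points); total points map back to the linear predictor and to
    Breslow baseline survival at the requested horizons.
    """

    terms: pd.DataFrame          # index term; columns coef, min_contrib, max_contrib, points_per_unit
    points_scale: float          # lp units per 100 points (widest contribution range)
    lp_offset: float             # sum of per-term min contributions
    mean_lp: float               # lp at which the baseline survival is anchored
    baseline: pd.DataFrame       # index time; column baseline_survival (at mean lp)
    horizons: tuple
    point_resolution: float = 1.0

    def points(self, covariates: dict) -> pd.Series:
        pts = {}
        for term, row in self.terms.iterrows():
            contrib = row["coef"] * float(covariates[term])
            raw = 100.0 * (contrib - row["min_contrib"]) / self.points_scale
            pts[term] = np.round(raw / self.point_resolution) * self.point_resolution
        return pd.Series(pts, name="points")

    def _lp_from_points(self, total_points: float) -> float:
        return self.lp_offset + total_points * self.points_scale / 100.0

    def predict_survival(self, total_points: float, horizon: float) -> float:
        lp = self._lp_from_points(total_points)
        s0 = km_survival_at(self.baseline.rename(columns={"baseline_survival": "survival"}).assign(variance=0.0), horizon)[0]
        return float(s0 ** np.exp(lp - self.mean_lp))

    def predict(self, covariates: dict) -> dict:
        pts = self.points(covariates)
        total = float(pts.sum())
        return {
            "points": pts.to_dict(),
            "total_points": total,
            **{f"survival_{int(h)}m": self.predict_survival(total, h) for h in self.horizons},
        }


@dataclass
class EvalReport:
    """All evaluation outputs for one model/cohort/endpoint/subgroup."""

    endpoint: str
    subgroup: str
    n_samples: int
    cutoff: float
    cutoff_source: str
    group_sizes: dict
    logrank_chi2: float
    logrank_p: float
    hazard_ratio: float
    hr_ci: tuple
    hr_p: float
    auc_by_horizon: dict
    km_curves: dict = field(default_factory=dict)       # group -> KmCurve
    calibration_bins: Optional[pd.DataFrame] = None
    net_benefit: Optional[pd.DataFrame] = None
    scores: Optional[pd.Series] = None
    groups: Optional[pd.Series] = None

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "subgroup": self.subgroup,
            "n_samples": self.n_samples,
            "cutoff": self.cutoff,
            "cutoff_source": self.cutoff_source,
            "group_sizes": self.group_sizes,
            "logrank_chi2": self.logrank_chi2,
            "logrank_p": self.logrank_p,
            "hazard_ratio": self.hazard_ratio,
            "hr_ci": list(self.hr_ci),
            "hr_p": self.hr_p,
            "auc_by_horizon": {str(k): v for k, v in self.auc_by_horizon.items()},
            "km_curves": {
                g: c.table.reset_index().to_dict(orient="list") for g, c in self.km_curves.items()
            },
            "calibration_bins": (
                self.calibration_bins.to_dict(orient="list") if self.calibration_bins is not None else None
            ),
            "net_benefit": (
                self.net_benefit.to_dict(orient="list") if self.net_benefit is not None else None
            ),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def km_fit(cohort: SurvivalCohort, groups: pd.Series, endpoint: str = "os") -> dict:
    """Kaplan-Meier curve per group; returns {group: KmCurve}."""
    time, event = cohort.endpoint(endpoint)
    groups = groups.reindex(cohort.sample_ids)
    if event.sum() < 1:
        pass  # all-censored cohorts are legal: curves stay at 1
    out = {}
    for g in pd.unique(groups.dropna()):
        mask = (groups == g).to_numpy()
        out[str(g)] = KmCurve(
            group=str(g),
            table=km_estimate(time.to_numpy()[mask], event.to_numpy()[mask]),
            n=int(mask.sum()),
        )
    return out


def logrank(cohort: SurvivalCohort, groups: pd.Series, endpoint: str = "os") -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p)."""
    time, event = cohort.endpoint(endpoint)
    groups = groups.reindex(cohort.sample_ids)
    levels = pd.unique(groups.dropna())
    if len(levels) != 2:
        raise ValueError(f"log-rank requires exactly 2 groups, got {list(levels)}")
    mask = (groups == levels[0]).to_numpy()
    _, chi2, p = logrank_statistic(time.to_numpy(), event.to_numpy(), mask)
    return chi2, p


def _prepare_covariates(cohort: SurvivalCohort, covariates: Sequence[str], stage_binary: bool = True) -> pd.DataFrame:
    """Numeric design columns for Cox fits (Table-style codings)."""
    out = {}
    clin = cohort.clinical
    for c in covariates:
        if c == "age":
            out["age"] = clin["age"].astype(float)
        elif c == "sex":
            out["sex_male"] = (clin["sex"] == "male").astype(float)
        elif c == "stage":
            if stage_binary:
                out["stage_iii_iv"] = (clin["stage"] >= 3).astype(float)
            else:
                for lev in (2, 3, 4):
                    out[f"stage_{lev}"] = (clin["stage"] == lev).astype(float)
        elif c == "chemo":
            out["chemo"] = clin["chemo"].astype(float)
        else:
            out[c] = clin[c].astype(float)
    return pd.DataFrame(out, index=clin.index)


def cox_groups(
    cohort: SurvivalCohort,
    groups: Optional[pd.Series] = None,
    score: Optional[pd.Series] = None,
    covariates: Sequence[str] = (),
    endpoint: str = "os",
    stage_binary: bool = True,
) -> pd.DataFrame:
    """Cox PH fit of risk group (high vs low) or a continuous score,
    optionally adjusted for clinical covariates.

    Returns a per-term table with coef, HR, 95% Wald CI and p. Stage is
    dichotomized III/IV vs I/II by default; sex coded male vs female; age
    continuous.
    """
    time, event = cohort.endpoint(endpoint)
    df = pd.DataFrame({"time": time, "event": event})
    if groups is not None:
        df["risk_high"] = (groups.reindex(cohort.sample_ids) == "high").astype(float)
    elif score is not None:
        df["risk_score"] = score.reindex(cohort.sample_ids).astype(float)
    else:
        raise ValueError("provide groups or score")
    if covariates:
        df = df.join(_prepare_covariates(cohort, covariates, stage_binary))
    n_terms = df.shape[1] - 2
    if event.sum() < n_terms + 1:
        raise ValueError("too few events for the number of model terms")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
    s = cph.summary
    return pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": np.exp(s["coef"]),
            "ci_low": np.exp(s["coef"] - 1.96 * s["se(coef)"]),
            "ci_high": np.exp(s["coef"] + 1.96 * s["se(coef)"]),
            "p": s["p"],
        }
    )


def _horizon_case_control(time: np.ndarray, event: np.ndarray, horizon: float) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative cases (event by the horizon) and dynamic controls
    (event-free follow-up to the horizon); early-censored samples excluded."""
    cases = (event == 1) & (time <= horizon)
    controls = (time >= horizon) & ~cases
    return cases, controls


def horizon_roc(
    scores: pd.Series,
    cohort: SurvivalCohort,
    horizon: float,
    endpoint: str = "os",
) -> tuple[float, pd.DataFrame]:
    """Time-horizon ROC: cumulative cases vs dynamic controls.

    AUC is the Mann-Whitney statistic of the scores (ties 1/2); the ROC
    table gives (threshold, tpr, fpr) over unique score thresholds.
    """
    time, event = cohort.endpoint(endpoint)
    s = scores.reindex(cohort.sample_ids).to_numpy(float)
    cases, controls = _horizon_case_control(time.to_numpy(), event.to_numpy(), horizon)
    if cases.sum() == 0 or controls.sum() == 0:
        raise ValueError(f"no cases or no controls at horizon {horizon}")
    keep = cases | controls
    from .signature import rank_auc

    auc = rank_auc(s[keep], cases[keep])
    thr = np.r_[np.inf, np.unique(s[keep])[::-1]]
    tpr = [(s[cases] >= t).mean() for t in thr]
    fpr = [(s[controls] >= t).mean() for t in thr]
    roc = pd.DataFrame({"threshold": thr, "tpr": tpr, "fpr": fpr})
    return auc, roc


def calibration(
    predicted_survival: pd.Series,
    cohort: SurvivalCohort,
    horizon: float,
    n_bins: int = 10,
    endpoint: str = "os",
) -> pd.DataFrame:
    """Calibration of predicted survival probabilities at a horizon.

    Samples are binned by predicted-probability quantiles; observed
    survival per bin is the KM estimate at the horizon with a Greenwood
    95% CI. Returns one row per bin.
    """
    p = predicted_survival.reindex(cohort.sample_ids).astype(float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("predicted survival probabilities must lie in [0, 1]")
    time, event = cohort.endpoint(endpoint)
    if p.nunique() == 1:
        bins = pd.Series(pd.Categorical([f"[{p.iloc[0]:.3g}]"] * len(p)), index=p.index)
    else:
        bins = pd.qcut(p, q=n_bins, duplicates="drop")
    rows = []
    for b, idx in p.groupby(bins, observed=True).groups.items():
        mask = p.index.isin(idx)
        km = km_estimate(time.to_numpy()[mask], event.to_numpy()[mask])
        obs, var = km_survival_at(km, horizon)
        half = 1.96 * np.sqrt(var)
        rows.append(
            (str(b), int(mask.sum()), float(p[mask].mean()), obs, max(obs - half, 0.0), min(obs + half, 1.0))
        )
    return pd.DataFrame(rows, columns=["bin", "n", "predicted", "observed", "ci_low", "ci_high"])


def decision_curve(
    predicted_event: pd.Series,
    cohort: SurvivalCohort,
    horizon: float,
    thresholds: Optional[np.ndarray] = None,
    endpoint: str = "os",
) -> pd.DataFrame:
    """Decision-curve net benefit over threshold probabilities.

    net benefit(pt) = TP/n - (FP/n) * pt / (1 - pt), with cases/controls
    defined at the horizon as in :func:`horizon_roc` (early-censored
    samples excluded from n). Treat-all and treat-none references included.
    """
    if thresholds is None:
        thresholds = np.linspace(0.05, 0.75, 29)
    thresholds = np.asarray(thresholds, float)
    if ((thresholds <= 0) | (thresholds >= 1)).any():
        raise ValueError("thresholds must lie in (0, 1)")
    p = predicted_event.reindex(cohort.sample_ids).to_numpy(float)
    time, event = cohort.endpoint(endpoint)
    cases, controls = _horizon_case_control(time.to_numpy(), event.to_numpy(), horizon)
    keep = cases | controls
    p, cases = p[keep], cases[keep]
    n = int(keep.sum())
    prev = cases.mean()
    rows = []
    for pt in thresholds:
        treat = p >= pt
        tp = (treat & cases).sum()
        fp = (treat & ~cases).sum()
        odds = pt / (1 - pt)
        rows.append(
            (pt, tp / n - (fp / n) * odds, prev - (1 - prev) * odds, 0.0)
        )
    return pd.DataFrame(rows, columns=["threshold", "net_benefit", "treat_all", "treat_none"])


def build_nomogram(
    cohort: SurvivalCohort,
    scores: pd.Series,
    covariates: Sequence[str] = ("age", "sex", "stage"),
    horizons: Sequence[float] = (36.0, 60.0),
    endpoint: str = "os",
    point_resolution: float = 1.0,
) -> Nomogram:
    """Points-based nomogram from a multivariable Cox fit of score + clinic.

    Per-term points are the term's linear-predictor contribution rescaled
    so the widest-ranging term spans 0-100 points; total points map to
    survival through the Breslow baseline of the underlying Cox model.
    """
    time, event = cohort.endpoint(endpoint)
    design = _prepare_covariates(cohort, covariates)
    design.insert(0, "risk_score", scores.reindex(cohort.sample_ids).astype(float))
    df = pd.DataFrame({"time": time, "event": event}).join(design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")

    coefs = cph.params_
    contrib = design * coefs  # per-sample, per-term lp contributions
    lo, hi = contrib.min(axis=0), contrib.max(axis=0)
    ranges = (hi - lo).to_numpy()
    scale = float(ranges.max())
    if scale <= 0:
        raise ValueError("all nomogram terms are constant")
    terms = pd.DataFrame(
        {
            "coef": coefs,
            "min_contrib": lo,
            "max_contrib": hi,
            "points_per_unit": 100.0 * coefs.abs() / scale,
        }
    )
    baseline = cph.baseline_survival_.rename(columns={"baseline hazard": "baseline_survival"})
    baseline.columns = ["baseline_survival"]
    baseline.index.name = "time"
    mean_lp = float((design.mean(axis=0) * coefs).sum())
    return Nomogram(
        terms=terms,
        points_scale=scale,
        lp_offset=float(lo.sum()),
        mean_lp=mean_lp,
        baseline=baseline,
        horizons=tuple(horizons),
        point_resolution=point_resolution,
    )


def rank_sum_test(x, y) -> tuple[float, float]:
    """Wilcoxon rank-sum comparison of two samples.

    Exact null distribution for n <= 25 per group (no ties), normal
    approximation with continuity correction otherwise. Returns (U, p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    method = "exact" if max(len(x), len(y)) <= 25 and len(np.unique(np.r_[x, y])) == len(x) + len(y) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _score_to_survival(
    scores: pd.Series, cohort: SurvivalCohort, horizon: float, endpoint: str
) -> pd.Series:
    """Predicted survival at a horizon from a univariate Cox fit on the score."""
    time, event = cohort.endpoint(endpoint)
    df = pd.DataFrame({"time": time, "event": event, "risk_score": scores.reindex(cohort.sample_ids)})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
    sf = cph.predict_survival_function(df[["risk_score"]], times=[horizon])
    return pd.Series(sf.iloc[0].to_numpy(), index=cohort.sample_ids)


def evaluate(
    model: RiskModel,
    cohort: SurvivalCohort,
    endpoint: str = "os",
    subgroup: str = "all",
    horizons: Sequence[float] = (36.0, 60.0),
    cutoff: Optional[float] = None,
    n_bins: int = 10,
) -> EvalReport:
    """Full evaluation of a risk model on one cohort.

    Scores the cohort, splits at ``cutoff`` (explicit value > the model's
    frozen cutoff > a cohort-specific maximally selected cutpoint, in that
    order of preference), then computes KM curves, the log-rank test, the
    high-vs-low hazard ratio, horizon AUCs, calibration and net benefit at
    the first horizon.
    """
    cohort = cohort.subgroup(subgroup)
    _ = cohort.endpoint(endpoint)  # validate endpoint columns early
    if cohort.expression is None:
        raise ValueError("cohort carries no expression matrix")
    scores = risk_score(model, cohort.expression)
    if cutoff is not None:
        cut, source = float(cutoff), "explicit"
    elif model.cutoff is not None:
        cut, source = float(model.cutoff), "model"
    else:
        cut, source = find_cutoff(scores, cohort, endpoint=endpoint), "maxstat"
    groups = assign_groups(scores, cut)
    if groups.nunique() < 2:
        raise ValueError("cutoff puts every sample in one risk group")

    curves = km_fit(cohort, groups, endpoint)
    chi2, p = logrank(cohort, groups, endpoint)
    hr_tab = cox_groups(cohort, groups=groups, endpoint=endpoint)
    hr_row = hr_tab.loc["risk_high"]

    aucs = {}
    for h in horizons:
        try:
            aucs[float(h)], _roc = horizon_roc(scores, cohort, h, endpoint)
        except ValueError:
            aucs[float(h)] = float("nan")

    h0 = float(horizons[0])
    try:
        surv_pred = _score_to_survival(scores, cohort, h0, endpoint)
        calib = calibration(surv_pred, cohort, h0, n_bins=n_bins, endpoint=endpoint)
        nb = decision_curve(1.0 - surv_pred, cohort, h0, endpoint=endpoint)
    except ValueError:
        calib, nb = None, None

    return EvalReport(
        endpoint=endpoint,
        subgroup=subgroup,
        n_samples=cohort.n_samples,
        cutoff=cut,
        cutoff_source=source,
        group_sizes=groups.value_counts().to_dict(),
        logrank_chi2=float(chi2),
        logrank_p=float(p),
        hazard_ratio=float(hr_row["hr"]),
        hr_ci=(float(hr_row["ci_low"]), float(hr_row["ci_high"])),
        hr_p=float(hr_row["p"]),
        auc_by_horizon=aucs,
        km_curves=curves,
        calibration_bins=calib,
        net_benefit=nb,
        scores=scores,
        groups=groups,
    )
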