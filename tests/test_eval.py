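"""Survival evaluation: KM, log-rank, Cox HRs, horizon ROC, calibration,
decision curves and the nomogram."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test
from scipy.stats import linregress

from mipm import evaluate as ev
from mipm import model as rm
from mipm.datatypes import SurvivalCohort
from mipm.simulate import BulkSimConfig, CovariateSpec, simulate_bulk
from mipm.stats import km_estimate, km_survival_at, logrank_statistic

from conftest import make_cohort


class TestKm:
    def test_worked_fixture(self):
        # times 1, 2+, 3, 4, 5+, 6 -> S = 5/6, 5/8, 5/12, 0
        cohort = make_cohort([1, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 1])
        curves = ev.km_fit(cohort, pd.Series("all", index=cohort.sample_ids))
        s = curves["all"].table["survival"]
        assert np.allclose(s.to_numpy(), [5 / 6, 5 / 8, 5 / 12, 0.0])

    def test_no_censoring_equals_empirical_survivor(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(10, 40)
        cohort = make_cohort(t, np.ones(40, int))
        km = km_estimate(t, np.ones(40, int))
        for u in np.quantile(t, [0.1, 0.5, 0.9]):
            assert km_survival_at(km, u)[0] == pytest.approx((t > u).mean())

    def test_all_censored_stays_at_one(self):
        km = km_estimate(np.array([1.0, 2.0, 3.0]), np.array([0, 0, 0]))
        assert km.empty  # no event times; the curve is identically 1

    def test_greenwood_variance_positive_between_events(self):
        km = km_estimate(np.array([1.0, 2, 3, 4, 5]), np.array([1, 1, 0, 1, 0]))
        assert (km["variance"].iloc[:-1] > 0).all()


class TestLogrank:
    def test_identical_groups_give_null(self):
        t = [1.0, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        e = [1, 1, 0, 1, 0] * 2
        cohort = make_cohort(t, e)
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=cohort.sample_ids)
        chi2, p = ev.logrank(cohort, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 30)
        e = (rng.random(30) < 0.8).astype(int)
        g = rng.random(30) < 0.5
        z1, chi1, p1 = logrank_statistic(t, e, g)
        z2, chi2, p2 = logrank_statistic(t, e, ~g)
        assert z1 == pytest.approx(-z2)
        assert chi1 == pytest.approx(chi2) and p1 == pytest.approx(p2)

    def test_agrees_with_lifelines(self):
        rng = np.random.default_rng(4)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 60
            g = rng.random(n) < 0.5
            t = rng.exponential(np.where(g, 6, 10))
            e = (rng.random(n) < 0.7).astype(int)
            _, chi2, p = logrank_statistic(t, e, g)
            ref = logrank_test(t[g], t[~g], e[g], e[~g])
            assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
            assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_power_against_planted_hazard_ratio(self):
        rng = np.random.default_rng(1)
        n = 300
        g = rng.random(n) < 0.5
        t = rng.exponential(np.where(g, 1 / 0.02, 1 / 0.01))
        e = (rng.random(n) < 0.85).astype(int)
        _, _, p = logrank_statistic(t, e, g)
        assert p < 0.001


class TestCoxGroups:
    def test_planted_group_effect_recovered(self):
        rng = np.random.default_rng(1)
        n = 500
        g = rng.random(n) < 0.5
        t = rng.exponential(1 / (0.01 * np.exp(0.8 * g)))
        cohort = make_cohort(t, np.ones(n, int))
        groups = pd.Series(np.where(g, "high", "low"), index=cohort.sample_ids)
        tab = ev.cox_groups(cohort, groups=groups)
        assert abs(tab.loc["risk_high", "coef"] - 0.8) <= 0.15
        assert tab.loc["risk_high", "ci_low"] < tab.loc["risk_high", "hr"] < tab.loc["risk_high", "ci_high"]

    def test_nominal_ci_coverage(self):
        covered = 0
        n_reps = 200
        for seed in range(n_reps):
            rng = np.random.default_rng(seed)
            n = 120
            g = rng.random(n) < 0.5
            t = rng.exponential(1 / (0.02 * np.exp(0.7 * g)))
            cohort = make_cohort(t, np.ones(n, int))
            groups = pd.Series(np.where(g, "high", "low"), index=cohort.sample_ids)
            tab = ev.cox_groups(cohort, groups=groups)
            if tab.loc["risk_high", "ci_low"] <= np.exp(0.7) <= tab.loc["risk_high", "ci_high"]:
                covered += 1
        assert abs(covered / n_reps - 0.95) <= 0.03

    def test_confounder_attenuates_group_effect(self):
        # group effect operates only through the confounder: adjusting for
        # it must pull the group HR toward 1
        rng = np.random.default_rng(1)
        n = 400
        conf = rng.normal(size=n)
        g = conf + 0.5 * rng.normal(size=n) > 0
        t = rng.exponential(1 / (0.02 * np.exp(1.0 * conf)))
        cohort = make_cohort(t, np.ones(n, int), conf=conf)
        groups = pd.Series(np.where(g, "high", "low"), index=cohort.sample_ids)
        uni = ev.cox_groups(cohort, groups=groups)
        multi = ev.cox_groups(cohort, groups=groups, covariates=["conf"])
        assert abs(np.log(multi.loc["risk_high", "hr"])) < abs(np.log(uni.loc["risk_high", "hr"]))

    def test_stage_dichotomized_as_advanced_vs_early(self):
        _, cohort, _ = simulate_bulk(
            BulkSimConfig(n_samples=300, n_genes=4,
                          covariates=CovariateSpec(stage_beta=0.5), seed=5)
        )
        noise = pd.Series(
            np.random.default_rng(0).normal(size=300), index=cohort.sample_ids
        )
        tab = ev.cox_groups(cohort, score=noise, covariates=["age", "sex", "stage"])
        assert "stage_iii_iv" in tab.index
        assert tab.loc["stage_iii_iv", "hr"] > 1.0


class TestHorizonRoc:
    def test_constant_scores_give_half(self):
        cohort = make_cohort([10, 20, 30, 40, 50, 60], [1, 1, 1, 0, 0, 0])
        s = pd.Series(1.0, index=cohort.sample_ids)
        auc, _ = ev.horizon_roc(s, cohort, horizon=35)
        assert auc == 0.5

    def test_perfect_ranking_gives_one(self):
        cohort = make_cohort([10, 20, 30, 100, 100, 100], [1, 1, 1, 0, 0, 0])
        s = pd.Series([6, 5, 4, 3, 2, 1], index=cohort.sample_ids, dtype=float)
        auc, _ = ev.horizon_roc(s, cohort, horizon=36)
        assert auc == 1.0

    def test_brute_force_fixture(self):
        # 12 samples: 4 cases by t=36, 6 controls, 2 censored early (excluded)
        time = [10, 20, 30, 36, 40, 50, 60, 70, 80, 90, 12, 18]
        event = [1, 1, 1, 1, 0, 0, 0, 1, 0, 0, 0, 0]
        cohort = make_cohort(time, event)
        rng = np.random.default_rng(7)
        s = pd.Series(np.round(rng.normal(size=12), 1), index=cohort.sample_ids)
        auc, _ = ev.horizon_roc(s, cohort, horizon=36)
        cases = np.array([True] * 4 + [False] * 6 + [False] * 2)
        ctrls = np.array([False] * 4 + [True] * 6 + [False] * 2)
        wins = sum(
            1.0 if sc > sn else 0.5 if sc == sn else 0.0
            for sc in s[cases]
            for sn in s[ctrls]
        )
        assert auc == pytest.approx(wins / (4 * 6))

    def test_no_cases_rejected(self):
        cohort = make_cohort([100, 120], [0, 0])
        with pytest.raises(ValueError):
            ev.horizon_roc(pd.Series([1.0, 2.0], index=cohort.sample_ids), cohort, 36)


class TestCalibration:
    @staticmethod
    def _true_model_cohort(seed=1, n=600):
        cfg = BulkSimConfig(
            n_samples=n, n_genes=6, prognostic_genes={"G0001": 0.7},
            censoring_rate=0.004, seed=seed,
        )
        expr, cohort, truth = simulate_bulk(cfg)
        x = expr.loc["G0001"]
        lp = 0.7 * (x - x.mean())
        true_surv = np.exp(-cfg.baseline_hazard * np.exp(lp) * 36.0)
        return cohort, pd.Series(true_surv, index=cohort.sample_ids)

    def test_true_model_predictions_calibrated(self):
        cohort, pred = self._true_model_cohort()
        bins = ev.calibration(pred, cohort, horizon=36.0)
        within_ci = bins["predicted"].between(bins["ci_low"], bins["ci_high"])
        assert within_ci.sum() >= 8

    def test_constant_prediction_single_bin(self):
        cohort = make_cohort(np.linspace(5, 100, 30), np.ones(30, int))
        pred = pd.Series(0.5, index=cohort.sample_ids)
        bins = ev.calibration(pred, cohort, horizon=36.0)
        assert len(bins) == 1
        km = km_estimate(cohort.clinical["os_time"].to_numpy(), np.ones(30, int))
        assert bins["observed"].iloc[0] == pytest.approx(km_survival_at(km, 36.0)[0])

    def test_anticorrelated_predictions_detected(self):
        cohort, pred = self._true_model_cohort(seed=3)
        bins = ev.calibration(1.0 - pred, cohort, horizon=36.0)
        slope = linregress(bins["predicted"], bins["observed"]).slope
        assert slope < 0

    def test_out_of_range_predictions_rejected(self):
        cohort = make_cohort([1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError):
            ev.calibration(pd.Series([0.5, 1.2, 0.1], index=cohort.sample_ids), cohort, 36.0)


class TestDecisionCurve:
    def test_treat_none_is_zero_and_treat_all_closed_form(self):
        rng = np.random.default_rng(2)
        n = 40
        t = rng.exponential(50, n)
        e = (rng.random(n) < 0.8).astype(int)
        cohort = make_cohort(t, e)
        pred = pd.Series(rng.random(n), index=cohort.sample_ids)
        dca = ev.decision_curve(pred, cohort, horizon=36.0)
        assert (dca["treat_none"] == 0).all()
        cases, controls = ev._horizon_case_control(t, e, 36.0)
        keep = cases | controls
        prev = cases[keep].mean()
        pt = dca["threshold"]
        assert np.allclose(dca["treat_all"], prev - (1 - prev) * pt / (1 - pt))

    def test_hand_computed_net_benefit(self):
        # 20 evaluable samples: 8 cases, 12 controls; predictions above 0.2
        # for 6 cases (TP) and 3 controls (FP):
        # nb = 6/20 - (3/20) * 0.25 = 0.2625
        time = [10] * 8 + [80] * 12
        event = [1] * 8 + [0] * 12
        cohort = make_cohort(time, event)
        pred = pd.Series([0.9] * 6 + [0.1] * 2 + [0.6] * 3 + [0.05] * 9,
                         index=cohort.sample_ids)
        dca = ev.decision_curve(pred, cohort, horizon=36.0, thresholds=[0.2])
        assert dca["net_benefit"].iloc[0] == pytest.approx(6 / 20 - (3 / 20) * (0.2 / 0.8))

    def test_invalid_thresholds_rejected(self):
        cohort = make_cohort([10, 80], [1, 0])
        with pytest.raises(ValueError):
            ev.decision_curve(pd.Series([0.5, 0.5], index=cohort.sample_ids),
                              cohort, 36.0, thresholds=[0.0, 0.5])


class TestNomogram:
    @staticmethod
    def _cohort(seed=2, n=400):
        cfg = BulkSimConfig(
            n_samples=n, n_genes=8, prognostic_genes={"G0002": 0.6},
            covariates=CovariateSpec(age_beta=0.02, stage_beta=0.4),
            censoring_rate=0.004, seed=seed,
        )
        expr, cohort, _ = simulate_bulk(cfg)
        scores = pd.Series(expr.loc["G0002"].to_numpy(), index=cohort.sample_ids)
        return cohort, scores

    def test_zero_coefficient_term_gets_zero_points(self):
        cohort, scores = self._cohort()
        nom = ev.build_nomogram(cohort, scores)
        nom.terms.loc["sex_male", "coef"] = 0.0
        nom.terms.loc["sex_male", "min_contrib"] = 0.0
        nom.terms.loc["sex_male", "max_contrib"] = 0.0
        for level in (0.0, 1.0):
            pts = nom.points({"risk_score": 0, "age": 0, "sex_male": level, "stage_iii_iv": 0})
            assert pts["sex_male"] == 0.0

    def test_five_year_never_exceeds_three_year(self):
        cohort, scores = self._cohort()
        nom = ev.build_nomogram(cohort, scores)
        for total in np.linspace(0, 300, 13):
            assert nom.predict_survival(total, 60.0) <= nom.predict_survival(total, 36.0) + 1e-12

    def test_round_trip_against_cox_prediction(self):
        cohort, scores = self._cohort()
        nom = ev.build_nomogram(cohort, scores)
        design = ev._prepare_covariates(cohort, ["age", "sex", "stage"])
        design.insert(0, "risk_score", scores)
        df = pd.DataFrame({
            "time": cohort.clinical["os_time"], "event": cohort.clinical["os_event"],
        }).join(design)
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        direct = cph.predict_survival_function(design, times=[36.0]).iloc[0]
        for sid in cohort.sample_ids[:40]:
            pred = nom.predict(design.loc[sid].to_dict())
            assert abs(pred["survival_36m"] - direct[sid]) <= 0.02


class TestEvaluate:
    @staticmethod
    def _fitted_and_validation():
        common = dict(n_genes=15, prognostic_genes={"G0004": 0.7, "G0009": -0.6},
                      gene_param_seed=31, censoring_rate=0.006)
        _, train, _ = simulate_bulk(BulkSimConfig(n_samples=350, seed=1, **common))
        _, val, _ = simulate_bulk(BulkSimConfig(n_samples=350, seed=2, **common))
        _, model = rm.lasso_cox(train, list(train.expression.index), seed=1)
        model.cutoff = rm.find_cutoff(rm.risk_score(model, train.expression), train)
        return model, val

    def test_model_transfers_to_validation_cohort(self):
        model, val = self._fitted_and_validation()
        report = ev.evaluate(model, val)
        assert report.hazard_ratio > 1.0
        assert report.logrank_p < 0.05
        assert report.cutoff_source == "model"
        assert sum(report.group_sizes.values()) == val.n_samples

    def test_determinism_of_report_json(self):
        model, val = self._fitted_and_validation()
        r1 = ev.evaluate(model, val).to_json()
        r2 = ev.evaluate(model, val).to_json()
        assert r1 == r2

    def test_missing_dfs_columns_rejected(self):
        model, val = self._fitted_and_validation()
        with pytest.raises(ValueError, match="DFS"):
            ev.evaluate(model, val, endpoint="dfs")

    def test_empty_subgroup_rejected(self):
        model, val = self._fitted_and_validation()
        val.clinical["chemo"] = 0  # nobody treated
        with pytest.raises(ValueError, match="empty"):
            ev.evaluate(model, val, subgroup="chemo")

    def test_dfs_and_subgroup_paths(self):
        common = dict(n_genes=10, prognostic_genes={"G0002": 0.8},
                      gene_param_seed=32, with_dfs=True)
        _, train, _ = simulate_bulk(BulkSimConfig(n_samples=400, seed=3, **common))
        model = rm.RiskModel(genes=["G0002"], coefficients=[0.8])
        model.cutoff = rm.find_cutoff(rm.risk_score(model, train.expression), train)
        rep_dfs = ev.evaluate(model, train, endpoint="dfs")
        assert rep_dfs.endpoint == "dfs" and np.isfinite(rep_dfs.hazard_ratio)
        rep_naive = ev.evaluate(model, train, subgroup="chemo-naive")
        assert rep_naive.n_samples == (train.clinical["chemo"] == 0).sum()
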