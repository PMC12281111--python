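import numpy as np
import pandas as pd
import pytest

from causalreport import (
    CausalQuery,
    estimate_propensity,
    fit_iptw,
    fit_outcome_regression,
    fit_s_standardization,
    fit_t_standardization,
    fit_tmle,
    run_all_estimators,
    validate_query,
)
from causalreport.estimators import PropensityFit
from causalreport.exceptions import ArmSizeError, CollinearityError, EstimationError
from causalreport.query import ESTIMATOR_ORDER
from causalreport.simulate import default_query, generate, make_scenario

from conftest import stratum_ate


def _validated(table, **kw):
    kw.setdefault("bootstrap_reps", 50)
    data = validate_query(CausalQuery(**kw), table)
    return data, data.query


class TestPropensity:
    def test_intercept_only_equals_exposure_proportion(self):
        table = pd.DataFrame({"y": np.arange(10.0), "a": [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]})
        data, q = _validated(table, outcome_name="y", exposure_name="a")
        ps = estimate_propensity(data, q)
        assert np.allclose(ps.scores, 0.4, atol=1e-9)

    def test_scores_concentrate_under_randomization(self):
        scen = make_scenario("randomized", n=50_000, seed=5)
        df, _ = generate(scen)
        data = validate_query(default_query(scen), df)
        ps = estimate_propensity(data, data.query)
        assert np.max(np.abs(ps.scores - df["A"].mean())) < 0.03

    def test_bounding(self, big_linear_run):
        data, q = big_linear_run
        ps = estimate_propensity(data, q)
        assert ps.bounded_scores.min() >= q.ps_bound
        assert ps.bounded_scores.max() <= 1 - q.ps_bound
        assert (ps.scores >= 0).all() and (ps.scores <= 1).all()

    def test_separation_recorded_not_fatal(self):
        # x perfectly predicts a -> logistic separation
        table = pd.DataFrame(
            {
                "y": np.arange(8.0),
                "a": [0, 0, 0, 0, 1, 1, 1, 1],
                "x": [-2.0, -1.5, -1.0, -0.5, 0.5, 1.0, 1.5, 2.0],
            }
        )
        data, q = _validated(table, outcome_name="y", exposure_name="a", adjustment_set=("x",))
        ps = estimate_propensity(data, q)
        assert len(ps.scores) == 8
        assert not ps.converged or ps.warnings


class TestOutcomeRegression:
    def test_matches_hand_solved_normal_equations(self, toy4):
        data, q = _validated(
            toy4, outcome_name="y", exposure_name="a", adjustment_set=("w",)
        )
        X = np.column_stack([np.ones(4), toy4["a"], toy4["w"]])
        beta = np.linalg.solve(X.T @ X, X.T @ toy4["y"].to_numpy())
        est = fit_outcome_regression(data, q)
        assert est.estimate == pytest.approx(beta[1], abs=1e-10)

    def test_unbiased_under_randomized_null(self):
        scen = make_scenario("randomized", n=100_000, seed=21, tau=0.0)
        df, _ = generate(scen)
        data = validate_query(default_query(scen), df)
        est = fit_outcome_regression(data, data.query)
        assert abs(est.estimate) < 3 * est.se

    def test_collinear_columns_named(self, linear_run):
        data, q, _ = linear_run
        df = data.df.assign(w1_copy=data.df["w1"])
        q2 = CausalQuery(
            "Y", "A", ("w1", "w2", "w3", "w4", "w5", "w1_copy"), seed=q.seed
        )
        data2 = validate_query(q2, df)
        with pytest.raises(CollinearityError, match="w1_copy"):
            fit_outcome_regression(data2, data2.query)

    def test_binomial_reports_risk_difference(self):
        scen = make_scenario("binary_outcome", n=1500, seed=9)
        df, truth = generate(scen)
        q = default_query(scen, bootstrap_reps=60)
        data = validate_query(q, df)
        est = fit_outcome_regression(data, data.query)
        assert -1.0 <= est.estimate <= 1.0
        assert est.inference == "bootstrap"
        # in a rich-enough sample the RD is in the oracle's vicinity
        assert est.estimate == pytest.approx(truth["true_ate"], abs=0.1)


class TestIptw:
    def test_constant_scores_reduce_to_mean_difference(self, toy4):
        data, q = _validated(
            toy4, outcome_name="y", exposure_name="a", adjustment_set=("w",)
        )
        n = len(toy4)
        ps = PropensityFit(
            scores=np.full(n, 0.5),
            bounded_scores=np.full(n, 0.5),
            model_coefficients=pd.Series(dtype=float),
            bound=0.025,
        )
        est = fit_iptw(data, q, ps)
        diff = toy4.loc[toy4.a == 1, "y"].mean() - toy4.loc[toy4.a == 0, "y"].mean()
        assert est.estimate == pytest.approx(diff, abs=1e-12)

    def test_weight_sums_recover_sample_size(self, big_linear_run):
        data, q = big_linear_run
        ps = estimate_propensity(data, q)
        a = data.exposure_indicator
        n = len(a)
        assert np.sum(a / ps.bounded_scores) == pytest.approx(n, rel=0.10)
        assert np.sum((1 - a) / (1 - ps.bounded_scores)) == pytest.approx(n, rel=0.10)

    def test_matches_stratum_formula_on_saturated_confounder(self, saturated_table):
        data, q = _validated(
            saturated_table, outcome_name="y", exposure_name="a", adjustment_set=("w",)
        )
        ps = estimate_propensity(data, q)
        est = fit_iptw(data, q, ps)
        assert est.estimate == pytest.approx(stratum_ate(saturated_table), abs=1e-10)


class TestStandardization:
    def test_s_collapses_to_regression_coefficient(self, linear_run):
        data, q, _ = linear_run
        s = fit_s_standardization(data, q)
        reg = fit_outcome_regression(data, q)
        assert s.estimate == pytest.approx(reg.estimate, abs=1e-10)

    def test_t_handles_constant_outcome(self):
        table = pd.DataFrame(
            {"y": [5.0] * 12, "a": [0, 1] * 6, "w": list(range(12))}
        )
        data, q = _validated(
            table, outcome_name="y", exposure_name="a", adjustment_set=("w",)
        )
        assert fit_t_standardization(data, q).estimate == pytest.approx(0.0, abs=1e-12)

    def test_small_arm_rejected_with_arm_name(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            {
                "y": rng.standard_normal(40),
                "a": [1] * 3 + [0] * 37,
                "w1": rng.standard_normal(40),
                "w2": rng.standard_normal(40),
                "w3": rng.standard_normal(40),
            }
        )
        data, q = _validated(
            table,
            outcome_name="y",
            exposure_name="a",
            adjustment_set=("w1", "w2", "w3"),
        )
        with pytest.raises(ArmSizeError, match="treated"):
            fit_t_standardization(data, q)

    def test_both_match_stratum_formula_on_saturated_confounder(self, saturated_table):
        data, q = _validated(
            saturated_table, outcome_name="y", exposure_name="a", adjustment_set=("w",)
        )
        oracle = stratum_ate(saturated_table)
        assert fit_s_standardization(data, q).estimate == pytest.approx(oracle, abs=1e-10)
        assert fit_t_standardization(data, q).estimate == pytest.approx(oracle, abs=1e-10)


class TestTmle:
    def test_influence_curve_mean_zero(self, linear_run):
        data, q, _ = linear_run
        ps = estimate_propensity(data, q)
        _, comp = fit_tmle(data, q, ps)
        assert abs(np.mean(comp.influence_curve)) <= 1e-8

    def test_targeted_predictions_stay_in_unit_interval(self, linear_run):
        data, q, _ = linear_run
        ps = estimate_propensity(data, q)
        _, comp = fit_tmle(data, q, ps)
        assert ((comp.targeted_q1 > 0) & (comp.targeted_q1 < 1)).all()
        assert ((comp.targeted_q0 > 0) & (comp.targeted_q0 < 1)).all()

    def test_recovers_tau_within_3_se(self):
        scen = make_scenario("linear", n=20_000, seed=13)
        df, truth = generate(scen)
        data = validate_query(default_query(scen), df)
        ps = estimate_propensity(data, data.query)
        est, _ = fit_tmle(data, data.query, ps)
        assert abs(est.estimate - truth["true_ate"]) < 3 * est.se

    def test_constant_outcome_rejected(self):
        table = pd.DataFrame({"y": [2.0] * 10, "a": [0, 1] * 5})
        data, q = _validated(table, outcome_name="y", exposure_name="a")
        ps = estimate_propensity(data, q)
        from causalreport.exceptions import DegenerateOutcomeError

        with pytest.raises(DegenerateOutcomeError):
            fit_tmle(data, q, ps)


class TestRunAll:
    def test_fixed_order_and_extremes(self, linear_run):
        data, q, _ = linear_run
        out = run_all_estimators(data, q)
        assert tuple(e.method for e in out.effects) == ESTIMATOR_ORDER
        points = [e.estimate for e in out.effects]
        assert out.min_estimate == min(points)
        assert out.max_estimate == max(points)
        assert out.tmle_components is not None

    def test_seeded_determinism(self, linear_run):
        data, q, _ = linear_run
        out1 = run_all_estimators(data, q)
        out2 = run_all_estimators(data, q)
        for e1, e2 in zip(out1.effects, out2.effects):
            assert e1 == e2

    def test_randomization_limit_empty_adjustment_set(self, linear_run):
        data, _, _ = linear_run
        q0 = CausalQuery("Y", "A", (), bootstrap_reps=40, seed=2)
        data0 = validate_query(q0, data.df)
        out = run_all_estimators(
            data0,
            data0.query,
            estimators=("outcome_regression", "iptw", "s_standardization", "t_standardization"),
        )
        df = data.df
        diff = df.loc[df.A == 1, "Y"].mean() - df.loc[df.A == 0, "Y"].mean()
        for e in out.effects:
            assert e.estimate == pytest.approx(diff, abs=1e-10), e.method

    def test_subset_and_unknown_estimator(self, linear_run):
        data, q, _ = linear_run
        out = run_all_estimators(data, q, estimators=("iptw",))
        assert [e.method for e in out.effects] == ["iptw"]
        with pytest.raises(EstimationError, match="unknown"):
            run_all_estimators(data, q, estimators=("magic",))
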