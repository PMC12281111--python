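import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from causalreport import (
    CausalQuery,
    balance_table,
    estimate_propensity,
    overlap_data,
    ps_summary,
    smd,
    validate_query,
)
from causalreport.estimators import PropensityFit
from causalreport.simulate import default_query, generate, make_scenario


def _constant_ps(n, value=0.5):
    return PropensityFit(
        scores=np.full(n, value),
        bounded_scores=np.full(n, value),
        model_coefficients=pd.Series(dtype=float),
        bound=0.025,
    )


class TestSmd:
    def test_hand_computed_example(self):
        # treated {1,2,3}: mean 2, var 1; control {2,3,4}: mean 3, var 1
        # d = (2 - 3) / sqrt((1 + 1) / 2) = -1
        x = np.array([1.0, 2.0, 3.0, 2.0, 3.0, 4.0])
        arms = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        assert smd(x, arms) == pytest.approx(-1.0, abs=1e-12)

    def test_formula_evaluation(self):
        # treated [0,2]: m=1, s2=2; control [-1,1]: m=0, s2=2 -> d=1/sqrt(2)
        x = np.array([0.0, 2.0, -1.0, 1.0])
        arms = np.array([1, 1, 0, 0], dtype=bool)
        assert smd(x, arms) == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_identical_distributions_give_zero(self):
        x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        arms = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        assert smd(x, arms) == 0.0

    def test_sign_flips_with_labels_magnitude_invariant(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(30)
        arms = rng.integers(0, 2, 30).astype(bool)
        assert smd(x, arms) == pytest.approx(-smd(x, ~arms), abs=1e-12)

    def test_constant_covariate_returns_zero(self):
        x = np.ones(10)
        arms = np.array([1] * 5 + [0] * 5, dtype=bool)
        assert smd(x, arms) == 0.0

    def test_single_arm_rejected(self):
        with pytest.raises(ValueError):
            smd(np.ones(4), np.ones(4, dtype=bool))

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_invariant_to_weight_rescaling(self, c):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(40)
        arms = np.array([1, 0] * 20, dtype=bool)
        w = rng.uniform(0.5, 2.0, 40)
        assert smd(x, arms, w) == pytest.approx(smd(x, arms, c * w), rel=1e-9)


class TestPsSummary:
    def test_constant_scores(self):
        table = pd.DataFrame({"y": np.arange(8.0), "a": [0, 1] * 4})
        data = validate_query(CausalQuery("y", "a"), table)
        summary = ps_summary(_constant_ps(8), data, data.query)
        assert summary.label == "PS range for 1"
        for _, row in summary.table.iterrows():
            assert (row["min"], row["max"]) == (0.5, 0.5)

    def test_bounds_within_score_range(self, big_linear_run):
        data, q = big_linear_run
        ps = estimate_propensity(data, q)
        summary = ps_summary(ps, data, q)
        assert summary.table["min"].min() >= ps.scores.min()
        assert summary.table["max"].max() <= ps.scores.max()
        assert list(summary.table.index) == [q.reference_level, q.exposure_level]

    def test_poor_overlap_detected(self):
        scen = make_scenario("poor_overlap", n=5000, seed=17)
        df, _ = generate(scen)
        data = validate_query(default_query(scen), df)
        ps = estimate_propensity(data, data.query)
        summary = ps_summary(ps, data, data.query)
        assert (summary.table["min"] < 0.01).any() or (summary.table["max"] > 0.99).any()

    def test_uses_unbounded_scores(self):
        scen = make_scenario("poor_overlap", n=5000, seed=17)
        df, _ = generate(scen)
        data = validate_query(default_query(scen), df)
        ps = estimate_propensity(data, data.query)
        summary = ps_summary(ps, data, data.query)
        # truncation would clamp these at the bound; diagnostics must not
        assert summary.table["min"].min() < ps.bound


class TestBalanceTable:
    def test_empty_adjustment_set(self):
        table = pd.DataFrame({"y": np.arange(8.0), "a": [0, 1] * 4})
        data = validate_query(CausalQuery("y", "a"), table)
        ps = estimate_propensity(data, data.query)
        assert len(balance_table(data, data.query, ps)) == 0

    def test_categorical_covariate_has_level_rows(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(
            {
                "y": rng.standard_normal(60),
                "a": rng.integers(0, 2, 60),
                "g": rng.choice(["lo", "mid", "hi"], 60),
            }
        )
        data = validate_query(CausalQuery("y", "a", ("g",)), table)
        ps = estimate_propensity(data, data.query)
        bal = balance_table(data, data.query, ps)
        assert len(bal) == 2  # k - 1 rows for k = 3 levels
        assert set(bal["covariate"]) == {"g[lo]", "g[mid]"}  # "hi" is reference

    def test_true_model_weighting_improves_balance(self, big_linear_run):
        data, q = big_linear_run
        ps = estimate_propensity(data, q)
        bal = balance_table(data, q, ps)
        assert bal["smd_weighted"].abs().max() < bal["smd_raw"].abs().max()
        assert bal["smd_weighted"].abs().max() < 0.05
        assert not bal["imbalanced_weighted"].any()

    def test_flags_follow_threshold(self, big_linear_run):
        data, q = big_linear_run
        ps = estimate_propensity(data, q)
        bal = balance_table(data, q, ps)
        assert (bal["imbalanced_raw"] == (bal["smd_raw"].abs() > 0.1)).all()


class TestOverlap:
    def test_constant_scores_fill_one_bin(self):
        table = pd.DataFrame({"y": np.arange(8.0), "a": [0, 1] * 4})
        data = validate_query(CausalQuery("y", "a"), table)
        ov = overlap_data(_constant_ps(8), data, data.query, n_bins=10)
        for counts in ov.counts.values():
            assert (counts > 0).sum() == 1

    def test_counts_conserve_group_sizes(self, big_linear_run):
        data, q = big_linear_run
        ps = estimate_propensity(data, q)
        ov = overlap_data(ps, data, q)
        a = data.exposure_indicator
        assert ov.counts[q.exposure_level].sum() == a.sum()
        assert ov.counts[q.reference_level].sum() == (1 - a).sum()

    def test_shared_bins_span_unit_interval(self, big_linear_run):
        data, q = big_linear_run
        ps = estimate_propensity(data, q)
        ov = overlap_data(ps, data, q, n_bins=25)
        assert ov.bin_edges[0] == 0.0 and ov.bin_edges[-1] == 1.0
        assert len(ov.bin_edges) == 26

    def test_well_overlapped_bins_contain_both_arms(self, big_linear_run):
        # every bin carrying a non-negligible share of units (>= 0.1% of n)
        # holds units from both arms when the design is well overlapped
        data, q = big_linear_run
        ps = estimate_propensity(data, q)
        ov = overlap_data(ps, data, q, n_bins=10)
        c0 = ov.counts[q.reference_level]
        c1 = ov.counts[q.exposure_level]
        floor = 0.001 * len(data.df)
        substantial = (c0 + c1) >= floor
        assert (c0[substantial] > 0).all() and (c1[substantial] > 0).all()

    def test_minimum_bins(self, big_linear_run):
        data, q = big_linear_run
        ps = estimate_propensity(data, q)
        with pytest.raises(ValueError):
            overlap_data(ps, data, q, n_bins=1)
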