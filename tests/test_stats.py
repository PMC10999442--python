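"""Transformations, assumption checks, factorial/mixed models, correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ovitherm import (
    ModelSpec,
    check_assumptions,
    correlation_matrix,
    fit_factorial,
    fit_mixed_periods,
    inverse_transform,
    transform_variable,
)


class TestTransforms:
    @pytest.mark.parametrize(
        "name,value,expected",
        [("oxy_pre", 1.0, 0.0),       # ln 1
         ("prolactin", 4.0, 0.25),    # reciprocal
         ("dhea", 4.0, 0.5),          # 1/sqrt
         ("cortisol", 7.5, 7.5)],     # identity
    )
    def test_name_driven_mapping(self, name, value, expected):
        res = transform_variable(name, [value])
        assert res.values[0] == pytest.approx(expected)

    def test_domain_violations_flagged_not_dropped(self):
        res = transform_variable("oxy_post", [1.0, 0.0, -2.0, 3.0])
        assert res.excluded == [1, 2]
        assert np.isnan(res.values[1]) and np.isnan(res.values[2])
        assert res.values[3] == pytest.approx(np.log(3.0))

    @settings(derandomize=True, deadline=None)
    @given(st.lists(st.floats(1e-3, 1e3), min_size=1, max_size=20),
           st.sampled_from(["oxy_pre", "prolactin", "dhea", "ibt_lwt"]))
    def test_back_transform_recovers_input(self, values, name):
        res = transform_variable(name, values)
        back = inverse_transform(name, res.values)
        assert np.allclose(back, values, rtol=1e-12, atol=1e-12)


class TestCheckAssumptions:
    def test_normal_residuals_pass_skewed_fail(self, rng):
        groups = np.repeat(["a", "b"], 150)
        normal = rng.normal(0, 1, 300) + (groups == "b") * 2.0
        d = check_assumptions(normal, groups)
        assert d.shapiro_p > 0.001 and not d.flagged
        skewed = rng.exponential(1.0, 300)
        d2 = check_assumptions(skewed, groups)
        assert d2.shapiro_p < 0.001

    def test_unequal_variances_detected_by_bartlett(self, rng):
        groups = np.repeat(["a", "b"], 100)
        vals = np.concatenate([rng.normal(0, 1, 100), rng.normal(0, 4, 100)])
        d = check_assumptions(vals, groups)
        assert d.bartlett_p < 1e-6

    def test_constant_data_flagged(self):
        d = check_assumptions(np.ones(10), np.repeat(["a", "b"], 5))
        assert d.flagged and "constant" in d.flag_reason

    def test_tiny_group_flagged(self):
        d = check_assumptions([1.0, 2.0, 3.0, 4.0], ["a", "a", "a", "b"])
        assert d.flagged


def _balanced_2x2x2(rng, effects=None, n_cell=4, sigma=1.0):
    effects = effects or {}
    rows = []
    for g, s, t in itertools.product("AB", "12", "xy"):
        cell_mean = (10.0 + effects.get("g", 0) * (g == "B")
                     + effects.get("s", 0) * (s == "2")
                     + effects.get("t", 0) * (t == "y")
                     + effects.get("gs", 0) * ((g == "B") & (s == "2")))
        for _ in range(n_cell):
            rows.append({"group": g, "session": s, "time": t,
                         "y": cell_mean + rng.normal(0, sigma)})
    return pd.DataFrame(rows)


class TestFitFactorial:
    def test_sum_of_squares_identity_on_balanced_design(self, rng):
        data = _balanced_2x2x2(rng, {"g": 2.0, "s": 1.0})
        spec = ModelSpec(outcome="y", fixed_factors=["group", "session", "time"],
                         pruning=False, transform="none")
        res = fit_factorial(spec, data)
        y = data["y"].to_numpy()
        ss_total = float(((y - y.mean()) ** 2).sum())
        # recover each term's SS from its F statistic (SS_term = F q MSE) and
        # solve for MSE via the identity ss_total = sum(SS_terms) + MSE df_den,
        # which only holds if the balanced decomposition is orthogonal
        df_den = res.terms["df_den"].iloc[0]
        denom = float((res.terms["F"] * res.terms["df_num"]).sum() + df_den)
        mse = ss_total / denom
        ss_terms = (res.terms["F"] * res.terms["df_num"] * mse).sum()
        ss_resid = mse * df_den
        assert ss_terms + ss_resid == pytest.approx(ss_total, rel=1e-9)

    def test_two_group_f_matches_one_way_anova(self, rng):
        import scipy.stats
        data = pd.DataFrame({
            "group": np.repeat(["lo", "hi"], 9),
            "y": rng.normal(0, 1, 18) + np.repeat([0.0, 1.0], 9),
        })
        spec = ModelSpec(outcome="y", fixed_factors=["group"], transform="none")
        res = fit_factorial(spec, data)
        F, p = scipy.stats.f_oneway(data.y[data.group == "lo"],
                                    data.y[data.group == "hi"])
        row = res.terms.iloc[0]
        assert row["F"] == pytest.approx(F, rel=1e-9)
        assert row["p"] == pytest.approx(p, rel=1e-9)

    def test_additive_truth_prunes_all_interactions(self, rng):
        data = _balanced_2x2x2(rng, {"g": 3.0, "s": 2.0, "t": 1.5},
                               n_cell=8, sigma=0.5)
        spec = ModelSpec(outcome="y", fixed_factors=["group", "session", "time"],
                         transform="none")
        res = fit_factorial(spec, data)
        kept = set(res.terms["term"])
        assert kept == {"group", "session", "time"}
        assert len(res.pruned_terms) == 4  # three 2-way + one 3-way

    def test_strong_interaction_is_retained(self, rng):
        data = _balanced_2x2x2(rng, {"g": 1.0, "gs": 5.0}, n_cell=10, sigma=0.3)
        spec = ModelSpec(outcome="y", fixed_factors=["group", "session"],
                         transform="none")
        res = fit_factorial(spec, data)
        assert "group:session" in set(res.terms["term"])
        assert res.terms.set_index("term").loc["group:session", "p"] < 0.05

    def test_pairwise_contrast_equals_cell_mean_difference_when_balanced(self, rng):
        data = _balanced_2x2x2(rng, {"g": 2.5}, n_cell=6)
        spec = ModelSpec(outcome="y", fixed_factors=["group", "session", "time"],
                         pruning=False, transform="none")
        res = fit_factorial(spec, data)
        row = res.pairwise.query("factor == 'group'").iloc[0]
        diff = data.groupby("group")["y"].mean()
        expected = diff["A"] - diff["B"]
        assert row["estimate"] == pytest.approx(expected, rel=1e-9)

    def test_bonferroni_adjustment_matches_bruteforce(self, rng):
        data = pd.DataFrame({
            "group": np.repeat(["a", "b", "c", "d"], 6),
            "y": rng.normal(0, 1, 24),
        })
        spec = ModelSpec(outcome="y", fixed_factors=["group"], transform="none")
        res = fit_factorial(spec, data)
        m = len(res.pairwise)
        assert m == 6
        for _, r in res.pairwise.iterrows():
            assert r["p_adj"] == pytest.approx(min(1.0, m * r["p_raw"]), rel=1e-12)

    def test_outcome_transform_applied_by_name(self, rng):
        data = pd.DataFrame({
            "group": np.repeat(["a", "b"], 10),
            "prolactin": rng.uniform(50, 400, 20),
        })
        spec = ModelSpec(outcome="prolactin", fixed_factors=["group"])
        res = fit_factorial(spec, data)
        assert res.transformation == "reciprocal"

    def test_saturated_model_rejected(self):
        data = pd.DataFrame({"group": ["a", "b"], "y": [1.0, 2.0]})
        spec = ModelSpec(outcome="y", fixed_factors=["group"], transform="none")
        with pytest.raises(ValueError, match="residual degrees of freedom"):
            fit_factorial(spec, data)

    def test_null_rejection_rate_is_calibrated(self, rng):
        hits = 0
        reps = 200
        for _ in range(reps):
            data = pd.DataFrame({"group": np.repeat(["lo", "hi"], 9),
                                 "y": rng.normal(0, 1, 18)})
            spec = ModelSpec(outcome="y", fixed_factors=["group"],
                             transform="none")
            res = fit_factorial(spec, data)
            hits += res.terms["p"].iloc[0] < 0.05
        # binomial(200, 0.05): central 99.9% range
        assert 1 <= hits <= 22


def _period_frame(rng, n_animals=8, effects=None, sigma=0.05):
    effects = effects or {}
    rows = []
    for a in range(n_animals):
        intercept = 0.30 + rng.normal(0, 0.03)
        for p in ("P1", "P2", "P3", "P4", "P5"):
            rows.append({"animal_id": f"a{a:02d}", "period": p,
                         "value": intercept + effects.get(p, 0.0)
                         + rng.normal(0, sigma)})
    return pd.DataFrame(rows)


class TestFitMixedPeriods:
    def test_identical_values_give_zero_contrasts(self):
        frame = _period_frame(np.random.default_rng(0), sigma=0.0)
        res = fit_mixed_periods(frame)
        assert np.allclose(res.pairwise["estimate"], 0.0, atol=1e-10)

    def test_programmed_p4_elevation_recovered_and_significant(self, rng):
        frame = _period_frame(rng, effects={"P4": 0.2})
        res = fit_mixed_periods(frame)
        row = res.pairwise.query("level_a == 'P4' and level_b == 'P1'").iloc[0]
        assert row["estimate"] == pytest.approx(0.2, abs=0.06)
        assert row["p_adj"] < 0.01
        assert res.terms["p"].iloc[0] < 0.01

    def test_balanced_fixed_effects_equal_cell_mean_contrasts(self, rng):
        frame = _period_frame(rng, effects={"P2": 0.1})
        res = fit_mixed_periods(frame)
        cell = frame.groupby("period")["value"].mean()
        row = res.pairwise.query("level_a == 'P2' and level_b == 'P1'").iloc[0]
        assert row["estimate"] == pytest.approx(cell["P2"] - cell["P1"],
                                                abs=1e-6)

    def test_fdr_adjustment_matches_bruteforce_benjamini_hochberg(self, rng):
        frame = _period_frame(rng, effects={"P3": 0.05, "P4": 0.15})
        res = fit_mixed_periods(frame)
        praw = res.pairwise["p_raw"].to_numpy()
        m = len(praw)
        order = np.argsort(praw)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, praw[i] * m / (rank + 1))
            adj[i] = running
        assert np.allclose(res.pairwise["p_adj"], adj, rtol=1e-12)
        # monotone in raw p
        s = res.pairwise.sort_values("p_raw")
        assert (np.diff(s["p_adj"]) >= -1e-15).all()

    def test_single_animal_degenerates_with_warning(self):
        one = _period_frame(np.random.default_rng(1), n_animals=1, sigma=0.01)
        two = _period_frame(np.random.default_rng(2), n_animals=1, sigma=0.01)
        frame = pd.concat([one, two], ignore_index=True)  # replicate measures
        res = fit_mixed_periods(frame)
        assert any("single animal" in w for w in res.warnings)

    def test_single_animal_saturated_design_rejected(self):
        frame = _period_frame(np.random.default_rng(1), n_animals=1, sigma=0.01)
        with pytest.raises(ValueError, match="no residual degrees"):
            fit_mixed_periods(frame)

    def test_fewer_than_two_periods_rejected(self):
        frame = pd.DataFrame({"animal_id": ["a", "b"], "period": ["P1", "P1"],
                              "value": [1.0, 2.0]})
        with pytest.raises(ValueError, match="two periods"):
            fit_mixed_periods(frame)


class TestCorrelationMatrix:
    def test_perfect_linear_and_antilinear(self):
        x = np.arange(10, dtype=float)
        table = pd.DataFrame({"animal_id": [f"a{i}" for i in range(10)],
                              "x": x, "y": 2 * x + 1, "z": -x})
        corr = correlation_matrix(table)
        assert corr.r.loc["x", "y"] == pytest.approx(1.0)
        assert corr.r.loc["x", "z"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(corr.r), 1.0)
        assert np.allclose(corr.r, corr.r.T, equal_nan=True)

    def test_listwise_exclusion_of_incomplete_animals(self, rng):
        table = pd.DataFrame({"animal_id": [f"a{i}" for i in range(8)],
                              "x": rng.normal(size=8),
                              "y": rng.normal(size=8)})
        table.loc[2, "y"] = np.nan
        corr = correlation_matrix(table)
        assert corr.n == 7
        assert corr.excluded_animals == ["a2"]

    def test_zero_variance_variable_reported_undefined(self, rng):
        table = pd.DataFrame({"animal_id": list("abcde"),
                              "x": rng.normal(size=5),
                              "c": np.ones(5)})
        corr = correlation_matrix(table)
        assert corr.undefined == ["c"]
        assert np.isnan(corr.r.loc["x", "c"])

    def test_null_simulation_mean_r_near_zero(self, rng):
        rs, hits = [], 0
        for _ in range(200):
            table = pd.DataFrame({"animal_id": [f"a{i}" for i in range(10)],
                                  "x": rng.normal(size=10),
                                  "y": rng.normal(size=10)})
            corr = correlation_matrix(table)
            rs.append(corr.r.loc["x", "y"])
            hits += corr.p.loc["x", "y"] < 0.05
        assert abs(np.mean(rs)) < 0.08
        assert 1 <= hits <= 25

    def test_too_few_complete_animals_rejected(self):
        table = pd.DataFrame({"animal_id": ["a", "b"], "x": [1.0, 2.0],
                              "y": [2.0, 1.0]})
        with pytest.raises(ValueError, match="at least 3"):
            correlation_matrix(table)
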