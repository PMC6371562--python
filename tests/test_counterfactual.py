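import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from unmetneed import DGPConfig, generate_synthetic_survey
from unmetneed.counterfactual import (
    ALL, NEED_CATEGORIES, SCENARIOS, adjusted_disease_disutility,
    apply_scenario, decompose_need, remove_condition,
    scenario_mean_utilities, tidy_decomposition,
)
from unmetneed.model import (
    FittedUtilityModel, ModelSpec, fit_utility_model,
    paper_signed_coefficients, predict_utility,
)

from conftest import make_respondents


def model_from_truth(coefficients=None) -> FittedUtilityModel:
    """A model whose coefficients are the DGP truth, with zero covariance."""
    beta = (paper_signed_coefficients() if coefficients is None
            else coefficients)
    terms = list(beta.index)
    return FittedUtilityModel(
        spec=ModelSpec(), region="US", coefficients=beta,
        covariance=pd.DataFrame(np.zeros((len(terms), len(terms))),
                                index=terms, columns=terms),
        residual_sd=0.0, n_obs=len(terms), r_squared=1.0)


def scenario_frame(u_obs, u_worst, u_opt, u_nd, **keys):
    base = {"condition": "copd", "region": "US", "age_group": ALL,
            "gender": ALL, "n_respondents": 10}
    base.update(keys)
    rows = []
    for scenario, value in [("observed", u_obs), ("worst", u_worst),
                            ("optimal", u_opt),
                            ("no_disease_optimal", u_nd)]:
        rows.append(dict(base, scenario=scenario, mean_utility=value))
    return pd.DataFrame(rows)


class TestApplyScenario:
    def test_observed_is_identity(self):
        table = make_respondents([{"copd": True, "cost_cutting": True}])
        out = apply_scenario(table, "observed", "copd")
        pd.testing.assert_frame_equal(out, table)

    def test_worst_values(self):
        table = make_respondents([{"copd": True, "adherence_level": "high",
                                   "doctor_attentive": True}])
        out = apply_scenario(table, "worst", "copd")
        assert out.loc[0, "adherence_level"] == "low_medium"
        assert bool(out.loc[0, "cost_prevented"]) is True
        assert bool(out.loc[0, "cost_cutting"]) is True
        assert bool(out.loc[0, "doctor_attentive"]) is False
        assert bool(out.loc[0, "copd"]) is True  # disease untouched

    def test_worst_adherence_switch(self):
        table = make_respondents([{"copd": True}])
        out = apply_scenario(table, "worst", "copd",
                             worst_adherence="not_using")
        assert out.loc[0, "adherence_level"] == "not_using"

    def test_optimal_values(self):
        table = make_respondents([{"copd": True, "cost_prevented": True}])
        out = apply_scenario(table, "optimal", "copd")
        assert out.loc[0, "adherence_level"] == "high"
        assert not out.loc[0, "cost_prevented"]
        assert not out.loc[0, "cost_cutting"]
        assert bool(out.loc[0, "doctor_attentive"]) is True

    def test_no_disease_optimal_removes_only_target_condition(self):
        table = make_respondents([{"copd": True, "hepatitis_c": True}])
        out = apply_scenario(table, "no_disease_optimal", "copd")
        assert not out.loc[0, "copd"]
        assert bool(out.loc[0, "hepatitis_c"]) is True
        assert out.loc[0, "adherence_level"] == "high"

    def test_input_never_mutated(self):
        table = make_respondents([{"copd": True}])
        before = table.copy()
        apply_scenario(table, "worst", "copd")
        pd.testing.assert_frame_equal(table, before)

    @pytest.mark.parametrize("scenario",
                             ["worst", "optimal", "no_disease_optimal"])
    def test_idempotence(self, scenario):
        table = make_respondents(
            [{"copd": True, "adherence_level": "low_medium"}])
        once = apply_scenario(table, scenario, "copd")
        twice = apply_scenario(once, scenario, "copd")
        pd.testing.assert_frame_equal(once, twice)

    def test_unknown_condition_rejected(self):
        table = make_respondents([{}])
        with pytest.raises(ValueError, match="condition"):
            apply_scenario(table, "worst", "gout")

    def test_demographics_untouched(self):
        table = make_respondents([{"copd": True, "age_group": "75+",
                                   "comorbidity_class": "3+"}])
        out = apply_scenario(table, "optimal", "copd")
        assert out.loc[0, "age_group"] == "75+"
        assert out.loc[0, "comorbidity_class"] == "3+"
        assert out.loc[0, "utility"] == table.loc[0, "utility"]


class TestScenarioMeans:
    def test_single_respondent_stratum_equals_prediction(self):
        model = model_from_truth()
        table = make_respondents([{"copd": True, "age_group": "55-74"}])
        out = scenario_mean_utilities(model, table, "copd")
        for scenario in SCENARIOS:
            transformed = apply_scenario(table, scenario, "copd")
            expected = predict_utility(model, transformed).iloc[0]
            cell = out[(out["scenario"] == scenario)
                       & (out["age_group"] == "55-74")]
            assert cell["mean_utility"].iloc[0] == pytest.approx(expected)
            assert cell["n_respondents"].iloc[0] == 1

    def test_overall_mean_equals_brute_force_average(self, survey_table,
                                                     fitted_model):
        out = scenario_mean_utilities(fitted_model, survey_table, "copd")
        subset = survey_table[survey_table["copd"]]
        brute = predict_utility(fitted_model, subset).mean()
        overall = out[(out["scenario"] == "observed")
                      & (out["age_group"] == ALL)]
        assert overall["mean_utility"].iloc[0] == pytest.approx(brute,
                                                                abs=1e-12)
        assert overall["n_respondents"].iloc[0] == len(subset)

    def test_no_respondent_with_condition_rejected(self, fitted_model):
        table = make_respondents([{"copd": True}])
        with pytest.raises(ValueError, match="parkinsons"):
            scenario_mean_utilities(fitted_model, table, "parkinsons")

    def test_zero_access_effects_collapse_scenarios(self):
        """With no access effects, care scenarios cannot move utility."""
        beta = paper_signed_coefficients()
        for term in beta.index:
            if ("adherence" in term or "cost" in term or "doctor" in term):
                beta[term] = 0.0
        model = model_from_truth(beta)
        cfg = DGPConfig(n_respondents=5000, seed=31,
                        true_coefficients=beta)
        table = generate_synthetic_survey(cfg)
        out = scenario_mean_utilities(model, table, "copd")
        wide = out[out["age_group"] == ALL].set_index("scenario")
        assert wide.loc["worst", "mean_utility"] == pytest.approx(
            wide.loc["observed", "mean_utility"], abs=1e-12)
        assert wide.loc["optimal", "mean_utility"] == pytest.approx(
            wide.loc["observed", "mean_utility"], abs=1e-12)
        # removing the disease still moves utility
        assert wide.loc["no_disease_optimal", "mean_utility"] > \
            wide.loc["optimal", "mean_utility"]


class TestDecomposition:
    def test_worked_arithmetic_example(self):
        out = decompose_need(scenario_frame(0.6, 0.5, 0.65, 0.8))
        row = out.iloc[0]
        assert row["met_need"] == pytest.approx(0.10)
        assert row["unmet_ineffective_use"] == pytest.approx(0.05)
        assert row["unmet_lack_of_tech"] == pytest.approx(0.15)
        assert row["comorbidity_residual"] == pytest.approx(0.20)
        assert row["total_need"] == pytest.approx(0.5)

    def test_equal_utilities_zero_gaps(self):
        out = decompose_need(scenario_frame(0.7, 0.7, 0.7, 0.7))
        row = out.iloc[0]
        assert row["met_need"] == 0
        assert row["unmet_ineffective_use"] == 0
        assert row["unmet_lack_of_tech"] == 0
        assert row["comorbidity_residual"] == pytest.approx(0.3)

    @given(st.lists(
        st.tuples(*[st.floats(-0.5, 1.0, allow_nan=False)] * 4),
        min_size=1, max_size=20))
    def test_additivity_for_random_quadruples(self, quads):
        frames = [
            scenario_frame(o, w, p, n, condition="copd",
                           age_group=f"g{i}", gender="female")
            for i, (o, w, p, n) in enumerate(quads)]
        out = decompose_need(pd.concat(frames, ignore_index=True))
        total = out[list(NEED_CATEGORIES)].sum(axis=1)
        np.testing.assert_allclose(total, out["total_need"], atol=1e-12)
        expected = {f"g{i}": 1.0 - w for i, (_, w, _, _) in enumerate(quads)}
        np.testing.assert_allclose(
            total, out["age_group"].map(expected), atol=1e-12)

    def test_missing_scenario_named(self):
        frame = scenario_frame(0.6, 0.5, 0.65, 0.8)
        frame = frame[frame["scenario"] != "optimal"]
        with pytest.raises(ValueError, match="optimal"):
            decompose_need(frame)

    def test_tidy_long_format(self):
        out = tidy_decomposition(decompose_need(
            scenario_frame(0.6, 0.5, 0.65, 0.8)))
        assert set(out["category"]) == set(NEED_CATEGORIES)
        assert len(out) == 4
        assert out["value"].sum() == pytest.approx(0.5)


class TestMonotonicityAndAdjustedDisutility:
    def test_scenario_monotonicity_under_true_signs(self):
        """worst <= observed <= optimal <= no_disease in every stratum.

        Holds pointwise for the data-generating coefficients, whose access
        effects carry the expected signs; checked with those coefficients
        rather than a noisy refit, where sign flips of weakly identified
        interactions can break the ordering.
        """
        model = model_from_truth()
        table = generate_synthetic_survey(
            DGPConfig(n_respondents=30_000, seed=37))
        for condition in model.spec.conditions:
            out = scenario_mean_utilities(model, table, condition)
            wide = out.pivot_table(index=["age_group", "gender"],
                                   columns="scenario",
                                   values="mean_utility", observed=True)
            assert (wide["worst"] <= wide["observed"] + 1e-12).all()
            assert (wide["observed"] <= wide["optimal"] + 1e-12).all()
            assert (wide["optimal"]
                    <= wide["no_disease_optimal"] + 1e-12).all()

    def test_adjusted_disutility_matches_no_disease_gap_at_observed_access(
            self):
        """Removing the disease at observed access reproduces the adjusted
        disutility; with truth coefficients it is exactly the condition's
        own effect block."""
        model = model_from_truth()
        table = generate_synthetic_survey(
            DGPConfig(n_respondents=10_000, seed=41))
        value = adjusted_disease_disutility(model, table, "copd")
        subset = table[table["copd"]]
        beta = model.coefficients
        from unmetneed.model import build_design_matrix
        X = build_design_matrix(subset, model.spec)
        inter_cols = [f"copd:{t}" for t in model.spec.access_terms]
        manual = -(beta["copd"]
                   + (X[inter_cols].to_numpy()
                      @ beta[inter_cols].to_numpy()).mean())
        # observed minus disease-removed = +condition effect block
        assert value == pytest.approx(-manual, abs=1e-12)
        assert value < 0  # a disease reduces utility under true signs
        obs = predict_utility(model, subset)
        rem = predict_utility(model, remove_condition(subset, "copd"))
        assert value == pytest.approx((obs - rem).mean(), abs=1e-12)

    def test_adjusted_disutility_in_reported_range(self, survey_table,
                                                   fitted_model):
        """Adjusted disutilities fall in the plausible −0.03..−0.13 band."""
        for condition in fitted_model.spec.conditions:
            value = adjusted_disease_disutility(fitted_model, survey_table,
                                                condition)
            assert -0.2 < value < 0
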