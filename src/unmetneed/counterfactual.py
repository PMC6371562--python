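"""Counterfactual care scenarios and the need decomposition.

For each index condition, utility is re-predicted under four scenarios
("recycled predictions" / marginal standardization):

* ``observed`` — covariates at their observed values (current burden);
* ``worst`` — access/utilization at their worst values: low/medium
  adherence, costs prevented medication use, cost-cutting strategy used,
  doctor not attentive (untreated burden);
* ``optimal`` — high adherence, no cost barriers, attentive doctor
  (achievable burden with current technologies);
* ``no_disease_optimal`` — optimal access and the condition indicator
  switched off (burden without the disease).

Scenario means over the respondents with the condition decompose total need
(1 − U_worst) into four additive pieces::

    met_need              = U_observed − U_worst
    unmet_ineffective_use = U_optimal  − U_observed
    unmet_lack_of_tech    = U_no_disease − U_optimal
    comorbidity_residual  = 1 − U_no_disease
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import model as model_mod
from . import survey

SCENARIOS: tuple[str, ...] = (
    "observed", "worst", "optimal", "no_disease_optimal")
NEED_CATEGORIES: tuple[str, ...] = (
    "met_need", "unmet_ineffective_use", "unmet_lack_of_tech",
    "comorbidity_residual")

#: sentinel level for stratum-marginal ("overall") rows
ALL = "all"


def apply_scenario(table: pd.DataFrame, scenario: str, condition: str,
                   worst_adherence: str = "low_medium") -> pd.DataFrame:
    """Return a copy of the table with access variables set per scenario.

    ``worst_adherence`` defaults to ``low_medium``; ``not_using`` may be
    chosen instead to interpret "no care" literally. The input table is
    never mutated; non-access fields are untouched except the condition
    flag under ``no_disease_optimal``.
    """
    if condition not in survey.CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; one of {SCENARIOS}")
    if worst_adherence not in survey.ADHERENCE_LEVELS:
        raise ValueError(f"unknown adherence level {worst_adherence!r}")

    out = table.copy()
    if scenario == "observed":
        return out
    if scenario == "worst":
        out["adherence_level"] = worst_adherence
        out["cost_prevented"] = True
        out["cost_cutting"] = True
        out["doctor_attentive"] = False
        return out
    # optimal and no_disease_optimal share the optimal access settings
    out["adherence_level"] = "high"
    out["cost_prevented"] = False
    out["cost_cutting"] = False
    out["doctor_attentive"] = True
    if scenario == "no_disease_optimal":
        out[condition] = False
    return out


def remove_condition(table: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Copy of the table with the condition flag off, access untouched."""
    if condition not in survey.CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    out = table.copy()
    out[condition] = False
    return out


def _stratum_means(pred: pd.Series, table: pd.DataFrame) -> pd.DataFrame:
    frame = pd.DataFrame({
        "age_group": table["age_group"].to_numpy(),
        "gender": table["gender"].to_numpy(),
        "mean_utility": pred.to_numpy(),
    })
    cells = (frame.groupby(["age_group", "gender"], observed=True)
             .agg(mean_utility=("mean_utility", "mean"),
                  n_respondents=("mean_utility", "size"))
             .reset_index())
    overall = pd.DataFrame({
        "age_group": [ALL], "gender": [ALL],
        "mean_utility": [frame["mean_utility"].mean()],
        "n_respondents": [len(frame)],
    })
    return pd.concat([cells, overall], ignore_index=True)


def scenario_mean_utilities(model: model_mod.FittedUtilityModel,
                            table: pd.DataFrame, condition: str,
                            worst_adherence: str = "low_medium",
                            ) -> pd.DataFrame:
    """Mean predicted utility per scenario and age × gender stratum.

    The table is restricted internally to respondents whose flag for
    ``condition`` is true. Rows with ``age_group == gender == 'all'`` carry
    the unstratified means. Cells with no respondents are omitted.
    """
    subset = table[table[condition].astype(bool)]
    if len(subset) == 0:
        raise ValueError(f"no respondent has condition {condition!r}")
    region = model.region

    pieces = []
    for scenario in SCENARIOS:
        transformed = apply_scenario(subset, scenario, condition,
                                     worst_adherence=worst_adherence)
        pred = model_mod.predict_utility(model, transformed)
        means = _stratum_means(pred, subset)
        means.insert(0, "scenario", scenario)
        pieces.append(means)
    out = pd.concat(pieces, ignore_index=True)
    out.insert(0, "region", region)
    out.insert(0, "condition", condition)
    return out[["condition", "region", "age_group", "gender", "scenario",
                "mean_utility", "n_respondents"]]


def decompose_need(utilities: pd.DataFrame) -> pd.DataFrame:
    """Turn scenario means into the four-part need decomposition.

    Expects the output of :func:`scenario_mean_utilities` (possibly
    concatenated over conditions/regions). Every (condition, region,
    stratum) cell must carry all four scenarios. The four components sum to
    1 − U_worst by construction; this additivity is asserted.
    """
    keys = ["condition", "region", "age_group", "gender"]
    wide = utilities.pivot_table(index=keys, columns="scenario",
                                 values="mean_utility", observed=True)
    missing = [s for s in SCENARIOS if s not in wide.columns]
    if missing or wide[list(SCENARIOS)].isna().any().any():
        if not missing:
            bad = wide[wide[list(SCENARIOS)].isna().any(axis=1)]
            missing = sorted(
                {s for s in SCENARIOS if bad[s].isna().any()})
        raise ValueError(f"missing scenario(s) {missing} for some strata")

    n = (utilities[utilities["scenario"] == "observed"]
         .set_index(keys)["n_respondents"])
    out = pd.DataFrame({
        "met_need": wide["observed"] - wide["worst"],
        "unmet_ineffective_use": wide["optimal"] - wide["observed"],
        "unmet_lack_of_tech": wide["no_disease_optimal"] - wide["optimal"],
        "comorbidity_residual": 1.0 - wide["no_disease_optimal"],
        "total_need": 1.0 - wide["worst"],
        "n_respondents": n,
    }).reset_index()

    gap = (out[list(NEED_CATEGORIES)].sum(axis=1)
           - out["total_need"]).abs().max()
    assert gap <= 1e-10, f"decomposition additivity violated by {gap:g}"
    return out


def tidy_decomposition(decomposition: pd.DataFrame) -> pd.DataFrame:
    """Long-format view: one row per (stratum, need category)."""
    keys = ["condition", "region", "age_group", "gender"]
    return decomposition.melt(
        id_vars=keys, value_vars=list(NEED_CATEGORIES),
        var_name="category", value_name="value",
    ).sort_values(keys + ["category"]).reset_index(drop=True)


def adjusted_disease_disutility(model: model_mod.FittedUtilityModel,
                                table: pd.DataFrame, condition: str) -> float:
    """Mean utility change attributable to the condition at observed access.

    Predicted utility minus the prediction with the condition indicator
    switched off, access/utilization left at observed values, averaged over
    the respondents who have the condition. Negative under sign-correct
    models: it is the adjusted disutility of the disease given current
    access to and use of technology.
    """
    subset = table[table[condition].astype(bool)]
    if len(subset) == 0:
        raise ValueError(f"no respondent has condition {condition!r}")
    observed = model_mod.predict_utility(model, subset)
    removed = model_mod.predict_utility(
        model, remove_condition(subset, condition))
    return float((observed - removed).mean())
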