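import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from unmetneed import DGPConfig, ModelSpec, fit_utility_model
from unmetneed import generate_synthetic_survey
from unmetneed.survey import CONDITIONS

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

_DEFAULTS = {
    "region": "US",
    "age_group": "18-34",
    "gender": "female",
    **{c: False for c in CONDITIONS},
    "comorbidity_class": "0",
    "adherence_level": "not_using",
    "cost_prevented": False,
    "cost_cutting": False,
    "doctor_attentive": False,
    "utility": 0.75,
}


def make_respondents(rows):
    """Build a schema-complete respondent table from partial row dicts."""
    full = []
    for i, row in enumerate(rows):
        rec = dict(_DEFAULTS)
        rec.update(row)
        rec.setdefault("respondent_id", f"r{i:04d}")
        full.append(rec)
    table = pd.DataFrame(full)
    for col in CONDITIONS + ("cost_prevented", "cost_cutting",
                             "doctor_attentive"):
        table[col] = table[col].astype(bool)
    return table


@pytest.fixture(scope="session")
def survey_table():
    """Medium synthetic survey: every interaction cell populated."""
    return generate_synthetic_survey(DGPConfig(n_respondents=20_000, seed=42))


@pytest.fixture(scope="session")
def fitted_model(survey_table):
    return fit_utility_model(survey_table)


@pytest.fixture(scope="session")
def small_spec():
    """11-term spec a 12-row fixture can identify."""
    return ModelSpec(conditions=("copd",),
                     access_terms=("cost_prevented", "doctor_attentive"),
                     include_interactions=False)


@pytest.fixture(scope="session")
def twelve_row_table():
    """Hand-made full-rank fixture for normal-equations oracles.

    Rows 2–11 each flip exactly one dummy of the 11-term reduced spec
    relative to the all-reference first row, guaranteeing full column rank.
    """
    return make_respondents([
        {"utility": 0.90},
        {"age_group": "35-54", "utility": 0.85},
        {"age_group": "55-74", "utility": 0.80},
        {"age_group": "75+", "utility": 0.70},
        {"gender": "male", "utility": 0.88},
        {"comorbidity_class": "1", "utility": 0.78},
        {"comorbidity_class": "2", "utility": 0.75},
        {"comorbidity_class": "3+", "utility": 0.60},
        {"copd": True, "utility": 0.72},
        {"cost_prevented": True, "utility": 0.68},
        {"doctor_attentive": True, "utility": 0.95},
        {"age_group": "35-54", "gender": "male", "comorbidity_class": "1",
         "copd": True, "cost_prevented": True, "doctor_attentive": True,
         "utility": 0.50},
    ])


def normal_equations_ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent brute-force OLS oracle: (XᵀX)⁻¹Xᵀy."""
    return np.linalg.inv(X.T @ X) @ (X.T @ y)
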