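"""Linear utility regression with condition × access interactions.

Utility (1 − disutility) is modeled by ordinary least squares on four blocks
of covariates: indicators for the index conditions, comorbidity-class
dummies, age-group and gender dummies, and the access/utilization variables
(adherence level, two cost barriers, physician attentiveness). Each access
term is additionally interacted with each condition indicator so the payoff
of access and use can differ by condition. The coefficients on the condition
indicators measure the conditions' disutilities after adjustment, and the
fitted coefficient covariance feeds the simulation-based intervals in
:mod:`unmetneed.uncertainty`.

Fits are performed within a single region; regions are modeled separately
rather than pooled with region interactions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import survey
from .errors import CollinearityError, ConfigurationError, SchemaError

ACCESS_TERMS: tuple[str, ...] = (
    "adherence_low_medium",
    "adherence_high",
    "cost_prevented",
    "cost_cutting",
    "doctor_attentive",
)


@dataclass(frozen=True)
class ModelSpec:
    """Regression design specification.

    Defaults give the full 43-term design: intercept, 3 age dummies
    (reference 18-34), gender (reference female), 3 comorbidity dummies
    (reference 0), 5 condition indicators, 5 access terms (adherence
    reference not_using), and 25 condition × access interactions.
    Reduced specs (fewer conditions, no interactions) are valid and useful
    for small samples.
    """

    conditions: tuple[str, ...] = survey.CONDITIONS
    access_terms: tuple[str, ...] = ACCESS_TERMS
    include_interactions: bool = True
    age_reference: str = "18-34"
    gender_reference: str = "female"
    comorbidity_reference: str = "0"
    adherence_reference: str = "not_using"

    def __post_init__(self):
        for cond in self.conditions:
            if cond not in survey.CONDITIONS:
                raise ConfigurationError(f"unknown condition {cond!r}")
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigurationError("duplicate condition names")
        if self.age_reference not in survey.AGE_GROUPS:
            raise ConfigurationError(
                f"age reference {self.age_reference!r} is not a level")
        if self.gender_reference not in survey.GENDERS:
            raise ConfigurationError(
                f"gender reference {self.gender_reference!r} is not a level")
        if self.comorbidity_reference not in survey.COMORBIDITY_CLASSES:
            raise ConfigurationError(
                f"comorbidity reference {self.comorbidity_reference!r} "
                "is not a level")
        if self.adherence_reference not in survey.ADHERENCE_LEVELS:
            raise ConfigurationError(
                f"adherence reference {self.adherence_reference!r} "
                "is not a level")

    @property
    def reference_levels(self) -> dict[str, str]:
        return {
            "age_group": self.age_reference,
            "gender": self.gender_reference,
            "comorbidity_class": self.comorbidity_reference,
            "adherence_level": self.adherence_reference,
        }

    def term_names(self) -> list[str]:
        terms = ["intercept"]
        terms += [f"age_{a}" for a in survey.AGE_GROUPS
                  if a != self.age_reference]
        terms += [f"gender_{g}" for g in survey.GENDERS
                  if g != self.gender_reference]
        terms += [f"comorbid_{c}" for c in survey.COMORBIDITY_CLASSES
                  if c != self.comorbidity_reference]
        terms += list(self.conditions)
        terms += list(self.access_terms)
        if self.include_interactions:
            terms += [f"{cond}:{acc}" for cond in self.conditions
                      for acc in self.access_terms]
        if len(set(terms)) != len(terms):
            raise ConfigurationError("duplicate term names in spec")
        return terms

    def to_dict(self) -> dict:
        return {
            "conditions": list(self.conditions),
            "access_terms": list(self.access_terms),
            "include_interactions": self.include_interactions,
            "age_reference": self.age_reference,
            "gender_reference": self.gender_reference,
            "comorbidity_reference": self.comorbidity_reference,
            "adherence_reference": self.adherence_reference,
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "ModelSpec":
        return cls(
            conditions=tuple(raw.get("conditions", survey.CONDITIONS)),
            access_terms=tuple(raw.get("access_terms", ACCESS_TERMS)),
            include_interactions=raw.get("include_interactions", True),
            age_reference=raw.get("age_reference", "18-34"),
            gender_reference=raw.get("gender_reference", "female"),
            comorbidity_reference=raw.get("comorbidity_reference", "0"),
            adherence_reference=raw.get("adherence_reference", "not_using"),
        )


def _access_columns(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    cols = {}
    for term in spec.access_terms:
        if term.startswith("adherence_"):
            level = term[len("adherence_"):]
            cols[term] = (table["adherence_level"] == level).astype(float)
        else:
            cols[term] = table[term].astype(float)
    return pd.DataFrame(cols, index=table.index)


def build_design_matrix(table: pd.DataFrame,
                        spec: ModelSpec | None = None) -> pd.DataFrame:
    """Expand a respondent table into the regression design matrix.

    One row per respondent, one column per term of ``spec`` (intercept
    first), dummy coding against the spec's reference levels, and an
    interaction column (condition dummy × access dummy) for every
    condition/access pair when interactions are enabled. Column order is
    deterministic from the spec.
    """
    spec = spec or ModelSpec()
    if len(table) == 0:
        raise ValueError("cannot build a design matrix from an empty table")
    needed = {"age_group", "gender", "comorbidity_class", "adherence_level",
              "cost_prevented", "cost_cutting", "doctor_attentive",
              *spec.conditions}
    missing = sorted(needed - set(table.columns))
    if missing:
        raise SchemaError(f"table missing columns: {missing}")

    X = pd.DataFrame(index=table.index)
    X["intercept"] = 1.0
    for a in survey.AGE_GROUPS:
        if a != spec.age_reference:
            X[f"age_{a}"] = (table["age_group"] == a).astype(float)
    for g in survey.GENDERS:
        if g != spec.gender_reference:
            X[f"gender_{g}"] = (table["gender"] == g).astype(float)
    for c in survey.COMORBIDITY_CLASSES:
        if c != spec.comorbidity_reference:
            X[f"comorbid_{c}"] = (table["comorbidity_class"] == c).astype(float)
    for cond in spec.conditions:
        X[cond] = table[cond].astype(float)
    access = _access_columns(table, spec)
    for term in spec.access_terms:
        X[term] = access[term]
    if spec.include_interactions:
        for cond in spec.conditions:
            for term in spec.access_terms:
                X[f"{cond}:{term}"] = X[cond] * access[term]
    assert list(X.columns) == spec.term_names()
    return X


@dataclass
class FittedUtilityModel:
    """OLS fit of the utility regression for one region.

    ``covariance`` is the classical (non-robust) coefficient covariance,
    residual variance times (XᵀX)⁻¹.
    """

    spec: ModelSpec
    region: str
    coefficients: pd.Series
    covariance: pd.DataFrame
    residual_sd: float
    n_obs: int
    r_squared: float

    def __post_init__(self):
        terms = list(self.coefficients.index)
        if list(self.covariance.index) != terms or \
                list(self.covariance.columns) != terms:
            raise ValueError("covariance terms do not match coefficients")
        asym = np.abs(self.covariance.to_numpy()
                      - self.covariance.to_numpy().T).max()
        if asym > 1e-10:
            raise ValueError(f"covariance not symmetric (max asym {asym:g})")

    @property
    def standard_errors(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.covariance.to_numpy())),
                         index=self.coefficients.index)

    def confidence_intervals(self, level: float = 0.95) -> pd.DataFrame:
        from scipy import stats
        dof = self.n_obs - len(self.coefficients)
        half = stats.t.ppf(0.5 + level / 2, dof) * self.standard_errors
        return pd.DataFrame({
            "estimate": self.coefficients,
            "lower": self.coefficients - half,
            "upper": self.coefficients + half,
        })

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "region": self.region,
            "term_names": list(self.coefficients.index),
            "coefficients": [float(v) for v in self.coefficients],
            "covariance": self.covariance.to_numpy().tolist(),
            "residual_sd": float(self.residual_sd),
            "n_obs": int(self.n_obs),
            "r_squared": float(self.r_squared),
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "FittedUtilityModel":
        terms = raw["term_names"]
        return cls(
            spec=ModelSpec.from_dict(raw["spec"]),
            region=raw["region"],
            coefficients=pd.Series(raw["coefficients"], index=terms,
                                   dtype=float),
            covariance=pd.DataFrame(np.asarray(raw["covariance"], dtype=float),
                                    index=terms, columns=terms),
            residual_sd=raw["residual_sd"],
            n_obs=raw["n_obs"],
            r_squared=raw["r_squared"],
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FittedUtilityModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _check_rank(X: pd.DataFrame) -> None:
    """Raise CollinearityError naming dependent columns if X is rank deficient."""
    from scipy import linalg

    A = X.to_numpy()
    _, R, piv = linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag.size == 0 or diag[0] == 0.0:
        raise CollinearityError(list(X.columns))
    tol = diag[0] * max(A.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = [X.columns[piv[i]] for i in range(rank, X.shape[1])]
        raise CollinearityError(bad)


def fit_utility_model(table: pd.DataFrame,
                      spec: ModelSpec | None = None,
                      region: str | None = None) -> FittedUtilityModel:
    """Fit the utility regression by OLS within one region.

    If ``region`` is given the table is filtered to it; otherwise the table
    must contain a single region. A ``weight`` column, when present, is used
    as least-squares weights. Rank-deficient designs raise
    :class:`CollinearityError` naming the collinear terms (a condition with
    no variation in an access variable is the typical cause).
    """
    spec = spec or ModelSpec()
    if region is not None:
        table = table[table["region"] == region]
        if len(table) == 0:
            raise ValueError(f"no respondents in region {region!r}")
    else:
        regions = table["region"].unique()
        if len(regions) != 1:
            raise ValueError(
                f"table spans regions {sorted(regions)}; fit one at a time "
                "or pass region=")
        region = regions[0]

    X = build_design_matrix(table, spec)
    if len(table) < X.shape[1]:
        raise ValueError(
            f"need at least {X.shape[1]} rows to fit {X.shape[1]} terms, "
            f"got {len(table)}")
    _check_rank(X)

    y = table["utility"].astype(float)
    if "weight" in table.columns:
        result = sm.WLS(y, X, weights=table["weight"].astype(float)).fit()
    else:
        result = sm.OLS(y, X).fit()

    cov = pd.DataFrame(np.asarray(result.cov_params()),
                       index=X.columns, columns=X.columns)
    cov = (cov + cov.T) / 2  # enforce exact symmetry
    return FittedUtilityModel(
        spec=spec,
        region=str(region),
        coefficients=pd.Series(np.asarray(result.params), index=X.columns),
        covariance=cov,
        residual_sd=float(np.sqrt(result.scale)),
        n_obs=int(result.nobs),
        r_squared=float(result.rsquared),
    )


def predict_utility(model: FittedUtilityModel, table: pd.DataFrame,
                    clamp: bool = False) -> pd.Series:
    """Predicted utility per respondent: design row · coefficients.

    Predictions are not truncated unless ``clamp=True``, which caps them at
    the utility maximum of 1 for reporting.
    """
    return predict_with_coefficients(
        model.spec, table, model.coefficients, clamp=clamp)


def predict_with_coefficients(spec: ModelSpec, table: pd.DataFrame,
                              coefficients: pd.Series,
                              clamp: bool = False) -> pd.Series:
    X = build_design_matrix(table, spec)
    if list(coefficients.index) != list(X.columns):
        raise SchemaError("coefficient terms do not match the design")
    pred = pd.Series(X.to_numpy() @ coefficients.to_numpy(), index=table.index)
    if clamp:
        pred = pred.clip(upper=survey.UTILITY_MAX)
    return pred


def paper_signed_coefficients() -> pd.Series:
    """A sign-realistic 43-term coefficient vector for the default spec.

    Signs follow the pattern reported in multi-condition utility studies:
    negative condition effects (−0.05 to −0.12 here), utility falling with
    comorbidity count, negative cost-barrier effects, positive effects of
    high adherence and physician attentiveness. Used as the default truth of
    the synthetic data-generating process.
    """
    spec = ModelSpec()
    values = {term: 0.0 for term in spec.term_names()}
    values["intercept"] = 0.80
    values["age_35-54"] = 0.010
    values["age_55-74"] = 0.020
    values["age_75+"] = -0.010
    values["gender_male"] = 0.015
    values["comorbid_1"] = -0.035
    values["comorbid_2"] = -0.060
    values["comorbid_3+"] = -0.110
    condition_effects = {
        "rheumatoid_arthritis": -0.090,
        "breast_cancer": -0.050,
        "parkinsons": -0.120,
        "hepatitis_c": -0.070,
        "copd": -0.080,
    }
    access_effects = {
        "adherence_low_medium": -0.020,
        "adherence_high": 0.020,
        "cost_prevented": -0.045,
        "cost_cutting": -0.030,
        "doctor_attentive": 0.025,
    }
    interaction_effects = {
        "adherence_low_medium": -0.010,
        "adherence_high": 0.015,
        "cost_prevented": -0.020,
        "cost_cutting": -0.010,
        "doctor_attentive": 0.015,
    }
    values.update(condition_effects)
    values.update(access_effects)
    for cond in spec.conditions:
        for acc, eff in interaction_effects.items():
            values[f"{cond}:{acc}"] = eff
    return pd.Series(values, dtype=float)[spec.term_names()]
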