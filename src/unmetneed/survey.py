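"""Survey microdata: schema, validation, I/O, and a synthetic generator.

The estimator consumes one row per survey respondent with an SF-6D utility
score (1 = perfect health, values below 0 = states worse than death),
indicators for five index conditions, a comorbidity-count class, and four
access/utilization variables: a three-level medication-adherence state
(MMAS-8 high vs. low/medium, plus "not using medications"), two cost-barrier
indicators, and a physician-attentiveness indicator.

The real survey source is proprietary, so :func:`generate_synthetic_survey`
emulates its variable structure: covariates are drawn independently from
configured marginals and utility is generated from the same linear model the
estimator fits (see :mod:`unmetneed.model`), plus Gaussian noise.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, SchemaError

logger = logging.getLogger(__name__)

# Canonical categorical levels -------------------------------------------------

CONDITIONS: tuple[str, ...] = (
    "rheumatoid_arthritis",
    "breast_cancer",
    "parkinsons",
    "hepatitis_c",
    "copd",
)
REGIONS: tuple[str, ...] = ("EU5", "US")
AGE_GROUPS: tuple[str, ...] = ("18-34", "35-54", "55-74", "75+")
GENDERS: tuple[str, ...] = ("female", "male")
COMORBIDITY_CLASSES: tuple[str, ...] = ("0", "1", "2", "3+")
ADHERENCE_LEVELS: tuple[str, ...] = ("not_using", "low_medium", "high")

BOOL_COLUMNS: tuple[str, ...] = CONDITIONS + (
    "cost_prevented",
    "cost_cutting",
    "doctor_attentive",
)
CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "region": REGIONS,
    "age_group": AGE_GROUPS,
    "gender": GENDERS,
    "comorbidity_class": COMORBIDITY_CLASSES,
    "adherence_level": ADHERENCE_LEVELS,
}
REQUIRED_COLUMNS: tuple[str, ...] = (
    ("respondent_id", "region", "age_group", "gender")
    + CONDITIONS
    + ("comorbidity_class", "adherence_level", "cost_prevented",
       "cost_cutting", "doctor_attentive", "utility")
)
#: accepted but not required
OPTIONAL_COLUMNS: tuple[str, ...] = ("weight",)

UTILITY_MAX = 1.0
UTILITY_MIN = -1.0  # defensive floor; SF-6D-like scales never reach it

_TRUE_TOKENS = {"1", "yes", "true", "t", "y"}
_FALSE_TOKENS = {"0", "no", "false", "f", "n"}


# Synthetic data-generating process --------------------------------------------

def _default(value, fallback):
    return fallback if value is None else value


DEFAULT_CONDITION_PROBABILITIES: dict[str, float] = {
    # plausible adult prevalence fractions for the five index conditions
    "rheumatoid_arthritis": 0.010,
    "breast_cancer": 0.015,
    "parkinsons": 0.004,
    "hepatitis_c": 0.008,
    "copd": 0.020,
}
DEFAULT_ADHERENCE_DISTRIBUTION: dict[str, float] = {
    "not_using": 0.40,
    "low_medium": 0.35,
    "high": 0.25,
}
DEFAULT_COMORBIDITY_DISTRIBUTION: dict[str, float] = {
    "0": 0.35, "1": 0.20, "2": 0.15, "3+": 0.30,
}
DEFAULT_AGE_DISTRIBUTION: dict[str, float] = {
    "18-34": 0.26, "35-54": 0.35, "55-74": 0.34, "75+": 0.05,
}
DEFAULT_GENDER_DISTRIBUTION: dict[str, float] = {"female": 0.52, "male": 0.48}


@dataclass
class AccessProbabilities:
    """Marginal distributions for the access/utilization variables.

    ``adherence_by_condition`` optionally overrides the adherence
    distribution for respondents flagged with a given condition; when a
    respondent has several overridden conditions the first one in canonical
    condition order takes precedence.
    """

    adherence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ADHERENCE_DISTRIBUTION))
    adherence_by_condition: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict)
    cost_prevented: float = 0.23
    cost_cutting: float = 0.41
    doctor_attentive: float = 0.91


@dataclass
class DemographicDistribution:
    """Age × gender distribution; independent marginals unless ``joint`` given.

    ``joint`` maps ``(age_group, gender)`` pairs to probabilities and, when
    present, replaces the product of the marginals.
    """

    age: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_DISTRIBUTION))
    gender: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENDER_DISTRIBUTION))
    joint: Mapping[tuple[str, str], float] | None = None

    def cell_probabilities(self) -> pd.Series:
        cells = pd.MultiIndex.from_product(
            [AGE_GROUPS, GENDERS], names=["age_group", "gender"])
        if self.joint is not None:
            probs = pd.Series(
                [self.joint.get((a, g), 0.0) for a, g in cells], index=cells)
        else:
            probs = pd.Series(
                [self.age.get(a, 0.0) * self.gender.get(g, 0.0)
                 for a, g in cells],
                index=cells,
            )
        return probs


@dataclass
class DGPConfig:
    """Configuration of the synthetic survey data-generating process.

    ``true_coefficients`` is a coefficient vector for the default model
    specification (see :func:`unmetneed.model.paper_signed_coefficients`);
    utility is generated as the corresponding linear predictor plus
    ``N(0, noise_sd²)`` noise, clipped to the valid utility range when
    ``truncate_utility`` is set.
    """

    n_respondents: int = 10_000
    seed: int = 0
    region: str = "US"
    condition_probabilities: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_PROBABILITIES))
    access_probabilities: AccessProbabilities = field(
        default_factory=AccessProbabilities)
    comorbidity_distribution: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_DISTRIBUTION))
    demographic_distribution: DemographicDistribution = field(
        default_factory=DemographicDistribution)
    true_coefficients: pd.Series | None = None
    noise_sd: float = 0.15
    truncate_utility: bool = True

    def validate(self) -> None:
        if self.n_respondents < 0:
            raise ConfigurationError("n_respondents must be non-negative")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.region not in REGIONS:
            raise ConfigurationError(
                f"region must be one of {REGIONS}, got {self.region!r}")
        _check_probability_vector(
            self.comorbidity_distribution, COMORBIDITY_CLASSES,
            "comorbidity_distribution")
        _check_probability_vector(
            self.access_probabilities.adherence, ADHERENCE_LEVELS,
            "access_probabilities.adherence")
        for cond, dist in self.access_probabilities.adherence_by_condition.items():
            if cond not in CONDITIONS:
                raise ConfigurationError(
                    f"adherence_by_condition: unknown condition {cond!r}")
            _check_probability_vector(
                dist, ADHERENCE_LEVELS,
                f"access_probabilities.adherence_by_condition[{cond}]")
        for cond in CONDITIONS:
            p = self.condition_probabilities.get(cond)
            if p is None or not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"condition_probabilities[{cond}] must be in [0, 1]")
        for name in ("cost_prevented", "cost_cutting", "doctor_attentive"):
            p = getattr(self.access_probabilities, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"access_probabilities.{name} must be in [0, 1]")
        cells = self.demographic_distribution.cell_probabilities()
        if abs(cells.sum() - 1.0) > 1e-9 or (cells < 0).any():
            raise ConfigurationError(
                "demographic_distribution must define a probability "
                f"distribution over age_group × gender (sum={cells.sum():.12f})")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "DGPConfig":
        raw = dict(raw)
        kwargs: dict = {}
        for key in ("n_respondents", "seed", "region", "noise_sd",
                    "truncate_utility"):
            if key in raw:
                kwargs[key] = raw[key]
        if "condition_probabilities" in raw:
            kwargs["condition_probabilities"] = dict(
                raw["condition_probabilities"])
        if "comorbidity_distribution" in raw:
            kwargs["comorbidity_distribution"] = {
                str(k): v for k, v in raw["comorbidity_distribution"].items()}
        if "access_probabilities" in raw:
            ap = dict(raw["access_probabilities"])
            by_cond = {k: dict(v) for k, v in
                       ap.pop("adherence_by_condition", {}).items()}
            kwargs["access_probabilities"] = AccessProbabilities(
                adherence=dict(ap.get(
                    "adherence", DEFAULT_ADHERENCE_DISTRIBUTION)),
                adherence_by_condition=by_cond,
                cost_prevented=ap.get("cost_prevented", 0.23),
                cost_cutting=ap.get("cost_cutting", 0.41),
                doctor_attentive=ap.get("doctor_attentive", 0.91),
            )
        if "demographic_distribution" in raw:
            dd = dict(raw["demographic_distribution"])
            joint = dd.get("joint")
            if joint is not None:
                joint = {tuple(str(k).split("|")): v for k, v in joint.items()}
            kwargs["demographic_distribution"] = DemographicDistribution(
                age=dict(dd.get("age", DEFAULT_AGE_DISTRIBUTION)),
                gender=dict(dd.get("gender", DEFAULT_GENDER_DISTRIBUTION)),
                joint=joint,
            )
        if raw.get("true_coefficients") is not None:
            kwargs["true_coefficients"] = pd.Series(
                raw["true_coefficients"], dtype=float)
        config = cls(**kwargs)
        config.validate()
        return config

    @classmethod
    def from_yaml(cls, path) -> "DGPConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        ap = self.access_probabilities
        dd = self.demographic_distribution
        out = {
            "n_respondents": self.n_respondents,
            "seed": self.seed,
            "region": self.region,
            "condition_probabilities": dict(self.condition_probabilities),
            "access_probabilities": {
                "adherence": dict(ap.adherence),
                "adherence_by_condition": {
                    k: dict(v) for k, v in ap.adherence_by_condition.items()},
                "cost_prevented": ap.cost_prevented,
                "cost_cutting": ap.cost_cutting,
                "doctor_attentive": ap.doctor_attentive,
            },
            "comorbidity_distribution": dict(self.comorbidity_distribution),
            "demographic_distribution": {
                "age": dict(dd.age),
                "gender": dict(dd.gender),
                "joint": None if dd.joint is None else {
                    "|".join(k): v for k, v in dd.joint.items()},
            },
            "true_coefficients": (
                None if self.true_coefficients is None
                else {k: float(v)
                      for k, v in self.true_coefficients.items()}),
            "noise_sd": self.noise_sd,
            "truncate_utility": self.truncate_utility,
        }
        return out


def _check_probability_vector(dist, levels, name) -> None:
    missing = [lvl for lvl in levels if lvl not in dist]
    if missing:
        raise ConfigurationError(f"{name}: missing levels {missing}")
    values = np.array([dist[lvl] for lvl in levels], dtype=float)
    if (values < 0).any():
        raise ConfigurationError(f"{name}: negative probability")
    if abs(values.sum() - 1.0) > 1e-9:
        raise ConfigurationError(
            f"{name}: probabilities sum to {values.sum():.12f}, expected 1")


def _draw_categorical(rng, levels, probs, n) -> np.ndarray:
    idx = rng.choice(len(levels), size=n, p=np.asarray(probs, dtype=float))
    return np.asarray(levels, dtype=object)[idx]


def generate_synthetic_survey(config: DGPConfig) -> pd.DataFrame:
    """Draw a synthetic respondent table from the configured process.

    Covariates are sampled independently from their configured marginals;
    utility is the linear predictor under ``config.true_coefficients``
    (default: a sign-realistic coefficient set, see
    :func:`unmetneed.model.paper_signed_coefficients`) plus Gaussian noise.
    Identical configs (including seed) give bit-identical tables.
    """
    from . import model  # local import to avoid a module cycle

    config.validate()
    n = config.n_respondents
    rng = np.random.default_rng(config.seed)

    cells = config.demographic_distribution.cell_probabilities()
    cell_idx = rng.choice(len(cells), size=n, p=cells.to_numpy())
    age = np.asarray([cells.index[i][0] for i in range(len(cells))],
                     dtype=object)[cell_idx]
    gender = np.asarray([cells.index[i][1] for i in range(len(cells))],
                        dtype=object)[cell_idx]

    comorbidity = _draw_categorical(
        rng, COMORBIDITY_CLASSES,
        [config.comorbidity_distribution[c] for c in COMORBIDITY_CLASSES], n)

    flags = {
        cond: rng.random(n) < config.condition_probabilities[cond]
        for cond in CONDITIONS
    }

    ap = config.access_probabilities
    adherence_probs = np.tile(
        np.array([ap.adherence[lvl] for lvl in ADHERENCE_LEVELS]), (n, 1))
    # later conditions first so the first canonical condition wins
    for cond in reversed(CONDITIONS):
        override = ap.adherence_by_condition.get(cond)
        if override is not None:
            row = np.array([override[lvl] for lvl in ADHERENCE_LEVELS])
            adherence_probs[flags[cond]] = row
    u = rng.random(n)
    cum = np.cumsum(adherence_probs, axis=1)
    adherence = np.asarray(ADHERENCE_LEVELS, dtype=object)[
        (u[:, None] > cum).sum(axis=1).clip(0, len(ADHERENCE_LEVELS) - 1)]

    cost_prevented = rng.random(n) < ap.cost_prevented
    cost_cutting = rng.random(n) < ap.cost_cutting
    doctor_attentive = rng.random(n) < ap.doctor_attentive

    table = pd.DataFrame({
        "respondent_id": [f"r{i:07d}" for i in range(n)],
        "region": np.repeat(config.region, n),
        "age_group": age,
        "gender": gender,
        **{cond: flags[cond] for cond in CONDITIONS},
        "comorbidity_class": comorbidity,
        "adherence_level": adherence,
        "cost_prevented": cost_prevented,
        "cost_cutting": cost_cutting,
        "doctor_attentive": doctor_attentive,
    })

    beta = config.true_coefficients
    if beta is None:
        beta = model.paper_signed_coefficients()
    spec = model.ModelSpec()
    if list(beta.index) != spec.term_names():
        raise ConfigurationError(
            "true_coefficients must be indexed by the default model terms; "
            f"got {len(beta)} terms, expected {len(spec.term_names())}")

    if n == 0:
        table["utility"] = pd.Series(dtype=float)
        table.attrs["provenance"] = "synthetic"
        return table

    design = model.build_design_matrix(table, spec)
    linpred = design.to_numpy() @ beta.to_numpy()
    utility = linpred + rng.normal(0.0, config.noise_sd, size=n)
    if config.truncate_utility:
        utility = np.clip(utility, UTILITY_MIN, UTILITY_MAX)
    table["utility"] = utility
    table.attrs["provenance"] = "synthetic"
    return table


# Validation -------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    row_id: object
    field: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)

    def __str__(self) -> str:
        if self.ok:
            return "no violations"
        return "\n".join(
            f"[{v.row_id}] {v.field}: {v.message}" for v in self.violations)


def validate_survey(table: pd.DataFrame) -> ValidationReport:
    """Check every table invariant; report violations without mutating.

    Checks: required columns present, respondent_id uniqueness, categorical
    levels, boolean dtypes, and the utility range [−1, 1].
    """
    report = ValidationReport()
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    for col in missing:
        report.violations.append(Violation("<table>", col, "missing column"))
    if missing:
        return report

    dup = table["respondent_id"][table["respondent_id"].duplicated()]
    for rid in dup.unique():
        report.violations.append(
            Violation(rid, "respondent_id", "duplicate identifier"))

    for col, levels in CATEGORY_LEVELS.items():
        bad = ~table[col].isin(levels)
        for rid, value in zip(table.loc[bad, "respondent_id"],
                              table.loc[bad, col]):
            report.violations.append(Violation(
                rid, col, f"level {value!r} not in {levels}"))

    for col in BOOL_COLUMNS:
        values = table[col]
        if values.dtype != bool:
            ok = values.isin([0, 1, True, False])
            for rid in table.loc[~ok, "respondent_id"]:
                report.violations.append(
                    Violation(rid, col, "not interpretable as boolean"))

    utility = pd.to_numeric(table["utility"], errors="coerce")
    bad = utility.isna() | (utility > UTILITY_MAX) | (utility < UTILITY_MIN)
    for rid, value in zip(table.loc[bad, "respondent_id"],
                          table.loc[bad, "utility"]):
        report.violations.append(Violation(
            rid, "utility",
            f"value {value!r} outside [{UTILITY_MIN}, {UTILITY_MAX}]"))
    return report


# I/O ---------------------------------------------------------------------------

def _coerce_bool(series: pd.Series, col: str) -> pd.Series:
    tokens = series.astype(str).str.strip().str.lower()
    out = pd.Series(index=series.index, dtype=object)
    out[tokens.isin(_TRUE_TOKENS)] = True
    out[tokens.isin(_FALSE_TOKENS)] = False
    bad = out.isna()
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"column {col!r}, row {i}: cannot interpret "
            f"{series.iloc[i]!r} as a boolean")
    return out.astype(bool)


def _coerce_category(series: pd.Series, col: str,
                     levels: Sequence[str]) -> pd.Series:
    lookup = {lvl.lower(): lvl for lvl in levels}
    # accept en-dash in age bands
    tokens = series.astype(str).str.strip().str.replace(
        "–", "-", regex=False).str.lower()
    mapped = tokens.map(lookup)
    bad = mapped.isna()
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"column {col!r}, row {i}: level {series.iloc[i]!r} "
            f"not one of {tuple(levels)}")
    return mapped


def read_survey(path, delimiter: str | None = None) -> pd.DataFrame:
    """Read and validate a delimited survey file.

    Comma is the default delimiter; tab is accepted (``delimiter=None``
    sniffs between the two). Booleans may be coded ``0/1`` or ``no/yes``;
    categorical levels are matched case-insensitively. Rows with missing
    values in any modeled field are dropped with a logged count. Invariant
    violations (bad level, utility outside [−1, 1], duplicate ids) raise.
    """
    if delimiter is None:
        raw = pd.read_csv(path, sep=None, engine="python", dtype=str)
    else:
        raw = pd.read_csv(path, sep=delimiter, dtype=str)
    raw.columns = [c.strip().lower() for c in raw.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"survey file missing columns: {missing}")

    n_before = len(raw)
    keep = list(REQUIRED_COLUMNS) + [
        c for c in OPTIONAL_COLUMNS if c in raw.columns]
    raw = raw[keep].dropna()
    if len(raw) < n_before:
        logger.info("dropped %d row(s) with missing values",
                    n_before - len(raw))
    raw = raw.reset_index(drop=True)

    table = pd.DataFrame({"respondent_id": raw["respondent_id"].str.strip()})
    for col, levels in CATEGORY_LEVELS.items():
        table[col] = _coerce_category(raw[col], col, levels)
    # keep spec column order
    for col in BOOL_COLUMNS:
        table[col] = _coerce_bool(raw[col], col)
    utility = pd.to_numeric(raw["utility"], errors="coerce")
    if utility.isna().any():
        i = int(np.flatnonzero(utility.isna().to_numpy())[0])
        raise ValueError(f"column 'utility', row {i}: not a number")
    table["utility"] = utility
    if "weight" in raw.columns:
        table["weight"] = pd.to_numeric(raw["weight"])
    table = table[[c for c in REQUIRED_COLUMNS] +
                  [c for c in OPTIONAL_COLUMNS if c in table.columns]]

    report = validate_survey(table)
    if not report.ok:
        first = report.violations[0]
        raise ValueError(
            f"invalid survey file ({len(report)} violation(s)); first: "
            f"row id {first.row_id}, {first.field}: {first.message}")
    table.attrs["provenance"] = str(path)
    return table


def write_survey(table: pd.DataFrame, path, delimiter: str = ",") -> None:
    """Write a survey table as delimited text (booleans as 0/1)."""
    out = table.copy()
    for col in BOOL_COLUMNS:
        if col in out.columns:
            out[col] = out[col].astype(int)
    out.to_csv(path, sep=delimiter, index=False)


def survey_to_string(table: pd.DataFrame, delimiter: str = ",") -> str:
    buf = io.StringIO()
    write_survey(table, buf, delimiter=delimiter)
    return buf.getvalue()
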