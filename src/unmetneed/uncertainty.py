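"""Simulation-based confidence intervals for derived quantities.

Coefficients are drawn from the asymptotic multivariate normal distribution
of the fitted regression (1000 draws by default). Each derived quantity —
a scenario mean utility, a decomposition component, an adjusted disease
disutility, a YLD total — is recomputed per draw, and the point estimate and
95% interval are the mean and the empirical 2.5/97.5 percentiles of the
resulting draw distribution (percentiles by linear interpolation between
order statistics). Prevalence uncertainty is not propagated: only the
regression coefficients are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import counterfactual, model as model_mod
from .errors import NumericError

DEFAULT_N_SIMS = 1000


@dataclass
class CoefficientDraws:
    """Matrix of simulated coefficient vectors (n_sims × n_terms)."""

    draws: np.ndarray
    term_names: list[str]
    seed: int
    source_model: model_mod.FittedUtilityModel

    def __post_init__(self):
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 2 or self.draws.shape[0] < 1:
            raise ValueError("draws must be a non-empty 2-D matrix")
        if self.draws.shape[1] != len(self.term_names):
            raise ValueError("draw columns do not align with term_names")

    @property
    def n_sims(self) -> int:
        return self.draws.shape[0]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=self.term_names)


@dataclass(frozen=True)
class IntervalEstimate:
    """Mean and empirical 95% interval of a simulated quantity."""

    mean: float
    lower_2_5: float
    upper_97_5: float
    n_sims: int

    def __post_init__(self):
        if not (self.lower_2_5 <= self.mean + 1e-12
                and self.mean <= self.upper_97_5 + 1e-12):
            raise ValueError("interval does not bracket the mean")

    @property
    def width(self) -> float:
        return self.upper_97_5 - self.lower_2_5

    def contains(self, value: float) -> bool:
        return self.lower_2_5 <= value <= self.upper_97_5


def _factor_covariance(cov: np.ndarray) -> np.ndarray:
    """Lower-triangular factor L with LLᵀ = cov; jitter fallback for PSD."""
    asym = np.abs(cov - cov.T).max()
    scale = max(np.abs(cov).max(), 1.0)
    if asym > 1e-8 * scale:
        raise NumericError(f"covariance not symmetric (max asym {asym:g})")
    if not cov.any():  # degenerate: zero covariance
        return np.zeros_like(cov)
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        pass
    jitter = 1e-10 * scale
    try:
        return np.linalg.cholesky(cov + jitter * np.eye(cov.shape[0]))
    except np.linalg.LinAlgError as exc:
        raise NumericError(
            "covariance is not positive semidefinite within tolerance; "
            "consider a nearest-PSD repair of the input model") from exc


def simulate_coefficients(model: model_mod.FittedUtilityModel,
                          n_sims: int = DEFAULT_N_SIMS,
                          seed: int = 0) -> CoefficientDraws:
    """Draw coefficient vectors from N(estimates, covariance).

    Reproducible for identical (model, n_sims, seed). A zero covariance
    matrix yields draws identical to the point estimates.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    cov = model.covariance.to_numpy()
    mean = model.coefficients.to_numpy()
    L = _factor_covariance(cov)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_sims, len(mean)))
    draws = mean + z @ L.T
    return CoefficientDraws(draws=draws,
                            term_names=list(model.coefficients.index),
                            seed=seed, source_model=model)


class LinearFunctional:
    """A quantity linear in the coefficients: q(β) = w·β + offset.

    Scenario means, decomposition components, adjusted disutilities, and YLD
    cells are all of this form (the design is fixed; only β varies), so
    intervals for them can be vectorized across draws.
    """

    def __init__(self, weights: pd.Series, offset: float = 0.0):
        self.weights = weights.astype(float)
        self.offset = float(offset)

    def __call__(self, coefficients: pd.Series) -> float:
        return float(self.weights @ coefficients.loc[self.weights.index]
                     ) + self.offset

    def evaluate_draws(self, draws: CoefficientDraws) -> np.ndarray:
        # terms absent from the weights contribute nothing
        w = self.weights.reindex(draws.term_names, fill_value=0.0).to_numpy()
        return draws.draws @ w + self.offset


def interval_for_quantity(draws: CoefficientDraws, quantity,
                          ) -> IntervalEstimate:
    """Mean and 2.5/97.5 percentiles of a quantity across coefficient draws.

    ``quantity`` maps a coefficient vector (pd.Series indexed by term name)
    to a real number; :class:`LinearFunctional` instances are evaluated
    vectorized. Evaluation failures are reported with the draw index.
    """
    if isinstance(quantity, LinearFunctional):
        values = quantity.evaluate_draws(draws)
    else:
        values = np.empty(draws.n_sims)
        for i, row in enumerate(draws.draws):
            try:
                values[i] = quantity(
                    pd.Series(row, index=draws.term_names))
            except Exception as exc:
                raise RuntimeError(
                    f"quantity evaluation failed on draw {i}") from exc
    lower, upper = np.percentile(values, [2.5, 97.5])
    if values.max() == values.min():  # degenerate draws: avoid mean round-off
        return IntervalEstimate(mean=float(values[0]),
                                lower_2_5=float(values[0]),
                                upper_97_5=float(values[0]),
                                n_sims=draws.n_sims)
    return IntervalEstimate(mean=float(values.mean()),
                            lower_2_5=float(lower), upper_97_5=float(upper),
                            n_sims=draws.n_sims)


# Functional builders -----------------------------------------------------------

def scenario_mean_functional(model: model_mod.FittedUtilityModel,
                             table: pd.DataFrame, condition: str,
                             scenario: str,
                             worst_adherence: str = "low_medium",
                             ) -> LinearFunctional:
    """Mean scenario utility over the condition's respondents, as w·β."""
    subset = table[table[condition].astype(bool)]
    if len(subset) == 0:
        raise ValueError(f"no respondent has condition {condition!r}")
    transformed = counterfactual.apply_scenario(
        subset, scenario, condition, worst_adherence=worst_adherence)
    X = model_mod.build_design_matrix(transformed, model.spec)
    return LinearFunctional(X.mean(axis=0))


def adjusted_disutility_functional(model: model_mod.FittedUtilityModel,
                                   table: pd.DataFrame, condition: str,
                                   ) -> LinearFunctional:
    """Adjusted disease disutility (observed minus disease-removed) as w·β."""
    subset = table[table[condition].astype(bool)]
    if len(subset) == 0:
        raise ValueError(f"no respondent has condition {condition!r}")
    X_obs = model_mod.build_design_matrix(subset, model.spec)
    X_rem = model_mod.build_design_matrix(
        counterfactual.remove_condition(subset, condition), model.spec)
    return LinearFunctional(X_obs.mean(axis=0) - X_rem.mean(axis=0))


def component_functional(model: model_mod.FittedUtilityModel,
                         table: pd.DataFrame, condition: str, category: str,
                         worst_adherence: str = "low_medium",
                         ) -> LinearFunctional:
    """A need-decomposition component (overall stratum) as w·β (+ offset)."""
    def w(scenario):
        return scenario_mean_functional(
            model, table, condition, scenario,
            worst_adherence=worst_adherence).weights

    if category == "met_need":
        return LinearFunctional(w("observed") - w("worst"))
    if category == "unmet_ineffective_use":
        return LinearFunctional(w("optimal") - w("observed"))
    if category == "unmet_lack_of_tech":
        return LinearFunctional(w("no_disease_optimal") - w("optimal"))
    if category == "comorbidity_residual":
        return LinearFunctional(-w("no_disease_optimal"), offset=1.0)
    raise ValueError(f"unknown category {category!r}; one of "
                     f"{counterfactual.NEED_CATEGORIES}")
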