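"""Prevalence input and years-lost-to-disutility (YLD) aggregation.

Burden per stratum is the disutility weight of a need category multiplied by
the prevalent case count in that stratum::

    YLD(a, g, c) = DW(a, g, c) · p(a, g, c)

where the disutility weight DW is a component of the need decomposition
(met need, unmet need from ineffective use of current technologies, unmet
need from lack of technologies, or the comorbidity residual) and p comes
from a Global Burden of Disease (GBD) Results Tool export. Totals are sums
across age and gender. The mortality (YLL) term of the DALY is out of
scope: the survey source carries no mortality data.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .counterfactual import ALL, NEED_CATEGORIES
from .errors import JoinError, SchemaError
from .survey import AGE_GROUPS, CONDITIONS, GENDERS, REGIONS

logger = logging.getLogger(__name__)

GBD_COLUMNS = ("measure", "location", "sex", "age", "cause", "metric",
               "year", "val")

DEFAULT_LOCATION_TO_REGION: dict[str, str] = {
    "united states": "US",
    "united states of america": "US",
    "united kingdom": "EU5",
    "germany": "EU5",
    "france": "EU5",
    "italy": "EU5",
    "spain": "EU5",
}
EU5_COUNTRIES = ("United Kingdom", "Germany", "France", "Italy", "Spain")

DEFAULT_CAUSE_TO_CONDITION: dict[str, str] = {
    "rheumatoid arthritis": "rheumatoid_arthritis",
    "breast cancer": "breast_cancer",
    "parkinson's disease": "parkinsons",
    "parkinson disease": "parkinsons",
    "hepatitis c": "hepatitis_c",
    "acute hepatitis c": "hepatitis_c",
    "chronic obstructive pulmonary disease": "copd",
}
DEFAULT_SEX_TO_GENDER: dict[str, str] = {"male": "male", "female": "female"}

#: survey age-group boundaries the GBD bands must nest within
_BOUNDS = {"18-34": (15, 34), "35-54": (35, 54), "55-74": (55, 74),
           "75+": (75, None)}

_AGE_RE = re.compile(
    r"^\s*(\d+)\s*(?:to|-|–)\s*(\d+)|^\s*(\d+)\s*(?:plus|\+)", re.IGNORECASE)


def map_age_band(label: str) -> str | None:
    """Map a GBD age-band label onto a survey age group.

    Five-year GBD bands nest cleanly at the 35/55/75 boundaries; bands that
    straddle a boundary raise. The 15–19 band is assigned to 18–34 (the
    survey covers adults only) and bands entirely below 15 return None, to
    be skipped by the caller.
    """
    cleaned = label.strip().lower().replace("years", "").strip()
    m = _AGE_RE.match(cleaned)
    if not m:
        raise ValueError(f"unparseable GBD age band {label!r}")
    if m.group(3) is not None:  # open-ended "NN plus"
        lo, hi = int(m.group(3)), None
    else:
        lo, hi = int(m.group(1)), int(m.group(2))
    if hi is not None and hi < 15:
        return None
    if hi is None:
        if lo >= 75:
            return "75+"
        raise ValueError(
            f"open-ended band {label!r} straddles the 75+ boundary")
    for group, (glo, ghi) in _BOUNDS.items():
        if lo >= glo and (ghi is None or hi <= ghi):
            if group == "18-34" and lo < 18:
                logger.info(
                    "GBD band %r assigned to 18-34 (survey covers adults)",
                    label)
            return group
    raise ValueError(
        f"GBD age band {label!r} straddles a survey age-group boundary "
        "(35/55/75); pre-aggregate or exclude it")


def read_gbd_prevalence(path,
                        location_to_region: dict[str, str] | None = None,
                        cause_to_condition: dict[str, str] | None = None,
                        ) -> pd.DataFrame:
    """Read a GBD Results Tool CSV export into a prevalence table.

    Keeps rows with ``measure == Prevalence`` and ``metric == Number``,
    collapses GBD five-year age bands into the four survey age groups by
    summation, maps the five EU5 countries onto one EU5 region (counts
    summed), and maps cause names onto the five condition labels. Rows with
    unmapped locations, causes, or sexes are skipped with a logged count.

    Returns a frame keyed uniquely by (region, condition, age_group,
    gender) with a ``prevalent_count`` column.
    """
    loc_map = {k.lower(): v for k, v in
               (location_to_region or DEFAULT_LOCATION_TO_REGION).items()}
    cause_map = {k.lower(): v for k, v in
                 (cause_to_condition or DEFAULT_CAUSE_TO_CONDITION).items()}

    raw = pd.read_csv(path)
    raw.columns = [c.strip().lower() for c in raw.columns]
    missing = [c for c in GBD_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"GBD export missing columns: {missing}")

    raw = raw[raw["measure"].str.strip().str.lower() == "prevalence"]
    raw = raw[raw["metric"].str.strip().str.lower() == "number"]

    region = raw["location"].str.strip().str.lower().map(loc_map)
    condition = raw["cause"].str.strip().str.lower().map(cause_map)
    gender = raw["sex"].str.strip().str.lower().map(DEFAULT_SEX_TO_GENDER)
    keep = region.notna() & condition.notna() & gender.notna()
    skipped = int((~keep).sum())
    if skipped:
        logger.warning(
            "skipped %d GBD row(s) with unmapped location, cause, or sex",
            skipped)
    raw = raw[keep]

    age_group = raw["age"].map(map_age_band)
    below = int(age_group.isna().sum())
    if below:
        logger.info("skipped %d GBD row(s) below the adult age range", below)

    out = pd.DataFrame({
        "region": region[keep].to_numpy(),
        "condition": condition[keep].to_numpy(),
        "age_group": age_group.to_numpy(),
        "gender": gender[keep].to_numpy(),
        "prevalent_count": pd.to_numeric(raw["val"]).to_numpy(),
    }).dropna(subset=["age_group"])
    if (out["prevalent_count"] < 0).any():
        raise ValueError("negative prevalent count in GBD export")

    return (out.groupby(["region", "condition", "age_group", "gender"],
                        observed=True, as_index=False)["prevalent_count"]
            .sum())


def compute_yld(decomposition: pd.DataFrame,
                prevalence: pd.DataFrame) -> pd.DataFrame:
    """Multiply decomposition components by prevalent counts per stratum.

    ``decomposition`` is the output of
    :func:`unmetneed.counterfactual.decompose_need`; overall rows
    (age_group == gender == 'all') are ignored for the join. Every remaining
    stratum must have a matching prevalence row, otherwise a
    :class:`JoinError` lists the unmatched strata.
    """
    keys = ["region", "condition", "age_group", "gender"]
    strata = decomposition[(decomposition["age_group"] != ALL)
                           & (decomposition["gender"] != ALL)]
    long = strata.melt(id_vars=keys + ["total_need"],
                       value_vars=list(NEED_CATEGORIES),
                       var_name="category", value_name="disutility_weight")
    merged = long.merge(
        prevalence[keys + ["prevalent_count"]], on=keys, how="left")
    unmatched = merged[merged["prevalent_count"].isna()]
    if len(unmatched):
        missing = sorted(set(map(tuple, unmatched[keys].to_numpy())))
        raise JoinError(missing)
    merged["yld"] = merged["disutility_weight"] * merged["prevalent_count"]
    return merged[["region", "condition", "category", "age_group", "gender",
                   "disutility_weight", "prevalent_count", "yld"]]


def aggregate_yld(table: pd.DataFrame,
                  by: tuple[str, ...] = ("region", "condition", "category"),
                  ) -> pd.DataFrame:
    """Sum YLD within the requested grouping keys (default: across strata)."""
    allowed = {"region", "condition", "category", "age_group", "gender"}
    unknown = [k for k in by if k not in allowed]
    if unknown:
        raise ValueError(f"unknown grouping key(s) {unknown}; "
                         f"choose from {sorted(allowed)}")
    return (table.groupby(list(by), observed=True, as_index=False)["yld"]
            .sum())


def synthetic_gbd_export(path=None) -> pd.DataFrame:
    """Construct a synthetic GBD Results Tool export (no real GBD data).

    Deterministic stand-in for a Results Tool prevalence query covering the
    five study conditions in the US and the five EU5 countries, with
    five-year age bands from 15–19 through 95 plus. Case counts are
    plausible orders of magnitude for 2013 adult prevalence, split over age
    bands with condition-typical age profiles; they are invented, not
    measured. Writes CSV to ``path`` when given; returns the frame.
    """
    base_counts = {  # total adult prevalent cases, US scale
        "Rheumatoid arthritis": 1.3e6,
        "Breast cancer": 3.1e6,
        "Parkinson's disease": 0.7e6,
        "Acute hepatitis C": 2.4e6,
        "Chronic obstructive pulmonary disease": 15.0e6,
    }
    female_share = {
        "Rheumatoid arthritis": 0.72,
        "Breast cancer": 0.99,
        "Parkinson's disease": 0.42,
        "Acute hepatitis C": 0.40,
        "Chronic obstructive pulmonary disease": 0.52,
    }
    # relative weight per 5-year band, young → old
    bands = ["15 to 19", "20 to 24", "25 to 29", "30 to 34", "35 to 39",
             "40 to 44", "45 to 49", "50 to 54", "55 to 59", "60 to 64",
             "65 to 69", "70 to 74", "75 to 79", "80 to 84", "85 to 89",
             "90 to 94", "95 plus"]
    age_profile = {
        "Rheumatoid arthritis": [1, 2, 3, 4, 6, 8, 10, 12, 13, 13, 12, 10,
                                 8, 5, 3, 1, 0.5],
        "Breast cancer": [0.2, 0.5, 1, 2, 4, 7, 10, 12, 13, 13, 12, 10, 8,
                          5, 3, 1, 0.5],
        "Parkinson's disease": [0.1, 0.1, 0.2, 0.3, 0.5, 1, 2, 4, 7, 10, 13,
                                15, 15, 12, 8, 4, 1],
        "Acute hepatitis C": [2, 4, 6, 8, 10, 12, 13, 13, 11, 8, 5, 3, 2, 1,
                              0.5, 0.3, 0.2],
        "Chronic obstructive pulmonary disease": [0.5, 1, 2, 3, 5, 7, 9, 11,
                                                  13, 13, 12, 10, 7, 4, 2,
                                                  0.7, 0.3],
    }
    country_scale = {
        "United States": 1.0,
        "United Kingdom": 0.20, "Germany": 0.26, "France": 0.21,
        "Italy": 0.19, "Spain": 0.15,
    }
    rows = []
    for cause, total in base_counts.items():
        profile = np.asarray(age_profile[cause], dtype=float)
        profile = profile / profile.sum()
        for country, scale in country_scale.items():
            for sex in ("Female", "Male"):
                share = (female_share[cause] if sex == "Female"
                         else 1 - female_share[cause])
                for band, w in zip(bands, profile):
                    val = total * scale * share * w
                    rows.append({
                        "measure": "Prevalence", "location": country,
                        "sex": sex, "age": band, "cause": cause,
                        "metric": "Number", "year": 2013,
                        "val": round(val, 1),
                        "upper": round(val * 1.15, 1),
                        "lower": round(val * 0.85, 1),
                    })
    frame = pd.DataFrame(rows)
    if path is not None:
        frame.to_csv(path, index=False)
    return frame
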