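"""Synthetic NHANES-like cohort generation with known ground truth.

The generator draws participant tables whose marginals emulate a US adult
survey cohort — sex-specific right-skewed nutrient intakes, categorical
lifestyle factors, covariate prevalences near published baseline tables — and
whose serum uric acid (SUA) is generated from a known linear effect of lnOBS,
so scoring and association stages can be validated by parameter recovery.

Generative model
----------------
* Dietary intakes are log-normal per sex.  Default (mu, sigma) per component
  are solved from the published sex-specific tertile cutoffs (c1, c2): the
  tertile boundaries of LogNormal(mu, sigma) sit at exp(mu ± z * sigma) with
  z = Phi^{-1}(2/3), so mu = (ln c1 + ln c2)/2 and
  sigma = (ln c2 − ln c1)/(2 z).  A shared standard-normal "diet quality"
  factor with loading lambda correlates the log-intakes (marginals unchanged),
  which widens the OBS distribution toward the dispersion seen in real data.
* Lifestyle factors and covariates are categorical draws with configurable
  probabilities; BMI is drawn within its sampled category.
* SUA = intercept(sex) + obs_effect(sex) * lnOBS + Normal(0, sd(sex)), with
  lnOBS computed from data-driven sex-stratified tertile cutoffs on the
  complete (pre-missingness) intakes — so the true conditional slope of SUA
  on lnOBS given sex equals ``obs_effect``.
* Missingness is then applied independently per dietary component.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy.stats import norm

from .errors import CohortParseError, InsufficientDataError
from .scoring import DIETARY_COMPONENTS, SEXES, builtin_table, compute_obs, derive_cutoffs

_Z_TERTILE = float(norm.ppf(2 / 3))

#: canonical cohort column order
COHORT_COLUMNS = (
    ("id", "sex", "age")
    + DIETARY_COMPONENTS
    + (
        "physical_activity",
        "alcohol_g_per_day",
        "smoking3",
        "bmi_kg_m2",
        "sua_umol_l",
        "race",
        "education",
        "pir",
        "smoking_binary",
        "drinking_binary",
        "hypertension",
        "diabetes",
        "hyperlipidemia",
        "weight",
    )
)

#: columns that must parse as numbers when reading a cohort file
NUMERIC_COLUMNS = ("age",) + DIETARY_COMPONENTS + (
    "alcohol_g_per_day",
    "bmi_kg_m2",
    "sua_umol_l",
    "pir",
    "weight",
)

RACE_LEVELS = (
    "Mexican American",
    "Other Hispanic",
    "Non-Hispanic White",
    "Non-Hispanic Black",
    "Other Race",
)

EDUCATION_LEVELS = (
    "Less than 9th grade",
    "9-11th grade",
    "High school graduate",
    "College degree",
    "College graduate or above",
)


def default_nutrient_params() -> dict[str, dict[str, tuple[float, float]]]:
    """Per-component, per-sex (mu, sigma) of log intake solved from the
    published tertile cutoffs, so simulated tertiles land near the published
    ones."""
    out: dict[str, dict[str, tuple[float, float]]] = {}
    table = builtin_table()
    for comp in table:
        if comp.mode != "tertile":
            continue
        out[comp.name] = {}
        for sex in SEXES:
            c1, c2 = comp.cutoffs[sex]
            mu = (math.log(c1) + math.log(c2)) / 2
            sigma = (math.log(c2) - math.log(c1)) / (2 * _Z_TERTILE)
            out[comp.name][sex] = (mu, sigma)
    return out


class LifestyleProbs(BaseModel):
    """Category probabilities for the lifestyle draws."""

    model_config = ConfigDict(frozen=True)

    physical_activity: dict[str, float] = Field(
        default={"low": 0.30, "moderate": 0.40, "high": 0.30}
    )
    smoking3: dict[str, float] = Field(
        default={"never": 0.56, "former": 0.22, "current": 0.22}
    )
    bmi_category: dict[str, float] = Field(
        default={"underweight": 0.015, "normal": 0.265, "overweight": 0.32, "obese": 0.40}
    )
    #: probability of zero alcohol intake (non-drinker point mass)
    alcohol_p_nondrinker: float = Field(default=0.34, ge=0.0, le=1.0)
    #: log-normal (mu, sigma) of g/d among drinkers
    alcohol_log_mu: float = 2.08
    alcohol_log_sigma: float = Field(default=1.0, gt=0.0)

    @field_validator("physical_activity", "smoking3", "bmi_category")
    @classmethod
    def _probs_sum_to_one(cls, v, info):
        if any(p < 0 or p > 1 for p in v.values()):
            raise ValueError(f"{info.field_name}: probabilities must lie in [0, 1]")
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError(f"{info.field_name}: probabilities must sum to 1")
        return v


class CohortConfig(BaseModel):
    """Full specification of a synthetic cohort draw.

    Invalid values raise a validation error naming the offending field.
    """

    model_config = ConfigDict(frozen=True)

    n_participants: int = Field(default=15096, ge=1)
    seed: int = 0
    prop_male: float = Field(default=0.497, ge=0.0, le=1.0)
    age_range: tuple[int, int] = (18, 80)
    nutrient_params: dict[str, dict[str, tuple[float, float]]] = Field(
        default_factory=default_nutrient_params
    )
    #: loading of the shared latent diet-quality factor on log intakes
    diet_quality_loading: float = Field(default=0.74, ge=0.0, lt=1.0)
    lifestyle_probs: LifestyleProbs = Field(default_factory=LifestyleProbs)
    #: per-sex (intercept µmol/L, noise SD µmol/L) of the SUA draw
    sua_baseline: dict[str, tuple[float, float]] = Field(
        default={"male": (411.0, 60.0), "female": (338.0, 60.0)}
    )
    #: true SUA change (µmol/L) per unit lnOBS; scalar or per-sex mapping
    obs_effect: float | dict[str, float] = -14.0
    covariate_prevalences: dict[str, float] = Field(
        default={"hypertension": 0.36, "diabetes": 0.14, "hyperlipidemia": 0.35}
    )
    race_probs: dict[str, float] = Field(
        default={
            "Mexican American": 0.132,
            "Other Hispanic": 0.100,
            "Non-Hispanic White": 0.412,
            "Non-Hispanic Black": 0.214,
            "Other Race": 0.142,
        }
    )
    education_probs: dict[str, float] = Field(
        default={
            "Less than 9th grade": 0.076,
            "9-11th grade": 0.118,
            "High school graduate": 0.227,
            "College degree": 0.321,
            "College graduate or above": 0.258,
        }
    )
    #: gamma (shape, scale) of the poverty-to-income ratio
    pir_params: tuple[float, float] = (2.41, 1.05)
    missing_rate: float = Field(default=0.02, ge=0.0, le=1.0)

    @field_validator("age_range")
    @classmethod
    def _age_range_valid(cls, v):
        lo, hi = v
        if not (0 <= lo < hi):
            raise ValueError("age_range must satisfy 0 <= min < max")
        return v

    @field_validator("nutrient_params")
    @classmethod
    def _scales_positive(cls, v):
        for name, per_sex in v.items():
            for sex, (mu, sigma) in per_sex.items():
                if sigma <= 0:
                    raise ValueError(f"nutrient_params[{name}][{sex}]: scale must be > 0")
        return v

    @field_validator("sua_baseline")
    @classmethod
    def _sua_valid(cls, v):
        for sex in SEXES:
            if sex not in v:
                raise ValueError(f"sua_baseline must cover {sex!r}")
            mean, sd = v[sex]
            if sd <= 0:
                raise ValueError(f"sua_baseline[{sex}]: SD must be > 0")
        return v

    @field_validator("covariate_prevalences", "race_probs", "education_probs")
    @classmethod
    def _fractions(cls, v, info):
        if any(p < 0 or p > 1 for p in v.values()):
            raise ValueError(f"{info.field_name}: fractions must lie in [0, 1]")
        if info.field_name in ("race_probs", "education_probs"):
            if abs(sum(v.values()) - 1.0) > 1e-9:
                raise ValueError(f"{info.field_name}: probabilities must sum to 1")
        return v

    def effect_for(self, sex: str) -> float:
        if isinstance(self.obs_effect, Mapping):
            return float(self.obs_effect[sex])
        return float(self.obs_effect)


def _choice(rng: np.random.Generator, probs: Mapping[str, float], n: int) -> np.ndarray:
    levels = list(probs.keys())
    p = np.asarray(list(probs.values()), dtype=float)
    return rng.choice(levels, size=n, p=p / p.sum())


_BMI_RANGES = {"underweight": (16.0, 18.4), "normal": (18.5, 24.9), "overweight": (25.0, 29.9)}


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a cohort table per ``config``; identical config => identical table."""
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    sex = np.where(rng.random(n) < config.prop_male, "male", "female")
    lo, hi = config.age_range
    age = rng.integers(lo, hi + 1, size=n).astype(float)

    lam = config.diet_quality_loading
    factor = rng.standard_normal(n)
    intakes = {}
    for name in DIETARY_COMPONENTS:
        per_sex = config.nutrient_params[name]
        mu = np.where(sex == "male", per_sex["male"][0], per_sex["female"][0])
        sigma = np.where(sex == "male", per_sex["male"][1], per_sex["female"][1])
        z = lam * factor + math.sqrt(1 - lam**2) * rng.standard_normal(n)
        intakes[name] = np.exp(mu + sigma * z)

    lp = config.lifestyle_probs
    physical_activity = _choice(rng, lp.physical_activity, n)
    smoking3 = _choice(rng, lp.smoking3, n)
    bmi_cat = _choice(rng, lp.bmi_category, n)
    bmi = np.empty(n)
    for cat, (b_lo, b_hi) in _BMI_RANGES.items():
        mask = bmi_cat == cat
        bmi[mask] = rng.uniform(b_lo, b_hi, size=int(mask.sum()))
    obese = bmi_cat == "obese"
    bmi[obese] = np.clip(30.0 + rng.gamma(2.0, 2.5, size=int(obese.sum())), 30.0, 60.0)

    drinker = rng.random(n) >= lp.alcohol_p_nondrinker
    alcohol = np.where(
        drinker, rng.lognormal(lp.alcohol_log_mu, lp.alcohol_log_sigma, size=n), 0.0
    )

    race = _choice(rng, config.race_probs, n)
    education = _choice(rng, config.education_probs, n)
    shape, scale = config.pir_params
    pir = rng.gamma(shape, scale, size=n)
    prev = config.covariate_prevalences
    hypertension = np.where(rng.random(n) < prev["hypertension"], "yes", "no")
    diabetes = np.where(rng.random(n) < prev["diabetes"], "yes", "no")
    hyperlipidemia = np.where(rng.random(n) < prev["hyperlipidemia"], "yes", "no")
    smoking_binary = np.where(smoking3 == "never", "no", "yes")
    drinking_binary = np.where(alcohol > 0, "yes", "no")

    df = pd.DataFrame(
        {
            "id": [f"P{i:06d}" for i in range(n)],
            "sex": sex,
            "age": age,
            **intakes,
            "physical_activity": physical_activity,
            "alcohol_g_per_day": alcohol,
            "smoking3": smoking3,
            "bmi_kg_m2": bmi,
            "race": race,
            "education": education,
            "pir": pir,
            "smoking_binary": smoking_binary,
            "drinking_binary": drinking_binary,
            "hypertension": hypertension,
            "diabetes": diabetes,
            "hyperlipidemia": hyperlipidemia,
            "weight": np.ones(n),
        }
    )

    # true lnOBS from data-driven sex-stratified tertiles on complete intakes;
    # tiny or single-sex cohorts fall back to the fixed published cutoffs
    try:
        table = derive_cutoffs(df)
    except InsufficientDataError:
        table = builtin_table()
    obs = compute_obs(df, table)
    with np.errstate(divide="ignore", invalid="ignore"):
        ln_obs = np.where(obs["obs_total"] >= 1, np.log(obs["obs_total"].astype(float)), 0.0)

    intercept = np.where(
        sex == "male", config.sua_baseline["male"][0], config.sua_baseline["female"][0]
    )
    noise_sd = np.where(
        sex == "male", config.sua_baseline["male"][1], config.sua_baseline["female"][1]
    )
    effect = np.where(sex == "male", config.effect_for("male"), config.effect_for("female"))
    sua = intercept + effect * ln_obs + rng.normal(0.0, 1.0, size=n) * noise_sd
    df["sua_umol_l"] = np.clip(sua, 0.0, None)

    if config.missing_rate > 0:
        for name in DIETARY_COMPONENTS:
            mask = rng.random(n) < config.missing_rate
            df.loc[mask, name] = np.nan

    return df[list(COHORT_COLUMNS)]


def write_cohort(records: pd.DataFrame, path) -> None:
    """Write a cohort table as UTF-8 comma-separated text, missing = empty field."""
    records.to_csv(path, index=False, na_rep="")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort table written by :func:`write_cohort` (tolerant reader:
    unknown extra columns are preserved).

    Raises :class:`CohortParseError` naming the row and column on a malformed
    header or a non-numeric cell in a numeric column; empty cells are missing
    values, never zero.
    """
    try:
        df = pd.read_csv(path, dtype={"id": str})
    except Exception as exc:  # malformed file structure
        raise CohortParseError(f"could not parse cohort file {path}: {exc}") from exc
    missing_cols = [c for c in ("id", "sex") if c not in df.columns]
    if missing_cols:
        raise CohortParseError(
            f"cohort file {path} lacks required column(s): {', '.join(missing_cols)}"
        )
    for col in NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortParseError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, data row {row}",
                row=row,
                column=col,
            )
        df[col] = coerced
    return df
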