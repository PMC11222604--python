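"""Cohort preparation: exclusion chain, hyperuricemia definition, quartiles.

The analysis-ready cohort is produced by a fixed sequence of complete-case
filters (age, OBS-component completeness, serum uric acid, covariates), after
which hyperuricemia is classified from sex-specific serum-uric-acid thresholds
and participants are grouped into quartiles of the (log-transformed) OBS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigurationError
from .scoring import (
    DIETARY_COMPONENTS,
    LIFESTYLE_SOURCE_COLUMNS,
)

#: µmol/L per mg/dL of uric acid
UMOL_PER_MG_DL = 59.48

#: covariates whose absence removes a participant in the default filter chain
DEFAULT_REQUIRED_COVARIATES = (
    "age",
    "sex",
    "race",
    "education",
    "pir",
    "bmi_kg_m2",
    "smoking_binary",
    "drinking_binary",
    "hypertension",
    "diabetes",
    "hyperlipidemia",
)

#: cohort columns carrying the 20 OBS component inputs
COMPONENT_INPUT_COLUMNS = tuple(DIETARY_COMPONENTS) + tuple(
    LIFESTYLE_SOURCE_COLUMNS[name] for name in ("physical_activity", "alcohol", "bmi", "smoking")
)


def mg_dl_to_umol_l(mg_dl: float) -> float:
    """Convert uric acid from mg/dL to µmol/L, rounded to the integer µmol/L
    used in the clinical thresholds (7 mg/dL -> 416, 6 mg/dL -> 357)."""
    return round(mg_dl * UMOL_PER_MG_DL)


@dataclass(frozen=True)
class OutcomeSpec:
    """Sex-specific hyperuricemia thresholds on serum uric acid (µmol/L),
    boundary inclusive (>=): 416 for men (7 mg/dL), 357 for women (6 mg/dL)."""

    male_threshold: float = 416.0
    female_threshold: float = 357.0

    def __post_init__(self):
        if not (self.male_threshold > 0 and self.female_threshold > 0):
            raise ConfigurationError("thresholds must be positive")
        if not self.male_threshold > self.female_threshold:
            raise ConfigurationError("male threshold must exceed female threshold")


def classify_hyperuricemia(sua_umol_l, sex, spec: OutcomeSpec = OutcomeSpec()):
    """Classify hyperuricemia from serum uric acid and sex.

    Accepts scalars or aligned array-likes; returns bool or a boolean Series.
    Missing serum uric acid raises — such records should have been excluded.
    """
    scalar = np.isscalar(sua_umol_l) or sua_umol_l is None
    sua = pd.Series(sua_umol_l) if scalar else pd.Series(np.asarray(sua_umol_l, dtype=float))
    sexes = pd.Series([sex] * len(sua)) if isinstance(sex, str) else pd.Series(np.asarray(sex))
    if sua.isna().any():
        raise ValueError("serum uric acid is missing; exclude such records upstream")
    thr = sexes.map({"male": spec.male_threshold, "female": spec.female_threshold})
    if thr.isna().any():
        raise ValueError("sex must be 'male' or 'female'")
    result = sua.to_numpy() >= thr.to_numpy()
    if scalar:
        return bool(result[0])
    if isinstance(sua_umol_l, pd.Series):
        return pd.Series(result, index=sua_umol_l.index, name="hyperuricemia")
    return result


@dataclass
class ExclusionReport:
    """Stagewise counts of the sequential complete-case filter chain.

    Each participant is counted at the first failing stage only, so
    ``initial_n = removed_age + removed_obs_incomplete + removed_missing_sua
    + removed_missing_covariates + final_n``.
    """

    initial_n: int
    removed_age: int
    removed_obs_incomplete: int
    removed_missing_sua: int
    removed_missing_covariates: int
    final_n: int

    def __post_init__(self):
        removed = (
            self.removed_age
            + self.removed_obs_incomplete
            + self.removed_missing_sua
            + self.removed_missing_covariates
        )
        if self.final_n != self.initial_n - removed:
            raise ConfigurationError("exclusion counts do not conserve participants")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("initial", self.initial_n),
            ("removed_age", self.removed_age),
            ("removed_obs_incomplete", self.removed_obs_incomplete),
            ("removed_missing_sua", self.removed_missing_sua),
            ("removed_missing_covariates", self.removed_missing_covariates),
            ("final", self.final_n),
        ]
        return pd.DataFrame(rows, columns=["stage", "count"])


def count_complete_components(
    records: pd.DataFrame, component_columns: Sequence[str] = COMPONENT_INPUT_COLUMNS
) -> pd.Series:
    """Number of non-missing OBS component inputs per participant."""
    # columns absent from the table count as missing for every participant
    present = [c for c in component_columns if c in records.columns]
    return records[present].notna().sum(axis=1)


def apply_exclusions(
    records: pd.DataFrame,
    min_age: float = 18,
    min_complete: int = 17,
    required_covariates: Iterable[str] = DEFAULT_REQUIRED_COVARIATES,
    component_columns: Sequence[str] = COMPONENT_INPUT_COLUMNS,
    sua_column: str = "sua_umol_l",
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Sequential complete-case filter chain.

    Stages, applied in order with each participant removed at the first
    failing stage only:

    1. age below ``min_age`` (or missing age);
    2. fewer than ``min_complete`` of the 20 OBS component inputs present
       (i.e. "<= 16 complete" removed under the defaults);
    3. missing serum uric acid;
    4. missing any required covariate.

    Returns the retained records and an :class:`ExclusionReport`.
    """
    initial_n = len(records)
    df = records

    age_fail = df["age"].isna() | (df["age"] < min_age)
    removed_age = int(age_fail.sum())
    df = df[~age_fail]

    incomplete = count_complete_components(df, component_columns) < min_complete
    removed_incomplete = int(incomplete.sum())
    df = df[~incomplete]

    sua_missing = df[sua_column].isna()
    removed_sua = int(sua_missing.sum())
    df = df[~sua_missing]

    covs = [c for c in required_covariates]
    missing_any = df[covs].isna().any(axis=1) if covs else pd.Series(False, index=df.index)
    removed_cov = int(missing_any.sum())
    df = df[~missing_any]

    report = ExclusionReport(
        initial_n=initial_n,
        removed_age=removed_age,
        removed_obs_incomplete=removed_incomplete,
        removed_missing_sua=removed_sua,
        removed_missing_covariates=removed_cov,
        final_n=len(df),
    )
    return df.copy(), report


def quartile_boundaries(values) -> tuple[float, float, float]:
    """Quartile cutpoints for a possibly heavily tied variable.

    The k-th boundary (k = 1, 2, 3) is the largest observed value whose
    cumulative count is at most k·n/4, so ties at a boundary fall into the
    lower quartile and, on integer scores, the quartiles form contiguous
    integer ranges.  The rule is rank-based and therefore invariant under any
    strictly increasing transform of the values.
    """
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    uniq, counts = np.unique(v, return_counts=True)
    if len(uniq) < 4:
        raise ValueError(f"need at least 4 distinct values, got {len(uniq)}")
    cum = np.cumsum(counts)
    n = len(v)
    bounds = []
    for k in (1, 2, 3):
        idx = int(np.searchsorted(cum, k * n / 4, side="right")) - 1
        if idx < 0:
            raise ValueError("too many ties at the low end to form quartiles")
        bounds.append(float(uniq[idx]))
    if not (bounds[0] < bounds[1] < bounds[2]):
        raise ValueError(f"quartile boundaries are not strictly increasing: {bounds}")
    return tuple(bounds)


class QuartileBinner(BaseEstimator, TransformerMixin):
    """Learn empirical quartile boundaries of a column and label records Q1–Q4.

    Ties at a boundary go to the lower quartile (see
    :func:`quartile_boundaries`).  Because the rule is rank-based, fitting on
    OBS or on lnOBS yields identical labels.

    Attributes
    ----------
    boundaries_ : (b1, b2, b3) — upper bounds of Q1, Q2, Q3.
    counts_ : occupancy of each quartile in the fitting data.
    """

    def __init__(self, variable: str = "obs_total", out_column: str = "obs_quartile",
                 labels: tuple[str, str, str, str] = ("Q1", "Q2", "Q3", "Q4")):
        self.variable = variable
        self.out_column = out_column
        self.labels = labels

    def fit(self, X: pd.DataFrame, y=None):
        values = X[self.variable]
        self.boundaries_ = quartile_boundaries(values)
        self.counts_ = (
            self._assign(values).value_counts().reindex(list(self.labels), fill_value=0)
        )
        return self

    def _assign(self, values: pd.Series) -> pd.Series:
        b1, b2, b3 = self.boundaries_
        v = values.to_numpy(dtype=float)
        labels = np.select(
            [v <= b1, v <= b2, v <= b3],
            [self.labels[0], self.labels[1], self.labels[2]],
            default=self.labels[3],
        )
        out = pd.Series(labels, index=values.index, name=self.out_column)
        return out.where(values.notna())

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "boundaries_"):
            raise ConfigurationError("QuartileBinner is not fitted; call fit first")
        X = X.copy()
        X[self.out_column] = self._assign(X[self.variable])
        return X


def assign_quartiles(
    records: pd.DataFrame, variable: str = "obs_total", out_column: str = "obs_quartile"
) -> tuple[pd.DataFrame, tuple[float, float, float]]:
    """Label records with empirical quartiles of ``variable`` (thin wrapper
    over :class:`QuartileBinner`)."""
    binner = QuartileBinner(variable=variable, out_column=out_column).fit(records)
    return binner.transform(records), binner.boundaries_


def add_subgroup_columns(
    records: pd.DataFrame, age_cut: float = 60.0, bmi_cuts: tuple[float, float] = (25.0, 30.0)
) -> pd.DataFrame:
    """Attach stratification columns for subgroup analysis.

    Cutpoints default to age <60 / >=60 years and BMI <25 / 25–30 / >=30
    kg/m^2; both are configurable since the groupings are conventional rather
    than prescribed.
    """
    df = records.copy()
    df["age_group"] = np.where(df["age"] < age_cut, f"<{age_cut:g}", f">={age_cut:g}")
    lo, hi = bmi_cuts
    df["bmi_group"] = np.select(
        [df["bmi_kg_m2"] < lo, df["bmi_kg_m2"] < hi],
        [f"<{lo:g}", f"{lo:g}-{hi:g}"],
        default=f">={hi:g}",
    )
    return df
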