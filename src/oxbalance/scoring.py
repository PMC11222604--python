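"""Oxidative balance score (OBS) construction.

The OBS is a composite exposure summing 0–2 points over 20 dietary and
lifestyle components — 15 antioxidants scored in increasing direction of
exposure and 5 pro-oxidants scored in decreasing direction.  Sixteen dietary
components are scored against sex-specific tertile cutoffs; four lifestyle
components (physical activity, alcohol, BMI category, smoking) are scored from
categories.  Higher total OBS indicates a more antioxidant-dominated profile.

Two cutoff sources are supported:

* the fixed published rulebook (:func:`builtin_table`), transcribed verbatim;
* data-driven sex-stratified empirical tertiles (:func:`derive_cutoffs`).

Scoring is exposed both as plain functions and as the scikit-learn style
transformer :class:`OBSScorer`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (
    ConfigurationError,
    DegenerateCutoffsError,
    InsufficientDataError,
)

SEXES = ("male", "female")

ANTIOXIDANT = "antioxidant"
PRO_OXIDANT = "pro-oxidant"

#: the 16 dietary components, in rulebook order; names double as cohort columns
DIETARY_COMPONENTS = (
    "fiber",
    "carotene",
    "riboflavin",
    "niacin",
    "vitamin_b6",
    "total_folate",
    "vitamin_b12",
    "vitamin_c",
    "vitamin_e",
    "calcium",
    "magnesium",
    "zinc",
    "copper",
    "selenium",
    "total_fat",
    "iron",
)

#: the 4 lifestyle components
LIFESTYLE_COMPONENTS = ("physical_activity", "alcohol", "bmi", "smoking")

#: units for documentation and report headers
COMPONENT_UNITS = {
    "fiber": "g/d",
    "carotene": "RE/d",
    "riboflavin": "mg/d",
    "niacin": "mg/d",
    "vitamin_b6": "mg/d",
    "total_folate": "mcg/d",
    "vitamin_b12": "mcg/d",
    "vitamin_c": "mg/d",
    "vitamin_e": "mg ATE/d",
    "calcium": "mg/d",
    "magnesium": "mg/d",
    "zinc": "mg/d",
    "copper": "mg/d",
    "selenium": "mcg/d",
    "total_fat": "g/d",
    "iron": "mg/d",
    "alcohol": "g/d",
    "bmi": "kg/m^2",
}

#: cohort column that feeds each lifestyle component
LIFESTYLE_SOURCE_COLUMNS = {
    "physical_activity": "physical_activity",
    "alcohol": "alcohol_g_per_day",
    "bmi": "bmi_kg_m2",
    "smoking": "smoking3",
}

#: heavy-drinking thresholds, g/d, boundary inclusive (>= is heavy)
ALCOHOL_HEAVY_THRESHOLD = {"male": 30.0, "female": 15.0}


@dataclass(frozen=True)
class ComponentSpec:
    """One OBS component: its direction and how raw values map to 0/1/2 points.

    ``mode='tertile'`` components carry per-sex cutoff pairs ``(c1, c2)`` with
    c1 < c2; ``mode='categorical'`` components carry per-sex category->score
    maps with scores in {0, 1, 2}.
    """

    name: str
    cls: str  # 'dietary' | 'lifestyle'
    direction: str  # 'antioxidant' | 'pro-oxidant'
    mode: str  # 'tertile' | 'categorical'
    cutoffs: Mapping[str, tuple[float, float]] | None = None
    category_scores: Mapping[str, Mapping[str, int]] | None = None

    def __post_init__(self):
        if self.cls not in ("dietary", "lifestyle"):
            raise ConfigurationError(f"{self.name}: unknown class {self.cls!r}")
        if self.direction not in (ANTIOXIDANT, PRO_OXIDANT):
            raise ConfigurationError(f"{self.name}: unknown direction {self.direction!r}")
        if self.mode == "tertile":
            if self.cutoffs is None:
                raise ConfigurationError(f"{self.name}: tertile mode requires cutoffs")
            for sex, (c1, c2) in self.cutoffs.items():
                if not c1 < c2:
                    raise DegenerateCutoffsError(
                        f"{self.name} ({sex}): cutoffs must satisfy c1 < c2, got ({c1}, {c2})"
                    )
        elif self.mode == "categorical":
            if self.category_scores is None:
                raise ConfigurationError(f"{self.name}: categorical mode requires a score map")
            for sex, mapping in self.category_scores.items():
                bad = {v for v in mapping.values() if v not in (0, 1, 2)}
                if bad:
                    raise ConfigurationError(
                        f"{self.name} ({sex}): scores must be in {{0,1,2}}, got {sorted(bad)}"
                    )
        else:
            raise ConfigurationError(f"{self.name}: unknown mode {self.mode!r}")


@dataclass(frozen=True)
class ScoringTable:
    """An ordered collection of :class:`ComponentSpec` with unique names."""

    components: tuple[ComponentSpec, ...]

    def __post_init__(self):
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ConfigurationError("component names must be unique")

    def __iter__(self):
        return iter(self.components)

    def __len__(self):
        return len(self.components)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components)

    def __getitem__(self, name: str) -> ComponentSpec:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    def direction_counts(self) -> dict[str, int]:
        out = {ANTIOXIDANT: 0, PRO_OXIDANT: 0}
        for c in self.components:
            out[c.direction] += 1
        return out

    # -- plain-text (YAML) serialization so users can define OBS variants -----

    def to_dict(self) -> dict:
        out = {}
        for c in self.components:
            entry: dict = {"class": c.cls, "direction": c.direction, "mode": c.mode}
            if c.mode == "tertile":
                entry["cutoffs"] = {s: [float(v) for v in cc] for s, cc in c.cutoffs.items()}
            else:
                entry["categories"] = {s: dict(m) for s, m in c.category_scores.items()}
            out[c.name] = entry
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({"components": self.to_dict()}, fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: Mapping) -> "ScoringTable":
        comps = []
        for name, entry in data.items():
            comps.append(
                ComponentSpec(
                    name=name,
                    cls=entry["class"],
                    direction=entry["direction"],
                    mode=entry["mode"],
                    cutoffs={s: tuple(v) for s, v in entry.get("cutoffs", {}).items()} or None,
                    category_scores=entry.get("categories") or None,
                )
            )
        return cls(components=tuple(comps))

    @classmethod
    def from_yaml(cls, path) -> "ScoringTable":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data["components"])


# Fixed published cutoffs: component -> (male (c1, c2), female (c1, c2)).
_TABLE_CUTOFFS: dict[str, tuple[tuple[float, float], tuple[float, float], str]] = {
    # name: (male, female, direction)
    "fiber": ((13.20, 20.80), (11.30, 17.30), ANTIOXIDANT),
    "carotene": ((53.58, 176.81), (57.60, 198.53), ANTIOXIDANT),
    "riboflavin": ((1.80, 2.64), (1.40, 2.02), ANTIOXIDANT),
    "niacin": ((22.93, 32.73), (16.29, 23.49), ANTIOXIDANT),
    "vitamin_b6": ((1.74, 2.59), (1.29, 1.89), ANTIOXIDANT),
    "total_folate": ((328.33, 495.00), (257.39, 385.50), ANTIOXIDANT),
    "vitamin_b12": ((3.66, 4.40), (2.56, 4.50), ANTIOXIDANT),
    "vitamin_c": ((43.23, 104.13), (41.45, 90.35), ANTIOXIDANT),
    "vitamin_e": ((6.02, 9.57), (5.03, 7.98), ANTIOXIDANT),
    "calcium": ((751.00, 1130.50), (610.67, 921.50), ANTIOXIDANT),
    "magnesium": ((262.33, 366.50), (211.00, 293.00), ANTIOXIDANT),
    "zinc": ((10.00, 14.65), (7.24, 10.54), ANTIOXIDANT),
    "copper": ((1.08, 1.53), (0.88, 1.25), ANTIOXIDANT),
    "selenium": ((102.60, 145.48), (74.77, 105.73), ANTIOXIDANT),
    "total_fat": ((70.92, 104.62), (53.03, 77.44), PRO_OXIDANT),
    "iron": ((12.72, 18.74), (9.79, 14.12), PRO_OXIDANT),
}


def _both_sexes(mapping: Mapping[str, int]) -> dict[str, dict[str, int]]:
    return {"male": dict(mapping), "female": dict(mapping)}


def builtin_table(underweight_score: int = 2) -> ScoringTable:
    """The fixed published 20-component OBS rulebook.

    Dietary cutoffs are sex-specific published tertile boundaries; lifestyle
    components are categorical: physical activity low/moderate/high -> 0/1/2
    (antioxidant), alcohol heavy/non-heavy/none -> 0/1/2, BMI obese/overweight/
    normal -> 0/1/2 and smoking current/former/never -> 0/1/2 (pro-oxidants).

    The published table has no underweight BMI row; by default underweight
    (<18.5 kg/m^2) scores as "normal" (2 points) since the pro-oxidant scored
    here is adiposity.  Set ``underweight_score`` to change that.
    """
    if underweight_score not in (0, 1, 2):
        raise ConfigurationError("underweight_score must be 0, 1 or 2")
    comps = [
        ComponentSpec(
            name=name,
            cls="dietary",
            direction=direction,
            mode="tertile",
            cutoffs={"male": male, "female": female},
        )
        for name, (male, female, direction) in _TABLE_CUTOFFS.items()
    ]
    comps.append(
        ComponentSpec(
            name="physical_activity",
            cls="lifestyle",
            direction=ANTIOXIDANT,
            mode="categorical",
            category_scores=_both_sexes({"low": 0, "moderate": 1, "high": 2}),
        )
    )
    comps.append(
        ComponentSpec(
            name="alcohol",
            cls="lifestyle",
            direction=PRO_OXIDANT,
            mode="categorical",
            category_scores=_both_sexes({"heavy": 0, "non_heavy": 1, "none": 2}),
        )
    )
    comps.append(
        ComponentSpec(
            name="bmi",
            cls="lifestyle",
            direction=PRO_OXIDANT,
            mode="categorical",
            category_scores=_both_sexes(
                {"obese": 0, "overweight": 1, "normal": 2, "underweight": underweight_score}
            ),
        )
    )
    comps.append(
        ComponentSpec(
            name="smoking",
            cls="lifestyle",
            direction=PRO_OXIDANT,
            mode="categorical",
            category_scores=_both_sexes({"current": 0, "former": 1, "never": 2}),
        )
    )
    return ScoringTable(components=tuple(comps))


def tertile_cutpoints(values: np.ndarray) -> tuple[float, float]:
    """Empirical 1/3 and 2/3 quantiles under the type-1 (inverted CDF) rule.

    The cutpoint is the smallest observed value whose empirical CDF reaches
    the target fraction, so for values 1..9 the cutpoints are (3, 6) and the
    "<= c1 / (c1, c2] / > c2" scoring rule fills tertiles n/3 each up to ties.
    """
    values = np.asarray(values, dtype=float)
    c1 = float(np.quantile(values, 1 / 3, method="inverted_cdf"))
    c2 = float(np.quantile(values, 2 / 3, method="inverted_cdf"))
    return c1, c2


def derive_cutoffs(
    records: pd.DataFrame,
    component_names: Iterable[str] | None = None,
    base_table: ScoringTable | None = None,
) -> ScoringTable:
    """Replace tertile cutoffs with sex-stratified empirical tertiles.

    Parameters
    ----------
    records : cohort table with a ``sex`` column and one column per dietary
        component (missing values allowed).
    component_names : subset of tertile components to re-derive (default: all).
    base_table : table providing structure and categorical maps
        (default: the published rulebook).

    Raises
    ------
    InsufficientDataError : fewer than 3 non-missing values in a sex stratum.
    DegenerateCutoffsError : empirical cutoffs collapse (c1 == c2).
    """
    base = base_table if base_table is not None else builtin_table()
    tertile_names = {c.name for c in base if c.mode == "tertile"}
    if component_names is None:
        component_names = tertile_names
    else:
        component_names = set(component_names)
        unknown = component_names - tertile_names
        if unknown:
            raise ConfigurationError(f"not tertile components: {sorted(unknown)}")

    new_components = []
    for comp in base:
        if comp.name not in component_names:
            new_components.append(comp)
            continue
        cutoffs = {}
        for sex in SEXES:
            vals = records.loc[records["sex"] == sex, comp.name].dropna().to_numpy()
            if len(vals) < 3:
                raise InsufficientDataError(
                    f"component {comp.name!r}, sex {sex!r}: need >=3 non-missing values, "
                    f"got {len(vals)}"
                )
            c1, c2 = tertile_cutpoints(vals)
            if not c1 < c2:
                raise DegenerateCutoffsError(
                    f"component {comp.name!r}, sex {sex!r}: empirical tertile cutoffs "
                    f"collapsed at {c1}"
                )
            cutoffs[sex] = (c1, c2)
        new_components.append(replace(comp, cutoffs=cutoffs))
    return ScoringTable(components=tuple(new_components))


def score_tertile_component(value: float, spec: ComponentSpec, sex: str) -> int | None:
    """Score one tertile component: antioxidants 0/1/2 from lowest to highest
    tertile, pro-oxidants the reverse.  Ties at a cutoff fall to the lower
    tertile (<= c1 -> lowest).  Missing value returns None (a missing score,
    never 0)."""
    if spec.mode != "tertile":
        raise ConfigurationError(f"{spec.name} is not a tertile component")
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    c1, c2 = spec.cutoffs[sex]
    if value <= c1:
        s = 0
    elif value <= c2:
        s = 1
    else:
        s = 2
    return s if spec.direction == ANTIOXIDANT else 2 - s


def categorize_alcohol(grams_per_day: float, sex: str) -> str:
    """Map alcohol intake in g/d to none / non_heavy / heavy.

    Heavy means >= 30 g/d for men and >= 15 g/d for women (boundary inclusive);
    0 g/d is a non-drinker."""
    if grams_per_day < 0:
        raise ValueError(f"alcohol intake must be nonnegative, got {grams_per_day}")
    if grams_per_day == 0:
        return "none"
    if grams_per_day >= ALCOHOL_HEAVY_THRESHOLD[sex]:
        return "heavy"
    return "non_heavy"


def score_alcohol(grams_per_day: float, sex: str) -> int:
    """Alcohol points: heavy drinking 0, non-heavy 1, none 2."""
    return {"heavy": 0, "non_heavy": 1, "none": 2}[categorize_alcohol(grams_per_day, sex)]


def categorize_bmi(bmi: float) -> str:
    """BMI category: underweight <18.5, normal 18.5–24.9, overweight 25.0–29.9,
    obese >=30 kg/m^2."""
    if not bmi > 0:
        raise ValueError(f"BMI must be positive, got {bmi}")
    if bmi < 18.5:
        return "underweight"
    if bmi < 25.0:
        return "normal"
    if bmi < 30.0:
        return "overweight"
    return "obese"


def _component_values(records: pd.DataFrame, comp: ComponentSpec) -> pd.Series:
    """Raw per-participant input for a component (category string for
    lifestyle components)."""
    if comp.mode == "tertile":
        if comp.name not in records.columns:
            raise ConfigurationError(f"cohort table lacks column for component {comp.name!r}")
        return records[comp.name]
    source = LIFESTYLE_SOURCE_COLUMNS.get(comp.name, comp.name)
    if source not in records.columns:
        raise ConfigurationError(f"cohort table lacks column {source!r} for component {comp.name!r}")
    col = records[source]
    if comp.name == "alcohol":
        sexes = records["sex"]
        thr = sexes.map(ALCOHOL_HEAVY_THRESHOLD).astype(float)
        if (col.dropna() < 0).any():
            raise ValueError("alcohol intake must be nonnegative")
        cat = np.where(col == 0, "none", np.where(col >= thr, "heavy", "non_heavy"))
        return pd.Series(np.where(col.isna(), None, cat), index=records.index, dtype=object)
    if comp.name == "bmi":
        bins = [0, 18.5, 25.0, 30.0, np.inf]
        labels = ["underweight", "normal", "overweight", "obese"]
        cat = pd.cut(col, bins=bins, labels=labels, right=False)
        return cat.astype(object).where(col.notna(), None)
    return col


def score_components(records: pd.DataFrame, table: ScoringTable) -> pd.DataFrame:
    """Vectorised per-component scores; one float column per component,
    NaN where the input is missing."""
    if "sex" not in records.columns:
        raise ConfigurationError("cohort table lacks required column 'sex'")
    sex = records["sex"]
    out = {}
    for comp in table:
        values = _component_values(records, comp)
        scores = np.full(len(records), np.nan)
        if comp.mode == "tertile":
            v = values.to_numpy(dtype=float)
            for s in SEXES:
                c1, c2 = comp.cutoffs[s]
                mask = (sex == s).to_numpy() & ~np.isnan(v)
                raw = np.where(v <= c1, 0, np.where(v <= c2, 1, 2))
                if comp.direction == PRO_OXIDANT:
                    raw = 2 - raw
                scores[mask] = raw[mask]
        else:
            for s in SEXES:
                mapping = comp.category_scores[s]
                mask = (sex == s).to_numpy()
                mapped = values.map(lambda c: mapping.get(c, np.nan) if c is not None else np.nan)
                scores[mask] = mapped.to_numpy(dtype=float)[mask]
        out[f"score_{comp.name}"] = scores
    return pd.DataFrame(out, index=records.index)


def compute_obs(
    records: pd.DataFrame,
    table: ScoringTable | None = None,
    missing_policy: str = "zero",
) -> pd.DataFrame:
    """Compute per-participant component scores, total OBS, completeness and lnOBS.

    Returns a frame indexed like ``records`` with one ``score_<name>`` column
    per component plus:

    * ``n_complete`` — number of non-missing components (0–20 for the full table);
    * ``obs_total`` — sum of present component scores.  Under
      ``missing_policy='zero'`` (default) missing components contribute 0;
      ``'prorate'`` rescales by n_components / n_complete;
    * ``ln_obs`` — natural log of obs_total, NaN when obs_total < 1.
    """
    if table is None:
        table = builtin_table()
    if missing_policy not in ("zero", "prorate"):
        raise ConfigurationError(f"unknown missing_policy {missing_policy!r}")
    single = isinstance(records, (pd.Series, dict))
    if single:
        records = pd.DataFrame([records])
    scores = score_components(records, table)
    n_complete = scores.notna().sum(axis=1).astype(int)
    total = scores.sum(axis=1, skipna=True)
    if missing_policy == "prorate":
        with np.errstate(divide="ignore", invalid="ignore"):
            total = total * len(table) / n_complete.replace(0, np.nan)
    out = scores.copy()
    out["n_complete"] = n_complete
    out["obs_total"] = total
    with np.errstate(divide="ignore", invalid="ignore"):
        out["ln_obs"] = np.where(total >= 1, np.log(total.astype(float)), np.nan)
    if "id" in records.columns:
        out.insert(0, "id", records["id"])
    return out


class OBSScorer(BaseEstimator, TransformerMixin):
    """Transformer computing the oxidative balance score for a cohort table.

    Parameters
    ----------
    cutoffs : 'builtin', 'derive', or a ScoringTable.
        'builtin' uses the fixed published rulebook; 'derive' learns
        sex-stratified empirical tertile cutoffs from the data passed to
        :meth:`fit`.
    missing_policy : 'zero' (missing components contribute 0 points, reported
        via ``n_complete``) or 'prorate' (rescale by 20/n_complete).
    underweight_score : points for underweight BMI (<18.5), default 2
        ("normal"), since the published table only lists obese/overweight/normal.

    Attributes
    ----------
    table_ : ScoringTable
        The cutoffs actually used, fixed or learned.
    """

    def __init__(self, cutoffs="builtin", missing_policy="zero", underweight_score=2):
        self.cutoffs = cutoffs
        self.missing_policy = missing_policy
        self.underweight_score = underweight_score

    def fit(self, X: pd.DataFrame, y=None):
        base = builtin_table(underweight_score=self.underweight_score)
        if isinstance(self.cutoffs, ScoringTable):
            self.table_ = self.cutoffs
        elif self.cutoffs == "builtin":
            self.table_ = base
        elif self.cutoffs == "derive":
            self.table_ = derive_cutoffs(X, base_table=base)
        else:
            raise ConfigurationError(
                "cutoffs must be 'builtin', 'derive' or a ScoringTable, "
                f"got {self.cutoffs!r}"
            )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "table_"):
            raise ConfigurationError("OBSScorer is not fitted; call fit first")
        result = compute_obs(X, self.table_, missing_policy=self.missing_policy)
        drop = [c for c in result.columns if c == "id"]
        return pd.concat([X, result.drop(columns=drop)], axis=1)
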