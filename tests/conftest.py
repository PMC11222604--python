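"""Shared fixtures: hand-scored participant records and count-level cohorts."""

import numpy as np
import pandas as pd
import pytest

from oxbalance import DIETARY_COMPONENTS

# Values chosen so every component's tertile/category is unambiguous under the
# published cutoffs; expected totals were scored by hand, component by
# component, independently of the package code.

MALE_MIXED = {
    # dietary: fiber 2, carotene 1, riboflavin 0, niacin 2, b6 1, folate 0,
    # b12 1, vitC 2, vitE 0 (boundary <=c1), calcium 2, magnesium 1, zinc 0,
    # copper 2, selenium 1  -> 15
    "sex": "male", "fiber": 25.0, "carotene": 100.0, "riboflavin": 1.5,
    "niacin": 40.0, "vitamin_b6": 2.0, "total_folate": 300.0, "vitamin_b12": 4.0,
    "vitamin_c": 150.0, "vitamin_e": 6.02, "calcium": 1200.0, "magnesium": 300.0,
    "zinc": 9.0, "copper": 1.60, "selenium": 120.0,
    # pro-oxidants: total fat middle tertile 1, iron highest tertile 0
    "total_fat": 80.0, "iron": 20.0,
    # lifestyle: PA high 2, alcohol 10 g/d male non-heavy 1,
    # bmi 27 overweight 1, former smoker 1
    "physical_activity": "high", "alcohol_g_per_day": 10.0,
    "bmi_kg_m2": 27.0, "smoking3": "former",
}
MALE_MIXED_TOTAL = 21

FEMALE_MIXED = {
    # dietary: fiber 0 (boundary), carotene 2, riboflavin 1 (value == c2),
    # niacin 0 (boundary), b6 1, folate 2, b12 0, vitC 0 (boundary), vitE 2,
    # calcium 1, magnesium 0, zinc 1 (value == c2), copper 2, selenium 1 -> 13
    "sex": "female", "fiber": 11.30, "carotene": 200.0, "riboflavin": 2.02,
    "niacin": 16.29, "vitamin_b6": 1.5, "total_folate": 400.0, "vitamin_b12": 2.0,
    "vitamin_c": 41.45, "vitamin_e": 8.5, "calcium": 700.0, "magnesium": 180.0,
    "zinc": 10.54, "copper": 1.30, "selenium": 90.0,
    # pro-oxidants: fat lowest tertile 2, iron middle 1
    "total_fat": 50.0, "iron": 10.0,
    # lifestyle: PA low 0, alcohol 15 g/d female heavy (boundary) 0,
    # bmi 31 obese 0, current smoker 0
    "physical_activity": "low", "alcohol_g_per_day": 15.0,
    "bmi_kg_m2": 31.0, "smoking3": "current",
}
FEMALE_MIXED_TOTAL = 16

# MALE_MIXED with fiber (2 pts) and selenium (1 pt) missing: total 18 of 18
MALE_MISSING = {**MALE_MIXED, "fiber": np.nan, "selenium": np.nan}
MALE_MISSING_TOTAL = 18
MALE_MISSING_N_COMPLETE = 18

# every component at its minimum-scoring level except underweight BMI (default 2)
FEMALE_MINIMAL = {
    "sex": "female", "fiber": 1.0, "carotene": 1.0, "riboflavin": 0.1,
    "niacin": 1.0, "vitamin_b6": 0.1, "total_folate": 10.0, "vitamin_b12": 0.1,
    "vitamin_c": 1.0, "vitamin_e": 0.1, "calcium": 10.0, "magnesium": 10.0,
    "zinc": 0.1, "copper": 0.01, "selenium": 1.0,
    "total_fat": 200.0, "iron": 50.0,
    "physical_activity": "low", "alcohol_g_per_day": 20.0,
    "bmi_kg_m2": 17.0, "smoking3": "current",
}
FEMALE_MINIMAL_TOTAL = 2  # underweight scored as "normal" by default

# every component at its maximum-scoring level
MALE_MAXIMAL = {
    "sex": "male", "fiber": 50.0, "carotene": 500.0, "riboflavin": 5.0,
    "niacin": 60.0, "vitamin_b6": 5.0, "total_folate": 900.0, "vitamin_b12": 10.0,
    "vitamin_c": 300.0, "vitamin_e": 20.0, "calcium": 2000.0, "magnesium": 600.0,
    "zinc": 30.0, "copper": 3.0, "selenium": 300.0,
    "total_fat": 50.0, "iron": 9.0,
    "physical_activity": "high", "alcohol_g_per_day": 0.0,
    "bmi_kg_m2": 22.0, "smoking3": "never",
}
MALE_MAXIMAL_TOTAL = 40

HAND_SCORED = [
    (MALE_MIXED, MALE_MIXED_TOTAL, 20),
    (FEMALE_MIXED, FEMALE_MIXED_TOTAL, 20),
    (MALE_MISSING, MALE_MISSING_TOTAL, MALE_MISSING_N_COMPLETE),
    (FEMALE_MINIMAL, FEMALE_MINIMAL_TOTAL, 20),
    (MALE_MAXIMAL, MALE_MAXIMAL_TOTAL, 20),
]


@pytest.fixture
def hand_scored_records():
    """Five fixture records with independently hand-computed OBS totals."""
    df = pd.DataFrame([r for r, _, _ in HAND_SCORED])
    totals = [t for _, t, _ in HAND_SCORED]
    n_complete = [n for _, _, n in HAND_SCORED]
    return df, totals, n_complete


def _block(n: int, **overrides) -> pd.DataFrame:
    """n identical complete records, then apply overrides."""
    base = {
        "sex": "male", "age": 45.0,
        **{c: 10.0 for c in DIETARY_COMPONENTS},
        "physical_activity": "moderate", "alcohol_g_per_day": 5.0,
        "smoking3": "never", "bmi_kg_m2": 26.0, "sua_umol_l": 320.0,
        "race": "Non-Hispanic White", "education": "College degree", "pir": 2.5,
        "smoking_binary": "no", "drinking_binary": "yes",
        "hypertension": "no", "diabetes": "no", "hyperlipidemia": "no",
        "weight": 1.0,
    }
    base.update(overrides)
    df = pd.DataFrame({k: [v] * n for k, v in base.items()})
    return df


def make_exclusion_cohort(
    n_minor=15331, n_incomplete=3144, n_missing_sua=1149, n_missing_cov=4436, n_clean=15096
) -> pd.DataFrame:
    """Count-level cohort reproducing a staged exclusion flow.

    Each block fails exactly one stage (the incomplete block has only 16 of
    20 components present; the minor block also lacks serum uric acid so the
    first-failing-stage rule is exercised).
    """
    blocks = [
        _block(n_minor, age=10.0, sua_umol_l=np.nan),
        _block(n_incomplete, fiber=np.nan, zinc=np.nan, iron=np.nan, selenium=np.nan),
        _block(n_missing_sua, sua_umol_l=np.nan),
        _block(n_missing_cov, pir=np.nan),
        _block(n_clean),
    ]
    return pd.concat(blocks, ignore_index=True)


@pytest.fixture(scope="session")
def exclusion_cohort():
    return make_exclusion_cohort()
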