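"""Unit tests for the OBS scoring engine."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from oxbalance import (
    OBSScorer,
    ScoringTable,
    builtin_table,
    compute_obs,
    derive_cutoffs,
    score_alcohol,
    score_tertile_component,
)
from oxbalance.errors import (
    ConfigurationError,
    DegenerateCutoffsError,
    InsufficientDataError,
)
from oxbalance.scoring import ANTIOXIDANT, PRO_OXIDANT, categorize_bmi, tertile_cutpoints


class TestBuiltinTable:
    def test_component_census(self):
        table = builtin_table()
        assert len(table) == 20
        counts = table.direction_counts()
        assert counts[ANTIOXIDANT] == 15 and counts[PRO_OXIDANT] == 5
        classes = [c.cls for c in table]
        assert classes.count("dietary") == 16 and classes.count("lifestyle") == 4

    def test_transcribed_cutoffs(self):
        table = builtin_table()
        assert table["selenium"].cutoffs["male"] == (102.60, 145.48)
        assert table["fiber"].cutoffs["male"] == (13.20, 20.80)
        assert table["total_fat"].cutoffs["female"] == (53.03, 77.44)
        assert table["vitamin_b12"].cutoffs["male"] == (3.66, 4.40)

    def test_categorical_maps(self):
        table = builtin_table()
        assert table["physical_activity"].category_scores["male"] == {
            "low": 0, "moderate": 1, "high": 2,
        }
        assert table["smoking"].category_scores["female"] == {
            "current": 0, "former": 1, "never": 2,
        }
        assert table["bmi"].category_scores["male"]["obese"] == 0

    def test_yaml_round_trip(self, tmp_path):
        table = builtin_table()
        path = tmp_path / "table.yaml"
        table.to_yaml(path)
        assert ScoringTable.from_yaml(path).to_dict() == table.to_dict()

    def test_duplicate_names_rejected(self):
        table = builtin_table()
        with pytest.raises(ConfigurationError):
            ScoringTable(components=table.components + (table.components[0],))


class TestTertileScoring:
    @pytest.mark.parametrize(
        "component,value,sex,expected",
        [
            ("fiber", 25.0, "male", 2),       # above upper cutoff
            ("fiber", 13.20, "male", 0),      # tie at c1 falls to lowest tertile
            ("fiber", 13.21, "male", 1),
            ("fiber", 20.80, "male", 1),      # tie at c2 falls to middle
            ("total_fat", 50.0, "female", 2), # pro-oxidant: lowest tertile scores 2
            ("total_fat", 80.0, "female", 0),
            ("iron", 13.0, "male", 1),
        ],
    )
    def test_boundary_convention(self, component, value, sex, expected):
        spec = builtin_table()[component]
        assert score_tertile_component(value, spec, sex) == expected

    def test_missing_value_is_missing_not_zero(self):
        spec = builtin_table()["fiber"]
        assert score_tertile_component(float("nan"), spec, "male") is None

    def test_categorical_spec_rejected(self):
        spec = builtin_table()["smoking"]
        with pytest.raises(ConfigurationError):
            score_tertile_component(1.0, spec, "male")


class TestAlcohol:
    @pytest.mark.parametrize(
        "grams,sex,expected",
        [
            (35.0, "male", 0),   # heavy
            (30.0, "male", 0),   # boundary inclusive to heavy
            (29.9, "male", 1),
            (0.0, "female", 2),  # non-drinker
            (15.0, "female", 0), # female heavy boundary
            (14.9, "female", 1),
        ],
    )
    def test_three_category_rule(self, grams, sex, expected):
        assert score_alcohol(grams, sex) == expected

    def test_negative_intake_rejected(self):
        with pytest.raises(ValueError):
            score_alcohol(-1.0, "male")


class TestDeriveCutoffs:
    def test_small_sample_order_statistics(self):
        # independent oracle: the cutpoint is the smallest order statistic
        # whose empirical CDF reaches k/3
        values = np.arange(1, 10, dtype=float)
        assert tertile_cutpoints(values) == (3.0, 6.0)

        def oracle(vals, frac):
            vals = np.sort(vals)
            n = len(vals)
            for i, v in enumerate(vals, start=1):
                if i / n >= frac:
                    return v

        rng = np.random.default_rng(42)
        for _ in range(50):
            vals = rng.integers(0, 30, size=rng.integers(5, 40)).astype(float)
            c1, c2 = np.quantile(vals, 1 / 3, method="inverted_cdf"), np.quantile(
                vals, 2 / 3, method="inverted_cdf"
            )
            assert c1 == oracle(vals, 1 / 3)
            assert c2 == oracle(vals, 2 / 3)

    def test_derived_table_structure(self):
        rng = np.random.default_rng(0)
        n = 300
        df = pd.DataFrame({"sex": rng.choice(["male", "female"], n)})
        for comp in builtin_table():
            if comp.mode == "tertile":
                df[comp.name] = rng.lognormal(2.0, 0.5, n)
        table = derive_cutoffs(df)
        assert len(table) == 20
        # categorical components untouched
        assert table["smoking"].category_scores == builtin_table()["smoking"].category_scores
        for comp in table:
            if comp.mode == "tertile":
                for sex in ("male", "female"):
                    c1, c2 = comp.cutoffs[sex]
                    assert c1 < c2

    def test_tertile_occupancy(self):
        rng = np.random.default_rng(1)
        n = 3000
        df = pd.DataFrame(
            {
                "sex": ["male"] * n + ["female"] * n,
                "fiber": rng.lognormal(2.8, 0.4, 2 * n),
            }
        )
        table = derive_cutoffs(df, component_names=["fiber"])
        fiber_only = ScoringTable(components=(table["fiber"],))
        scores = compute_obs(df, fiber_only)["score_fiber"]
        for sex in ("male", "female"):
            counts = scores[df["sex"] == sex].value_counts()
            for s in (0, 1, 2):
                assert abs(counts[s] - n / 3) <= 2  # ties only

    def test_constant_values_error(self):
        df = pd.DataFrame({"sex": ["male"] * 10 + ["female"] * 10, "fiber": 5.0})
        for c in builtin_table().names:
            if c != "fiber" and builtin_table()[c].mode == "tertile":
                df[c] = np.linspace(1, 10, 20)
        with pytest.raises(DegenerateCutoffsError, match="fiber"):
            derive_cutoffs(df)

    def test_insufficient_stratum_error(self):
        df = pd.DataFrame({"sex": ["male"] * 10, "fiber": np.linspace(1, 10, 10)})
        with pytest.raises(InsufficientDataError, match="female"):
            derive_cutoffs(df, component_names=["fiber"])


class TestComputeObs:
    def test_hand_scored_fixture_records(self, hand_scored_records):
        df, totals, n_complete = hand_scored_records
        result = compute_obs(df)
        assert result["obs_total"].tolist() == totals
        assert result["n_complete"].tolist() == n_complete

    def test_bounds_attained(self, hand_scored_records):
        df, totals, _ = hand_scored_records
        assert max(totals) == 40 and min(totals) == 2
        result = compute_obs(df)
        assert result["obs_total"].between(0, 40).all()

    def test_ln_obs_full_precision(self, hand_scored_records):
        df, totals, _ = hand_scored_records
        result = compute_obs(df)
        assert result["ln_obs"].tolist() == pytest.approx([math.log(t) for t in totals])

    def test_missing_policy_zero_vs_prorate(self, hand_scored_records):
        df, _, _ = hand_scored_records
        zero = compute_obs(df, missing_policy="zero")
        prorate = compute_obs(df, missing_policy="prorate")
        # record 3 has 18 of 20 components, hand total 18
        assert zero.loc[2, "obs_total"] == 18
        assert prorate.loc[2, "obs_total"] == pytest.approx(18 * 20 / 18)
        # complete records are identical under both policies
        complete = zero["n_complete"] == 20
        assert (zero.loc[complete, "obs_total"] == prorate.loc[complete, "obs_total"]).all()

    def test_underweight_bmi_configurable(self):
        record = {"sex": "female", "physical_activity": "low",
                  "alcohol_g_per_day": 20.0, "bmi_kg_m2": 17.0, "smoking3": "current"}
        df = pd.DataFrame([record])
        bmi_only = lambda score: ScoringTable(
            components=(builtin_table(underweight_score=score)["bmi"],)
        )
        assert compute_obs(df, bmi_only(2)).loc[0, "score_bmi"] == 2
        assert compute_obs(df, bmi_only(0)).loc[0, "score_bmi"] == 0

    def test_unknown_component_column_error(self):
        df = pd.DataFrame([{"sex": "male"}])
        with pytest.raises(ConfigurationError):
            compute_obs(df)

    def test_bmi_categories(self):
        assert categorize_bmi(17.0) == "underweight"
        assert categorize_bmi(24.9) == "normal"
        assert categorize_bmi(25.0) == "overweight"
        assert categorize_bmi(30.0) == "obese"


class TestOBSScorerEstimator:
    def test_sklearn_contract(self):
        scorer = OBSScorer(cutoffs="derive", missing_policy="prorate")
        assert clone(scorer).get_params() == scorer.get_params()
        scorer.set_params(missing_policy="zero")
        assert scorer.missing_policy == "zero"

    def test_fit_builtin_then_transform(self, hand_scored_records):
        df, totals, _ = hand_scored_records
        out = OBSScorer().fit(df).transform(df)
        assert out["obs_total"].tolist() == totals
        assert set(df.columns) <= set(out.columns)

    def test_fit_derive_matches_function(self):
        rng = np.random.default_rng(3)
        n = 400
        df = pd.DataFrame({"sex": rng.choice(["male", "female"], n)})
        for comp in builtin_table():
            if comp.mode == "tertile":
                df[comp.name] = rng.lognormal(2.0, 0.5, n)
        scorer = OBSScorer(cutoffs="derive").fit(df)
        expected = derive_cutoffs(df)
        for comp in expected:
            if comp.mode == "tertile":
                assert scorer.table_[comp.name].cutoffs == comp.cutoffs

    def test_unfitted_transform_errors(self, hand_scored_records):
        df, _, _ = hand_scored_records
        with pytest.raises(ConfigurationError):
            OBSScorer().transform(df)
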