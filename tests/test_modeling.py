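"""Substitution scenarios, EAR prevalence and summary statistics."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from milkswap.composition import CompositionTable, FoodCompositionEntry
from milkswap.intake import RecallLine, compute_intake
from milkswap.modeling import (
    ScenarioError,
    ScenarioSpec,
    prevalence_below_reference,
    relative_reduction,
    round_half_up,
    run_scenario,
    substitute,
    summarize_distribution,
)
from milkswap.nutrients import NutrientVector
from milkswap.references import ReferenceError, ReferenceValueSet


@pytest.fixture(scope="module")
def milk_table():
    return CompositionTable(
        [
            FoodCompositionEntry(
                "skm", "Condensed beverage", "per_100_mL",
                NutrientVector(energy_kcal=80, vitd_ug=0.0, iron_mg=0.05, calcium_mg=71),
                milk_type="condensed",
            ),
            FoodCompositionEntry(
                "gum", "YCM", "per_100_mL",
                NutrientVector(energy_kcal=40, vitd_ug=2.8, iron_mg=1.8, calcium_mg=180),
                milk_type="ycm", ycm_ageband="1+",
            ),
            FoodCompositionEntry(
                "rice", "Rice", "per_100_g", NutrientVector(energy_kcal=130, iron_mg=0.2)
            ),
        ]
    )


def _spec(milk_table, mode):
    prof = milk_table["gum"]
    return ScenarioSpec(mode, "condensed", {(12, 35): prof, (36, 60): prof})


class TestSummarize:
    def test_one_to_five(self):
        s = summarize_distribution([1, 2, 3, 4, 5])
        assert s.mean == 3 and s.p50 == 3
        assert s.sd == pytest.approx(np.std([1, 2, 3, 4, 5], ddof=1))

    def test_single_value_sd_zero_by_convention(self):
        s = summarize_distribution([4.2])
        assert s.mean == 4.2 and s.sd == 0.0

    def test_zero_inflated_quartiles(self):
        s = summarize_distribution([0, 0, 0, 10])
        assert s.p25 == 0.0 and s.mean == 2.5

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            summarize_distribution([])


class TestRounding:
    @pytest.mark.parametrize(
        ("value", "expected"), [(30.952, 31.0), (0.5, 1.0), (2.5, 3.0), (62.49, 62.0)]
    )
    def test_round_half_up(self, value, expected):
        assert round_half_up(value) == expected

    def test_relative_reduction_printed_cells(self):
        assert relative_reduction(84, 58) == pytest.approx(30.952380952, abs=1e-9)
        assert relative_reduction(84, 84) == 0.0
        with pytest.raises(ValueError):
            relative_reduction(0, 10)


class TestPrevalence:
    def _intakes(self, pairs):
        return [
            dataclasses.make_dataclass("CI", ["age_months", "intake"])(a, v)
            for a, v in pairs
        ]

    def test_direct_count_below_cutpoint(self, refs):
        intakes = self._intakes(
            (20, NutrientVector(iron_mg=v)) for v in (2.8, 5.9, 6.0)
        )
        res = prevalence_below_reference(intakes, "iron_mg", refs)
        assert res.prevalence_pct == pytest.approx(100 / 3)
        assert (res.count_below, res.n) == (1, 3)

    def test_all_zero_intakes_are_all_inadequate(self, refs):
        intakes = self._intakes((20, NutrientVector()) for _ in range(4))
        assert prevalence_below_reference(intakes, "iron_mg", refs).prevalence_pct == 100.0

    def test_each_child_judged_against_own_band(self, refs):
        # 6.0 mg clears the 36-47 m cut-point (5.8) but not the 48-60 m one (6.3)
        intakes = self._intakes((a, NutrientVector(iron_mg=6.0)) for a in (40, 50))
        assert prevalence_below_reference(intakes, "iron_mg", refs).prevalence_pct == 50.0

    def test_boundary_intake_is_adequate(self, refs):
        intakes = self._intakes([(20, NutrientVector(iron_mg=5.8))])
        assert prevalence_below_reference(intakes, "iron_mg", refs).prevalence_pct == 0.0

    def test_empty_population_rejected(self, refs):
        with pytest.raises(ValueError):
            prevalence_below_reference([], "iron_mg", refs)

    def test_missing_reference_names_nutrient(self, refs):
        intakes = self._intakes([(20, NutrientVector(vitc_mg=50))])
        with pytest.raises(ReferenceError, match="vitc_mg"):
            prevalence_below_reference(intakes, "vitc_mg", refs)

    @settings(max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 2**16), n=st.integers(1, 40))
    def test_matches_brute_force_count(self, refs, seed, n):
        rng = np.random.default_rng(seed)
        ages = rng.integers(12, 61, size=n)
        values = rng.lognormal(1.0, 1.0, size=n)
        intakes = self._intakes(
            (int(a), NutrientVector(zinc_mg=float(v))) for a, v in zip(ages, values)
        )
        res = prevalence_below_reference(intakes, "zinc_mg", refs)
        brute = sum(
            v < refs.cutpoint("zinc_mg", int(a)) for a, v in zip(ages, values)
        )
        assert res.count_below == brute
        assert res.prevalence_pct == pytest.approx(100.0 * brute / n)


class TestSubstitute:
    def test_equal_volume_keeps_volume(self, milk_table):
        (line,) = substitute(
            [RecallLine("c", "skm", 100.0)], milk_table, _spec(milk_table, "equal_volume"), 24
        )
        assert (line.food_id, line.amount) == ("gum", 100.0)

    def test_isocaloric_rescales_by_energy_ratio(self, milk_table):
        # condensed is 80 kcal/100 mL, replacement 40: double the volume
        (line,) = substitute(
            [RecallLine("c", "skm", 100.0)], milk_table, _spec(milk_table, "isocaloric"), 24
        )
        assert line.amount == pytest.approx(200.0)

    def test_non_target_lines_pass_through_unchanged(self, milk_table):
        rice = RecallLine("c", "rice", 120.0)
        out = substitute([rice], milk_table, _spec(milk_table, "equal_volume"), 24)
        assert out == [rice]

    @pytest.mark.parametrize("mode", ["equal_volume", "isocaloric"])
    def test_self_substitution_is_identity(self, milk_table, mode):
        prof = milk_table["skm"]
        spec = ScenarioSpec(mode, "condensed", {(12, 35): prof, (36, 60): prof})
        lines = [RecallLine("c", "skm", 73.5), RecallLine("c", "rice", 10.0)]
        out = substitute(lines, milk_table, spec, 30)
        base = compute_intake(lines, milk_table).to_array()
        scen = compute_intake(out, milk_table).to_array()
        np.testing.assert_allclose(scen, base, rtol=1e-12)

    def test_isocaloric_conserves_energy_exactly(self, milk_table):
        lines = [RecallLine("c", "skm", 87.3), RecallLine("c", "rice", 140.0)]
        out = substitute(lines, milk_table, _spec(milk_table, "isocaloric"), 24)
        e0 = compute_intake(lines, milk_table).energy_kcal
        e1 = compute_intake(out, milk_table).energy_kcal
        assert e1 == pytest.approx(e0, rel=1e-12)

    def test_zero_replacement_energy_rejected_for_isocaloric(self, milk_table):
        prof = FoodCompositionEntry(
            "water", "Water", "per_100_mL", NutrientVector(), milk_type="ycm",
            ycm_ageband="1+",
        )
        with pytest.raises(ScenarioError, match="energy"):
            ScenarioSpec("isocaloric", "condensed", {(12, 35): prof, (36, 60): prof})


class TestRunScenario:
    def _population(self, groups):
        return pd.DataFrame(
            {
                "child_id": [f"c{i}" for i in range(len(groups))],
                "age_months": [12 + (7 * i) % 49 for i in range(len(groups))],
                "milk_group": groups,
            }
        )

    def test_no_target_consumers_yields_empty_result(self, milk_table, refs):
        pop = self._population(["ycm", "non_milk"])
        recall = pd.DataFrame(
            {"child_id": ["c0"], "food_id": ["gum"], "amount_g": [100.0]}
        )
        assert run_scenario(recall, pop, milk_table, _spec(milk_table, "equal_volume"), refs) == []

    def test_paired_structure_and_monotone_prevalence(self, milk_table, refs):
        rng = np.random.default_rng(5)
        n = 60
        pop = self._population(["condensed"] * n)
        recall = pd.DataFrame(
            {
                "child_id": [f"c{i}" for i in range(n)],
                "food_id": ["skm"] * n,
                "amount_g": rng.lognormal(np.log(150), 0.4, n),
            }
        )
        comps = run_scenario(
            recall, pop, milk_table, _spec(milk_table, "equal_volume"), refs
        )
        assert comps, "expected one comparison per nutrient"
        ages = pop["age_months"]
        stratum_n = {
            (12, 35): int((ages <= 35).sum()),
            (36, 60): int((ages >= 36).sum()),
        }
        for c in comps:
            assert c.n == stratum_n[c.age_stratum]  # same paired child set per arm
            # replacement dominates condensed per mL in every tracked nutrient
            assert c.scenario_prevalence <= c.baseline_prevalence
            assert 0 <= c.p_distribution <= 1 and 0 <= c.p_prevalence <= 1


def test_reference_set_rejects_nonpositive_cutpoint():
    with pytest.raises(ReferenceError):
        ReferenceValueSet({("iron_mg", (12, 35)): 0.0})
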