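"""Substitution scenarios and EAR cut-point inadequacy prevalence.

The modeling replaces every recall line of a target milk type (condensed
milk in the motivating analysis) with a young-child-milk profile matched
to the child's age stratum, under one of two rules:

* ``equal_volume`` — the replacement keeps the consumed volume (mL);
* ``isocaloric``  — the replacement keeps the energy, i.e. the volume is
  rescaled by the ratio of energy densities per 100 mL, so each child's
  total daily energy is conserved exactly.

Inadequacy uses the EAR cut-point method with strict inequality
(intake < cut-point counts as inadequate); children are judged against
their own age band's cut-point even when an analysis stratum pools two
bands.  Quantiles use linear interpolation between order statistics and
the SD uses the n-1 denominator (a single value has SD 0 by convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import yaml

from .composition import CompositionTable, FoodCompositionEntry, convert_basis
from .intake import RecallLine, intake_table
from .references import MODELING_STRATA, ReferenceValueSet
from .stats import fisher_exact_2x2, wilcoxon_signed_rank


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class ScenarioSpec:
    """One substitution scenario.

    ``replacement_profiles`` maps each modeling age stratum (lo, hi in
    months) to the as-consumed per-100-mL profile that replaces the target
    milk for children in that stratum.
    """

    mode: str  # equal_volume | isocaloric
    target_milk: str
    replacement_profiles: dict[tuple[int, int], FoodCompositionEntry]
    name: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("equal_volume", "isocaloric"):
            raise ScenarioError(f"unknown scenario mode {self.mode!r}")
        if self.target_milk not in ("ycm", "condensed", "cow"):
            raise ScenarioError(f"target_milk must be a milk type, got {self.target_milk!r}")
        for stratum, prof in self.replacement_profiles.items():
            if prof.basis != "per_100_mL":
                raise ScenarioError(
                    f"replacement profile {prof.food_id!r} for {stratum} must be per_100_mL"
                )
            if self.mode == "isocaloric" and prof.nutrients.energy_kcal <= 0:
                raise ScenarioError(
                    f"isocaloric mode needs positive energy density in {prof.food_id!r}"
                )

    def profile_for_age(self, age_months: int) -> FoodCompositionEntry:
        for (lo, hi), prof in self.replacement_profiles.items():
            if lo <= age_months <= hi:
                return prof
        raise ScenarioError(f"no replacement profile covers age {age_months} months")


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    p25: float
    p50: float
    p75: float

    def __post_init__(self) -> None:
        if not self.p25 <= self.p50 <= self.p75:
            raise ValueError("quantiles must be ordered")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class PrevalenceResult:
    prevalence_pct: float
    count_below: int
    n: int


@dataclass(frozen=True)
class ScenarioComparison:
    """Machine twin of one nutrient block of a scenario table."""

    nutrient: str
    age_stratum: tuple[int, int]
    scenario_name: str
    n: int
    baseline: SummaryStats
    scenario: SummaryStats
    baseline_prevalence: float
    scenario_prevalence: float
    p_distribution: float
    p_prevalence: float
    relative_reduction: float


def scenario_from_dict(data: dict, table: CompositionTable) -> ScenarioSpec:
    """Build a scenario from its YAML mapping.

    Expected keys: ``mode``, ``target_milk``, optional ``name``, and
    ``replacement_profiles`` mapping ``"lo-hi"`` age strata to food ids
    that resolve in ``table``.
    """
    profiles = {}
    for key, food_id in data["replacement_profiles"].items():
        lo, hi = (int(x) for x in str(key).split("-"))
        profiles[(lo, hi)] = convert_basis(table[food_id], "per_100_mL")
    return ScenarioSpec(
        mode=data["mode"],
        target_milk=data["target_milk"],
        replacement_profiles=profiles,
        name=data.get("name", ""),
    )


def load_scenario(path, table: CompositionTable) -> ScenarioSpec:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh), table)


def default_scenarios(table: CompositionTable) -> list[ScenarioSpec]:
    """The two condensed-milk -> YCM scenarios (equal-volume, isocaloric)."""
    profiles = {
        (12, 35): convert_basis(table["ycm_1plus"], "per_100_mL"),
        (36, 60): convert_basis(table["ycm_3plus"], "per_100_mL"),
    }
    return [
        ScenarioSpec("equal_volume", "condensed", profiles, name="scenario_1_equal_volume"),
        ScenarioSpec("isocaloric", "condensed", profiles, name="scenario_2_isocaloric"),
    ]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def relative_reduction(baseline_prev: float, scenario_prev: float) -> float:
    """100 x (baseline - scenario) / baseline, in percent of baseline."""
    if baseline_prev <= 0:
        raise ValueError("relative reduction undefined for baseline prevalence <= 0")
    return 100.0 * (baseline_prev - scenario_prev) / baseline_prev


def summarize_distribution(values) -> SummaryStats:
    """Mean, sample SD and quartiles (linear interpolation)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 1:
        raise ValueError("cannot summarise an empty sample")
    sd = 0.0 if arr.size == 1 else float(arr.std(ddof=1))
    p25, p50, p75 = np.percentile(arr, [25, 50, 75], method="linear")
    return SummaryStats(float(arr.mean()), sd, float(p25), float(p50), float(p75))


def prevalence_below_reference(intakes, nutrient: str, refs: ReferenceValueSet) -> PrevalenceResult:
    """Fraction of children strictly below their age band's EAR cut-point.

    ``intakes`` is an iterable of objects with ``age_months`` and an
    ``intake`` NutrientVector (e.g. :class:`milkswap.intake.ChildIntake`).
    """
    values, cuts = [], []
    for child in intakes:
        values.append(child.intake[nutrient])
        cuts.append(refs.cutpoint(nutrient, child.age_months))
    n = len(values)
    if n == 0:
        raise ValueError("empty population: prevalence undefined")
    below = int((np.asarray(values) < np.asarray(cuts)).sum())
    return PrevalenceResult(100.0 * below / n, below, n)


def _prevalence_frame(frame: pd.DataFrame, nutrient: str, refs: ReferenceValueSet) -> PrevalenceResult:
    """Vectorised prevalence for a frame with age_months + nutrient columns."""
    cuts = frame["age_months"].map(lambda a: refs.cutpoint(nutrient, int(a))).to_numpy()
    vals = frame[nutrient].to_numpy()
    n = len(frame)
    if n == 0:
        raise ValueError("empty population: prevalence undefined")
    below = int((vals < cuts).sum())
    return PrevalenceResult(100.0 * below / n, below, n)


def substitute(lines, table: CompositionTable, spec: ScenarioSpec, age_months: int) -> list[RecallLine]:
    """Apply one substitution scenario to one child's recall lines.

    Lines whose food is not of the target milk type pass through
    unchanged (same objects); each target line becomes one line of the
    age-appropriate replacement profile with the volume given by the
    scenario mode.  A child with no target lines is returned unchanged.
    """
    out: list[RecallLine] = []
    for line in lines:
        entry = table[line.food_id]
        if entry.milk_type != spec.target_milk:
            out.append(line)
            continue
        as_ml = convert_basis(entry, "per_100_mL")
        volume_ml = line.amount if entry.basis == "per_100_mL" else (
            line.amount / entry.density_g_per_mL
            if entry.density_g_per_mL
            else _missing_density(entry)
        )
        prof = spec.profile_for_age(age_months)
        if spec.mode == "equal_volume":
            new_amount = volume_ml
        else:  # isocaloric: conserve the line's energy exactly
            new_amount = volume_ml * as_ml.nutrients.energy_kcal / prof.nutrients.energy_kcal
        out.append(RecallLine(child_id=line.child_id, food_id=prof.food_id, amount=new_amount))
    return out


def _missing_density(entry):
    raise ScenarioError(f"{entry.food_id}: density required to express amount in mL")


def substitute_frame(
    recall: pd.DataFrame,
    table: CompositionTable,
    spec: ScenarioSpec,
    ages: pd.Series,
) -> pd.DataFrame:
    """Scenario recall frame for a whole population.

    ``ages`` maps child_id -> age_months.  The output preserves row order;
    the replacement profiles must be registered in ``table`` before the
    scenario intakes are computed.
    """
    recs = []
    for r in recall.itertuples(index=False):
        line = RecallLine(str(r.child_id), str(r.food_id), float(r.amount_g))
        (new_line,) = substitute([line], table, spec, int(ages[str(r.child_id)]))
        recs.append((new_line.child_id, new_line.food_id, new_line.amount))
    return pd.DataFrame(recs, columns=["child_id", "food_id", "amount_g"])


def register_profiles(table: CompositionTable, spec: ScenarioSpec) -> None:
    """Ensure scenario replacement profiles resolve in the composition table."""
    for prof in spec.replacement_profiles.values():
        if prof.food_id not in table:
            table.add(prof)


def run_scenario(
    recall: pd.DataFrame,
    population: pd.DataFrame,
    table: CompositionTable,
    spec: ScenarioSpec,
    refs: ReferenceValueSet,
    strata: tuple[tuple[int, int], ...] = MODELING_STRATA,
) -> list[ScenarioComparison]:
    """Paired baseline/scenario comparison among target-milk consumers.

    ``population`` needs columns child_id, age_months, milk_group.  The
    result has one :class:`ScenarioComparison` per (nutrient with a
    reference value, modeling stratum); an empty target group yields an
    empty list.  Baseline and scenario child sets are identical and
    identically ordered, as the paired signed-rank test requires.
    """
    register_profiles(table, spec)
    consumers = population[population["milk_group"] == spec.target_milk]
    if consumers.empty:
        return []
    ages = consumers.set_index("child_id")["age_months"]
    sub_recall = recall[recall["child_id"].isin(set(ages.index))]
    scen_recall = substitute_frame(sub_recall, table, spec, ages)

    base = intake_table(sub_recall, table).set_index("child_id")
    scen = intake_table(scen_recall, table).set_index("child_id")
    base["age_months"] = ages
    scen["age_months"] = ages

    out: list[ScenarioComparison] = []
    for lo, hi in strata:
        ids = ages.index[(ages >= lo) & (ages <= hi)]
        if len(ids) == 0:
            continue
        b, s = base.loc[ids], scen.loc[ids]
        for nutrient in refs.nutrients():
            prev_b = _prevalence_frame(b, nutrient, refs)
            prev_s = _prevalence_frame(s, nutrient, refs)
            p1 = wilcoxon_signed_rank(b[nutrient].to_numpy(), s[nutrient].to_numpy()).p_value
            p2 = fisher_exact_2x2(
                [
                    [prev_b.count_below, prev_b.n - prev_b.count_below],
                    [prev_s.count_below, prev_s.n - prev_s.count_below],
                ]
            ).p_value
            rel = (
                relative_reduction(prev_b.prevalence_pct, prev_s.prevalence_pct)
                if prev_b.prevalence_pct > 0
                else float("nan")
            )
            out.append(
                ScenarioComparison(
                    nutrient=nutrient,
                    age_stratum=(lo, hi),
                    scenario_name=spec.name or spec.mode,
                    n=prev_b.n,
                    baseline=summarize_distribution(b[nutrient]),
                    scenario=summarize_distribution(s[nutrient]),
                    baseline_prevalence=prev_b.prevalence_pct,
                    scenario_prevalence=prev_s.prevalence_pct,
                    p_distribution=p1,
                    p_prevalence=p2,
                    relative_reduction=rel,
                )
            )
    return out


def comparisons_frame(comparisons) -> pd.DataFrame:
    """Long-format table mirroring a scenario-modeling table block."""
    rows = []
    for c in comparisons:
        for arm, stats_, prev in (
            ("baseline", c.baseline, c.baseline_prevalence),
            (c.scenario_name, c.scenario, c.scenario_prevalence),
        ):
            rows.append(
                {
                    "nutrient": c.nutrient,
                    "age_lo": c.age_stratum[0],
                    "age_hi": c.age_stratum[1],
                    "arm": arm,
                    "n": c.n,
                    "mean": stats_.mean,
                    "sd": stats_.sd,
                    "p25": stats_.p25,
                    "p50": stats_.p50,
                    "p75": stats_.p75,
                    "pct_below": prev,
                    "p1": float("nan") if arm == "baseline" else c.p_distribution,
                    "p2": float("nan") if arm == "baseline" else c.p_prevalence,
                    "relative_reduction": float("nan") if arm == "baseline" else c.relative_reduction,
                }
            )
    return pd.DataFrame(rows)
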