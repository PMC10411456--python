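"""Report tables: characteristics, inadequacy by milk group, scenario blocks.

Mirrors the analysis layer of a milk-consumer survey report: a population
characteristics table, characteristics by milk-consumer group with
chi-square tests, inadequacy prevalence by group x nutrient x age stratum
with Fisher's exact tests against a reference group (Bonferroni-adjusted),
and the scenario-modeling blocks.  Every number also lands in one
machine-readable JSON bundle so the CSVs carry no hand-edited values.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .modeling import comparisons_frame, _prevalence_frame
from .references import ADEQUACY_STRATA, ReferenceValueSet
from .stats import bonferroni_adjust, chi_square, fisher_exact_2x2
from .synthetic import EDUCATION_LEVELS, MILK_GROUPS, REGIONS, SES_LEVELS, SEXES

_CHARACTERISTICS = {
    "region": REGIONS,
    "sex": SEXES,
    "ses": SES_LEVELS,
    "mother_education": EDUCATION_LEVELS,
}


def _age_stratum_label(age: int) -> str:
    for lo, hi in ADEQUACY_STRATA:
        if lo <= age <= hi:
            return f"{lo}-{hi}"
    raise ValueError(f"age {age} outside 12–60 months")


def characteristics_table(population: pd.DataFrame) -> pd.DataFrame:
    """Population counts and percentages per characteristic category."""
    rows = []
    frames = dict(_CHARACTERISTICS)
    pop = population.copy()
    pop["age_group"] = pop["age_months"].map(_age_stratum_label)
    frames["age_group"] = tuple(f"{lo}-{hi}" for lo, hi in ADEQUACY_STRATA)
    n = len(pop)
    for var, cats in frames.items():
        counts = pop[var].value_counts()
        for cat in cats:
            c = int(counts.get(cat, 0))
            rows.append({"variable": var, "category": cat, "count": c,
                         "pct": 100.0 * c / n if n else float("nan")})
    return pd.DataFrame(rows)


def characteristics_by_group(population: pd.DataFrame) -> pd.DataFrame:
    """Category percentages within each milk group, with chi-square p.

    The chi-square tests independence of the characteristic and the milk
    group over the full r x c count table (no continuity correction).
    """
    rows = []
    pop = population.copy()
    pop["age_group"] = pop["age_months"].map(_age_stratum_label)
    frames = dict(_CHARACTERISTICS)
    frames["age_group"] = tuple(f"{lo}-{hi}" for lo, hi in ADEQUACY_STRATA)
    for var, cats in frames.items():
        counts = pd.crosstab(pop[var], pop["milk_group"])
        counts = counts.reindex(index=list(cats), columns=list(MILK_GROUPS), fill_value=0)
        nonzero = counts.loc[counts.sum(axis=1) > 0, counts.sum(axis=0) > 0]
        p = (
            chi_square(nonzero.to_numpy()).p_value
            if nonzero.shape[0] >= 2 and nonzero.shape[1] >= 2
            else float("nan")
        )
        group_totals = counts.sum(axis=0)
        for cat in cats:
            row = {"variable": var, "category": cat, "chi_square_p": p}
            for g in MILK_GROUPS:
                total = group_totals[g]
                row[f"pct_{g}"] = (
                    100.0 * counts.loc[cat, g] / total if total else float("nan")
                )
            rows.append(row)
    return pd.DataFrame(rows)


def inadequacy_by_group(
    intakes: pd.DataFrame,
    refs: ReferenceValueSet,
    reference_group: str = "ycm",
    comparators: tuple[str, ...] = ("condensed", "cow"),
    family_size: int | None = None,
) -> pd.DataFrame:
    """Inadequacy % by milk group, nutrient and age stratum.

    ``intakes`` needs child_id, age_months, milk_group and nutrient
    columns.  Each comparator group is tested against the reference group
    with Fisher's exact test; raw p values are Bonferroni-adjusted with
    family size ``family_size`` (default: the number of comparators) per
    (nutrient, age stratum).
    """
    m = family_size or len(comparators)
    rows = []
    for lo, hi in ADEQUACY_STRATA:
        sub = intakes[(intakes["age_months"] >= lo) & (intakes["age_months"] <= hi)]
        if sub.empty:
            continue
        for nutrient in refs.nutrients():
            prev = {}
            for g in MILK_GROUPS:
                grp = sub[sub["milk_group"] == g]
                prev[g] = _prevalence_frame(grp, nutrient, refs) if len(grp) else None
            ref_prev = prev[reference_group]
            raw_ps = {}
            for g in comparators:
                if prev[g] is None or ref_prev is None:
                    raw_ps[g] = float("nan")
                    continue
                raw_ps[g] = fisher_exact_2x2(
                    [
                        [ref_prev.count_below, ref_prev.n - ref_prev.count_below],
                        [prev[g].count_below, prev[g].n - prev[g].count_below],
                    ]
                ).p_value
            for g in MILK_GROUPS:
                if prev[g] is None:
                    continue
                raw = raw_ps.get(g, float("nan"))
                adj = (
                    bonferroni_adjust([raw], m)[0] if np.isfinite(raw) else float("nan")
                )
                rows.append(
                    {
                        "age_lo": lo,
                        "age_hi": hi,
                        "nutrient": nutrient,
                        "milk_group": g,
                        "n": prev[g].n,
                        "pct_inadequate": prev[g].prevalence_pct,
                        "fisher_p_vs_reference": raw,
                        "fisher_p_bonferroni": adj,
                        "bonferroni_family_size": m,
                    }
                )
    return pd.DataFrame(rows)


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    return obj


def build_report(
    population: pd.DataFrame,
    intakes: pd.DataFrame,
    comparisons,
    refs: ReferenceValueSet,
    out_dir,
    reference_group: str = "ycm",
    family_size: int | None = None,
) -> dict:
    """Write the CSV report set plus a machine-readable JSON bundle.

    Returns the bundle; CSVs are byte-deterministic for a fixed input.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    char = characteristics_table(population)
    by_group = characteristics_by_group(population)
    inad = inadequacy_by_group(
        intakes, refs, reference_group=reference_group, family_size=family_size
    )
    comp = (
        comparisons
        if isinstance(comparisons, pd.DataFrame)
        else comparisons_frame(comparisons)
    )
    char.to_csv(out / "characteristics.csv", index=False)
    by_group.to_csv(out / "characteristics_by_group.csv", index=False)
    inad.to_csv(out / "inadequacy_by_group.csv", index=False)
    comp.to_csv(out / "scenario_comparisons.csv", index=False)
    bundle = {
        "n_children": int(len(population)),
        "characteristics": char.to_dict(orient="records"),
        "characteristics_by_group": by_group.to_dict(orient="records"),
        "inadequacy_by_group": inad.to_dict(orient="records"),
        "scenario_comparisons": comp.to_dict(orient="records"),
    }
    bundle = _json_safe(bundle)
    with (out / "report.json").open("w") as fh:
        json.dump(bundle, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return bundle
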