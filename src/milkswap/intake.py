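"""Per-child daily intake from one-day 24-h recall lines.

The computation is the standard food-composition lookup: each recall line
contributes ``amount / 100 x nutrient density per 100 units``, summed over
the day's lines.  The amount is expressed in the food's own basis unit
(grams for per_100_g entries, millilitres for per_100_mL entries), on an
as-consumed basis — exactly what a 24-h recall records.

Children are classified into mutually exclusive milk-consumer groups from
the same recall: ``non_milk`` if no milk-typed line appears, otherwise the
group of the milk type contributing the most energy among the child's milk
lines (dominant-energy rule), with ties broken by the fixed preference
order ycm > cow > condensed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composition import CompositionTable
from .nutrients import NUTRIENT_FIELDS, NutrientVector

RECALL_HEADER = ("child_id", "food_id", "amount_g")

MILK_GROUPS = ("non_milk", "ycm", "condensed", "cow")
#: Tie-break preference for the dominant-energy rule (earlier wins).
_TIE_ORDER = ("ycm", "cow", "condensed")


@dataclass(frozen=True)
class RecallLine:
    """One food line of a one-day 24-h recall."""

    child_id: str
    food_id: str
    amount: float  # g or mL as consumed, in the food's basis unit

    def __post_init__(self) -> None:
        if not np.isfinite(self.amount) or self.amount < 0:
            raise ValueError(
                f"recall amount must be finite and >= 0, got {self.amount!r}"
            )


@dataclass(frozen=True)
class ChildIntake:
    child_id: str
    age_months: int
    milk_group: str
    intake: NutrientVector


def compute_intake(lines, table: CompositionTable) -> NutrientVector:
    """Daily nutrient intake: ``sum(amount / 100 * density_per_100)``.

    Linear and permutation-invariant; an empty line list yields the zero
    vector.  Unresolved food ids raise :class:`CompositionError`.
    """
    total = np.zeros(len(NUTRIENT_FIELDS))
    for line in lines:
        entry = table[line.food_id]
        total += (line.amount / 100.0) * entry.nutrients.to_array()
    return NutrientVector.from_array(total)


def classify_consumer(lines, table: CompositionTable) -> str:
    """Milk-consumer group for one child's recall (see module docstring)."""
    energy_by_type: dict[str, float] = {}
    for line in lines:
        entry = table[line.food_id]
        if entry.milk_type != "none":
            e = (line.amount / 100.0) * entry.nutrients.energy_kcal
            energy_by_type[entry.milk_type] = energy_by_type.get(entry.milk_type, 0.0) + e
    if not energy_by_type:
        return "non_milk"
    best = max(energy_by_type.values())
    for milk_type in _TIE_ORDER:  # fixed deterministic tie-break
        if energy_by_type.get(milk_type, -1.0) == best:
            return milk_type
    raise AssertionError("unreachable")


def read_recall_csv(path) -> pd.DataFrame:
    """Recall lines CSV (``child_id,food_id,amount_g``) as a DataFrame."""
    df = pd.read_csv(path, dtype={"child_id": str, "food_id": str})
    missing = set(RECALL_HEADER) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (df["amount_g"] < 0).any() or not np.isfinite(df["amount_g"]).all():
        raise ValueError(f"{path}: amounts must be finite and >= 0")
    return df


def lines_from_frame(df: pd.DataFrame) -> list[RecallLine]:
    return [
        RecallLine(child_id=str(r.child_id), food_id=str(r.food_id), amount=float(r.amount_g))
        for r in df.itertuples(index=False)
    ]


def intake_table(recall: pd.DataFrame, table: CompositionTable) -> pd.DataFrame:
    """Per-child intakes for a whole recall frame (one row per child).

    Vectorised equivalent of calling :func:`compute_intake` per child;
    returns columns ``child_id`` plus every nutrient component.
    """
    densities = pd.DataFrame(
        {fid: table[fid].nutrients.to_array() for fid in recall["food_id"].unique()},
        index=list(NUTRIENT_FIELDS),
    ).T
    contrib = densities.loc[recall["food_id"]].to_numpy() * (
        recall["amount_g"].to_numpy()[:, None] / 100.0
    )
    out = pd.DataFrame(contrib, columns=list(NUTRIENT_FIELDS))
    out.insert(0, "child_id", recall["child_id"].to_numpy())
    return out.groupby("child_id", as_index=False, sort=True).sum()


def classify_table(recall: pd.DataFrame, table: CompositionTable) -> pd.DataFrame:
    """Milk-consumer group per child id for a whole recall frame."""
    groups = {
        cid: classify_consumer(lines_from_frame(sub), table)
        for cid, sub in recall.groupby("child_id", sort=True)
    }
    return pd.DataFrame(
        {"child_id": list(groups), "milk_group": list(groups.values())}
    )
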