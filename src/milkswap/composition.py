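"""Food-composition table: nutrient densities per 100 g or 100 mL as consumed.

A composition entry describes one food on an *as consumed* basis — for a
condensed-milk beverage that means the diluted drink, and for a young-child
milk (YCM, powder products in practice) the reconstituted liquid.  The
``milk_type`` tag drives the milk-consumer classification and the
substitution scenarios.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

from .nutrients import NUTRIENT_FIELDS, NutrientVector

MILK_TYPES = ("none", "ycm", "condensed", "cow")
BASES = ("per_100_g", "per_100_mL")
YCM_AGEBANDS = ("", "1+", "3+")

#: CSV header, fixed.
COMPOSITION_HEADER = (
    "food_id",
    "name",
    "basis",
    "density_g_per_mL",
    "milk_type",
    "ycm_ageband",
) + NUTRIENT_FIELDS


class CompositionError(ValueError):
    """Malformed or inconsistent composition input."""


@dataclass(frozen=True)
class FoodCompositionEntry:
    """One food's nutrient density per 100 units as consumed."""

    food_id: str
    name: str
    basis: str  # per_100_g | per_100_mL
    nutrients: NutrientVector
    milk_type: str = "none"
    ycm_ageband: str = ""  # "1+" or "3+" for YCM entries
    density_g_per_mL: float | None = None

    def __post_init__(self) -> None:
        if self.basis not in BASES:
            raise CompositionError(f"{self.food_id}: unknown basis {self.basis!r}")
        if self.milk_type not in MILK_TYPES:
            raise CompositionError(f"{self.food_id}: unknown milk_type {self.milk_type!r}")
        if self.milk_type == "ycm" and self.ycm_ageband not in ("1+", "3+"):
            raise CompositionError(
                f"{self.food_id}: YCM entries need ycm_ageband '1+' or '3+'"
            )
        if self.density_g_per_mL is not None and self.density_g_per_mL <= 0:
            raise CompositionError(f"{self.food_id}: density must be positive")


class CompositionTable:
    """Keyed collection of :class:`FoodCompositionEntry`, unique by food_id."""

    def __init__(self, entries=()):
        self._entries: dict[str, FoodCompositionEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: FoodCompositionEntry) -> None:
        if entry.food_id in self._entries:
            raise CompositionError(f"duplicate food_id {entry.food_id!r}")
        self._entries[entry.food_id] = entry

    def __getitem__(self, food_id: str) -> FoodCompositionEntry:
        try:
            return self._entries[food_id]
        except KeyError:
            raise CompositionError(f"unresolved food_id {food_id!r}") from None

    def __contains__(self, food_id: str) -> bool:
        return food_id in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def milk_entries(self, milk_type: str | None = None):
        out = [e for e in self if e.milk_type != "none"]
        if milk_type is not None:
            out = [e for e in out if e.milk_type == milk_type]
        return out


def read_composition_table(path) -> CompositionTable:
    """Read and validate a composition CSV (header ``COMPOSITION_HEADER``).

    Every row is validated (non-negative nutrient densities, known milk
    type and basis); duplicates and malformed rows raise
    :class:`CompositionError` naming the offending row.
    """
    path = Path(path)
    table = CompositionTable()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(COMPOSITION_HEADER) - set(reader.fieldnames or ())
        if missing:
            raise CompositionError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):  # header is line 1
            try:
                dens = row["density_g_per_mL"].strip()
                nutrients = NutrientVector.from_mapping(
                    {k: float(row[k]) for k in NUTRIENT_FIELDS}
                )
                entry = FoodCompositionEntry(
                    food_id=row["food_id"],
                    name=row["name"],
                    basis=row["basis"],
                    density_g_per_mL=float(dens) if dens else None,
                    milk_type=row["milk_type"],
                    ycm_ageband=row["ycm_ageband"].strip(),
                    nutrients=nutrients,
                )
            except (ValueError, KeyError) as exc:
                raise CompositionError(f"{path} row {i}: {exc}") from exc
            table.add(entry)
    return table


def write_composition_table(table: CompositionTable, path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COMPOSITION_HEADER)
        for e in table:
            writer.writerow(
                [
                    e.food_id,
                    e.name,
                    e.basis,
                    "" if e.density_g_per_mL is None else repr(e.density_g_per_mL),
                    e.milk_type,
                    e.ycm_ageband,
                ]
                + [repr(x) for x in e.nutrients.to_array().tolist()]
            )


def convert_basis(entry: FoodCompositionEntry, target_basis: str) -> FoodCompositionEntry:
    """Re-express an entry per 100 g or per 100 mL using its density.

    100 mL of the food weighs ``100 * density`` g, so per-100-mL densities
    are per-100-g densities scaled by the g/mL density, and conversely.
    The round trip is the identity up to floating point.
    """
    if target_basis not in BASES:
        raise CompositionError(f"unknown basis {target_basis!r}")
    if entry.basis == target_basis:
        return entry
    if entry.density_g_per_mL is None:
        raise CompositionError(
            f"{entry.food_id}: density_g_per_mL required to convert basis"
        )
    if entry.basis == "per_100_g":  # -> per_100_mL
        factor = entry.density_g_per_mL
    else:  # per_100_mL -> per_100_g
        factor = 1.0 / entry.density_g_per_mL
    return replace(entry, basis=target_basis, nutrients=entry.nutrients.scale(factor))


def reconstitute_powder(
    powder: FoodCompositionEntry,
    grams_per_100_mL: float,
    food_id: str | None = None,
    name: str | None = None,
) -> FoodCompositionEntry:
    """As-consumed per-100-mL profile of a reconstituted milk powder.

    ``grams_per_100_mL`` is the label dosing (g of powder per 100 mL of
    prepared drink).  The powder entry must be per_100_g.
    """
    if powder.basis != "per_100_g":
        raise CompositionError("powder entry must be per_100_g")
    if grams_per_100_mL <= 0:
        raise CompositionError("grams_per_100_mL must be positive")
    return replace(
        powder,
        food_id=food_id or f"{powder.food_id}_reconstituted",
        name=name or f"{powder.name} (reconstituted)",
        basis="per_100_mL",
        nutrients=powder.nutrients.scale(grams_per_100_mL / 100.0),
        density_g_per_mL=None,
    )
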