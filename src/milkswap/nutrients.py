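"""Fixed nutrient vector used throughout the package.

The component set is closed: daily energy and protein plus the eight
micronutrients tracked in the adequacy analysis (vitamin A as retinol
equivalents, vitamins C and D, folate, calcium, iron and zinc).  All
amounts are per day (for a child's intake) or per 100 g / 100 mL as
consumed (for a food-composition entry).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

#: Canonical component order.  Column names double as CSV headers.
NUTRIENT_FIELDS: tuple[str, ...] = (
    "energy_kcal",
    "protein_g",
    "vita_ug",
    "vitc_mg",
    "vitd_ug",
    "folate_ug",
    "calcium_mg",
    "iron_mg",
    "zinc_mg",
)

#: Micronutrients evaluated against EAR cut-points.
MICRONUTRIENTS: tuple[str, ...] = (
    "vita_ug",
    "vitc_mg",
    "vitd_ug",
    "folate_ug",
    "calcium_mg",
    "iron_mg",
    "zinc_mg",
)

#: Human-readable unit per component.
UNITS: dict[str, str] = {
    "energy_kcal": "kcal",
    "protein_g": "g",
    "vita_ug": "ug RE",
    "vitc_mg": "mg",
    "vitd_ug": "ug",
    "folate_ug": "ug",
    "calcium_mg": "mg",
    "iron_mg": "mg",
    "zinc_mg": "mg",
}


@dataclass(frozen=True)
class NutrientVector:
    """Non-negative amounts for the closed set of tracked components."""

    energy_kcal: float = 0.0
    protein_g: float = 0.0
    vita_ug: float = 0.0
    vitc_mg: float = 0.0
    vitd_ug: float = 0.0
    folate_ug: float = 0.0
    calcium_mg: float = 0.0
    iron_mg: float = 0.0
    zinc_mg: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"non-finite {f.name}: {v!r}")
            if v < 0:
                raise ValueError(f"negative {f.name}: {v!r}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in NUTRIENT_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "NutrientVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(NUTRIENT_FIELDS),):
            raise ValueError(f"expected {len(NUTRIENT_FIELDS)} components, got {arr.shape}")
        return cls(**dict(zip(NUTRIENT_FIELDS, arr.tolist())))

    @classmethod
    def from_mapping(cls, mapping) -> "NutrientVector":
        unknown = set(mapping) - set(NUTRIENT_FIELDS)
        if unknown:
            raise ValueError(f"unknown nutrient components: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        return NutrientVector.from_array(self.to_array() + other.to_array())

    def scale(self, factor: float) -> "NutrientVector":
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return NutrientVector.from_array(self.to_array() * factor)

    def __getitem__(self, key: str) -> float:
        if key not in NUTRIENT_FIELDS:
            raise KeyError(key)
        return getattr(self, key)


ZERO = NutrientVector()
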