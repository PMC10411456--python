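"""EAR reference values (cut-points) per nutrient and age band.

The EAR cut-point method estimates the prevalence of inadequate intake as
the fraction of children whose single-day intake falls strictly below the
estimated average requirement for their age band.  Reference lookup uses
three bands: 12–35, 36–47 and 48–60 months; the 3–4 y modeling stratum
spans two of them, and each child is judged against their own band.

The bundled ``data/ear_reference.csv`` carries WHO EAR cut-points for the
six micronutrients with published values in this analysis.  Vitamin C is
evaluated in the group-comparison analysis but has no bundled cut-point;
supply one via the CSV if needed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .nutrients import MICRONUTRIENTS

#: Age bands (lo inclusive, hi inclusive, in months) for reference lookup.
AGE_BANDS = ((12, 35), (36, 47), (48, 60))

#: Age strata used in the adequacy-by-group analysis.
ADEQUACY_STRATA = ((12, 23), (24, 35), (36, 47), (48, 60))

#: Age strata used for dietary modeling (1–2 y and 3–4 y).
MODELING_STRATA = ((12, 35), (36, 60))

REFERENCE_HEADER = ("nutrient", "age_band_lo", "age_band_hi", "cutpoint", "unit")


class ReferenceError(ValueError):
    """Missing or invalid reference value."""


def age_band(age_months: int) -> tuple[int, int]:
    for lo, hi in AGE_BANDS:
        if lo <= age_months <= hi:
            return (lo, hi)
    raise ReferenceError(f"age {age_months} months outside 12–60")


class ReferenceValueSet:
    """Mapping (nutrient, age band) -> EAR cut-point in the nutrient's unit."""

    def __init__(self, values: dict[tuple[str, tuple[int, int]], float]):
        for (nutrient, band), cut in values.items():
            if cut <= 0:
                raise ReferenceError(f"cut-point for {nutrient} {band} must be > 0")
        self._values = dict(values)

    def cutpoint(self, nutrient: str, age_months: int) -> float:
        band = age_band(age_months)
        try:
            return self._values[(nutrient, band)]
        except KeyError:
            raise ReferenceError(
                f"no reference value for {nutrient!r} in band {band}"
            ) from None

    def nutrients(self) -> list[str]:
        return sorted({n for n, _ in self._values}, key=MICRONUTRIENTS.index)

    def has(self, nutrient: str, age_months: int) -> bool:
        return (nutrient, age_band(age_months)) in self._values

    @classmethod
    def from_csv(cls, path) -> "ReferenceValueSet":
        df = pd.read_csv(path)
        missing = set(REFERENCE_HEADER) - set(df.columns)
        if missing:
            raise ReferenceError(f"{path}: missing columns {sorted(missing)}")
        values = {}
        for r in df.itertuples(index=False):
            if r.nutrient not in MICRONUTRIENTS:
                raise ReferenceError(f"{path}: unknown nutrient {r.nutrient!r}")
            band = (int(r.age_band_lo), int(r.age_band_hi))
            if band not in AGE_BANDS:
                raise ReferenceError(f"{path}: unknown age band {band}")
            values[(r.nutrient, band)] = float(r.cutpoint)
        return cls(values)


def load_default_references() -> ReferenceValueSet:
    """Bundled WHO EAR cut-points (six micronutrients, three age bands)."""
    with resources.as_file(
        resources.files("milkswap.data").joinpath("ear_reference.csv")
    ) as p:
        return ReferenceValueSet.from_csv(p)


def fraction_of_requirement_status(
    intake: float, requirement: float, fraction: float = 0.8
) -> bool:
    """Approximate energy/protein adequacy flag.

    True when intake >= ``fraction`` of the stated requirement.  The survey
    programme's own energy/protein classification rule is not public; this
    configurable threshold is an explicit approximation, not a
    reproduction of it.
    """
    if requirement <= 0:
        raise ValueError("requirement must be positive")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    return intake >= fraction * requirement
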