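"""Synthetic one-day dietary recall survey for children 12–60 months.

Emulates the structure of the Indonesian Individual Food Consumption
Survey 2014 (IFCS, part of the SDT 2014 total-diet study): children aged
12–60 months with sex / region / socioeconomic-status / maternal-education
covariates, mutually exclusive milk-consumer groups (non-milk, young-child
milk, condensed milk, cow's milk) with age-band-specific membership
probabilities, and right-skewed single-day nutrient intakes.

A child's day is emitted as recall lines: one background-diet line per
nutrient-bearing pseudo-food (whose density is 100 units per 100 g, so the
line amount in grams equals the nutrient amount) plus, for milk consumers,
exactly one line of the group's milk product with a log-normally
distributed consumed volume.  Background amounts are zero-inflated
log-normal — the minimal shape that reproduces published intake quantiles
where the 25th percentile is zero while the median is positive.

Randomness uses one root seed; each child draws from a substream keyed by
the child's index (``SeedSequence(seed, spawn_key=(index, phase))``), so
growing the population does not reshuffle earlier children.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .nutrients import NUTRIENT_FIELDS
from .references import ADEQUACY_STRATA, MODELING_STRATA

SEXES = ("boy", "girl")
REGIONS = ("urban", "rural")
SES_LEVELS = ("low", "middle", "high")
EDUCATION_LEVELS = (
    "none",
    "not_graduated_elementary",
    "elementary",
    "junior_high",
    "senior_high",
    "diploma",
    "university",
)
MILK_GROUPS = ("non_milk", "ycm", "condensed", "cow")

POPULATION_HEADER = (
    "child_id",
    "age_months",
    "sex",
    "region",
    "ses",
    "mother_education",
    "milk_group",
)


class ConfigError(ValueError):
    """Invalid population configuration."""


@dataclass(frozen=True)
class ChildProfile:
    child_id: str
    age_months: int
    sex: str
    region: str
    ses: str
    mother_education: str

    def __post_init__(self) -> None:
        if not 12 <= self.age_months <= 60:
            raise ValueError(f"age_months must be in [12, 60], got {self.age_months}")
        for value, allowed, name in (
            (self.sex, SEXES, "sex"),
            (self.region, REGIONS, "region"),
            (self.ses, SES_LEVELS, "ses"),
            (self.mother_education, EDUCATION_LEVELS, "mother_education"),
        ):
            if value not in allowed:
                raise ValueError(f"{name} must be one of {allowed}, got {value!r}")


@dataclass(frozen=True)
class IntakeDist:
    """Zero-inflated log-normal for one nutrient's background-diet amount."""

    median: float
    log_sd: float
    zero_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.median < 0:
            raise ConfigError("intake median must be >= 0")
        if self.log_sd <= 0:
            raise ConfigError("intake dispersion (log_sd) must be > 0")
        if not 0 <= self.zero_prob < 1:
            raise ConfigError("zero_prob must be in [0, 1)")


@dataclass(frozen=True)
class PortionDist:
    """Log-normal daily consumed volume (mL) for one milk type."""

    median_ml: float
    log_sd: float

    def __post_init__(self) -> None:
        if self.median_ml < 0:
            raise ConfigError("portion median must be >= 0")
        if self.log_sd <= 0:
            raise ConfigError("portion dispersion must be > 0")


def _check_table(name: str, table: dict, categories: tuple[str, ...]) -> None:
    if set(table) != set(categories):
        raise ConfigError(f"probability table {name!r}: categories {sorted(table)} "
                          f"do not match {categories}")
    vals = np.array([table[c] for c in categories], dtype=float)
    if (vals < 0).any():
        raise ConfigError(f"probability table {name!r}: negative probability")
    if abs(vals.sum() - 1.0) > 1e-9:
        raise ConfigError(f"probability table {name!r}: probabilities sum to "
                          f"{vals.sum():.12f}, not 1")


@dataclass
class PopulationConfig:
    """Everything needed to generate a synthetic survey population.

    ``covariate_probs`` maps covariate name -> age band -> category -> p;
    ``milk_group_probs`` maps age band -> group -> p; ``intake_model`` maps
    nutrient -> modeling stratum -> :class:`IntakeDist`; and
    ``milk_portion_model`` maps milk type -> :class:`PortionDist`.  Age
    bands are the four adequacy strata; modeling strata are 12–35 and
    36–60 months.
    """

    n_children: int
    seed: int
    age_group_probs: dict[tuple[int, int], float]
    covariate_probs: dict[str, dict[tuple[int, int], dict[str, float]]]
    milk_group_probs: dict[tuple[int, int], dict[str, float]]
    intake_model: dict[str, dict[tuple[int, int], IntakeDist]]
    milk_portion_model: dict[str, PortionDist]
    milk_food_ids: dict[str, str] = field(
        default_factory=lambda: {
            "condensed": "condensed_beverage",
            "cow": "cow_milk",
            "ycm_1plus": "ycm_1plus",
            "ycm_3plus": "ycm_3plus",
        }
    )

    def __post_init__(self) -> None:
        if self.n_children < 0:
            raise ConfigError("n_children must be >= 0")
        _check_table("age_group_probs", self.age_group_probs, ADEQUACY_STRATA)
        for var, per_band in self.covariate_probs.items():
            cats = {
                "sex": SEXES,
                "region": REGIONS,
                "ses": SES_LEVELS,
                "mother_education": EDUCATION_LEVELS,
            }.get(var)
            if cats is None:
                raise ConfigError(f"unknown covariate {var!r}")
            for band in ADEQUACY_STRATA:
                if band not in per_band:
                    raise ConfigError(f"covariate_probs[{var!r}] missing age band {band}")
                _check_table(f"{var}@{band}", per_band[band], cats)
        for band in ADEQUACY_STRATA:
            if band not in self.milk_group_probs:
                raise ConfigError(f"milk_group_probs missing age band {band}")
            _check_table(f"milk_group@{band}", self.milk_group_probs[band], MILK_GROUPS)
        for nutrient, per_stratum in self.intake_model.items():
            if nutrient not in NUTRIENT_FIELDS:
                raise ConfigError(f"intake_model: unknown nutrient {nutrient!r}")
            for stratum in MODELING_STRATA:
                if stratum not in per_stratum:
                    raise ConfigError(
                        f"intake_model[{nutrient!r}] missing stratum {stratum}"
                    )
        for milk_type in ("ycm", "condensed", "cow"):
            if milk_type not in self.milk_portion_model:
                raise ConfigError(f"milk_portion_model missing {milk_type!r}")


def _age_band_of(age_months: int) -> tuple[int, int]:
    for lo, hi in ADEQUACY_STRATA:
        if lo <= age_months <= hi:
            return (lo, hi)
    raise ConfigError(f"age {age_months} months outside the 12–60 population range")


def _modeling_stratum(age_months: int) -> tuple[int, int]:
    for lo, hi in MODELING_STRATA:
        if lo <= age_months <= hi:
            return (lo, hi)
    raise ConfigError(f"age {age_months} months outside the 12–60 population range")


def _child_rng(seed: int, index: int, phase: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index, phase)))


def _draw(rng: np.random.Generator, table: dict[str, float], categories) -> str:
    probs = np.array([table[c] for c in categories], dtype=float)
    return categories[rng.choice(len(categories), p=probs / probs.sum())]


def generate_population(config: PopulationConfig) -> list[ChildProfile]:
    """Draw ``n_children`` covariate profiles; deterministic in (config, seed)."""
    profiles = []
    for i in range(config.n_children):
        rng = _child_rng(config.seed, i, 0)
        band = _draw(rng, config.age_group_probs, ADEQUACY_STRATA)
        age = int(rng.integers(band[0], band[1] + 1))
        profiles.append(
            ChildProfile(
                child_id=f"c{i:06d}",
                age_months=age,
                sex=_draw(rng, config.covariate_probs["sex"][band], SEXES),
                region=_draw(rng, config.covariate_probs["region"][band], REGIONS),
                ses=_draw(rng, config.covariate_probs["ses"][band], SES_LEVELS),
                mother_education=_draw(
                    rng, config.covariate_probs["mother_education"][band], EDUCATION_LEVELS
                ),
            )
        )
    return profiles


def assign_milk_group(profile: ChildProfile, config: PopulationConfig, rng) -> str:
    """Draw one of the four mutually exclusive milk groups for this child."""
    band = _age_band_of(profile.age_months)
    return _draw(rng, config.milk_group_probs[band], MILK_GROUPS)


def generate_recall(profile: ChildProfile, group: str, config: PopulationConfig, rng):
    """One child's synthetic recall lines (see module docstring).

    Returns ``(child_id, food_id, amount)`` tuples: one background line per
    nutrient pseudo-food, plus one milk line for milk consumers.
    """
    if group not in MILK_GROUPS:
        raise ConfigError(f"unknown milk group {group!r}")
    stratum = _modeling_stratum(profile.age_months)
    lines = []
    for nutrient in NUTRIENT_FIELDS:
        dist = config.intake_model[nutrient][stratum]
        amount = 0.0
        if rng.random() >= dist.zero_prob and dist.median > 0:
            amount = float(dist.median * np.exp(dist.log_sd * rng.standard_normal()))
        lines.append((profile.child_id, f"bg_{nutrient}", amount))
    if group != "non_milk":
        portion = config.milk_portion_model[group]
        volume = float(portion.median_ml * np.exp(portion.log_sd * rng.standard_normal()))
        if group == "ycm":
            key = "ycm_1plus" if profile.age_months <= 35 else "ycm_3plus"
        else:
            key = group
        lines.append((profile.child_id, config.milk_food_ids[key], volume))
    return lines


def generate_survey(config: PopulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full survey: population frame + recall frame, deterministic in config.

    Population columns follow ``POPULATION_HEADER``; recall columns are
    ``child_id,food_id,amount_g``.
    """
    profiles = generate_population(config)
    pop_rows, recall_rows = [], []
    for i, profile in enumerate(profiles):
        group = assign_milk_group(profile, config, _child_rng(config.seed, i, 1))
        pop_rows.append(
            (
                profile.child_id,
                profile.age_months,
                profile.sex,
                profile.region,
                profile.ses,
                profile.mother_education,
                group,
            )
        )
        recall_rows.extend(
            generate_recall(profile, group, config, _child_rng(config.seed, i, 2))
        )
    population = pd.DataFrame(pop_rows, columns=list(POPULATION_HEADER))
    recall = pd.DataFrame(recall_rows, columns=["child_id", "food_id", "amount_g"])
    return population, recall


def focus_config(
    config: PopulationConfig,
    group: str,
    stratum: tuple[int, int],
    n_children: int,
    seed: int,
) -> PopulationConfig:
    """Variant of ``config`` that samples only one milk group and stratum.

    Useful for drawing a fresh sample of, say, condensed-milk consumers
    aged 12–35 months when validating a calibration: ages are restricted
    to the adequacy bands inside ``stratum`` (with their relative shares
    preserved) and the milk-group distribution is degenerate at ``group``.
    """
    bands = [b for b in ADEQUACY_STRATA if stratum[0] <= b[0] and b[1] <= stratum[1]]
    if not bands:
        raise ConfigError(f"stratum {stratum} covers no age band")
    total = sum(config.age_group_probs[b] for b in bands)
    age_probs = {
        b: (config.age_group_probs[b] / total if b in bands else 0.0)
        for b in ADEQUACY_STRATA
    }
    milk_probs = {
        b: {g: 1.0 if g == group else 0.0 for g in MILK_GROUPS} for b in ADEQUACY_STRATA
    }
    return dataclasses.replace(
        config,
        n_children=n_children,
        seed=seed,
        age_group_probs=age_probs,
        milk_group_probs=milk_probs,
    )


# ---------------------------------------------------------------------------
# Default configuration calibrated to the published IFCS 2014 summaries.
# ---------------------------------------------------------------------------

#: Share of children per age band (published survey marginals).
_AGE_SHARES = {(12, 23): 2529, (24, 35): 2701, (36, 47): 2847, (48, 60): 2943}

#: P(milk group | age band), published survey percentages.
_MILK_SHARES = {
    (12, 23): {"non_milk": 54.8, "ycm": 35.3, "condensed": 6.5, "cow": 3.4},
    (24, 35): {"non_milk": 45.8, "ycm": 33.4, "condensed": 13.5, "cow": 7.3},
    (36, 47): {"non_milk": 18.5, "ycm": 57.7, "condensed": 15.5, "cow": 8.3},
    (48, 60): {"non_milk": 56.8, "ycm": 21.9, "condensed": 13.3, "cow": 8.0},
}

#: Group sizes and group-conditional covariate percentages (published);
#: used to derive population marginals for SES and maternal education.
_GROUP_SIZES = (6283, 3138, 991, 608)
_SES_BY_GROUP = {
    "low": (69.6, 40.0, 60.9, 48.4),
    "middle": (27.2, 46.7, 34.8, 43.2),
    "high": (3.3, 14.4, 4.3, 8.4),
}
_EDU_BY_GROUP = {
    "none": (6.2, 3.1, 4.1, 3.1),
    "not_graduated_elementary": (12.4, 8.2, 9.2, 8.2),
    "elementary": (34.0, 25.5, 34.7, 33.7),
    "junior_high": (20.6, 20.4, 23.5, 21.4),
    "senior_high": (20.6, 30.6, 21.4, 25.5),
    "diploma": (3.1, 5.1, 4.1, 4.1),
    "university": (3.1, 7.1, 4.1, 4.1),
}


def _normalise(table: dict[str, float]) -> dict[str, float]:
    total = sum(table.values())
    return {k: v / total for k, v in table.items()}


def _marginal_from_groups(by_group: dict[str, tuple]) -> dict[str, float]:
    weights = np.array(_GROUP_SIZES, dtype=float)
    return _normalise(
        {k: float(np.dot(weights, v) / weights.sum()) for k, v in by_group.items()}
    )


def _uniform_bands(table: dict[str, float]) -> dict:
    return {band: dict(table) for band in ADEQUACY_STRATA}


#: Default background-diet parameters (median in the nutrient's unit,
#: log-sd, zero mass).  Field-plausible starting values for a one-day
#: recall in this population; the calibration step refines them.
_DEFAULT_INTAKE = {
    "energy_kcal": IntakeDist(700.0, 0.35),
    "protein_g": IntakeDist(20.0, 0.45),
    "vita_ug": IntakeDist(110.0, 1.10),
    "vitc_mg": IntakeDist(12.0, 1.00),
    "vitd_ug": IntakeDist(0.35, 1.20, zero_prob=0.30),
    "folate_ug": IntakeDist(25.0, 0.95),
    "calcium_mg": IntakeDist(190.0, 0.80),
    "iron_mg": IntakeDist(2.7, 0.70),
    "zinc_mg": IntakeDist(2.1, 0.55),
}


def default_config(n_children: int = 11020, seed: int = 0) -> PopulationConfig:
    """Configuration calibrated to the published survey marginals.

    Covariate and milk-group probabilities come from the published survey
    summaries; background-diet distributions are starting values meant to
    be refined by :func:`milkswap.calibrate.calibrate_to_baseline`.
    """
    older = {
        n: IntakeDist(d.median * 1.25, d.log_sd, d.zero_prob)
        for n, d in _DEFAULT_INTAKE.items()
    }
    return PopulationConfig(
        n_children=n_children,
        seed=seed,
        age_group_probs=_normalise({b: float(n) for b, n in _AGE_SHARES.items()}),
        covariate_probs={
            "sex": _uniform_bands({"boy": 0.517, "girl": 0.483}),
            "region": _uniform_bands({"urban": 0.429, "rural": 0.571}),
            "ses": _uniform_bands(_marginal_from_groups(_SES_BY_GROUP)),
            "mother_education": _uniform_bands(_marginal_from_groups(_EDU_BY_GROUP)),
        },
        milk_group_probs={b: _normalise(t) for b, t in _MILK_SHARES.items()},
        intake_model={
            n: {(12, 35): d, (36, 60): older[n]} for n, d in _DEFAULT_INTAKE.items()
        },
        milk_portion_model={
            "ycm": PortionDist(200.0, 0.40),
            "condensed": PortionDist(150.0, 0.40),
            "cow": PortionDist(200.0, 0.40),
        },
    )


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------

def _band_key(band: tuple[int, int]) -> str:
    return f"{band[0]}-{band[1]}"


def _parse_band(key: str) -> tuple[int, int]:
    lo, hi = key.split("-")
    return (int(lo), int(hi))


def config_to_dict(config: PopulationConfig) -> dict:
    return {
        "n_children": config.n_children,
        "seed": config.seed,
        "age_group_probs": {_band_key(b): p for b, p in config.age_group_probs.items()},
        "covariate_probs": {
            var: {_band_key(b): dict(t) for b, t in per_band.items()}
            for var, per_band in config.covariate_probs.items()
        },
        "milk_group_probs": {
            _band_key(b): dict(t) for b, t in config.milk_group_probs.items()
        },
        "intake_model": {
            n: {_band_key(s): dataclasses.asdict(d) for s, d in per.items()}
            for n, per in config.intake_model.items()
        },
        "milk_portion_model": {
            t: dataclasses.asdict(d) for t, d in config.milk_portion_model.items()
        },
        "milk_food_ids": dict(config.milk_food_ids),
    }


def config_from_dict(data: dict) -> PopulationConfig:
    return PopulationConfig(
        n_children=int(data["n_children"]),
        seed=int(data["seed"]),
        age_group_probs={_parse_band(k): float(v) for k, v in data["age_group_probs"].items()},
        covariate_probs={
            var: {_parse_band(k): {c: float(p) for c, p in t.items()} for k, t in per.items()}
            for var, per in data["covariate_probs"].items()
        },
        milk_group_probs={
            _parse_band(k): {g: float(p) for g, p in t.items()}
            for k, t in data["milk_group_probs"].items()
        },
        intake_model={
            n: {_parse_band(k): IntakeDist(**d) for k, d in per.items()}
            for n, per in data["intake_model"].items()
        },
        milk_portion_model={
            t: PortionDist(**d) for t, d in data["milk_portion_model"].items()
        },
        milk_food_ids=dict(data.get("milk_food_ids", {})) or None
        or {
            "condensed": "condensed_beverage",
            "cow": "cow_milk",
            "ycm_1plus": "ycm_1plus",
            "ycm_3plus": "ycm_3plus",
        },
    )


def save_config(config: PopulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def load_config(path) -> PopulationConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
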