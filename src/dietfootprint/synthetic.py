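"""Synthetic cohort, LCA database, product catalog and link table generators.

The real inputs to this kind of analysis — a prospective cohort's FFQ records
and a multi-farm LCA review — are access-restricted, so this module generates
stand-ins with the statistical structure the downstream analysis assumes:

* per-category LCA indicators drawn from right-skewed, zero-bounded laws
  (log-normal, parameterized by median and log-scale sigma), with stage-level
  CO2e split into enteric / fertilizer / other fractions and a fraction of
  records flagged organic;
* six diet groups whose age, gender, energy and food-group intake profiles
  follow the published descriptive table of the cohort this emulates,
  including near-zero "contamination" intakes of animal foods in the
  plant-based groups (self-assigned diet groups are imperfect);
* retail products with ground-truth compositions that sum to 100% and are
  non-increasing in label order, partially masked to exercise the
  composition estimator.

Everything is deterministic given (spec, seed).  Defaults are desk-scale
study conditions: 500 participants per group, ~25 LCA records per category,
category medians with a plant < animal ordering on every indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cohort import GROUP_ORDER, item_column
from .errors import ConfigurationError
from .lca import LCADatabase, LCA_COLUMNS
from .linkage import FFQItem, Ingredient, LinkTable, Product

_TOL = 1e-9


# ---------------------------------------------------------------------------
# LCA database generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoryLaw:
    """Generating law for one food category's LCA records.

    Medians are per kg at retail: total CO2e (kg), land (m^2), water (m^3),
    eutrophication (g PO4e), biodiversity (extinction units x1e-12).
    ``sigma`` is the log-scale spread shared by all indicators;
    ``stage_split`` divides each record's total CO2e into (enteric,
    fertilizer, other) fractions.
    """

    co2e_median: float
    land_m2: float
    water_m3: float
    eutrophication_gpo4e: float
    biodiversity: float
    sigma: float = 0.7
    stage_split: tuple[float, float, float] = (0.0, 0.4, 0.6)
    n_records: int = 25
    organic_fraction: float = 0.2

    def __post_init__(self):
        for name in ("co2e_median", "land_m2", "water_m3", "eutrophication_gpo4e", "biodiversity"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"CategoryLaw.{name} must be >= 0")
        if self.sigma < 0:
            raise ConfigurationError("CategoryLaw.sigma must be >= 0")
        if abs(sum(self.stage_split) - 1.0) > _TOL or min(self.stage_split) < 0:
            raise ConfigurationError("CategoryLaw.stage_split fractions must be >= 0 and sum to 1")
        if self.n_records < 1:
            raise ConfigurationError("CategoryLaw.n_records must be >= 1")
        if not 0.0 <= self.organic_fraction <= 1.0:
            raise ConfigurationError("CategoryLaw.organic_fraction must be in [0, 1]")


@dataclass(frozen=True)
class LCAGeneratorSpec:
    """Category id -> :class:`CategoryLaw`."""

    categories: dict

    def __post_init__(self):
        if not self.categories:
            raise ConfigurationError("LCAGeneratorSpec.categories must be non-empty")
        for cat, law in self.categories.items():
            if not isinstance(law, CategoryLaw):
                raise ConfigurationError(f"LCAGeneratorSpec.categories[{cat!r}] is not a CategoryLaw")


def default_lca_spec(sigma_scale: float = 1.0, n_records: int = 25) -> LCAGeneratorSpec:
    """Desk-scale default database: 11 categories, plant < animal on every indicator.

    Medians are realistic per-kg magnitudes for each food group (e.g. tens of
    kg CO2e and hundreds of m^2 per kg for beef versus ~1 kg CO2e and a few
    m^2 for grains); sigmas reflect the larger sourcing spread of animal
    foods.  ``sigma_scale`` multiplies all sigmas (0 gives a point-mass
    database).
    """
    def law(co2e, split, land, water, eutro, bio, sigma):
        return CategoryLaw(co2e_median=co2e, stage_split=split, land_m2=land, water_m3=water,
                           eutrophication_gpo4e=eutro, biodiversity=bio,
                           sigma=sigma * sigma_scale, n_records=n_records)

    cats = {
        #                co2e   (ent,  fert, other) land  water  eutro  bio   sigma
        "wheat_grains":  law(1.4, (0.00, 0.45, 0.55), 3.0, 0.50, 5.0, 0.6, 0.5),
        "potatoes":      law(0.5, (0.00, 0.40, 0.60), 0.9, 0.06, 4.0, 0.15, 0.5),
        "legumes":       law(1.0, (0.00, 0.50, 0.50), 7.0, 0.30, 7.0, 1.0, 0.6),
        "fruit_veg":     law(0.7, (0.00, 0.40, 0.60), 0.9, 0.20, 3.5, 0.4, 0.6),
        "beef":          law(45.0, (0.45, 0.15, 0.40), 150.0, 4.00, 300.0, 80.0, 1.0),
        "lamb":          law(24.0, (0.50, 0.12, 0.38), 120.0, 3.00, 100.0, 40.0, 0.9),
        "pork_poultry":  law(7.0, (0.05, 0.25, 0.70), 12.0, 0.60, 45.0, 5.0, 0.7),
        "fish_farmed":   law(6.0, (0.20, 0.15, 0.65), 6.0, 2.00, 100.0, 4.0, 0.9),
        "dairy_milk":    law(2.0, (0.40, 0.20, 0.40), 3.0, 0.30, 10.0, 1.5, 0.7),
        "cheese":        law(18.0, (0.40, 0.20, 0.40), 25.0, 2.50, 90.0, 10.0, 0.8),
        "yogurt":        law(3.0, (0.35, 0.20, 0.45), 4.0, 0.40, 12.0, 2.0, 0.7),
    }
    return LCAGeneratorSpec(cats)


def gen_lca_database(spec: LCAGeneratorSpec, seed: int) -> LCADatabase:
    """Generate an LCA database from per-category log-normal laws.

    Each indicator of each record is ``median * exp(sigma * Z)`` with
    independent standard-normal ``Z`` (right-skewed, zero-bounded, empirical
    median converging to the spec median); stage CO2e is the record's total
    times the fixed stage fractions.  Deterministic given (spec, seed).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for cat, law in spec.categories.items():
        n = law.n_records
        z = rng.standard_normal((n, 5))
        medians = np.array([law.co2e_median, law.land_m2, law.water_m3,
                            law.eutrophication_gpo4e, law.biodiversity])
        vals = medians * np.exp(law.sigma * z)
        n_org = int(round(law.organic_fraction * n))
        organic = np.zeros(n, dtype=bool)
        organic[rng.permutation(n)[:n_org]] = True
        ent, fert, other = law.stage_split
        for i in range(n):
            rows.append({
                "category": cat,
                "enteric_co2e": vals[i, 0] * ent,
                "fertilizer_co2e": vals[i, 0] * fert,
                "other_co2e": vals[i, 0] * other,
                "land_m2": vals[i, 1],
                "water_m3": vals[i, 2],
                "eutrophication_gpo4e": vals[i, 3],
                "biodiversity": vals[i, 4],
                "organic": bool(organic[i]),
                "source_id": f"{cat}-{i:03d}",
            })
    return LCADatabase(pd.DataFrame(rows, columns=LCA_COLUMNS))


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

#: FFQ item intake profiles per diet group: (mean, sd) grams/day; mean 0 marks
#: a should-be-nil intake, subject to contamination.  Values follow the
#: published cohort's descriptive table (fruit/veg portions converted at
#: 80 g per portion).
_TABLE_PROFILES = {
    #            vegan        vegetarian   fish_eater   low_meat     medium_meat  high_meat
    "grains":   [(251, 117), (235, 103), (231, 105), (204, 103), (189, 95),  (190, 94)],
    "potatoes": [(81.6, 67.1), (76.6, 52.1), (72.6, 51.0), (71.6, 49.1), (89.3, 52.2), (107, 58.9)],
    "beans":    [(60.2, 48.9), (43.6, 40.2), (37.1, 33.4), (25.2, 28.2), (21.6, 24.2), (23.4, 25.2)],
    "fruit_veg": [(696, 448), (568, 312), (584, 312), (552, 320), (504, 256), (488, 256)],
    "meat":     [(0, 0), (0, 0), (0, 0), (28.3, 12.9), (74.0, 14.0), (140, 39.7)],
    "fish":     [(0, 0), (0, 0), (38.9, 33.6), (38.6, 29.5), (43.7, 28.6), (44.2, 29.7)],
    "cheese":   [(0, 0), (30.0, 25.2), (27.3, 24.0), (22.8, 20.5), (19.8, 18.0), (19.3, 17.1)],
    "milk":     [(0, 0), (260, 203), (273, 190), (300, 186), (331, 182), (349, 187)],
    "yogurt":   [(0, 0), (33.7, 40.9), (37.6, 42.5), (38.1, 43.5), (34.4, 39.3), (31.8, 39.2)],
}

_DEMOGRAPHICS = {
    #  group          age mean/sd  p(woman)  energy mean/sd kcal
    "vegan":        ((37.3, 13.1), 0.634, (1754, 556)),
    "vegetarian":   ((38.6, 12.7), 0.769, (1879, 530)),
    "fish_eater":   ((41.8, 12.9), 0.822, (1897, 528)),
    "low_meat":     ((47.5, 13.3), 0.800, (1816, 510)),
    "medium_meat":  ((49.8, 12.6), 0.778, (1940, 502)),
    "high_meat":    ((49.7, 12.3), 0.721, (2222, 530)),
}

_ANSWERS = {
    "vegan": ("No", "No", "No", "No"),
    "vegetarian": ("No", "No", "Yes", "Yes"),
    "fish_eater": ("No", "Yes", "Yes", "Yes"),
    "low_meat": ("Yes", "Yes", "Yes", "Yes"),
    "medium_meat": ("Yes", "Yes", "Yes", "Yes"),
    "high_meat": ("Yes", "Yes", "Yes", "Yes"),
}

#: Meat-gram bands enforced for the meat-eating groups (consistent with the
#: 50/100 g/day classification cut-offs).
_MEAT_BANDS = {"low_meat": (0.5, 50.0), "medium_meat": (50.0, 100.0), "high_meat": (100.0, np.inf)}


@dataclass(frozen=True)
class GroupProfile:
    """Generating parameters for one diet group."""

    n: int
    age_mean: float
    age_sd: float
    prop_women: float
    energy_mean: float
    energy_sd: float
    intakes: dict  # item id -> (mean, sd) g/day; mean 0 marks should-be-nil

    def __post_init__(self):
        if self.n < 0:
            raise ConfigurationError("GroupProfile.n must be >= 0")
        if not 0.0 <= self.prop_women <= 1.0:
            raise ConfigurationError("GroupProfile.prop_women must be in [0, 1]")
        if self.energy_mean <= 0 or self.energy_sd < 0 or self.age_sd < 0:
            raise ConfigurationError("GroupProfile energy/age parameters out of range")
        for item, (m, s) in self.intakes.items():
            if m < 0 or s < 0:
                raise ConfigurationError(f"GroupProfile intake for {item!r} must be >= 0")


@dataclass(frozen=True)
class CohortGeneratorSpec:
    """Six diet-group profiles plus the contamination model for nil intakes."""

    groups: dict
    contamination_prob: float = 0.05
    contamination_mean_g: float = 4.0
    meat_cutoffs: tuple[float, float] = (50.0, 100.0)

    def __post_init__(self):
        unknown = [g for g in self.groups if g not in GROUP_ORDER]
        if unknown:
            raise ConfigurationError(f"unknown diet groups in spec: {unknown}")
        for g, p in self.groups.items():
            if not isinstance(p, GroupProfile):
                raise ConfigurationError(f"CohortGeneratorSpec.groups[{g!r}] is not a GroupProfile")
        if not 0.0 <= self.contamination_prob <= 1.0:
            raise ConfigurationError("contamination_prob must be in [0, 1]")
        if self.contamination_mean_g < 0:
            raise ConfigurationError("contamination_mean_g must be >= 0")

    @property
    def item_ids(self) -> list[str]:
        first = next(iter(self.groups.values()))
        return list(first.intakes)


def default_cohort_spec(n_per_group: int = 500, contamination_prob: float = 0.05,
                        contamination_mean_g: float = 4.0) -> CohortGeneratorSpec:
    """Default cohort conditions: published group profiles, equal group sizes."""
    groups = {}
    for gi, g in enumerate(GROUP_ORDER):
        (age_m, age_s), p_women, (en_m, en_s) = _DEMOGRAPHICS[g]
        intakes = {item: tuple(profiles[gi]) for item, profiles in _TABLE_PROFILES.items()}
        groups[g] = GroupProfile(n=n_per_group, age_mean=age_m, age_sd=age_s,
                                 prop_women=p_women, energy_mean=en_m, energy_sd=en_s,
                                 intakes=intakes)
    return CohortGeneratorSpec(groups, contamination_prob=contamination_prob,
                               contamination_mean_g=contamination_mean_g)


def _gamma_draw(rng, mean, sd, size):
    """Right-skewed non-negative intake draw matching a (mean, sd) pair."""
    if mean <= 0:
        return np.zeros(size)
    if sd == 0:
        return np.full(size, mean)
    shape = (mean / sd) ** 2
    return rng.gamma(shape, scale=sd * sd / mean, size=size)


def _banded_draw(rng, mean, sd, lo, hi, size):
    """Gamma draw constrained to [lo, hi) by rejection, clipping stragglers."""
    out = np.empty(size)
    todo = np.arange(size)
    for _ in range(200):
        cand = _gamma_draw(rng, mean, sd, len(todo))
        ok = (cand >= lo) & (cand < hi)
        out[todo[ok]] = cand[ok]
        todo = todo[~ok]
        if todo.size == 0:
            break
    if todo.size:
        out[todo] = np.clip(_gamma_draw(rng, mean, sd, len(todo)), lo,
                            hi if np.isfinite(hi) else lo + 10 * max(sd, 1.0))
    return out


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    todo = np.arange(size)
    for _ in range(200):
        cand = rng.normal(mean, sd, size=len(todo))
        ok = (cand >= lo) & (cand < hi)
        out[todo[ok]] = cand[ok]
        todo = todo[~ok]
        if todo.size == 0:
            break
    if todo.size:
        out[todo] = np.clip(rng.normal(mean, sd, size=len(todo)), lo, np.nextafter(hi, lo))
    return out


def gen_cohort(spec: CohortGeneratorSpec, seed: int) -> pd.DataFrame:
    """Generate a cohort table, one row per participant.

    Screening answers are group-consistent (all four "No" for vegans, ...);
    meat grams for the meat-eating groups are drawn within their
    classification band; should-be-nil intakes receive small gamma-distributed
    contamination with the stated probability (self-assigned groups are not
    perfectly clean).  Ages are truncated to [20, 80); energy is positive.
    Deterministic given (spec, seed).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    item_ids = spec.item_ids
    frames = []
    start = 0
    for g in GROUP_ORDER:
        if g not in spec.groups:
            continue
        prof = spec.groups[g]
        n = prof.n
        if n == 0:
            continue
        q = _ANSWERS[g]
        df = pd.DataFrame({
            "id": [f"P{start + i:06d}" for i in range(n)],
            "age": _truncated_normal(rng, prof.age_mean, prof.age_sd, 20.0, 80.0, n),
            "gender": np.where(rng.random(n) < prof.prop_women, "F", "M"),
            "q_meat": q[0], "q_fish": q[1], "q_eggs": q[2], "q_dairy": q[3],
            "energy_kcal": np.maximum(_gamma_draw(rng, prof.energy_mean, prof.energy_sd, n), 500.0),
            "ffq_completion": 1.0,
            "diet_group_true": g,
        })
        for item in item_ids:
            mean, sd = prof.intakes.get(item, (0.0, 0.0))
            if item == "meat" and g in _MEAT_BANDS:
                lo, hi = _MEAT_BANDS[g]
                vals = _banded_draw(rng, mean, sd, lo, hi, n)
            elif mean > 0:
                vals = _gamma_draw(rng, mean, sd, n)
            else:  # should-be-nil: Bernoulli contamination with gamma magnitude
                hit = rng.random(n) < spec.contamination_prob
                vals = np.where(hit, rng.gamma(1.0, spec.contamination_mean_g, size=n), 0.0)
            df[item_column(item)] = vals
        frames.append(df)
        start += n
    if not frames:
        raise ConfigurationError("cohort spec has no participants")
    return pd.concat(frames, ignore_index=True)


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Product catalog generator
# ---------------------------------------------------------------------------

def gen_product_catalog(n_products: int, known_fraction: float, seed: int,
                        categories=None, max_ingredients: int = 6):
    """Products with ground-truth compositions, partially masked.

    Ground truth per product: a Dirichlet draw sorted in descending order
    (sums to 100%, non-increasing in label order).  The emitted product keeps
    each true percent declared independently with probability
    ``known_fraction`` and masks the rest.  Returns
    ``(products, ground_truth)`` with ``ground_truth[product_id]`` the true
    percent array.
    """
    if not 0.0 <= known_fraction <= 1.0:
        raise ConfigurationError("known_fraction must be in [0, 1]")
    if n_products < 0:
        raise ConfigurationError("n_products must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    categories = list(categories) if categories is not None else list(default_lca_spec().categories)
    products, truth = [], {}
    for p in range(n_products):
        k = int(rng.integers(2, max_ingredients + 1))
        pct = np.sort(rng.dirichlet(np.ones(k)))[::-1] * 100.0
        keep = rng.random(k) < known_fraction
        ingredients = []
        for i in range(k):
            cats = rng.choice(len(categories), size=2, replace=False)
            if rng.random() < 0.3:
                share = float(rng.uniform(0.3, 0.7))
                links = [(categories[cats[0]], share), (categories[cats[1]], 1.0 - share)]
            else:
                links = [(categories[cats[0]], 1.0)]
            ingredients.append(Ingredient(
                name=f"ing_{p}_{i}",
                links=links,
                declared_percent=float(pct[i]) if keep[i] else None,
                organic=bool(rng.random() < 0.1),
            ))
        pid = f"SP{p:04d}"
        products.append(Product(id=pid, ingredients=ingredients))
        truth[pid] = pct
    return products, truth


# ---------------------------------------------------------------------------
# Link table
# ---------------------------------------------------------------------------

def default_link_table() -> LinkTable:
    """Default FFQ-item link table matching the default cohort and database.

    Eight items link directly to single categories; the meat item goes
    through three multi-ingredient retail dishes (beef, lamb, poultry based)
    whose footprints are averaged, exercising composition estimation and
    multi-category draws.
    """
    dishes = [
        Product("beef_dish", [
            Ingredient("beef", [("beef", 1.0)], declared_percent=60.0),
            Ingredient("wheat", [("wheat_grains", 1.0)]),
            Ingredient("vegetables", [("fruit_veg", 1.0)]),
        ]),
        Product("lamb_dish", [
            Ingredient("lamb", [("lamb", 1.0)], declared_percent=65.0),
            Ingredient("wheat", [("wheat_grains", 1.0)]),
            Ingredient("vegetables", [("fruit_veg", 1.0)]),
        ]),
        Product("poultry_dish", [
            Ingredient("poultry", [("pork_poultry", 1.0)], declared_percent=70.0),
            Ingredient("wheat", [("wheat_grains", 1.0)]),
            Ingredient("vegetables", [("fruit_veg", 1.0)]),
        ]),
    ]
    items = [
        FFQItem("grains", name="Grains, bread, cereal, rice and pasta", category="wheat_grains"),
        FFQItem("potatoes", name="Potatoes", category="potatoes"),
        FFQItem("beans", name="Beans and pulses", category="legumes"),
        FFQItem("fruit_veg", name="Fruit and vegetables", category="fruit_veg"),
        FFQItem("meat", name="Meat and meat products", products=["beef_dish", "lamb_dish", "poultry_dish"],
                is_meat=True),
        FFQItem("fish", name="Fish and fish products", category="fish_farmed"),
        FFQItem("cheese", name="Cheese", category="cheese"),
        FFQItem("milk", name="Animal milk", category="dairy_milk"),
        FFQItem("yogurt", name="Yogurt", category="yogurt"),
    ]
    return LinkTable(items, dishes)


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def lca_spec_from_yaml(path) -> LCAGeneratorSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    cats = {name: CategoryLaw(**{**params, "stage_split": tuple(params.get("stage_split", (0, 0.4, 0.6)))})
            for name, params in doc["categories"].items()}
    return LCAGeneratorSpec(cats)


def cohort_spec_from_yaml(path) -> CohortGeneratorSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    groups = {
        g: GroupProfile(
            n=int(p["n"]), age_mean=p["age_mean"], age_sd=p["age_sd"],
            prop_women=p["prop_women"], energy_mean=p["energy_mean"], energy_sd=p["energy_sd"],
            intakes={k: tuple(v) for k, v in p["intakes"].items()},
        )
        for g, p in doc["groups"].items()
    }
    return CohortGeneratorSpec(
        groups,
        contamination_prob=doc.get("contamination_prob", 0.05),
        contamination_mean_g=doc.get("contamination_mean_g", 4.0),
    )
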