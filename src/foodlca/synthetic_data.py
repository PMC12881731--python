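"""Synthetic input bundles with the statistical structure of the real
sources.

The generator emulates the shape of the external data the pipeline
consumes — a cultivation-impact table with partial country coverage and
Rest-of-World fallback rows, country centroids grouped into continents
with nearest ports and a detoured sea-distance matrix, log-uniform
electricity emission factors, crop water-demand calendars with contiguous
growing seasons, and a food catalog mixing raw produce, frozen/canned/
dried variants, animal products and grain products — so every pipeline
stage is exercised without any external download. Magnitudes are
literature-plausible (see docs/methods.md) but make no claim to match any
specific database.
"""
from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd

from .geography import great_circle_km
from .model import (
    CookingClass,
    CookingEnergyTable,
    Country,
    CropCalendar,
    CultivationImpactTable,
    EmissionFactorSet,
    FoodCategory,
    FoodItem,
    InputBundle,
    NutrientProfile,
    PortNetwork,
    ProcessRecipeTable,
    ProcessingType,
    RetentionTable,
    StorageClass,
    StorageParams,
    TempClass,
    TransportMode,
)
from .nutrients import complete_profiles

NUTRIENT_COLS = ["energy_kj", "protein_g", "fat_g", "carb_g", "fiber_g", "vitamin_c_mg"]

# (crop, air_perishable, cooked, variants); the banana-like entry is the
# tropical fruit explicitly excluded from air freight.
_CROP_TEMPLATES: list[tuple[str, bool, bool, tuple[str, ...]]] = [
    ("apricot", False, False, ("fresh", "frozen", "canned", "dried")),
    ("strawberry", True, False, ("fresh", "frozen")),
    ("spinach", True, True, ("fresh", "frozen")),
    ("mango", True, False, ("fresh", "dried")),
    ("banana", False, False, ("fresh", "dried")),
    ("corn", False, True, ("fresh", "canned", "frozen")),
    ("tomato", False, True, ("fresh", "canned")),
    ("asparagus", True, True, ("fresh", "canned")),
    ("potato", False, True, ("fresh", "frozen", "dried")),
    ("pea", False, True, ("fresh", "frozen", "canned")),
    ("apple", False, False, ("fresh", "dried")),
    ("carrot", False, True, ("fresh", "frozen")),
]

_VARIANT_PROCESS = {
    "frozen": ProcessingType.FREEZING,
    "canned": ProcessingType.GENERAL_CANNING,
    "dried": ProcessingType.DEHYDRATING,
}

# cultivation-impact medians, kgCO2eq per g of product
_CATEGORY_MEDIAN = {
    FoodCategory.FRESH_PRODUCE: 4e-4,
    FoodCategory.MEAT: 1.2e-2,
    FoodCategory.FISH_WILD: 3e-3,
    FoodCategory.FISH_AQUACULTURE: 5e-3,
    FoodCategory.DAIRY: 4e-3,
    FoodCategory.GRAIN: 1e-3,
    FoodCategory.LEGUME: 9e-4,
    FoodCategory.EGG: 3.5e-3,
    FoodCategory.MEAT_SUBSTITUTE: 2.5e-3,
    FoodCategory.OTHER: 1e-3,
}


def _iso_codes(n: int) -> list[str]:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    codes = ["".join(p) for p in itertools.product(letters, repeat=2)]
    return codes[:n]


def _crop_food(crop: str, variant: str, air: bool, cooked: bool, suffix: str) -> FoodItem:
    name = crop.capitalize() + suffix
    if variant == "fresh":
        return FoodItem(
            id=f"{crop}{suffix}_fresh",
            display_name=f"{name}, fresh",
            base_crop=crop + suffix,
            category=FoodCategory.FRESH_PRODUCE,
            processing_type=ProcessingType.NONE,
            processing_builtin=False,
            transport_temp_class=TempClass.REFRIGERATED,
            air_perishable=air,
            cooking_class=CookingClass.STANDARD if cooked else CookingClass.NONE,
            storage_class=StorageClass.REFRIGERATED_DISPLAY,
        )
    process = _VARIANT_PROCESS[variant]
    frozen = process is ProcessingType.FREEZING
    return FoodItem(
        id=f"{crop}{suffix}_{variant}",
        display_name=f"{name}, {variant}",
        base_crop=crop + suffix,
        category=FoodCategory.FRESH_PRODUCE,
        processing_type=process,
        processing_builtin=False,
        transport_temp_class=TempClass.FROZEN if frozen else TempClass.AMBIENT,
        air_perishable=False,
        cooking_class=CookingClass.STANDARD if cooked else CookingClass.NONE,
        storage_class=StorageClass.FROZEN_STORAGE if frozen else StorageClass.NONE,
    )


def _staple_foods() -> list[FoodItem]:
    def item(fid, name, category, process=ProcessingType.NONE, builtin=False,
             temp=TempClass.AMBIENT, cooking=CookingClass.NONE,
             storage=StorageClass.NONE, crop=""):
        return FoodItem(
            id=fid, display_name=name, base_crop=crop or fid, category=category,
            processing_type=process, processing_builtin=builtin,
            transport_temp_class=temp, air_perishable=False,
            cooking_class=cooking, storage_class=storage,
        )

    return [
        item("beef", "Beef", FoodCategory.MEAT, temp=TempClass.FROZEN,
             cooking=CookingClass.STANDARD, storage=StorageClass.REFRIGERATED_DISPLAY),
        item("chicken", "Chicken", FoodCategory.MEAT, temp=TempClass.FROZEN,
             cooking=CookingClass.STANDARD, storage=StorageClass.REFRIGERATED_DISPLAY),
        item("cod", "Cod, wild", FoodCategory.FISH_WILD, temp=TempClass.FROZEN,
             cooking=CookingClass.STANDARD, storage=StorageClass.REFRIGERATED_DISPLAY),
        item("salmon", "Salmon, farmed", FoodCategory.FISH_AQUACULTURE,
             temp=TempClass.FROZEN, cooking=CookingClass.STANDARD,
             storage=StorageClass.REFRIGERATED_DISPLAY),
        item("tuna_canned", "Tuna, canned", FoodCategory.FISH_WILD,
             process=ProcessingType.LARGE_FISH_CANNING, crop="tuna"),
        item("sardines_canned", "Sardines, canned", FoodCategory.FISH_WILD,
             process=ProcessingType.SMALL_FISH_CANNING, crop="sardine"),
        item("milk", "Milk", FoodCategory.DAIRY, builtin=True,
             temp=TempClass.REFRIGERATED, storage=StorageClass.REFRIGERATED_DISPLAY),
        item("cheese", "Cheese", FoodCategory.DAIRY, builtin=True,
             temp=TempClass.REFRIGERATED, storage=StorageClass.REFRIGERATED_DISPLAY),
        item("eggs", "Eggs", FoodCategory.EGG, temp=TempClass.REFRIGERATED,
             cooking=CookingClass.STANDARD, storage=StorageClass.REFRIGERATED_DISPLAY),
        item("tofu", "Tofu", FoodCategory.MEAT_SUBSTITUTE, temp=TempClass.REFRIGERATED,
             cooking=CookingClass.STANDARD, storage=StorageClass.REFRIGERATED_DISPLAY),
        item("beans_dried", "Beans, dried", FoodCategory.LEGUME,
             process=ProcessingType.DEHYDRATING, cooking=CookingClass.DRIED_BEANS,
             crop="bean"),
        item("rice", "Rice", FoodCategory.GRAIN, cooking=CookingClass.STANDARD,
             crop="rice"),
        item("bread", "Bread", FoodCategory.GRAIN, process=ProcessingType.BREAD,
             crop="wheat"),
        item("pasta", "Pasta", FoodCategory.GRAIN, process=ProcessingType.PASTA,
             cooking=CookingClass.STANDARD, crop="wheat"),
        item("cereal", "Breakfast cereal", FoodCategory.GRAIN,
             process=ProcessingType.BREAKFAST_CEREAL, crop="wheat"),
    ]


def _build_catalog(n_foods: int) -> list[FoodItem]:
    foods = _staple_foods()
    clone = 0
    while len(foods) < n_foods:
        suffix = "" if clone == 0 else str(clone + 1)
        for crop, air, cooked, variants in _CROP_TEMPLATES:
            for v in variants:
                if len(foods) >= n_foods:
                    break
                foods.append(_crop_food(crop, v, air, cooked, suffix))
            if len(foods) >= n_foods:
                break
        clone += 1
    return foods[:n_foods]


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(median * math.exp(rng.normal(0.0, sigma)))


def generate_bundle(
    seed: int,
    n_countries: int = 12,
    n_continents: int = 3,
    n_foods: int = 40,
    coverage: float = 0.7,
) -> InputBundle:
    """Generate a complete, internally consistent input bundle.

    ``coverage`` is the fraction of each food's producing countries that
    get a country-specific cultivation row; the rest fall back to the
    Rest-of-World row (the geometric mean of the specific rows).
    """
    if n_continents < 2:
        raise ValueError("need at least 2 continents")
    if n_countries < n_continents:
        raise ValueError("need at least one country per continent")
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must be in [0, 1]")
    if n_foods < 20:
        raise ValueError("catalog needs at least 20 foods to cover all processes")
    rng = np.random.default_rng(seed)

    # --- geography: continents as disjoint longitude bands -------------
    band = 360.0 / n_continents
    continents = [f"Continent_{chr(65 + i)}" for i in range(n_continents)]
    iso = _iso_codes(n_countries)
    countries: dict[str, Country] = {}
    ports: dict[str, tuple[float, float]] = {}
    port_continent: dict[str, str] = {}
    for ci, cont in enumerate(continents):
        lo = -180.0 + ci * band + 3.0
        hi = -180.0 + (ci + 1) * band - 3.0
        n_ports = 2 if n_countries // n_continents > 3 else 1
        for k in range(n_ports):
            pid = f"P{ci}{k}"
            ports[pid] = (float(rng.uniform(-45, 55)), float(rng.uniform(lo, hi)))
            port_continent[pid] = cont
    for i, code in enumerate(iso):
        cont = continents[i % n_continents]
        ci = continents.index(cont)
        lo = -180.0 + ci * band + 3.0
        hi = -180.0 + (ci + 1) * band - 3.0
        lat = float(rng.uniform(-50, 60))
        lon = float(rng.uniform(lo, hi))
        nearest = min(ports, key=lambda p: great_circle_km((lat, lon), ports[p]))
        countries[code] = Country(code, cont, lat, lon, nearest)

    pids = sorted(ports)
    sea = pd.DataFrame(0.0, index=pids, columns=pids)
    sea.index.name = "port_id"
    for i, pa in enumerate(pids):
        for pb in pids[i + 1:]:
            gc = great_circle_km(ports[pa], ports[pb])
            d = gc * float(rng.uniform(1.05, 1.6))
            sea.loc[pa, pb] = d
            sea.loc[pb, pa] = d
    network = PortNetwork(ports=ports, sea_km=sea)

    # --- emission factors ---------------------------------------------
    elec = {
        code: float(np.exp(rng.uniform(math.log(0.02), math.log(1.2))))
        for code in iso
    }
    elec["GLO"] = float(np.exp(np.mean(np.log(list(elec.values())))))

    mode_base = {
        TransportMode.ROAD: _lognormal(rng, 1.0e-7, 0.25),
        TransportMode.SEA: _lognormal(rng, 1.2e-8, 0.25),
        TransportMode.AIR: _lognormal(rng, 6.0e-7, 0.25),
    }
    transport = {}
    for mode, base in mode_base.items():
        refrig_mult = 1.0 + float(rng.uniform(0.10, 0.25))
        frozen_mult = refrig_mult + float(rng.uniform(0.10, 0.30))
        transport[(mode, TempClass.AMBIENT)] = base
        transport[(mode, TempClass.REFRIGERATED)] = base * refrig_mult
        transport[(mode, TempClass.FROZEN)] = base * frozen_mult
    efs = EmissionFactorSet(
        elec=elec, transport=transport, steam_global=_lognormal(rng, 0.09, 0.2)
    )

    # --- catalog and crop calendars -----------------------------------
    foods = _build_catalog(n_foods)
    crops = sorted({f.base_crop for f in foods if f.category is FoodCategory.FRESH_PRODUCE})
    crops += sorted({f.base_crop for f in foods if f.category in
                     (FoodCategory.GRAIN, FoodCategory.LEGUME) and f.base_crop in
                     ("wheat", "rice", "bean")})
    demand: dict[tuple[str, str], np.ndarray] = {}
    for crop in crops:
        n_prod = int(rng.integers(2, max(3, n_countries // 2) + 1))
        producers = rng.choice(iso, size=min(n_prod, n_countries), replace=False)
        for ctry in producers:
            vec = np.zeros(12)
            for _run in range(int(rng.integers(1, 3))):
                length = int(rng.integers(2, 6))
                start = int(rng.integers(0, 12))
                for j in range(length):
                    vec[(start + j) % 12] = float(rng.uniform(0.5, 2.0))
            demand[(crop, str(ctry))] = vec
    calendar = CropCalendar(demand=demand)

    # --- cultivation impacts with partial coverage --------------------
    entries: dict[tuple[str, str], float] = {}
    fallback: dict[str, float] = {}
    crop_set = {cr for (cr, _c) in demand}
    food_median = {
        f.id: _lognormal(rng, _CATEGORY_MEDIAN[f.category], 0.3) for f in foods
    }
    for f in foods:
        if f.base_crop in crop_set:
            producers = sorted({c for (cr, c) in demand if cr == f.base_crop})
        else:
            producers = list(iso)
        k = int(round(coverage * len(producers)))
        covered = sorted(rng.choice(producers, size=k, replace=False)) if k else []
        vals = []
        for ctry in covered:
            v = _lognormal(rng, food_median[f.id], 0.4)
            entries[(f.id, str(ctry))] = v
            vals.append(v)
        fallback[f.id] = (
            float(np.exp(np.mean(np.log(vals)))) if vals else food_median[f.id]
        )
    cultivation = CultivationImpactTable(entries=entries, row_fallback=fallback)

    # --- process, cooking and storage energies ------------------------
    recipe_medians = {
        ProcessingType.BREAD: (3.0e-4, 1.0e-3),
        ProcessingType.PASTA: (2.5e-4, 1.2e-3),
        ProcessingType.BREAKFAST_CEREAL: (4.0e-4, 1.5e-3),
        ProcessingType.LARGE_FISH_CANNING: (3.0e-4, 1.2e-3),
        ProcessingType.SMALL_FISH_CANNING: (3.5e-4, 1.4e-3),
        ProcessingType.GENERAL_CANNING: (2.0e-4, 1.0e-3),
        ProcessingType.FREEZING: (5.0e-4, 0.0),
        ProcessingType.DEHYDRATING: (8.0e-4, 2.0e-3),
    }
    recipes = ProcessRecipeTable(
        recipes={
            p: (_lognormal(rng, e, 0.3), _lognormal(rng, s, 0.3) if s else 0.0)
            for p, (e, s) in recipe_medians.items()
        }
    )
    standard = _lognormal(rng, 8.0e-4, 0.25)
    cooking = CookingEnergyTable(
        energy_kwh_per_g={
            CookingClass.STANDARD: standard,
            CookingClass.DRIED_BEANS: standard * float(rng.uniform(2.0, 3.5)),
        }
    )
    storage = StorageParams(
        frozen_kwh_per_g_per_month=_lognormal(rng, 6.0e-5, 0.25),
        frozen_storage_months=10.0,
        display_kwh_per_g={
            StorageClass.FROZEN_STORAGE: _lognormal(rng, 1.2e-4, 0.25),
            StorageClass.REFRIGERATED_DISPLAY: _lognormal(rng, 5.0e-5, 0.25),
        },
    )

    # --- nutrients -----------------------------------------------------
    nutrient_median = {
        "energy_kj": 4.0, "protein_g": 0.05, "fat_g": 0.04,
        "carb_g": 0.15, "fiber_g": 0.02, "vitamin_c_mg": 0.1,
    }
    raw_values: dict[str, np.ndarray] = {}
    derived: dict[str, tuple[str, ProcessingType]] = {}
    raw_of_crop: dict[str, str] = {}
    for f in foods:
        if f.processing_type is ProcessingType.NONE:
            raw_of_crop.setdefault(f.base_crop, f.id)
    for f in foods:
        if f.processing_type is ProcessingType.NONE or f.base_crop not in raw_of_crop:
            raw_values[f.id] = np.array(
                [_lognormal(rng, nutrient_median[n], 0.4) for n in NUTRIENT_COLS]
            )
        else:
            derived[f.id] = (raw_of_crop[f.base_crop], f.processing_type)
    retention_ranges = {
        ProcessingType.GENERAL_CANNING: (0.40, 0.70),
        ProcessingType.LARGE_FISH_CANNING: (0.50, 0.80),
        ProcessingType.SMALL_FISH_CANNING: (0.50, 0.80),
        ProcessingType.FREEZING: (0.75, 0.95),
        ProcessingType.DEHYDRATING: (0.45, 0.80),
        ProcessingType.BREAD: (0.70, 0.95),
        ProcessingType.PASTA: (0.70, 0.95),
        ProcessingType.BREAKFAST_CEREAL: (0.60, 0.90),
    }
    factors = {}
    for p, (lo, hi) in retention_ranges.items():
        factors[(p, "vitamin_c_mg")] = float(rng.uniform(lo, hi))
        factors[(p, "fiber_g")] = float(rng.uniform(0.85, 1.0))
    retention = RetentionTable(factors=factors)
    nutrients = complete_profiles(raw_values, derived, retention, NUTRIENT_COLS)

    bundle = InputBundle(
        foods={f.id: f for f in foods},
        countries=countries,
        ports=network,
        efs=efs,
        cultivation=cultivation,
        recipes=recipes,
        cooking=cooking,
        storage=storage,
        calendar=calendar,
        nutrients=nutrients,
        retention=retention,
        consumers=list(iso),
        road_uplift=0.20,
    )
    bundle.validate()
    return bundle


def table1_fixture() -> InputBundle:
    """A minimal two-country, same-continent bundle with fresh and frozen
    apricots, shaped like the worked example of apricots consumed in Spain
    in August: the domestic fresh record collapses to pure production, the
    imported fresh record to production + transport, and frozen variants
    add processing and freezing but never home cooking or refrigeration.
    Stage-level magnitudes are free parameters, not reference values."""
    countries = {
        "ES": Country("ES", "Europe", 40.2, -3.6, "P_ES"),
        "IT": Country("IT", "Europe", 42.8, 12.1, "P_IT"),
    }
    ports = {"P_ES": (41.3, 2.2), "P_IT": (40.8, 14.3)}
    pids = sorted(ports)
    sea = pd.DataFrame(0.0, index=pids, columns=pids)
    sea.index.name = "port_id"
    d = great_circle_km(ports["P_ES"], ports["P_IT"]) * 1.3
    sea.loc["P_ES", "P_IT"] = sea.loc["P_IT", "P_ES"] = d
    foods = {
        "apricot_fresh": FoodItem(
            "apricot_fresh", "Apricots, fresh", "apricot",
            FoodCategory.FRESH_PRODUCE, ProcessingType.NONE, False,
            TempClass.REFRIGERATED, False, CookingClass.NONE, StorageClass.NONE,
        ),
        "apricot_frozen": FoodItem(
            "apricot_frozen", "Apricots, frozen", "apricot",
            FoodCategory.FRESH_PRODUCE, ProcessingType.FREEZING, False,
            TempClass.FROZEN, False, CookingClass.NONE, StorageClass.FROZEN_STORAGE,
        ),
    }
    efs = EmissionFactorSet(
        elec={"ES": 0.25, "IT": 0.38, "GLO": 0.45},
        transport={
            (m, t): base * mult
            for m, base in (
                (TransportMode.ROAD, 1.0e-7),
                (TransportMode.SEA, 1.2e-8),
                (TransportMode.AIR, 6.0e-7),
            )
            for t, mult in (
                (TempClass.AMBIENT, 1.0),
                (TempClass.REFRIGERATED, 1.15),
                (TempClass.FROZEN, 1.35),
            )
        },
        steam_global=0.09,
    )
    cultivation = CultivationImpactTable(
        entries={
            ("apricot_fresh", "ES"): 1.5e-4,
            ("apricot_fresh", "IT"): 1.05e-4,
            ("apricot_frozen", "ES"): 1.5e-4,
            ("apricot_frozen", "IT"): 1.05e-4,
        },
        row_fallback={"apricot_fresh": 1.3e-4, "apricot_frozen": 1.3e-4},
    )
    recipes = ProcessRecipeTable(
        recipes={
            ProcessingType.BREAD: (3.0e-4, 1.0e-3),
            ProcessingType.PASTA: (2.5e-4, 1.2e-3),
            ProcessingType.BREAKFAST_CEREAL: (4.0e-4, 1.5e-3),
            ProcessingType.LARGE_FISH_CANNING: (3.0e-4, 1.2e-3),
            ProcessingType.SMALL_FISH_CANNING: (3.5e-4, 1.4e-3),
            ProcessingType.GENERAL_CANNING: (2.0e-4, 1.0e-3),
            ProcessingType.FREEZING: (9.0e-4, 0.0),
            ProcessingType.DEHYDRATING: (8.0e-4, 2.0e-3),
        }
    )
    cooking = CookingEnergyTable(
        energy_kwh_per_g={CookingClass.STANDARD: 8.0e-4, CookingClass.DRIED_BEANS: 2.4e-3}
    )
    storage = StorageParams(
        frozen_kwh_per_g_per_month=6.0e-5,
        frozen_storage_months=10.0,
        display_kwh_per_g={
            StorageClass.FROZEN_STORAGE: 1.2e-4,
            StorageClass.REFRIGERATED_DISPLAY: 5.0e-5,
        },
    )
    calendar = CropCalendar(
        demand={
            ("apricot", "ES"): np.array([0, 0, 0, 0, 1, 1, 1, 0, 0, 0, 0, 0], dtype=float),
            ("apricot", "IT"): np.array([0, 0, 0, 0, 1, 1, 1, 0, 0, 0, 0, 0], dtype=float),
        }
    )
    nutrients = NutrientProfile(
        nutrients=NUTRIENT_COLS,
        values={
            "apricot_fresh": np.array([2.0, 0.008, 0.001, 0.09, 0.02, 0.06]),
            "apricot_frozen": np.array([2.0, 0.008, 0.001, 0.09, 0.02, 0.05]),
        },
    )
    retention = RetentionTable(factors={(ProcessingType.FREEZING, "vitamin_c_mg"): 0.85})
    bundle = InputBundle(
        foods=foods,
        countries=countries,
        ports=PortNetwork(ports=ports, sea_km=sea),
        efs=efs,
        cultivation=cultivation,
        recipes=recipes,
        cooking=cooking,
        storage=storage,
        calendar=calendar,
        nutrients=nutrients,
        retention=retention,
        consumers=["ES"],
        road_uplift=0.20,
    )
    bundle.validate()
    return bundle
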