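"""Shared domain types for the food life-cycle impact pipeline.

Everything downstream works on a single functional unit: 1 gram of food as
consumed. Impacts are kgCO2eq per gram (GWP100), electricity is kWh, steam
is MJ, distance is km. Months are 1-based integers (1 = January).
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

#: Life-cycle stage keys, in output column order.
STAGES: tuple[str, ...] = (
    "production",
    "transport",
    "processing",
    "home_cooking",
    "freezing",
    "refrigeration",
)

MONTH_NAMES: tuple[str, ...] = (
    "January", "February", "March", "April", "May", "June",
    "July", "August", "September", "October", "November", "December",
)


class ValidationError(ValueError):
    """An input table or domain object violates an invariant."""


class FoodCategory(str, enum.Enum):
    FRESH_PRODUCE = "fresh_produce"
    MEAT = "meat"
    FISH_WILD = "fish_wild"
    FISH_AQUACULTURE = "fish_aquaculture"
    DAIRY = "dairy"
    GRAIN = "grain"
    LEGUME = "legume"
    EGG = "egg"
    MEAT_SUBSTITUTE = "meat_substitute"
    OTHER = "other"


class ProcessingType(str, enum.Enum):
    NONE = "none"
    BREAD = "bread"
    PASTA = "pasta"
    BREAKFAST_CEREAL = "breakfast_cereal"
    LARGE_FISH_CANNING = "large_fish_canning"
    SMALL_FISH_CANNING = "small_fish_canning"
    GENERAL_CANNING = "general_canning"
    FREEZING = "freezing"
    DEHYDRATING = "dehydrating"


#: Industrial processes that extend shelf life; any food carrying one of
#: these is treated as available year-round regardless of crop calendar.
SHELF_LIFE_PROCESSES = frozenset(p for p in ProcessingType if p is not ProcessingType.NONE)


class TempClass(str, enum.Enum):
    AMBIENT = "ambient"
    REFRIGERATED = "refrigerated"
    FROZEN = "frozen"


class TransportMode(str, enum.Enum):
    ROAD = "road"
    SEA = "sea"
    AIR = "air"


class CookingClass(str, enum.Enum):
    NONE = "none"
    STANDARD = "standard"
    DRIED_BEANS = "dried_beans"


class StorageClass(str, enum.Enum):
    NONE = "none"
    REFRIGERATED_DISPLAY = "refrigerated_display"
    FROZEN_STORAGE = "frozen_storage"


@dataclass(frozen=True)
class FoodItem:
    """One catalog entry: a raw food or a processed variant of one.

    ``base_crop`` keys into the crop calendar for seasonal fresh produce;
    for animal products and other non-calendar foods it is informational.
    ``processing_builtin`` marks items (milk, cheese, processed meat) whose
    processing energy is already inside the cultivation impact, so no
    separate processing stage may be added.
    """

    id: str
    display_name: str
    base_crop: str
    category: FoodCategory
    processing_type: ProcessingType
    processing_builtin: bool
    transport_temp_class: TempClass
    air_perishable: bool
    cooking_class: CookingClass
    storage_class: StorageClass

    def validate(self) -> None:
        if self.processing_type is ProcessingType.FREEZING:
            if self.transport_temp_class is not TempClass.FROZEN:
                raise ValidationError(
                    f"food {self.id!r}: freezing process requires frozen transport"
                )
            if self.storage_class is not StorageClass.FROZEN_STORAGE:
                raise ValidationError(
                    f"food {self.id!r}: freezing process requires frozen storage"
                )
        if self.air_perishable and self.processing_type is not ProcessingType.NONE:
            raise ValidationError(
                f"food {self.id!r}: only unprocessed fresh items may be air-perishable"
            )


@dataclass(frozen=True)
class Country:
    iso2: str
    continent: str
    lat: float
    lon: float
    nearest_port: str

    def validate(self) -> None:
        if not (-90.0 <= self.lat <= 90.0 and -180.0 <= self.lon <= 180.0):
            raise ValidationError(
                f"country {self.iso2!r}: centroid ({self.lat}, {self.lon}) out of range"
            )

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.lat, self.lon)


@dataclass
class PortNetwork:
    """Ports with coordinates and a symmetric port-to-port sea-distance matrix."""

    ports: dict[str, tuple[float, float]]
    sea_km: pd.DataFrame  # square, index and columns are port ids

    def distance(self, port_a: str, port_b: str) -> float:
        try:
            return float(self.sea_km.loc[port_a, port_b])
        except KeyError as exc:
            raise ValidationError(
                f"sea-distance matrix has no entry for ports ({port_a!r}, {port_b!r})"
            ) from exc

    def validate(self) -> None:
        ids = list(self.sea_km.index)
        if list(self.sea_km.columns) != ids:
            raise ValidationError("sea-distance matrix rows and columns disagree")
        for pid in self.ports:
            if pid not in ids:
                raise ValidationError(f"port {pid!r} missing from sea-distance matrix")
        m = self.sea_km.to_numpy(dtype=float)
        if not np.all(np.isfinite(m)) or (m < 0).any():
            raise ValidationError("sea distances must be finite and nonnegative")
        if not np.allclose(np.diag(m), 0.0):
            raise ValidationError("sea-distance matrix diagonal must be zero")
        if not np.allclose(m, m.T):
            raise ValidationError("sea-distance matrix must be symmetric")
        for pid, (lat, lon) in self.ports.items():
            if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
                raise ValidationError(f"port {pid!r}: coordinates out of range")


@dataclass
class EmissionFactorSet:
    """Electricity (per country), transport (per mode x temperature class),
    and a single global steam factor.

    Electricity lookups fall back to a designated global-average row when a
    country has no entry, mirroring the Rest-of-World proxy philosophy used
    for cultivation impacts.
    """

    elec: dict[str, float]  # country iso2 -> kgCO2eq / kWh
    transport: dict[tuple[TransportMode, TempClass], float]  # kgCO2eq / (g km)
    steam_global: float  # kgCO2eq / MJ
    global_elec_key: str = "GLO"

    def elec_ef(self, country: str) -> float:
        if country in self.elec:
            return self.elec[country]
        return self.elec[self.global_elec_key]

    def transport_ef(self, mode: TransportMode, temp: TempClass) -> float:
        try:
            return self.transport[(mode, temp)]
        except KeyError as exc:
            raise ValidationError(
                f"no transport emission factor for mode={mode.value!r}, "
                f"temp_class={temp.value!r}"
            ) from exc

    def validate(self) -> None:
        if self.global_elec_key not in self.elec:
            raise ValidationError(
                f"electricity table lacks the global-average row {self.global_elec_key!r}"
            )
        for k, v in self.elec.items():
            if not (math.isfinite(v) and v >= 0):
                raise ValidationError(f"electricity EF for {k!r} must be >= 0")
        for (mode, temp), v in self.transport.items():
            if not (math.isfinite(v) and v >= 0):
                raise ValidationError(
                    f"transport EF for ({mode.value}, {temp.value}) must be >= 0"
                )
        if not (math.isfinite(self.steam_global) and self.steam_global >= 0):
            raise ValidationError("steam EF must be >= 0")


@dataclass
class CultivationImpactTable:
    """Cradle-to-farm-gate impact per (food, production country), with a
    Rest-of-World fallback row per food for countries lacking specific data."""

    entries: dict[tuple[str, str], float]  # (food id, iso2) -> kgCO2eq / g
    row_fallback: dict[str, float]  # food id -> kgCO2eq / g

    def lookup(self, food_id: str, country: str) -> float:
        key = (food_id, country)
        if key in self.entries:
            return self.entries[key]
        try:
            return self.row_fallback[food_id]
        except KeyError as exc:
            raise ValidationError(f"no fallback cultivation impact for food {food_id!r}") from exc

    def validate(self, food_ids: set[str] | None = None) -> None:
        for key, v in self.entries.items():
            if not (math.isfinite(v) and v >= 0):
                raise ValidationError(f"cultivation impact for {key} must be >= 0")
        for fid, v in self.row_fallback.items():
            if not (math.isfinite(v) and v >= 0):
                raise ValidationError(f"fallback cultivation impact for {fid!r} must be >= 0")
        if food_ids is not None:
            missing = sorted(food_ids - set(self.row_fallback))
            if missing:
                raise ValidationError(
                    f"cultivation table missing fallback rows for foods: {missing}"
                )


@dataclass
class ProcessRecipeTable:
    """Average electricity and steam inputs per gram for each of the eight
    industrial process categories."""

    recipes: dict[ProcessingType, tuple[float, float]]  # (kWh/g, MJ/g)

    def validate(self) -> None:
        expected = SHELF_LIFE_PROCESSES
        got = set(self.recipes)
        if got != expected:
            raise ValidationError(
                "process recipe table must contain exactly the 8 process "
                f"categories; missing={sorted(p.value for p in expected - got)}, "
                f"extra={sorted(p.value for p in got - expected)}"
            )
        for p, (e, s) in self.recipes.items():
            if e < 0 or s < 0:
                raise ValidationError(f"recipe {p.value!r}: energies must be >= 0")


@dataclass
class CookingEnergyTable:
    energy_kwh_per_g: dict[CookingClass, float]

    def validate(self) -> None:
        std = self.energy_kwh_per_g.get(CookingClass.STANDARD)
        beans = self.energy_kwh_per_g.get(CookingClass.DRIED_BEANS)
        if std is None or beans is None:
            raise ValidationError("cooking table needs both standard and dried_beans rows")
        if std < 0 or beans < 0:
            raise ValidationError("cooking energies must be >= 0")
        if beans < std:
            raise ValidationError(
                "dried-beans cooking energy must be >= standard (extended cooking time)"
            )


@dataclass
class StorageParams:
    """Long-term frozen storage and retail display energy, per gram."""

    frozen_kwh_per_g_per_month: float
    frozen_storage_months: float = 10.0
    display_kwh_per_g: dict[StorageClass, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.frozen_storage_months <= 0:
            raise ValidationError("frozen_storage_months must be > 0")
        if self.frozen_kwh_per_g_per_month < 0:
            raise ValidationError("frozen storage rate must be >= 0")
        for k, v in self.display_kwh_per_g.items():
            if v < 0:
                raise ValidationError(f"display energy for {k.value!r} must be >= 0")


@dataclass
class CropCalendar:
    """Monthly crop water demand per (crop, country); positivity marks a
    harvest month."""

    demand: dict[tuple[str, str], np.ndarray]  # (crop, iso2) -> 12-vector >= 0

    def validate(self) -> None:
        for key, vec in self.demand.items():
            if vec.shape != (12,):
                raise ValidationError(f"calendar row {key}: demand vector must have 12 months")
            if not np.all(np.isfinite(vec)) or (vec < 0).any():
                raise ValidationError(f"calendar row {key}: demand must be finite and >= 0")

    def countries_for(self, crop: str) -> list[str]:
        return sorted(c for (cr, c) in self.demand if cr == crop)


@dataclass
class NutrientProfile:
    """Per-gram nutrient content of every catalog food.

    Nutrient units are free-form, carried in the column names (e.g.
    ``protein_g``, ``vitamin_c_mg``); amounts are per gram of food.
    """

    nutrients: list[str]
    values: dict[str, np.ndarray]  # food id -> vector aligned with nutrients

    def validate(self, food_ids: set[str] | None = None) -> None:
        n = len(self.nutrients)
        for fid, vec in self.values.items():
            if vec.shape != (n,):
                raise ValidationError(f"nutrient row {fid!r} has wrong length")
            if not np.all(np.isfinite(vec)) or (vec < 0).any():
                raise ValidationError(f"nutrient amounts for {fid!r} must be finite and >= 0")
        if food_ids is not None:
            missing = sorted(food_ids - set(self.values))
            if missing:
                raise ValidationError(f"nutrient table missing catalog foods: {missing}")


@dataclass
class RetentionTable:
    """Nutrient retention fractions per (process, nutrient); absent entries
    mean full retention (factor 1)."""

    factors: dict[tuple[ProcessingType, str], float]

    def get(self, process: ProcessingType, nutrient: str) -> float:
        return self.factors.get((process, nutrient), 1.0)

    def validate(self) -> None:
        for key, v in self.factors.items():
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"retention factor {key} = {v} outside [0, 1]")


@dataclass(frozen=True)
class ImpactRecord:
    """One output row: six stage impacts, their total, and percentages, for
    a (food, production country, consumption country, month) combination."""

    food_id: str
    display_name: str
    production_country: str
    consumption_country: str
    month: int
    stage_impacts: Mapping[str, float]  # keys STAGES, kgCO2eq / g
    total: float
    stage_pct: Mapping[str, float]  # keys STAGES, percent of total

    def validate(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValidationError(f"record {self.food_id!r}: month {self.month} outside 1-12")
        if set(self.stage_impacts) != set(STAGES) or set(self.stage_pct) != set(STAGES):
            raise ValidationError(f"record {self.food_id!r}: stage keys incomplete")
        s = sum(self.stage_impacts.values())
        if any(v < 0 for v in self.stage_impacts.values()):
            raise ValidationError(f"record {self.food_id!r}: negative stage impact")
        if self.total <= 0:
            raise ValidationError(f"record {self.food_id!r}: total must be > 0")
        if abs(s - self.total) > 1e-12 * max(abs(self.total), 1e-300):
            raise ValidationError(f"record {self.food_id!r}: stages do not sum to total")
        if abs(sum(self.stage_pct.values()) - 100.0) > 1e-9:
            raise ValidationError(f"record {self.food_id!r}: percentages do not sum to 100")


@dataclass
class InputBundle:
    """Everything the pipeline needs, loaded and cross-validated."""

    foods: dict[str, FoodItem]
    countries: dict[str, Country]
    ports: PortNetwork
    efs: EmissionFactorSet
    cultivation: CultivationImpactTable
    recipes: ProcessRecipeTable
    cooking: CookingEnergyTable
    storage: StorageParams
    calendar: CropCalendar
    nutrients: NutrientProfile
    retention: RetentionTable
    consumers: list[str] = field(default_factory=list)
    road_uplift: float = 0.20

    def validate(self) -> None:
        """Check every cross-table invariant; raise ValidationError on the
        first violation, naming the offending row."""
        for food in self.foods.values():
            food.validate()
        port_ids = set(self.ports.ports)
        for c in self.countries.values():
            c.validate()
            if c.nearest_port not in port_ids:
                raise ValidationError(
                    f"country {c.iso2!r}: nearest port {c.nearest_port!r} not in port table"
                )
        self.ports.validate()
        self.efs.validate()
        self.cultivation.validate(set(self.foods))
        self.recipes.validate()
        self.cooking.validate()
        self.storage.validate()
        self.calendar.validate()
        self.nutrients.validate(set(self.foods))
        self.retention.validate()
        # transport EF coverage: diff the (mode, temp) demand set of the
        # catalog against the table
        demanded: set[tuple[TransportMode, TempClass]] = set()
        for food in self.foods.values():
            tc = food.transport_temp_class
            demanded.add((TransportMode.ROAD, tc))
            if food.air_perishable:
                demanded.add((TransportMode.AIR, tc))
            else:
                demanded.add((TransportMode.SEA, tc))
        missing = sorted(
            (m.value, t.value) for (m, t) in demanded - set(self.efs.transport)
        )
        if missing:
            raise ValidationError(
                f"transport EF table missing (mode, temp_class) pairs required "
                f"by the catalog: {missing}"
            )
        for iso2 in self.consumers:
            if iso2 not in self.countries:
                raise ValidationError(f"consumer country {iso2!r} not in country table")
        if not (0 <= self.road_uplift < 10):
            raise ValidationError(f"road uplift {self.road_uplift} implausible")
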