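"""Reading the input tables and writing the output workbooks.

Inputs are UTF-8, comma-delimited text tables with a mandatory header row
and "." decimal separator, named in a YAML config file; all paths in the
config are relative to the config's directory. Outputs are one XLSX
workbook per consumer country (12 sheets, January through December) plus a
Food_Nutrients table; a CSV-bundle mode writes 12 per-month CSV files with
identical columns instead of a workbook.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .model import (
    CookingClass,
    CookingEnergyTable,
    Country,
    CropCalendar,
    CultivationImpactTable,
    EmissionFactorSet,
    FoodCategory,
    FoodItem,
    ImpactRecord,
    InputBundle,
    MONTH_NAMES,
    NutrientProfile,
    PortNetwork,
    ProcessRecipeTable,
    ProcessingType,
    RetentionTable,
    StorageClass,
    StorageParams,
    TempClass,
    TransportMode,
    ValidationError,
)

#: Output column order; stage percentages occupy the six columns after
#: Food_Item, followed by the total and the two country columns.
OUTPUT_COLUMNS = (
    "Food_Item",
    "Production_%",
    "Transport_%",
    "Processing_%",
    "Home_Cooking_%",
    "Freezing_%",
    "Refrigeration_%",
    "GHG_Impact_total",
    "Production_Country",
    "Consumption_Country",
)

TABLE_KEYS = (
    "foods",
    "countries",
    "ports",
    "sea_distances",
    "electricity_ef",
    "transport_ef",
    "cultivation",
    "process_recipes",
    "cooking_energy",
    "storage_params",
    "crop_calendar",
    "nutrients",
    "retention",
)

_FALLBACK_COUNTRY = "ROW"  # cultivation-table marker for the Rest-of-World row


def _enum(cls, value: str, context: str):
    try:
        return cls(str(value))
    except ValueError as exc:
        raise ValidationError(
            f"{context}: unknown {cls.__name__} value {value!r} "
            f"(expected one of {[m.value for m in cls]})"
        ) from exc


def _bool(value, context: str) -> bool:
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValidationError(f"{context}: cannot interpret {value!r} as boolean")


def _read_table(path: Path, name: str) -> pd.DataFrame:
    if not path.exists():
        raise ValidationError(f"input table {name!r} not found at {path}")
    return pd.read_csv(path, float_precision="round_trip")



def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    # %.17g round-trips any float64 exactly through the CSV dialect
    df.to_csv(path, index=index, float_format="%.17g")

def load_inputs(config_path: str | Path) -> InputBundle:
    """Load every input table named in the config, cross-validate, and
    return the bundle. Any violated invariant raises ValidationError
    naming the offending table or row."""
    config_path = Path(config_path)
    if not config_path.exists():
        raise ValidationError(f"config file not found: {config_path}")
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    base = config_path.parent
    tables = cfg.get("tables", {})
    missing = [k for k in TABLE_KEYS if k not in tables]
    if missing:
        raise ValidationError(f"config missing table entries: {missing}")
    params = cfg.get("parameters", {})

    dfs = {k: _read_table(base / tables[k], k) for k in TABLE_KEYS}

    foods: dict[str, FoodItem] = {}
    for _, r in dfs["foods"].iterrows():
        fid = str(r["id"])
        foods[fid] = FoodItem(
            id=fid,
            display_name=str(r["display_name"]),
            base_crop=str(r["base_crop"]),
            category=_enum(FoodCategory, r["category"], f"food {fid}"),
            processing_type=_enum(ProcessingType, r["processing_type"], f"food {fid}"),
            processing_builtin=_bool(r["processing_builtin"], f"food {fid}"),
            transport_temp_class=_enum(TempClass, r["transport_temp_class"], f"food {fid}"),
            air_perishable=_bool(r["air_perishable"], f"food {fid}"),
            cooking_class=_enum(CookingClass, r["cooking_class"], f"food {fid}"),
            storage_class=_enum(StorageClass, r["storage_class"], f"food {fid}"),
        )

    countries = {
        str(r["iso2"]): Country(
            iso2=str(r["iso2"]),
            continent=str(r["continent"]),
            lat=float(r["lat"]),
            lon=float(r["lon"]),
            nearest_port=str(r["nearest_port"]),
        )
        for _, r in dfs["countries"].iterrows()
    }

    ports = {
        str(r["port_id"]): (float(r["lat"]), float(r["lon"]))
        for _, r in dfs["ports"].iterrows()
    }
    sea = dfs["sea_distances"].set_index(dfs["sea_distances"].columns[0])
    sea.index = sea.index.astype(str)
    sea.columns = sea.columns.astype(str)
    sea.index.name = "port_id"
    network = PortNetwork(ports=ports, sea_km=sea.astype(float))

    elec = {
        str(r["country"]): float(r["ef_kg_per_kwh"])
        for _, r in dfs["electricity_ef"].iterrows()
    }
    transport = {
        (
            _enum(TransportMode, r["mode"], "transport EF"),
            _enum(TempClass, r["temp_class"], "transport EF"),
        ): float(r["ef_kg_per_g_km"])
        for _, r in dfs["transport_ef"].iterrows()
    }
    efs = EmissionFactorSet(
        elec=elec,
        transport=transport,
        steam_global=float(params.get("steam_ef_kg_per_mj", 0.0)),
        global_elec_key=str(params.get("global_elec_key", "GLO")),
    )

    entries: dict[tuple[str, str], float] = {}
    fallback: dict[str, float] = {}
    for _, r in dfs["cultivation"].iterrows():
        fid, ctry, val = str(r["food_id"]), str(r["country"]), float(r["kgco2eq_per_g"])
        if ctry == _FALLBACK_COUNTRY:
            fallback[fid] = val
        else:
            entries[(fid, ctry)] = val
    cultivation = CultivationImpactTable(entries=entries, row_fallback=fallback)

    recipes = ProcessRecipeTable(
        recipes={
            _enum(ProcessingType, r["process_type"], "recipe"): (
                float(r["elec_kwh_per_g"]),
                float(r["steam_mj_per_g"]),
            )
            for _, r in dfs["process_recipes"].iterrows()
        }
    )

    cooking = CookingEnergyTable(
        energy_kwh_per_g={
            _enum(CookingClass, r["cooking_class"], "cooking"): float(r["kwh_per_g"])
            for _, r in dfs["cooking_energy"].iterrows()
        }
    )

    sp = {str(r["parameter"]): float(r["value"]) for _, r in dfs["storage_params"].iterrows()}
    storage = StorageParams(
        frozen_kwh_per_g_per_month=sp.get("frozen_kwh_per_g_per_month", 0.0),
        frozen_storage_months=sp.get("frozen_storage_months", 10.0),
        display_kwh_per_g={
            StorageClass.FROZEN_STORAGE: sp.get("display_frozen_kwh_per_g", 0.0),
            StorageClass.REFRIGERATED_DISPLAY: sp.get("display_refrigerated_kwh_per_g", 0.0),
        },
    )

    month_cols = [f"m{i}" for i in range(1, 13)]
    calendar = CropCalendar(
        demand={
            (str(r["crop"]), str(r["country"])): np.array(
                [float(r[c]) for c in month_cols], dtype=float
            )
            for _, r in dfs["crop_calendar"].iterrows()
        }
    )

    nut_df = dfs["nutrients"]
    nutrient_cols = [c for c in nut_df.columns if c != "food_id"]
    nutrients = NutrientProfile(
        nutrients=nutrient_cols,
        values={
            str(r["food_id"]): np.array([float(r[c]) for c in nutrient_cols], dtype=float)
            for _, r in nut_df.iterrows()
        },
    )

    retention = RetentionTable(
        factors={
            (
                _enum(ProcessingType, r["process_type"], "retention"),
                str(r["nutrient"]),
            ): float(r["retention"])
            for _, r in dfs["retention"].iterrows()
        }
    )

    bundle = InputBundle(
        foods=foods,
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
        consumers=[str(c) for c in cfg.get("consumers", [])],
        road_uplift=float(params.get("road_uplift", 0.20)),
    )
    bundle.validate()
    return bundle


def write_bundle(bundle: InputBundle, out_dir: str | Path, config_name: str = "config.yaml") -> Path:
    """Serialize a bundle to delimited tables plus a config file; the
    result is loadable by load_inputs (round-trip exact for the CSV
    dialect). Returns the config path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {
                "id": f.id,
                "display_name": f.display_name,
                "base_crop": f.base_crop,
                "category": f.category.value,
                "processing_type": f.processing_type.value,
                "processing_builtin": f.processing_builtin,
                "transport_temp_class": f.transport_temp_class.value,
                "air_perishable": f.air_perishable,
                "cooking_class": f.cooking_class.value,
                "storage_class": f.storage_class.value,
            }
            for f in bundle.foods.values()
        ]
    ).pipe(_write_csv, out / "foods.csv", index=False)

    pd.DataFrame(
        [
            {"iso2": c.iso2, "continent": c.continent, "lat": c.lat, "lon": c.lon,
             "nearest_port": c.nearest_port}
            for c in bundle.countries.values()
        ]
    ).pipe(_write_csv, out / "countries.csv", index=False)

    pd.DataFrame(
        [{"port_id": pid, "lat": lat, "lon": lon} for pid, (lat, lon) in bundle.ports.ports.items()]
    ).pipe(_write_csv, out / "ports.csv", index=False)
    _write_csv(bundle.ports.sea_km, out / "sea_distances.csv", index=True)

    pd.DataFrame(
        [{"country": k, "ef_kg_per_kwh": v} for k, v in bundle.efs.elec.items()]
    ).pipe(_write_csv, out / "electricity_ef.csv", index=False)
    pd.DataFrame(
        [
            {"mode": m.value, "temp_class": t.value, "ef_kg_per_g_km": v}
            for (m, t), v in bundle.efs.transport.items()
        ]
    ).pipe(_write_csv, out / "transport_ef.csv", index=False)

    cult_rows = [
        {"food_id": fid, "country": ctry, "kgco2eq_per_g": v}
        for (fid, ctry), v in bundle.cultivation.entries.items()
    ] + [
        {"food_id": fid, "country": _FALLBACK_COUNTRY, "kgco2eq_per_g": v}
        for fid, v in bundle.cultivation.row_fallback.items()
    ]
    pd.DataFrame(cult_rows).pipe(_write_csv, out / "cultivation.csv", index=False)

    pd.DataFrame(
        [
            {"process_type": p.value, "elec_kwh_per_g": e, "steam_mj_per_g": s}
            for p, (e, s) in bundle.recipes.recipes.items()
        ]
    ).pipe(_write_csv, out / "process_recipes.csv", index=False)

    pd.DataFrame(
        [{"cooking_class": c.value, "kwh_per_g": v} for c, v in bundle.cooking.energy_kwh_per_g.items()]
    ).pipe(_write_csv, out / "cooking_energy.csv", index=False)

    pd.DataFrame(
        [
            {"parameter": "frozen_kwh_per_g_per_month", "value": bundle.storage.frozen_kwh_per_g_per_month},
            {"parameter": "frozen_storage_months", "value": bundle.storage.frozen_storage_months},
            {"parameter": "display_frozen_kwh_per_g",
             "value": bundle.storage.display_kwh_per_g.get(StorageClass.FROZEN_STORAGE, 0.0)},
            {"parameter": "display_refrigerated_kwh_per_g",
             "value": bundle.storage.display_kwh_per_g.get(StorageClass.REFRIGERATED_DISPLAY, 0.0)},
        ]
    ).pipe(_write_csv, out / "storage_params.csv", index=False)

    pd.DataFrame(
        [
            {"crop": crop, "country": ctry, **{f"m{i+1}": vec[i] for i in range(12)}}
            for (crop, ctry), vec in bundle.calendar.demand.items()
        ]
    ).pipe(_write_csv, out / "crop_calendar.csv", index=False)

    pd.DataFrame(
        [
            {"food_id": fid, **dict(zip(bundle.nutrients.nutrients, vec))}
            for fid, vec in bundle.nutrients.values.items()
        ]
    ).pipe(_write_csv, out / "nutrients.csv", index=False)

    ret_rows = [
        {"process_type": p.value, "nutrient": n, "retention": v}
        for (p, n), v in bundle.retention.factors.items()
    ]
    _write_csv(
        pd.DataFrame(ret_rows, columns=["process_type", "nutrient", "retention"]),
        out / "retention.csv",
    )

    cfg = {
        "tables": {
            "foods": "foods.csv",
            "countries": "countries.csv",
            "ports": "ports.csv",
            "sea_distances": "sea_distances.csv",
            "electricity_ef": "electricity_ef.csv",
            "transport_ef": "transport_ef.csv",
            "cultivation": "cultivation.csv",
            "process_recipes": "process_recipes.csv",
            "cooking_energy": "cooking_energy.csv",
            "storage_params": "storage_params.csv",
            "crop_calendar": "crop_calendar.csv",
            "nutrients": "nutrients.csv",
            "retention": "retention.csv",
        },
        "parameters": {
            "road_uplift": bundle.road_uplift,
            "steam_ef_kg_per_mj": bundle.efs.steam_global,
            "global_elec_key": bundle.efs.global_elec_key,
        },
        "consumers": list(bundle.consumers),
    }
    cfg_path = out / config_name
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return cfg_path


def _records_frame(records: Iterable[ImpactRecord], round_percent: bool = False) -> pd.DataFrame:
    rows = []
    for r in records:
        pct = {k: (round(v) if round_percent else v) for k, v in r.stage_pct.items()}
        rows.append(
            {
                "Food_Item": r.display_name,
                "Production_%": pct["production"],
                "Transport_%": pct["transport"],
                "Processing_%": pct["processing"],
                "Home_Cooking_%": pct["home_cooking"],
                "Freezing_%": pct["freezing"],
                "Refrigeration_%": pct["refrigeration"],
                "GHG_Impact_total": r.total,
                "Production_Country": r.production_country,
                "Consumption_Country": r.consumption_country,
                "_sort": (r.display_name, r.production_country),
            }
        )
    df = pd.DataFrame(rows, columns=list(OUTPUT_COLUMNS) + ["_sort"])
    if len(df):
        df = df.sort_values("_sort", kind="mergesort")
    return df.drop(columns="_sort").reset_index(drop=True)


def write_consumer_workbook(
    records: Sequence[ImpactRecord],
    consumer: str,
    out_dir: str | Path,
    csv: bool = False,
    round_percent: bool = False,
) -> Path:
    """Write one consumer country's outputs: an XLSX workbook named by the
    ISO code with 12 monthly sheets, or (csv=True) a directory of 12
    monthly CSV files with identical columns."""
    for r in records:
        if r.consumption_country != consumer:
            raise ValidationError(
                f"record for {r.consumption_country!r} passed to writer for {consumer!r}"
            )
        if not 1 <= r.month <= 12:
            raise ValidationError(f"record month {r.month} outside 1-12")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_month: dict[int, list[ImpactRecord]] = {m: [] for m in range(1, 13)}
    for r in records:
        by_month[r.month].append(r)

    if csv:
        dest = out / consumer
        dest.mkdir(exist_ok=True)
        for m in range(1, 13):
            df = _records_frame(by_month[m], round_percent)
            df.to_csv(dest / f"{consumer}_{MONTH_NAMES[m - 1]}.csv", index=False)
        return dest

    path = out / f"{consumer}.xlsx"
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        for m in range(1, 13):
            _records_frame(by_month[m], round_percent).to_excel(
                writer, sheet_name=MONTH_NAMES[m - 1], index=False
            )
    return path


def write_nutrient_table(
    profiles: NutrientProfile, out_dir: str | Path, csv: bool = False
) -> Path:
    """Write the Food_Nutrients table: one row per food, per-gram amounts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [
            {"Food_Item": fid, **dict(zip(profiles.nutrients, vec))}
            for fid, vec in sorted(profiles.values.items())
        ],
        columns=["Food_Item"] + list(profiles.nutrients),
    )
    if csv:
        path = out / "Food_Nutrients.csv"
        df.to_csv(path, index=False)
    else:
        path = out / "Food_Nutrients.xlsx"
        df.to_excel(path, index=False, engine="openpyxl")
    return path
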