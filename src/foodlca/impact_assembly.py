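"""Assembling full cradle-to-plate impact records.

For each (food, production country, consumption country, month) in which
the food is available, the six stage impacts are summed into a total and
re-expressed as percentage contributions — the hotspot breakdown. The
production and processing stages depend only on the producing country;
transport on the pair; cooking, freezing and refrigeration only on the
consuming country.
"""
from __future__ import annotations

import logging
from pathlib import Path
from types import MappingProxyType

from .model import (
    CultivationImpactTable,
    FoodItem,
    ImpactRecord,
    InputBundle,
    STAGES,
    ValidationError,
)
from . import schema_io, seasonality
from .stage_energy import cooking_impact, processing_impact, storage_impacts
from .transport_model import assign_route, transport_impact

logger = logging.getLogger(__name__)


def production_impact(food_id: str, prod_country: str, table: CultivationImpactTable) -> float:
    """Country-specific cultivation impact, or the Rest-of-World fallback
    when no country row exists."""
    return table.lookup(food_id, prod_country)


def build_record(
    food: FoodItem, prod: str, cons: str, month: int, bundle: InputBundle
) -> ImpactRecord:
    """Compute one record; total must come out positive (every real food
    has a nonzero production impact)."""
    prod_c = bundle.countries[prod]
    cons_c = bundle.countries[cons]
    assignment = assign_route(food, prod_c, cons_c, bundle.ports, bundle.road_uplift)
    freezing, refrigeration = storage_impacts(food, cons, bundle.storage, bundle.efs)
    impacts = {
        "production": production_impact(food.id, prod, bundle.cultivation),
        "transport": transport_impact(assignment, bundle.efs),
        "processing": processing_impact(food, prod, bundle.recipes, bundle.efs),
        "home_cooking": cooking_impact(food, cons, bundle.cooking, bundle.efs),
        "freezing": freezing,
        "refrigeration": refrigeration,
    }
    total = sum(impacts[k] for k in STAGES)
    if total <= 0:
        raise ValidationError(
            f"record ({food.id}, {prod}->{cons}, month {month}) has zero total impact"
        )
    pct = {k: 100.0 * impacts[k] / total for k in STAGES}
    record = ImpactRecord(
        food_id=food.id,
        display_name=food.display_name,
        production_country=prod,
        consumption_country=cons,
        month=month,
        stage_impacts=MappingProxyType(impacts),
        total=total,
        stage_pct=MappingProxyType(pct),
    )
    return record


def enumerate_records(consumer: str, month: int, bundle: InputBundle) -> list[ImpactRecord]:
    """All records for one consumer country and month: one per (food,
    producing country) pair whose availability set contains the month.
    Deterministic order: food id, then producer ISO code."""
    if consumer not in bundle.countries:
        raise ValidationError(f"unknown consumer country {consumer!r}")
    records = []
    all_iso = list(bundle.countries)
    for fid in sorted(bundle.foods):
        food = bundle.foods[fid]
        for prod in seasonality.producing_countries(food, bundle.calendar, all_iso):
            if month in seasonality.availability(food, prod, bundle.calendar):
                records.append(build_record(food, prod, consumer, month, bundle))
    return records


def run_pipeline(
    config: str | Path | InputBundle,
    out_dir: str | Path,
    consumers: list[str] | None = None,
    months: list[int] | None = None,
    csv: bool = False,
    round_percent: bool = False,
) -> list[Path]:
    """Full run: one workbook per consumer country plus the Food_Nutrients
    table. ``consumers``/``months`` restrict the run; unrestricted months
    still produce 12 sheets (the others empty). Partial outputs are removed
    on failure."""
    bundle = config if isinstance(config, InputBundle) else schema_io.load_inputs(config)
    out = Path(out_dir)
    targets = consumers if consumers is not None else bundle.consumers
    unknown = [c for c in targets if c not in bundle.countries]
    if unknown:
        raise ValidationError(
            f"unknown consumer countries {unknown}; known codes: {sorted(bundle.countries)}"
        )
    month_list = sorted(months) if months else list(range(1, 13))
    for m in month_list:
        if not 1 <= m <= 12:
            raise ValidationError(f"month {m} outside 1-12")

    written: list[Path] = []
    try:
        for consumer in targets:
            records: list[ImpactRecord] = []
            for m in month_list:
                recs = enumerate_records(consumer, m, bundle)
                logger.info("%s month %d: %d records", consumer, m, len(recs))
                records.extend(recs)
            written.append(
                schema_io.write_consumer_workbook(
                    records, consumer, out, csv=csv, round_percent=round_percent
                )
            )
        written.append(schema_io.write_nutrient_table(bundle.nutrients, out, csv=csv))
    except Exception:
        for p in written:
            if p.is_dir():
                for f in p.iterdir():
                    f.unlink()
                p.rmdir()
            elif p.exists():
                p.unlink()
        raise
    return written
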