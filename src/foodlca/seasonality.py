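"""Monthly availability of foods per production country.

Harvest months are the months with positive crop water demand. Fresh
produce becomes available for consumption two months after harvest (a
fixed forward shift on the 12-month cycle). Items processed for extended
shelf life — canned, frozen, dehydrated, and grain products such as bread,
pasta and breakfast cereals — are available year-round, as are animal
products, dairy, eggs and other foods without a crop calendar.
"""
from __future__ import annotations

import logging

from .model import (
    CropCalendar,
    FoodCategory,
    FoodItem,
    ProcessingType,
    SHELF_LIFE_PROCESSES,
)

logger = logging.getLogger(__name__)

ALL_MONTHS = frozenset(range(1, 13))

#: Months between harvest and availability on the shelf.
HARVEST_TO_SHELF_SHIFT = 2


def harvest_months(calendar: CropCalendar, crop: str, country: str) -> frozenset[int]:
    """Months (1-12) in which ``crop`` is harvested in ``country``: the
    months with positive water demand. Unknown (crop, country) pairs yield
    the empty set — the country cannot produce the crop."""
    vec = calendar.demand.get((crop, country))
    if vec is None:
        return frozenset()
    return frozenset(m for m in range(1, 13) if vec[m - 1] > 0)


def shift_months(months: frozenset[int], shift: int = HARVEST_TO_SHELF_SHIFT) -> frozenset[int]:
    """Shift a month set forward on the 12-cycle (a bijection)."""
    return frozenset(((m - 1 + shift) % 12) + 1 for m in months)


def is_seasonal(food: FoodItem) -> bool:
    """Only unprocessed fresh produce follows the crop calendar."""
    return (
        food.processing_type is ProcessingType.NONE
        and food.category is FoodCategory.FRESH_PRODUCE
    )


def availability(food: FoodItem, country: str, calendar: CropCalendar) -> frozenset[int]:
    """Consumption months in which ``food`` from ``country`` is on the shelf.

    Fresh produce: harvest months shifted forward by two. Shelf-life
    processed variants: all twelve months, in every country that can grow
    the base crop. Foods with no crop calendar at all (animal products,
    dairy, eggs, substitutes): all twelve months.
    """
    has_calendar = any(cr == food.base_crop for (cr, _c) in calendar.demand)
    if not has_calendar:
        if is_seasonal(food):
            logger.warning(
                "fresh item %s has no calendar for crop %s; excluded from %s",
                food.id, food.base_crop, country,
            )
            return frozenset()
        return ALL_MONTHS
    if is_seasonal(food):
        return shift_months(harvest_months(calendar, food.base_crop, country))
    if food.processing_type in SHELF_LIFE_PROCESSES:
        # year-round, but only where the crop is grown at all
        if harvest_months(calendar, food.base_crop, country):
            return ALL_MONTHS
        return frozenset()
    # crop-derived but not seasonal (e.g. grain eaten raw): year-round where grown
    if harvest_months(calendar, food.base_crop, country):
        return ALL_MONTHS
    return frozenset()


def producing_countries(food: FoodItem, calendar: CropCalendar, all_countries: list[str]) -> list[str]:
    """Countries that can supply ``food`` in at least one month."""
    has_calendar = any(cr == food.base_crop for (cr, _c) in calendar.demand)
    if not has_calendar:
        return sorted(all_countries)
    return [c for c in sorted(all_countries) if availability(food, c, calendar)]
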