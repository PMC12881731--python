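"""Processing, home-cooking and storage impacts per gram.

Processing runs on the producing country's electricity mix plus a global
steam factor; foods whose processing is already inside the production
impact (milk, cheese, processed meat) contribute nothing here. Home
cooking uses the consuming country's electricity, with dried beans as a
separate, more energy-intensive class. Storage is either long-term frozen
storage plus frozen retail display (the "freezing" stage) or refrigerated
retail display (the "refrigeration" stage) — never both. Fresh fruit and
vegetables carry no long-term storage energy.
"""
from __future__ import annotations

from .model import (
    CookingClass,
    CookingEnergyTable,
    EmissionFactorSet,
    FoodItem,
    ProcessRecipeTable,
    ProcessingType,
    StorageClass,
    StorageParams,
)


def processing_impact(
    food: FoodItem,
    prod_country: str,
    recipes: ProcessRecipeTable,
    efs: EmissionFactorSet,
) -> float:
    """kgCO2eq/g of industrial processing in the producing country."""
    if food.processing_type is ProcessingType.NONE or food.processing_builtin:
        return 0.0
    elec_kwh, steam_mj = recipes.recipes[food.processing_type]
    return elec_kwh * efs.elec_ef(prod_country) + steam_mj * efs.steam_global


def cooking_impact(
    food: FoodItem,
    cons_country: str,
    table: CookingEnergyTable,
    efs: EmissionFactorSet,
) -> float:
    """kgCO2eq/g of home cooking in the consuming country, independent of
    where the food was produced."""
    if food.cooking_class is CookingClass.NONE:
        return 0.0
    return table.energy_kwh_per_g[food.cooking_class] * efs.elec_ef(cons_country)


def storage_impacts(
    food: FoodItem,
    cons_country: str,
    params: StorageParams,
    efs: EmissionFactorSet,
) -> tuple[float, float]:
    """(freezing, refrigeration) impacts in kgCO2eq/g, in the consuming
    country; at most one of the two is nonzero."""
    ef = efs.elec_ef(cons_country)
    if food.storage_class is StorageClass.FROZEN_STORAGE:
        energy = (
            params.frozen_kwh_per_g_per_month * params.frozen_storage_months
            + params.display_kwh_per_g.get(StorageClass.FROZEN_STORAGE, 0.0)
        )
        return energy * ef, 0.0
    if food.storage_class is StorageClass.REFRIGERATED_DISPLAY:
        energy = params.display_kwh_per_g.get(StorageClass.REFRIGERATED_DISPLAY, 0.0)
        return 0.0, energy * ef
    return 0.0, 0.0
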