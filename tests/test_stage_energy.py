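"""Processing, home-cooking and storage stage energies."""
import pytest

from foodlca import (
    CookingClass,
    CookingEnergyTable,
    EmissionFactorSet,
    FoodCategory,
    FoodItem,
    ProcessRecipeTable,
    ProcessingType,
    StorageClass,
    StorageParams,
    TempClass,
    cooking_impact,
    processing_impact,
    storage_impacts,
)

_ALL_RECIPES = {p: (1e-4, 0.0) for p in ProcessingType if p is not ProcessingType.NONE}


def _efs(**elec):
    elec.setdefault("GLO", 0.5)
    return EmissionFactorSet(elec=elec, transport={}, steam_global=0.08)


def _item(fid, process=ProcessingType.NONE, builtin=False,
          cooking=CookingClass.NONE, storage=StorageClass.NONE,
          category=FoodCategory.OTHER):
    frozen = process is ProcessingType.FREEZING
    return FoodItem(
        fid, fid, fid, category, process, builtin,
        TempClass.FROZEN if frozen else TempClass.AMBIENT, False, cooking,
        StorageClass.FROZEN_STORAGE if frozen else storage,
    )


class TestProcessing:
    def test_builtin_processing_contributes_nothing(self):
        cheese = _item("cheese", builtin=True, category=FoodCategory.DAIRY)
        recipes = ProcessRecipeTable(recipes=dict(_ALL_RECIPES))
        assert processing_impact(cheese, "AA", recipes, _efs(AA=1.0)) == 0.0

    def test_unprocessed_contributes_nothing(self):
        raw = _item("apple")
        recipes = ProcessRecipeTable(recipes=dict(_ALL_RECIPES))
        assert processing_impact(raw, "AA", recipes, _efs(AA=1.0)) == 0.0

    def test_canning_electricity_times_country_ef(self):
        canned = _item("corn_canned", process=ProcessingType.GENERAL_CANNING)
        recipes = ProcessRecipeTable(
            recipes={**_ALL_RECIPES, ProcessingType.GENERAL_CANNING: (1e-4, 0.0)}
        )
        efs = _efs(AA=0.5)
        assert processing_impact(canned, "AA", recipes, efs) == pytest.approx(5e-5)

    def test_linear_in_producer_electricity_ef(self):
        canned = _item("corn_canned", process=ProcessingType.GENERAL_CANNING)
        recipes = ProcessRecipeTable(
            recipes={**_ALL_RECIPES, ProcessingType.GENERAL_CANNING: (2e-4, 0.0)}
        )
        efs = _efs(AA=0.3, BB=0.6)
        a = processing_impact(canned, "AA", recipes, efs)
        b = processing_impact(canned, "BB", recipes, efs)
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_steam_uses_global_factor(self):
        bread = _item("bread", process=ProcessingType.BREAD)
        recipes = ProcessRecipeTable(
            recipes={**_ALL_RECIPES, ProcessingType.BREAD: (0.0, 1e-3)}
        )
        efs = _efs(AA=0.5)
        assert processing_impact(bread, "AA", recipes, efs) == pytest.approx(
            1e-3 * efs.steam_global
        )

    def test_unknown_country_falls_back_to_global_average(self):
        canned = _item("corn_canned", process=ProcessingType.GENERAL_CANNING)
        recipes = ProcessRecipeTable(
            recipes={**_ALL_RECIPES, ProcessingType.GENERAL_CANNING: (1e-4, 0.0)}
        )
        efs = _efs()
        assert processing_impact(canned, "ZZ", recipes, efs) == pytest.approx(
            1e-4 * efs.elec["GLO"]
        )


class TestCooking:
    table = CookingEnergyTable(
        energy_kwh_per_g={CookingClass.STANDARD: 2e-4, CookingClass.DRIED_BEANS: 6e-4}
    )

    def test_uncooked_food_has_zero_impact(self):
        apricot = _item("apricot")
        assert cooking_impact(apricot, "AA", self.table, _efs(AA=0.3)) == 0.0

    def test_standard_class_is_energy_times_consumer_ef(self):
        rice = _item("rice", cooking=CookingClass.STANDARD)
        assert cooking_impact(rice, "AA", self.table, _efs(AA=0.3)) == pytest.approx(6e-5)

    def test_dried_beans_cost_at_least_standard(self):
        rice = _item("rice", cooking=CookingClass.STANDARD)
        beans = _item("beans", cooking=CookingClass.DRIED_BEANS)
        efs = _efs(AA=0.3)
        assert cooking_impact(beans, "AA", self.table, efs) >= cooking_impact(
            rice, "AA", self.table, efs
        )


class TestStorage:
    def test_no_storage_class_means_zero_both(self):
        canned = _item("corn_canned", process=ProcessingType.GENERAL_CANNING)
        params = StorageParams(1e-5, 10.0, {})
        assert storage_impacts(canned, "AA", params, _efs(AA=0.4)) == (0.0, 0.0)

    def test_frozen_storage_formula(self):
        frozen = _item("apricot_frozen", process=ProcessingType.FREEZING)
        params = StorageParams(1e-5, 10.0, {StorageClass.FROZEN_STORAGE: 0.0})
        freezing, refrigeration = storage_impacts(frozen, "AA", params, _efs(AA=0.4))
        assert freezing == pytest.approx(4e-5, rel=1e-12)  # (1e-5 * 10) * 0.4
        assert refrigeration == 0.0

    def test_frozen_display_added_to_long_term_storage(self):
        frozen = _item("apricot_frozen", process=ProcessingType.FREEZING)
        params = StorageParams(1e-5, 10.0, {StorageClass.FROZEN_STORAGE: 2e-5})
        freezing, _ = storage_impacts(frozen, "AA", params, _efs(AA=0.4))
        assert freezing == pytest.approx((1e-5 * 10 + 2e-5) * 0.4, rel=1e-12)

    def test_refrigerated_display_only(self):
        milk = _item("milk", builtin=True, storage=StorageClass.REFRIGERATED_DISPLAY,
                     category=FoodCategory.DAIRY)
        params = StorageParams(1e-5, 10.0, {StorageClass.REFRIGERATED_DISPLAY: 3e-5})
        freezing, refrigeration = storage_impacts(milk, "AA", params, _efs(AA=0.4))
        assert freezing == 0.0
        assert refrigeration == pytest.approx(3e-5 * 0.4, rel=1e-12)

    def test_storage_outputs_mutually_exclusive_across_catalog(self, bundle):
        for food in bundle.foods.values():
            fr, rf = storage_impacts(food, "AA", bundle.storage, bundle.efs)
            assert not (fr > 0 and rf > 0)

    def test_linear_in_consumer_electricity_ef(self):
        frozen = _item("apricot_frozen", process=ProcessingType.FREEZING)
        params = StorageParams(1e-5, 10.0, {StorageClass.FROZEN_STORAGE: 2e-5})
        efs = _efs(AA=0.2, BB=0.4)
        fa, _ = storage_impacts(frozen, "AA", params, efs)
        fb, _ = storage_impacts(frozen, "BB", params, efs)
        assert fb == pytest.approx(2 * fa, rel=1e-12)
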