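"""Mode selection and per-gram transport impact conversion."""
import pytest

from foodlca import (
    EmissionFactorSet,
    RouteLeg,
    TempClass,
    TransportAssignment,
    TransportMode,
    ValidationError,
    assign_route,
    transport_impact,
)
from foodlca.model import FoodCategory, ProcessingType


def _food_by(bundle, **attrs):
    for f in bundle.foods.values():
        if all(getattr(f, k) == v for k, v in attrs.items()):
            return f
    raise AssertionError(f"no catalog food with {attrs}")


def _pair(bundle, same_continent):
    iso = sorted(bundle.countries)
    for a in iso:
        for b in iso:
            if a != b and (
                (bundle.countries[a].continent == bundle.countries[b].continent)
                == same_continent
            ):
                return bundle.countries[a], bundle.countries[b]
    raise AssertionError("no such pair")


def test_domestic_supply_has_no_transport(bundle):
    food = next(iter(bundle.foods.values()))
    c = next(iter(bundle.countries.values()))
    assign = assign_route(food, c, c, bundle.ports)
    assert assign.legs == ()
    assert transport_impact(assign, bundle.efs) == 0.0


def test_same_continent_is_single_road_leg(bundle):
    a, b = _pair(bundle, same_continent=True)
    food = next(iter(bundle.foods.values()))
    assign = assign_route(food, a, b, bundle.ports, bundle.road_uplift)
    assert [leg.mode for leg in assign.legs] == [TransportMode.ROAD]


def test_air_perishable_flies_intercontinentally(bundle):
    food = _food_by(bundle, air_perishable=True)
    a, b = _pair(bundle, same_continent=False)
    assign = assign_route(food, a, b, bundle.ports)
    assert [leg.mode for leg in assign.legs] == [TransportMode.AIR]


def test_banana_like_tropical_fruit_goes_by_sea(bundle):
    food = _food_by(
        bundle, base_crop="banana", processing_type=ProcessingType.NONE,
    )
    assert not food.air_perishable
    a, b = _pair(bundle, same_continent=False)
    assign = assign_route(food, a, b, bundle.ports)
    assert [leg.mode for leg in assign.legs] == [
        TransportMode.ROAD, TransportMode.SEA, TransportMode.ROAD
    ]


def test_canned_goods_travel_ambient(bundle):
    food = _food_by(bundle, processing_type=ProcessingType.GENERAL_CANNING)
    a, b = _pair(bundle, same_continent=False)
    assign = assign_route(food, a, b, bundle.ports)
    assert assign.temp_class is TempClass.AMBIENT
    assert [leg.mode for leg in assign.legs] == [
        TransportMode.ROAD, TransportMode.SEA, TransportMode.ROAD
    ]


def test_meat_and_fish_travel_frozen(bundle):
    for cat in (FoodCategory.MEAT, FoodCategory.FISH_WILD, FoodCategory.FISH_AQUACULTURE):
        food = _food_by(bundle, category=cat)
        assert food.transport_temp_class is TempClass.FROZEN


def test_fresh_produce_and_dairy_travel_refrigerated(bundle):
    fresh = _food_by(
        bundle, category=FoodCategory.FRESH_PRODUCE, processing_type=ProcessingType.NONE
    )
    dairy = _food_by(bundle, category=FoodCategory.DAIRY)
    assert fresh.transport_temp_class is TempClass.REFRIGERATED
    assert dairy.transport_temp_class is TempClass.REFRIGERATED


def test_single_leg_impact_is_distance_times_ef():
    efs = EmissionFactorSet(
        elec={"GLO": 0.4},
        transport={(TransportMode.ROAD, TempClass.AMBIENT): 2e-7},
        steam_global=0.0,
    )
    assign = TransportAssignment(
        (RouteLeg(TransportMode.ROAD, 100.0),), TempClass.AMBIENT
    )
    assert transport_impact(assign, efs) == pytest.approx(2e-5, rel=1e-15)


def test_multi_leg_impact_matches_leg_by_leg_oracle(bundle):
    food = _food_by(bundle, processing_type=ProcessingType.GENERAL_CANNING)
    a, b = _pair(bundle, same_continent=False)
    assign = assign_route(food, a, b, bundle.ports)
    expected = sum(
        leg.distance_km * bundle.efs.transport[(leg.mode, assign.temp_class)]
        for leg in assign.legs
    )
    assert transport_impact(assign, bundle.efs) == pytest.approx(expected, rel=1e-15)


def test_missing_ef_error_names_pair():
    efs = EmissionFactorSet(elec={"GLO": 0.4}, transport={}, steam_global=0.0)
    assign = TransportAssignment(
        (RouteLeg(TransportMode.AIR, 5000.0),), TempClass.REFRIGERATED
    )
    with pytest.raises(ValidationError, match="air.*refrigerated"):
        transport_impact(assign, efs)


def test_impact_monotone_in_leg_distance(bundle):
    tc = TempClass.REFRIGERATED
    base = transport_impact(
        TransportAssignment((RouteLeg(TransportMode.ROAD, 100.0),), tc), bundle.efs
    )
    for d in (150.0, 500.0, 5000.0):
        bigger = transport_impact(
            TransportAssignment((RouteLeg(TransportMode.ROAD, d),), tc), bundle.efs
        )
        assert bigger >= base
        base = bigger


def test_generator_efs_ordered_by_temperature_class(bundle):
    for mode in TransportMode:
        amb = bundle.efs.transport[(mode, TempClass.AMBIENT)]
        ref = bundle.efs.transport[(mode, TempClass.REFRIGERATED)]
        fro = bundle.efs.transport[(mode, TempClass.FROZEN)]
        assert fro >= ref >= amb
        # identical legs therefore rank the same way
        legs = (RouteLeg(mode, 1234.5),)
        impacts = [
            transport_impact(TransportAssignment(legs, t), bundle.efs)
            for t in (TempClass.AMBIENT, TempClass.REFRIGERATED, TempClass.FROZEN)
        ]
        assert impacts == sorted(impacts)
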