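"""Mode selection and per-gram transport impact.

Domestic supply has no transport stage. Same-continent trade travels by
road between country centroids. Intercontinental trade goes port-routed by
sea — except air-perishable fresh items (berries, leafy vegetables and
similar), which fly centroid to centroid. The whole route uses the food's
single temperature class (frozen for meat and fish, refrigerated for fresh
produce and dairy, ambient for canned and dried goods).
"""
from __future__ import annotations

from dataclasses import dataclass

from .geography import RouteLegs, air_route, road_distance_km, sea_route, RouteLeg
from .model import (
    Country,
    EmissionFactorSet,
    FoodItem,
    PortNetwork,
    TempClass,
    TransportMode,
)


@dataclass(frozen=True)
class TransportAssignment:
    legs: RouteLegs
    temp_class: TempClass


def assign_route(
    food: FoodItem,
    prod: Country,
    cons: Country,
    ports: PortNetwork,
    road_uplift: float = 0.20,
) -> TransportAssignment:
    """Pick the route for a (food, producer, consumer) combination."""
    tc = food.transport_temp_class
    if prod.iso2 == cons.iso2:
        return TransportAssignment((), tc)
    if prod.continent == cons.continent:
        leg = RouteLeg(TransportMode.ROAD, road_distance_km(prod, cons, road_uplift))
        return TransportAssignment((leg,), tc)
    if food.air_perishable:
        return TransportAssignment(air_route(prod, cons), tc)
    return TransportAssignment(sea_route(prod, cons, ports, road_uplift), tc)


def transport_impact(assign: TransportAssignment, efs: EmissionFactorSet) -> float:
    """kgCO2eq per gram: sum over legs of distance x EF(mode, temp class)."""
    return sum(
        leg.distance_km * efs.transport_ef(leg.mode, assign.temp_class)
        for leg in assign.legs
    )
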