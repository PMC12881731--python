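"""Distance computation: great-circle centroid distances, road uplift,
port-routed sea paths, and centroid-to-centroid flight legs.

Road distance between two points is approximated as the great-circle
distance increased by a fixed uplift (default 20%) to account for road
networks not following straight lines. Intercontinental sea routes have
three legs: road to the production country's nearest port, ship between
ports (from an input distance matrix), and road from the receiving port to
the consumption country's centroid.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .model import Country, PortNetwork, TransportMode, ValidationError

#: IUGG mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088

#: Road-distance uplift over the straight-line great circle. The single
#: constant used everywhere a road leg is built.
DEFAULT_ROAD_UPLIFT = 0.20


@dataclass(frozen=True)
class RouteLeg:
    mode: TransportMode
    distance_km: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.distance_km) and self.distance_km >= 0):
            raise ValidationError(f"route leg distance {self.distance_km} invalid")


RouteLegs = tuple[RouteLeg, ...]


def _check_coords(p: tuple[float, float]) -> None:
    lat, lon = p
    if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
        raise ValidationError(f"coordinates ({lat}, {lon}) out of range")


def great_circle_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine distance in km between two (lat, lon) points in degrees,
    on a sphere of radius 6371.0088 km."""
    _check_coords(a)
    _check_coords(b)
    lat1, lon1 = map(math.radians, a)
    lat2, lon2 = map(math.radians, b)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = math.sin(dlat / 2.0) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def road_distance_km(a: Country, b: Country, uplift: float = DEFAULT_ROAD_UPLIFT) -> float:
    """Road distance proxy between two country centroids: great circle
    scaled by (1 + uplift)."""
    return (1.0 + uplift) * great_circle_km(a.centroid, b.centroid)


def sea_route(
    a: Country, b: Country, ports: PortNetwork, uplift: float = DEFAULT_ROAD_UPLIFT
) -> RouteLegs:
    """Port-routed intercontinental path: road feeder to the outgoing port,
    ship between nearest ports, road from the receiving port to the
    consuming country's centroid. Feeder legs carry the road uplift."""
    pa, pb = a.nearest_port, b.nearest_port
    for pid in (pa, pb):
        if pid not in ports.ports:
            raise ValidationError(f"port {pid!r} has no coordinates in the port table")
    leg_out = (1.0 + uplift) * great_circle_km(a.centroid, ports.ports[pa])
    leg_sea = ports.distance(pa, pb)
    leg_in = (1.0 + uplift) * great_circle_km(ports.ports[pb], b.centroid)
    return (
        RouteLeg(TransportMode.ROAD, leg_out),
        RouteLeg(TransportMode.SEA, leg_sea),
        RouteLeg(TransportMode.ROAD, leg_in),
    )


def air_route(a: Country, b: Country) -> RouteLegs:
    """Single centroid-to-centroid flight leg; no road feeders."""
    return (RouteLeg(TransportMode.AIR, great_circle_km(a.centroid, b.centroid)),)
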