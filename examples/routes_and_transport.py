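"""Route construction and transport impacts for contrasting foods.

Shows how the same country pair yields different routes: same-continent
trade is a single uplifted road leg; intercontinental canned goods go
road-sea-road through nearest ports at ambient temperature; an
air-perishable berry flies centroid to centroid.
"""
from foodlca import assign_route, generate_bundle, transport_impact

bundle = generate_bundle(seed=1)
iso = sorted(bundle.countries)
same = next(
    (a, b) for a in iso for b in iso
    if a < b and bundle.countries[a].continent == bundle.countries[b].continent
)
inter = next(
    (a, b) for a in iso for b in iso
    if bundle.countries[a].continent != bundle.countries[b].continent
)

foods = {
    "canned": next(f for f in bundle.foods.values() if "canned" in f.id),
    "air-perishable fresh": next(f for f in bundle.foods.values() if f.air_perishable),
}

for label, food in foods.items():
    for pair in (same, inter):
        a, b = (bundle.countries[p] for p in pair)
        assign = assign_route(food, a, b, bundle.ports, bundle.road_uplift)
        legs = ", ".join(f"{l.mode.value} {l.distance_km:.0f} km" for l in assign.legs)
        impact = transport_impact(assign, bundle.efs)
        print(f"{food.display_name:22} {pair[0]}->{pair[1]} "
              f"[{assign.temp_class.value:12}] {legs:55} -> {impact:.2e} kgCO2eq/g")

print("\nEach leg's impact is distance x mode/temperature emission factor;")
print("domestic supply would have no legs and zero transport impact.")
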