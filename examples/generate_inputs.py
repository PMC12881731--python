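"""Generate a synthetic input bundle and write it to disk as CSV tables.

The bundle emulates the structure of the real sources: country centroids
grouped into continents with nearest ports and a sea-distance matrix,
log-uniform electricity emission factors, a cultivation table with
partial country coverage plus Rest-of-World fallback rows, crop
water-demand calendars, and a catalog mixing raw produce, processed
variants and animal products.
"""
from collections import Counter

from foodlca import generate_bundle, write_bundle

bundle = generate_bundle(seed=1)
cfg = write_bundle(bundle, "scratch/example_bundle")

print(f"wrote config + {13} tables to {cfg.parent}/")
print(f"countries: {len(bundle.countries)} over "
      f"{len({c.continent for c in bundle.countries.values()})} continents")
print(f"foods: {len(bundle.foods)}")
print("  by processing:", dict(Counter(f.processing_type.value for f in bundle.foods.values())))
print(f"cultivation rows: {len(bundle.cultivation.entries)} country-specific, "
      f"{len(bundle.cultivation.row_fallback)} Rest-of-World fallbacks")
print(f"electricity EF range: {min(bundle.efs.elec.values()):.3f}-"
      f"{max(bundle.efs.elec.values()):.3f} kgCO2eq/kWh")
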