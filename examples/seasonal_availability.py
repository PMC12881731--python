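"""Seasonal availability: harvest months versus shelf months.

For a fresh item the consumption window is the harvest window (months
with positive crop water demand) shifted forward by two months; the
frozen variant of the same crop is on the shelf all year wherever the
crop is grown at all.
"""
from foodlca import availability, generate_bundle, harvest_months
from foodlca.model import MONTH_NAMES, ProcessingType

bundle = generate_bundle(seed=1)
fresh = next(
    f for f in bundle.foods.values()
    if f.base_crop == "apricot" and f.processing_type is ProcessingType.NONE
)
frozen = next(
    f for f in bundle.foods.values()
    if f.base_crop == "apricot" and f.processing_type is ProcessingType.FREEZING
)


def names(months):
    return ", ".join(MONTH_NAMES[m - 1][:3] for m in sorted(months)) or "-"


for country in bundle.calendar.countries_for("apricot"):
    hm = harvest_months(bundle.calendar, "apricot", country)
    print(f"{country}: harvest [{names(hm)}]")
    print(f"    fresh on shelf  [{names(availability(fresh, country, bundle.calendar))}]")
    print(f"    frozen on shelf [{names(availability(frozen, country, bundle.calendar))}]")

print("\nThe fresh window is the harvest window shifted +2 months (with")
print("December wrapping into the new year); processing removes seasonality.")
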