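"""Worked example: apricots consumed in Spain in August.

Builds the minimal two-country fixture (Spain and Italy, same continent)
and assembles the four records a consumer sheet would hold: fresh and
frozen apricots, domestic and imported. Domestic fresh collapses to pure
production; imported fresh splits between production and transport;
frozen variants add processing (producer electricity) and freezing
storage (consumer electricity); refrigeration and home cooking stay zero.
"""
from foodlca import STAGES, build_record, table1_fixture

bundle = table1_fixture()

header = f"{'Food':18} {'Prod':>4} " + " ".join(f"{s[:9].title():>10}" for s in STAGES) + f" {'Total kg/g':>12}"
print(header)
for fid in ("apricot_fresh", "apricot_frozen"):
    for prod in ("ES", "IT"):
        rec = build_record(bundle.foods[fid], prod, "ES", 8, bundle)
        pcts = " ".join(f"{rec.stage_pct[s]:9.0f}%" for s in STAGES)
        print(f"{rec.display_name:18} {prod:>4} {pcts} {rec.total:12.6f}")

print("\nPercentages are each stage's share of the cradle-to-plate total;")
print("the total is kgCO2eq per gram of apricot as purchased in Spain.")
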