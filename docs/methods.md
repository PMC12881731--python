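# Methods

## Functional unit and units

All impacts are expressed per **1 gram of food as consumed** (kgCO₂eq/g,
GWP100). Electricity is kWh, steam MJ, distance km. Months are 1-based;
sheet names are English month names. Percentages are stored at full
floating precision; rounding to integers (as a presentation choice) is a
writer option, off by default.

## Stage models

**Production.** A lookup table (food, country) → kgCO₂eq/g. Coverage of
real cultivation databases is partial, so every food carries a
Rest-of-World fallback row used for any producing country without a
specific value. A missing fallback row is a load-time error: every food
must be computable for every producer.

**Transport.** Routes are built from country centroids and a port network:

- domestic: no legs — in-country distribution is excluded, which will
  understate impacts for very large countries;
- same continent: one road leg, great-circle centroid distance × (1 + u)
  with u = 0.20 (a single configuration constant used for every road leg,
  including port feeders);
- different continents: road feeder to the producer's nearest port, sea
  leg from an input port-to-port distance matrix, road feeder from the
  receiving port to the consuming centroid;
- air-perishable fresh items (berry- and leafy-vegetable-like; the
  banana-like tropical fruit is deliberately excluded) instead fly one
  centroid-to-centroid leg, with no airport feeder legs — the flight
  distance is taken literally as the great circle.

Great-circle distances use the haversine formula on the IUGG mean sphere,
R = 6371.0088 km. Each leg contributes distance × EF(mode, temperature
class), with one temperature class per food for the whole route: frozen
for meat and fish (thawing on arrival carries no energy term), refrigerated
for fresh produce and dairy (including intercontinental sea-refrigerated
dairy), ambient for canned and dried goods. Transport EFs are expressed in
kgCO₂eq per gram·km so the functional unit needs no conversion
(literature magnitudes per tonne-km ÷ 10⁶).

**Processing.** Eight categories (bread, pasta, breakfast cereal, large
fish canning, small fish canning, general canning, freezing, dehydrating),
each with an average electricity and steam intensity per gram. Impact =
elec × producer grid EF + steam × global steam EF. A country missing from
the electricity table falls back to the designated global-average row.
Items with processing built into the production value (milk, cheese,
processed meat) are flagged `processing_builtin` and add nothing.

**Home cooking.** Energy per gram (global constant per cooking class) ×
consumer grid EF, independent of origin. Dried beans have their own class
with strictly higher energy (enforced at load) for their extended cooking
time. Gas and wood fuels, and cooking-method differences, are out of scope.

**Storage.** Frozen items: (monthly storage rate × 10 months + frozen
display energy) × consumer grid EF, reported as the *freezing* stage.
Refrigerated-display items (fresh meat, dairy, eggs, some produce):
display energy × consumer grid EF, the *refrigeration* stage. The two are
mutually exclusive by construction. Fresh fruit and vegetables carry no
long-term storage energy — display only, if classed for it.

**Assembly.** Total = Σ six stages; percentage shares = 100 × stage/total.
A zero total is an error rather than a 0/0 percentage — every real food
has positive production impact. Records are enumerated per (consumer,
month) over every (food, producer) pair whose availability set contains
the month, ordered by food id then producer code; sheets are sorted by
display name then producer for stable output. Consumer-side stages
(cooking, freezing, refrigeration) are identical across producers of the
same food; producer-side stages (production, processing) are identical
across consumers.

## Seasonality

Harvest months are the months with **positive crop water demand** in the
(crop, country) calendar — a declared interpretation; the underlying idea
is that generic water-demand calendars proxy growing seasons where true
harvest data are unavailable. Fresh produce is available in the harvest
months **shifted forward by two** on the 12-month cycle (a bijection, so a
3-month season stays a 3-month window, December wrapping into February).
Items processed for shelf life are available in all 12 months in every
country that grows the base crop; animal products, dairy, eggs and
substitutes are available everywhere year-round. A fresh item whose crop
has no calendar is excluded from that country with a logged warning.
Greenhouse production, which decouples availability from open-field
calendars, is out of scope.

## Synthetic data generator

The generator exists so the whole pipeline can run and be tested without
any proprietary or external source. It emulates structure, not values:

- **Geography** — continents as disjoint longitude bands; country
  centroids sampled within their band; one to two ports per continent;
  each country assigned its geometrically nearest port; sea distances =
  port great-circle × a detour factor ≥ 1 (sampled 1.05–1.6), symmetric
  with zero diagonal.
- **Emission factors** — electricity log-uniform on [0.02, 1.2]
  kgCO₂eq/kWh (the span from hydro-dominated to coal-dominated grids),
  plus a global-average row (geometric mean). Transport EF bases per mode
  near 1×10⁻⁷ (road), 1.2×10⁻⁸ (sea), 6×10⁻⁷ (air) kgCO₂eq/(g·km), with
  refrigerated and frozen multipliers ordered frozen > refrigerated >
  ambient.
- **Cultivation** — lognormal around category medians (fresh produce
  4×10⁻⁴ up to meat 1.2×10⁻², kgCO₂eq/g); a `coverage` fraction of each
  food's producers get country rows, the fallback is their geometric mean.
- **Calendars** — one or two contiguous runs of 2–5 months of positive
  demand per (crop, country).
- **Catalog** — raw + frozen + canned + dried variants over a crop pool
  (including air-perishable berry-like items and a banana-like exclusion),
  plus meat, wild and farmed fish, canned large/small fish, dairy with
  built-in processing, eggs, a meat substitute, dried beans, and grain
  products covering all eight process categories. Default size 40 foods,
  12 countries, 3 continents (seconds-scale tests); a "paper" profile (85
  countries, 6 continents, 500 foods) reproduces output shape at scale.
- **Energies** — processing electricity 2–8×10⁻⁴ kWh/g and steam 1–2×10⁻³
  MJ/g by category; cooking 8×10⁻⁴ kWh/g standard, ×2–3.5 for dried
  beans; frozen storage 6×10⁻⁵ kWh/(g·month) over 10 months; display
  1.2×10⁻⁴ (frozen) and 5×10⁻⁵ (refrigerated) kWh/g — all lognormal
  around these medians. These magnitudes are plausible for household and
  industrial food energy use, but the pipeline's correctness is defined
  over arbitrary nonnegative values, and none of the numeric energy
  intensities claims to match a specific published inventory.
- **Nutrients** — six per-gram columns with free-form units in the header;
  processed variants derived from the raw profile via retention factors in
  [0,1] (vitamin C losing the most under canning and drying); absent
  retention entries mean full retention.

What passing tests on synthetic data do **not** show: agreement with real
cultivation databases, real trade routes or real sea distances; the
generator guarantees structure (coverage gaps, seasons, EF spreads,
orderings), not real-world magnitudes.

`table1_fixture()` is a hand-built two-country bundle (Spain- and
Italy-like, same continent, fresh and frozen apricots, overlapping summer
harvests) used to assert the *structural* stage pattern of the worked
consumption example — domestic fresh → 100% production; imported fresh →
production + transport only; frozen → adds processing and freezing; home
cooking and refrigeration zero throughout. Its stage-level magnitudes are
free parameters, not reference values.

## Numerical choices

- Haversine clamped before `asin`/`acos` to dodge domain errors at
  antipodes; triangle inequality holds to 1×10⁻⁶ km in tests.
- Record invariants: Σ stages = total to 1×10⁻¹² relative; Σ percentages
  = 100 to 1×10⁻⁹ absolute.
- CSV round-trip is exact: floats written with `%.17g` and read with
  round-trip parsing, so `load(write(bundle))` reproduces every table
  bit-for-bit.
- Determinism: one `numpy` Generator seeded once; identical seed and
  config give byte-identical CSV outputs.
- Dehydration keeps the per-gram basis of the final product; no mass
  concentration factor is applied to the cultivation value of dried items,
  which understates their per-gram production impact.

## Problem sizes

The default test and acceptance runs use the 12-country × 40-food bundle
(~2,900 records per consumer-year, ~35,000 for all twelve consumers),
which exercises every code path including Rest-of-World fallback, all
three transport modes, all temperature classes and all eight process
categories. The 85-country × 500-food profile is available through the
generator and CLI for shape-scale runs.

## Known limitations

- In-country distribution and last-mile retail transport are excluded.
- No trade-volume weighting: every possible origin is enumerated, not a
  weighted national supply mix.
- Food losses, greenhouse production, gas/wood cooking and fresh-produce
  long-term storage are out of scope.
- Air routes have no airport feeder legs; sea legs assume a single port
  pair with no transshipment.
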