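# foodlca

Regionalized cradle-to-plate climate-change impacts of food items, per
production country, consumption country, and month — with the contribution
of every life-cycle stage broken out, and a per-gram nutrient table
alongside.

## The problem

The climate impact of "a gram of apricots" is not one number. It depends on
where the apricots were grown (country-specific cultivation impacts), how
they reached the consumer (road, sea, or air, under ambient, refrigerated,
or frozen conditions), whether they were processed for shelf life (freezing,
canning, drying — powered by the producing country's electricity mix), how
long they sat in frozen storage and retail display (the consuming country's
electricity), and whether they need home cooking. It also depends on the
month: fresh produce is only on the shelf in the window that follows its
harvest, so off-season consumption means either long-distance imports or
processed, stored alternatives. This package computes that full breakdown
for every (food, production country, consumption country, month)
combination, so fresh-import versus local-processed trade-offs can be
compared directly.

## The model

For food *f* produced in country *p*, consumed in country *c* in month *m*,
the total impact per gram (kgCO₂eq/g, GWP100) is the sum of six stages:

```
I_total = I_prod(f,p) + I_transp(f,p,c) + I_proc(f,p) + I_cook(f,c) + I_freeze(f,c) + I_refrig(f,c)
```

- **Production** — a cultivation-impact lookup per (food, country), falling
  back to a Rest-of-World row when no country-specific value exists.
- **Transport** — Σ legs d·EF(mode, temp class). Domestic supply: no legs.
  Same continent: one road leg, the centroid great-circle distance × 1.2
  (straight lines understate driving distance by ~20%). Different
  continents: road to the nearest port, ship between ports (input distance
  matrix), road to the consuming centroid — except air-perishable fresh
  items (berries, leafy vegetables, …), which fly centroid to centroid.
  Meat and fish travel frozen, fresh produce and dairy refrigerated,
  canned/dried goods ambient.
- **Processing** — for eight industrial categories (bread, pasta, breakfast
  cereals, large/small fish canning, general canning, freezing,
  dehydrating): electricity per gram × producer-country grid EF + steam per
  gram × a global steam EF. Foods whose processing is already inside the
  production value (milk, cheese, processed meat) add nothing here.
- **Home cooking** — energy per gram × consumer-country grid EF; dried
  beans form their own, more energy-intensive class.
- **Freezing / refrigeration** — frozen items: 10 months of frozen storage
  plus frozen display, on the consumer grid; refrigerated-display items:
  display energy only; mutually exclusive.

Seasonality: a crop's harvest months are the months with positive crop
water demand; fresh produce is available those months **shifted forward by
two** (harvest → shelf); processed variants and animal products are
available year-round.

Each record carries the six stage impacts, the total, and each stage's
percentage share of the total.

## Worked example

Apricots consumed in Spain in August, on the built-in two-country fixture
(`python examples/apricot_worked_example.py`):

```
Food               Prod  Productio  Transport  Processin  Home_Cook   Freezing  Refrigera   Total kg/g
Apricots, fresh      ES       100%         0%         0%         0%         0%         0%     0.000150
Apricots, fresh      IT        36%        64%         0%         0%         0%         0%     0.000289
Apricots, frozen     ES        27%         0%        41%         0%        32%         0%     0.000555
Apricots, frozen     IT        12%        26%        41%         0%        21%         0%     0.000844
```

Domestic fresh apricots are pure production. Imported fresh ones split
between production and road transport. Frozen variants add processing
(producer electricity) and freezing storage (consumer electricity) — the
price of year-round availability. Home cooking and refrigeration are zero
for all four rows.

## Usage

```python
from foodlca import generate_bundle, run_pipeline

bundle = generate_bundle(seed=1)          # synthetic 12-country, 40-food inputs
run_pipeline(bundle, "out/", consumers=["AA", "AB"])
```

writes one workbook per consumer country (12 monthly sheets; columns:
Food_Item, six stage percentages, GHG_Impact_total, Production_Country,
Consumption_Country) plus a `Food_Nutrients` table. The same flow from the
shell:

```bash
foodlca generate --seed 1 --out bundle/
foodlca run --config bundle/config.yaml --out out/ --consumers AA,AB --csv
```

Real input tables (cultivation impacts, emission factors, sea distances,
crop calendars, …) can replace the synthetic ones: they are plain CSV files
named in `config.yaml`. The `examples/` directory has one short script per
capability.

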