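"""End-to-end run: synthetic bundle -> per-consumer monthly workbooks.

Generates the default 12-country, 40-food bundle, runs the full pipeline
for two consumer countries, and peeks at one June sheet. Equivalent CLI:

    foodlca generate --seed 1 --out scratch/bundle
    foodlca run --config scratch/bundle/config.yaml --out scratch/out --consumers AA,AB
"""
import openpyxl

from foodlca import generate_bundle, run_pipeline

bundle = generate_bundle(seed=1)
paths = run_pipeline(bundle, "scratch/pipeline_out", consumers=["AA", "AB"])
print("wrote:", ", ".join(p.name for p in paths))

wb = openpyxl.load_workbook("scratch/pipeline_out/AA.xlsx")
ws = wb["June"]
print(f"\nAA.xlsx has {len(wb.sheetnames)} sheets; June holds {ws.max_row - 1} records")
print("first rows (stage shares in %, total in kgCO2eq/g):")
for row in list(ws.iter_rows(min_row=2, max_row=4, values_only=True)):
    name, *pcts, total, prod, cons = row[0], *row[1:7], row[7], row[8], row[9]
    shares = "/".join(f"{p:.0f}" for p in pcts)
    print(f"  {name:24} {shares:>22}  {total:.2e}  {prod}->{cons}")
print("\nEach record is one (food, producing country) option available to the")
print("consumer that month; several rows per food = several possible origins.")
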