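"""Table loading/validation, workbook layout, and round-trip fidelity."""
import dataclasses

import numpy as np
import openpyxl
import pandas as pd
import pytest

from foodlca import (
    MONTH_NAMES,
    NutrientProfile,
    ValidationError,
    build_record,
    load_inputs,
    write_bundle,
    write_consumer_workbook,
    write_nutrient_table,
)
from foodlca.schema_io import OUTPUT_COLUMNS


def test_bundle_round_trips_through_csv_exactly(bundle, tmp_path):
    cfg = write_bundle(bundle, tmp_path / "in")
    again = load_inputs(cfg)
    assert again.efs.elec == bundle.efs.elec
    assert again.efs.transport == bundle.efs.transport
    assert again.efs.steam_global == bundle.efs.steam_global
    assert again.cultivation.entries == bundle.cultivation.entries
    assert again.cultivation.row_fallback == bundle.cultivation.row_fallback
    assert again.foods == bundle.foods
    assert again.countries == bundle.countries
    assert again.recipes.recipes == bundle.recipes.recipes
    assert again.cooking.energy_kwh_per_g == bundle.cooking.energy_kwh_per_g
    assert again.storage.frozen_kwh_per_g_per_month == bundle.storage.frozen_kwh_per_g_per_month
    assert again.storage.display_kwh_per_g == bundle.storage.display_kwh_per_g
    for key, vec in bundle.calendar.demand.items():
        assert np.array_equal(again.calendar.demand[key], vec)
    assert np.array_equal(
        again.ports.sea_km.to_numpy(), bundle.ports.sea_km.to_numpy()
    )
    for fid, vec in bundle.nutrients.values.items():
        assert np.array_equal(again.nutrients.values[fid], vec)
    assert again.retention.factors == bundle.retention.factors
    assert again.consumers == bundle.consumers
    assert again.road_uplift == bundle.road_uplift


def test_missing_table_is_fatal_with_table_name(bundle, tmp_path):
    cfg = write_bundle(bundle, tmp_path)
    (tmp_path / "cooking_energy.csv").unlink()
    with pytest.raises(ValidationError, match="cooking_energy"):
        load_inputs(cfg)


def test_missing_fallback_row_names_the_food(bundle, tmp_path):
    cfg = write_bundle(bundle, tmp_path)
    df = pd.read_csv(tmp_path / "cultivation.csv")
    victim = df[df.country == "ROW"].food_id.iloc[0]
    df[~((df.country == "ROW") & (df.food_id == victim))].to_csv(
        tmp_path / "cultivation.csv", index=False
    )
    with pytest.raises(ValidationError, match=victim):
        load_inputs(cfg)


def test_missing_transport_ef_coverage_is_fatal(bundle, tmp_path):
    # some catalog item flies refrigerated; drop that EF row
    cfg = write_bundle(bundle, tmp_path)
    df = pd.read_csv(tmp_path / "transport_ef.csv")
    df[~((df["mode"] == "air") & (df.temp_class == "refrigerated"))].to_csv(
        tmp_path / "transport_ef.csv", index=False
    )
    with pytest.raises(ValidationError, match="air.*refrigerated"):
        load_inputs(cfg)


def test_unknown_enum_value_is_fatal(bundle, tmp_path):
    cfg = write_bundle(bundle, tmp_path)
    df = pd.read_csv(tmp_path / "foods.csv")
    df.loc[0, "category"] = "snack"
    df.to_csv(tmp_path / "foods.csv", index=False)
    with pytest.raises(ValidationError, match="snack"):
        load_inputs(cfg)


def test_valid_generated_bundle_loads_without_error(bundle, tmp_path):
    cfg = write_bundle(bundle, tmp_path)
    loaded = load_inputs(cfg)
    loaded.validate()


class TestWorkbook:
    def _records(self, fixture_bundle):
        b = fixture_bundle
        return [
            build_record(b.foods[fid], prod, "ES", month, b)
            for month in (7, 8, 9)
            for fid in ("apricot_fresh", "apricot_frozen")
            for prod in ("ES", "IT")
        ]

    def test_workbook_always_has_12_monthly_sheets(self, fixture_bundle, tmp_path):
        path = write_consumer_workbook(self._records(fixture_bundle), "ES", tmp_path)
        wb = openpyxl.load_workbook(path)
        assert wb.sheetnames == list(MONTH_NAMES)
        assert path.name == "ES.xlsx"

    def test_empty_record_list_gives_12_header_only_sheets(self, tmp_path):
        path = write_consumer_workbook([], "CH", tmp_path)
        wb = openpyxl.load_workbook(path)
        assert len(wb.sheetnames) == 12
        for name in wb.sheetnames:
            ws = wb[name]
            assert ws.max_row == 1
            assert [c.value for c in ws[1]] == list(OUTPUT_COLUMNS)

    def test_august_sheet_contains_the_four_apricot_rows(self, fixture_bundle, tmp_path):
        path = write_consumer_workbook(self._records(fixture_bundle), "ES", tmp_path)
        ws = openpyxl.load_workbook(path)["August"]
        rows = list(ws.iter_rows(min_row=2, values_only=True))
        assert len(rows) == 4
        assert {r[8] for r in rows} == {"IT", "ES"}
        assert all(r[9] == "ES" for r in rows)

    def test_csv_mode_writes_12_monthly_files(self, fixture_bundle, tmp_path):
        dest = write_consumer_workbook(
            self._records(fixture_bundle), "ES", tmp_path, csv=True
        )
        files = sorted(p.name for p in dest.iterdir())
        assert files == sorted(f"ES_{m}.csv" for m in MONTH_NAMES)
        df = pd.read_csv(dest / "ES_August.csv")
        assert list(df.columns) == list(OUTPUT_COLUMNS)
        assert len(df) == 4

    def test_foreign_record_rejected(self, fixture_bundle, tmp_path):
        b = fixture_bundle
        rec = build_record(b.foods["apricot_fresh"], "ES", "ES", 8, b)
        with pytest.raises(ValidationError):
            write_consumer_workbook([rec], "IT", tmp_path)

    def test_out_of_range_month_rejected(self, fixture_bundle, tmp_path):
        b = fixture_bundle
        rec = build_record(b.foods["apricot_fresh"], "ES", "ES", 8, b)
        bad = dataclasses.replace(rec, month=13)
        with pytest.raises(ValidationError):
            write_consumer_workbook([bad], "ES", tmp_path)


class TestNutrientTable:
    def test_one_row_per_food(self, tmp_path):
        profile = NutrientProfile(
            nutrients=["protein_g"],
            values={"a": np.array([0.1]), "b": np.array([0.2]), "c": np.array([0.0])},
        )
        path = write_nutrient_table(profile, tmp_path)
        assert path.name == "Food_Nutrients.xlsx"
        ws = openpyxl.load_workbook(path).active
        rows = list(ws.iter_rows(min_row=2, values_only=True))
        assert len(rows) == 3

    def test_zero_amount_written_as_zero_not_blank(self, tmp_path):
        profile = NutrientProfile(nutrients=["protein_g"], values={"a": np.array([0.0])})
        path = write_nutrient_table(profile, tmp_path, csv=True)
        df = pd.read_csv(path)
        assert df.loc[0, "protein_g"] == 0.0
        assert not df.protein_g.isna().any()

    def test_catalog_food_missing_from_profile_is_fatal(self, bundle):
        incomplete = NutrientProfile(
            nutrients=bundle.nutrients.nutrients,
            values={
                k: v for k, v in bundle.nutrients.values.items()
                if k != sorted(bundle.nutrients.values)[0]
            },
        )
        with pytest.raises(ValidationError):
            incomplete.validate(set(bundle.foods))
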