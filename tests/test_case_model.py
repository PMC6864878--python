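"""Case representation, validation, standardization and I/O round-trips."""

import dataclasses
import json

import numpy as np
import pytest

from tricase.case_model import (
    CaseBase,
    CaseRecord,
    CaseValidationError,
    Standardizer,
    default_schema,
    import_deposited_case_base,
    load_case_base,
    save_case_base,
    standardize_case,
    validate_case,
)
from tricase.measures import DegenerateVectorError, tsm_raw
from tricase.synthetic_cases import GenerationConfig, generate_case_base


class TestValidation:
    def test_printed_test_case_is_valid(self, new_case_1):
        assert validate_case(new_case_1) is new_case_1
        assert new_case_1.humidity == pytest.approx(0.5749)
        assert new_case_1.rainfall == pytest.approx(0.7215)

    def test_out_of_range_humidity(self, new_case_1):
        bad = dataclasses.replace(new_case_1, humidity=1.7)
        with pytest.raises(CaseValidationError, match="humidity"):
            validate_case(bad)

    def test_unknown_pest_stage(self, new_case_1):
        bad = dataclasses.replace(new_case_1, pest_stage="Imago")
        with pytest.raises(CaseValidationError, match="pest_stage"):
            validate_case(bad)

    def test_inverted_temperature_interval(self, new_case_1):
        bad = dataclasses.replace(new_case_1, temperature=(30.0, 21.0))
        with pytest.raises(CaseValidationError, match="temperature"):
            validate_case(bad)

    def test_all_violations_reported_together(self, new_case_1):
        bad = dataclasses.replace(
            new_case_1, humidity=2.0, pest_stage="Imago", pest_quantity=-5
        )
        with pytest.raises(CaseValidationError) as exc:
            validate_case(bad)
        assert len(exc.value.errors) == 3


class TestStandardization:
    def test_range_midpoint_maps_to_half(self, new_case_1):
        case = dataclasses.replace(new_case_1, planting_density=352.5)
        vec = standardize_case(case).vector
        assert vec[4] == pytest.approx(0.5)  # planting_density slot

    def test_ordinal_endpoints(self, new_case_1):
        egg = dataclasses.replace(new_case_1, pest_stage="Egg")
        adult = dataclasses.replace(new_case_1, pest_stage="Adult")
        assert standardize_case(egg).vector[1] == 0.0
        assert standardize_case(adult).vector[1] == 1.0

    def test_numeric_range_endpoints_map_to_unit_interval(self, new_case_1):
        schema = default_schema()
        lo_case = dataclasses.replace(
            new_case_1,
            pest_quantity=309, infected_area=56, planting_density=180,
            temperature=(15.0, 24.0), humidity=0.2573, rainfall=0.1250,
            sunlight=831, wind_speed=0,
        )
        vec = standardize_case(lo_case, schema).vector
        numeric_slots = [0, 2, 4, 5, 6, 7, 8, 9, 10]
        assert all(vec[i] == 0.0 for i in numeric_slots)
        hi_case = dataclasses.replace(
            new_case_1,
            pest_quantity=458, infected_area=168, planting_density=525,
            temperature=(22.0, 32.0), humidity=0.8706, rainfall=0.8290,
            sunlight=4830, wind_speed=12,
        )
        vec = standardize_case(hi_case, schema).vector
        assert all(vec[i] == 1.0 for i in numeric_slots)

    def test_dimension_is_eleven(self, new_case_1):
        assert standardize_case(new_case_1).vector.shape == (11,)
        assert default_schema().dimension == 11

    def test_transform_is_deterministic(self, new_case_1):
        std = Standardizer()
        v1 = std.transform(new_case_1).vector
        v2 = std.transform(new_case_1).vector
        np.testing.assert_array_equal(v1, v2)

    def test_monotone_per_attribute(self, new_case_1):
        lo = dataclasses.replace(new_case_1, sunlight=1000)
        hi = dataclasses.replace(new_case_1, sunlight=4000)
        assert standardize_case(lo).vector[9] < standardize_case(hi).vector[9]

    def test_out_of_range_value_clipped(self, new_case_1, caplog):
        wild = dataclasses.replace(new_case_1, sunlight=99999)
        with caplog.at_level("WARNING"):
            vec = standardize_case(wild).vector
        assert vec[9] == 1.0
        assert "clipped" in caplog.text

    def test_all_minimum_record_is_degenerate_for_angles(self, new_case_1):
        floor = dataclasses.replace(
            new_case_1,
            pest_quantity=309, pest_stage="Egg", infected_area=56,
            growth_stage="Vege", planting_density=180,
            temperature=(15.0, 24.0), humidity=0.2573, rainfall=0.1250,
            sunlight=831, wind_speed=0,
        )
        vec = standardize_case(floor).vector
        assert not np.any(vec)
        with pytest.raises(DegenerateVectorError):
            tsm_raw(vec, standardize_case(new_case_1).vector)

    def test_zscore_scheme(self, synthetic_base):
        std = Standardizer(scheme="zscore").fit(synthetic_base.cases)
        vecs = np.array([std.transform(c).vector for c in synthetic_base.cases])
        np.testing.assert_allclose(vecs.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(vecs.std(axis=0), 1.0, atol=1e-9)

    def test_zscore_requires_fit(self, new_case_1):
        with pytest.raises(RuntimeError):
            Standardizer(scheme="zscore").transform(new_case_1)

    def test_unknown_scheme(self):
        with pytest.raises(ValueError):
            Standardizer(scheme="robust")


class TestCaseBaseIO:
    @pytest.mark.parametrize("fmt", ["json", "csv"])
    def test_round_trip_synthetic_base(self, tmp_path, fmt):
        base = generate_case_base(GenerationConfig(n_past=50, seed=5))
        path = tmp_path / f"base.{fmt}"
        save_case_base(base, path)
        loaded = load_case_base(path)
        assert loaded.cases == base.cases

    def test_csv_and_json_twins_load_identically(self, tmp_path, small_base):
        save_case_base(small_base, tmp_path / "b.json")
        save_case_base(small_base, tmp_path / "b.csv")
        assert load_case_base(tmp_path / "b.json").cases == load_case_base(
            tmp_path / "b.csv"
        ).cases

    @pytest.mark.parametrize("fmt", ["json", "csv"])
    def test_empty_base_round_trips(self, tmp_path, fmt):
        path = tmp_path / f"empty.{fmt}"
        save_case_base(CaseBase(cases=[]), path)
        assert len(load_case_base(path)) == 0

    def test_mixed_pest_types_preserve_order(self, tmp_path, small_base):
        path = tmp_path / "b.json"
        save_case_base(small_base, path)
        loaded = load_case_base(path)
        assert [c.pest_type for c in loaded] == ["RP", "RP", "CS", "RP"]

    def test_duplicate_ids_rejected(self, new_case_1):
        twin = dataclasses.replace(new_case_1, sunlight=2000)
        with pytest.raises(ValueError, match="duplicate"):
            CaseBase(cases=[new_case_1, twin])

    def test_csv_without_id_column_assigns_row_order(self, tmp_path, small_base):
        path = tmp_path / "b.csv"
        save_case_base(small_base, path)
        text = path.read_text().splitlines()
        header = text[0].split(",")
        drop = header.index("case_id")
        stripped = "\n".join(
            ",".join(v for i, v in enumerate(line.split(",")) if i != drop)
            for line in text
        )
        (tmp_path / "noid.csv").write_text(stripped + "\n")
        loaded = load_case_base(tmp_path / "noid.csv")
        assert [c.case_id for c in loaded] == [1, 2, 3, 4]

    def test_malformed_csv_reports_row(self, tmp_path, small_base):
        path = tmp_path / "b.csv"
        save_case_base(small_base, path)
        broken = path.read_text().replace("Pupae", "")
        (tmp_path / "broken.csv").write_text(broken)
        with pytest.raises((ValueError, CaseValidationError)):
            load_case_base(tmp_path / "broken.csv")

    def test_percent_strings_accepted_in_json(self, tmp_path, new_case_1):
        doc = {"cases": [{**new_case_1.to_dict(), "humidity": "57.49%"}]}
        path = tmp_path / "p.json"
        path.write_text(json.dumps(doc))
        assert load_case_base(path).cases[0].humidity == pytest.approx(0.5749)


class TestRetention:
    def test_retain_assigns_next_free_id(self, small_base, new_case_1):
        solved = dataclasses.replace(new_case_1, solution="Apply X at 1 mL/ha")
        stored = small_base.retain(solved)
        assert stored.case_id == 5
        assert small_base[5].solution == "Apply X at 1 mL/ha"
        assert len(small_base) == 5


class TestDepositedImport:
    """The adapter accepts the plausible shapes of an external deposit."""

    def test_canonical_json_passthrough(self, tmp_path, small_base):
        path = tmp_path / "deposit"
        save_case_base(small_base, path.with_suffix(".json"))
        path.with_suffix(".json").rename(path)
        loaded = import_deposited_case_base(path)
        assert loaded.cases == small_base.cases

    def test_headerless_delimited_table(self, tmp_path, small_base):
        rows = []
        for c in small_base:
            d = c.to_dict()
            tmin, tmax = d["temperature"]
            rows.append(
                f"{d['case_id']},{d['pest_type']},{d['pest_quantity']},"
                f"{d['pest_stage']},{d['infected_area']},{d['crop_name']},"
                f"{d['growth_stage']},{d['planting_density']},{tmin},{tmax},"
                f"{d['humidity']},{d['rainfall']},{d['sunlight']},{d['wind_speed']}"
            )
        path = tmp_path / "deposit.txt"
        path.write_text("\n".join(rows) + "\n")
        loaded = import_deposited_case_base(path)
        assert [c.case_id for c in loaded] == [1, 2, 3, 4]
        assert loaded.cases[0].humidity == pytest.approx(0.5749)

    def test_short_rows_reported_with_line(self, tmp_path):
        path = tmp_path / "deposit.txt"
        path.write_text("1,RP,335\n")
        with pytest.raises(ValueError, match="line 1"):
            import_deposited_case_base(path)
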