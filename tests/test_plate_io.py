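import numpy as np
import openpyxl
import pandas as pd
import pytest

from inflascreen import plate_io
from inflascreen.errors import FormatError, ValidationError, WellLabelError


class TestWellCoordinates:
    def test_label_index_bijection_all_384_wells(self):
        seen = set()
        for r in range(16):
            for c in range(24):
                label = plate_io.format_well(r, c)
                assert plate_io.parse_well(label) == (r, c)
                seen.add(label)
        assert len(seen) == 384

    @pytest.mark.parametrize("padded,canonical", [("A01", "A1"), ("p09", "P9"), ("B012", "B12")])
    def test_zero_padded_labels_accepted(self, padded, canonical):
        assert plate_io.format_well(*plate_io.parse_well(padded)) == canonical

    @pytest.mark.parametrize("bad", ["Q25", "Z9", "A0", "A25", "11", "A", "", "AA1"])
    def test_out_of_plate_labels_rejected(self, bad):
        with pytest.raises(WellLabelError):
            plate_io.parse_well(bad)


class TestWellTable:
    def test_round_trip_is_identity(self, small_screen, tmp_path):
        wells = small_screen.wells.head(200)
        plate_io.write_results({"wells": wells}, tmp_path)
        back = plate_io.read_well_table(tmp_path / "wells.csv")
        pd.testing.assert_frame_equal(back, wells.reset_index(drop=True),
                                      check_dtype=False)

    def test_tab_delimited_autodetected(self, small_screen, tmp_path):
        wells = small_screen.wells.head(50)
        plate_io.write_results({"wells": wells}, tmp_path, sep="\t")
        back = plate_io.read_well_table(tmp_path / "wells.tsv")
        assert len(back) == 50

    def test_invalid_well_label_names_row(self, small_screen, tmp_path):
        wells = small_screen.wells.head(10).copy()
        wells.iloc[3, wells.columns.get_loc("well")] = "Z9"
        path = tmp_path / "bad.csv"
        wells.to_csv(path, index=False)
        with pytest.raises(ValidationError) as exc:
            plate_io.read_well_table(path)
        assert 4 in exc.value.rows  # 1-based data row

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("plate_id,well\nP1,A1\n")
        with pytest.raises(FormatError):
            plate_io.read_well_table(path)

    def test_header_only_file_yields_empty_collection(self, tmp_path, caplog):
        path = tmp_path / "empty.csv"
        path.write_text(",".join(plate_io.WELL_TABLE_COLUMNS) + "\n")
        with caplog.at_level("WARNING"):
            df = plate_io.read_well_table(path)
        assert df.empty and "no rows" in caplog.text

    def test_control_well_with_compound_id_rejected(self, small_screen, tmp_path):
        hc = small_screen.wells[small_screen.wells["role"] == "high_control"]
        wells = pd.concat([small_screen.wells.head(5), hc.head(1)], ignore_index=True)
        wells.loc[5, "compound_id"] = "CPD00001"
        path = tmp_path / "bad.csv"
        wells.to_csv(path, index=False)
        with pytest.raises(ValidationError):
            plate_io.read_well_table(path)


class TestPlateMap:
    def _map_df(self, small_screen):
        return small_screen.plate_map[small_screen.plate_map["plate_id"] == "P01"]

    def test_sixteen_high_sixteen_low_accepted(self, small_screen, tmp_path):
        df = self._map_df(small_screen)
        path = tmp_path / "map.csv"
        df.to_csv(path, index=False)
        pm = plate_io.read_plate_map(path)
        assert len(pm.wells_with_role("high_control")) == 16
        assert len(pm.wells_with_role("low_control")) == 16
        assert len(pm.assignments) == 384

    def test_duplicate_well_assignment_rejected(self, small_screen, tmp_path):
        df = self._map_df(small_screen)
        df = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        path = tmp_path / "map.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="more than once"):
            plate_io.read_plate_maps(path)

    def test_control_count_mismatch_rejected(self, small_screen, tmp_path):
        df = self._map_df(small_screen).copy()
        hc = df.index[df["role"] == "high_control"]
        df.loc[hc[0], "role"] = "empty"  # 15 high controls left
        path = tmp_path / "map.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="15 high"):
            plate_io.read_plate_maps(path)


class TestAnnotations:
    def test_round_trip_and_flags(self, tmp_path):
        df = pd.DataFrame({
            "compound_id": ["C1", "C2", "C3", "C4"],
            "library": ["lib"] * 4,
            "duplicate_group": [None, "g1", "g1", None],
            "is_steroid": [True, False, False, True],
        })
        path = tmp_path / "ann.csv"
        df.to_csv(path, index=False)
        back = plate_io.read_annotations(path)
        assert back["is_steroid"].tolist() == [True, False, False, True]

    def test_duplicate_compound_ids_rejected(self, tmp_path):
        path = tmp_path / "ann.csv"
        path.write_text("compound_id,library,duplicate_group,is_steroid\n"
                        "C1,l,,False\nC1,l,,False\n")
        with pytest.raises(ValidationError, match="duplicated compound_id"):
            plate_io.read_annotations(path)

    def test_singleton_duplicate_group_rejected(self, tmp_path):
        path = tmp_path / "ann.csv"
        path.write_text("compound_id,library,duplicate_group,is_steroid\n"
                        "C1,l,g1,False\nC2,l,,False\n")
        with pytest.raises(ValidationError, match="single member"):
            plate_io.read_annotations(path)


class TestSupplementaryWorkbook:
    def test_renamed_headers_tolerated(self, tmp_path):
        # synthetic stand-in for the per-compound result workbook
        wb = openpyxl.Workbook()
        ws = wb.active
        ws.append(["Compound Name", "IL-1b % inhibition", "IL-6 % inhibition"])
        for i, (a, b) in enumerate([(45.2, 10.0), (-12.0, 3.3), (88.8, 71.0)]):
            ws.append([f"C{i}", a, b])
        path = tmp_path / "synthetic_s2.xlsx"
        wb.save(path)
        df = plate_io.read_supplementary_workbook(path)
        assert list(df.columns) == ["compound_id", "il1b_percent", "il6_percent"]
        assert len(df) == 3 and df["il1b_percent"].iloc[2] == pytest.approx(88.8)

    def test_unrecognizable_headers_raise(self, tmp_path):
        wb = openpyxl.Workbook()
        wb.active.append(["foo", "bar"])
        path = tmp_path / "bad.xlsx"
        wb.save(path)
        with pytest.raises(FormatError):
            plate_io.read_supplementary_workbook(path)


class TestWriteResults:
    def test_manifest_row_counts_match_tables(self, small_screen, tmp_path):
        tables = {"a": small_screen.truth.head(7),
                  "b": small_screen.truth.iloc[0:0]}
        manifest = plate_io.write_results(tables, tmp_path)
        assert manifest.set_index("name")["rows"].to_dict() == {"a": 7, "b": 0}
        # 0-row table still gets a header
        header = (tmp_path / "b.csv").read_text().splitlines()[0]
        assert header.split(",") == list(small_screen.truth.columns)
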