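"""Workbook dialect parsing, multi-file merge and canonical output."""

import pytest
from openpyxl import Workbook

from xmapqc.analysis import analyze_run
from xmapqc.bioplex_io import (
    detect_table_kind,
    merge_run_files,
    parse_sample_type,
    parse_workbook,
    write_canonical,
)
from xmapqc.errors import FormatError, MergeError
from xmapqc.models import Exclusion, RowKind, SampleRole
from xmapqc.synthetic import default_config, generate_run_workbook


@pytest.mark.parametrize(
    "code,role,index",
    [
        ("S3", SampleRole.STANDARD, 3),
        ("B", SampleRole.BACKGROUND, None),
        ("x12", SampleRole.UNKNOWN, 12),
        ("c2", SampleRole.QC_CONTROL, 2),
        ("X1", SampleRole.UNKNOWN, 1),
        ("s10", SampleRole.STANDARD, 10),
    ],
)
def test_sample_type_codes(code, role, index):
    assert parse_sample_type(code) == (role, index)


@pytest.mark.parametrize("bad", ["", "Q3", "7", "??"])
def test_sample_type_rejects_unknown_codes(bad):
    with pytest.raises(FormatError):
        parse_sample_type(bad)


@pytest.mark.parametrize(
    "header,kind",
    [
        (["Type", "Well", "Description", "FI"], RowKind.RAW),
        (["Type", "Wells", "Description", "FI"], RowKind.SUMMARY),
    ],
)
def test_table_kind_from_well_column(header, kind):
    assert detect_table_kind(header) == kind


def test_table_kind_requires_well_column():
    with pytest.raises(FormatError):
        detect_table_kind(["Type", "Description", "FI"])


class TestParseWorkbook:
    def test_round_trip_matches_ground_truth(self, default_run):
        """Every generated raw row comes back with identical role,
        dilution and FI (to the written precision)."""
        _, _, truth, run = default_run
        assert len(run.wells) == len(truth.well_rows)
        parsed = {
            (w.analyte, w.wells[0]): w for w in run.wells
        }
        for row in truth.well_rows:
            w = parsed[(row["analyte"], row["well"])]
            assert w.sample_id == row["sample_id"]
            assert w.dilution == row["dilution"]
            assert w.fi == row["fi"]
            assert w.description == row["description"]
            if row["expected_conc"] is not None:
                # Excel XML serialization can drop the last ulp
                assert w.expected_conc == pytest.approx(
                    row["expected_conc"], rel=1e-12
                )

    def test_round_trip_ten_seeded_configs(self, tmp_path):
        for seed in range(10):
            cfg = default_config(seed=seed, n_replicates=2)
            path, truth = generate_run_workbook(
                cfg, tmp_path / f"r{seed}.xlsx"
            )
            run = parse_workbook(path)
            got = {
                (w.analyte, w.wells[0]): (w.sample_id, w.dilution, w.fi)
                for w in run.wells
            }
            want = {
                (r["analyte"], r["well"]):
                    (r["sample_id"], r["dilution"], r["fi"])
                for r in truth.well_rows
            }
            assert got == want

    def test_parse_is_pure(self, default_run):
        _, path, _, run = default_run
        again = parse_workbook(path)
        assert [w.__dict__ for w in again.wells] == [
            w.__dict__ for w in run.wells
        ]

    def test_sheet_name_gives_bead_number(self, default_run):
        _, _, _, run = default_run
        assert run.bead_numbers == {"ENV1": 34, "ENV2": 35, "ENV3": 36}

    def test_header_metadata_captured(self, default_run):
        _, _, _, run = default_run
        assert run.metadata.extra["Reader Serial Number"] == "LX200-0001"

    def test_footer_captured_opaquely(self, default_run):
        _, _, _, run = default_run
        assert "ENV1" in run.annotations
        assert any("Quantitative" in str(c)
                   for row in run.annotations["ENV1"] for c in row)

    def test_summary_and_raw_tables_both_captured(self, tmp_path):
        cfg = default_config(seed=3, include_summary=True,
                             n_replicates=2)
        path, _ = generate_run_workbook(cfg, tmp_path / "both.xlsx")
        run = parse_workbook(path)
        kinds = {w.row_kind for w in run.wells}
        assert kinds == {RowKind.RAW, RowKind.SUMMARY}
        summary = [w for w in run.wells if w.row_kind is RowKind.SUMMARY]
        assert all(len(w.wells) == 2 for w in summary)
        assert all(w.bead_count is None for w in summary)
        raw = [w for w in run.wells if w.row_kind is RowKind.RAW]
        assert all(len(w.wells) == 1 for w in raw)

    def test_empty_workbook_is_format_error(self, tmp_path):
        wb = Workbook()
        p = tmp_path / "empty.xlsx"
        wb.save(p)
        with pytest.raises(FormatError):
            parse_workbook(p)

    def test_duplicate_well_is_format_error(self, tmp_path):
        wb = Workbook()
        ws = wb.active
        ws.title = "ENV1 (34)"
        ws.append(["Type", "Well", "Description", "FI", "Dilution"])
        ws.append(["S1", "A1", "Standard1", 100.0, 1.0])
        ws.append(["S1", "A1", "Standard1", 101.0, 1.0])
        p = tmp_path / "dup.xlsx"
        wb.save(p)
        with pytest.raises(FormatError, match="duplicate well"):
            parse_workbook(p)

    def test_unparseable_numeric_cell_names_location(self, tmp_path):
        wb = Workbook()
        ws = wb.active
        ws.title = "ENV1"
        ws.append(["Type", "Well", "FI"])
        ws.append(["S1", "A1", "oops"])
        p = tmp_path / "badnum.xlsx"
        wb.save(p)
        with pytest.raises(FormatError, match="ENV1"):
            parse_workbook(p)


class TestMerge:
    def test_single_fragment_identity(self, default_run):
        _, _, _, run = default_run
        assert merge_run_files([run]) is run

    def test_standard_in_one_file_serves_the_other(self, tmp_path):
        """A standards-only file merged with an unknowns-only file lets
        the second file's samples interpolate off the first's curve."""
        cfg_std = default_config(seed=5)
        cfg_std.unknowns = []
        p_std, _ = generate_run_workbook(cfg_std, tmp_path / "std.xlsx")
        p_unk, _ = generate_run_workbook(
            default_config(seed=6), tmp_path / "unk.xlsx"
        )
        frag_std = parse_workbook(p_std)
        frag_unk = parse_workbook(p_unk)
        frag_unk.wells = [
            w for w in frag_unk.wells
            if w.sample_role is SampleRole.UNKNOWN
        ]
        from xmapqc.bioplex_io import _attach_titrations

        _attach_titrations(frag_unk)
        assert frag_unk.standard_assignment == {}

        merged = merge_run_files([frag_std, frag_unk])
        assert merged.standard_assignment["ENV1"] == "Standard"
        state = analyze_run(merged)
        unk = state.interpolation_table()
        assert (unk["status"] == "ok").any()
        files = set(unk_w.source_file for unk_w in merged.wells)
        assert files == {"std.xlsx", "unk.xlsx"}

    def test_conflicting_bead_numbers_rejected(self, default_run):
        import copy

        _, _, _, run = default_run
        other = copy.deepcopy(run)
        other.bead_numbers["ENV1"] = 99
        with pytest.raises(MergeError, match="ENV1"):
            merge_run_files([run, other])


class TestWriteCanonical:
    def test_files_and_row_counts(self, default_run, tmp_path):
        _, _, _, run = default_run
        state = analyze_run(run)
        files = write_canonical(run, state, tmp_path / "out")
        names = {f.name for f in files}
        assert names == {"wells.csv", "curves.csv", "metrics.csv",
                         "manifest.json"}
        import pandas as pd

        metrics = pd.read_csv(tmp_path / "out" / "metrics.csv")
        # one row per analyte x titration (3 analytes, standard only)
        assert len(metrics) == 3
        wells = pd.read_csv(tmp_path / "out" / "wells.csv")
        assert len(wells) == len(run.wells)

    def test_rerun_is_byte_identical(self, default_run, tmp_path):
        _, _, _, run = default_run
        a = write_canonical(run, analyze_run(run), tmp_path / "a")
        b = write_canonical(run, analyze_run(run), tmp_path / "b")
        for fa, fb in zip(a, b):
            assert fa.read_bytes() == fb.read_bytes()

    def test_fully_excluded_analyte_keeps_metric_row(
        self, default_run, tmp_path
    ):
        _, _, _, run = default_run
        excl = Exclusion(scope="analyte", analyte="ENV3", reason="qc")
        state = analyze_run(run, exclusions=[excl])
        write_canonical(run, state, tmp_path / "ex")
        import pandas as pd

        metrics = pd.read_csv(tmp_path / "ex" / "metrics.csv")
        row = metrics[metrics.analyte == "ENV3"]
        assert len(row) == 1
        assert row[["ec50_4pl", "ec50_5pl", "auc", "high_mfi"]].isna().all(
            axis=None
        )
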