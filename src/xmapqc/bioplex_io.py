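"""Reading Bio-Plex-Manager-style Excel run workbooks.

Each run workbook has one worksheet per bead type (analyte).  A sheet is
laid out as: a header of key/value metadata rows, then one or two data
tables (a per-sample "summary" table and/or a per-well "raw" table), then
an opaque footer.  The boundary rules used here: metadata rows are all
rows above the first row whose first cell equals ``Type``; each data table
starts at such a row and ends at the first fully blank row; remaining
non-blank rows are captured as footer annotations, never interpreted.

Sheet names may carry the bead number as a parenthesized trailing integer
(``"ENV1 (34)"``).  Column headers are matched case-insensitively against
the canonical set (Type, Well/Wells, Description, FI, FI - Bkgd, %CV,
Std Dev, Obs Conc, Exp Conc, Dilution, Bead Count); unknown columns are
preserved per row in an extras map.  Any letter+number well label is
accepted, so plates larger than 96 wells parse unchanged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Any

from openpyxl import load_workbook

from .errors import FormatError, MergeError
from .models import (
    RowKind,
    RunData,
    RunMetadata,
    SampleRole,
    TitrationInfo,
    WellRecord,
)

__all__ = [
    "ParseOptions",
    "parse_sample_type",
    "detect_table_kind",
    "parse_workbook",
    "merge_run_files",
    "write_canonical",
]

logger = logging.getLogger(__name__)

STANDARD_TITRATION = "Standard"
QC_TITRATION = "QC Control"

_ROLE_BY_LETTER = {
    "B": SampleRole.BACKGROUND,
    "S": SampleRole.STANDARD,
    "C": SampleRole.QC_CONTROL,
    "X": SampleRole.UNKNOWN,
}

_SHEET_NAME_RE = re.compile(r"^(?P<name>.*?)\s*\((?P<bead>\d+)\)\s*$")
_TYPE_CODE_RE = re.compile(r"^(?P<letters>[A-Za-z]+)\s*(?P<digits>\d*)$")
_WELL_RE = re.compile(r"^[A-Za-z]+\d+$")

# canonical column names, lower-cased for matching
_CANONICAL_COLUMNS = {
    "type": "type",
    "well": "well",
    "wells": "wells",
    "outlier": "outlier",
    "description": "description",
    "fi": "fi",
    "fi - bkgd": "fi_bkgd",
    "%cv": "pct_cv",
    "std dev": "std_dev",
    "obs conc": "obs_conc",
    "exp conc": "exp_conc",
    "dilution": "dilution",
    "bead count": "bead_count",
}


@dataclass(frozen=True)
class ParseOptions:
    """``lenient=True`` downgrades row-level numeric errors to warnings and
    skips the row (the skip is logged, never silent)."""

    lenient: bool = False


def parse_sample_type(code: str) -> tuple[SampleRole, int | None]:
    """Split a type code like ``"S3"`` into (role, index).

    The leading letters select the role (B background, S standard, C QC
    control, X unknown; case-insensitive) and trailing digits, when
    present, give the sample index.
    """
    if not code:
        raise FormatError("empty sample type code")
    m = _TYPE_CODE_RE.match(code.strip())
    if not m:
        raise FormatError(f"unparseable sample type code {code!r}")
    letters = m.group("letters").upper()
    role = _ROLE_BY_LETTER.get(letters[0])
    if role is None:
        raise FormatError(f"unrecognized sample type code {code!r}")
    digits = m.group("digits")
    return role, int(digits) if digits else None


def detect_table_kind(header_cells: list[str]) -> RowKind:
    """A table with a ``Well`` column is raw (per-well); ``Wells`` marks a
    summary (per-sample) table."""
    lowered = {str(c).strip().lower() for c in header_cells if c is not None}
    if "wells" in lowered:
        return RowKind.SUMMARY
    if "well" in lowered:
        return RowKind.RAW
    raise FormatError(
        "data table header lacks a well-location column (Well/Wells): "
        f"{header_cells!r}"
    )


def _cell_str(value: Any) -> str:
    return "" if value is None else str(value).strip()


def _num(value: Any, sheet: str, rownum: int, column: str) -> float | None:
    if value is None or (isinstance(value, str) and not value.strip()):
        return None
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    try:
        return float(str(value).strip())
    except ValueError:
        raise FormatError(
            f"unparseable numeric cell in sheet {sheet!r} row {rownum}, "
            f"column {column!r}: {value!r}"
        ) from None


def _parse_table(
    rows: list[tuple[int, tuple]],
    sheet: str,
    analyte: str,
    source_file: str,
    options: ParseOptions,
) -> list[WellRecord]:
    header_num, header = rows[0]
    header_cells = [_cell_str(c) for c in header]
    kind = detect_table_kind(header_cells)
    colmap: dict[int, str] = {}
    extras_cols: dict[int, str] = {}
    for idx, cell in enumerate(header_cells):
        if not cell:
            continue
        canon = _CANONICAL_COLUMNS.get(cell.lower())
        if canon:
            colmap[idx] = canon
        else:
            extras_cols[idx] = cell
    records: list[WellRecord] = []
    seen_wells: set[str] = set()
    for rownum, row in rows[1:]:
        values = {name: row[i] if i < len(row) else None
                  for i, name in colmap.items()}
        code = _cell_str(values.get("type"))
        try:
            if not code:
                raise FormatError(
                    f"missing sample type in sheet {sheet!r} row {rownum}"
                )
            role, index = parse_sample_type(code)
            if kind is RowKind.RAW:
                well_field = _cell_str(values.get("well"))
                wells = [well_field] if well_field else []
            else:
                wells = [
                    w.strip()
                    for w in _cell_str(values.get("wells")).split(",")
                    if w.strip()
                ]
            for w in wells:
                if not _WELL_RE.match(w):
                    raise FormatError(
                        f"bad well label {w!r} in sheet {sheet!r} "
                        f"row {rownum}"
                    )
            if kind is RowKind.RAW:
                if len(wells) != 1:
                    raise FormatError(
                        f"raw row without a single well in sheet {sheet!r} "
                        f"row {rownum}"
                    )
                if wells[0] in seen_wells:
                    raise FormatError(
                        f"duplicate well {wells[0]!r} in raw table of "
                        f"sheet {sheet!r}"
                    )
                seen_wells.add(wells[0])
            num = lambda col: _num(values.get(col), sheet, rownum, col)  # noqa: E731
            exp_conc = num("exp_conc")
            bead_count = num("bead_count")
            record = WellRecord(
                analyte=analyte,
                sample_role=role,
                sample_index=index,
                sample_id=code,
                description=_cell_str(values.get("description")),
                wells=wells,
                dilution=num("dilution") or 1.0,
                expected_conc=(
                    exp_conc
                    if role in (SampleRole.STANDARD, SampleRole.QC_CONTROL)
                    else None
                ),
                fi=num("fi") or 0.0,
                fi_bkgd=num("fi_bkgd"),
                reported_pct_cv=num("pct_cv"),
                bead_count=(
                    int(bead_count)
                    if bead_count is not None and kind is RowKind.RAW
                    else None
                ),
                source_file=source_file,
                row_kind=kind,
                extras={
                    name: row[i] if i < len(row) else None
                    for i, name in extras_cols.items()
                },
            )
        except FormatError as exc:
            if options.lenient and "duplicate well" not in str(exc):
                logger.warning("skipping row: %s", exc)
                continue
            raise
        records.append(record)
    return records


def parse_workbook(
    path: Path | str, options: ParseOptions | None = None
) -> RunData:
    """Parse one run workbook into a :class:`RunData` fragment.

    One analyte per worksheet; header key/value pairs are captured into
    ``RunMetadata.extra``; every data-table row becomes a
    :class:`WellRecord`; footer rows are kept opaquely per analyte.  The
    input file is never modified.
    """
    options = options or ParseOptions()
    path = Path(path)
    try:
        wb = load_workbook(path, read_only=True, data_only=True)
    except Exception as exc:
        raise FormatError(f"cannot read workbook {path}: {exc}") from exc
    try:
        analytes: list[str] = []
        bead_numbers: dict[str, int] = {}
        wells: list[WellRecord] = []
        annotations: dict[str, list[list[Any]]] = {}
        extra: dict[str, str] = {}
        any_table = False
        for ws in wb.worksheets:
            m = _SHEET_NAME_RE.match(ws.title)
            if m:
                analyte = m.group("name").strip() or ws.title.strip()
                bead_numbers[analyte] = int(m.group("bead"))
            else:
                analyte = ws.title.strip()
            all_rows = [
                tuple(r) for r in ws.iter_rows(values_only=True)
            ]
            type_rows = [
                i for i, r in enumerate(all_rows)
                if r and _cell_str(r[0]).lower() == "type"
            ]
            if not type_rows:
                raise FormatError(
                    f"sheet {ws.title!r} has no data-table header row"
                )
            any_table = True
            analytes.append(analyte)
            # header metadata: key/value pairs above the first table
            for r in all_rows[: type_rows[0]]:
                key = _cell_str(r[0]) if r else ""
                if key:
                    value = _cell_str(r[1]) if len(r) > 1 else ""
                    extra.setdefault(key, value)
            # tables
            consumed_until = type_rows[0]
            for start in type_rows:
                if start < consumed_until:
                    continue
                end = start + 1
                while end < len(all_rows) and any(
                    c is not None and _cell_str(c) != ""
                    for c in all_rows[end]
                ):
                    end += 1
                table = [
                    (i + 1, all_rows[i]) for i in range(start, end)
                ]
                wells.extend(
                    _parse_table(table, ws.title, analyte, path.name,
                                 options)
                )
                consumed_until = end
            # footer: non-blank rows after the last table
            footer = [
                [c for c in r]
                for i, r in enumerate(all_rows)
                if i >= consumed_until
                and i not in type_rows
                and any(_cell_str(c) for c in r)
            ]
            if footer:
                annotations[analyte] = footer
        if not any_table:
            raise FormatError(f"workbook {path} contains no data tables")
    finally:
        wb.close()

    metadata = RunMetadata(run_name=path.stem, extra=extra)
    run = RunData(
        metadata=metadata,
        analytes=analytes,
        wells=wells,
        bead_numbers=bead_numbers,
        annotations=annotations,
    )
    _attach_titrations(run)
    run.validate()
    return run


def _attach_titrations(run: RunData) -> None:
    """Register the standard / QC titrations present and default the
    per-analyte standard assignment."""
    roles_present = {w.sample_role for w in run.wells}
    titrations: list[TitrationInfo] = []
    if SampleRole.STANDARD in roles_present:
        titrations.append(
            TitrationInfo(STANDARD_TITRATION, SampleRole.STANDARD)
        )
    if SampleRole.QC_CONTROL in roles_present:
        titrations.append(TitrationInfo(QC_TITRATION, SampleRole.QC_CONTROL))
    run.titrations = titrations
    if any(t.name == STANDARD_TITRATION for t in titrations):
        run.standard_assignment = {
            a: STANDARD_TITRATION for a in run.analytes
        }
    else:
        run.standard_assignment = {}


def merge_run_files(fragments: list[RunData]) -> RunData:
    """Combine per-file fragments into one run.

    Wells are concatenated in file order with their source file retained,
    so a standard titration present in any fragment serves analytes from
    any other.  The same analyte name must map to the same bead number
    wherever both are given.
    """
    if not fragments:
        raise MergeError("no run fragments to merge")
    if len(fragments) == 1:
        return fragments[0]
    analytes: list[str] = []
    bead_numbers: dict[str, int] = {}
    wells: list[WellRecord] = []
    annotations: dict[str, list[list[Any]]] = {}
    extra: dict[str, str] = {}
    for frag in fragments:
        for a in frag.analytes:
            if a not in analytes:
                analytes.append(a)
            if a in frag.bead_numbers:
                bead = frag.bead_numbers[a]
                if bead_numbers.get(a, bead) != bead:
                    raise MergeError(
                        f"conflicting bead numbers for analyte {a!r}: "
                        f"{bead_numbers[a]} vs {bead}"
                    )
                bead_numbers[a] = bead
        wells.extend(frag.wells)
        for a, rows in frag.annotations.items():
            annotations.setdefault(a, []).extend(rows)
        for k, v in frag.metadata.extra.items():
            extra.setdefault(k, v)
    metadata = RunMetadata(
        run_name=fragments[0].metadata.run_name,
        acquisition_date=fragments[0].metadata.acquisition_date,
        isotype=fragments[0].metadata.isotype,
        conjugate=fragments[0].metadata.conjugate,
        performer=fragments[0].metadata.performer,
        reagent_lot=fragments[0].metadata.reagent_lot,
        batch_id=fragments[0].metadata.batch_id,
        extra=extra,
    )
    run = RunData(
        metadata=metadata,
        analytes=analytes,
        wells=wells,
        bead_numbers=bead_numbers,
        annotations=annotations,
    )
    _attach_titrations(run)
    run.validate()
    return run


def write_canonical(run: RunData, results, out_dir: Path | str) -> list[Path]:
    """Write the canonical tidy outputs for an analysed run.

    Emits ``wells.csv`` (one row per WellRecord with normalization,
    exclusion and flag columns), ``curves.csv`` (fitted parameters, one
    row per analyte x titration x model), ``metrics.csv`` (4pl/5pl EC50,
    AUC, HighMFI per analyte x titration; metric cells are empty — the
    row remains — when a titration could not be fitted) and
    ``manifest.json``.  Re-running on identical input is byte-identical.

    ``results`` is the :class:`~xmapqc.analysis.RunAnalysis` for the run.
    """
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    wells_path = out_dir / "wells.csv"
    results.well_table().to_csv(wells_path, index=False, lineterminator="\n")
    written.append(wells_path)

    curves_path = out_dir / "curves.csv"
    results.curve_table().to_csv(curves_path, index=False,
                                 lineterminator="\n")
    written.append(curves_path)

    metrics_path = out_dir / "metrics.csv"
    results.metric_table().to_csv(metrics_path, index=False,
                                  lineterminator="\n")
    written.append(metrics_path)

    manifest = {
        "run_name": run.metadata.run_name,
        "isotype": run.metadata.isotype,
        "conjugate": run.metadata.conjugate,
        "reagent_lot": run.metadata.reagent_lot,
        "batch_id": run.metadata.batch_id,
        "analytes": run.analytes,
        "bead_numbers": run.bead_numbers,
        "source_files": sorted({w.source_file for w in run.wells}),
        "header_metadata": run.metadata.extra,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    written.append(manifest_path)
    return written
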