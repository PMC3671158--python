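"""Canonical in-memory data model for bead-array immunoassay runs.

A *run* is one acquisition of a multiplexed plate: for every bead region
(analyte) the instrument reports the median fluorescence intensity (FI) of
each well, either per well ("raw" rows) or averaged over sample replicates
("summary" rows).  These records, together with run-level metadata and the
titrations they form, are the inputs to normalization, curve fitting and
quality control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from typing import Any


class SampleRole(str, Enum):
    """What a well's sample is for.

    ``background`` wells contain buffer only and estimate detector
    non-specific signal; ``standard`` and ``qc_control`` are titrations of
    known concentration; ``control`` is an untitrated positive/negative
    control; ``unknown`` is a study sample.
    """

    BACKGROUND = "background"
    STANDARD = "standard"
    QC_CONTROL = "qc_control"
    CONTROL = "control"
    UNKNOWN = "unknown"


class RowKind(str, Enum):
    RAW = "raw"
    SUMMARY = "summary"


#: Roles that form dilution series with expected concentrations.
TITRATION_ROLES = (SampleRole.STANDARD, SampleRole.QC_CONTROL)


@dataclass
class RunMetadata:
    """Run-level annotations used for tracking and cross-run QC scoping."""

    run_name: str
    acquisition_date: date | None = None
    isotype: str = ""
    conjugate: str = ""
    performer: str = ""
    reagent_lot: str = ""
    batch_id: str = ""
    #: Unrecognized header key/value pairs from the workbook, kept verbatim.
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.run_name:
            raise ValueError("run_name must be non-empty")

    @property
    def lot_scope(self) -> tuple[str, str, str]:
        """Scope key for guide sets: (reagent lot, isotype, conjugate)."""
        return (self.reagent_lot, self.isotype, self.conjugate)


@dataclass
class WellRecord:
    """One bead-type measurement in one well (raw) or one sample (summary)."""

    analyte: str
    sample_role: SampleRole
    sample_id: str                     # type code as printed, e.g. "S3"
    wells: list[str]                   # well positions; length 1 for raw rows
    fi: float                          # median FI (replicate mean for summary)
    row_kind: RowKind
    bead_number: int | None = None
    sample_index: int | None = None
    description: str = ""              # specimen / participant mapping key
    dilution: float = 1.0              # fold-dilution (100 means 1:100)
    expected_conc: float | None = None
    fi_bkgd: float | None = None       # file's own "FI - Bkgd" column
    reported_pct_cv: float | None = None
    bead_count: int | None = None      # raw rows only
    source_file: str = ""
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dilution <= 0:
            raise ValueError("dilution must be > 0")
        if self.row_kind is RowKind.RAW:
            if len(self.wells) != 1:
                raise ValueError("raw rows must reference exactly one well")
        elif self.bead_count is not None:
            raise ValueError("summary rows never carry a bead count")
        if (
            self.expected_conc is not None
            and self.sample_role not in TITRATION_ROLES
        ):
            raise ValueError(
                "expected_conc is only meaningful for titration sample roles"
            )


@dataclass
class TitrationInfo:
    """Identity of a titration within a run (points are built per analyte)."""

    name: str
    role: SampleRole


@dataclass
class RunData:
    """A complete run: metadata, analyte list, well records, titrations."""

    metadata: RunMetadata
    analytes: list[str] = field(default_factory=list)
    wells: list[WellRecord] = field(default_factory=list)
    titrations: list[TitrationInfo] = field(default_factory=list)
    #: analyte -> name of the standard titration used for interpolation
    standard_assignment: dict[str, str] = field(default_factory=dict)
    #: analyte -> bead number parsed from the sheet name, where given
    bead_numbers: dict[str, int] = field(default_factory=dict)
    #: analyte -> opaque footer rows captured from the workbook
    annotations: dict[str, list[list[Any]]] = field(default_factory=dict)

    def validate(self) -> None:
        names = {t.name for t in self.titrations}
        for analyte, target in self.standard_assignment.items():
            if target not in names:
                raise ValueError(
                    f"standard assignment for {analyte!r} targets unknown "
                    f"titration {target!r}"
                )
        known = set(self.analytes)
        for w in self.wells:
            if w.analyte not in known:
                raise ValueError(f"well analyte {w.analyte!r} not in analytes")

    def wells_for(self, analyte: str) -> list[WellRecord]:
        return [w for w in self.wells if w.analyte == analyte]


@dataclass
class ReplicateGroup:
    """Wells sharing (analyte, sample, dilution): the unit of %CV and
    exclusion."""

    analyte: str
    sample_key: tuple[str, str]        # (sample_id, description)
    dilution: float
    members: list[WellRecord]
    mean_fi: float
    pct_cv: float | None               # absent when members < 2 (raw rows)
    role: SampleRole
    excluded: bool = False

    @property
    def key(self) -> tuple[str, str, str, float]:
        return (self.analyte, *self.sample_key, self.dilution)


@dataclass
class QCFlag:
    """A reviewable quality-control flag; inactivation never deletes it."""

    kind: str                          # "high_cv" | "guideset_outlier"
    target: Any                        # replicate-group key or (run, metric)
    value: float
    rule: str
    active: bool = True
    comment: str = ""
    flag_id: int = -1


@dataclass
class Exclusion:
    """Reviewable removal of data from analysis; rows are marked, kept."""

    scope: str                         # "analyte" | "replicate_group"
    analyte: str
    sample_key: tuple[str, str] | None = None
    dilution: float | None = None
    reason: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if self.scope not in ("analyte", "replicate_group"):
            raise ValueError(f"unknown exclusion scope {self.scope!r}")
        if self.scope == "replicate_group" and (
            self.sample_key is None or self.dilution is None
        ):
            raise ValueError(
                "replicate_group exclusions need sample_key and dilution"
            )

    def matches(self, group: ReplicateGroup) -> bool:
        if group.analyte != self.analyte:
            return False
        if self.scope == "analyte":
            return True
        return (
            group.sample_key == tuple(self.sample_key)
            and group.dilution == self.dilution
        )
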