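"""Synthetic Bio-Plex-style run workbooks with known ground truth.

Every downstream stage (parsing, normalization, fitting, QC) is exercised
against workbooks produced here, for which the true dose-response curves,
well concentrations and noiseless FIs are known exactly.

The emulated plate contains buffer-only background wells, a titrated
standard (S1 = highest concentration), an optional titrated QC control,
and unknowns at known concentrations, each replicated in ``n_replicates``
wells.  Measured FI is the true curve value times a multiplicative
lognormal factor with unit median and coefficient of variation
``noise_cv`` — FI is positive and its spread grows with signal, which is
the heteroscedasticity that motivates power-law fit weights.  Background
wells draw from a truncated-at-zero normal around ``background_fi_mean``
with 10% CV.  An optional uncoupled ("blank") bead sheet carries
background-only signal in every well, with no dose dependence.
"""

from __future__ import annotations

import json
import math
import zipfile
from dataclasses import asdict, dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
from openpyxl import Workbook

from .curves import LogisticParams, eval_logistic
from .errors import ConfigError, DomainError

__all__ = [
    "AnalyteSpec",
    "UnknownSpec",
    "TitrationSpec",
    "SynthConfig",
    "GroundTruth",
    "simulate_well_fi",
    "generate_run_workbook",
    "default_config",
]

_FIXED_TIMESTAMP = datetime(2013, 4, 30, 0, 0, 0)

RAW_HEADER = [
    "Type", "Well", "Description", "FI", "FI - Bkgd", "%CV", "Std Dev",
    "Obs Conc", "Exp Conc", "Dilution", "Bead Count",
]
SUMMARY_HEADER = [
    "Type", "Wells", "Description", "FI", "FI - Bkgd", "%CV", "Std Dev",
    "Obs Conc", "Exp Conc", "Dilution",
]


@dataclass
class AnalyteSpec:
    name: str
    bead_number: int
    params: LogisticParams
    unit: str = "pg/ml"


@dataclass
class UnknownSpec:
    """An unknown sample: ``true_conc`` is the concentration of the
    undiluted specimen; the well sees ``true_conc / dilution``."""

    id: str
    true_conc: float
    dilution: float = 100.0


@dataclass
class TitrationSpec:
    """A dilution series: point k sits at ``top_conc / dilutions[k]``."""

    top_conc: float = 10000.0
    dilutions: list[float] = field(
        default_factory=lambda: [3.0 ** k for k in range(10)]
    )


@dataclass
class SynthConfig:
    analytes: list[AnalyteSpec]
    standard: TitrationSpec = field(default_factory=TitrationSpec)
    qc: TitrationSpec | None = None
    unknowns: list[UnknownSpec] = field(default_factory=list)
    n_replicates: int = 3
    background_fi_mean: float = 25.0
    blank_bead: bool = False
    noise_cv: float = 0.05
    seed: int = 0
    include_summary: bool = False
    run_name: str = "synthetic-run"
    plate_columns: int = 12
    plate_rows: str = "ABCDEFGH"

    def validate(self) -> None:
        if not self.analytes:
            raise ConfigError("at least one analyte is required")
        for tit, label in ((self.standard, "standard"), (self.qc, "qc")):
            if tit is None:
                continue
            d = tit.dilutions
            if not d or any(
                b <= a for a, b in zip(d, d[1:])
            ):
                raise ConfigError(
                    f"{label} dilutions must be strictly increasing"
                )
            if tit.top_conc <= 0:
                raise ConfigError(f"{label} top_conc must be > 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.background_fi_mean < 0:
            raise ConfigError("background_fi_mean must be >= 0")


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would estimate."""

    analytes: dict[str, dict]          # name -> true LogisticParams fields
    well_rows: list[dict]              # one per raw data-table row
    unknown_conc: dict[str, float]     # unknown id -> true concentration
    seed: int

    def save(self, path: Path | str) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=1, sort_keys=True) + "\n"
        )

    @classmethod
    def load(cls, path: Path | str) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def simulate_well_fi(
    params: LogisticParams,
    conc: float,
    noise_cv: float,
    rng: np.random.Generator,
) -> float:
    """Realized FI at ``conc``: curve value times a lognormal factor with
    unit median and CV ``noise_cv`` (exact curve value when noise_cv=0)."""
    if conc <= 0:
        raise DomainError("conc must be > 0")
    value = eval_logistic(params, float(conc))
    if noise_cv > 0:
        sigma = math.sqrt(math.log1p(noise_cv**2))
        value *= math.exp(rng.normal(0.0, sigma))
    return float(value)


def _truncated_normal(
    mean: float, cv: float, rng: np.random.Generator
) -> float:
    """Normal(mean, cv*mean) resampled until nonnegative."""
    sd = cv * mean
    if sd == 0:
        return mean
    while True:
        v = rng.normal(mean, sd)
        if v >= 0:
            return float(v)


@dataclass
class _PlateRow:
    code: str
    description: str
    conc: float | None                 # well concentration (None: background)
    exp_conc: float | None             # printed Exp Conc (titrations only)
    dilution: float
    wells: list[str]


def _plate_layout(config: SynthConfig) -> list[_PlateRow]:
    """Sample layout shared by every analyte sheet (multiplexed plate)."""
    positions = [
        f"{r}{c}"
        for r in config.plate_rows
        for c in range(1, config.plate_columns + 1)
    ]
    rows: list[_PlateRow] = []
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        if cursor + n > len(positions):
            raise ConfigError("configuration does not fit on the plate")
        out = positions[cursor:cursor + n]
        cursor += n
        return out

    rows.append(
        _PlateRow("B", "Background", None, None, 1.0,
                  take(config.n_replicates))
    )
    for prefix, tit, desc in (
        ("S", config.standard, "Standard"),
        ("C", config.qc, "QC Control"),
    ):
        if tit is None:
            continue
        for i, fold in enumerate(tit.dilutions, start=1):
            conc = tit.top_conc / fold
            rows.append(
                _PlateRow(f"{prefix}{i}", f"{desc}{i}", conc, conc, fold,
                          take(config.n_replicates))
            )
    for i, unk in enumerate(config.unknowns, start=1):
        rows.append(
            _PlateRow(f"X{i}", unk.id, unk.true_conc / unk.dilution, None,
                      unk.dilution, take(config.n_replicates))
        )
    return rows


def _sheet_header(config: SynthConfig, analyte: str) -> list[tuple[str, str]]:
    return [
        ("File Name", f"{config.run_name}.pdf"),
        ("Acquisition Date", "30-Apr-2013 12:00"),
        ("Reader Serial Number", "LX200-0001"),
        ("Analyte", analyte),
        ("RP1 PMT (Volts)", "650"),
        ("RP1 Target", "10000"),
    ]


_FOOTER = [
    ["Analysis Type", "Quantitative"],
    ["Std. Curve", "Fitted during analysis"],
]


def generate_run_workbook(
    config: SynthConfig, path: Path | str
) -> tuple[Path, GroundTruth]:
    """Write a run workbook in the Bio-Plex dialect plus a ground-truth
    JSON sidecar (``<path stem>.truth.json``); byte-identical for identical
    config (including seed)."""
    config.validate()
    path = Path(path)
    rng = np.random.default_rng(config.seed)
    layout = _plate_layout(config)

    wb = Workbook()
    wb.remove(wb.active)
    truth_rows: list[dict] = []
    analyte_truth: dict[str, dict] = {}

    def write_sheet(title: str, analyte_name: str,
                    fi_for: dict[tuple[str, str], float],
                    true_for: dict[tuple[str, str], float | None]) -> None:
        ws = wb.create_sheet(title=title)
        for key, value in _sheet_header(config, analyte_name):
            ws.append([key, value])
        ws.append([])
        bkgd = _mean(
            [fi_for[(r.code, w)] for r in layout if r.code == "B"
             for w in r.wells]
        )
        if config.include_summary:
            ws.append(SUMMARY_HEADER)
            for r in layout:
                fis = [fi_for[(r.code, w)] for w in r.wells]
                mean = _mean(fis)
                sd = _sd(fis)
                cv = 100.0 * sd / mean if (len(fis) > 1 and mean) else None
                ws.append([
                    r.code, ",".join(r.wells), r.description,
                    round(mean, 2), round(mean - bkgd, 2),
                    round(cv, 2) if cv is not None else None,
                    round(sd, 2) if len(fis) > 1 else None,
                    None, r.exp_conc, r.dilution,
                ])
            ws.append([])
        ws.append(RAW_HEADER)
        for r in layout:
            for w in r.wells:
                fi = fi_for[(r.code, w)]
                ws.append([
                    r.code, w, r.description, round(fi, 2),
                    round(fi - bkgd, 2), None, None, None,
                    r.exp_conc, r.dilution,
                    int(rng.integers(35, 120)),
                ])
                truth_rows.append({
                    "analyte": analyte_name,
                    "sheet": title,
                    "sample_id": r.code,
                    "well": w,
                    "description": r.description,
                    "dilution": r.dilution,
                    "expected_conc": r.exp_conc,
                    "true_conc": true_for[(r.code, w)],
                    "fi_true": (
                        None if r.conc is None
                        else float(eval_logistic(
                            _params_of(analyte_name, config), r.conc))
                        if analyte_name != "Blank" else None
                    ),
                    "fi": round(fi, 2),
                })
        ws.append([])
        for row in _FOOTER:
            ws.append(row)

    for spec in config.analytes:
        analyte_truth[spec.name] = {
            "a_min": spec.params.a_min, "a_max": spec.params.a_max,
            "m": spec.params.m, "h": spec.params.h, "s": spec.params.s,
            "bead_number": spec.bead_number, "unit": spec.unit,
        }
        fi_for: dict[tuple[str, str], float] = {}
        true_for: dict[tuple[str, str], float | None] = {}
        for r in layout:
            for w in r.wells:
                if r.conc is None:
                    fi = _truncated_normal(
                        config.background_fi_mean, 0.10, rng)
                else:
                    fi = simulate_well_fi(
                        spec.params, r.conc, config.noise_cv, rng)
                fi_for[(r.code, w)] = fi
                true_for[(r.code, w)] = r.conc
        write_sheet(f"{spec.name} ({spec.bead_number})", spec.name,
                    fi_for, true_for)

    if config.blank_bead:
        fi_for = {
            (r.code, w): _truncated_normal(
                config.background_fi_mean, 0.10, rng)
            for r in layout for w in r.wells
        }
        true_for = {(r.code, w): None for r in layout for w in r.wells}
        write_sheet("Blank (0)", "Blank", fi_for, true_for)

    wb.properties.created = _FIXED_TIMESTAMP
    wb.properties.modified = _FIXED_TIMESTAMP
    wb.save(path)
    _normalize_zip(path)

    truth = GroundTruth(
        analytes=analyte_truth,
        well_rows=truth_rows,
        unknown_conc={u.id: u.true_conc for u in config.unknowns},
        seed=config.seed,
    )
    truth.save(path.with_suffix(".truth.json"))
    return path, truth


def _params_of(name: str, config: SynthConfig) -> LogisticParams:
    for spec in config.analytes:
        if spec.name == name:
            return spec.params
    raise KeyError(name)


def _mean(xs: list[float]) -> float:
    return sum(xs) / len(xs)


def _sd(xs: list[float]) -> float:
    if len(xs) < 2:
        return 0.0
    mu = _mean(xs)
    return math.sqrt(sum((x - mu) ** 2 for x in xs) / (len(xs) - 1))


def _normalize_zip(path: Path) -> None:
    """Rewrite the xlsx zip with fixed entry timestamps so identical
    content yields identical bytes."""
    with zipfile.ZipFile(path) as zin:
        items = sorted((n, zin.read(n)) for n in zin.namelist())
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zout:
        for name, data in items:
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            info.external_attr = 0o644 << 16
            zout.writestr(info, data)


def default_config(seed: int = 0, **overrides) -> SynthConfig:
    """Study-condition defaults: three HIV envelope antigens on a 10-point
    3-fold standard series (top 10,000 pg/ml), triplicate wells, four
    unknowns, 5% replicate noise."""
    analytes = [
        AnalyteSpec("ENV1", 34, LogisticParams(50.0, 30000.0, 150.0, 1.0)),
        AnalyteSpec("ENV2", 35, LogisticParams(80.0, 24000.0, 400.0, 1.1)),
        AnalyteSpec("ENV3", 36, LogisticParams(40.0, 27000.0, 900.0, 0.9)),
    ]
    unknowns = [
        UnknownSpec("specimen-A", 5000.0, 100.0),
        UnknownSpec("specimen-B", 20000.0, 100.0),
        UnknownSpec("specimen-C", 60000.0, 100.0),
        UnknownSpec("specimen-D", 150000.0, 100.0),
    ]
    cfg = SynthConfig(
        analytes=analytes, unknowns=unknowns, seed=seed, **overrides
    )
    return cfg
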