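"""Per-run analysis engine.

Ties the pieces together for one run: select the authoritative rows (raw
rows win when a file carries both raw and summary tables), normalize FI,
form replicate groups and %CVs, apply the high-%CV flag rule, build the
standard/QC titrations, fit 4pl and 5pl curves per (analyte, titration),
compute EC50/AUC/HighMFI, interpolate unknown concentrations from the
assigned standard curve, and make positivity calls.

Exclusions are applied either up front (``analyze_run(...,
exclusions=...)``) or incrementally (:func:`xmapqc.qc_within.
apply_exclusion` followed by :meth:`RunAnalysis.recompute`); both routes
yield identical results because curve fitting is deterministic given the
surviving points and a seed derived from stable keys.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import pandas as pd

from . import qc_within
from .curves import (
    CurveFit,
    InterpolationResult,
    TitrationPoint,
    auc_trapezoid,
    fit_both_models,
    high_mfi,
    interpolate_concentration,
)
from .errors import ConfigError
from .models import (
    Exclusion,
    QCFlag,
    ReplicateGroup,
    RowKind,
    RunData,
    SampleRole,
    WellRecord,
)
from .normalization import NormalizationOptions, prepare_response
from .qc_crossrun import RunMetrics
from .qc_within import FlagThresholds, PositivityParams, flag_high_cv

__all__ = ["AnalysisOptions", "RunAnalysis", "analyze_run"]

MODELS = ("fourpl", "fivepl")


@dataclass(frozen=True)
class AnalysisOptions:
    normalization: NormalizationOptions = NormalizationOptions()
    weight_exponent: float = 1.8
    thresholds: FlagThresholds = FlagThresholds()
    #: %CV basis: "subtracted" (post blank/background subtraction, pre
    #: conversion — the reported-FI scale) or "raw".
    cv_basis: str = "subtracted"
    #: model used for interpolating unknowns; falls back to the other
    #: model when this one fails to converge.
    interpolation_model: str = "fivepl"
    #: (sample description, analyte) -> positivity parameters
    positivity: dict[tuple[str, str], PositivityParams] = field(
        default_factory=dict
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_basis not in ("subtracted", "raw"):
            raise ConfigError(f"unknown cv_basis {self.cv_basis!r}")
        if self.interpolation_model not in MODELS:
            raise ConfigError(
                f"unknown interpolation model {self.interpolation_model!r}"
            )


def _fit_seed(base: int, analyte: str, titration: str) -> int:
    """Stable per-titration seed so full and incremental recomputation
    fit with identical starts."""
    key = f"{base}:{analyte}:{titration}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


@dataclass
class _WellCtx:
    """Working state for one authoritative well row."""

    record: WellRecord
    response: float                    # prepared response (fit scale)
    subtracted: float                  # post-subtraction, pre-conversion FI
    converted: float                   # converted (non-log) FI
    excluded: bool = False


@dataclass
class RunAnalysis:
    run: RunData
    options: AnalysisOptions
    ctx: list[_WellCtx] = field(default_factory=list)
    groups: list[ReplicateGroup] = field(default_factory=list)
    #: (analyte, titration name) -> {"fourpl": CurveFit, "fivepl": CurveFit}
    fits: dict[tuple[str, str], dict[str, CurveFit]] = field(
        default_factory=dict
    )
    #: (analyte, titration name) -> points used for the current fits
    points: dict[tuple[str, str], list[TitrationPoint]] = field(
        default_factory=dict
    )
    flags: list[QCFlag] = field(default_factory=list)
    exclusions: list[Exclusion] = field(default_factory=list)
    #: one row per unknown replicate group per analyte
    interpolations: list[dict] = field(default_factory=list)
    steps_applied: tuple[str, ...] = ()

    # ---- group / titration helpers -------------------------------------

    def titration_of(self, group: ReplicateGroup) -> str | None:
        """Name of the titration a replicate group belongs to, if any."""
        from .bioplex_io import QC_TITRATION, STANDARD_TITRATION

        if group.role is SampleRole.STANDARD:
            return STANDARD_TITRATION
        if group.role is SampleRole.QC_CONTROL:
            return QC_TITRATION
        return None

    def group_map(self) -> dict[tuple, ReplicateGroup]:
        return {g.key: g for g in self.groups}

    def mark_excluded_rows(self) -> None:
        """Propagate group exclusion status down to well rows."""
        excluded_keys = {g.key for g in self.groups if g.excluded}
        for c in self.ctx:
            w = c.record
            key = (w.analyte, w.sample_id, w.description, w.dilution)
            c.excluded = key in excluded_keys

    # ---- fitting --------------------------------------------------------

    def _build_points(
        self, analyte: str, titration: str
    ) -> list[TitrationPoint]:
        role = (
            SampleRole.STANDARD
            if titration == _standard_name() else SampleRole.QC_CONTROL
        )
        pts = []
        for g in self.groups:
            if g.analyte != analyte or g.role is not role:
                continue
            dose = _group_dose(g)
            if dose is None or dose <= 0:
                continue
            members = _group_ctx(self, g)
            resp = sum(c.response for c in members) / len(members)
            conv = sum(c.converted for c in members) / len(members)
            pts.append(
                TitrationPoint(
                    dose=dose, mean_response=resp, n_wells=len(members),
                    excluded=g.excluded, mean_fi=conv,
                )
            )
        pts.sort(key=lambda p: p.dose)
        return pts

    def _fit_one(self, analyte: str, titration: str) -> None:
        pts = self._build_points(analyte, titration)
        self.points[(analyte, titration)] = pts
        seed = _fit_seed(self.options.seed, analyte, titration)
        fits = fit_both_models(
            pts,
            weight_exponent=self.options.weight_exponent,
            log_transformed=self.options.normalization.log_transform,
            seed=seed,
        )
        auc = auc_trapezoid(pts)
        hm = high_mfi(pts)
        for fit in fits.values():
            fit.auc = auc
            fit.high_mfi = hm
        self.fits[(analyte, titration)] = fits

    def _interpolate_all(self) -> None:
        self.interpolations = []
        for g in self.groups:
            if g.role is not SampleRole.UNKNOWN:
                continue
            std_name = self.run.standard_assignment.get(g.analyte)
            members = _group_ctx(self, g)
            resp = sum(c.response for c in members) / len(members)
            result = InterpolationResult(conc=None, status="no_standard")
            model_used = None
            if std_name is not None:
                fits = self.fits.get((g.analyte, std_name), {})
                for model in _model_preference(
                    self.options.interpolation_model
                ):
                    fit = fits.get(model)
                    if fit is not None and fit.converged:
                        result = interpolate_concentration(
                            fit, resp, g.dilution
                        )
                        model_used = model
                        break
            positivity = None
            pp = self.options.positivity.get(
                (g.sample_key[1], g.analyte)
            )
            if pp is not None:
                positivity = qc_within.positivity_call(g.mean_fi, pp)
            self.interpolations.append(
                {
                    "analyte": g.analyte,
                    "sample_id": g.sample_key[0],
                    "description": g.sample_key[1],
                    "dilution": g.dilution,
                    "mean_response": resp,
                    "model": model_used,
                    "conc": result.conc,
                    "status": result.status,
                    "excluded": g.excluded,
                    "positive": positivity,
                }
            )

    def recompute(self, recompute_set: set[tuple[str, str]]) -> None:
        """Refit the given (analyte, titration) pairs and refresh every
        downstream interpolation; equivalent to a full re-analysis with
        the current exclusions."""
        for analyte, titration in sorted(recompute_set):
            self._fit_one(analyte, titration)
        self._interpolate_all()

    # ---- cross-run metrics ----------------------------------------------

    def run_metrics(self) -> list[RunMetrics]:
        """Per-(analyte, titration) metric records for cross-run QC."""
        out = []
        for (analyte, titration), fits in sorted(self.fits.items()):
            four, five = fits["fourpl"], fits["fivepl"]
            role = (
                "standard" if titration == _standard_name()
                else "qc_control"
            )
            rm = RunMetrics(
                run_id=self.run.metadata.run_name,
                analyte=analyte,
                titration_role=role,
                lot_scope=self.run.metadata.lot_scope,
                ec50_4pl=four.ec50,
                ec50_5pl=five.ec50,
                auc=four.auc,
                high_mfi=four.high_mfi,
            )
            if rm.any_metric_present():
                out.append(rm)
        return out

    # ---- canonical tables -----------------------------------------------

    def well_table(self) -> pd.DataFrame:
        flag_keys = {
            f.target: f for f in self.flags if f.kind == "high_cv"
        }
        group_by_key = self.group_map()
        rows = []
        for c in self.ctx:
            w = c.record
            gkey = (w.analyte, w.sample_id, w.description, w.dilution)
            g = group_by_key.get(gkey)
            flag = flag_keys.get(gkey)
            rows.append(
                {
                    "analyte": w.analyte,
                    "bead_number": self.run.bead_numbers.get(w.analyte),
                    "sample_type": w.sample_id,
                    "sample_role": w.sample_role.value,
                    "description": w.description,
                    "wells": ";".join(w.wells),
                    "row_kind": w.row_kind.value,
                    "dilution": w.dilution,
                    "expected_conc": w.expected_conc,
                    "fi_raw": w.fi,
                    "fi_subtracted": c.subtracted,
                    "fi_converted": c.converted,
                    "response_used": c.response,
                    "bead_count": w.bead_count,
                    "pct_cv": g.pct_cv if g else None,
                    "excluded": c.excluded,
                    "flag_kind": flag.kind if flag else None,
                    "flag_active": flag.active if flag else None,
                    "source_file": w.source_file,
                }
            )
        return pd.DataFrame(rows)

    def curve_table(self) -> pd.DataFrame:
        rows = []
        for (analyte, titration), fits in sorted(self.fits.items()):
            for model in MODELS:
                fit = fits[model]
                p = fit.params
                rows.append(
                    {
                        "run": self.run.metadata.run_name,
                        "analyte": analyte,
                        "titration": titration,
                        "model": model,
                        "converged": fit.converged,
                        "a_min": p.a_min if p else None,
                        "a_max": p.a_max if p else None,
                        "inflection_m": p.m if p else None,
                        "slope_h": p.h if p else None,
                        "asymmetry_s": p.s if p else None,
                        "weight_exponent": fit.weight_exponent,
                        "log_transformed": fit.log_transformed,
                        "weighted_rss": fit.rss,
                    }
                )
        return pd.DataFrame(rows)

    def metric_table(self) -> pd.DataFrame:
        rows = []
        for (analyte, titration), fits in sorted(self.fits.items()):
            four, five = fits["fourpl"], fits["fivepl"]
            rows.append(
                {
                    "run": self.run.metadata.run_name,
                    "analyte": analyte,
                    "titration": titration,
                    "ec50_4pl": four.ec50,
                    "ec50_5pl": five.ec50,
                    "auc": four.auc,
                    "high_mfi": four.high_mfi,
                }
            )
        return pd.DataFrame(rows)

    def interpolation_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.interpolations)

    def run_metrics_table(self) -> pd.DataFrame:
        """Cross-run metric rows with lot scope, for guide-set building."""
        md = self.run.metadata
        rows = [
            {
                "run": rm.run_id,
                "analyte": rm.analyte,
                "titration_role": rm.titration_role,
                "reagent_lot": md.reagent_lot,
                "isotype": md.isotype,
                "conjugate": md.conjugate,
                "ec50_4pl": rm.ec50_4pl,
                "ec50_5pl": rm.ec50_5pl,
                "auc": rm.auc,
                "high_mfi": rm.high_mfi,
            }
            for rm in self.run_metrics()
        ]
        return pd.DataFrame(rows)


def _standard_name() -> str:
    from .bioplex_io import STANDARD_TITRATION

    return STANDARD_TITRATION


def _model_preference(first: str) -> tuple[str, str]:
    return (first, "fourpl" if first == "fivepl" else "fivepl")


def _group_dose(g: ReplicateGroup) -> float | None:
    exp = [
        w.expected_conc for w in g.members if w.expected_conc is not None
    ]
    if exp:
        return exp[0]
    return 1.0 / g.dilution if g.dilution else None


def _group_ctx(state: RunAnalysis, g: ReplicateGroup) -> list[_WellCtx]:
    ids = {id(w) for w in g.members}
    return [c for c in state.ctx if id(c.record) in ids]


def _authoritative_rows(run: RunData) -> list[WellRecord]:
    """Raw rows win where both kinds exist for an analyte; summary rows
    are used only when they are all the analyte has."""
    has_raw = {
        w.analyte for w in run.wells if w.row_kind is RowKind.RAW
    }
    return [
        w for w in run.wells
        if w.row_kind is RowKind.RAW or w.analyte not in has_raw
    ]


def analyze_run(
    run: RunData,
    options: AnalysisOptions | None = None,
    exclusions: list[Exclusion] | None = None,
) -> RunAnalysis:
    """Full analysis of one (possibly merged) run."""
    options = options or AnalysisOptions()
    state = RunAnalysis(run=run, options=options)

    norm = options.normalization
    blank_analyte = norm.blank_bead_analyte
    blank_wells = (
        [w for w in run.wells if w.analyte == blank_analyte]
        if norm.subtract_blank_bead else None
    )
    if norm.subtract_blank_bead and not blank_wells:
        raise ConfigError(
            f"blank-bead analyte {blank_analyte!r} not present in run"
        )

    rows = _authoritative_rows(run)
    for analyte in run.analytes:
        if analyte == blank_analyte:
            continue
        wells = [w for w in rows if w.analyte == analyte]
        if not wells:
            continue
        responses, subtracted, steps = prepare_response(
            wells, norm, blank_wells=blank_wells
        )
        state.steps_applied = steps
        from .normalization import convert_fi

        for w, resp, sub in zip(wells, responses, subtracted):
            state.ctx.append(
                _WellCtx(
                    record=w, response=resp, subtracted=sub,
                    converted=convert_fi(sub),
                )
            )

    # replicate groups over authoritative rows
    order: list[tuple] = []
    members: dict[tuple, list[_WellCtx]] = {}
    for c in state.ctx:
        w = c.record
        key = (w.analyte, w.sample_id, w.description, w.dilution)
        if key not in members:
            members[key] = []
            order.append(key)
        members[key].append(c)
    for key in order:
        ctxs = members[key]
        records = [c.record for c in ctxs]
        basis = (
            [c.subtracted for c in ctxs]
            if options.cv_basis == "subtracted"
            else [float(c.record.fi) for c in ctxs]
        )
        mean_fi = sum(basis) / len(basis)
        if len(records) == 1 and records[0].row_kind is RowKind.SUMMARY:
            pct = records[0].reported_pct_cv
        else:
            pct = qc_within.percent_cv(basis)
        state.groups.append(
            ReplicateGroup(
                analyte=key[0],
                sample_key=(key[1], key[2]),
                dilution=key[3],
                members=records,
                mean_fi=mean_fi,
                pct_cv=pct,
                role=records[0].sample_role,
            )
        )

    # exclusions requested up front
    for excl in exclusions or []:
        for g in state.groups:
            if excl.matches(g):
                g.excluded = True
        if excl not in state.exclusions:
            state.exclusions.append(excl)
    state.mark_excluded_rows()

    # high-%CV flags (flag even when excluded; exclusion is separate)
    next_id = 0
    for g in state.groups:
        flag = flag_high_cv(g, options.thresholds)
        if flag is not None:
            flag.flag_id = next_id
            next_id += 1
            state.flags.append(flag)

    # titration fits + metrics
    for analyte in run.analytes:
        if analyte == blank_analyte:
            continue
        for tit in run.titrations:
            has_points = any(
                g.analyte == analyte and state.titration_of(g) == tit.name
                for g in state.groups
            )
            if has_points:
                state._fit_one(analyte, tit.name)

    state._interpolate_all()
    return state
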