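"""Cross-run quality control: guide sets, expected ranges, Levey-Jennings
series and automatic outlier flags.

Four per-titration metrics are tracked across runs: the 4pl EC50, the 5pl
EC50, AUC and HighMFI.  A *guide set* is a user-selected suite of baseline
runs sharing a lot scope (reagent lot, isotype, conjugate); its per-metric
mean and sample SD define expected ranges at mu +/- 1, 2 and 3 sigma.  A
later run's metric is flagged when it falls strictly outside mu +/- 3
sigma; values exactly on the boundary are not flagged.  Flags can be
inactivated after review — the record is kept, never deleted.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import XmapError
from .models import QCFlag

__all__ = [
    "CROSSRUN_METRICS",
    "RunMetrics",
    "GuideSet",
    "MetricBand",
    "build_guide_set",
    "expected_ranges",
    "flag_metrics",
    "inactivate_flag",
    "levey_jennings_series",
    "save_guide_sets",
    "load_guide_sets",
]

#: The cross-run performance metrics, in reporting order.
CROSSRUN_METRICS = ("ec50_4pl", "ec50_5pl", "auc", "high_mfi")

#: Guide-set flag rule: strictly outside mean +/- 3 SD.
SD_MULTIPLIER = 3.0


@dataclass
class RunMetrics:
    """One run's curve metrics for one (analyte, titration role)."""

    run_id: str
    analyte: str
    titration_role: str                # "standard" | "qc_control"
    lot_scope: tuple[str, str, str]    # (reagent_lot, isotype, conjugate)
    ec50_4pl: float | None = None
    ec50_5pl: float | None = None
    auc: float | None = None
    high_mfi: float | None = None
    acquisition_order: int = 0

    def metric(self, name: str) -> float | None:
        if name not in CROSSRUN_METRICS:
            raise KeyError(name)
        return getattr(self, name)

    def any_metric_present(self) -> bool:
        return any(self.metric(m) is not None for m in CROSSRUN_METRICS)


@dataclass
class GuideSet:
    """Baseline-run statistics defining expected metric ranges."""

    analyte: str
    titration_role: str
    lot_scope: tuple[str, str, str]
    member_run_ids: list[str]
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float | None] = field(default_factory=dict)


@dataclass
class MetricBand:
    metric: str
    mu: float
    sigma: float
    bands: dict[int, tuple[float, float]]   # k -> (mu - k sigma, mu + k sigma)


def _mean_sd(values: list[float]) -> tuple[float, float | None]:
    n = len(values)
    mu = sum(values) / n
    if n < 2:
        return mu, None
    var = sum((v - mu) ** 2 for v in values) / (n - 1)
    return mu, math.sqrt(var)


def build_guide_set(
    metrics: list[RunMetrics], member_run_ids: list[str]
) -> GuideSet:
    """Compute per-metric mean and sample SD over the chosen member runs.

    Members must share analyte, titration role and lot scope.  A metric
    absent from some member is averaged over the members that carry it;
    its SD is absent (and flagging for it disabled) with fewer than two
    such members.
    """
    members = [m for m in metrics if m.run_id in set(member_run_ids)]
    if not members:
        raise XmapError("guide set needs at least one member run")
    keys = {(m.analyte, m.titration_role, m.lot_scope) for m in members}
    if len(keys) > 1:
        raise XmapError(
            f"guide-set members span multiple analyte/role/lot scopes: "
            f"{sorted(keys)}"
        )
    analyte, role, lot = next(iter(keys))
    gs = GuideSet(
        analyte=analyte, titration_role=role, lot_scope=lot,
        member_run_ids=[m.run_id for m in members],
    )
    for name in CROSSRUN_METRICS:
        values = [m.metric(name) for m in members
                  if m.metric(name) is not None]
        if not values:
            continue
        mu, sd = _mean_sd(values)
        gs.means[name] = mu
        gs.sds[name] = sd
        if sd is None:
            warnings.warn(
                f"guide set for {analyte}/{role}: single member carries "
                f"{name}; SD undefined, flagging disabled for this metric",
                stacklevel=2,
            )
    return gs


def expected_ranges(gs: GuideSet, metric: str) -> MetricBand | None:
    """Nested mu +/- k sigma bands (k = 1, 2, 3); None when the SD is
    unavailable for the metric."""
    if metric not in gs.means:
        return None
    sigma = gs.sds.get(metric)
    if sigma is None:
        return None
    mu = gs.means[metric]
    return MetricBand(
        metric=metric, mu=mu, sigma=sigma,
        bands={k: (mu - k * sigma, mu + k * sigma) for k in (1, 2, 3)},
    )


def flag_metrics(
    run: RunMetrics, gs: GuideSet, _next_id: int = 0
) -> list[QCFlag]:
    """Flag each present metric strictly outside mu +/- 3 sigma.

    Guide-set member runs are never flagged against their own set.  With
    no applicable guide set (scope mismatch), returns no flags with a
    warning.
    """
    if (run.analyte, run.titration_role, run.lot_scope) != (
        gs.analyte, gs.titration_role, gs.lot_scope
    ):
        warnings.warn(
            f"no applicable guide set for run {run.run_id!r} "
            f"({run.analyte}/{run.titration_role}); no flags raised",
            stacklevel=2,
        )
        return []
    if run.run_id in set(gs.member_run_ids):
        return []
    flags: list[QCFlag] = []
    for name in CROSSRUN_METRICS:
        value = run.metric(name)
        if value is None:
            continue
        band = expected_ranges(gs, name)
        if band is None:
            continue
        lo, hi = band.bands[3]
        if value < lo or value > hi:
            flags.append(
                QCFlag(
                    kind="guideset_outlier",
                    target=(run.run_id, run.analyte, run.titration_role,
                            name),
                    value=value,
                    rule=(
                        f"{name} outside mean +/- "
                        f"{SD_MULTIPLIER:g} SD [{lo:g}, {hi:g}]"
                    ),
                    flag_id=_next_id + len(flags),
                )
            )
    return flags


def inactivate_flag(
    flags: list[QCFlag], flag_id: int, comment: str = ""
) -> QCFlag:
    """Mark a flag reviewed-and-acceptable: active=False with the review
    comment; the record is retained.  Idempotent; unknown ids raise."""
    for flag in flags:
        if flag.flag_id == flag_id:
            if flag.active:
                flag.active = False
                flag.comment = comment
            return flag
    raise XmapError(f"no flag with id {flag_id}")


def levey_jennings_series(
    runs: list[RunMetrics],
    guide_sets: dict[tuple[str, str, str], GuideSet],
    metric: str,
) -> pd.DataFrame:
    """Plot-ready Levey-Jennings series for one metric.

    Runs must already be ordered (acquisition date, ties by run id).  Each
    row carries the run's value, the applicable lot-scope guide-set bands
    (band columns are empty where no guide set applies or its SD is
    undefined) and the flag status; band regimes change at lot boundaries.
    """
    if metric not in CROSSRUN_METRICS:
        raise KeyError(metric)
    rows = []
    for run in runs:
        gs = guide_sets.get(run.lot_scope)
        band = expected_ranges(gs, metric) if gs is not None else None
        value = run.metric(metric)
        flagged = False
        if gs is not None and value is not None:
            flagged = any(
                f.target[3] == metric for f in flag_metrics(run, gs)
            )
        row = {
            "run_id": run.run_id,
            "analyte": run.analyte,
            "titration_role": run.titration_role,
            "reagent_lot": run.lot_scope[0],
            "metric": metric,
            "value": value,
            "mu": band.mu if band else None,
            "sigma": band.sigma if band else None,
            "flagged": flagged,
        }
        for k in (1, 2, 3):
            lo, hi = band.bands[k] if band else (None, None)
            row[f"band{k}_lo"] = lo
            row[f"band{k}_hi"] = hi
        rows.append(row)
    return pd.DataFrame(rows)


def save_guide_sets(
    guide_sets: list[GuideSet], path: Path | str
) -> None:
    payload = [
        {
            "analyte": gs.analyte,
            "titration_role": gs.titration_role,
            "lot_scope": list(gs.lot_scope),
            "member_run_ids": gs.member_run_ids,
            "means": gs.means,
            "sds": gs.sds,
        }
        for gs in guide_sets
    ]
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_guide_sets(path: Path | str) -> list[GuideSet]:
    payload = json.loads(Path(path).read_text())
    return [
        GuideSet(
            analyte=item["analyte"],
            titration_role=item["titration_role"],
            lot_scope=tuple(item["lot_scope"]),
            member_run_ids=item["member_run_ids"],
            means=item["means"],
            sds=item["sds"],
        )
        for item in payload
    ]
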