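"""Within-run quality control: replicate %CV, the automatic flagging rule,
exclusions with recomputation, and positivity calls.

The flagging rule marks a replicate group when its mean FI exceeds 100
*and* its %CV exceeds 15 (unknowns) or 20 (standards and QC controls).
The FI gate saves review time: only samples with appreciable signal
warrant investigation.  Thresholds are configurable; these are the
defaults.  Comparisons are strict (greater than).

Exclusions never delete data: rows are marked excluded and retained, and
every titration containing an excluded point is reported for recomputation
of its curve fits and metrics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .models import Exclusion, QCFlag, ReplicateGroup, SampleRole

__all__ = [
    "FlagThresholds",
    "PositivityParams",
    "percent_cv",
    "flag_high_cv",
    "apply_exclusion",
    "positivity_call",
]


@dataclass(frozen=True)
class FlagThresholds:
    """Constants of the high-%CV flag rule (printed defaults)."""

    fi_gate: float = 100.0
    cv_limit_unknown: float = 15.0
    cv_limit_titration: float = 20.0

    def cv_limit(self, role: SampleRole) -> float:
        if role in (SampleRole.STANDARD, SampleRole.QC_CONTROL):
            return self.cv_limit_titration
        return self.cv_limit_unknown


@dataclass(frozen=True)
class PositivityParams:
    """Per-(sample, analyte) baseline, per-analyte threshold, and the
    fold-change a value must reach over baseline to be called positive."""

    baseline: float
    threshold: float
    fold_change: float = 3.0

    def __post_init__(self) -> None:
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")


def percent_cv(values: list[float]) -> float | None:
    """100 x sample SD (n-1 denominator) / mean; None for n < 2 or when
    the mean is zero (with a warning)."""
    n = len(values)
    if n < 2:
        return None
    mean = sum(values) / n
    if mean == 0:
        warnings.warn("%CV undefined for zero-mean replicates",
                      stacklevel=2)
        return None
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return 100.0 * math.sqrt(var) / mean


def flag_high_cv(
    group: ReplicateGroup,
    thresholds: FlagThresholds = FlagThresholds(),
) -> QCFlag | None:
    """Apply the high-%CV rule to one replicate group; None when the group
    passes or %CV is unavailable."""
    if group.pct_cv is None:
        return None
    limit = thresholds.cv_limit(group.role)
    if group.mean_fi > thresholds.fi_gate and group.pct_cv > limit:
        return QCFlag(
            kind="high_cv",
            target=group.key,
            value=group.pct_cv,
            rule=(
                f"FI > {thresholds.fi_gate:g} and %CV > {limit:g} "
                f"({group.role.value})"
            ),
        )
    return None


def apply_exclusion(state, exclusion: Exclusion) -> set[tuple[str, str]]:
    """Mark the targeted wells of an analysis state as excluded.

    Returns the recompute set: every (analyte, titration name) whose curve
    and metrics must be refreshed because the exclusion touched one of its
    points.  Excluding non-titration data (unknown/control/background
    groups) marks rows but triggers no refit.  Re-applying an identical
    exclusion is a no-op.

    ``state`` is a :class:`~xmapqc.analysis.RunAnalysis`; the actual
    refitting is done by :meth:`~xmapqc.analysis.RunAnalysis.recompute`.
    """
    from .errors import XmapError

    matched = [g for g in state.groups if exclusion.matches(g)]
    if not matched:
        raise XmapError(
            f"exclusion target not found: {exclusion.scope} "
            f"{exclusion.analyte!r} {exclusion.sample_key!r}"
        )
    recompute: set[tuple[str, str]] = set()
    changed = False
    for g in matched:
        if not g.excluded:
            g.excluded = True
            changed = True
        name = state.titration_of(g)
        if name is not None:
            recompute.add((g.analyte, name))
    if changed and exclusion not in state.exclusions:
        state.exclusions.append(exclusion)
    state.mark_excluded_rows()
    return recompute


def positivity_call(value: float, params: PositivityParams) -> bool:
    """Positive iff the value reached ``fold_change x baseline`` and
    strictly exceeds the analyte-specific threshold."""
    return (
        value >= params.fold_change * params.baseline
        and value > params.threshold
    )


# ---- exclusion sidecar (append-only JSON log) ---------------------------

def save_exclusions(exclusions: list[Exclusion], path) -> None:
    """Write the exclusion log; raw parsed data is never mutated, so this
    sidecar is the durable record of what was removed and why."""
    import json
    from pathlib import Path

    payload = [
        {
            "scope": e.scope,
            "analyte": e.analyte,
            "sample_id": e.sample_key[0] if e.sample_key else None,
            "description": e.sample_key[1] if e.sample_key else None,
            "dilution": e.dilution,
            "reason": e.reason,
            "timestamp": e.timestamp,
        }
        for e in exclusions
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def load_exclusions(path) -> list[Exclusion]:
    import json
    from pathlib import Path

    path = Path(path)
    if not path.exists():
        return []
    out = []
    for item in json.loads(path.read_text()):
        sample_key = None
        if item.get("sample_id") is not None:
            sample_key = (item["sample_id"], item.get("description", ""))
        out.append(
            Exclusion(
                scope=item["scope"],
                analyte=item["analyte"],
                sample_key=sample_key,
                dilution=item.get("dilution"),
                reason=item.get("reason", ""),
                timestamp=item.get("timestamp", ""),
            )
        )
    return out
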