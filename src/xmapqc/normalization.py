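"""FI normalization: blank-bead / background subtraction, conversion, log.

Raw median fluorescence intensities may be adjusted before curve fitting:

1. blank-bead subtraction (optional) — subtract, per well position, the FI
   of an uncoupled ("blank") bead region measured in the same well, which
   removes signal from non-specific binding to the beads themselves;
2. background subtraction (optional) — subtract the mean FI of buffer-only
   background wells for the analyte, removing detector non-specific signal;
3. conversion (always) — ``converted FI = max(FI, 0) + 1``, which maps the
   possibly-negative subtracted values onto [1, inf);
4. natural-log transform (optional) — stabilises variance extremes before
   fitting.

Both subtractions are additive constants per well, so their order does not
change the result.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import ConfigError, FormatError
from .models import SampleRole, WellRecord

__all__ = [
    "NormalizationOptions",
    "background_mean",
    "subtract_blank_bead",
    "convert_fi",
    "prepare_response",
]


@dataclass(frozen=True)
class NormalizationOptions:
    subtract_blank_bead: bool = False
    subtract_background: bool = False
    log_transform: bool = False
    blank_bead_analyte: str | None = None

    def __post_init__(self) -> None:
        if self.subtract_blank_bead and not self.blank_bead_analyte:
            raise ConfigError(
                "blank_bead_analyte is required when subtract_blank_bead "
                "is enabled"
            )

    @property
    def steps(self) -> tuple[str, ...]:
        """Names of the processing steps that will be applied, in order."""
        out = []
        if self.subtract_blank_bead:
            out.append("blank_bead_subtraction")
        if self.subtract_background:
            out.append("background_subtraction")
        out.append("convert")
        if self.log_transform:
            out.append("log")
        return tuple(out)


def background_mean(wells: list[WellRecord]) -> float:
    """Arithmetic mean FI of the background (buffer-only) wells among
    ``wells``; raises if there are none."""
    fis = [w.fi for w in wells if w.sample_role is SampleRole.BACKGROUND]
    if not fis:
        raise FormatError("no background wells available for subtraction")
    return sum(fis) / len(fis)


def _blank_lookup(blank_wells: list[WellRecord]) -> dict[str, float]:
    table: dict[str, float] = {}
    for w in blank_wells:
        for pos in w.wells:
            table[pos] = w.fi
    return table


def subtract_blank_bead(
    wells: list[WellRecord], blank_wells: list[WellRecord]
) -> list[float]:
    """FI minus the blank-bead FI measured in the same well position.

    Results may be negative; the mandatory conversion step accounts for
    that later.  Raises when a target well has no positional match on the
    blank-bead sheet.
    """
    table = _blank_lookup(blank_wells)
    missing = sorted(
        {pos for w in wells for pos in w.wells if pos not in table}
    )
    if missing:
        raise FormatError(
            "blank-bead sheet is missing well positions: "
            + ", ".join(missing)
        )
    out = []
    for w in wells:
        blank = sum(table[pos] for pos in w.wells) / len(w.wells)
        out.append(w.fi - blank)
    return out


def convert_fi(fi: float) -> float:
    """Mandatory conversion ``max(FI, 0) + 1``: clamps negatives introduced
    by blank/background subtraction and keeps responses >= 1."""
    return max(fi, 0.0) + 1.0


def prepare_response(
    wells: list[WellRecord],
    options: NormalizationOptions,
    blank_wells: list[WellRecord] | None = None,
    mismatch_rtol: float = 1e-6,
) -> tuple[list[float], list[float], tuple[str, ...]]:
    """Run the normalization pipeline on one analyte's wells.

    Returns ``(responses, subtracted_fi, steps)`` where ``responses`` are
    the values handed to curve fitting (converted, optionally logged),
    ``subtracted_fi`` the values after the subtraction steps but before
    conversion (the scale %CV is computed on), and ``steps`` the applied
    step names.

    Background subtraction recomputes the background mean from the run's
    own background wells; when a file carries a stale "FI - Bkgd" column
    that disagrees, a warning is emitted and the recomputed value wins.
    """
    values = [float(w.fi) for w in wells]
    if options.subtract_blank_bead:
        if blank_wells is None:
            raise ConfigError(
                "blank-bead subtraction requested but no blank-bead wells "
                "were supplied"
            )
        values = subtract_blank_bead(wells, blank_wells)
    if options.subtract_background:
        bkgd = background_mean(wells)
        values = [v - bkgd for v in values]
        if not options.subtract_blank_bead:
            for w, v in zip(wells, values):
                if w.fi_bkgd is None:
                    continue
                tol = mismatch_rtol * max(1.0, abs(w.fi))
                if abs(w.fi_bkgd - v) > tol:
                    warnings.warn(
                        f"file-reported FI-Bkgd {w.fi_bkgd} differs from "
                        f"recomputed {v:.6g} for well(s) {w.wells} "
                        f"({w.analyte}); using the recomputed value",
                        stacklevel=2,
                    )
    subtracted = list(values)
    responses = [convert_fi(v) for v in values]
    if options.log_transform:
        responses = [math.log(v) for v in responses]
    return responses, subtracted, options.steps
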