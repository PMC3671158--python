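"""Dose-response curve fitting and titration metrics.

The model is the five-parameter logistic in log dose,

    f(x) = A_min + (A_max - A_min) / (1 + exp(-h * (ln x - ln m)))**s

with lower/upper asymptotes ``A_min``/``A_max`` (at dose -> 0 and dose ->
infinity respectively, for positive slope ``h``), inflection dose ``m > 0``,
slope ``h`` and asymmetry ``s > 0``.  ``s = 1`` gives the symmetric
four-parameter logistic (4pl), for which the midpoint dose EC50 equals
``m`` exactly; in general

    EC50 = m * (2**(1/s) - 1)**(-1/h).

Fits minimise the weighted sum of squared errors with power-law FI weights
``w_i = 1 / max(y_i, 1)**p`` (observed response, floor of 1 to guard the
division), the weighting scheme used to counter the lower variance of
low-FI measurements.  The default exponent is p = 1.8.

Per-titration summary metrics are EC50, AUC (trapezoidal area under the
observed titration points over log10 dose) and HighMFI (highest replicate
mean FI).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError, FitError

__all__ = [
    "LogisticParams",
    "TitrationPoint",
    "CurveFit",
    "InterpolationResult",
    "eval_logistic",
    "fit_titration",
    "ec50_from_params",
    "auc_trapezoid",
    "high_mfi",
    "interpolate_concentration",
]

#: Floor applied to observed responses inside the weight computation.
WEIGHT_FLOOR = 1.0
DEFAULT_WEIGHT_EXPONENT = 1.8


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of the 4pl/5pl logistic; see module docstring."""

    a_min: float
    a_max: float
    m: float
    h: float
    s: float = 1.0

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError("inflection dose m must be > 0")
        if self.s <= 0:
            raise ValueError("asymmetry s must be > 0")
        if self.h == 0:
            raise ValueError("slope h must be nonzero")


@dataclass
class TitrationPoint:
    """One dilution point of a titration (replicate-group aggregate)."""

    dose: float                        # expected conc, or 1/dilution
    mean_response: float               # replicate mean of prepared response
    n_wells: int = 1
    excluded: bool = False
    #: replicate mean on the converted-FI scale; equals ``mean_response``
    #: unless fitting used a log-transformed response.
    mean_fi: float | None = None

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError("dose must be > 0")
        if self.mean_fi is None:
            self.mean_fi = self.mean_response


@dataclass
class CurveFit:
    """Result of fitting one titration with one model."""

    model: str                         # "fourpl" | "fivepl"
    params: LogisticParams | None
    weight_exponent: float
    log_transformed: bool
    converged: bool
    rss: float | None                  # weighted residual sum of squares
    ec50: float | None = None
    auc: float | None = None
    high_mfi: float | None = None
    n_points: int = 0


@dataclass
class InterpolationResult:
    """Interpolated sample concentration, or an out-of-range marker."""

    conc: float | None
    status: str                        # "ok" | "below_range" | "above_range"

    @property
    def in_range(self) -> bool:
        return self.status == "ok"


def eval_logistic(params: LogisticParams, dose) -> np.ndarray | float:
    """Evaluate the logistic at ``dose`` (scalar or array of doses > 0)."""
    x = np.asarray(dose, dtype=float)
    if np.any(x <= 0):
        raise DomainError("dose must be > 0")
    z = -params.h * (np.log(x) - math.log(params.m))
    # (1+e^z)^s computed in log space to avoid overflow at extreme doses
    denom_log = params.s * np.logaddexp(0.0, z)
    out = params.a_min + (params.a_max - params.a_min) * np.exp(-denom_log)
    return float(out) if np.isscalar(dose) else out


def _active(points: list[TitrationPoint]) -> list[TitrationPoint]:
    return [p for p in points if not p.excluded]


def _initial_guess(x: np.ndarray, y: np.ndarray) -> LogisticParams:
    """Heuristic start: asymptotes from data range, m near the half-range
    crossing, slope sign from the observed monotone direction."""
    a_min, a_max = float(y.min()), float(y.max())
    if a_max == a_min:
        a_max = a_min + 1.0
    half = 0.5 * (a_min + a_max)
    m = float(x[np.argmin(np.abs(y - half))])
    increasing = y[np.argmax(x)] >= y[np.argmin(x)]
    h = 1.0 if increasing else -1.0
    if not increasing:
        a_min, a_max = a_max, a_min
    return LogisticParams(a_min=a_min, a_max=a_max, m=m, h=h, s=1.0)


def _pack(p: LogisticParams, fivepl: bool) -> np.ndarray:
    theta = [p.a_min, p.a_max, math.log(p.m), p.h]
    if fivepl:
        theta.append(math.log(p.s))
    return np.array(theta, dtype=float)


def _unpack(theta: np.ndarray, fivepl: bool) -> LogisticParams:
    s = math.exp(theta[4]) if fivepl else 1.0
    return LogisticParams(
        a_min=float(theta[0]),
        a_max=float(theta[1]),
        m=math.exp(float(theta[2])),
        h=float(theta[3]),
        s=s,
    )


def fit_titration(
    points: list[TitrationPoint],
    model: str = "fivepl",
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
    log_transformed: bool = False,
    seed: int = 0,
    n_restarts: int = 3,
    extra_starts: list[LogisticParams] | None = None,
) -> CurveFit:
    """Weighted least-squares fit of a 4pl or 5pl curve to titration points.

    Excluded points never enter the objective.  The 4pl fit is the 5pl
    problem with ``s`` pinned at 1.  For 5pl fits the 4pl solution should be
    supplied via ``extra_starts`` so the richer model can never do worse
    than the nested one; :func:`fit_both_models` arranges this.

    Parameters are optimised on an unconstrained scale (log m, log s), with
    up to ``n_restarts`` seeded jittered restarts on non-convergence.

    Raises
    ------
    FitError
        If fewer non-excluded points than free parameters remain.
    """
    if model not in ("fourpl", "fivepl"):
        raise ValueError(f"unknown model {model!r}")
    fivepl = model == "fivepl"
    n_free = 5 if fivepl else 4
    active = _active(points)
    if len(active) < n_free:
        raise FitError(
            f"{model} fit needs >= {n_free} non-excluded points, "
            f"got {len(active)}"
        )
    x = np.array([p.dose for p in active], dtype=float)
    y = np.array([p.mean_response for p in active], dtype=float)
    w = 1.0 / np.maximum(y, WEIGHT_FLOOR) ** weight_exponent
    sw = np.sqrt(w)

    def residuals(theta: np.ndarray) -> np.ndarray:
        return sw * (y - eval_logistic(_unpack(theta, fivepl), x))

    def wrss(theta: np.ndarray) -> float:
        return float(np.sum(residuals(theta) ** 2))

    starts = [_initial_guess(x, y)]
    if extra_starts:
        starts += [
            replace(st, s=st.s if fivepl else 1.0) for st in extra_starts
        ]
    rng = np.random.default_rng(seed)
    jitter_base = starts[0]
    for _ in range(n_restarts):
        starts.append(
            LogisticParams(
                a_min=jitter_base.a_min * rng.uniform(0.8, 1.2),
                a_max=jitter_base.a_max * rng.uniform(0.8, 1.2),
                m=jitter_base.m * rng.uniform(0.5, 2.0),
                h=jitter_base.h * rng.uniform(0.5, 2.0),
                s=1.0 if not fivepl else rng.uniform(0.5, 2.0),
            )
        )

    best_theta = None
    best_cost = math.inf
    any_success = False
    for start in starts:
        try:
            res = least_squares(
                residuals, _pack(start, fivepl), method="lm", xtol=1e-12,
                ftol=1e-12, gtol=1e-12, max_nfev=20000,
            )
        except Exception:
            continue
        cost = wrss(res.x)
        if res.success and np.isfinite(cost):
            any_success = True
            if cost < best_cost:
                best_cost = cost
                best_theta = res.x

    if not any_success or best_theta is None:
        return CurveFit(
            model=model, params=None, weight_exponent=weight_exponent,
            log_transformed=log_transformed, converged=False, rss=None,
            n_points=len(active),
        )
    params = _unpack(best_theta, fivepl)
    fit = CurveFit(
        model=model, params=params, weight_exponent=weight_exponent,
        log_transformed=log_transformed, converged=True, rss=best_cost,
        n_points=len(active),
    )
    fit.ec50 = ec50_from_params(fit)
    return fit


def fit_both_models(
    points: list[TitrationPoint],
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
    log_transformed: bool = False,
    seed: int = 0,
) -> dict[str, CurveFit]:
    """Fit 4pl and 5pl to the same points; the 5pl start set includes the
    4pl solution so the nested-model RSS ordering holds.

    Unlike :func:`fit_titration`, an under-determined model yields a
    non-converged :class:`CurveFit` rather than raising, so a titration
    reduced below four points by exclusions still reports a (metric-less)
    row.
    """

    def _try(model: str, extra: list[LogisticParams] | None) -> CurveFit:
        try:
            return fit_titration(
                points, model=model, weight_exponent=weight_exponent,
                log_transformed=log_transformed, seed=seed,
                extra_starts=extra,
            )
        except FitError:
            return CurveFit(
                model=model, params=None, weight_exponent=weight_exponent,
                log_transformed=log_transformed, converged=False, rss=None,
                n_points=len(_active(points)),
            )

    four = _try("fourpl", None)
    extra = [four.params] if four.converged and four.params else None
    five = _try("fivepl", extra)
    return {"fourpl": four, "fivepl": five}


def ec50_from_params(fit: CurveFit) -> float | None:
    """Midpoint dose: where the curve reaches (A_min + A_max)/2.

    Closed form ``m * (2**(1/s) - 1)**(-1/h)``; exactly ``m`` when s = 1.
    Returns None when the fit did not converge or the form is non-finite.
    """
    if not fit.converged or fit.params is None:
        return None
    p = fit.params
    if p.s == 1.0:
        return p.m
    try:
        ec50 = p.m * (2.0 ** (1.0 / p.s) - 1.0) ** (-1.0 / p.h)
    except (OverflowError, ZeroDivisionError, ValueError):
        return None
    return ec50 if math.isfinite(ec50) and ec50 > 0 else None


def auc_trapezoid(points: list[TitrationPoint]) -> float | None:
    """Trapezoidal area under (log10 dose, mean response), ascending dose.

    Uses only non-excluded points; returns None with fewer than two
    distinct doses.
    """
    active = _active(points)
    doses = sorted({p.dose for p in active})
    if len(doses) < 2:
        return None
    pairs = sorted(((p.dose, p.mean_response) for p in active))
    x = np.log10([d for d, _ in pairs])
    y = np.array([r for _, r in pairs])
    return float(np.trapezoid(y, x))


def high_mfi(points: list[TitrationPoint]) -> float | None:
    """Highest replicate-group mean FI (converted, non-log scale) among
    non-excluded points; None if every point is excluded."""
    active = _active(points)
    if not active:
        return None
    return max(float(p.mean_fi) for p in active)


def interpolate_concentration(
    fit: CurveFit, y: float, dilution: float = 1.0
) -> InterpolationResult:
    """Invert the fitted curve at response ``y`` and scale by fold-dilution.

    ``y`` must be on the same prepared-response scale the fit used.
    Responses outside the open interval between the asymptotes are reported
    as out-of-range on the corresponding concentration side — never
    extrapolated.
    """
    if not fit.converged or fit.params is None:
        raise FitError("cannot interpolate from a non-converged fit")
    if dilution <= 0:
        raise DomainError("dilution must be > 0")
    p = fit.params
    lo, hi = min(p.a_min, p.a_max), max(p.a_min, p.a_max)
    # response approached as dose -> 0 (A_min for h>0, A_max for h<0)
    low_dose_resp = p.a_min if p.h > 0 else p.a_max
    if not lo < y < hi:
        if y <= lo:
            side = "below_range" if low_dose_resp == lo else "above_range"
        else:
            side = "below_range" if low_dose_resp == hi else "above_range"
        return InterpolationResult(conc=None, status=side)
    ratio = (p.a_max - p.a_min) / (y - p.a_min)
    try:
        x = p.m * (ratio ** (1.0 / p.s) - 1.0) ** (-1.0 / p.h)
    except (OverflowError, ZeroDivisionError, ValueError):
        return InterpolationResult(conc=None, status="above_range")
    if not math.isfinite(x) or x <= 0:
        return InterpolationResult(conc=None, status="above_range")
    return InterpolationResult(conc=x * dilution, status="ok")
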