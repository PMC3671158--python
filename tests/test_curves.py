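"""Logistic model, weighted fits, EC50/AUC/HighMFI, interpolation."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from xmapqc.curves import (
    CurveFit,
    LogisticParams,
    TitrationPoint,
    auc_trapezoid,
    ec50_from_params,
    eval_logistic,
    fit_both_models,
    fit_titration,
    high_mfi,
    interpolate_concentration,
)
from xmapqc.errors import FitError

FOURPL = LogisticParams(a_min=0, a_max=100, m=10, h=1, s=1)


def make_fit(params, **kw):
    fit = CurveFit(
        model="fivepl" if params.s != 1 else "fourpl", params=params,
        weight_exponent=0.0, log_transformed=False, converged=True,
        rss=0.0, **kw,
    )
    fit.ec50 = ec50_from_params(fit)
    return fit


def noiseless_points(params, doses):
    return [
        TitrationPoint(dose=d,
                       mean_response=float(eval_logistic(params, d)))
        for d in doses
    ]


DOSES = [10000.0 / 3.0 ** k for k in range(10)]


class TestEvalLogistic:
    def test_midpoint_at_inflection_when_symmetric(self):
        assert eval_logistic(FOURPL, 10.0) == pytest.approx(50.0)

    def test_upper_asymptote(self):
        assert eval_logistic(FOURPL, 1e12) == pytest.approx(100.0,
                                                            abs=1e-6)

    def test_asymmetry_shifts_inflection_value(self):
        p5 = LogisticParams(a_min=0, a_max=100, m=10, h=1, s=2)
        assert eval_logistic(p5, 10.0) == pytest.approx(25.0)  # 100 / 2^2

    def test_curve_bounded_by_asymptotes(self):
        doses = np.logspace(-6, 8, 100)
        y = eval_logistic(FOURPL, doses)
        assert np.all(y >= 0.0) and np.all(y <= 100.0)


class TestEc50:
    def test_fourpl_ec50_is_m(self):
        fit = make_fit(LogisticParams(0, 100, 250, 1, 1))
        assert fit.ec50 == 250.0

    def test_fivepl_closed_form(self):
        fit = make_fit(LogisticParams(0, 100, 100, 1, 2))
        assert fit.ec50 == pytest.approx(100.0 / (math.sqrt(2) - 1))

    def test_fivepl_s_one_collapses_to_m(self):
        fit = make_fit(LogisticParams(5, 80, 37.5, -2, 1))
        assert fit.ec50 == 37.5

    @pytest.mark.parametrize("s,h", [(0.5, 1.0), (2.0, -1.5), (3.0, 0.7)])
    def test_closed_form_agrees_with_root_finding(self, s, h):
        """Independent check: EC50 is where the curve crosses the
        midpoint of its asymptotes, found numerically."""
        p = LogisticParams(a_min=10, a_max=1000, m=50, h=h, s=s)
        fit = make_fit(p)
        mid = (p.a_min + p.a_max) / 2

        root = brentq(
            lambda x: eval_logistic(p, x) - mid, 1e-9, 1e12, xtol=1e-12,
            rtol=1e-14,
        )
        assert fit.ec50 == pytest.approx(root, rel=1e-8)


class TestAuc:
    def test_constant_response_area(self):
        pts = [TitrationPoint(1, 5.0), TitrationPoint(10, 5.0)]
        assert auc_trapezoid(pts) == pytest.approx(5.0)

    def test_triangle_area(self):
        pts = [TitrationPoint(1, 0.0), TitrationPoint(10, 10.0),
               TitrationPoint(100, 0.0)]
        assert auc_trapezoid(pts) == pytest.approx(10.0)

    def test_single_point_absent(self):
        assert auc_trapezoid([TitrationPoint(1, 5.0)]) is None

    def test_excluded_points_ignored(self):
        pts = [TitrationPoint(1, 5.0), TitrationPoint(10, 5.0),
               TitrationPoint(100, 1000.0, excluded=True)]
        assert auc_trapezoid(pts) == pytest.approx(5.0)

    def test_matches_dense_riemann_oracle(self):
        """Trapezoid equals a midpoint-Riemann integral of the piecewise
        linear interpolant, computed independently, to 1e-9."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = rng.integers(3, 12)
            doses = np.sort(rng.uniform(0.1, 1e4, n))
            doses = np.unique(doses)
            ys = rng.uniform(0, 3e4, len(doses))
            pts = [TitrationPoint(float(d), float(y))
                   for d, y in zip(doses, ys)]
            got = auc_trapezoid(pts)

            # oracle: midpoint rule on each segment (exact for linear)
            x = np.log10(doses)
            total = 0.0
            k = 1000
            for i in range(len(x) - 1):
                edges = np.linspace(x[i], x[i + 1], k + 1)
                mids = 0.5 * (edges[:-1] + edges[1:])
                frac = (mids - x[i]) / (x[i + 1] - x[i])
                vals = ys[i] + frac * (ys[i + 1] - ys[i])
                total += vals.sum() * (x[i + 1] - x[i]) / k
            assert got == pytest.approx(total, abs=1e-9 * max(1, abs(total)))


class TestHighMfi:
    def test_max_of_mean_responses(self):
        pts = [TitrationPoint(1, 120.0), TitrationPoint(10, 450.0),
               TitrationPoint(100, 390.0)]
        assert high_mfi(pts) == 450.0

    def test_exclusion_respected(self):
        pts = [TitrationPoint(1, 120.0),
               TitrationPoint(10, 450.0, excluded=True),
               TitrationPoint(100, 390.0)]
        assert high_mfi(pts) == 390.0

    def test_singleton_and_all_excluded(self):
        assert high_mfi([TitrationPoint(1, 7.0)]) == 7.0
        assert high_mfi([TitrationPoint(1, 7.0, excluded=True)]) is None


class TestFitTitration:
    def test_noiseless_recovery_unweighted(self):
        truth = LogisticParams(0, 30000, 1000, 1, 1)
        pts = noiseless_points(truth, DOSES)
        fit = fit_titration(pts, model="fourpl", weight_exponent=0.0)
        assert fit.converged
        for name in ("a_min", "a_max", "m", "h"):
            got, want = getattr(fit.params, name), getattr(truth, name)
            assert got == pytest.approx(want, rel=1e-4, abs=1e-3)

    def test_fivepl_nests_fourpl_truth(self):
        truth = LogisticParams(0, 30000, 1000, 1, 1)
        pts = noiseless_points(truth, DOSES)
        fits = fit_both_models(pts, weight_exponent=0.0)
        assert fits["fivepl"].params.s == pytest.approx(1.0, abs=1e-3)
        assert fits["fivepl"].rss <= fits["fourpl"].rss + 1e-9

    def test_underdetermined_is_fit_error(self):
        pts = noiseless_points(FOURPL, [1.0, 10.0, 100.0])
        with pytest.raises(FitError):
            fit_titration(pts, model="fourpl")

    def test_excluded_point_never_used(self):
        """Refit on (all minus point) equals fit with the point flagged
        excluded, exactly."""
        truth = LogisticParams(50, 25000, 300, 1.2, 1)
        rng = np.random.default_rng(5)
        pts = [
            TitrationPoint(d, float(eval_logistic(truth, d))
                           * float(rng.lognormal(0, 0.05)))
            for d in DOSES
        ]
        import copy

        flagged = copy.deepcopy(pts)
        flagged[4].excluded = True
        reduced = [p for i, p in enumerate(pts) if i != 4]
        fit_a = fit_titration(flagged, model="fourpl", seed=3)
        fit_b = fit_titration(reduced, model="fourpl", seed=3)
        assert fit_a.params == fit_b.params
        assert fit_a.rss == fit_b.rss

    def test_weighted_fit_prefers_low_fi_accuracy(self):
        """Power-law weights down-weight high-FI points, so a corrupted
        top point distorts the weighted fit less at the low end."""
        truth = LogisticParams(10, 20000, 500, 1, 1)
        pts = noiseless_points(truth, DOSES)
        # corrupt the highest-FI (top concentration) point
        pts[0] = TitrationPoint(pts[0].dose,
                                pts[0].mean_response * 1.3)
        unweighted = fit_titration(pts, model="fourpl",
                                   weight_exponent=0.0)
        weighted = fit_titration(pts, model="fourpl",
                                 weight_exponent=1.8)
        lo_dose = DOSES[-1]  # lowest concentration
        err_u = abs(eval_logistic(unweighted.params, lo_dose)
                    - eval_logistic(truth, lo_dose))
        err_w = abs(eval_logistic(weighted.params, lo_dose)
                    - eval_logistic(truth, lo_dose))
        assert err_w < err_u


class TestInterpolation:
    def test_round_trip_identity(self):
        fit = make_fit(LogisticParams(0, 100, 10, 1, 1))
        y = eval_logistic(fit.params, 37.5)
        res = interpolate_concentration(fit, y, dilution=1.0)
        assert res.in_range
        assert res.conc == pytest.approx(37.5, rel=1e-9)

    def test_midpoint_inverse_is_ec50_times_dilution(self):
        p = LogisticParams(0, 100, 10, 1, 2)
        fit = make_fit(p)
        y = (p.a_min + p.a_max) / 2
        res = interpolate_concentration(fit, y, dilution=100.0)
        assert res.conc == pytest.approx(100.0 * fit.ec50, rel=1e-9)

    def test_above_asymptote_marked_high(self):
        p = LogisticParams(0, 100, 10, 1, 1)
        res = interpolate_concentration(make_fit(p), 105.0)
        assert not res.in_range
        assert res.status == "above_range"
        assert res.conc is None

    def test_below_asymptote_marked_low(self):
        p = LogisticParams(20, 100, 10, 1, 1)
        res = interpolate_concentration(make_fit(p), 10.0)
        assert res.status == "below_range"

    def test_descending_curve_sides_swap(self):
        # h < 0: the curve descends from a_max (dose -> 0) to a_min, so a
        # response above the dose->0 asymptote means the sample sits below
        # the measurable range
        p = LogisticParams(a_min=5, a_max=100, m=10, h=-1, s=1)
        res = interpolate_concentration(make_fit(p), 150.0)
        assert res.status == "below_range"

    def test_round_trip_sweep(self):
        p = LogisticParams(5, 2000, 25, 1.4, 0.8)
        fit = make_fit(p)
        xs = np.logspace(-2, 5, 1000)
        for x in xs:
            y = float(eval_logistic(p, float(x)))
            if not (min(p.a_min, p.a_max) < y < max(p.a_min, p.a_max)):
                continue
            res = interpolate_concentration(fit, y)
            assert res.conc == pytest.approx(float(x), rel=1e-6)
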