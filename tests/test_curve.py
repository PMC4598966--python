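"""Trend-curve fitting and inflection-index extraction.

The analytic oracle throughout is symbolic differentiation (sympy) of the
generating polynomial, with roots found in closed form — independent of the
companion-matrix root path used by the implementation.
"""

import numpy as np
import pytest
import sympy

from careshed import (
    BinnedDistances,
    ValidationError,
    find_indices,
    find_pwd,
    find_tld,
    fit_trend_curve,
    report_index_bin,
    select_degree_aic,
)


def binned_from_poly(expr_fn, bin_width, n_bins):
    """Exact counts sampled from a polynomial at bin midpoints."""
    mids = (np.arange(n_bins) + 0.5) * bin_width
    return BinnedDistances(bin_width=bin_width, counts=expr_fn(mids))


def sympy_first_sign_change(expr, var, lo, hi, positive_before):
    """Closed-form smallest interior root of expr with the given sign change."""
    eps = 1e-9
    roots = sorted(float(r) for r in sympy.solve(expr, var)
                   if r.is_real and lo < float(r) < hi)
    for r in roots:
        before = float(expr.subs(var, r - eps))
        after = float(expr.subs(var, r + eps))
        if positive_before and before > 0 > after:
            return r
        if not positive_before and before < 0 < after:
            return r
    return None


class TestFit:
    def test_exact_cubic_interpolation_km_units(self):
        # y = x(x-4)^2 with x in km, sampled at 50-m midpoints
        b = binned_from_poly(lambda x: x * (x - 4.0) ** 2, 0.05, 100)
        curve = fit_trend_curve(b, degree=3, tail_quantile=None)
        np.testing.assert_allclose(curve.coef, [0.0, 16.0, -8.0, 1.0], atol=1e-8)
        assert curve.rss == pytest.approx(0.0, abs=1e-12)

    def test_constant_counts_quadratic(self):
        b = BinnedDistances(bin_width=50, counts=np.full(30, 7.0))
        curve = fit_trend_curve(b, degree=2, tail_quantile=None)
        assert curve.coef[0] == pytest.approx(7.0, abs=1e-9)
        np.testing.assert_allclose(curve.coef[1:], 0.0, atol=1e-10)

    def test_rss_nonincreasing_in_degree(self, rng):
        b = BinnedDistances(bin_width=50, counts=rng.poisson(40, 60).astype(float))
        rss = [fit_trend_curve(b, degree=d, tail_quantile=None).rss
               for d in range(2, 7)]
        assert all(a >= b_ - 1e-9 for a, b_ in zip(rss, rss[1:]))

    def test_underdetermined_fit_rejected(self):
        b = BinnedDistances(bin_width=50, counts=np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValidationError, match="underdetermined"):
            fit_trend_curve(b, degree=4, tail_quantile=None)

    def test_all_zero_counts_rejected(self):
        b = BinnedDistances(bin_width=50, counts=np.zeros(10))
        with pytest.raises(ValidationError):
            fit_trend_curve(b, degree=2)

    def test_aic_degree_selection_in_range(self, rng):
        b = BinnedDistances(bin_width=50, counts=rng.poisson(30, 50).astype(float))
        d = select_degree_aic(b, degrees=range(2, 7), tail_quantile=None)
        assert 2 <= d <= 6


class TestInflectionIndices:
    def cubic_binned(self):
        # y = x(x-4)^2 in km units over [0, 5]
        return binned_from_poly(lambda x: x * (x - 4.0) ** 2, 0.05, 100)

    def test_pwd_tld_match_symbolic_oracle(self):
        x = sympy.symbols("x")
        f = x * (x - 4) ** 2
        d1_true = sympy_first_sign_change(sympy.diff(f, x), x, 0, 5, True)
        d2_true = sympy_first_sign_change(sympy.diff(f, x, 2), x, 0, 5, False)
        assert d1_true == pytest.approx(4.0 / 3.0)
        assert d2_true == pytest.approx(8.0 / 3.0)

        curve = fit_trend_curve(self.cubic_binned(), degree=3, tail_quantile=None)
        pwd = find_pwd(curve)
        tld = find_tld(curve, pwd)
        span = curve.domain_hi - curve.domain_lo
        assert abs(pwd.root - d1_true) <= 1e-6 * span
        assert abs(tld.root - d2_true) <= 1e-6 * span
        assert pwd.root < tld.root

    def test_parabola_vertex(self):
        b = binned_from_poly(lambda x: -((x - 2.0) ** 2) + 10.0, 0.05, 80)
        curve = fit_trend_curve(b, degree=2, tail_quantile=None)
        pwd = find_pwd(curve)
        assert pwd.root == pytest.approx(2.0, abs=1e-9)
        assert find_tld(curve, pwd) is None  # f'' constant: no curvature change

    def test_monotone_decreasing_counts_pwd_undetected(self):
        b = BinnedDistances(bin_width=50,
                            counts=200.0 * 0.9 ** np.arange(60))
        curve = fit_trend_curve(b, degree=4, tail_quantile=None)
        assert find_pwd(curve) is None

    def test_monotone_increasing_counts_pwd_undetected(self):
        b = BinnedDistances(bin_width=50, counts=np.linspace(1, 100, 40))
        curve = fit_trend_curve(b, degree=3, tail_quantile=None)
        assert find_pwd(curve) is None  # maximum at the domain boundary

    def test_tld_undetected_when_only_curvature_root_below_pwd(self):
        # y = 10 - x(x-4)^2: local max at x = 4, sole f'' root at 8/3 < 4
        # with the wrong (+ -> -) orientation for either convention beyond D1
        b = binned_from_poly(lambda x: 10.0 - x * (x - 4.0) ** 2, 0.05, 100)
        curve = fit_trend_curve(b, degree=3, tail_quantile=None)
        pwd = find_pwd(curve)
        assert pwd.root == pytest.approx(4.0, abs=1e-9)
        assert find_tld(curve, pwd) is None
        assert find_tld(curve, pwd, convention="up-down") is None

    def test_tld_convention_switch(self):
        # y = x(x-4)^2 has a - -> + curvature change at 8/3; under the
        # opposite convention no + -> - root exists beyond the peak
        curve = fit_trend_curve(self.cubic_binned(), degree=3, tail_quantile=None)
        pwd = find_pwd(curve)
        assert find_tld(curve, pwd, convention="down-up") is not None
        assert find_tld(curve, pwd, convention="up-down") is None

    def test_tld_searched_from_origin_when_pwd_undetected(self):
        # y = (x-2)^3 + 9: monotone increasing (no interior slope maximum)
        # but with a - -> + curvature change at x = 2
        b = binned_from_poly(lambda x: (x - 2.0) ** 3 + 9.0, 0.05, 100)
        curve = fit_trend_curve(b, degree=3, tail_quantile=None)
        assert find_pwd(curve) is None
        tld = find_tld(curve, None)
        assert tld is not None and tld.root == pytest.approx(2.0, abs=1e-9)

    @pytest.mark.parametrize("scale", [0.5, 2.0, 1000.0])
    def test_scale_equivariance(self, scale):
        b0 = self.cubic_binned()
        b1 = BinnedDistances(bin_width=b0.bin_width * scale, counts=b0.counts)
        c0 = fit_trend_curve(b0, degree=3, tail_quantile=None)
        c1 = fit_trend_curve(b1, degree=3, tail_quantile=None)
        p0, p1 = find_pwd(c0), find_pwd(c1)
        t0, t1 = find_tld(c0, p0), find_tld(c1, p1)
        assert p1.root == pytest.approx(p0.root * scale, rel=1e-9)
        assert t1.root == pytest.approx(t0.root * scale, rel=1e-9)

    def test_find_indices_reports_argmax_bin(self):
        b = BinnedDistances(bin_width=50, counts=np.array(
            [1.0, 5.0, 9.0, 9.0, 4.0, 2.0, 1.0, 0.5]))
        _, idx = find_indices(b, degree=3, tail_quantile=None)
        assert idx.argmax_bin == (100.0, 150.0)  # tie -> nearest the origin


class TestReportIndexBin:
    @pytest.mark.parametrize("root,expected", [
        (1612.0, (1600.0, 1650.0, 1650.0)),
        (600.0, (600.0, 650.0, 650.0)),   # half-open lower edge
        (4000.0 / 3.0, (1300.0, 1350.0, 1350.0)),
    ])
    def test_containing_bin_and_buffer_radius(self, root, expected):
        assert report_index_bin(root, 50.0) == pytest.approx(expected)

    def test_negative_root_rejected(self):
        with pytest.raises(ValidationError):
            report_index_bin(-1.0, 50.0)
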