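"""Closed-form correctness and invariants of the Sine-G distributions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import sinesurv as sv

T_GRID = np.array([0.01, 0.1, 0.5, 1.0, 2.0, 5.0, 10.0])


class TestBaselines:
    def test_cdf_at_origin_and_median(self):
        e = sv.Exponential(1.0)
        assert e.cdf(0.0) == 0.0
        assert e.cdf(math.log(2)) == pytest.approx(0.5, abs=1e-14)

    def test_weibull_cdf_value(self):
        assert sv.Weibull(1.0, 2.0).cdf(1.0) == pytest.approx(0.6321205588285577, abs=1e-12)

    @pytest.mark.parametrize(
        "dist,expected",
        [
            (sv.Exponential(1.0), 1.0),
            (sv.Lomax(1.0, 1.0), 1.0),
            (sv.Gompertz(0.5, 1.0), 0.5),
        ],
    )
    def test_pdf_at_origin(self, dist, expected):
        assert dist.pdf(0.0) == pytest.approx(expected, abs=1e-12)

    def test_negative_time_has_zero_mass(self, sine_dist):
        base = sine_dist.baseline
        assert base.cdf(-1.0) == 0.0
        assert base.pdf(-0.5) == 0.0

    def test_quantile_closed_forms(self):
        assert sv.Exponential(2.0).ppf(1 - math.exp(-2)) == pytest.approx(1.0, rel=1e-12)
        assert sv.Lomax(1.0, 1.0).ppf(0.5) == pytest.approx(1.0, rel=1e-12)
        assert sv.Weibull(1.0, 2.0).ppf(0.0) == 0.0

    def test_quantile_roundtrip(self, sine_dist):
        base = sine_dist.baseline
        p = np.linspace(0.0, 0.999, 25)
        assert np.abs(base.cdf(base.ppf(p)) - p).max() < 1e-10

    @pytest.mark.parametrize("bad", [0.0, -1.0, np.nan])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError, match="positive"):
            sv.Exponential(bad)
        with pytest.raises(ValueError, match="positive"):
            sv.Weibull(1.0, bad)

    def test_unknown_family_name(self):
        with pytest.raises(ValueError, match="unknown baseline family"):
            sv.get_baseline("cauchy", 1.0)

    def test_aliases_resolve(self):
        assert sv.get_baseline("SW", 1.0, 2.0).name == "weibull"
        assert sv.get_baseline("see", 1.0, 2.0).name == "exponentiated_exponential"


class TestSineTransform:
    def test_median_maps_to_sin_quarter_pi(self, sine_dist):
        t_med = sine_dist.baseline.ppf(0.5)
        assert sine_dist.cdf(t_med) == pytest.approx(math.sin(math.pi / 4), abs=1e-10)
        assert sine_dist.sf(t_med) == pytest.approx(1 - math.sin(math.pi / 4), abs=1e-10)
        assert sine_dist.odds(t_med) == pytest.approx(1 + math.sqrt(2), abs=1e-8)
        assert sine_dist.cumhaz(t_med) == pytest.approx(
            -math.log(1 - math.sin(math.pi / 4)), abs=1e-8
        )

    def test_sine_exponential_values(self):
        """Frozen high-precision evaluations of the sine-exponential at t=1."""
        d = sv.make_sine("exponential", 1.0)
        assert d.cdf(1.0) == pytest.approx(0.8376314975597857, abs=1e-12)
        assert d.pdf(1.0) == pytest.approx(0.3156497871259330, abs=1e-12)
        assert d.sf(1.0) == pytest.approx(0.1623685024402143, abs=1e-12)
        assert d.hazard(1.0) == pytest.approx(1.9440333708944, rel=1e-10)
        assert d.cumhaz(1.0) == pytest.approx(1.8178868205567, rel=1e-10)
        assert d.pdf(0.0) == pytest.approx(math.pi / 2, abs=1e-12)
        assert d.hazard(0.0) == pytest.approx(math.pi / 2, abs=1e-10)

    def test_boundary_values(self, sine_dist):
        assert sine_dist.cdf(0.0) == 0.0
        assert sine_dist.sf(0.0) == pytest.approx(1.0, abs=1e-14)
        assert sine_dist.cumhaz(0.0) == pytest.approx(0.0, abs=1e-14)
        assert sine_dist.odds(0.0) == pytest.approx(0.0, abs=1e-14)

    def test_definitional_identities(self, sine_dist):
        t = T_GRID
        f, S, F = sine_dist.pdf(t), sine_dist.sf(t), sine_dist.cdf(t)
        assert np.abs(S - (1 - F)).max() < 1e-10
        assert np.abs(sine_dist.hazard(t) / (f / S) - 1).max() < 1e-10
        assert np.abs(sine_dist.cumhaz(t) - (-np.log(S))).max() < 1e-10
        assert np.abs(sine_dist.odds(t) - F / S).max() < 1e-10

    def test_stochastic_ordering_over_baseline(self, sine_dist):
        t = T_GRID
        assert np.all(sine_dist.cdf(t) >= sine_dist.baseline.cdf(t) - 1e-14)

    def test_cdf_and_cumhaz_nondecreasing(self, sine_dist):
        t = np.linspace(0, 20, 400)
        assert np.all(np.diff(sine_dist.cdf(t)) >= -1e-12)
        assert np.all(np.diff(sine_dist.cumhaz(t)) >= -1e-12)

    def test_pdf_normalizes(self, sine_dist):
        # piecewise quadrature between quantiles handles heavy-tailed cases
        knots = sine_dist.ppf([0.0, 0.5, 0.9, 0.99, 0.999, 0.9999, 0.99999, 0.999999])
        integral = sum(
            quad(sine_dist.pdf, a, b, limit=200)[0] for a, b in zip(knots[:-1], knots[1:])
        )
        assert 0.999 <= integral <= 1.001

    def test_pdf_matches_cdf_derivative(self, sine_dist):
        t = np.linspace(0.05, 5.0, 40)
        h = 1e-5
        numeric = (sine_dist.cdf(t + h) - sine_dist.cdf(t - h)) / (2 * h)
        assert np.abs(numeric - sine_dist.pdf(t)).max() < 1e-6

    def test_quantile_roundtrip(self, sine_dist):
        u = np.linspace(0.0, 0.999, 30)
        assert np.abs(sine_dist.cdf(sine_dist.ppf(u)) - u).max() < 1e-10

    def test_sine_exponential_quantile_at_sin_quarter_pi(self):
        d = sv.make_sine("exponential", 1.0)
        assert d.ppf(math.sin(math.pi / 4)) == pytest.approx(math.log(2), rel=1e-12)

    def test_cumhaz_inverse_roundtrip(self, sine_dist):
        v = np.linspace(0.0, 20.0, 40)
        err = np.abs(sine_dist.cumhaz(sine_dist.cumhaz_inv(v)) - v)
        assert (err / np.maximum(v, 1.0)).max() < 1e-10

    def test_cumhaz_inverse_exact_value(self):
        # 1 - e^{-ln 2} = 1/2, arcsin(1/2) = pi/6, G = 1/3 -> t = -ln(2/3)
        d = sv.make_sine("exponential", 1.0)
        assert d.cumhaz_inv(math.log(2)) == pytest.approx(math.log(1.5), rel=1e-12)

    def test_logsf_stable_deep_in_tail(self, sine_dist):
        """log-survival stays finite and the hazard positive at extreme times."""
        t = sine_dist.baseline.ppf(1 - 1e-12) * np.array([1.0, 2.0, 5.0])
        logsf = np.atleast_1d(sine_dist.logsf(t))
        assert np.all(np.isfinite(logsf))
        assert np.all(np.diff(logsf) < 0)

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_quantile_domain_errors(self, bad):
        with pytest.raises(ValueError):
            sv.make_sine("exponential", 1.0).ppf(bad)
        with pytest.raises(ValueError):
            sv.make_sine("exponential", 1.0).cumhaz_inv(-1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        t=st.floats(min_value=0.0, max_value=50.0),
        lam=st.floats(min_value=0.05, max_value=5.0),
        alpha=st.floats(min_value=0.2, max_value=4.0),
    )
    def test_sine_dominates_baseline_property(self, t, lam, alpha):
        d = sv.make_sine("weibull", lam, alpha)
        assert d.cdf(t) >= d.baseline.cdf(t) - 1e-14
        assert 0.0 <= d.cdf(t) <= 1.0
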