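"""Closed-form Beta IRM layer: shapes, mean, density, variance, information."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats
from scipy.special import expit

from vascareless.beta_irm import (
    ItemParams,
    TraitVector,
    conditional_variance,
    expected_response,
    item_information,
    log_density,
    shape_params,
)

finite_floats = st.floats(-3, 3, allow_nan=False)


def item(b=0.0, a=0.0, s=1, d=0):
    return ItemParams(difficulty=b, dispersion=a, wording=s, dimension=d)


class TestShapeParams:
    @pytest.mark.parametrize(
        "theta, b, a, s, accept, refuse",
        [
            (0.0, 0.0, 0.0, 1, 1.0, 1.0),                      # uniform Beta(1,1)
            (1.0, 0.0, 0.0, 1, np.exp(0.5), np.exp(-0.5)),
            (1.0, 0.0, 0.0, -1, np.exp(-0.5), np.exp(0.5)),
        ],
    )
    def test_closed_form(self, theta, b, a, s, accept, refuse):
        sp = shape_params(TraitVector(np.array([theta])), item(b, a, s))
        assert sp.accept == pytest.approx(accept, rel=1e-12)
        assert sp.refuse == pytest.approx(refuse, rel=1e-12)

    def test_mean_is_logistic_of_linear_predictor(self):
        sp = shape_params([1.0], item())
        assert sp.accept / (sp.accept + sp.refuse) == pytest.approx(expit(1.0), rel=1e-12)

    def test_invalid_wording_rejected(self):
        with pytest.raises(ValueError):
            ItemParams(difficulty=0.0, dispersion=0.0, wording=0)

    def test_nonfinite_trait_rejected(self):
        with pytest.raises(ValueError):
            shape_params([np.nan], item())

    def test_dimension_out_of_range(self):
        with pytest.raises(ValueError):
            shape_params([0.0], item(d=3))


class TestExpectedResponse:
    def test_half_at_zero_predictor(self):
        assert expected_response([0.5], item(b=0.5)) == pytest.approx(0.5)

    def test_logistic_value(self):
        assert expected_response([1.0], item()) == pytest.approx(expit(1.0), rel=1e-12)

    @given(theta=finite_floats, b=finite_floats, a=st.floats(0, 3))
    @settings(deadline=None, max_examples=50)
    def test_mean_invariant_to_dispersion(self, theta, b, a):
        # bit-identical, not merely close
        assert expected_response([theta], item(b, a)) == expected_response([theta], item(b, 0.0))

    @given(theta=finite_floats, delta=st.floats(0.01, 1.0), s=st.sampled_from([-1, 1]))
    @settings(deadline=None, max_examples=50)
    def test_strict_monotonicity_in_trait(self, theta, delta, s):
        lo = expected_response([theta], item(s=s))
        hi = expected_response([theta + delta], item(s=s))
        assert (hi > lo) if s == 1 else (hi < lo)


class TestLogDensity:
    def test_uniform_case_zero(self):
        assert log_density(0.5, [0.0], item()) == pytest.approx(0.0, abs=1e-12)

    def test_beta_2_2_closed_form(self):
        # eta=0 and dispersion 2*log(2) gives a=b=2; density at 1/2 is 1.5
        it = item(a=2 * np.log(2.0))
        assert log_density(0.5, [0.0], it) == pytest.approx(np.log(1.5), rel=1e-12)

    def test_matches_scipy_beta(self):
        it = item(b=0.3, a=1.7, s=-1)
        sp = shape_params([0.8], it)
        expected = stats.beta.logpdf(0.37, sp.accept, sp.refuse)
        assert log_density(0.37, [0.8], it) == pytest.approx(expected, rel=1e-10)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            log_density(0.0, [0.0], item())
        with pytest.raises(ValueError):
            log_density(1.0, [0.0], item())

    def test_normalizes_over_unit_interval(self):
        # quadrature oracle: exp(log f) integrates to 1 for random parameters
        rng = np.random.default_rng(7)
        for _ in range(100):
            it = item(b=rng.normal(), a=rng.uniform(0, 3),
                      s=int(rng.choice([-1, 1])))
            th = [rng.normal()]
            total, _ = integrate.quad(lambda y: np.exp(log_density(y, th, it)), 0, 1)
            assert total == pytest.approx(1.0, abs=1e-6)


class TestConditionalVariance:
    def test_uniform_variance(self):
        assert conditional_variance([0.0], item()) == pytest.approx(1 / 12, rel=1e-12)

    @given(theta=finite_floats, b=finite_floats,
           a=st.floats(0, 2.5), delta=st.floats(0.1, 0.5))
    @settings(deadline=None, max_examples=50)
    def test_strictly_decreasing_in_dispersion(self, theta, b, a, delta):
        assert conditional_variance([theta], item(b, a)) > conditional_variance(
            [theta], item(b, a + delta))

    def test_matches_monte_carlo(self):
        it = item(b=-0.4, a=1.2)
        sp = shape_params([0.6], it)
        rng = np.random.default_rng(3)
        draws = rng.beta(sp.accept, sp.refuse, size=100_000)
        mc = draws.var()
        se = draws.var() / np.sqrt(len(draws))  # loose sampling-error scale
        assert conditional_variance([0.6], it) == pytest.approx(mc, abs=10 * se + 1e-4)


class TestItemInformation:
    def test_nonnegative_on_grid(self):
        grid = np.linspace(-3, 3, 31)
        info = item_information(grid, item(b=0.5, a=1.0))
        assert np.all(info >= -1e-9)

    def test_higher_dispersion_more_peaked(self):
        grid = np.linspace(-4, 4, 81)
        low = item_information(grid, item(a=0.0))
        high = item_information(grid, item(a=2.0))
        assert high.max() > low.max()

    def test_matches_monte_carlo_score_variance(self):
        # Fisher information equals the variance of the score; estimate the
        # score by finite differences on Monte-Carlo response draws
        it = item(b=0.2, a=1.0)
        th = 0.4
        sp = shape_params([th], it)
        rng = np.random.default_rng(11)
        y = np.clip(rng.beta(sp.accept, sp.refuse, size=200_000), 1e-12, 1 - 1e-12)
        h = 1e-4

        def logf(t):
            s = shape_params([t], it)
            return stats.beta.logpdf(y, s.accept, s.refuse)

        score = (logf(th + h) - logf(th - h)) / (2 * h)
        mc_info = score.var()
        quad_info = item_information([th], it)[0]
        assert quad_info == pytest.approx(mc_info, rel=0.05)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            item_information([], item())
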