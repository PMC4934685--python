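"""Analytic engine: offer density, acceptance curve, payoff, summaries."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from emoug import (
    JointParameterDistribution,
    OfferCurves,
    acceptance_curve,
    compute_curves,
    expected_payoff,
    make_joint,
    mean_offer,
    median_offer,
    modal_offer,
    offer_density,
    optimal_offer,
    summary_table,
)
from emoug.engine import round_half_up


def closed_form_same_marginal_P(F, s):
    """Independent algebraic oracle: P(s) = F(1-2s)(F(s)-1) + 1."""
    s = np.asarray(s, dtype=float)
    return F(1.0 - 2.0 * s) * (F(s) - 1.0) + 1.0


class TestUniformClosedForms:
    """With both parameters uniform: p(s) = 3 - 4s, P(s) = 3s - 2s^2."""

    def test_offer_density(self, uniform_joint):
        s = np.array([0.0, 0.25, 0.4])
        assert offer_density(uniform_joint, s) == pytest.approx(3.0 - 4.0 * s)

    def test_acceptance_curve(self, uniform_joint):
        s = np.array([0.0, 0.2, 0.5])
        assert acceptance_curve(uniform_joint, s) == pytest.approx(
            [0.0, 0.52, 1.0]
        )

    def test_density_normalises_to_one(self, uniform_joint):
        total, _ = integrate.quad(
            lambda s: float(offer_density(uniform_joint, s)), 0.0, 0.5
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_density_decreasing_hence_mode_at_zero(self, uniform_joint):
        curves = compute_curves(uniform_joint)
        assert np.all(np.diff(curves.p) < 0)
        assert modal_offer(uniform_joint) == pytest.approx(0.0, abs=1e-3)

    def test_optimal_offer_closed_form_root(self, uniform_joint):
        # stationary point of (1-s)(3s-2s^2): 6s^2 - 10s + 3 = 0
        assert optimal_offer(uniform_joint) == pytest.approx(
            (10.0 - math.sqrt(28.0)) / 12.0, abs=1e-6
        )

    def test_median_from_quadratic_root(self, uniform_joint):
        assert median_offer(uniform_joint) == pytest.approx(
            (3.0 - math.sqrt(5.0)) / 4.0, abs=1e-8
        )

    def test_mean_is_first_moment_of_density(self, uniform_joint):
        assert mean_offer(uniform_joint) == pytest.approx(5.0 / 24.0, abs=1e-8)


class TestGeneralStructure:
    @pytest.mark.parametrize("fixture", ["uniform_joint", "gaussian_joint"])
    def test_survival_form_equals_same_marginal_closed_form(
        self, fixture, request
    ):
        joint = request.getfixturevalue(fixture)
        s = np.linspace(0.0, 0.5, 501)
        oracle = closed_form_same_marginal_P(joint.lam_marginal.cdf, s)
        assert acceptance_curve(joint, s) == pytest.approx(oracle, abs=1e-14)

    @pytest.mark.parametrize("fixture", ["uniform_joint", "gaussian_joint"])
    def test_density_is_derivative_of_acceptance_curve(self, fixture, request):
        joint = request.getfixturevalue(fixture)
        s = np.linspace(0.0, 0.5, 1001)
        h = s[1] - s[0]
        P = acceptance_curve(joint, s)
        dPds = np.gradient(P, h, edge_order=2)
        assert np.max(np.abs(dPds - offer_density(joint, s))) < 1e-4

    @pytest.mark.parametrize("fixture", ["uniform_joint", "gaussian_joint"])
    def test_curves_invariants(self, fixture, request):
        joint = request.getfixturevalue(fixture)
        curves = compute_curves(joint)
        assert np.all(np.diff(curves.P) >= -1e-15)  # monotone acceptance
        assert np.all(curves.p >= 0.0)
        assert np.all(curves.g <= curves.P + 1e-15)
        tol = 1e-6 if fixture == "uniform_joint" else 1e-2
        assert curves.P[-1] == pytest.approx(1.0, abs=tol)
        assert curves.g[-1] == pytest.approx(0.5, abs=tol)

    def test_gaussian_density_mass_at_least_0995(self, gaussian_joint):
        total, _ = integrate.quad(
            lambda s: float(offer_density(gaussian_joint, s)), 0.0, 0.5,
            limit=200,
        )
        assert total >= 0.995

    def test_expected_payoff_recomputes_pointwise_product(self, uniform_joint):
        curves = compute_curves(uniform_joint)
        again = expected_payoff(curves)
        assert np.array_equal(again.g, (1.0 - curves.grid) * curves.P)
        assert again.g[0] == 0.0

    def test_different_marginals_use_general_survival_form(self):
        joint = make_joint("uniform", tau_family="normal",
                           tau_params={"mu": 0.5, "sigma": 1.0 / 6.0})
        s = np.linspace(0.0, 0.5, 301)
        F_lam = joint.lam_marginal.cdf
        F_tau = joint.tau_marginal.cdf
        expected = 1.0 - (1.0 - F_lam(s)) * F_tau(1.0 - 2.0 * s)
        assert acceptance_curve(joint, s) == pytest.approx(expected)

    def test_non_independent_joint_rejected(self):
        joint = JointParameterDistribution(
            make_joint("uniform").lam_marginal,
            make_joint("uniform").tau_marginal,
            independent=False,
        )
        with pytest.raises(NotImplementedError):
            acceptance_curve(joint, 0.2)

    def test_density_unavailable_for_atomic_marginals(self):
        joint = make_joint("point", value=0.3)
        with pytest.raises(ValueError, match="density"):
            offer_density(joint, 0.2)


class TestDegeneratePopulations:
    def test_point_mass_mao_makes_step_acceptance_and_optimal_at_step(self):
        # lam = 0.3 and tau = 0 everywhere: every MAO is 0.3
        joint = make_joint("point", value=0.3,
                           tau_params={"value": 0.0})
        s = np.array([0.0, 0.29, 0.3, 0.5])
        assert acceptance_curve(joint, s) == pytest.approx([0, 0, 1, 1])
        assert optimal_offer(joint) == pytest.approx(0.3, abs=1e-3)
        assert median_offer(joint) == pytest.approx(0.3, abs=1e-8)
        assert mean_offer(joint) == pytest.approx(0.3, abs=1e-4)

    def test_fully_rational_population_offers_and_rejects_nothing(self):
        # lam = 0, tau = 1: pure income-maximisers, MAO = 0
        joint = make_joint("point", value=0.0, tau_params={"value": 1.0})
        table = summary_table(joint).rounded()
        assert table["modal_offer"] == 0
        assert table["median_offer"] == 0
        assert table["mean_offer"] == 0
        assert table["rejection_1_20"] == 0
        assert table["rejection_40_50"] == 0
        assert table["optimal_offer"] == 0

    def test_flat_payoff_returns_smallest_maximiser_with_warning(self):
        grid = np.linspace(0.0, 0.5, 11)
        flat = OfferCurves(grid=grid, p=None, P=np.zeros(11), g=np.zeros(11))
        with pytest.warns(UserWarning, match="flat"):
            assert optimal_offer(flat) == 0.0


class TestSummaryTable:
    def test_uniform_population_statistics(self, uniform_joint):
        table = summary_table(uniform_joint)
        rounded = table.rounded()
        assert rounded["median_offer"] == 19
        assert rounded["mean_offer"] == 21
        assert rounded["offers_1_10"] == 28
        assert rounded["rejection_1_20"] == 48
        assert rounded["offers_50_100"] == 0
        assert rounded["optimal_offer"] == 39
        assert table.raw()["offers_1_10"] == pytest.approx(28.0)

    def test_gaussian_population_statistics(self, gaussian_joint):
        rounded = summary_table(gaussian_joint).rounded()
        assert rounded["median_offer"] == 24
        assert rounded["mean_offer"] == 24
        assert rounded["offers_1_10"] == 4
        assert rounded["rejection_1_20"] == 70
        assert rounded["offers_50_100"] == 0

    @pytest.mark.parametrize("fixture", ["uniform_joint", "gaussian_joint"])
    def test_rejection_curve_nonincreasing(self, fixture, request):
        joint = request.getfixturevalue(fixture)
        s = np.linspace(0.0, 0.5, 501)
        rejection = 1.0 - acceptance_curve(joint, s)
        assert np.all(np.diff(rejection) <= 1e-15)

    def test_monte_carlo_mao_cdf_agrees_with_acceptance_curve(
        self, uniform_joint, gaussian_joint
    ):
        """Empirical MAO CDF of sampled agents tracks analytic P(s)."""
        from emoug import build_population

        n = 100_000
        for joint in (uniform_joint, gaussian_joint):
            pop = build_population(joint, n, seed=13)
            ks = stats.kstest(
                pop.maos, lambda x: np.asarray(acceptance_curve(joint, x))
            ).statistic
            assert ks < 3.0 / math.sqrt(n)

    def test_markdown_report_uses_conventional_row_labels(self, uniform_joint):
        md = summary_table(uniform_joint).to_markdown()
        assert "Modal offer" in md
        assert "Rejection of offers in range 1-20%" in md
        assert "| 19% |" in md

    def test_json_dict_round_trips(self, uniform_joint):
        import json

        table = summary_table(uniform_joint)
        payload = table.to_json_dict(spec=uniform_joint.spec())
        assert json.loads(json.dumps(payload)) == payload


class TestRounding:
    @pytest.mark.parametrize(
        "x, expected",
        [(0.5, 1), (5.5, 6), (2.4, 2), (2.6, 3), (5.4999999999999995, 6)],
    )
    def test_half_up_with_representation_guard(self, x, expected):
        assert round_half_up(x) == expected
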