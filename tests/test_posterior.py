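"""Unit tests for the beta-binomial posterior engine."""

import numpy as np
import pytest

from miebl import (
    JEFFREYS,
    UNIFORM,
    CriterionSpec,
    PriorSpec,
    TrialCount,
    criterion_table,
    lower_credible_bound,
    mastery_prob,
    mastery_summary,
    posterior_density_grid,
    posterior_from_counts,
    posterior_mean,
)

from conftest import GOLDEN_B_P70, GOLDEN_B_P90
from oracle import tail_prob as oracle_tail_prob


def _post(n, x, prior=JEFFREYS):
    return posterior_from_counts(TrialCount(n=n, x=x), prior)


class TestConjugateUpdate:
    @pytest.mark.parametrize(
        "n,x,alpha,beta",
        [(10, 8, 8.5, 2.5), (1, 0, 0.5, 1.5), (5, 5, 5.5, 0.5)],
    )
    def test_jeffreys_update(self, n, x, alpha, beta):
        post = _post(n, x)
        assert post.alpha == alpha
        assert post.beta == beta

    def test_uniform_prior_update(self):
        post = _post(10, 8, UNIFORM)
        assert (post.alpha, post.beta) == (9.0, 3.0)

    def test_total_mass_conserved(self):
        post = _post(7, 3)
        assert post.alpha + post.beta == 7 + 1.0

    @pytest.mark.parametrize(
        "n,x,msg",
        [(0, 0, "n must be"), (5, -1, "x must be >= 0"), (5, 6, "x must be <= n")],
    )
    def test_invalid_counts_rejected(self, n, x, msg):
        with pytest.raises(ValueError, match=msg):
            TrialCount(n=n, x=x)

    def test_nonpositive_prior_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            PriorSpec(0.0, 1.0)


class TestPriorParsing:
    @pytest.mark.parametrize(
        "spec,expected",
        [("jeffreys", (0.5, 0.5)), ("uniform", (1.0, 1.0)), ("2,3", (2.0, 3.0))],
    )
    def test_parse(self, spec, expected):
        prior = PriorSpec.parse(spec)
        assert (prior.prior_alpha, prior.prior_beta) == expected

    def test_parse_garbage(self):
        with pytest.raises(ValueError, match="prior must be"):
            PriorSpec.parse("flat-ish")


class TestMasteryProb:
    @pytest.mark.parametrize(
        "n,x,p_star,expected,places",
        [
            (10, 8, 0.90, 0.143, 3),  # tutorial report statement [3]
            (5, 5, 0.90, 0.71, 2),  # 100% criterion on 5 trials
            (10, 9, 0.90, 0.44, 2),  # "less than a coin toss"
            (8, 8, 0.90, 0.81, 2),
        ],
    )
    def test_published_values(self, n, x, p_star, expected, places):
        assert round(mastery_prob(_post(n, x), p_star), places) == expected

    def test_matches_numeric_oracle(self):
        # independent trapezoid quadrature, incl. an endpoint-singular case
        post = _post(4, 4)
        got = mastery_prob(post, 0.90)
        assert got == pytest.approx(oracle_tail_prob(post.alpha, post.beta, 0.90), abs=1e-9)
        assert got == pytest.approx(0.657, abs=5e-4)

    def test_threshold_endpoints(self):
        post = _post(5, 5)
        assert mastery_prob(post, 0.0) == 1.0
        assert mastery_prob(post, 1.0) == 0.0

    def test_out_of_range_threshold(self):
        with pytest.raises(ValueError, match="p_star"):
            mastery_prob(_post(5, 3), 1.2)


class TestLowerCredibleBound:
    @pytest.mark.parametrize(
        "a,expected", [(0.05, 0.5475), (0.10, 0.6052)]  # report statements [4]
    )
    def test_published_bounds(self, a, expected):
        assert round(lower_credible_bound(_post(10, 8), a), 4) == expected

    def test_small_tail_approaches_support_endpoint(self):
        # the a-quantile decreases towards the lower support endpoint as a -> 0+
        levels = [0.2, 0.05, 1e-3, 1e-6, 1e-10]
        qs = [lower_credible_bound(_post(10, 8), a) for a in levels]
        assert qs == sorted(qs, reverse=True)
        assert lower_credible_bound(_post(1, 0), 1e-10) < 1e-6

    @pytest.mark.parametrize("a", [0.0, 1.0, -0.1])
    def test_invalid_tail_level(self, a):
        with pytest.raises(ValueError, match="tail level"):
            lower_credible_bound(_post(10, 8), a)


class TestPosteriorMean:
    def test_closed_form(self):
        assert posterior_mean(_post(10, 8)) == 8.5 / 11.0

    def test_published_point_estimate(self):
        # 9 of 10 correct -> 86% point estimate of mastery
        assert round(100 * posterior_mean(_post(10, 9))) == 86

    def test_symmetric_counts(self):
        assert posterior_mean(_post(2, 1)) == pytest.approx(0.5)


class TestDensityGrid:
    def test_symmetric_posterior_grid(self):
        grid = posterior_density_grid(_post(2, 1), npoints=101)
        dens = grid[:, 1]
        np.testing.assert_allclose(dens, dens[::-1], atol=1e-12)

    def test_mode_location(self):
        grid = posterior_density_grid(_post(10, 9), npoints=4097)
        mode = grid[np.argmax(grid[:, 1]), 0]
        assert mode == pytest.approx(8.5 / 9.0, abs=1e-3)

    def test_normalization(self):
        grid = posterior_density_grid(_post(10, 8), npoints=4097)
        assert np.trapezoid(grid[:, 1], grid[:, 0]) == pytest.approx(1.0, abs=1e-3)

    def test_singular_endpoint_is_finite(self):
        grid = posterior_density_grid(_post(5, 5), npoints=65)
        assert np.isfinite(grid[:, 1]).all()
        assert (grid[:, 1] >= 0).all()

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="npoints"):
            posterior_density_grid(_post(5, 5), npoints=1)


class TestCriterionSpec:
    def test_x_required(self):
        assert CriterionSpec.from_percent(80, 10).x_required == 8

    def test_non_integral_criterion_rejected(self):
        with pytest.raises(ValueError, match="attainable"):
            CriterionSpec.from_percent(85, 10)


class TestCriterionTable:
    @pytest.mark.parametrize(
        "p_star,golden", [(0.90, GOLDEN_B_P90), (0.70, GOLDEN_B_P70)]
    )
    def test_reproduces_published_tables(self, p_star, golden):
        """Every printed cell of both criterion tables, within 2-dp rounding."""
        for n, expected in golden.items():
            tab = criterion_table(n=n, p_star=p_star)
            for x, want in enumerate(expected):
                assert tab.row(x).summary.b == pytest.approx(want, abs=0.005), (
                    f"n={n}, x={x}, p*={p_star}"
                )

    def test_structure(self):
        tab = criterion_table(n=6, p_star=0.8, a=0.1)
        assert [r.x for r in tab] == list(range(7))
        assert [r.tau for r in tab] == [x / 6 for x in range(7)]
        df = tab.to_dataframe()
        assert list(df.columns) == ["x", "tau", "b", "lower_bound", "mean"]
        assert len(df) == 7

    def test_degenerate_threshold(self):
        tab = criterion_table(n=1, p_star=0.0)
        assert all(r.summary.b == 1.0 for r in tab)

    def test_summary_bundles_components(self):
        s = mastery_summary(TrialCount(10, 8), p_star=0.9, a=0.05)
        post = _post(10, 8)
        assert s.b == mastery_prob(post, 0.9)
        assert s.lower_bound == lower_credible_bound(post, 0.05)
        assert s.mean == posterior_mean(post)
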