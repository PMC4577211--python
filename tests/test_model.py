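"""Static-model operations: likelihoods, posteriors, shrinkage, tension."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from uncanny import (
    Category,
    Cue,
    ModelConfig,
    category_likelihood,
    category_posterior,
    combined_response,
    displacement,
    emotional_response,
    expected_humanness,
    marginal_density,
    perceptual_tension,
    response_curve,
)
from uncanny.model import UnsupportedConfigurationError

from conftest import quadrature_category_posterior, quadrature_posterior_mean


class TestCategoryLikelihood:
    def test_noise_free_peak_is_gaussian_maximum(self):
        cat = Category(mean=0.5, sd=0.5, prior=1.0)
        dens = category_likelihood(0.5, Cue(sigma_s=0.0), cat)
        assert dens == pytest.approx(1.0 / (0.5 * np.sqrt(2 * np.pi)), rel=1e-12)

    def test_variances_add_at_category_mean(self):
        cat = Category(mean=1.0, sd=0.05, prior=0.5)
        dens = category_likelihood(1.0, Cue(sigma_s=0.2), cat)
        assert dens == pytest.approx(1.0 / np.sqrt(0.0425 * 2 * np.pi), rel=1e-12)

    def test_matches_quadrature_over_latent_humanness(self):
        # P(S | C) = integral N(S; H, sigma_s^2) N(H; mu, sigma_c^2) dH
        cat, cue = Category(mean=0.5, sd=0.5, prior=1.0), Cue(sigma_s=0.05)
        expected, _ = quad(
            lambda h: norm.pdf(0.7, h, cue.sigma_s) * norm.pdf(h, cat.mean, cat.sd),
            -6, 7, limit=200, epsabs=1e-13,
        )
        assert category_likelihood(0.7, cue, cat) == pytest.approx(expected, rel=1e-9)

    def test_vectorized_over_stimuli(self):
        cat, cue = Category(mean=0.5, sd=0.5, prior=1.0), Cue(sigma_s=0.05)
        h = np.array([0.1, 0.5, 0.9])
        out = category_likelihood(h, cue, cat)
        assert out.shape == h.shape
        assert out[1] == max(out)


class TestCategoryPosterior:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(h=st.floats(-2.0, 3.0))
    def test_normalizes_everywhere(self, typical, h):
        for cue in typical.cues:
            post = category_posterior(h, cue, typical)
            assert np.all(post >= 0)
            assert post.sum() == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_setup_gives_even_odds(self):
        config = ModelConfig(
            categories=(
                Category(mean=0.0, sd=0.3, prior=0.5),
                Category(mean=1.0, sd=0.3, prior=0.5),
            ),
            cues=(Cue(sigma_s=0.1), Cue(sigma_s=0.2)),
        )
        post = category_posterior(0.5, config.cues[0], config)
        np.testing.assert_allclose(post, [0.5, 0.5], atol=1e-12)

    def test_agrees_with_generative_quadrature(self, typical):
        cue = typical.cues[1]  # the reliable cue
        post = category_posterior(1.0, cue, typical)
        oracle = quadrature_category_posterior(1.0, cue.sigma_s, typical)
        np.testing.assert_allclose(post, oracle, atol=1e-6)

    def test_far_tail_does_not_underflow(self, typical):
        # log-space evaluation keeps the narrow human category finite far away
        post = category_posterior(-30.0, typical.cues[1], typical)
        assert np.all(np.isfinite(post))
        assert post.sum() == pytest.approx(1.0, abs=1e-12)


class TestMarginalDensity:
    def test_single_category_equals_likelihood(self, single_category):
        cue = single_category.cues[0]
        assert marginal_density(0.3, cue, single_category) == pytest.approx(
            category_likelihood(0.3, cue, single_category.categories[0]), rel=1e-12
        )

    def test_two_term_mixture_closed_form(self, typical):
        cue = typical.cues[0]  # sigma_s = 0.2
        expected = 0.5 * norm.pdf(0.5, 0.5, np.sqrt(0.29)) + 0.5 * norm.pdf(
            0.5, 1.0, np.sqrt(0.0425)
        )
        assert marginal_density(0.5, cue, typical) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("cue_index", [0, 1])
    def test_integrates_to_one(self, typical, cue_index):
        grid = np.linspace(-3.0, 4.0, 20001)
        dens = marginal_density(grid, typical.cues[cue_index], typical)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-6)


class TestExpectedHumanness:
    def test_zero_noise_returns_stimulus(self, typical):
        h = np.linspace(0.0, 1.0, 11)
        np.testing.assert_allclose(
            expected_humanness(h, Cue(sigma_s=0.0), typical), h, atol=1e-12
        )

    def test_single_category_fixed_point_at_mean(self, single_category):
        assert expected_humanness(
            0.5, single_category.cues[0], single_category
        ) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("condition", ["typical", "asd"])
    def test_matches_posterior_mean_by_quadrature(self, condition, request):
        config = request.getfixturevalue(condition)
        for cue in config.cues:
            for h in np.linspace(0.0, 1.2, 7):
                oracle = quadrature_posterior_mean(h, cue.sigma_s, config)
                assert expected_humanness(h, cue, config) == pytest.approx(
                    oracle, abs=1e-6
                )

    def test_stays_in_convex_hull(self, typical):
        h = np.linspace(-0.5, 1.5, 41)
        lo = np.minimum(h, min(c.mean for c in typical.categories))
        hi = np.maximum(h, max(c.mean for c in typical.categories))
        for cue in typical.cues:
            e = expected_humanness(h, cue, typical)
            assert np.all(e >= lo - 1e-12) and np.all(e <= hi + 1e-12)


class TestDisplacement:
    def test_zero_for_noiseless_cue(self, typical):
        h = np.linspace(0.0, 1.0, 11)
        np.testing.assert_allclose(
            displacement(h, Cue(sigma_s=0.0), typical), np.zeros_like(h), atol=1e-12
        )

    def test_pulls_toward_dominant_human_category(self, typical):
        # just below the human mean the magnet pulls the percept upward
        assert displacement(0.9, typical.cues[0], typical) > 0
        # and the sign agrees with the quadrature posterior mean
        oracle = quadrature_posterior_mean(0.9, 0.2, typical) - 0.9
        assert displacement(0.9, typical.cues[0], typical) == pytest.approx(
            oracle, abs=1e-6
        )


class TestPerceptualTension:
    def test_zero_for_identical_cues(self, typical):
        config = ModelConfig(
            categories=typical.categories,
            cues=(Cue(sigma_s=0.1), Cue(sigma_s=0.1)),
        )
        h = np.linspace(0.0, 1.0, 21)
        np.testing.assert_allclose(perceptual_tension(h, config), 0.0, atol=1e-15)

    def test_zero_for_single_cue(self, typical):
        config = ModelConfig(
            categories=typical.categories, cues=(Cue(sigma_s=0.2),)
        )
        assert perceptual_tension(0.7, config) == 0.0

    @pytest.mark.parametrize("ddof,denom", [(0, 4.0), (1, 2.0)])
    def test_two_cue_closed_form(self, typical, ddof, denom):
        h = np.linspace(0.0, 1.0, 21)
        d1 = displacement(h, typical.cues[0], typical)
        d2 = displacement(h, typical.cues[1], typical)
        np.testing.assert_allclose(
            perceptual_tension(h, typical, ddof=ddof),
            (d1 - d2) ** 2 / denom,
            atol=1e-14,
        )

    def test_beta_weighted_equals_equal_weight_at_half(self, typical):
        h = np.linspace(0.0, 1.0, 21)
        np.testing.assert_allclose(
            perceptual_tension(h, typical, beta_weighted=True),
            perceptual_tension(h, typical),
            atol=1e-14,
        )

    def test_nonnegative_everywhere(self, asd):
        h = np.linspace(-1.0, 2.0, 61)
        assert np.all(perceptual_tension(h, asd) >= 0)


class TestResponses:
    def test_alpha_zero_reduces_to_marginal(self, typical):
        config = ModelConfig(
            categories=typical.categories, cues=typical.cues, alpha=0.0
        )
        h = np.linspace(0.0, 1.0, 11)
        for cue in config.cues:
            np.testing.assert_allclose(
                emotional_response(h, cue, config),
                marginal_density(h, cue, config),
                atol=1e-14,
            )

    @pytest.mark.parametrize("beta,cue_index", [(1.0, 0), (0.0, 1)])
    def test_combined_degenerates_to_single_cue(self, typical, beta, cue_index):
        config = ModelConfig(
            categories=typical.categories, cues=typical.cues, beta=beta
        )
        h = np.linspace(0.0, 1.0, 11)
        np.testing.assert_allclose(
            combined_response(h, config),
            emotional_response(h, config.cues[cue_index], config),
            atol=1e-14,
        )

    def test_requires_exactly_two_cues(self, typical):
        config = ModelConfig(
            categories=typical.categories, cues=(Cue(sigma_s=0.2),)
        )
        with pytest.raises(UnsupportedConfigurationError):
            combined_response(0.5, config)

    def test_reliable_cue_response_dips_between_the_category_means(self, typical):
        from uncanny import stimulus_grid

        grid = stimulus_grid()
        curve = response_curve(typical, grid)
        f2 = curve.per_cue_F[1]
        interior = (grid > 0.5) & (grid < 1.0)
        i = np.argmin(f2[interior])
        # regression value from this implementation at step 0.005
        assert grid[interior][i] == pytest.approx(0.715, abs=0.005)
        assert f2[interior][i] < f2[np.isclose(grid, 0.5)][0]
        assert f2[interior][i] < f2[np.isclose(grid, 1.0)][0]


class TestResponseCurve:
    def test_single_point_grid_matches_pointwise_ops(self, typical):
        curve = response_curve(typical, [0.7])
        assert curve.Y[0] == pytest.approx(combined_response(0.7, typical), rel=1e-12)
        assert curve.V[0] == pytest.approx(perceptual_tension(0.7, typical), rel=1e-12)

    def test_spot_checks_match_single_point_evaluations(self, asd):
        grid = np.arange(0.0, 1.0001, 0.01)
        curve = response_curve(asd, grid)
        for h in (0.25, 0.5, 0.9):
            i = np.flatnonzero(np.isclose(grid, h))[0]
            assert curve.Y[i] == pytest.approx(combined_response(h, asd), rel=1e-12)
            for k, cue in enumerate(asd.cues):
                assert curve.per_cue_F[k, i] == pytest.approx(
                    emotional_response(h, cue, asd), rel=1e-12
                )

    def test_deterministic_bit_identical(self, typical):
        grid = np.arange(0.0, 1.0001, 0.01)
        a, b = response_curve(typical, grid), response_curve(typical, grid)
        assert np.array_equal(a.Y, b.Y)
        assert np.array_equal(a.V, b.V)
        assert np.array_equal(a.per_cue_F, b.per_cue_F)

    def test_rejects_unordered_grid(self, typical):
        with pytest.raises(ValueError):
            response_curve(typical, [0.5, 0.2])


class TestValidation:
    def test_category_sd_must_be_positive(self):
        with pytest.raises(ValueError, match="sd"):
            Category(mean=0.5, sd=0.0, prior=0.5)

    def test_priors_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ModelConfig(
                categories=(
                    Category(mean=0.5, sd=0.5, prior=0.4),
                    Category(mean=1.0, sd=0.05, prior=0.4),
                ),
                cues=(Cue(sigma_s=0.2),),
            )

    def test_beta_range_enforced(self, typical):
        with pytest.raises(ValueError, match="beta"):
            ModelConfig(categories=typical.categories, cues=typical.cues, beta=1.5)
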