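"""Effect-size indices, posterior containers, diagnostics and sampler contracts."""

import arviz as az
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pongocog import (
    PosteriorDraws,
    SamplerSettings,
    contrast_draws,
    diagnostics,
    hdi,
    prob_direction,
    sample_posterior,
    summarize_effect,
)


class BernoulliToy:
    """Flat-prior Bernoulli model on the logit scale (conjugate check)."""

    names = ["logit_p"]
    dim = 1

    def __init__(self, successes: int, trials: int):
        self.k, self.n = successes, trials

    def logp_and_grad(self, theta):
        eta = theta[0]
        if abs(eta) > 30:
            return -np.inf, np.zeros(1)
        p = 1.0 / (1.0 + np.exp(-eta))
        logp = self.k * eta - self.n * np.logaddexp(0.0, eta)
        return float(logp), np.array([self.k - self.n * p])

    def initial_position(self, rng):
        return 0.5 * rng.standard_normal(1)

    def transform(self, theta):
        return theta.copy()


class NormalLocationToy:
    """Known-variance normal location model with Normal(0, 5) prior."""

    names = ["mu"]
    dim = 1

    def __init__(self, data, sigma=1.0, prior_sd=5.0):
        self.data = np.asarray(data, dtype=float)
        self.sigma, self.prior_sd = sigma, prior_sd

    def logp_and_grad(self, theta):
        mu = theta[0]
        r = self.data - mu
        logp = -0.5 * np.sum(r**2) / self.sigma**2 - 0.5 * (mu / self.prior_sd) ** 2
        grad = np.sum(r) / self.sigma**2 - mu / self.prior_sd**2
        return float(logp), np.array([grad])

    def initial_position(self, rng):
        return rng.standard_normal(1)

    def transform(self, theta):
        return theta.copy()

    def posterior_moments(self):
        n = self.data.size
        prec = n / self.sigma**2 + 1.0 / self.prior_sd**2
        mean = (self.data.sum() / self.sigma**2) / prec
        return mean, np.sqrt(1.0 / prec)


class TestHdi:
    def test_uniform_draws_length_near_mass(self):
        rng = np.random.default_rng(1)
        lo, hi = hdi(rng.random(100_000), 0.89)
        assert hi - lo == pytest.approx(0.89, abs=0.01)

    def test_normal_draws_match_central_interval(self):
        rng = np.random.default_rng(2)
        lo, hi = hdi(rng.standard_normal(200_000), 0.89)
        assert lo == pytest.approx(-1.598, abs=0.03)
        assert hi == pytest.approx(1.598, abs=0.03)

    def test_constant_samples_zero_length(self):
        assert hdi(np.full(100, 3.25), 0.89) == (3.25, 3.25)

    def test_invalid_mass_rejected(self):
        with pytest.raises(ValueError):
            hdi(np.arange(100), 1.2)

    def test_agrees_with_arviz(self):
        rng = np.random.default_rng(3)
        x = rng.gamma(2.0, 1.0, 50_000)
        ours = hdi(x, 0.89)
        theirs = az.hdi(x, hdi_prob=0.89)
        assert ours[0] == pytest.approx(theirs[0], abs=0.02)
        assert ours[1] == pytest.approx(theirs[1], abs=0.02)

    @given(
        # distinct values: ties can only widen the inside fraction trivially
        data=st.lists(
            st.floats(min_value=-1e6, max_value=1e6), min_size=60, max_size=400, unique=True
        ),
        mass=st.floats(min_value=0.5, max_value=0.99),
    )
    @settings(max_examples=80, deadline=None)
    def test_inside_fraction_bound(self, data, mass):
        arr = np.asarray(data)
        lo, hi = hdi(arr, mass)
        inside = np.mean((arr >= lo) & (arr <= hi))
        assert mass <= inside <= mass + 2.0 / arr.size + 1e-12


class TestProbDirection:
    @pytest.mark.parametrize(
        "samples, expected",
        [([1, 2, 3], 1.0), ([-1, 1, -2, 2], 0.5), ([-1, 2, 3, 4], 0.75)],
    )
    def test_examples(self, samples, expected):
        assert prob_direction(samples) == expected

    def test_zeros_excluded_and_renormalised(self):
        assert prob_direction([0, 0, 1, -1]) == 0.5
        assert prob_direction([0, 0, 0]) == 0.5

    def test_invariant_to_sign_preserving_scaling(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(1000) + 0.3
        assert prob_direction(x) == prob_direction(17.0 * x) == prob_direction(np.expm1(x) + x**3)


class TestSummarizeEffect:
    def test_shift_equivariance(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(5000)
        a, b = summarize_effect(x), summarize_effect(x + 10.0)
        assert b.median == pytest.approx(a.median + 10.0)
        assert b.mad == pytest.approx(a.mad)
        assert b.hdi_low == pytest.approx(a.hdi_low + 10.0, abs=1e-9)

    def test_symmetric_samples(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(20_001)
        s = summarize_effect(x)
        assert abs(s.median) < 0.03 and abs(s.pd - 0.5) < 0.02

    def test_monotone_transform_consistency_on_odd_draws(self):
        rng = np.random.default_rng(7)
        x = rng.normal(np.log(0.67), 0.1, 10_001)  # odd count: median is a draw
        assert np.median(np.exp(x)) == np.exp(np.median(x))
        s = summarize_effect(np.exp(x))
        assert s.median == pytest.approx(0.67, abs=0.01)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            summarize_effect(np.arange(10))


def _draws_from(arr3d, names):
    return PosteriorDraws(names=list(names), draws=np.asarray(arr3d, dtype=float))


class TestContrastDraws:
    @pytest.fixture()
    def draws(self):
        rng = np.random.default_rng(8)
        return _draws_from(rng.standard_normal((2, 100, 3)), ["a", "b", "c"])

    def test_identity_weight(self, draws):
        np.testing.assert_array_equal(contrast_draws(draws, {"b": 1.0}), draws.get("b"))

    def test_sum_coding_doubles_coefficient(self, draws):
        np.testing.assert_allclose(contrast_draws(draws, {"a": 2.0}), 2.0 * draws.get("a"))

    def test_zero_weights(self, draws):
        assert (contrast_draws(draws, {"a": 0.0, "c": 0.0}) == 0).all()

    def test_unknown_parameter_rejected(self, draws):
        with pytest.raises(KeyError):
            contrast_draws(draws, {"nope": 1.0})


class TestDiagnostics:
    def test_iid_chains_rhat_near_one(self):
        rng = np.random.default_rng(9)
        d = _draws_from(rng.standard_normal((4, 500, 2)), ["x", "y"])
        rep = diagnostics(d)
        assert rep.max_rhat < 1.02
        assert rep.converged()

    def test_offset_chain_flags_rhat(self):
        rng = np.random.default_rng(10)
        arr = rng.standard_normal((4, 500, 1))
        arr[0] += 10.0
        rep = diagnostics(_draws_from(arr, ["x"]))
        assert rep.rhat["x"] > 1.1

    def test_constant_chain_flags_autocorrelation(self):
        arr = np.zeros((2, 200, 1))
        rep = diagnostics(_draws_from(arr, ["x"]))
        assert rep.max_lag1_autocorr == 1.0

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            diagnostics(_draws_from(np.zeros((1, 100, 1)), ["x"]))


class TestSamplePosterior:
    def test_bernoulli_toy_symmetric_data(self):
        from scipy.special import expit

        model = BernoulliToy(10, 20)
        draws = sample_posterior(model, SamplerSettings(2, 2500, 500, seed=1))
        p = expit(draws.get("logit_p"))
        assert p.mean() == pytest.approx(0.5, abs=0.02)

    def test_normal_location_matches_conjugate_closed_form(self):
        rng = np.random.default_rng(11)
        model = NormalLocationToy(rng.normal(3.0, 1.0, 200))
        draws = sample_posterior(model, SamplerSettings(2, 3000, 500, seed=2))
        mu = draws.get("mu")
        mean, sd = model.posterior_moments()
        assert mu.mean() == pytest.approx(mean, abs=3 * sd / 10)
        assert mu.std() == pytest.approx(sd, rel=0.1)

    def test_same_seed_identical_draws(self):
        model = NormalLocationToy(np.array([1.0, 2.0, 3.0]))
        settings_ = SamplerSettings(2, 800, 300, seed=3)
        a = sample_posterior(model, settings_)
        b = sample_posterior(model, settings_)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_two_seeds_agree_within_mc_error(self):
        model = NormalLocationToy(np.full(100, 2.0))
        _, sd = model.posterior_moments()
        medians = []
        for seed in (4, 5):
            d = sample_posterior(model, SamplerSettings(2, 3000, 500, seed=seed))
            medians.append(np.median(d.get("mu")))
        mc_se = sd / np.sqrt(1000)  # conservative ESS guess
        assert abs(medians[0] - medians[1]) < 3 * mc_se * 2

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            SamplerSettings(n_chains=1)
        with pytest.raises(ValueError):
            SamplerSettings(n_iterations=100, n_warmup=100)
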