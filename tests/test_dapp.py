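import numpy as np
import pytest

from spikemux.dapp import (
    AlphaDraws,
    DAPPConfig,
    DAPPIndices,
    DAPPPosterior,
    compute_indices,
    fit_dapp,
    predict_alpha,
    rate_priors_from_triplet,
    smooth_to_gamma_priors,
    tag_triplet,
)
from spikemux.synthetic import GeneratorConfig, make_triplet
from spikemux.trials import bin_spikes

FAST = DAPPConfig(n_iter=1000, burn_in=400, thin=2, seed=5, n_pred_draws=400)


class TestRatePriors:
    def _binned(self, rate, n, rng, t_end=600):
        from spikemux.synthetic import gen_poisson_trials, _mk_record
        trains = gen_poisson_trials(rate, n, t_end, rng)
        trials = [_mk_record("n", i, "A", t, t_end) for i, t in enumerate(trains)]
        return bin_spikes(trials, 50, t_end)

    def test_constant_rate_recovered(self, rng):
        binned = self._binned(20.0, 20, rng)
        curve = smooth_to_gamma_priors(binned)
        assert np.all(np.abs(curve.mean - 20.0) < 3 * curve.sd + 1e-9)

    def test_doubling_counts_doubles_means(self, rng):
        binned = self._binned(40.0, 20, rng)
        curve = smooth_to_gamma_priors(binned)
        binned.counts = binned.counts * 2
        doubled = smooth_to_gamma_priors(binned)
        np.testing.assert_allclose(doubled.mean, 2 * curve.mean, rtol=1e-9)

    def test_moment_matching_identity(self, rng):
        curve = smooth_to_gamma_priors(self._binned(30.0, 15, rng))
        np.testing.assert_allclose(curve.shape / curve.rate**2, curve.sd**2,
                                   rtol=1e-9)

    def test_too_few_trials_error(self, rng):
        with pytest.raises(ValueError):
            smooth_to_gamma_priors(self._binned(20.0, 4, rng))


class TestIndicesAndTags:
    def test_all_large_swings_give_infinite_waviness(self):
        draws = AlphaDraws(curves=np.full((200, 12), 0.5),
                           swings=np.full(200, 0.9), means=np.full(200, 0.5))
        assert compute_indices(draws).r_w == np.inf

    def test_extremeness_odds_are_a_simple_ratio(self):
        means = np.concatenate([np.full(80, 0.5), np.full(20, 0.9)])
        draws = AlphaDraws(curves=np.zeros((100, 12)),
                           swings=np.full(100, 0.1), means=means)
        assert compute_indices(draws).r_c == pytest.approx(4.0)

    def test_symmetric_means_give_unit_skew(self, rng):
        means = np.clip(0.5 + 0.1 * rng.standard_normal(4000), 0.01, 0.99)
        means = np.concatenate([means, 1 - means])  # exactly symmetric
        draws = AlphaDraws(curves=np.zeros((8000, 12)),
                           swings=np.full(8000, 0.1), means=means)
        assert compute_indices(draws).r_s == pytest.approx(1.0, abs=0.01)

    def test_too_few_draws_error(self):
        draws = AlphaDraws(np.zeros((50, 12)), np.zeros(50), np.full(50, 0.5))
        with pytest.raises(ValueError):
            compute_indices(draws)

    @pytest.mark.parametrize("r_w,r_c,r_s,expected", [
        (2.0, 5.0, 1.5, ("Wavy", "Central", "Symmetric")),
        (1.0, 5.0, 1.5, ("Ambiguous", "Central", "Symmetric")),
        (0.5, 1.0, 10.0, ("Flat", "Extreme", "Skewed")),
        (1.3, 3.24, 4.0, ("Ambiguous", "Ambiguous", "Unlabeled")),
        (0.77, 1.68, 2.0, ("Ambiguous", "Ambiguous", "Unlabeled")),
        (np.inf, np.inf, np.inf, ("Wavy", "Central", "Skewed")),
    ])
    def test_threshold_application(self, r_w, r_c, r_s, expected):
        tags = tag_triplet(DAPPIndices(r_w=r_w, r_c=r_c, r_s=r_s))
        assert (tags.waviness, tags.extremeness, tags.symmetry) == expected


def _degenerate_posterior(phi, psi, ell_weights, n_draws=4):
    trunc, g = 3, 5
    shape = (n_draws, trunc)
    return DAPPPosterior(
        lam_a=np.full((n_draws, 12), 20.0), lam_b=np.full((n_draws, 12), 5.0),
        alpha=np.full((n_draws, 5, 12), 0.5),
        phi=np.full((n_draws, 5), phi), psi=np.full((n_draws, 5), psi),
        ell=np.full((n_draws, 5), 75.0),
        atom_phi=np.full(shape, phi), atom_psi=np.full(shape, psi),
        atom_weight=np.tile(np.array([1.0, 0.0, 0.0]), (n_draws, 1)),
        p_ell=np.tile(np.asarray(ell_weights, float), (n_draws, 1)),
        config=DAPPConfig(),
    )


class TestPredictAlpha:
    def test_degenerate_generator_is_flat_at_half(self):
        post = _degenerate_posterior(0.0, 1e-8, [1, 0, 0, 0, 0])
        draws = predict_alpha(post, n_draws=200, seed=1)
        assert np.all(np.abs(draws.means - 0.5) < 0.01)
        assert np.all(draws.swings < 0.05)

    def test_short_length_scale_swings_more(self):
        short = predict_alpha(_degenerate_posterior(0.0, 4.0, [1, 0, 0, 0, 0]),
                              n_draws=800, seed=2)
        long = predict_alpha(_degenerate_posterior(0.0, 4.0, [0, 0, 0, 0, 1]),
                             n_draws=800, seed=3)
        assert short.swings.mean() > long.swings.mean()

    def test_seed_determinism(self):
        post = _degenerate_posterior(0.5, 2.0, [0.2] * 5)
        d1 = predict_alpha(post, n_draws=50, seed=9)
        d2 = predict_alpha(post, n_draws=50, seed=9)
        np.testing.assert_array_equal(d1.curves, d2.curves)

    def test_alpha_strictly_inside_unit_interval(self):
        post = _degenerate_posterior(3.0, 9.0, [0.2] * 5)
        draws = predict_alpha(post, n_draws=300, seed=4)
        assert np.all((draws.curves > 0) & (draws.curves < 1))
        assert np.all(draws.swings < 1)


class TestFitRecovery:
    def test_constant_alpha_mean_recovered(self):
        trip, _ = make_triplet(GeneratorConfig(
            rate_a=20.0, rate_b=10.0, regime="constant_alpha", alpha0=0.5,
            n_ab=15, seed=21))
        post = fit_dapp(trip, config=FAST)
        abar = post.alpha_trial_means().mean()
        assert 0.35 < abar < 0.65

    def test_single_regime_alpha_mass_above_half(self):
        trip, _ = make_triplet(GeneratorConfig(
            rate_a=100 / 3, rate_b=25 / 3, regime="single", which="A",
            n_ab=15, seed=22))
        post = fit_dapp(trip, config=FAST)
        assert np.all(post.alpha_trial_means() > 0.5)

    def test_whole_trial_switch_trial_means_are_bimodal(self):
        trip, latent = make_triplet(GeneratorConfig(
            rate_a=100 / 3, rate_b=25 / 3, regime="whole_trial_switch",
            pi_a=0.5, n_ab=15, seed=23))
        post = fit_dapp(trip, config=FAST)
        abar = post.alpha_trial_means()
        labels = latent["labels"].astype(bool)
        assert abar[labels].mean() > 0.6 > abar[~labels].mean()

    def test_posterior_predictive_bin_coverage(self):
        # on matched data the 90% predictive interval for held-out bin counts
        # should cover at roughly its nominal rate
        gen = GeneratorConfig(rate_a=100 / 3, rate_b=25 / 3,
                              regime="constant_alpha", alpha0=0.5,
                              n_ab=15, seed=24)
        trip, _ = make_triplet(gen)
        post = fit_dapp(trip, config=FAST)
        rng = np.random.default_rng(7)
        n_rep, scale = 400, 50 / 1000.0
        draws = rng.integers(0, post.n_draws, size=n_rep)
        trial = rng.integers(0, 15, size=n_rep)
        mu = scale * (
            post.alpha[draws, trial] * post.lam_a[draws]
            + (1 - post.alpha[draws, trial]) * post.lam_b[draws]
        )
        sims = rng.poisson(mu)  # (n_rep, C) predictive bin counts
        lo = np.quantile(sims, 0.05, axis=0)
        hi = np.quantile(sims, 0.95, axis=0)
        held, _ = make_triplet(GeneratorConfig(**{**gen.__dict__, "seed": 99}))
        held_counts = bin_spikes(held.trials_ab, 50, 600).counts
        cover = np.mean((held_counts >= lo) & (held_counts <= hi))
        assert 0.80 <= cover <= 1.0

    def test_rate_prior_pair_shapes(self):
        trip, _ = make_triplet(GeneratorConfig(seed=25))
        prior = rate_priors_from_triplet(trip, 50)
        assert prior.a.shape.shape == (12,) and prior.b.shape.shape == (12,)
        assert np.all(prior.a.shape > 0) and np.all(prior.a.rate > 0)
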