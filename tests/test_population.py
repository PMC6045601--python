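import numpy as np
import pytest
from scipy import stats

from spikemux.population import (
    assignment_score,
    behavior_link,
    binwise_scores,
    classify_trials_AB,
    lfp_compare,
    pair_condition_filter,
    pair_population_test,
    pair_trial_correlations,
    whole_trial_scores,
)
from spikemux.synthetic import (
    GeneratorConfig,
    PairConfig,
    gen_correlated_pair,
    gen_lfp_trials,
    make_triplet,
)
from spikemux.trials import Triplet

from conftest import triplet_from_counts


class TestAssignmentScore:
    def test_equal_rates_give_half(self):
        for count in (0, 3, 40):
            assert assignment_score(count, 7.0, 7.0) == pytest.approx(0.5)

    def test_worked_example(self):
        # frozen from direct evaluation of the two Poisson pmfs:
        # 1024 e^-5 / (1 + 1024 e^-5)
        expected = 1024 * np.exp(-5.0) / (1 + 1024 * np.exp(-5.0))
        assert assignment_score(10, 10.0, 5.0) == pytest.approx(expected)
        assert expected == pytest.approx(0.8734, abs=2e-4)

    def test_zero_count_prefers_smaller_rate(self):
        s1 = assignment_score(0, 10.0, 5.0)
        s2 = assignment_score(0, 20.0, 5.0)
        assert s2 < s1 < 0.5

    def test_extreme_rates_never_nan(self):
        s = assignment_score(1000, 1e-3, 500.0)
        assert 0.0 <= s <= 1.0 and np.isfinite(s)

    def test_complementarity(self):
        s = assignment_score(7, 12.0, 4.0)
        s_swapped = assignment_score(7, 4.0, 12.0)
        assert s + s_swapped == pytest.approx(1.0)


class TestBinwiseScores:
    def test_z_moments(self):
        trip, _ = make_triplet(GeneratorConfig(regime="constant_alpha", seed=3))
        sc = binwise_scores(trip)
        ok = ~sc.degenerate_bins
        np.testing.assert_allclose(sc.z_scores[:, ok].mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(sc.z_scores[:, ok].std(axis=0), 1.0, atol=1e-9)

    def test_pure_a_trials_score_above_half(self):
        trip, _ = make_triplet(GeneratorConfig(
            rate_a=40.0, rate_b=5.0, regime="single", which="A", seed=4))
        sc = binwise_scores(trip)
        assert np.all(sc.scores.mean(axis=0) > 0.5)

    def test_degenerate_bin_flagged_and_zeroed(self):
        trip = triplet_from_counts([5] * 5, [1] * 5, [0] * 5)
        sc = binwise_scores(trip)
        assert sc.degenerate_bins.any()
        assert np.all(sc.z_scores[:, sc.degenerate_bins] == 0.0)

    def test_square_wave_scores_track_the_generator_period(self):
        cfg = GeneratorConfig(rate_a=120.0, rate_b=30.0, regime="square_wave",
                              period_ms=200.0, n_ab=200, seed=5)
        trip, _ = make_triplet(cfg)
        sc = binwise_scores(trip)
        mean_by_bin = sc.scores.mean(axis=0)
        # alpha = 0.95 in bins 0,1,4,5,8,9 and 0.05 in bins 2,3,6,7,10,11
        hi = mean_by_bin[[0, 1, 4, 5, 8, 9]].mean()
        lo = mean_by_bin[[2, 3, 6, 7, 10, 11]].mean()
        assert hi > 0.6 > 0.4 > lo


class TestTrialClassification:
    def test_threshold_and_tie_rules(self):
        from spikemux.population import AssignmentScores
        sc = AssignmentScores("t", "whole_trial",
                              scores=np.array([0.9, 0.2, 0.5]))
        labels, usable = classify_trials_AB(sc)
        assert labels[0] and not labels[1]
        assert usable.tolist() == [True, True, False]

    def test_switching_fraction_matches_pi(self):
        trip, latent = make_triplet(GeneratorConfig(
            rate_a=100 / 3, rate_b=25 / 3, regime="whole_trial_switch",
            pi_a=0.7, n_ab=400, seed=6))
        labels, usable = classify_trials_AB(whole_trial_scores(trip))
        frac = labels[usable].mean()
        assert abs(frac - 0.7) < 0.08
        # labels should agree with the generator's latent state
        agree = (labels == latent["labels"].astype(bool))[usable].mean()
        assert agree > 0.9


class TestPairAnalyses:
    def _pair_triplets(self, rho, regime="square_wave", seed=7, n_ab=20):
        # random per-trial phase: the shared switching state then varies
        # across trials, which is what survives the within-bin Z-normalization
        mk = lambda s: GeneratorConfig(rate_a=120.0, rate_b=30.0, regime=regime,
                                       period_ms=200.0, n_ab=n_ab, seed=s,
                                       random_phase=True)
        pair = PairConfig(config1=mk(seed), config2=mk(seed + 1), rho=rho)
        (t1, _), (t2, _) = gen_correlated_pair(pair)
        trips = []
        for trains in (t1, t2):
            cfg = mk(seed)
            trip, _ = make_triplet(cfg)
            ab = trip.trials_ab[: len(trains)]
            for rec, train in zip(ab, trains):
                rec.spike_times = np.sort(train)
            trips.append(Triplet(
                neuron_id=trip.neuron_id, stim_a=trip.stim_a, stim_b=trip.stim_b,
                trials_a=trip.trials_a, trials_b=trip.trials_b,
                trials_ab=ab, t_end=trip.t_end,
            ))
        return trips

    def test_filter_rejects_identical_tuning_and_few_trials(self):
        same = triplet_from_counts([10] * 6, [10, 11, 9, 10, 10, 10], [10] * 6)
        diff = triplet_from_counts([20, 22, 18, 21, 19], [5, 6, 4, 5, 5], [12] * 5)
        assert not pair_condition_filter(same, diff)
        few = triplet_from_counts([20, 22, 18, 21, 19], [5, 6, 4, 5, 5], [12] * 4)
        assert not pair_condition_filter(few, diff)
        assert pair_condition_filter(diff, diff)

    def test_identical_scores_give_unit_correlation(self):
        t1, _ = self._pair_triplets(1.0)
        sc = binwise_scores(t1)
        res = pair_trial_correlations(sc, sc)
        np.testing.assert_allclose(res.per_trial_r, 1.0, atol=1e-12)

    def test_shared_state_pairs_correlate_positively(self):
        means = []
        for seed in range(3):
            t1, t2 = self._pair_triplets(1.0, seed=100 + 10 * seed)
            res = pair_trial_correlations(binwise_scores(t1), binwise_scores(t2))
            means.append(res.mean_r)
        assert np.mean(means) > 0.15

    def test_population_test_statistics(self):
        res = pair_population_test(np.array([0.2, 0.3, 0.25, 0.15, 0.22]))
        ref = stats.ttest_1samp([0.2, 0.3, 0.25, 0.15, 0.22], 0.0)
        assert res.t_stat == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)


class TestLFP:
    def test_constant_traces_recover_offsets_exactly(self):
        labels = np.array([1, 1, 0, 0])
        traces = gen_lfp_trials(labels, 2.0, -2.0, 0.0, seed=1)
        res = lfp_compare(traces, labels.astype(bool), session_mean=0.0)
        assert np.allclose(res.mean_trace_a[:600], 2.0)
        assert np.allclose(res.mean_trace_b[:600], -2.0)

    def test_separated_offsets_detected_pre_onset(self):
        labels = np.concatenate([np.ones(60), np.zeros(60)])
        traces = gen_lfp_trials(labels, 5.0, 0.0, 1.0, seed=2)
        res = lfp_compare(traces, labels.astype(bool))
        assert res.p_pre < 0.01

    def test_amplitude_exclusion(self):
        labels = np.array([1, 1, 0, 0, 1])
        traces = gen_lfp_trials(labels, 1.0, -1.0, 0.0, seed=3)
        traces[2, 100] = 900.0
        res = lfp_compare(traces, labels.astype(bool), session_mean=0.0)
        assert res.n_excluded_amplitude == 1

    def test_single_group_errors(self):
        traces = gen_lfp_trials(np.ones(4), 1.0, -1.0, 0.0, seed=4)
        with pytest.raises(ValueError):
            lfp_compare(traces, np.ones(4, dtype=bool))

    def test_null_false_positive_rate(self, rng):
        hits = 0
        n_rep = 300
        for rep in range(n_rep):
            labels = rng.permutation(np.concatenate([np.ones(30), np.zeros(30)]))
            traces = gen_lfp_trials(labels, 1.0, 1.0, 1.0, seed=rep)
            res = lfp_compare(traces, labels.astype(bool))
            hits += res.p_pre < 0.05
        assert 0.02 <= hits / n_rep <= 0.08


class TestBehaviorLink:
    def _scores(self, values):
        from spikemux.population import AssignmentScores
        return AssignmentScores("t", "whole_trial", scores=np.asarray(values))

    def test_coupled_scores_differ_between_saccade_groups(self):
        trip, latent = make_triplet(GeneratorConfig(
            rate_a=100 / 3, rate_b=25 / 3, regime="whole_trial_switch",
            pi_a=0.5, n_ab=100, seed=8))
        saccade = np.where(latent["labels"] == 1, "A", "B")
        link = behavior_link(whole_trial_scores(trip), saccade)
        assert link.mean_score_a_first > link.mean_score_b_first
        assert link.p_value < 0.01

    def test_null_labels_do_not_flag(self, rng):
        ps = []
        for rep in range(100):
            scores = self._scores(rng.uniform(size=40))
            labels = rng.permutation(np.array(["A"] * 20 + ["B"] * 20))
            ps.append(behavior_link(scores, labels).p_value)
        assert 0.01 <= np.mean(np.asarray(ps) < 0.05) + 1e-9 <= 0.12

    def test_stereotyped_behavior_flagged(self):
        link = behavior_link(self._scores([0.4, 0.6, 0.7]),
                             np.array(["A", "A", "A"]))
        assert link.stereotyped and np.isnan(link.p_value)

    def test_unknown_saccades_excluded(self):
        link = behavior_link(self._scores([0.9, 0.1, 0.5, 0.6]),
                             np.array(["A", "B", "unknown", "B"]))
        assert link.n_a_first == 1 and link.n_b_first == 2

    def test_per_bin_variant_reports_sign(self):
        trip, latent = make_triplet(GeneratorConfig(
            rate_a=100 / 3, rate_b=25 / 3, regime="whole_trial_switch",
            pi_a=0.5, n_ab=60, seed=9))
        saccade = np.where(latent["labels"] == 1, "A", "B")
        link = behavior_link(whole_trial_scores(trip), saccade,
                             bin_scores=binwise_scores(trip))
        assert link.bin_p_values.shape == (12,)
        assert (link.bin_signs > 0).mean() > 0.8
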