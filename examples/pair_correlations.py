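"""Do two simultaneously recorded neurons switch together within trials?

Per 50 ms bin, each dual trial of each neuron gets a probability that its
count came from the A-alone rather than the B-alone rate.  Z-normalizing
within bins across trials removes stimulus-locked structure; the per-trial
correlation of the two neurons' Z sequences then isolates shared switching.
"""

import numpy as np

from spikemux import (
    GeneratorConfig,
    PairConfig,
    Triplet,
    binwise_scores,
    gen_correlated_pair,
    make_triplet,
    pair_population_test,
    pair_trial_correlations,
)


def coupled_pair(rho, seed):
    mk = lambda s: GeneratorConfig(
        rate_a=120.0, rate_b=30.0, regime="square_wave", period_ms=200.0,
        n_ab=16, n_a=10, n_b=10, random_phase=True, seed=s)
    (t1, _), (t2, _) = gen_correlated_pair(
        PairConfig(config1=mk(seed), config2=mk(seed + 1), rho=rho))
    triplets = []
    for offset, trains in ((0, t1), (1, t2)):
        trip, _ = make_triplet(mk(seed + offset))
        ab = trip.trials_ab[: len(trains)]
        for rec, train in zip(ab, trains):
            rec.spike_times = np.sort(train)
        triplets.append(Triplet(trip.neuron_id, trip.stim_a, trip.stim_b,
                                trip.trials_a, trip.trials_b, ab, trip.t_end))
    return triplets


for rho in (0.0, 1.0):
    means = []
    for i in range(14):
        n1, n2 = coupled_pair(rho, seed=2 * i + int(rho) * 1000)
        res = pair_trial_correlations(binwise_scores(n1), binwise_scores(n2))
        means.append(res.mean_r)
    pop = pair_population_test(np.array(means))
    print(f"rho={rho}: population mean r = {pop.mean_of_means:+.3f}, "
          f"t = {pop.t_stat:+.2f}, p = {pop.p_value:.2g}")
# Uncoupled pairs hover near zero; pairs sharing their switching state show
# a clearly positive mean correlation.
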