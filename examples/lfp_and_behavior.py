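"""Link single-trial switching state to the LFP and to behavior.

Dual trials are labeled A-like or B-like by their whole-trial assignment
score.  If switching reflects a network state, the pre-stimulus LFP should
already differ between the two groups; and if it matters for behavior, the
score should predict which stimulus the subject orients to first.
"""

import numpy as np

from spikemux import (
    GeneratorConfig,
    behavior_link,
    classify_trials_AB,
    gen_lfp_trials,
    lfp_compare,
    make_triplet,
    whole_trial_scores,
)

triplet, latent = make_triplet(GeneratorConfig(
    regime="whole_trial_switch", pi_a=0.5, n_ab=120, seed=4))
scores = whole_trial_scores(triplet)
labels, usable = classify_trials_AB(scores)
print(f"{labels[usable].sum()} A-like and {(~labels[usable]).sum()} B-like "
      "dual trials by whole-trial assignment score")

# LFP whose pre-stimulus mean covaries with the trial's switching state
traces = gen_lfp_trials(latent["labels"], pre_offset_a=-3.0, pre_offset_b=3.0,
                        noise_sd=2.0, seed=5, evoked_a=-4.0, evoked_b=4.0)
res = lfp_compare(traces[usable], labels[usable])
print(f"LFP group difference: pre-onset p = {res.p_pre:.2g}, "
      f"post-onset p = {res.p_post:.2g}")

# first saccade coupled to the latent state
saccade = np.where(latent["labels"] == 1, "A", "B")
link = behavior_link(scores, saccade)
print(f"assignment score when looking at A first: {link.mean_score_a_first:.2f}, "
      f"at B first: {link.mean_score_b_first:.2f} (t-test p = {link.p_value:.2g})")
# Both the pre-stimulus network state and the upcoming saccade choice carry
# information about which stimulus the neuron is encoding on that trial.
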