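"""Does the pooled dual-stimulus response look like a sum or an average?

The dual response mean is Z-scored against two predictions built from the
single-stimulus trials: their baseline-corrected sum and their average.
|Z| <= 1.96 means the dual response lies inside the 95% band of that
prediction.
"""

from spikemux import GeneratorConfig, make_triplet, summation_vs_averaging

triplet, _ = make_triplet(GeneratorConfig(
    regime="whole_trial_switch", pi_a=0.5, n_ab=40, baseline_rate=5.0, seed=1))
s = summation_vs_averaging(triplet)

print(f"mean counts: A={s.mean_resp_a:.1f}  B={s.mean_resp_b:.1f}  "
      f"AB={s.mean_resp_ab:.1f}  baseline={s.mean_base:.1f}")
print(f"predicted sum {s.predicted_sum:.1f}, predicted average {s.predicted_avg:.1f}")
print(f"Zsum = {s.z_sum:+.2f}, ZAvg = {s.z_avg:+.2f}  ->  closer to {s.closer_to}")
# A switching neuron spends part of its trials at each single-stimulus rate,
# so its pooled dual response resembles the average, not the sum.
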