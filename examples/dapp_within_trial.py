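"""Fit the dynamic admixture model and tag within-trial switching.

Each dual trial gets a smooth mixing curve alpha(t): the moment-to-moment
weight on the A-alone rate.  Posterior-predictive alpha curves are reduced
to a maximum swing and a time average, whose odds against fixed thresholds
give the Wavy/Flat, Central/Extreme and Skewed/Symmetric tags.

Within-trial switching is only identifiable when bins carry enough spikes,
so this demo uses a vigorously driven neuron.  Takes ~10 s.
"""

from spikemux import DAPPConfig, GeneratorConfig, analyze_dapp, make_triplet

triplet, _ = make_triplet(GeneratorConfig(
    rate_a=240.0, rate_b=60.0, regime="square_wave",
    period_ms=300.0, levels=(0.15, 0.85), n_ab=25, seed=26,
))
config = DAPPConfig(n_iter=1500, burn_in=500, thin=2, seed=3, n_pred_draws=600)
posterior, draws, indices, tags = analyze_dapp(triplet, config)

print(f"converged: {posterior.converged} (split-chain R-hat "
      f"{max(posterior.rhat.values()):.3f})")
print(f"mean predictive swing {draws.swings.mean():.2f}, "
      f"mean time-average alpha {draws.means.mean():.2f}")
print(f"r_w={indices.r_w:.2f}  r_c={indices.r_c:.2f}  r_s={indices.r_s:.2f}")
print(f"tags: {tags.waviness}-{tags.extremeness}-{tags.symmetry}")
# A square-wave admixture alternating between mostly-A and mostly-B within
# each trial is tagged Wavy (big swings) and Central (time average near 0.5).
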