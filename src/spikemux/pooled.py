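"""Time-and-trial pooled comparison of dual responses to sum and average.

The dual-sound mean count is expressed as a Z-score relative to two
predictions built from the single-sound responses:

    PredictedSum = mean(Resp_A) + mean(Resp_B) - mean(Base_{A,B})
    PredictedAvg = (mean(Resp_A) + mean(Resp_B)) / 2
    Zsum = (mean(Resp_AB) - PredictedSum) / mean(std(Resp_A), std(Resp_B))
    ZAvg = (mean(Resp_AB) - PredictedAvg) / mean(std(Resp_A), std(Resp_B))

The baseline pool Base_{A,B} concatenates the pre-onset counts of the A and
B single-sound trials; subtracting it keeps the predicted sum from counting
spontaneous activity twice.  |Z| <= 1.96 marks a dual response within the
95% band of the corresponding prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trials import Triplet, count_spikes

Z_BAND = 1.96


@dataclass
class PooledSummary:
    mean_resp_a: float
    mean_resp_b: float
    mean_resp_ab: float
    mean_base: float
    std_resp_a: float
    std_resp_b: float
    predicted_sum: float
    predicted_avg: float
    z_sum: float
    z_avg: float
    closer_to: str  # "sum" | "avg" | "tie"
    within_band_sum: bool
    within_band_avg: bool
    degenerate: bool  # both single-sound SDs were zero


def summation_vs_averaging(
    triplet: Triplet,
    resp_window: tuple[float, float] = (0.0, 600.0),
    base_window: tuple[float, float] = (-600.0, 0.0),
) -> PooledSummary:
    """Pooled summary of one triplet; see the module docstring for formulas."""
    resp_a = triplet.counts("A", resp_window).astype(float)
    resp_b = triplet.counts("B", resp_window).astype(float)
    resp_ab = triplet.counts("AB", resp_window).astype(float)
    base = np.concatenate([
        [count_spikes(t, base_window) for t in triplet.trials_a],
        [count_spikes(t, base_window) for t in triplet.trials_b],
    ]).astype(float)

    mean_a, mean_b, mean_ab = resp_a.mean(), resp_b.mean(), resp_ab.mean()
    mean_base = base.mean()
    std_a = resp_a.std(ddof=1)
    std_b = resp_b.std(ddof=1)
    predicted_sum = mean_a + mean_b - mean_base
    predicted_avg = (mean_a + mean_b) / 2.0

    denom = (std_a + std_b) / 2.0
    degenerate = denom == 0.0
    if degenerate:
        z_sum = z_avg = float("nan")
        closer = "tie"
        within_sum = within_avg = False
    else:
        z_sum = (mean_ab - predicted_sum) / denom
        z_avg = (mean_ab - predicted_avg) / denom
        if abs(z_avg) < abs(z_sum):
            closer = "avg"
        elif abs(z_sum) < abs(z_avg):
            closer = "sum"
        else:
            closer = "tie"
        within_sum = abs(z_sum) <= Z_BAND
        within_avg = abs(z_avg) <= Z_BAND

    return PooledSummary(
        mean_resp_a=float(mean_a),
        mean_resp_b=float(mean_b),
        mean_resp_ab=float(mean_ab),
        mean_base=float(mean_base),
        std_resp_a=float(std_a),
        std_resp_b=float(std_b),
        predicted_sum=float(predicted_sum),
        predicted_avg=float(predicted_avg),
        z_sum=float(z_sum),
        z_avg=float(z_avg),
        closer_to=closer,
        within_band_sum=within_sum,
        within_band_avg=within_avg,
        degenerate=degenerate,
    )
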