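"""A-vs-B assignment scores and the downstream population analyses.

The assignment score of a dual-stimulus spike count is the posterior
probability (equal 50/50 priors) that the count was drawn from the A-alone
rather than the B-alone Poisson distribution.  Scores are computed at the
whole-trial scale or independently within 50 ms bins; bin-scale scores are
Z-normalized across trials within each bin so that shared slow drifts do not
masquerade as coordination.  Three analyses build on the scores:

* pair correlations — per-trial Pearson correlation of the two neurons'
  Z-scored bin sequences, testing whether simultaneously recorded neurons
  switch together;
* LFP state comparison — dual trials grouped A-like/B-like by whole-trial
  score; mean LFP voltage compared between groups in the 600 ms windows
  before and after stimulus onset;
* behavior linkage — whole-trial (and per-bin) scores compared between
  trials whose first saccade went to A vs to B.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trials import Triplet, bin_spikes

RATE_FLOOR_COUNTS = 0.05  # floor on per-bin expected counts in score likelihoods
LFP_AMPLITUDE_LIMIT = 500.0  # mV; trials exceeding this at any sample are dropped


@dataclass
class AssignmentScores:
    triplet_id: str
    scale: str                      # "whole_trial" | "bin"
    scores: np.ndarray              # (n_trials,) or (n_trials, C) P(A)
    z_scores: np.ndarray | None = None  # bin scale only
    w: float | None = None
    degenerate_bins: np.ndarray | None = None  # bins with zero score SD


@dataclass
class PairCorrelation:
    per_trial_r: np.ndarray
    mean_r: float
    n_skipped: int


@dataclass
class PairPopulationTest:
    condition_means: np.ndarray
    mean_of_means: float
    t_stat: float
    p_value: float


@dataclass
class LFPComparison:
    labels: np.ndarray              # bool, True = A-like
    mean_trace_a: np.ndarray
    mean_trace_b: np.ndarray
    se_trace_a: np.ndarray
    se_trace_b: np.ndarray
    pre_means: np.ndarray           # per-trial mean voltage, pre window
    post_means: np.ndarray
    p_pre: float
    p_post: float
    n_excluded_amplitude: int


@dataclass
class BehaviorLink:
    mean_score_a_first: float
    mean_score_b_first: float
    se_a_first: float
    se_b_first: float
    p_value: float
    n_a_first: int
    n_b_first: int
    stereotyped: bool = False
    bin_p_values: np.ndarray | None = None
    bin_signs: np.ndarray | None = None


def assignment_score(count: int, mu_a: float, mu_b: float) -> float:
    """P(count came from Poi(mu_a)) vs Poi(mu_b), equal prior odds.

    Computed in log space; never NaN even when both likelihoods underflow.
    """
    if mu_a <= 0 or mu_b <= 0:
        raise ValueError("expected counts must be positive (floor upstream)")
    log_a = count * math.log(mu_a) - mu_a
    log_b = count * math.log(mu_b) - mu_b
    m = max(log_a, log_b)
    ea, eb = math.exp(log_a - m), math.exp(log_b - m)
    return ea / (ea + eb)


def _score_matrix(counts: np.ndarray, mu_a: np.ndarray, mu_b: np.ndarray) -> np.ndarray:
    log_a = counts * np.log(mu_a) - mu_a
    log_b = counts * np.log(mu_b) - mu_b
    m = np.maximum(log_a, log_b)
    ea, eb = np.exp(log_a - m), np.exp(log_b - m)
    return ea / (ea + eb)


def whole_trial_scores(triplet: Triplet, triplet_id: str = "") -> AssignmentScores:
    """Whole-trial P(A) score per dual trial from total window counts."""
    mu_a = max(float(triplet.counts("A").mean()), RATE_FLOOR_COUNTS)
    mu_b = max(float(triplet.counts("B").mean()), RATE_FLOOR_COUNTS)
    counts = triplet.counts("AB").astype(float)
    scores = _score_matrix(counts, np.array(mu_a), np.array(mu_b))
    return AssignmentScores(triplet_id=triplet_id, scale="whole_trial", scores=scores)


def binwise_scores(
    triplet: Triplet, w: float = 50.0, triplet_id: str = ""
) -> AssignmentScores:
    """Per-bin P(A) scores and their across-trial Z-normalized form.

    Single-stimulus per-bin expected counts are the unsmoothed bin means of
    the A and B trials, floored at 0.05 counts.  Z-normalization subtracts
    the mean score and divides by the SD of scores within each bin across
    dual trials; a bin with zero SD gets Z = 0 and is flagged.
    """
    binned_a = bin_spikes(triplet.trials_a, w, triplet.t_end)
    binned_b = bin_spikes(triplet.trials_b, w, triplet.t_end)
    binned_ab = bin_spikes(triplet.trials_ab, w, triplet.t_end)
    mu_a = np.maximum(binned_a.counts.mean(axis=0), RATE_FLOOR_COUNTS)
    mu_b = np.maximum(binned_b.counts.mean(axis=0), RATE_FLOOR_COUNTS)
    scores = _score_matrix(binned_ab.counts.astype(float), mu_a[None, :], mu_b[None, :])
    sd = scores.std(axis=0, ddof=0)
    mean = scores.mean(axis=0)
    degenerate = sd == 0.0
    z = np.zeros_like(scores)
    ok = ~degenerate
    z[:, ok] = (scores[:, ok] - mean[ok]) / sd[ok]
    return AssignmentScores(
        triplet_id=triplet_id, scale="bin", scores=scores, z_scores=z, w=w,
        degenerate_bins=degenerate,
    )


# ---------------------------------------------------------------------------
# Pairs

def pair_condition_filter(neuron1: Triplet, neuron2: Triplet, min_trials: int = 5) -> bool:
    """Include a simultaneously recorded pair only if each neuron's A and B
    responses differ (two-sample t, p < 0.05) and all trial types have at
    least ``min_trials`` correct trials for both neurons."""
    for trip in (neuron1, neuron2):
        if min(trip.n_a, trip.n_b, trip.n_ab) < min_trials:
            return False
        res = stats.ttest_ind(trip.counts("A"), trip.counts("B"))
        if not np.isfinite(res.pvalue) or res.pvalue >= 0.05:
            return False
    return True


def pair_trial_correlations(
    scores1: AssignmentScores, scores2: AssignmentScores, min_bins: int = 3
) -> PairCorrelation:
    """Per-trial Pearson correlation between two neurons' Z-scored bins."""
    if scores1.scale != "bin" or scores2.scale != "bin":
        raise ValueError("pair correlations need bin-scale scores")
    z1, z2 = scores1.z_scores, scores2.z_scores
    if z1.shape != z2.shape:
        raise ValueError("pair members must share trials and bin grid")
    ok_bins = ~(scores1.degenerate_bins | scores2.degenerate_bins)
    rs, skipped = [], 0
    for j in range(z1.shape[0]):
        a, b = z1[j, ok_bins], z2[j, ok_bins]
        if a.size < min_bins or a.std() == 0.0 or b.std() == 0.0:
            skipped += 1
            continue
        rs.append(float(np.corrcoef(a, b)[0, 1]))
    rs = np.asarray(rs)
    return PairCorrelation(
        per_trial_r=rs,
        mean_r=float(rs.mean()) if rs.size else float("nan"),
        n_skipped=skipped,
    )


def pair_population_test(condition_means: np.ndarray) -> PairPopulationTest:
    """One-sample two-tailed t-test of per-condition mean correlations vs 0."""
    condition_means = np.asarray(condition_means, dtype=float)
    res = stats.ttest_1samp(condition_means, 0.0)
    return PairPopulationTest(
        condition_means=condition_means,
        mean_of_means=float(condition_means.mean()),
        t_stat=float(res.statistic),
        p_value=float(res.pvalue),
    )


# ---------------------------------------------------------------------------
# LFP

def classify_trials_AB(scores: AssignmentScores) -> tuple[np.ndarray, np.ndarray]:
    """A-like / B-like labels from whole-trial scores.

    Returns ``(labels, usable)``: a trial is A-like iff its score > 0.5;
    exact-0.5 ties carry no information and are excluded via ``usable``.
    """
    if scores.scale != "whole_trial":
        raise ValueError("trial classification needs whole-trial scores")
    s = scores.scores
    usable = s != 0.5
    return s > 0.5, usable


def lfp_compare(
    lfp_traces: np.ndarray,
    labels: np.ndarray,
    onset_index: int = 600,
    window_ms: int = 600,
    session_mean: float | None = None,
    amplitude_limit: float = LFP_AMPLITUDE_LIMIT,
) -> LFPComparison:
    """Compare mean LFP between A-like and B-like dual trials.

    ``lfp_traces`` is (n_trials, n_samples) at 1 kHz with stimulus onset at
    ``onset_index``.  The session mean is subtracted (DC removal), trials
    whose absolute voltage exceeds ``amplitude_limit`` at any sample are
    excluded, and each remaining trial contributes one mean voltage in the
    pre-onset and post-onset windows to two-tailed t-tests.
    """
    traces = np.asarray(lfp_traces, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if traces.shape[0] != labels.size:
        raise ValueError("one label per LFP trial required")
    if session_mean is None:
        session_mean = float(traces.mean())
    traces = traces - session_mean
    keep = np.abs(traces).max(axis=1) <= amplitude_limit
    n_excluded = int((~keep).sum())
    traces, labels = traces[keep], labels[keep]
    if labels.all() or (~labels).all():
        raise ValueError("both A-like and B-like groups must be nonempty")

    pre = traces[:, onset_index - window_ms : onset_index].mean(axis=1)
    post = traces[:, onset_index : onset_index + window_ms].mean(axis=1)
    group_a, group_b = traces[labels], traces[~labels]
    p_pre = float(stats.ttest_ind(pre[labels], pre[~labels]).pvalue)
    p_post = float(stats.ttest_ind(post[labels], post[~labels]).pvalue)
    return LFPComparison(
        labels=labels,
        mean_trace_a=group_a.mean(axis=0),
        mean_trace_b=group_b.mean(axis=0),
        se_trace_a=group_a.std(axis=0, ddof=1) / math.sqrt(group_a.shape[0]),
        se_trace_b=group_b.std(axis=0, ddof=1) / math.sqrt(group_b.shape[0]),
        pre_means=pre,
        post_means=post,
        p_pre=p_pre,
        p_post=p_post,
        n_excluded_amplitude=n_excluded,
    )


# ---------------------------------------------------------------------------
# Behavior

def behavior_link(
    scores: AssignmentScores,
    first_saccade: np.ndarray,
    bin_scores: AssignmentScores | None = None,
) -> BehaviorLink:
    """Relate assignment scores to the first-saccade target.

    Trials with unknown saccade targets are dropped.  If every remaining
    trial went the same way the behavior is stereotyped and no test is run.
    Optionally repeats the comparison per 50 ms bin on bin-scale scores.
    """
    labels = np.asarray(first_saccade)
    known = (labels == "A") | (labels == "B")
    s = np.asarray(scores.scores, dtype=float)[known]
    labels = labels[known]
    to_a = labels == "A"
    n_a, n_b = int(to_a.sum()), int((~to_a).sum())
    if n_a == 0 or n_b == 0:
        return BehaviorLink(
            mean_score_a_first=float(s[to_a].mean()) if n_a else float("nan"),
            mean_score_b_first=float(s[~to_a].mean()) if n_b else float("nan"),
            se_a_first=float("nan"), se_b_first=float("nan"),
            p_value=float("nan"), n_a_first=n_a, n_b_first=n_b, stereotyped=True,
        )
    res = stats.ttest_ind(s[to_a], s[~to_a])
    out = BehaviorLink(
        mean_score_a_first=float(s[to_a].mean()),
        mean_score_b_first=float(s[~to_a].mean()),
        se_a_first=float(s[to_a].std(ddof=1) / math.sqrt(n_a)) if n_a > 1 else float("nan"),
        se_b_first=float(s[~to_a].std(ddof=1) / math.sqrt(n_b)) if n_b > 1 else float("nan"),
        p_value=float(res.pvalue),
        n_a_first=n_a,
        n_b_first=n_b,
    )
    if bin_scores is not None:
        sb = np.asarray(bin_scores.scores, dtype=float)[known]
        n_bins = sb.shape[1]
        ps = np.empty(n_bins)
        signs = np.zeros(n_bins, dtype=int)
        for c in range(n_bins):
            r = stats.ttest_ind(sb[to_a, c], sb[~to_a, c])
            ps[c] = r.pvalue
            diff = sb[to_a, c].mean() - sb[~to_a, c].mean()
            signs[c] = 0 if diff == 0 else (1 if diff > 0 else -1)
        out.bin_p_values = ps
        out.bin_signs = signs
    return out
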