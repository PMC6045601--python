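"""Whole-trial Bayesian analysis of dual-stimulus spike counts.

For a triplet of matched conditions, the single-stimulus spike counts are
modeled as Poisson with rates ``lambda_A`` and ``lambda_B``.  Four competing
hypotheses describe the dual-stimulus counts:

* **Mixture** — each trial is drawn from ``alpha*Poi(lambda_A) +
  (1-alpha)*Poi(lambda_B)`` with unknown mixing weight ``alpha`` (across-trial
  switching between the two pure rates);
* **Intermediate** — a single Poisson rate strictly between the two;
* **Outside** — a single Poisson rate below both or above both;
* **Single** — a rate exactly equal to one of the two.

Rates carry Jeffreys priors (truncated and renormalized for Intermediate /
Outside), alpha a uniform prior, and the models equal 1/4 prior weights.
Screening uses a Monte-Carlo chi-square goodness-of-fit test of the Poisson
assumption on each single-stimulus count set, and an intrinsic Bayes factor
test of rate separation.

Implementation notes.  The single-stimulus data enter the dual-trial model
comparison through proper gamma priors on ``lambda_A`` and ``lambda_B`` equal
to their Jeffreys posteriors (shape ``sum(x)+1/2``, rate ``n``), so no
training-sample correction is needed there; the separation test, where both
priors are improper, uses the arithmetic intrinsic Bayes factor with minimal
training samples of one observation per condition.  The Mixture marginal
likelihood is computed exactly by aggregating trial-to-component assignments
through a (subset size, subset sum) dynamic program; Intermediate and Outside
use fixed-order Gauss-Legendre quadrature in gamma-quantile space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

MODELS = ("mixture", "intermediate", "outside", "single")

#: log intrinsic Bayes factor at or above which single-stimulus rates count
#: as well separated (posterior P(rates differ) > 95% at even prior odds).
SEPARATION_LOG_IBF = 3.0

GOF_ALPHA = 0.1
TIER_CUTS = (0.95, 0.50)


# ---------------------------------------------------------------------------
# Goodness of fit screening

def _gof_statistics(samples: np.ndarray) -> np.ndarray:
    """Chi-square lack-of-fit statistic per row of Poisson count samples.

    Rate is estimated by the row mean; equal-probability bins come from the
    quantiles of that Poisson, with ``max(3, n // 5)`` bins.  Duplicate
    quantile edges produce empty (zero-probability) bins that contribute 0.
    """
    samples = np.atleast_2d(samples)
    n = samples.shape[1]
    n_bins = max(3, n // 5)
    lam = samples.mean(axis=1)
    qs = np.arange(1, n_bins) / n_bins
    edges = stats.poisson.ppf(qs[None, :], lam[:, None])  # (R, n_bins-1)
    # bin index of each count: number of edges strictly below it
    idx = (samples[:, :, None] > edges[:, None, :]).sum(axis=2)
    observed = np.zeros((samples.shape[0], n_bins))
    for k in range(n_bins):
        observed[:, k] = (idx == k).sum(axis=1)
    cdf = stats.poisson.cdf(edges, lam[:, None])
    probs = np.diff(np.concatenate(
        [np.zeros((samples.shape[0], 1)), cdf, np.ones((samples.shape[0], 1))], axis=1
    ), axis=1)
    expected = n * probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (observed - expected) ** 2 / expected
    terms[probs <= 1e-12] = 0.0
    return terms.sum(axis=1)


def poisson_gof_mc(
    counts: np.ndarray,
    n_mc: int = 10_000,
    alpha: float = GOF_ALPHA,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, bool]:
    """Monte-Carlo chi-square test of the Poisson assumption on spike counts.

    Returns ``(p, passed)`` where ``p`` is the fraction of ``n_mc`` simulated
    Poisson samples (drawn at the estimated rate, with the rate re-estimated
    and bins rebuilt per sample) whose lack-of-fit statistic is at least the
    observed one; ``passed = (p >= alpha)``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 5:
        raise ValueError("goodness-of-fit screen needs at least 5 trials")
    if counts.sum() == 0:
        return 0.0, False
    rng = np.random.default_rng(seed)
    observed_stat = float(_gof_statistics(counts[None, :])[0])
    sims = rng.poisson(counts.mean(), size=(n_mc, counts.size)).astype(float)
    sim_stats = _gof_statistics(sims)
    p = float(np.mean(sim_stats >= observed_stat - 1e-12))
    return p, p >= alpha


# ---------------------------------------------------------------------------
# Jeffreys-prior Poisson marginals

def _log_marginal_jeffreys(counts: np.ndarray) -> float:
    """log m(x) under the improper Jeffreys prior lambda^(-1/2)."""
    counts = np.asarray(counts, dtype=float)
    s, n = counts.sum(), counts.size
    return float(
        special.gammaln(s + 0.5) - (s + 0.5) * np.log(n)
        - special.gammaln(counts + 1).sum()
    )


def separation_logIBF(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    max_training_pairs: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, bool]:
    """Arithmetic intrinsic Bayes factor for unequal vs equal Poisson rates.

    The improper-prior Bayes factor of the two-rate model against the
    common-rate model is corrected by averaging the inverse Bayes factor over
    minimal training samples of one observation from each condition (all
    pairs, or a seeded subsample of at most ``max_training_pairs``).
    Returns ``(log_ibf, separated)`` with ``separated = log_ibf >=`` 3.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both count vectors must be nonempty")
    log_bf_full = (
        _log_marginal_jeffreys(a)
        + _log_marginal_jeffreys(b)
        - _log_marginal_jeffreys(np.concatenate([a, b]))
    )
    ai = np.repeat(a, b.size)
    bj = np.tile(b, a.size)
    if ai.size > max_training_pairs:
        rng = np.random.default_rng(seed)
        pick = rng.choice(ai.size, size=max_training_pairs, replace=False)
        ai, bj = ai[pick], bj[pick]
    # log BF_{equal vs unequal} on each minimal training pair
    log_m0 = (
        special.gammaln(ai + bj + 0.5) - (ai + bj + 0.5) * np.log(2.0)
        - special.gammaln(ai + 1) - special.gammaln(bj + 1)
    )
    log_m1 = (
        special.gammaln(ai + 0.5) + special.gammaln(bj + 0.5)
        - special.gammaln(ai + 1) - special.gammaln(bj + 1)
    )
    correction = special.logsumexp(log_m0 - log_m1) - np.log(ai.size)
    log_ibf = float(log_bf_full + correction)
    return log_ibf, log_ibf >= SEPARATION_LOG_IBF


# ---------------------------------------------------------------------------
# Four-model posterior

@dataclass
class WholeTrialInput:
    counts_a: np.ndarray
    counts_b: np.ndarray
    counts_ab: np.ndarray
    t_end: int = 600

    def __post_init__(self) -> None:
        for name in ("counts_a", "counts_b", "counts_ab"):
            arr = np.asarray(getattr(self, name))
            if arr.size == 0 or np.any(arr < 0):
                raise ValueError(f"{name} must be nonempty and nonnegative")
            setattr(self, name, arr.astype(int))


@dataclass
class ModelPosterior:
    p_mixture: float
    p_intermediate: float
    p_outside: float
    p_single: float
    winner: str
    tier: str
    tied: bool = False
    log_marginals: dict = field(default_factory=dict)
    screen: dict = field(default_factory=dict)

    @property
    def probs(self) -> np.ndarray:
        return np.array(
            [self.p_mixture, self.p_intermediate, self.p_outside, self.p_single]
        )


def _log_gamma_poisson(shape: float, rate: float, k: int, s: float) -> float:
    """log integral of prod_{j in S} lambda^{x_j} e^{-lambda} over a gamma law.

    ``k`` is the subset size, ``s`` its count sum; the 1/x! factors are
    excluded (they are a dataset constant).
    """
    return (
        shape * np.log(rate) - special.gammaln(shape)
        + special.gammaln(shape + s) - (shape + s) * np.log(rate + k)
    )


def _log_mixture_marginal(
    counts_ab: np.ndarray, shape_a: float, rate_a: float,
    shape_b: float, rate_b: float,
) -> float:
    """Exact mixture marginal via a (subset size, subset sum) DP.

    Summing over all 2^m assignments of trials to the A or B component, the
    contribution of a subset depends only on its size and count sum, so the
    sum collapses to a polynomial-size table; the uniform prior on alpha
    integrates to a Beta function per subset size.
    """
    x = np.asarray(counts_ab, dtype=int)
    m, total = x.size, int(x.sum())
    # dp[k, s] = number of subsets of size k with sum s
    dp = np.zeros((m + 1, total + 1))
    dp[0, 0] = 1.0
    for xj in x:
        dp[1:, xj:] += dp[:-1, : total + 1 - xj]
    ks = np.arange(m + 1)
    ss = np.arange(total + 1)
    log_a = _log_gamma_poisson(shape_a, rate_a, ks[:, None], ss[None, :])
    log_b = _log_gamma_poisson(
        shape_b, rate_b, (m - ks)[:, None], (total - ss)[None, :]
    )
    log_beta = special.betaln(ks + 1, m - ks + 1)[:, None]
    with np.errstate(divide="ignore"):
        log_dp = np.where(dp > 0, np.log(np.maximum(dp, 1e-300)), -np.inf)
    return float(special.logsumexp(log_dp + log_beta + log_a + log_b))


def _gauss_legendre_01(n: int) -> tuple[np.ndarray, np.ndarray]:
    nodes, weights = np.polynomial.legendre.leggauss(n)
    return 0.5 * (nodes + 1.0), 0.5 * weights


def _log_truncated_marginal(
    counts_ab: np.ndarray,
    shape_a: float, rate_a: float, shape_b: float, rate_b: float,
    model: str, lam_max: float, n_nodes: int = 80,
) -> float:
    """Marginal for Intermediate or Outside by quadrature over (lamA, lamB).

    For each realized (lamA, lamB) pair the dual rate carries a Jeffreys
    prior truncated to the open interval between them (Intermediate) or its
    complement bounded above at ``lam_max`` (Outside), renormalized; the
    inner rate integral has a closed incomplete-gamma form.
    """
    x = np.asarray(counts_ab, dtype=float)
    m, s = x.size, x.sum()
    u01, w01 = _gauss_legendre_01(n_nodes)
    a_in = s + 0.5
    log_kernel = special.gammaln(a_in) - a_in * np.log(m)

    def _log_piece(lo: np.ndarray, hi: np.ndarray, log_w2d: np.ndarray) -> float:
        # regularized lower incomplete gamma of the count-sum posterior kernel
        p_lo = special.gammainc(a_in, m * lo)
        p_hi = special.gammainc(a_in, m * hi)
        if model == "intermediate":
            mass = np.maximum(p_hi - p_lo, 0.0)
            z = 2.0 * (np.sqrt(hi) - np.sqrt(lo))
        elif model == "outside":
            p_max = special.gammainc(a_in, m * lam_max)
            upper = np.maximum(p_max - p_hi, 0.0)
            mass = p_lo + np.where(hi < lam_max, upper, 0.0)
            z = 2.0 * np.sqrt(lo) + 2.0 * np.maximum(
                np.sqrt(lam_max) - np.sqrt(hi), 0.0
            )
        else:  # pragma: no cover
            raise ValueError(model)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_inner = log_kernel + np.log(np.maximum(mass, 1e-300)) - np.log(
                np.maximum(z, 1e-300)
            )
        return float(special.logsumexp(log_inner + log_w2d))

    # The integrand has a kink along lam_a = lam_b, so the two orderings are
    # integrated separately, each smooth.  Nodes live directly on the rate
    # axis (Gauss-Legendre against the gamma density over its 1e-12..1-1e-12
    # quantile range), where the integrand is analytic, rather than in
    # quantile space, where the endpoint map degrades convergence.
    log_w = np.log(w01)
    pieces = []
    for sh_out, rt_out, sh_in, rt_in in (
        (shape_a, rate_a, shape_b, rate_b),  # lam_a < lam_b
        (shape_b, rate_b, shape_a, rate_a),  # lam_b < lam_a
    ):
        out_lo = stats.gamma.ppf(1e-12, sh_out, scale=1.0 / rt_out)
        out_hi = stats.gamma.ppf(1.0 - 1e-12, sh_out, scale=1.0 / rt_out)
        in_hi = stats.gamma.ppf(1.0 - 1e-12, sh_in, scale=1.0 / rt_in)
        lam_out = out_lo + (out_hi - out_lo) * u01
        width_in = np.maximum(in_hi - lam_out, 0.0)
        lam_in = lam_out[:, None] + width_in[:, None] * u01[None, :]
        log_w2d = (
            log_w[:, None] + log_w[None, :]
            + stats.gamma.logpdf(lam_out, sh_out, scale=1.0 / rt_out)[:, None]
            + stats.gamma.logpdf(lam_in, sh_in, scale=1.0 / rt_in)
            + np.log(out_hi - out_lo)
            + np.log(np.maximum(width_in, 1e-300))[:, None]
        )
        lo = np.broadcast_to(lam_out[:, None], lam_in.shape)
        pieces.append(_log_piece(lo, np.maximum(lam_in, lo), log_w2d))
    return float(special.logsumexp(pieces))


def model_posteriors(
    data: WholeTrialInput,
    prior_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    n_nodes: int = 80,
) -> ModelPosterior:
    """Posterior probabilities of the four dual-count hypotheses.

    ``lambda_A`` and ``lambda_B`` are integrated against their Jeffreys
    posteriors from the single-stimulus counts; the Single model splits its
    mass 50/50 between the two rates.  Marginal likelihoods are computed in
    log space and include the shared ``prod 1/x_j!`` constant so that they
    are directly comparable to brute-force integration.
    """
    a = np.asarray(data.counts_a, dtype=float)
    b = np.asarray(data.counts_b, dtype=float)
    x = np.asarray(data.counts_ab, dtype=float)
    shape_a, rate_a = a.sum() + 0.5, float(a.size)
    shape_b, rate_b = b.sum() + 0.5, float(b.size)
    m, s = x.size, x.sum()
    lam_max = 3.0 * (a.mean() + b.mean()) + 10.0
    log_const = -special.gammaln(x + 1).sum()

    log_single = special.logsumexp([
        _log_gamma_poisson(shape_a, rate_a, m, s),
        _log_gamma_poisson(shape_b, rate_b, m, s),
    ]) + np.log(0.5) + log_const
    log_mix = _log_mixture_marginal(x, shape_a, rate_a, shape_b, rate_b) + log_const
    log_int = _log_truncated_marginal(
        x, shape_a, rate_a, shape_b, rate_b, "intermediate", lam_max, n_nodes
    ) + log_const
    log_out = _log_truncated_marginal(
        x, shape_a, rate_a, shape_b, rate_b, "outside", lam_max, n_nodes
    ) + log_const

    log_marg = np.array([log_mix, log_int, log_out, log_single])
    log_post = np.log(np.asarray(prior_weights, dtype=float)) + log_marg
    probs = np.exp(log_post - special.logsumexp(log_post))
    probs /= probs.sum()

    winner, tier, tied = classify_probs(probs)
    return ModelPosterior(
        p_mixture=float(probs[0]),
        p_intermediate=float(probs[1]),
        p_outside=float(probs[2]),
        p_single=float(probs[3]),
        winner=winner,
        tier=tier,
        tied=tied,
        log_marginals=dict(zip(MODELS, log_marg.tolist())),
    )


def classify_probs(probs: np.ndarray) -> tuple[str, str, bool]:
    """Winner and confidence tier from four model probabilities.

    Ties break deterministically in the order mixture, intermediate,
    outside, single.  Tiers: winning probability > 0.95, > 0.50, or the
    no-threshold tier (any argmax, probability above the 0.33 minimum).
    """
    probs = np.asarray(probs, dtype=float)
    best = int(np.argmax(probs))
    tied = bool(np.count_nonzero(probs == probs[best]) > 1)
    p = probs[best]
    if p > TIER_CUTS[0]:
        tier = "p>0.95"
    elif p > TIER_CUTS[1]:
        tier = "p>0.50"
    else:
        tier = "p>0.33_winner"
    return MODELS[best], tier, tied


def classify_whole_trial(posterior: ModelPosterior) -> tuple[str, str]:
    """Winner label and confidence tier of a computed posterior."""
    winner, tier, _ = classify_probs(posterior.probs)
    return winner, tier


# ---------------------------------------------------------------------------
# Triplet-level screening + analysis

@dataclass
class ScreenResult:
    gof_p_a: float
    gof_p_b: float
    separation_log_ibf: float
    included: bool


def screen_counts(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    n_mc: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> ScreenResult:
    """Poisson goodness-of-fit on both single-stimulus count sets plus the
    rate-separation test; a triplet is included only if all three pass."""
    rng = np.random.default_rng(seed)
    p_a, ok_a = poisson_gof_mc(counts_a, n_mc=n_mc, seed=rng)
    p_b, ok_b = poisson_gof_mc(counts_b, n_mc=n_mc, seed=rng)
    log_ibf, separated = separation_logIBF(counts_a, counts_b, seed=rng)
    return ScreenResult(
        gof_p_a=p_a,
        gof_p_b=p_b,
        separation_log_ibf=log_ibf,
        included=bool(ok_a and ok_b and separated),
    )


def analyze_whole_trial(
    data: WholeTrialInput,
    n_mc: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> ModelPosterior:
    """Screen a triplet's counts and, regardless of the outcome, compute the
    four-model posterior; the screen result is attached for the caller."""
    screen = screen_counts(data.counts_a, data.counts_b, n_mc=n_mc, seed=seed)
    posterior = model_posteriors(data)
    posterior.screen = {
        "gof_p_a": screen.gof_p_a,
        "gof_p_b": screen.gof_p_b,
        "separation_log_ibf": screen.separation_log_ibf,
        "included": screen.included,
    }
    return posterior
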