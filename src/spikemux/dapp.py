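"""Dynamic Admixture Point Process (DAPP) model of within-trial switching.

Dual-stimulus bin counts are modeled as ``X_jc ~ Poi(w * lambda_j(t_c) /
1000)`` with ``lambda_j(t) = alpha_j(t) * lambda_A(t) + (1 - alpha_j(t)) *
lambda_B(t)``: each dual trial carries its own smooth mixing curve
``alpha_j(t) = S(eta_j(t))`` where ``S`` is the logistic function and
``eta_j`` is a Gaussian process with trial-specific mean ``phi_j``, variance
``psi_j`` and squared-exponential correlation with length scale ``ell_j``
restricted to a small grid.  The trial-level parameter triples are tied
together by a dynamic pattern generator ``P = P_phipsi x P_ell`` carrying a
Dirichlet-process prior (truncated stick-breaking) on ``P_phipsi`` and an
ordinary Dirichlet prior on ``P_ell``.

The single-stimulus rate curves enter only through independent per-bin gamma
priors whose mean and standard deviation match a kernel-smoothed PSTH
estimate and its across-trial standard error.

Posterior computation is Metropolis-within-Gibbs: elliptical slice sampling
for the latent curves, per-bin random-walk Metropolis on the log rates,
conjugate updates for the mixture atoms, stick weights and ``P_ell``.  The
fitted generator is then used to simulate alpha curves for hypothetical new
trials; their maximum swing ``|alpha| = max - min`` and time average
``alpha_bar`` feed three odds indices

    r_w = P(|alpha| > 0.5) / P(|alpha| < 0.5)           (waviness)
    r_c = P(alpha_bar in (0.25, 0.75)) / P(outside)     (extremeness)
    r_s = max{P(alpha_bar < .5)/P(alpha_bar > .5), reciprocal}   (skew)

which are thresholded into the Wavy/Flat, Central/Extreme and
Skewed/Symmetric tags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .trials import BinnedCounts, Triplet, bin_spikes

RATE_FLOOR = 0.5   # sp/s floor on smoothed single-stimulus rate estimates
SE_FLOOR = 0.25    # sp/s floor on their standard errors

WAVINESS_THRESHOLDS = (1.3, 0.77)   # Wavy if r_w > 1.3, Flat if r_w < 0.77
EXTREMENESS_THRESHOLDS = (3.24, 1.68)  # Central if r_c > 3.24, Extreme if < 1.68
SKEW_THRESHOLDS = (4.0, 2.0)        # Skewed if r_s > 4, Symmetric if r_s < 2


# ---------------------------------------------------------------------------
# Rate priors from single-stimulus trials

@dataclass
class GammaCurve:
    """Independent per-bin gamma laws for one stimulus's rate curve (sp/s)."""

    shape: np.ndarray
    rate: np.ndarray  # gamma rate parameter (1 / scale)

    @property
    def mean(self) -> np.ndarray:
        return self.shape / self.rate

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(self.shape) / self.rate


@dataclass
class RatePrior:
    """Conditional gamma priors for both single-stimulus rate curves."""

    a: GammaCurve
    b: GammaCurve
    w: float


def smooth_to_gamma_priors(binned: BinnedCounts) -> GammaCurve:
    """Gamma prior parameters per bin from kernel-smoothed single-sound data.

    Each trial's binned rate curve (sp/s) is smoothed with a Gaussian kernel
    of bandwidth one bin width; the per-bin estimate is the across-trial mean
    and its uncertainty the across-trial standard error.  The gamma law in
    each bin matches that mean and SD exactly (floors keep both positive).
    """
    if binned.n_trials < 5:
        raise ValueError("rate smoothing needs at least 5 trials")
    rates = binned.counts / (binned.w / 1000.0)  # (n, C) sp/s
    smoothed = gaussian_filter1d(rates.astype(float), sigma=1.0, axis=1, mode="nearest")
    est = np.maximum(smoothed.mean(axis=0), RATE_FLOOR)
    se = np.maximum(
        smoothed.std(axis=0, ddof=1) / math.sqrt(binned.n_trials), SE_FLOOR
    )
    shape = (est / se) ** 2
    rate = est / se**2
    return GammaCurve(shape=shape, rate=rate)


def rate_priors_from_triplet(triplet: Triplet, w: float) -> RatePrior:
    binned_a = bin_spikes(triplet.trials_a, w, triplet.t_end)
    binned_b = bin_spikes(triplet.trials_b, w, triplet.t_end)
    return RatePrior(
        a=smooth_to_gamma_priors(binned_a),
        b=smooth_to_gamma_priors(binned_b),
        w=float(w),
    )


# ---------------------------------------------------------------------------
# Configuration and posterior containers

@dataclass
class DAPPConfig:
    w: float = 50.0
    ell_grid: tuple[float, ...] = (75.0, 125.0, 200.0, 300.0, 500.0)
    n_iter: int = 4000
    burn_in: int = 2000
    thin: int = 2
    seed: int = 0
    dp_concentration: float = 1.0
    trunc: int = 20              # stick-breaking truncation level
    phi_prior_sd: float = 2.0    # base measure: phi ~ N(0, sd^2)
    psi_prior: tuple[float, float] = (2.0, 1.0)  # psi ~ InvGamma(a, b)
    n_pred_draws: int = 1000
    rw_scale: float = 0.25       # log-rate random-walk proposal SD

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if any(l <= 0 for l in self.ell_grid):
            raise ValueError("length-scale grid must be positive")


@dataclass
class DAPPPosterior:
    """Retained MCMC draws of the admixture model for one triplet."""

    lam_a: np.ndarray        # (n_draws, C) sp/s
    lam_b: np.ndarray        # (n_draws, C)
    alpha: np.ndarray        # (n_draws, n_trials, C)
    phi: np.ndarray          # (n_draws, n_trials)
    psi: np.ndarray          # (n_draws, n_trials)
    ell: np.ndarray          # (n_draws, n_trials) length scales in ms
    atom_phi: np.ndarray     # (n_draws, L)
    atom_psi: np.ndarray     # (n_draws, L)
    atom_weight: np.ndarray  # (n_draws, L), sums to 1
    p_ell: np.ndarray        # (n_draws, G)
    config: DAPPConfig
    rhat: dict = field(default_factory=dict)
    converged: bool = True

    @property
    def n_draws(self) -> int:
        return self.lam_a.shape[0]

    def alpha_trial_means(self) -> np.ndarray:
        """Posterior mean of the time-averaged alpha, per dual trial."""
        return self.alpha.mean(axis=(0, 2))


@dataclass
class AlphaDraws:
    """Posterior-predictive alpha curves with swing and mean summaries."""

    curves: np.ndarray   # (n_draws, C)
    swings: np.ndarray   # max - min per curve
    means: np.ndarray    # time average per curve (bin-grid Riemann mean)

    def __len__(self) -> int:
        return self.curves.shape[0]


@dataclass
class DAPPIndices:
    r_w: float
    r_c: float
    r_s: float


@dataclass
class DAPPTags:
    waviness: str     # Wavy | Flat | Ambiguous
    extremeness: str  # Central | Extreme | Ambiguous
    symmetry: str     # Skewed | Symmetric | Unlabeled


# ---------------------------------------------------------------------------
# MCMC

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _GPGrid:
    """Precomputed correlation matrices per length scale on the bin grid."""

    def __init__(self, midpoints: np.ndarray, ell_grid: tuple[float, ...]):
        d2 = (midpoints[:, None] - midpoints[None, :]) ** 2
        self.chol, self.inv, self.logdet = [], [], []
        for ell in ell_grid:
            r = np.exp(-0.5 * d2 / ell**2)
            r[np.diag_indices_from(r)] += 1e-8
            self.chol.append(np.linalg.cholesky(r))
            self.inv.append(np.linalg.inv(r))
            self.logdet.append(float(np.linalg.slogdet(r)[1]))
        self.one_q_one = np.array([q.sum() for q in self.inv])
        self.q_one = [q.sum(axis=1) for q in self.inv]


def _loglik_trial(x: np.ndarray, eta: np.ndarray, lam_a: np.ndarray,
                  lam_b: np.ndarray, scale: float) -> float:
    sig = _sigmoid(eta)
    mu = scale * (sig * lam_a + (1.0 - sig) * lam_b)
    mu = np.maximum(mu, 1e-12)
    return float(np.sum(x * np.log(mu) - mu))


def _loglik_batch(x: np.ndarray, etas: np.ndarray, lam_a: np.ndarray,
                  lam_b: np.ndarray, scale: float) -> np.ndarray:
    """Log likelihood of one trial's counts under K candidate curves (K, C)."""
    sig = _sigmoid(etas)
    mu = scale * (sig * lam_a[None, :] + (1.0 - sig) * lam_b[None, :])
    mu = np.maximum(mu, 1e-12)
    return (x[None, :] * np.log(mu) - mu).sum(axis=1)


def _elliptical_slice_whitened(
    x: np.ndarray, u: np.ndarray, phi: float, psi: float, chol: np.ndarray,
    lam_a: np.ndarray, lam_b: np.ndarray, scale: float, rng: np.random.Generator,
) -> np.ndarray:
    """One elliptical-slice update of a trial's whitened curve coefficients.

    The curve is parameterized non-centrally, ``eta = phi + sqrt(psi) * L u``
    with ``u ~ N(0, I)``, so amplitude (psi) and shape (u) mix independently.
    """
    sq = math.sqrt(psi)
    nu = rng.standard_normal(u.size)
    eta = phi + sq * (chol @ u)
    logy = _loglik_trial(x, eta, lam_a, lam_b, scale) + math.log(rng.uniform())
    theta = rng.uniform(0.0, 2.0 * math.pi)
    lo, hi = theta - 2.0 * math.pi, theta
    while True:
        prop = u * math.cos(theta) + nu * math.sin(theta)
        eta = phi + sq * (chol @ prop)
        if _loglik_trial(x, eta, lam_a, lam_b, scale) > logy:
            return prop
        if theta < 0:
            lo = theta
        else:
            hi = theta
        theta = rng.uniform(lo, hi)


def fit_dapp(
    triplet: Triplet,
    prior: RatePrior | None = None,
    config: DAPPConfig | None = None,
) -> DAPPPosterior:
    """Fit the admixture model to one triplet's dual trials by MCMC.

    The single-stimulus trials inform the fit only through the conditional
    gamma rate priors; everything else is estimated from the dual-trial bin
    counts.  Split-chain potential scale reduction factors on scalar
    summaries are reported; ``converged`` is False if any exceeds 1.1.
    """
    config = config or DAPPConfig()
    if prior is None:
        prior = rate_priors_from_triplet(triplet, config.w)
    binned = bin_spikes(triplet.trials_ab, config.w, triplet.t_end)
    x = binned.counts.astype(float)  # (n, C)
    n, c = x.shape
    scale = config.w / 1000.0
    mids = binned.bin_midpoints
    gp = _GPGrid(mids, config.ell_grid)
    g_count = len(config.ell_grid)
    ell_grid = np.asarray(config.ell_grid)
    rng = np.random.default_rng(config.seed)
    trunc = config.trunc
    a0, b0 = config.psi_prior
    sd0 = config.phi_prior_sd
    kappa = config.dp_concentration

    # --- initial state
    lam_a = prior.a.mean.copy()
    lam_b = prior.b.mean.copy()
    # per-bin crude alpha, lightly smoothed, seeds any within-trial structure
    alpha_bins = np.clip(
        (x / scale - lam_b[None, :]) / np.maximum(lam_a - lam_b, 1e-6)[None, :],
        0.05, 0.95,
    )
    eta_init = gaussian_filter1d(
        np.log(alpha_bins / (1.0 - alpha_bins)), sigma=1.0, axis=1, mode="nearest"
    )
    z = np.zeros(n, dtype=int)
    atom_phi = rng.normal(0.0, sd0, size=trunc)
    atom_psi = 1.0 / rng.gamma(a0, 1.0 / b0, size=trunc)
    atom_phi[0] = float(np.mean(eta_init))
    # start each trial at the length scale most compatible with its crude
    # curve, and the shared amplitude at the implied conjugate scale, so the
    # chain does not have to climb from psi ~ 1 against a flattened state
    ell_idx = np.zeros(n, dtype=int)
    quad0 = np.empty(n)
    for j in range(n):
        r = eta_init[j] - atom_phi[0]
        qs = np.array([float(r @ gp.inv[g] @ r) for g in range(g_count)])
        ell_idx[j] = int(np.argmin(qs))
        quad0[j] = qs[ell_idx[j]]
    atom_psi[0] = float(np.clip(np.median(quad0) / c, 0.5, 400.0))
    sticks = rng.beta(1.0, kappa, size=trunc)
    sticks[-1] = 1.0
    p_ell = np.full(g_count, 1.0 / g_count)
    # whitened curve coefficients: eta_j = phi + sqrt(psi) * L u_j
    u = np.zeros((n, c))
    for j in range(n):
        sol = np.linalg.solve(gp.chol[ell_idx[j]], eta_init[j] - atom_phi[0])
        u[j] = sol / math.sqrt(atom_psi[0])

    def eta_of(j: int, phi: float, psi: float, g: int) -> np.ndarray:
        return phi + math.sqrt(psi) * (gp.chol[g] @ u[j])

    n_keep = (config.n_iter - config.burn_in) // config.thin
    draws = {
        "lam_a": np.empty((n_keep, c)), "lam_b": np.empty((n_keep, c)),
        "alpha": np.empty((n_keep, n, c)),
        "phi": np.empty((n_keep, n)), "psi": np.empty((n_keep, n)),
        "ell": np.empty((n_keep, n)),
        "atom_phi": np.empty((n_keep, trunc)), "atom_psi": np.empty((n_keep, trunc)),
        "atom_weight": np.empty((n_keep, trunc)), "p_ell": np.empty((n_keep, g_count)),
    }
    kept = 0

    def stick_log_weights(v: np.ndarray) -> np.ndarray:
        logv = np.log(np.maximum(v, 1e-300))
        log1mv = np.log(np.maximum(1.0 - v, 1e-300))
        return logv + np.concatenate([[0.0], np.cumsum(log1mv[:-1])])

    log_w = stick_log_weights(sticks)

    eta = np.empty((n, c))
    for it in range(config.n_iter):
        for j in range(n):
            eta[j] = eta_of(j, atom_phi[z[j]], atom_psi[z[j]], ell_idx[j])
        sig = _sigmoid(eta)

        # -- per-bin random-walk Metropolis on log lam_a, log lam_b
        for which in ("a", "b"):
            lam = lam_a if which == "a" else lam_b
            other = lam_b if which == "a" else lam_a
            weight = sig if which == "a" else 1.0 - sig
            other_w = 1.0 - sig if which == "a" else sig
            curve = prior.a if which == "a" else prior.b
            prop = lam * np.exp(config.rw_scale * rng.standard_normal(c))
            mu_cur = scale * (weight * lam + other_w * other)
            mu_prop = scale * (weight * prop + other_w * other)
            mu_cur = np.maximum(mu_cur, 1e-12)
            mu_prop = np.maximum(mu_prop, 1e-12)
            ll_cur = (x * np.log(mu_cur) - mu_cur).sum(axis=0)
            ll_prop = (x * np.log(mu_prop) - mu_prop).sum(axis=0)
            # gamma prior with log-scale proposal Jacobian
            lp_cur = curve.shape * np.log(lam) - curve.rate * lam
            lp_prop = curve.shape * np.log(prop) - curve.rate * prop
            accept = np.log(rng.uniform(size=c)) < (ll_prop + lp_prop - ll_cur - lp_cur)
            lam[accept] = prop[accept]

        # -- whitened latent curves by elliptical slice sampling
        for j in range(n):
            u[j] = _elliptical_slice_whitened(
                x[j], u[j], atom_phi[z[j]], atom_psi[z[j]],
                gp.chol[ell_idx[j]], lam_a, lam_b, scale, rng,
            )

        # -- cluster labels: likelihood-based Gibbs (u fixed, eta moves with atom)
        sq_psi = np.sqrt(atom_psi)
        for j in range(n):
            lu = gp.chol[ell_idx[j]] @ u[j]
            etas = atom_phi[:, None] + sq_psi[:, None] * lu[None, :]
            logp = log_w + _loglik_batch(x[j], etas, lam_a, lam_b, scale)
            probs = np.exp(logp - logp.max())
            z[j] = rng.choice(trunc, p=probs / probs.sum())

        # -- atom updates: random-walk Metropolis against member likelihoods
        counts = np.bincount(z, minlength=trunc)
        for l in range(trunc):
            members = np.flatnonzero(z == l)
            if members.size == 0:
                atom_phi[l] = rng.normal(0.0, sd0)
                atom_psi[l] = 1.0 / rng.gamma(a0, 1.0 / b0)
                continue
            lus = [gp.chol[ell_idx[j]] @ u[j] for j in members]

            def cluster_logpost(phi: float, psi: float) -> float:
                lp = -0.5 * phi**2 / sd0**2 - (a0 + 1.0) * math.log(psi) - b0 / psi
                sq = math.sqrt(psi)
                for j, lu in zip(members, lus):
                    lp += _loglik_trial(x[j], phi + sq * lu, lam_a, lam_b, scale)
                return lp

            cur = cluster_logpost(atom_phi[l], atom_psi[l])
            for _ in range(2):
                phi_p = atom_phi[l] + 0.3 * rng.standard_normal()
                psi_p = atom_psi[l] * math.exp(0.3 * rng.standard_normal())
                prop_lp = cluster_logpost(phi_p, psi_p)
                # log-scale psi proposal Jacobian
                if math.log(rng.uniform()) < prop_lp - cur + math.log(
                    psi_p / atom_psi[l]
                ):
                    atom_phi[l], atom_psi[l], cur = phi_p, psi_p, prop_lp

        # -- interweaved centered update: conjugate (phi, psi) given eta, then
        #    re-whiten u (ancillarity-sufficiency interweaving; this is what
        #    lets the curve amplitude and psi move together)
        for j in range(n):
            eta[j] = eta_of(j, atom_phi[z[j]], atom_psi[z[j]], ell_idx[j])
        for l in range(trunc):
            members = np.flatnonzero(z == l)
            if members.size == 0:
                continue
            oqo = gp.one_q_one[ell_idx[members]]
            oqe = np.array([gp.q_one[ell_idx[j]] @ eta[j] for j in members])
            prec = 1.0 / sd0**2 + oqo.sum() / atom_psi[l]
            mean = (oqe.sum() / atom_psi[l]) / prec
            atom_phi[l] = rng.normal(mean, 1.0 / math.sqrt(prec))
            quad = 0.0
            for j in members:
                r = eta[j] - atom_phi[l]
                quad += float(r @ gp.inv[ell_idx[j]] @ r)
            atom_psi[l] = 1.0 / rng.gamma(
                a0 + members.size * c / 2.0, 1.0 / (b0 + quad / 2.0)
            )
            sq = math.sqrt(atom_psi[l])
            for j in members:
                u[j] = np.linalg.solve(gp.chol[ell_idx[j]], eta[j] - atom_phi[l]) / sq

        # -- stick-breaking weights
        tail = np.concatenate([np.cumsum(counts[::-1])[::-1][1:], [0]])
        sticks = rng.beta(1.0 + counts, kappa + tail)
        sticks[-1] = 1.0
        log_w = stick_log_weights(sticks)

        # -- length scales: two complementary moves per trial.  A centered
        #    Gibbs step given eta (curve preserved, prior re-scored under each
        #    ell) mixes ell without touching the fit; a whitened step (u
        #    preserved, curve reshaped against the likelihood) then explores.
        log_p_ell = np.log(np.maximum(p_ell, 1e-300))
        logdets = np.asarray(gp.logdet)
        for j in range(n):
            phi_j, psi_j = atom_phi[z[j]], atom_psi[z[j]]
            sq = math.sqrt(psi_j)
            eta_j = eta_of(j, phi_j, psi_j, ell_idx[j])
            r = eta_j - phi_j
            quad_g = np.array([float(r @ gp.inv[g] @ r) for g in range(g_count)])
            logp = log_p_ell - 0.5 * (logdets + quad_g / psi_j)
            probs = np.exp(logp - logp.max())
            ell_idx[j] = rng.choice(g_count, p=probs / probs.sum())
            u[j] = np.linalg.solve(gp.chol[ell_idx[j]], r) / sq

            etas = phi_j + sq * np.stack([gp.chol[g] @ u[j] for g in range(g_count)])
            logp = log_p_ell + _loglik_batch(x[j], etas, lam_a, lam_b, scale)
            probs = np.exp(logp - logp.max())
            ell_idx[j] = rng.choice(g_count, p=probs / probs.sum())
        p_ell = rng.dirichlet(1.0 + np.bincount(ell_idx, minlength=g_count))

        # -- retain
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            for j in range(n):
                eta[j] = eta_of(j, atom_phi[z[j]], atom_psi[z[j]], ell_idx[j])
            w_now = np.exp(log_w)
            draws["lam_a"][kept] = lam_a
            draws["lam_b"][kept] = lam_b
            draws["alpha"][kept] = _sigmoid(eta)
            draws["phi"][kept] = atom_phi[z]
            draws["psi"][kept] = atom_psi[z]
            draws["ell"][kept] = ell_grid[ell_idx]
            draws["atom_phi"][kept] = atom_phi
            draws["atom_psi"][kept] = atom_psi
            draws["atom_weight"][kept] = w_now / w_now.sum()
            draws["p_ell"][kept] = p_ell
            kept += 1

    for key in draws:
        draws[key] = draws[key][:kept]

    rhat = {
        "mean_lam_a": _split_rhat(draws["lam_a"].mean(axis=1)),
        "mean_lam_b": _split_rhat(draws["lam_b"].mean(axis=1)),
        "mean_alpha": _split_rhat(draws["alpha"].mean(axis=(1, 2))),
        "mean_psi": _split_rhat(draws["psi"].mean(axis=1)),
    }
    converged = all(v < 1.1 for v in rhat.values() if np.isfinite(v))
    return DAPPPosterior(
        lam_a=draws["lam_a"], lam_b=draws["lam_b"], alpha=draws["alpha"],
        phi=draws["phi"], psi=draws["psi"], ell=draws["ell"],
        atom_phi=draws["atom_phi"], atom_psi=draws["atom_psi"],
        atom_weight=draws["atom_weight"], p_ell=draws["p_ell"],
        config=config, rhat=rhat, converged=converged,
    )


def _split_rhat(chain: np.ndarray) -> float:
    """Split-chain potential scale reduction factor of one scalar chain."""
    m = chain.size // 2
    if m < 2:
        return float("nan")
    halves = np.stack([chain[:m], chain[m : 2 * m]])
    within = halves.var(axis=1, ddof=1).mean()
    between = m * halves.mean(axis=1).var(ddof=1)
    if within <= 1e-300:
        return 1.0
    var_plus = (m - 1) / m * within + between / m
    return float(math.sqrt(var_plus / within))


# ---------------------------------------------------------------------------
# Posterior-predictive alpha curves and classification

def predict_alpha(
    posterior: DAPPPosterior,
    n_draws: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> AlphaDraws:
    """Simulate alpha curves for hypothetical new dual trials.

    Each draw picks a retained MCMC iteration, samples an atom ``(phi, psi)``
    from that iteration's stick-breaking weights and a length scale from its
    ``P_ell``, then draws the curve from the Gaussian process and maps it
    through the logistic link.
    """
    config = posterior.config
    n_draws = n_draws or config.n_pred_draws
    rng = np.random.default_rng(seed)
    c = posterior.lam_a.shape[1]
    mids = (np.arange(c) + 0.5) * config.w
    gp = _GPGrid(mids, config.ell_grid)

    iters = rng.integers(0, posterior.n_draws, size=n_draws)
    curves = np.empty((n_draws, c))
    for d, t in enumerate(iters):
        l = rng.choice(posterior.atom_weight.shape[1], p=posterior.atom_weight[t])
        g = rng.choice(posterior.p_ell.shape[1], p=posterior.p_ell[t])
        phi, psi = posterior.atom_phi[t, l], posterior.atom_psi[t, l]
        eta = phi + math.sqrt(psi) * (gp.chol[g] @ rng.standard_normal(c))
        curves[d] = _sigmoid(eta)
    return AlphaDraws(
        curves=curves,
        swings=curves.max(axis=1) - curves.min(axis=1),
        means=curves.mean(axis=1),
    )


def _odds(p_num: float, p_den: float) -> float:
    if p_den == 0.0:
        return float("inf")
    return p_num / p_den


def compute_indices(draws: AlphaDraws) -> DAPPIndices:
    """Waviness, extremeness and skewness odds from predictive alpha draws."""
    if len(draws) < 100:
        raise ValueError("need at least 100 predictive draws")
    swings, means = draws.swings, draws.means
    r_w = _odds(float(np.mean(swings > 0.5)), float(np.mean(swings < 0.5)))
    inside = float(np.mean((means > 0.25) & (means < 0.75)))
    r_c = _odds(inside, float(np.mean((means <= 0.25) | (means >= 0.75))))
    p_lo = float(np.mean(means < 0.5))
    p_hi = float(np.mean(means > 0.5))
    if p_lo == 0.0 or p_hi == 0.0:
        r_s = float("inf")
    else:
        r_s = max(p_lo / p_hi, p_hi / p_lo)
    return DAPPIndices(r_w=r_w, r_c=r_c, r_s=r_s)


def tag_triplet(indices: DAPPIndices) -> DAPPTags:
    """Threshold the three odds indices into the categorical tags.

    Ambiguous bands are closed: an index exactly at a threshold stays
    Ambiguous (or Unlabeled for symmetry).
    """
    wavy_hi, flat_lo = WAVINESS_THRESHOLDS
    if indices.r_w > wavy_hi:
        waviness = "Wavy"
    elif indices.r_w < flat_lo:
        waviness = "Flat"
    else:
        waviness = "Ambiguous"
    central_hi, extreme_lo = EXTREMENESS_THRESHOLDS
    if indices.r_c > central_hi:
        extremeness = "Central"
    elif indices.r_c < extreme_lo:
        extremeness = "Extreme"
    else:
        extremeness = "Ambiguous"
    skew_hi, sym_lo = SKEW_THRESHOLDS
    if indices.r_s > skew_hi:
        symmetry = "Skewed"
    elif indices.r_s < sym_lo:
        symmetry = "Symmetric"
    else:
        symmetry = "Unlabeled"
    return DAPPTags(waviness=waviness, extremeness=extremeness, symmetry=symmetry)


def analyze_dapp(
    triplet: Triplet,
    config: DAPPConfig | None = None,
    seed: int | None = None,
) -> tuple[DAPPPosterior, AlphaDraws, DAPPIndices, DAPPTags]:
    """Fit, predict, index and tag one triplet in a single call."""
    config = config or DAPPConfig()
    posterior = fit_dapp(triplet, config=config)
    draws = predict_alpha(
        posterior, seed=config.seed + 1 if seed is None else seed
    )
    indices = compute_indices(draws)
    return posterior, draws, indices, tag_triplet(indices)
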