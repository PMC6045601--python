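"""Synthetic spike-train, pair and LFP generators for every switching regime.

Dual-stimulus trials are generated from the admixture rate
``lambda_AB(t) = alpha(t) * lambda_A(t) + (1 - alpha(t)) * lambda_B(t)``
where the mixing path ``alpha(t)`` is regime specific: a per-trial coin flip
between the pure A and pure B rates (``whole_trial_switch``), a constant, a
square wave, a sinusoid, a logistic-transformed Gaussian-process draw, or the
degenerate ``outside`` / ``single`` regimes.  Spike trains are inhomogeneous
Poisson realizations produced by thinning; alpha paths are piecewise constant
at 1 ms resolution regardless of any downstream analysis bin width.

Default rates give expected window counts of 20 (A) and 5 (B) spikes over the
600 ms response window — a well-separated pair of conditions typical of
midbrain auditory neurons — with 15 trials per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .trials import StimParams, TrialRecord, Triplet

REGIMES = (
    "whole_trial_switch",
    "constant_alpha",
    "square_wave",
    "sinusoid",
    "smooth_gp",
    "outside",
    "single",
)

#: default single-sound rates in spikes/s: expected counts 20 and 5 per 600 ms
DEFAULT_RATE_A = 100.0 / 3.0
DEFAULT_RATE_B = 25.0 / 3.0


@dataclass
class GeneratorConfig:
    """Full specification of one synthetic triplet's switching regime.

    Rates are in spikes/s, either scalars or arrays sampled on a 1 ms grid
    over ``[0, t_end)``.  ``seed`` makes the draw reproducible.
    """

    rate_a: float | np.ndarray = DEFAULT_RATE_A
    rate_b: float | np.ndarray = DEFAULT_RATE_B
    t_end: int = 600
    n_a: int = 15
    n_b: int = 15
    n_ab: int = 15
    regime: str = "constant_alpha"
    pi_a: float = 0.5          # whole_trial_switch: P(trial is A-like)
    alpha0: float = 0.5        # constant_alpha
    period_ms: float = 200.0   # square_wave / sinusoid
    levels: tuple[float, float] = (0.05, 0.95)
    phi: float = 0.0           # smooth_gp: GP mean of eta
    psi: float = 1.0           # smooth_gp: GP variance of eta
    ell: float = 125.0         # smooth_gp: GP length scale (ms)
    gain: float = 1.0          # outside: multiplier on rate_a + rate_b
    which: str = "A"           # single: which component the dual trials follow
    random_phase: bool = False  # square_wave/sinusoid: per-trial phase draw
    baseline_rate: float = 0.0  # spontaneous rate (sp/s) in the 600 ms pre-onset
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if np.any(np.asarray(self.rate_a) < 0) or np.any(np.asarray(self.rate_b) < 0):
            raise ValueError("rates must be nonnegative")
        if not (0.0 <= self.pi_a <= 1.0 and 0.0 <= self.alpha0 <= 1.0):
            raise ValueError("pi_a and alpha0 must lie in [0, 1]")
        lo, hi = self.levels
        if not (0.0 < lo < 1.0 and 0.0 < hi < 1.0):
            raise ValueError("levels must lie in (0, 1)")


@dataclass
class PairConfig:
    """Two generator configs sharing a regime, coupled with probability rho."""

    config1: GeneratorConfig
    config2: GeneratorConfig
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.config1.regime != self.config2.regime:
            raise ValueError("pair members must share a switching regime")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")


def _rate_grid(rate: float | np.ndarray, t_end: int) -> np.ndarray:
    """Rate in spikes/s on the 1 ms generation grid."""
    r = np.asarray(rate, dtype=float)
    if np.any(r < 0):
        raise ValueError("rates must be nonnegative")
    if r.ndim == 0:
        return np.full(t_end, float(r))
    if r.shape != (t_end,):
        raise ValueError(f"tabulated rate must have length {t_end}")
    return r


def _sample_train(rate_ms: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One inhomogeneous Poisson realization over [0, t_end) by thinning."""
    t_end = rate_ms.size
    rmax = float(rate_ms.max())
    if rmax <= 0.0:
        return np.empty(0)
    n = rng.poisson(rmax * t_end / 1000.0)
    times = rng.uniform(0.0, t_end, size=n)
    keep = rng.uniform(0.0, rmax, size=n) < rate_ms[np.minimum(times.astype(int), t_end - 1)]
    return np.sort(times[keep])


def gen_poisson_trials(
    rate: float | np.ndarray, n: int, t_end: int, seed: int | np.random.Generator
) -> list[np.ndarray]:
    """n independent Poisson spike trains (times in ms) over [0, t_end)."""
    rng = np.random.default_rng(seed)
    grid = _rate_grid(rate, t_end)
    return [_sample_train(grid, rng) for _ in range(n)]


def _alpha_path(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """One trial's mixing path on the 1 ms grid (sub-trial regimes only)."""
    t_end = config.t_end
    t = np.arange(t_end, dtype=float)
    if config.regime == "constant_alpha":
        return np.full(t_end, config.alpha0)
    lo, hi = config.levels
    shift = config.period_ms * rng.uniform() if config.random_phase else 0.0
    if config.regime == "square_wave":
        # starts at the high-alpha (A-dominant) level when the phase is fixed
        phase = np.floor(2.0 * (t + shift) / config.period_ms).astype(int) % 2
        return np.where(phase == 0, hi, lo)
    if config.regime == "sinusoid":
        mid, amp = (hi + lo) / 2.0, (hi - lo) / 2.0
        return mid + amp * np.sin(2.0 * np.pi * (t + shift) / config.period_ms)
    if config.regime == "smooth_gp":
        return _gp_alpha_path(config, rng)
    raise ValueError(f"regime {config.regime!r} has no alpha path")


_GP_STEP = 50.0  # ms; GP drawn on this grid, held piecewise constant


def _gp_alpha_path(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    knots = (np.arange(int(config.t_end / _GP_STEP)) + 0.5) * _GP_STEP
    d = knots[:, None] - knots[None, :]
    cov = config.psi * np.exp(-0.5 * d**2 / config.ell**2)
    cov[np.diag_indices_from(cov)] += 1e-9
    eta = config.phi + np.linalg.cholesky(cov) @ rng.standard_normal(knots.size)
    alpha_knots = 1.0 / (1.0 + np.exp(-eta))
    idx = np.minimum((np.arange(config.t_end) / _GP_STEP).astype(int), knots.size - 1)
    return alpha_knots[idx]


def gen_dual_trials(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[list[np.ndarray], dict]:
    """Dual-stimulus spike trains plus the latent switching state.

    Returns ``(trains, latent)`` where ``latent`` holds per-trial labels
    (``whole_trial_switch``: 1 = A-like) or 1 ms alpha paths (sub-trial
    regimes), so tests can condition on ground truth.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    ra = _rate_grid(config.rate_a, config.t_end)
    rb = _rate_grid(config.rate_b, config.t_end)
    trains: list[np.ndarray] = []
    latent: dict = {"regime": config.regime}

    if config.regime == "whole_trial_switch":
        labels = rng.uniform(size=config.n_ab) < config.pi_a
        for is_a in labels:
            trains.append(_sample_train(ra if is_a else rb, rng))
        latent["labels"] = labels.astype(int)
    elif config.regime == "outside":
        for _ in range(config.n_ab):
            trains.append(_sample_train(config.gain * (ra + rb), rng))
    elif config.regime == "single":
        grid = ra if config.which == "A" else rb
        for _ in range(config.n_ab):
            trains.append(_sample_train(grid, rng))
    else:
        paths = np.empty((config.n_ab, config.t_end))
        for j in range(config.n_ab):
            paths[j] = _alpha_path(config, rng)
            trains.append(_sample_train(paths[j] * ra + (1.0 - paths[j]) * rb, rng))
        latent["alpha_paths"] = paths
    return trains, latent


def gen_correlated_pair(
    pair: PairConfig,
) -> tuple[tuple[list[np.ndarray], dict], tuple[list[np.ndarray], dict]]:
    """Dual trials for two neurons with coupled switching states.

    With probability ``rho`` the second neuron reuses the first neuron's
    latent state — the trial label in the whole-trial regime, or the alpha
    path segment per 50 ms stretch in sub-trial regimes — otherwise its own
    independent draw.  Marginals of each neuron match its solo generator.
    """
    c1, c2 = pair.config1, pair.config2
    if c1.n_ab != c2.n_ab or c1.t_end != c2.t_end:
        raise ValueError("pair members must agree on n_ab and t_end")
    rng = np.random.default_rng(c1.seed)
    trains1, latent1 = gen_dual_trials(c1, rng)

    trains2: list[np.ndarray] = []
    latent2: dict = {"regime": c2.regime}
    ra2 = _rate_grid(c2.rate_a, c2.t_end)
    rb2 = _rate_grid(c2.rate_b, c2.t_end)

    if c1.regime == "whole_trial_switch":
        own = rng.uniform(size=c2.n_ab) < c2.pi_a
        share = rng.uniform(size=c2.n_ab) < pair.rho
        labels2 = np.where(share, latent1["labels"].astype(bool), own)
        for is_a in labels2:
            trains2.append(_sample_train(ra2 if is_a else rb2, rng))
        latent2["labels"] = labels2.astype(int)
    elif c1.regime in ("outside", "single"):
        out = gen_dual_trials(replace(c2, seed=c2.seed + 1))
        trains2, latent2 = out
    else:
        n_seg = int(np.ceil(c2.t_end / _GP_STEP))
        paths2 = np.empty((c2.n_ab, c2.t_end))
        for j in range(c2.n_ab):
            own_path = _alpha_path(c2, rng)
            shared = latent1["alpha_paths"][j]
            seg_share = rng.uniform(size=n_seg) < pair.rho
            mask = np.repeat(seg_share, int(_GP_STEP))[: c2.t_end]
            paths2[j] = np.where(mask, shared, own_path)
            trains2.append(_sample_train(paths2[j] * ra2 + (1 - paths2[j]) * rb2, rng))
        latent2["alpha_paths"] = paths2
    return (trains1, latent1), (trains2, latent2)


def gen_lfp_trials(
    labels: np.ndarray,
    pre_offset_a: float,
    pre_offset_b: float,
    noise_sd: float,
    seed: int | np.random.Generator,
    evoked_a: float = 0.0,
    evoked_b: float = 0.0,
    t_end: int = 600,
) -> np.ndarray:
    """Per-trial LFP voltage traces at 1 kHz over [-600, t_end) ms.

    Each trial's pre-onset segment sits at its label's offset plus one
    per-trial Gaussian perturbation of SD ``noise_sd``; the post-onset
    segment adds a label-dependent evoked deflection.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels).astype(bool)
    n = labels.size
    traces = np.empty((n, 600 + t_end))
    base = np.where(labels, pre_offset_a, pre_offset_b) + noise_sd * rng.standard_normal(n)
    evoked = np.where(labels, evoked_a, evoked_b)
    traces[:, :600] = base[:, None]
    traces[:, 600:] = (base + evoked)[:, None]
    return traces


# ---------------------------------------------------------------------------
# Triplet assembly

_STIM_A = StimParams(loc_deg=-24.0, freq_hz=742.0, level_db=55.0)
_STIM_B = StimParams(loc_deg=24.0, freq_hz=500.0, level_db=55.0)


def _mk_record(
    neuron_id: str, trial_id: int, condition: str, spikes: np.ndarray, t_end: int,
    first_saccade: str = "unknown", session_id: str = "synthetic",
) -> TrialRecord:
    return TrialRecord(
        session_id=session_id,
        neuron_id=neuron_id,
        trial_id=trial_id,
        condition=condition,
        stim_a=_STIM_B if condition == "B" else _STIM_A,
        stim_b=_STIM_B if condition == "AB" else None,
        spike_times=np.sort(spikes),
        t_end=t_end,
        correct=True,
        first_saccade=first_saccade,
    )


def make_triplet(
    config: GeneratorConfig, neuron_id: str = "synthetic-1"
) -> tuple[Triplet, dict]:
    """Generate a full (A, B, AB) triplet of trial records under one regime."""
    rng = np.random.default_rng(config.seed)
    trains_a = [
        _sample_train(_rate_grid(config.rate_a, config.t_end), rng)
        for _ in range(config.n_a)
    ]
    trains_b = [
        _sample_train(_rate_grid(config.rate_b, config.t_end), rng)
        for _ in range(config.n_b)
    ]
    trains_ab, latent = gen_dual_trials(config, rng)

    trial_id = 0
    records = {"A": [], "B": [], "AB": []}
    for cond, trains in (("A", trains_a), ("B", trains_b), ("AB", trains_ab)):
        for tr in trains:
            if config.baseline_rate > 0:
                n_base = rng.poisson(config.baseline_rate * 0.6)
                tr = np.concatenate([rng.uniform(-600.0, 0.0, n_base), tr])
            records[cond].append(_mk_record(neuron_id, trial_id, cond, tr, config.t_end))
            trial_id += 1
    triplet = Triplet(
        neuron_id=neuron_id,
        stim_a=_STIM_A,
        stim_b=_STIM_B,
        trials_a=records["A"],
        trials_b=records["B"],
        trials_ab=records["AB"],
        t_end=config.t_end,
    )
    return triplet, latent
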