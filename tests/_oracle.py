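"""Brute-force dense-grid integration of the four dual-count marginals.

Independent of the package's closed forms and quadrature: everything here is
Simpson integration of explicit Poisson likelihoods against the gamma
posteriors of the single-stimulus rates.  Only feasible for tiny instances.
"""

import numpy as np
from scipy import stats
from scipy.integrate import simpson


def _gamma_grid(shape, rate, n=401, extra_sum=0.0, extra_n=0):
    """Grid covering the prior range and, if the dual counts also weight this
    rate, the range of the likelihood-tilted gamma kernel."""
    lo = stats.gamma.ppf(1e-12, shape, scale=1.0 / rate)
    hi = stats.gamma.ppf(1.0 - 1e-12, shape, scale=1.0 / rate)
    if extra_n:
        tilted = stats.gamma.ppf(
            1.0 - 1e-12, shape + extra_sum, scale=1.0 / (rate + extra_n)
        )
        hi = max(hi, tilted)
        lo = min(lo, stats.gamma.ppf(1e-12, shape + extra_sum,
                                     scale=1.0 / (rate + extra_n)))
    lam = np.linspace(max(lo, 1e-12), hi, n)
    pdf = stats.gamma.pdf(lam, shape, scale=1.0 / rate)
    return lam, pdf


def _pois_prod(counts, lam):
    """prod_j Poi(x_j; lam) on an arbitrary-shape lam array."""
    from scipy.special import gammaln

    lam = np.maximum(np.asarray(lam, dtype=float), 1e-300)
    counts = np.asarray(counts, dtype=float)
    s, n = counts.sum(), counts.size
    log_norm = gammaln(counts + 1).sum()
    return np.exp(s * np.log(lam) - n * lam - log_norm)


def oracle_log_marginals(
    counts_a, counts_b, counts_ab, n_grid=201, n_alpha=401, n_inner=401
):
    """Log marginal likelihood of the dual counts under all four hypotheses."""
    a = np.asarray(counts_a, float)
    b = np.asarray(counts_b, float)
    x = np.asarray(counts_ab, float)
    shape_a, rate_a = a.sum() + 0.5, a.size
    shape_b, rate_b = b.sum() + 0.5, b.size
    lam_max = 3.0 * (a.mean() + b.mean()) + 10.0

    lam_a, pdf_a = _gamma_grid(shape_a, rate_a, n_grid, x.sum(), x.size)
    lam_b, pdf_b = _gamma_grid(shape_b, rate_b, n_grid, x.sum(), x.size)

    # Single: lambda_AB equals lambda_A or lambda_B, 50/50
    m_single = 0.5 * (
        simpson(_pois_prod(x, lam_a) * pdf_a, x=lam_a)
        + simpson(_pois_prod(x, lam_b) * pdf_b, x=lam_b)
    )

    # Mixture: per-trial assignment to Poi(lam_a) or Poi(lam_b), alpha uniform
    alphas = np.linspace(0.0, 1.0, n_alpha)
    la = lam_a[:, None]
    lb = lam_b[None, :]
    vals = np.empty(n_alpha)
    p_a = [stats.poisson.pmf(xj, la) for xj in x]  # each (n_grid, 1)
    p_b = [stats.poisson.pmf(xj, lb) for xj in x]  # each (1, n_grid)
    for i, al in enumerate(alphas):
        prod = np.ones((n_grid, n_grid))
        for pa, pb in zip(p_a, p_b):
            prod = prod * (al * pa + (1.0 - al) * pb)
        inner = simpson(prod * pdf_b[None, :], x=lam_b, axis=1)
        vals[i] = simpson(inner * pdf_a, x=lam_a)
    m_mixture = simpson(vals, x=alphas)

    # Intermediate / Outside: truncated, renormalized Jeffreys on lambda_AB,
    # integrated per (lam_a, lam_b) pair over its own sub-interval grid
    t = np.linspace(0.0, 1.0, n_inner)

    def _range_integral(lo_vec, hi_vec):
        # integral of lam^(-1/2) prod Poi(x; lam) over [lo, hi) per element
        lo_vec = np.maximum(lo_vec, 1e-12)
        width = hi_vec - lo_vec
        lam = lo_vec[:, None] + width[:, None] * t[None, :]
        lam = np.maximum(lam, 1e-300)
        f = _pois_prod(x, lam) * lam ** (-0.5)
        return simpson(f, x=t, axis=1) * width

    def _inner_over_lam_b(lam_ai, lb_lo, lb_hi):
        # integral over lam_b in [lb_lo, lb_hi] (kink-free sub-range)
        if lb_hi <= lb_lo:
            return 0.0, 0.0
        lbs = np.linspace(lb_lo, lb_hi, n_inner)
        pdf = stats.gamma.pdf(lbs, shape_b, scale=1.0 / rate_b)
        lo = np.minimum(lam_ai, lbs)
        hi = np.maximum(lam_ai, lbs)
        z_int = np.maximum(2.0 * (np.sqrt(hi) - np.sqrt(lo)), 1e-300)
        inner_int = _range_integral(lo, hi) / z_int
        # removable singularity at lam_b == lam_a: the ratio tends to the
        # plain Poisson product at that rate
        degenerate = (hi - lo) < 1e-9 * (1.0 + hi)
        if degenerate.any():
            inner_int[degenerate] = _pois_prod(x, lo[degenerate])
        z_out = 2.0 * np.sqrt(lo) + 2.0 * (np.sqrt(lam_max) - np.sqrt(hi))
        inner_out = (
            _range_integral(np.zeros_like(lo), lo)
            + _range_integral(hi, np.full_like(hi, lam_max))
        ) / z_out
        return (
            simpson(inner_int * pdf, x=lbs),
            simpson(inner_out * pdf, x=lbs),
        )

    m_int_rows = np.empty(n_grid)
    m_out_rows = np.empty(n_grid)
    for i, lam_ai in enumerate(lam_a):
        split = float(np.clip(lam_ai, lam_b[0], lam_b[-1]))
        lo_int, lo_out = _inner_over_lam_b(lam_ai, lam_b[0], split)
        hi_int, hi_out = _inner_over_lam_b(lam_ai, split, lam_b[-1])
        m_int_rows[i] = lo_int + hi_int
        m_out_rows[i] = lo_out + hi_out
    m_intermediate = simpson(m_int_rows * pdf_a, x=lam_a)
    m_outside = simpson(m_out_rows * pdf_a, x=lam_a)

    return {
        "mixture": float(np.log(m_mixture)),
        "intermediate": float(np.log(m_intermediate)),
        "outside": float(np.log(m_outside)),
        "single": float(np.log(m_single)),
    }
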