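# Methods

This note records the models, priors, numerical choices and design
decisions behind `spikemux`, and what the synthetic-data tests do and do
not establish.

## Data model

A trial holds spike times in ms relative to stimulus onset, a condition
label (A, B, or AB), stimulus parameters per component, an analysis window
end `T` ∈ {600, 1000} ms taken from the data file (not inferred), a
`correct` flag and an optional first-saccade label and LFP trace.  All
windows and bins are half-open `[lo, hi)`.  Single-sound trials carry their
one stimulus in the A-parameter columns; the condition label says which
role it plays in a triplet.  Triplets require ≥ 5 correct trials per member
(A, B, AB) with exactly matching stimulus parameters; the loader retains
incorrect trials but every assembler drops them.  Neuron responsiveness is
a one-tailed paired t-test of the 600 ms post-onset count against the
600 ms pre-onset count (keep if p ≤ 0.05); a zero-variance comparison is
reported as p = 1, not kept.

## Pooled summation-vs-averaging indices

The baseline pool `Base_{A,B}` concatenates the A-trial and B-trial
baseline counts; subtracting its mean from the predicted sum avoids
counting spontaneous activity twice.  The Z denominators use the *sample*
(n−1) standard deviation — the choice is not dictated by the index
definitions, and is noted here because it changes Z by a factor
√(n/(n−1)).  Exact |ZAvg| = |Zsum| ties are labeled `tie`; both-zero
single-sound SDs yield NaN Z-scores and a `degenerate` flag.

## Whole-trial analysis

**Screening.**  The Poisson goodness-of-fit test estimates the rate by the
sample mean, builds equal-probability bins from that Poisson's quantiles
with `max(3, n // 5)` bins, and computes Σ(O−E)²/E.  The Monte-Carlo
p-value re-estimates the rate and rebuilds the bins for every one of the
simulated samples (a full parametric bootstrap): this is what makes the
test's type-I error land near the nominal 0.1 cut, which the acceptance
suite verifies within [0.06, 0.14].  Duplicate quantile edges (small rates)
produce zero-probability bins that contribute nothing.  An all-zero count
vector fails screening by convention.

**Separation.**  The test of λ^A ≠ λ^B against equality uses the
*arithmetic intrinsic Bayes factor*: the improper-Jeffreys Bayes factor is
corrected by averaging the inverse training-sample Bayes factor over
minimal training samples of one observation from each condition (all pairs,
or a seeded subsample of at most 1000).  `log IBF ≥ 3` — equivalently a
posterior probability of inequality above 95% at even prior odds — counts
as separated.

**Four-model posterior.**  The single-stimulus counts enter the dual-count
model comparison through proper gamma priors on λ^A and λ^B equal to their
Jeffreys posteriors, Gamma(Σx + 1/2, n).  Because these priors are proper,
no training-sample correction is needed for the model comparison itself.
Per model:

* *Mixture*: summing over all 2^m assignments of dual trials to the A or B
  component collapses, via a (subset size, subset sum) dynamic program, to
  a polynomial-size exact sum; the uniform prior on α contributes a Beta
  function per subset size.  No quadrature error.
* *Intermediate / Outside*: λ^AB carries a Jeffreys prior truncated to the
  open interval between the *realized* (λ^A, λ^B) values inside the
  integral — not plug-in estimates — renormalized; Outside is additionally
  bounded above at λ_max = 3(λ̂^A + λ̂^B) + 10 to keep the prior proper.
  The inner rate integral is an incomplete-gamma closed form; the outer
  two-dimensional integral uses fixed-order Gauss–Legendre quadrature
  (80 nodes per dimension) on the rate axis over the 1e-12…1−1e-12
  quantile range, split into the two orderings λ^A < λ^B and λ^B < λ^A
  because the integrand kinks on the diagonal.  The split makes the
  quadrature spectrally accurate; agreement with brute-force dense-grid
  integration is better than 1e-6 relative (tested).
* *Single*: prior mass split 50/50 between λ^AB = λ^A and λ^AB = λ^B;
  gamma–Poisson closed forms.

Posteriors are proportional to prior weight (default 1/4 each) times
marginal likelihood, normalized in log space.  Winners are tiered at
posterior probability > 0.95, > 0.50, and the no-threshold tier; exact
argmax ties break deterministically in the order Mixture, Intermediate,
Outside, Single and are flagged.

**Sensitivity.**  Validation on synthetic triplets with expected window
counts 20 vs 5 and 15 trials per condition gives median true-model
posteriors ≈ 1.0 for Mixture and Intermediate.  The Outside condition
(dual rate = the summed rate, 25) is intrinsically harder: 25 lies close
to the upper single rate (20), so Single absorbs some posterior mass and
the Outside median is lower (winner still correct in a large majority).
Single itself is a boundary case of the other three hypotheses and is
detected with lower confidence by construction.

## Dynamic admixture point process

**Binning and likelihood.**  Dual trials are reduced to counts in C = T/w
contiguous bins (default w = 50 ms; the tags are insensitive to w = 25 on
smooth regimes), with X_jc ~ Poi(w·λ_j(t*_c)/1000), λ in spikes/s, and
λ_j(t) = α_j(t)λ^A(t) + (1−α_j(t))λ^B(t).

**Rate priors.**  Each single-stimulus trial's binned rate curve is
smoothed with a Gaussian kernel of bandwidth one bin; the per-bin gamma
prior matches the across-trial mean and standard error exactly.  Floors of
0.5 sp/s on the estimate and 0.25 sp/s on the SE keep the gamma parameters
finite; they bind only for nearly silent cells.

**Priors on the mixing curves.**  α_j = logistic(η_j); η_j is a Gaussian
process with mean φ_j, variance ψ_j and squared-exponential correlation
with length scale ℓ_j restricted to {75, 125, 200, 300, 500} ms.  The
(φ_j, ψ_j) pairs are tied by a Dirichlet process (stick-breaking truncation
20, concentration 1) with base measure φ ~ N(0, 2²), ψ ~ Inverse-Gamma(2, 1);
ℓ_j is categorical with a Dirichlet(1,…,1) prior on its weights.  The base
measure and concentration are package choices: the N(0, 2²) mean keeps the
implied time-averaged α roughly spread over (0, 1), and Inverse-Gamma(2, 1)
centers the logit amplitude near 1 while admitting the large values a
saturating switch requires.

**MCMC.**  Metropolis-within-Gibbs with a *non-centered* curve
parameterization η_j = φ + √ψ·L_ℓ·u_j, u_j ~ N(0, I):

* elliptical slice sampling on the whitened coefficients u_j;
* per-bin random-walk Metropolis on log λ^A_c, log λ^B_c (the single-sound
  data act only through the gamma priors);
* likelihood-based Gibbs for the cluster labels and for ℓ_j (two moves per
  trial: a centered, curve-preserving Gibbs step and a whitened,
  curve-reshaping step);
* random-walk Metropolis on the atoms (φ_l, ψ_l), *interweaved* with a
  centered conjugate update given η followed by re-whitening (ASIS).  The
  interweaving is essential: in either single parameterization the
  amplitude ψ and the curve shape cannot grow together and the chain sticks
  at flat α;
* stick-breaking Beta updates for the weights, Dirichlet-multinomial for
  P_ℓ;
* initialization from smoothed per-bin crude α estimates, with ψ and ℓ set
  to their implied conjugate values.

Defaults: 4000 iterations, 2000 burn-in, thinning 2.  Split-chain potential
scale reduction factors on scalar summaries (mean rates, mean α, mean ψ)
are reported; any value above 1.1 flags the fit as unconverged rather than
failing silently.

**Prediction and tags.**  Each posterior-predictive α curve samples a
retained iteration, an atom from its stick-breaking weights (including the
base-measure remainder), a length scale from its P_ℓ, then the GP.  Swing
|α| = max − min; ᾱ is the bin-grid mean (Riemann approximation of the time
integral).  Odds indices over the predictive draws:
r_w = P(|α| > 0.5)/P(|α| < 0.5); r_c = P(ᾱ ∈ (0.25, 0.75))/P(outside);
r_s = max of P(ᾱ < 0.5)/P(ᾱ > 0.5) and its reciprocal.  Tags: Wavy if
r_w > 1.3, Flat if r_w < 0.77; Central if r_c > 3.24, Extreme if
r_c < 1.68; Skewed if r_s > 4, Symmetric if r_s < 2; closed middle bands
are Ambiguous/Unlabeled.  (The Flat condition is stated inconsistently in
some descriptions of this rule; it is implemented as the complement
r_w < 0.77 of the Wavy condition and its closed ambiguity band.)  Infinite
odds (empty denominator) propagate as `inf`.

**Identifiability of within-trial switching.**  The per-bin Fisher
information about η scales with (w·(λ^A−λ^B)·σ(1−σ))²/μ, so sub-trial
waviness is only detectable when bins carry several spikes.  At expected
window counts of 20 vs 5 (the whole-trial validation condition) a wavy
logit curve's prior whitening cost exceeds its likelihood gain for every
amplitude, and the honest posterior is flat — a property of the data, not
the sampler.  The admixture recovery suite therefore emulates a vigorously
driven neuron: λ^A = 240 sp/s, λ^B = 60 sp/s, 25–30 dual trials, with the
wavy regime a 300 ms-period square wave between α = 0.17 and 0.83 (a full
swing saturating at 0/1 maps, under the smooth GP family, to amplitudes so
large that the predictive time-averages spread into the Extreme band; the
milder symmetric levels keep the fitted curves inside the Wavy-Central
zone while their true swing, 0.66, remains well above the 0.5 waviness
criterion).  Under these conditions 20-triplet batches recover whole-trial
switching as Flat-Extreme, the square wave as Wavy-Central, constant
α = 0.5 as Flat-Central, and a pure-A response as Flat-Extreme-Skewed,
each with a clear majority.  The reduced MCMC settings used by the test
suite (1500 iterations, 500 burn-in, 2000 predictive draws — the r_c index
sits nearest its threshold and needs the extra draws to keep its
Monte-Carlo noise small) match these problem sizes.

## Assignment scores and population analyses

The A-vs-B assignment score of a count x is
Poi(x; μ_A) / [Poi(x; μ_A) + Poi(x; μ_B)] — the posterior probability of
the A-alone Poisson under equal 50/50 priors (the prior is configurable in
principle; equal odds is the symmetric default).  Scores are computed in
log space and never NaN.  Bin-scale scores use *unsmoothed* single-sound
bin means (floored at 0.05 expected counts) — this is likelihood scoring,
not model fitting, so the DAPP smoothing is deliberately not reused.
Z-normalization is per bin across dual trials; a zero-SD bin gets Z = 0 and
a flag.  Note the normalization removes everything stimulus-locked: a
switching pattern shared by *every* trial (e.g. a fixed-phase oscillation)
leaves no across-trial variance and cannot produce pair correlations — by
design, since that component is indistinguishable from a stimulus response.

Pairs enter only if both neurons discriminate A from B (two-sample t,
p < 0.05) and all trial types have ≥ 5 correct trials; per trial, Pearson
correlation of the two Z sequences across usable bins (≥ 3 required); the
population test is a two-tailed one-sample t of per-condition mean
correlations against zero, weighting conditions equally.

LFP: session-mean subtraction (DC removal), exclusion of trials whose
absolute voltage exceeds 500 mV at any sample, one mean voltage per trial
per 600 ms window before and after onset, two-tailed t-tests between
A-like and B-like groups (labels from whole-trial scores; exact-0.5 ties
excluded).  Behavior: two-tailed t of whole-trial scores between A-first
and B-first saccade trials, with a per-bin variant recording the sign of
each bin's difference; all-one-way behavior is flagged stereotyped with no
test.

## Synthetic generator

Regimes: whole-trial switching (per-trial Bernoulli(π) label, pure A or B
rates), constant α, square wave and sinusoid (period, symmetric levels,
optional per-trial random phase), smooth-GP α (logistic of a GP draw from
the same family the DAPP assumes, so parameter recovery is well-posed),
outside (gain·(rate_A + rate_B)) and single.  Spike trains are
inhomogeneous Poisson by thinning against the rate maximum; α paths are
piecewise constant at 1 ms resolution regardless of the analysis bin
width (GP paths are drawn on a 50 ms knot grid and held constant within
knots).  Default rates give expected window counts 20 (A) and 5 (B) over
600 ms with 15 trials per condition; optional spontaneous baseline rate
adds pre-onset spikes.  Correlated pairs share the latent state (trial
label, or α path per 50 ms segment) with probability ρ; marginals are
unchanged.  LFP traces are per-trial constants: pre-onset offset by label
plus per-trial Gaussian noise, post-onset adding a label-dependent evoked
deflection.

What the generator does *not* emulate: refractoriness and spike-history
dependence, rate nonstationarities across a session, electrode drift,
correlated noise between spikes and LFP beyond the label coupling, and
realistic LFP spectra.  Passing tests therefore demonstrate correctness of
the statistical machinery under its own assumptions, not robustness to
every violation found in recordings.

## Problem sizes and numerical conventions

The validation experiment uses 100 triplets per hypothesis at 15 trials
per condition; goodness-of-fit calibration uses 500 replicates with 2000
Monte-Carlo samples each; admixture recovery uses 20 triplets per regime at
the reduced MCMC settings above; pair calibration uses 40 batches of 14
conditions.  Quadrature tolerance is set by the fixed 80-node rule
(verified to 1e-6 against dense-grid integration); posterior probabilities
are normalized in log space; infinite odds are serialized as `inf`; random
number streams derive from `numpy.random.default_rng`, with pipeline stages
seeded by spawning a single `SeedSequence`.
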