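# Methods

This note documents the models and numerical choices behind `bp_affect`:
what each stage computes, which parameters matter, and what the synthetic
data can and cannot tell you about real listeners.

## Tunings and triads

The Bohlen-Pierce (BP) system repeats at the *tritave* (3:1,
1200·log2 3 ≈ 1901.955 cents) divided into 13 chromatic steps.  Two
built-in variants:

* **Equal temperament** — step k at k·1901.955/13 cents.
* **Just intonation** — Bohlen's odd-integer ratios
  (27/25, 25/21, 9/7, 7/5, 75/49, 5/3, 9/5, 49/25, 15/7, 7/3, 63/25,
  25/9, 3/1), which agree with the equal-tempered steps to within
  14 cents.

A triad is a step pattern {0, a, b} with 0 < a < b; 78 patterns exist
within one tritave, 66 when the tritave itself is excluded.  Rooting each
tritave-free pattern on all 13 degrees (wrapping through the tritave) and
identifying chords by their two intervals above the bass (rounded to
0.1 cent — the precision of the tuning table) collapses all equal-tempered
realizations back to 66 classes but splits the just-intonation set into
414 distinct interval patterns.  Pitch is handled throughout as
continuous MIDI (1 unit = 100 cents; f = 440·2^((p−69)/12)).

User tunings are accepted as Scala `.scl` files (cents or ratio lines,
13 pitches per tritave).

## Chord predictors

Every tone is idealized as a harmonic complex tone with 64 partials of
magnitude 1/n — a fair approximation of the piano-like timbre the design
emulates.  Masking is not modelled; chord spectra superpose linearly.

**Roughness.** Summed pairwise sensory dissonance over all partial pairs
of the pooled three-tone spectrum, weighted by the product of partial
amplitudes.  The default pairwise kernel is Sethares' parametrization of
the Plomp–Levelt curve; Hutchinson–Knopoff is available behind the same
interface (`roughness_model="hutchinson_knopoff"`).  The model identity
is a free choice here — predictions enter the regressions only through
z-scores, and the two kernels rank the 66 triads nearly identically, with
the one-step cluster 0 1 2 maximal under both.

**Harmonicity.** A triad expectation matrix of the 64-partial tone: for
each reference partial i and each ordered pair of higher partials (j, k),
the spike at the interval pair (c_j−c_i, c_k−c_i) accumulates the weight
w_i·w_j·w_k, and the spike field is convolved with an isotropic 2-D
Gaussian modelling pitch-perception uncertainty.  A chord's harmonicity
is the smoothed value at its own interval pair — high when the chord sits
on (or near) a low-numbered harmonic triple.  A `pair_weighting="pair"`
option deposits w_j·w_k instead (the published worked example has
reference weight 1, which cannot distinguish the two conventions; the
triple product is the default because a triad count naturally involves
all three entries).  The matrix spans [0, 1902] cents per axis at 1-cent
resolution with the boundary padded by six kernel SDs, so smoothing
conserves total mass to < 1e-6 relative.

**Spectral entropy.** The pooled chord spectrum is binned on a 1-cent
grid, smoothed with the same Gaussian kernel, normalized to a probability
mass function x, and scored as H(x) = −Σ x_n·log2 x_n (bits; the base
only rescales and z-scoring removes it).

**Average pitch height** is the mean of the three MIDI pitches; its
square (squared *before* z-scoring) allows U-shaped pitch effects.  The
two z-scored columns correlate at ~0.999 over the stimulus set, so their
individual coefficients are weakly identified while their sum is sharp —
visible as wide, anti-correlated posteriors, exactly as in any analysis
that enters both terms raw.

**12-TET dissimilarity** is the minimal L1 pitch distance to any freely
transposed chord whose internal intervals are integer semitones.  For
each candidate integer pattern (roundings ±1 of the chord's intervals)
the optimal transposition is the median of the per-note targets; the
optimum of the piecewise-linear objective is attained there, which a
grid-plus-breakpoint search confirms to 1e-6.

**Kernel width.** The smoothing SD (shared by the expectation matrix and
the entropy) defaults to 10 cents, a mid-range value for complex-tone
pitch uncertainty.  Widths of ~6 cents leave the published ordinal
relation between the entropies of chords 0 9 10 and 0 8 11 inverted;
≥10 cents reproduces it, and the harmonicity ranking is insensitive over
6–15 cents.  Both the width and the 1-cent resolution are configurable.

Two caveats on the published feature tables: (a) the printed standardized
feature values are not bit-reproducible because the original roughness
model and kernel widths are unstated — this package treats them as
ordinal anchors only, and its Sethares column correlates ~0.9 with the
printed roughness values; (b) the printed tie in maximal harmonicity
between chords 0 6 10 and 0 3 5 cannot arise from the stated
construction (0 3 5's interval pair is ~25 cents from the nearest useful
harmonic triple, (17, 22, 26), at weight 1/9724, against 0 6 10 sitting
on (3, 5, 7) at weight 1/105), and the corresponding printed row
duplicates two of the reference chord's values exactly; we report
0 6 10 as the unique maximum.

## Synthetic ratings

The generator mirrors the regression model that will be fitted, so
parameter recovery is a well-posed calibration exercise:

* 60 participants (configurable) × 4 blocks × 66 trials; two blocks rate
  consonance (pleasantness), two valence (happiness), order randomized;
  each block is a permutation of the 66 patterns with a uniform random
  root 0–12 above a bass of MIDI 52.
* latent = intercept + Σ β_k x_k + g·(β_g + Σ γ_k x_k) + u_0j + Σ u_kj x_k
  + ρ·previous + ε, with x_k the six predictors z-scored over the
  design's trials, g the GMSI score centred at the published population
  mean 81.58 and scaled by the population SD (default 20; the population
  SD is not published), u_j a 7-dimensional participant effect drawn from
  a multivariate normal with per-effect SD 0.1 and exchangeable
  correlation 0.2, and ρ = 0.3 the carry-over on the previous response
  (zero at each block start).
* Default β/γ are the published posterior means of the consonance and
  valence models, e.g. Roughness −0.14 / −0.08, AveragePitch +0.15 /
  +0.40.  The GMSI main effect (reported directionally but without a
  printed value) defaults to +0.10.
* The latent value is mapped affinely from [−3, 3] onto the 700-point
  slider, rounded half-up and clipped; the recorded standardized rating
  is the quantized value mapped back, so an analyst can reconstruct
  exactly what the carry-over term used.
* Residual SD defaults to `"auto"`: σ² = (1−ρ²) − Var(signal), solved per
  response type so the total latent variance is ≈1.  This keeps the
  slider's standardized scale aligned with the generating coefficients —
  a fit of the mirrored model returns estimates directly comparable to
  the truth.  Under the default truths this yields a Bayesian R² of
  ≈0.33 for consonance and ≈0.65 for valence (the strong collinear pitch
  pair plus carry-over absorb more variance there).

What the generator does **not** emulate: ordinal/bounded response
behaviour beyond clipping, fatigue or attention drift beyond the single
carry-over term, absolute-pitch listeners, any acoustic rendering, and
real between-participant heterogeneity larger than the stated 0.1 SDs.
Passing recovery tests therefore demonstrate that the estimation
machinery is calibrated for data of this structure — not that the
published coefficients are correct for human listeners.

Known interaction of design choices: because the slider clips at ±3 and
the harmonicity predictor is heavy-tailed (a few chords carry most of its
identifying variation), harmonicity recovery attenuates by ~0.02–0.03
even at large n.  The roughness and pitch coefficients are unaffected.

## Hierarchical Bayesian models

All models share a Gaussian likelihood over z-scored slider ratings and
Student-t(3, 0, 2.5) priors on population effects (the intercept prior is
centred on the sample mean, brms-style).  Sampling is by a blocked Gibbs
sweep in which every conditional is exact:

* the Student-t prior is represented as a normal scale mixture with
  inverse-gamma mixing;
* participant effects u_j carry a multivariate normal with an
  inverse-Wishart prior on their covariance (ν₀ = q+2, scale set so the
  prior mean SD per effect is 0.5) — chosen over a half-t/LKJ
  factorization to keep the sweep fully conjugate; the SD scale is
  configurable;
* the residual variance carries an inverse-gamma(2, 1) prior.

Naively alternating fixed and group effects mixes slowly at small
participant counts (the random-effect means trade off against the fixed
effects, and — because GMSI is constant within participant — against the
GMSI interactions).  Each sweep therefore adds an interweaving step in
the centred parametrization v_j = u_j + M_j θ, jointly resampling the
duplicated fixed effects given the centred group effects.  With 2 chains
× (600 warmup + 2500 draws) the predictive model reaches split-R̂ ≤ 1.005
and bulk ESS ≳ 800 in ~10 s at 20 participants.  Fits raise a
`ConvergenceError` naming the offending parameters when any split-R̂
exceeds 1.01 (configurable; the published convergence statement "R̂ below
1" is read as the customary R̂ ≈ 1.00 since split-R̂ cannot fall below 1).

**Predictive model** — rating ~ six predictors + GMSI + six GMSI
interactions + previous response, with participant-varying intercept and
main-effect slopes (interaction slopes do not vary by default;
configurable).  The carry-over enters as a fixed covariate, the simplest
structure consistent with "autoregressive effects of each participant's
previous response".

**Descriptive model** — rating ~ chord factor (referenced to the BP
major chord 0 6 10) + average pitch + its square + carry-over, random
intercept; per-chord contrasts are reported with 50% and 95% intervals.

**Learning model** — rating ~ TrialNo + TrialNo² + ChordNo + ChordNo² +
carry-over, random intercept.  Quadratics square the *centred* counters
(raw squares correlate > .95 with the linear terms).  Note the block
design makes ChordNo itself nearly a coarse copy of TrialNo (each block
contains every chord once), so the two linear effects are intrinsically
hard to separate; recovery tests assert sign and interval coverage, not
interval exclusion of zero.

**Directed hypotheses.** For a parameter with posterior mass p in the
hypothesized direction the evidence ratio is p/(1−p) (∞ when all draws
agree), banded as none (<3), moderate (3–10), strong (10–30), very
strong (>30); the star marks one-sided 95% intervals excluding zero.
Tables are exported in the Estimate / Est.Error / CI / Evid.Ratio / Star
layout.

**Model comparison.** Chord-factor granularities (66 groups vs the
414 just-intonation items) are compared by PSIS-LOO (arviz) on pointwise
conditional log-likelihoods; results are reported as LOO-IC = −2·elpd
with the method recorded.  The per-parameter convergence gate is off by
default inside this comparison: the item-level model carries hundreds of
sparsely observed factor levels whose individual split-R̂ estimates are
noisy at the modest draw counts the comparison needs, while the LOO
aggregate is stable.

**Bayesian R²** is var(fitted)/(var(fitted)+σ²) averaged over draws,
with fitted values including group effects and the carry-over covariate.

## Problem sizes and reproducibility

Default test and acceptance problem sizes are chosen for a laptop-class
single core: recovery runs use 20 participants × 264 trials (the
published per-participant design at a third of the cohort), 20 replicate
simulations for interval-calibration checks, and 10 participants for the
LOO comparison.  All randomness flows from explicit integer seeds
(`numpy.random.SeedSequence`); identical configuration and seed give
byte-identical simulated datasets, and the pipeline manifest records
seeds, configuration, package version and content hashes of every data
artifact.

## Known limitations

* The original study's raw ratings are not public; nothing here estimates
  the published real-data coefficients — synthetic recovery is the only
  claim tested.
* The roughness model and smoothing widths of the original feature
  pipeline are unstated; printed standardized feature values are matched
  ordinally, not numerically.  The sign of the roughness–entropy
  correlation over the stimulus set is model-dependent and is left
  unasserted.
* The slider is modelled as a quantized, clipped Gaussian — not ordinal;
  this matches the original analysis choice, with the clipping caveat
  above.
* PSIS-LOO uses conditional (given participant effects) likelihoods, the
  same conditioning the original comparison used.
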