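# Methods

## Scope and data model

The package estimates how word length, frequency (negative log unigram
probability, bits) and surprisal (negative log conditional probability, bits)
shape three word-level fixation measures — First Fixation (FF), Gaze Duration
(GD) and Total Fixation (TF), all in ms — in native and non-native readers,
and how the resulting effect sizes depend on L2 proficiency.

Fixation measures are reduced from ordered event streams: FF is the duration
of the chronologically first fixation on the word; GD sums the maximal initial
run of consecutive fixations starting at that first fixation, ending at the
first departure to any other word; TF sums all fixations on the word within
the trial. This GD definition starts the first pass at the word's first
fixation regardless of whether material to its right was fixated earlier;
stricter first-pass dialects can be layered on top, but are not the default.
Blinks and track losses are assumed cleaned upstream.

Before modelling, word tokens are excluded in a fixed order (each removed
token is counted under the first rule that applies): sentence-initial/final
position, any punctuation character (Unicode categories P*, configurable),
any digit, out-of-vocabulary (absent from the frequency list by default; an
absent-from-LM hook and the union of both are available, since "OOV" can
reasonably mean either), and skipped (zero fixations of any kind by that
participant — no first-pass/ever-fixated distinction is made). Word *length*
strips punctuation characters but a punctuation-bearing token is excluded from
analysis anyway; the length function stays total (e.g. `"..."` has length 0
and is flagged).

## Additive models

Reading times are modelled with penalized additive Gaussian models. Univariate
smooths are cubic regression splines in the value-at-knot parameterization
with an integrated-squared-second-derivative penalty; knots sit at equally
spaced quantiles of the unique covariate values (robust to the skewed
surprisal/frequency distributions). k = 20 for current- and previous-word
property smooths (k = 10 for length, which has few distinct values; k is
automatically reduced with a warning when distinct values run out). Tensor
smooths are row-wise Kronecker products of k = 5 marginal spline bases with
one penalty per margin. Participant terms are ridge-penalized indicator
columns (random intercepts) and indicator-times-covariate columns (random
slopes; covariates standardized for conditioning), i.e. Gaussian random
effects. Every spline/tensor block carries one sum-to-zero constraint,
absorbed by reparameterization, so each partial effect is centered: its sum
over the fitted data is zero to ~1e-8.

Two model shapes are built in: a surprisal model — s(surp), s(surp_pr),
te(freq, len), te(freq_pr, len_pr), plus random intercept, random surprisal
slope, and a random slope on the freq·len product — and a frequency/length
model with univariate smooths for all six property terms plus random
intercept and per-property random slopes. Surprisal effect sizes are read
from the surprisal model and frequency/length effect sizes from the
frequency/length model (a config switch reuses the latter's s(surp) to halve
per-participant fitting cost).

### Smoothing-parameter selection

Smoothing parameters maximize the restricted likelihood (REML), iterated with
Fellner–Schall updates; generalized cross-validation is available as a config
switch (`criterion="gcv"`, simplex search on log smoothing parameters) and the
criterion used is recorded in the fit object. Numerical policy: smoothing
parameters live in [1e-9, 1e11]; update ratios are clipped to [1e-3, 1e3] and
square-root damped after 20 iterations; convergence is a relative criterion
change below 1e-6, with a cap of 200 outer iterations. Tensor blocks can have
a near-flat REML direction in the ratio of their two penalties; when the
criterion stops improving for 20 iterations the best point seen is accepted
(the fitted curves are insensitive to movement along such directions).
Genuine non-convergence raises an error carrying the last criterion value;
bootstrap replicates catch and count such failures (> 20% failed replicates
is an error). A fit with zero penalized residual sum of squares is guarded at
1e-300 before taking logs.

Oracle properties pinned by tests: with all smoothing parameters forced to 0
the fit equals unpenalized least squares on the same basis; forced to 1e10,
each second-derivative-penalized term collapses to a line; fitted values
decompose exactly into intercept plus per-term partial effects; linear
generative slopes are recovered within ±5% on 50,000 noiseless rows.

### Inference

The superlinearity test replaces the target property's current-word smooth
with standardized linear + quadratic columns (unpenalized) plus a
ridge-penalized per-participant random slope on the quadratic term — penalized
as its own block — and reports the Wald p-value of the fixed quadratic
coefficient against a normal reference, using the posterior covariance at the
selected smoothing parameters with scale RSS/(n − edf). The coefficient is
reported on the raw covariate scale (ms/unit²) so its sign is the curvature
sign. Whole-smooth significance (test m1 below) uses an approximate Wald
statistic on the term's coefficient block with a chi-square reference on the
term's effective degrees of freedom, rounded up — a simplification of the
reference tests reported by standard penalized-regression summaries.

Confidence bands are cluster bootstrap: participants resampled with
replacement (relabelled per replicate so random-effect structure is
preserved), model refitted, partial effect evaluated on a grid, pointwise
2.5/97.5 percentiles. Resampling whole participants matches the
random-effects dependence structure. Bands are deterministic given the seed.

## Effect sizes

A participant's slowdown for property p averages the fitted partial effect
over every retained corpus word's property value. Two conventions are
reconciled: fitted partial effects are *centered* (identifiability), while the
slowdown statistic treats a linear 5 ms/bit surprisal effect as contributing
30 ms at a 6-bit word, i.e. an effect *anchored at zero*. The slowdown
therefore evaluates s(x) − s(0). Property values outside a participant's
fitted covariate range (the corpus average runs over all words, not just that
participant's) are evaluated by linear extension of the boundary segment —
value plus first derivative at the boundary knot — and counted; for a linear
partial effect this keeps the closed form slowdown = slope × corpus mean
exact, which is verified to 1e-10 relative tolerance. The tradeoff difference
is computed row-by-row from the slowdown table, so Diff = Slowdown(freq) −
Slowdown(surp) holds exactly by construction.

Per-participant fits drop all random-effect terms and require a minimum of
200 retained rows (configurable); smaller participants are skipped and
logged. Group comparisons use Welch's unequal-variance t-test (group sizes
and variances differ between L1 and L2 samples) with across-participant
normal-approximation 95% intervals; frequency-vs-surprisal comparisons within
group use a paired t-test on per-participant values (identical columns return
t = 0 rather than 0/0).

## Proficiency analysis

MPT scores (integers 0–50) map to CEFR bands by the fixed lookup 0–16 A1,
17–21 A2, 22–31 B1, 32–36 B2, 37–50 C1 — a total monotone step function.
Native speakers enter the proficiency tests with MPT 50 but keep english = 1;
L2 participants who score 50 keep english = 0 (the indicator tests
nativeness, not score). The five shape tests are: m1 response ~ s(MPT)
(smooth-term test); m2 response ~ MPT + MPT² (quadratic t-test, OLS); m3
response ~ English + MPT on above-median-MPT participants (English term); m4
response ~ English + MPT + MPT² on everyone (English term); m5 response ~ MPT
on the above-median subset (slope). The median is computed over all
participants including L1-as-50 by default (`median_scope="l2"` restricts it),
and ties at the median are excluded from "above". All five tests are
deterministic given the records. The proficiency curve is a penalized spline
of response on MPT over L2 records only (k = 10), with a plain bootstrap over
records (these are participant-level summaries, one row each, so there is no
cluster structure) and the L1 mean with a normal CI as reference. The
percentage of correctly answered comprehension questions, rescaled to 0–50,
substitutes for the MPT in all of the above.

## Synthetic data

The generator supplies every statistical feature the pipeline assumes:

* **Corpus/LM.** A rank–frequency Zipf law with configurable exponent over a
  configurable vocabulary. Sentences are sampled from a bigram kernel that
  mixes, with weight 0.5, an independent unigram draw and a
  Metropolis–Hastings step over a random symmetric neighbor graph (degree
  ~20–40). Both component kernels leave the Zipf law invariant, so the
  stationary unigram marginal is exactly the target law (the law itself is
  the oracle for distributional tests), while the graph step gives
  conditional probabilities word-pair structure: surprisal varies between
  equal-frequency words, as in natural language, which keeps the s(surp) and
  s(freq) terms jointly identifiable. The true model implements the LM
  contract and is returned to callers; the emitted frequency table is the
  exact token count of the corpus.
* **Lengths.** Assigned per vocabulary item as round(0.5 + 0.6·nlf + ε),
  ε ~ N(0, 1.2²), clipped to [1, 15]. The jitter is deliberate: deterministic
  rounding yields a length–frequency correlation near 0.98, far above the
  ~0.6–0.7 of real lexicons, and makes the freq/len terms nearly collinear.
  With jitter the token-weighted correlation lands near 0.7–0.8.
* **Participants.** L1 participants carry MPT 50; L2 scores are drawn from a
  configurable distribution truncated to [0, 50]. Comprehension accuracy is
  tied to MPT (0.55 + 0.45·MPT/50 plus noise, clipped to [0, 1]). Random
  intercepts and per-property slopes are Gaussian with configurable SDs.
* **Reading times.** TF = 150 ms base + per-property polynomial effects
  (default linear: 5 ms/bit surprisal, 3 ms/bit frequency, 2 ms/char length)
  scaled by a proficiency amplitude, plus linear spillover from the previous
  word (1 / 0.5 / 0.5 ms per unit), the participant's random intercept and
  slopes, and Gaussian noise (SD 30 ms), truncated at 1 ms and rounded to
  integer ms. GD and FF are fractions of TF (0.6, 0.4) plus independent noise
  (SD 10, 8 ms), clamped so 1 ≤ FF ≤ GD ≤ TF — the analyses only require the
  inclusion ordering, so any generator honoring it suffices. A configurable
  proportion of words (default 10%) is skipped. The proficiency amplitude is
  1 + u_scale·4t(1−t) with t = MPT/50 — an inverted U peaking at MPT 25 —
  with u_scale = 0 (off) by default and 0.5 in the study preset, which gives
  the U-shaped proficiency–effect-size relation the proficiency tests are
  powered against, and makes top-proficiency L2 readers match L1 (amplitude
  1), as the m3/m4 nulls assume.
* **Events.** A measures table is realized as an event stream by a first pass
  (FF, then GD − FF when positive) over fixated words left to right, then
  revisits (TF − GD) in ascending order. The trial's last *fixated* word is
  generated with GD = TF (no late revisit): a revisit appended directly after
  that word's first-pass run would merge with it under the gaze-duration
  definition and make the triple unrealizable. Re-running the measures
  reduction on the events recovers every FF/GD/TF exactly (integer ms make
  the round trip bit-exact).

What the generator does *not* emulate: saccade landing positions and
regression paths, within-sentence syntactic structure (the bigram kernel has
no grammar), word-position effects beyond spillover, sub-word tokenization
(whole words are tokens), refixation strategy differences between groups, and
any dependence of skipping on word properties (skips are uniform). Passing
tests therefore show the *pipeline* is correct under the assumed generative
structure — effects faithfully recovered, tests calibrated — not that real
reading data satisfies that structure.

## Sample-size simulation

The reader's subjective language model is estimated from an n-token sample of
the true model (unigram + bigram counts, additive smoothing; the default is
smoothing 0 *plus exclusion*: tokens involving zero-count events in the
reference, small, or large corpora are dropped before analysis). Reading
times are strictly linear in the subjective property — the question is
whether sample size alone creates apparent nonlinearity, so the generative
truth must be linear. The analysis regresses the simulated reading times on
large-corpus property estimates with linear and quadratic terms (mimicking
the real pipeline, whose annotations come from far more text than any reader
has seen) and reports apparent slope, curvature with CI, and the
anchored-at-zero mean slowdown per learning size, aggregated over replicates
with Monte-Carlo standard errors. The convexity argument — for mean-unbiased
subjective probabilities x, E[−log2 x] ≥ −log2 E[x], strictly under positive
variance — is verified by Monte Carlo with Dirichlet(c·p) draws, which are
mean-unbiased by construction; concentrations 10/50/200 span noisy to
near-exact estimators. Default condition grid (an artifact choice; fully
configurable): learning sizes 500–100,000 tokens, large corpus 100,000,
reading corpus 8,000, slope 5 ms/bit, noise 20 ms, 20 replicates.

## Problem sizes used by the test suite

Monte-Carlo suites run at sizes chosen to give stable verdicts: the
superlinearity type-I study uses 500 datasets of 5,000 rows (20 participants)
against the binomial band [0.03, 0.08] at α = 0.05, with power (≥ 0.9) and
curvature-sign agreement (≥ 95%) at 100 datasets under 1 ms/bit² curvature;
full-pipeline recovery uses 50 participants × ~1,000 retained words with ±10%
slope tolerance; proficiency-test calibration and power use 500 simulations
of 300 participants; bootstrap coverage is spot-checked at 25 datasets ×
B = 49. Deterministic identities (worked example, closed forms, CEFR lookup,
fixation fixtures) are asserted at machine-level tolerances.

## Known limitations

* The REML optimizer is first-order (Fellner–Schall); on near-flat tensor
  directions it accepts the best stalled point rather than polishing to the
  exact optimum. No claim of numerical agreement with any external additive-
  model implementation is made — correctness is defined by the oracle and
  invariance tests above.
* The m1 smooth-term test is approximate (chi-square on rounded-up edf);
  calibration guarantees are only asserted for the OLS-based m2.
* The bootstrap is percentile-only; no studentization or bias correction.
* With unsmoothed subjective estimates, heavy zero-count exclusion at small
  learning sizes changes the analysed token population — apparent-slope
  trends across learning sizes partly reflect that selection, which is the
  phenomenon under study, but comparisons across sizes are not
  equal-population.
* Out-of-range evaluation in the slowdown statistic is a linear extension of
  the boundary segment; for strongly curved partial effects the extension is
  a first-order approximation.
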