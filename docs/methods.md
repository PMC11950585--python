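# Methods

## Monitoring model

`spcdrift` treats a deployed imaging model's *input stream* as an industrial
process to be kept in statistical control. The monitored quantity is never
the image itself but a geometric score of its embedding:

1. a feature extractor maps each image to a vector;
2. an in-distribution **reference profile** is fitted once: the mean feature
   vector μ⃗, the sample covariance **S** (plus a small ridge, below), and the
   mean μ / standard deviation σ of the chosen metric over the reference
   images themselves;
3. each test embedding is scored by cosine similarity to μ⃗ or by Mahalanobis
   distance under **S**;
4. SPC charts turn scores into decisions: a per-image 3σ chart for
   individual OOD detection, and a CUSUM chart over daily mean scores for
   drift detection.

Assumptions worth stating: the reference sample is itself clean and large
enough for μ, σ to be stable (≥ a few hundred images in practice; the fitter
refuses n < 2 and degenerate σ = 0); embeddings are finite and nonzero (a
zero vector raises rather than scoring 0 — it signals an extractor fault);
the per-image metric values are approximately i.i.d. within the in-control
period. Mahalanobis additionally assumes an approximately elliptical
reference cloud. Cosine similarity is scale-free and needs no covariance;
under drift it moves *down*, Mahalanobis moves *up*; charts are two-sided
and the report annotates the alarm side, so both directions are covered
without a one-sided default.

## Chart parameters

| parameter | meaning | default | why |
| --- | --- | --- | --- |
| multiplier | control-limit half-width, in σ | 3 | classical 3σ rule: 0.27% in-control flag rate |
| k | CUSUM allowance per step | σ/2 | standard choice, optimal-ish for detecting ~1σ mean shifts |
| h | CUSUM decision interval | 4σ | standard companion to k = σ/2 |
| regularization | ridge added to **S** | 10⁻⁶·tr(**S**)/p | guarantees a solvable system when n ≤ p without moving large eigenvalues |

Boundary values exactly on a control limit are **in control** (flags require
strict exceedance). The CUSUM state is not reset after an alarm; every
alarmed day is reported, so a sustained shift keeps signalling and a single
spurious crossing is visible as such. The low-side alarm uses |S⁻| > h,
since S⁻ is by construction non-positive.

**σ-scale convention.** The CUSUM runs on daily means, whose in-control
standard deviation is σ/√d for batches of d images. The default
(`sigma_scale="per-image"`) nevertheless expresses k and h in units of the
*per-image* σ. This is deliberate: the monitored stream is assumed to carry
a small nominal OOD trickle even in its in-control phase (0–1% per day in
the bundled scenarios), which shifts the daily mean by a fraction of the
per-image σ. An allowance of σ/2 per-image units swallows that trickle, so
the chart is quiet until the rate genuinely shifts; a textbook daily-mean
CUSUM (k = σ/(2√d), available as `sigma_scale="daily-mean"`) has an
in-control ARL of only ≈ 240 steps two-sided and would false-alarm on a
substantial fraction of 60-day horizons even without the trickle. With the
per-image convention a 3→5% rate shift still moves the daily mean by several
h per week, so detection is delayed by only a day or two.

The daily-mean 3σ chart reuses the per-image limits by default, which makes
it deliberately insensitive — daily averaging obscures few-percent
contamination, the observation that motivates CUSUM; √d-tightened limits are
opt-in (`tightened_daily_limits`).

## Synthetic scenario generator

The generator emulates a monitored hospital stream at the *embedding* level:
ID and OOD images become draws from diagonal Gaussian clusters. The bundled
presets use 8-dimensional features, the ID cluster at 4.2·(1,…,1) with unit
scale and the OOD cluster at the same radius in an orthogonal
(alternating-sign) direction. This geometry was chosen so that the
per-image cosine spread is ≈ 1.3% of the ID–OOD similarity gap — the
strong-separation regime a well-trained contrastive encoder produces —
which simultaneously makes per-image 3σ detection near-certain, keeps the
0–1% nominal trickle inside the CUSUM allowance, and yields a one-to-two-day
detection delay for a 3→5% rate shift. Streams are day-indexed: each day
draws its OOD rate uniformly from the active phase's interval, converts it
to a count by round-half-to-even (unbiased over uniform rates; a per-image
Bernoulli option exists), picks the subtype uniformly when several OOD
clusters are given, and shuffles within the day. Seeding is hierarchical
(scenario seed → per-day child seeds), so day k's batch is invariant to
every other day's parameters.

What the generator does **not** emulate: anatomy, scanner physics,
encoder-induced correlations between images, slow covariate shift within a
phase, or heavy-tailed embedding noise. Passing tests therefore demonstrate
the correctness and calibration of the charting machinery under its stated
assumptions, not clinical performance on real streams.

The toy *image* generator (for exercising the extractor pipeline end to
end) produces noisy centered discs; OOD images additionally carry one faint
Gaussian blob on a background annulus. The blob is a deliberately
low-variance cue: global intensity and co-occurrence statistics move only
slightly (the statistics baseline separates the classes above chance but
poorly), an unsupervised autoencoder largely ignores it (reconstructing it
buys little loss), while label-supervised encoders learn it — reproducing
the characteristic ranking in which supervised/contrastive features
dominate, and the autoencoder shows near-zero sensitivity at near-perfect
specificity. An earlier disc-vs-stripe design was discarded because texture
statistics alone separated the kinds almost perfectly, leaving nothing for
learned features to add.

## Feature extractors

The framework is encoder-agnostic; the bundled extractors are small *dense*
networks sized for CPU fits on 28×28 toys:

- **stats_baseline** — mean, std, skewness, kurtosis plus 8 co-occurrence
  texture summaries (contrast/homogeneity/energy/correlation at distance 1,
  horizontal and vertical). Skewness/kurtosis of a constant image are 0 by
  convention, so a blank frame cannot inject NaN into control limits. Scored
  with Mahalanobis downstream: its axes have incomparable units, which
  cosine would conflate.
- **autoencoder** — 64→32→64 ReLU bottleneck regressor; the 32-dim
  bottleneck is the embedding; fitted unsupervised.
- **supervised_bce** — 64→32 ReLU classifier under binary cross-entropy;
  embedding from the penultimate layer by default, logits optional.
- **contrastive** — one tanh hidden layer, linear 32-dim output, trained
  with the pairwise margin loss (same-label pairs pulled by d², different-
  label pairs pushed by max(0, m−d)², margin m = 1) via minibatch Adam with
  manual backprop; deterministic given its seed.

Training budgets in the bundled comparison are per-mode (autoencoder 30,
BCE 60, contrastive 20 epochs): the classifier needs the longest schedule to
pick up the subtle cue, while the contrastive net converges fast and can
collapse if driven much longer.

## Evaluation protocol

Sensitivity = flagged OOD / total OOD; specificity = unflagged ID / total
ID. Confidence intervals are percentile bootstrap (2.5/97.5) over replicates
drawn uniformly **with replacement** (n = 100 subsets of size m = 500 by
default); a replicate missing a truth class is redrawn and counted, with a
10× attempt cap. Scenario sweeps share the generated streams across all k
settings (a paired design), so the monotone false-alarm/delay trade-off is
not blurred by between-setting sampling noise. Detection delay is (first
alarm day ≥ shift day) − shift day; earlier alarms are reported separately
as false alarms.

## Numerical choices and degenerate inputs

- Mahalanobis is computed through a cached Cholesky factorization of the
  regularized covariance; no explicit inverse is formed.
- Cosine outputs are clipped to [−1, 1] to absorb last-ulp rounding.
- Reference metric μ/σ are computed on the fitting split itself (σ via the
  n−1 sample estimator); identical reference metrics (σ = 0) raise a
  degenerate-profile error, since control limits would be undefined.
- A day with zero records raises a gap error unless the stream is declared
  sparse; daily batch size for √d conversions is the median per-day count.
- A constant stream of *perfect* scores (every image exactly at the
  reference mean) produces zero 3σ flags but is itself an upward mean shift
  in cosine, which the two-sided CUSUM may legitimately flag high-side; the
  report's side annotation distinguishes this from drift, which for cosine
  is low-side.

## Problem sizes

Simulation-based checks use 60-day × 100-image streams with 8-dim features:
200 replicates for in-control and drift-delay estimates, 100 per setting for
the rate-monotonicity and allowance sweeps, 10⁶ draws for 3σ calibration,
10⁴ for reference recovery. The toy-image comparison trains on 400 images
per class and evaluates on 300 + 300. These sizes put Monte-Carlo error
comfortably below the margins being asserted while keeping a full run in
minutes on one CPU.

## Known limitations

- Alarms localize *when* the stream changed, not *why*; root-cause
  attribution is out of scope.
- The reference profile is static; no recalibration or retraining logic.
- Dense toy encoders are not translation-invariant, so cues at arbitrary
  positions (as a convolutional encoder would handle) are outside their
  reach; the toy task is constructed accordingly.
- Single-metric charts; no multivariate CUSUM or EWMA variants.
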