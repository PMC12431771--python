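# Methods

This note records the scientific and numerical choices behind `sfcode`:
what each stage assumes, which parameters matter, and where a convention
had to be picked among defensible alternatives.

## Stimulus construction

**Band-pass filter.**  Isotropic Butterworth band-pass in the 2-D Fourier
domain: the gain at radial frequency *r* (cycles per image, Euclidean
distance from DC in FFT index units) is the product of a low-pass factor
with cutoff at the upper band edge `f_hi` and a high-pass factor with
cutoff at the lower edge `f_lo`,

    B(r) = [1 + (r/f_hi)^2n]^-1 · [1 + (f_lo/r)^2n]^-1 .

The cutoffs are treated as the two half-power (−3 dB per factor)
Butterworth cutoffs of the printed pass-bands (1–5, 5–10, 10–18, 18–45,
45–75 cycles/image).  The order is not dictated by the experimental
design; the default `n = 4` keeps the five bands nearly disjoint at these
edges without ringing, and is exposed on `BandSpec` and the config.  The
high-pass factor vanishes at DC, so every filtered image is zero-mean
before re-normalization.  Filtering is exactly linear; a pure grating is
attenuated by the scalar gain at its frequency (both are tested).

**Phase scrambling.**  Fourier amplitudes are kept and phases replaced by
the phases of the FFT of a white-noise field.  Those phases are conjugate-
symmetric by construction, so the inverse transform is real to float
precision; the real part is extracted regardless (harmless, and robust if
a caller supplies non-symmetric phases).  The DC phase is preserved so the
image mean survives.  Scrambling therefore preserves the amplitude
spectrum exactly and the total spectral power to well under 1%.

**Moment equalization.**  The final step of every variant is the linear
map `C·(I − μ)/σ + L` with defaults `L = 0.5`, `C = 0.0314` (128 and 8 on
a 0–255 scale).  Because it is applied last, mean and contrast are equal
across bands, categories, and scrambling *by construction* — the tests
assert agreement to 1e−6.  Since the map fixes the spatial variance, total
AC power is also equalized (Parseval); an optional per-band power rescale
before this step exists for bookkeeping but is off by default.  Pixels may
leave [0, 1] after equalization; they are not clipped by default because
clipping would distort the moments.  Constant inputs raise a
`DegenerateImageError`.

**Set structure.**  Each base image yields 12 records (intact + R1–R5,
each with a scrambled sibling built by scrambling once, then filtering),
so 15 bases give 180 stimuli.  Base images can come from disk (8-bit
grayscale PNG) or from the built-in generator of 1/f-spectrum noise
textures — synthetic stand-ins with broadband content in all five bands,
labelled face / nonface / selective in the standard 6/3/6 proportion.

## Synthetic spike trains

No generative model of IT dynamics accompanies this paradigm, so the
simulator is an explicit stand-in, built to exhibit the statistical
structure the analyses are designed to detect — and nothing else.  Its
limitations are as important as its features: neurons are conditionally
independent given the stimulus (no noise correlations — which makes the
CMI independence null exact), spiking is Poisson (Fano ≈ 1), and there is
no adaptation, eye-movement, or attention structure.  Passing tests on
this generator demonstrate correctness of the estimators, not biological
claims.

* **Tuning profiles.**  Band-gain templates with ≥ 2:1 max/min contrast:
  LP strictly decreasing, HP strictly increasing, U with an interior
  minimum, IU an interior maximum, flat equal.  The default mixture (LP
  0.25, HP 0.06, U 0.34, IU 0.16, flat 0.19) makes U the largest and HP
  the smallest group, the qualitative composition reported for IT; the
  exact percentages are configuration, not ground truth.
* **Low-SF bias.**  A population-level multiplicative band bias
  (1.30…0.85 from R1 to R5) applied to non-flat profiles gives the
  population its low-SF-preferred average tuning.  Flat neurons are
  exempt: biasing them would contradict their defining invariant.
* **Latency gradient.**  Response latencies rise with band index
  (70, 76, 82, 88, 98 ms), carrying the coarse-to-fine property into the
  decoding onsets.
* **Temporal kernel.**  Difference of exponentials (rise 10 ms, decay
  60 ms, peak normalized to 1), placing the PSTH peak inside 70–170 ms.
  HP and U neurons get a second lobe delayed 130 ms whose amplitude ramps
  from 0 at R1 to half the response gain at R5; this late high-SF drive
  produces the late shift of the population's preferred SF toward high
  frequencies.  It is a modeling device, not a measured mechanism.
* **Category gain.**  A lognormal face gain per neuron (σ = 0.3), median
  shifted up for HP (+0.25 log units) and LP (+0.15) and down for IU
  (−0.15), applied only to unscrambled face stimuli.  This yields
  decodable category structure whose relation to SF profiles mirrors the
  qualitative finding that high-SF-preferring neurons carry the most face
  information.
* **Trial noise.**  A mean-one lognormal gain (σ = 0.2) per neuron-trial
  makes split-half consistency analyses non-trivial.
* **Sampling.**  Fine-bin (1 ms) Poisson sampling of the rate function
  over the −200…500 ms epoch; 15 blocks with every stimulus once per
  block in random order (33 ms stimulus, 465 ms blank).

## Response representation

Rates are counted in half-open 50-ms windows `[t−25, t+25)` stepped every
5 ms (the half-open convention avoids double counting; a dialect choice).
The responsiveness screen is a one-sided Wilcoxon signed-rank test of the
70–170 ms window mean against the −50…50 ms baseline mean across trials at
α = 0.05 — one-sided because the criterion is an *increase*.  Its null
false-positive rate is verified at α on 1000 simulated baseline-only
neurons.  Z-scoring uses the baseline epoch's across-trial mean and SD per
neuron (the whole-trial alternative is supported but not default); zero-SD
neurons are excluded with a log entry.  PSTHs are Gaussian-smoothed
(SD 20 ms) with edge-renormalized kernel mass.

## Decoding

LDA with shared within-class covariance.  With up to ~266 neurons and at
most a few thousand trials the empirical covariance is fragile, so
Ledoit–Wolf shrinkage is the default (`shrinkage=None` restores plain LDA
and raises an instructive error when the covariance is singular).
Resampling is leave-p-out: stratified random 30% test splits, 1000 runs at
full scale (reduced in desk-scale configs), class balancing by downsampling
to the minority class for category tasks (bands are balanced by design).
Single-neuron (1-D) decoding uses an exact closed-form specialization of
the same decision rule — pooled variance, class means, empirical
log-priors — verified against the matrix solver.

Onset detection: threshold = mean + 1 SD of the average trace over
−50…50 ms; a window counts as significant when fewer than 5% of runs fall
at or below the threshold; the onset is the first of five consecutive
significant windows.  Single-neuron inclusion uses the analogous
three-consecutive-window rule against the chance level.  "Significantly
greater" is deliberately made precise as the empirical run-distribution
criterion; the resampled runs are not independent samples, so these
p-values are calibration devices rather than exact test sizes.

## SF-tuning statistics

Preferred SF uses coefficients (−2, −1, 0, 1, 2) over mean band rates;
it is scale-invariant and bounded by the extreme coefficients for
non-negative rates (undefined, and flagged, when the rates sum to zero —
raw rates, not z-scores, are the intended input).

The profile classifier fits a quadratic to per-trial responses against
band *index* 1..5 (ordinal coordinate — the group definitions are stated
in band units, not cycles/image).  Vertex in [2, 4] with non-negligible
curvature (|a| ≥ 1e−8 × response scale) routes to the interior group,
where the band nearest the vertex is compared against R1 and R5
(one-sided signed-rank on per-block means): below both → U, above both →
IU.  Otherwise the monotone group compares pooled {R1, R2} against
{R4, R5}: greater → LP, smaller → HP.  Failures of all tests → flat.
Two deliberate readings are built in: the interior comparison uses the
band nearest the fitted vertex rather than a fixed middle band, and U is
the shape whose *middle* response is lower (matching the shapes' verbal
definitions).  Per-trial fitting is the default; fitting band means is a
one-line change at the call site.  On simulated populations with ≥ 2:1
gain contrast and ≥ 15 trials per band, ≥ 80% of non-flat neurons recover
their generative label; on label-free noise the false non-flat rate is
governed by the signed-rank test sizes (checked empirically in the suite).

## Population-coding metrics

* **SI.**  Within-class scatter is the centered outer-product sum
  Σ(r−μ)(r−μ)ᵀ per class; between-class scatter is n-weighted over
  centroids.  The matrix norm is Frobenius by default (defined for
  singular scatters; spectral available by flag).  The implementation is
  property-tested against an explicit double-loop oracle.
* **SNC.**  Leave-one-neuron-out accuracy drop in percentage points, with
  the train/test splits *shared* across all leave-outs (variance
  reduction; deterministic given the seed).  Drops can be negative and do
  not sum to anything meaningful — non-additivity is expected.
* **CMI.**  Plug-in estimator on 10 uniform bins per neuron spanning that
  neuron's observed range (per-neuron edges are a dialect choice vs
  global edges; constant neurons collapse to one bin and contribute 0).
  The shuffle correction permutes one neuron within label strata and
  subtracts the mean over shuffles; corrected values are reported as the
  default, and any cross-condition additive re-centering is left to a
  separate reporting step because it does not change the estimator.  The
  plug-in estimate is biased upward at small samples (a warning fires
  below ~10 samples/bin on average); bias-corrected estimators are out of
  scope.
* **Sparseness.**  `1 − E(|w|)²/E(w²)` over per-neuron decoder weights
  fitted on z-scored inputs; bounds [0, 1−1/N] and scale invariance are
  property-tested.  The SF task is the binary LSF (R1∪R2) vs HSF (R4∪R5)
  contrast on scrambled trials; category is face vs nonface on intact
  trials.

## Empirical statistics

For run distributions, the one-sided p-value for `x > y` is the fraction
of runs with `x − y < 0`; ties count against significance by default
(`ties="strict"` restores the literal count), and `r = 0` is censored at
`1/M`.  FDR adjustment is Benjamini–Hochberg via statsmodels.

## Problem sizes and reproducibility

The pipeline's default configuration runs 80 neurons, 15 blocks, and 200
resampling runs (50 for time courses) — a deliberate desk-scale setting
that completes in minutes on one core while preserving every qualitative
effect; a full-scale run is the same config with `n_neurons=266` and
`runs=1000`.  Every random draw flows from a single integer seed through
`numpy.random.Generator`; identical configs produce byte-identical
tables, and the output directory records the config hash alongside every
table.

## Known limitations

The recorded dataset this kind of analysis targets is not distributed, so
the package's quantitative claims are about its own estimators and
simulator, never about cortex: headline magnitudes from in-vivo studies
(peak accuracies, exact onset times, profile percentages) are qualitative
references only.  The simulator omits noise correlations, non-Poisson
variability, and any image-computable response model (responses depend on
the stimulus' condition labels, not its pixels).  The CNN comparison that
sometimes accompanies this paradigm requires pretrained external models
and is out of scope.
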