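# sfcode

Analyses of **spatial-frequency (SF) coding in high-level visual cortex**
from spiking data.  The package is written for electrophysiologists and
computational neuroscientists who present band-pass-filtered, phase-
scrambled images to a subject while recording single neurons (e.g. in
inferior temporal cortex), and who want to quantify how the population
encodes SF, how that code unfolds in time, and how it relates to category
coding.

Because such recordings are rarely public, the package ships a first-class
synthetic-data generator: inhomogeneous-Poisson neurons with SF tuning
profiles, SF-graded response latencies, and category gains.  Every analysis
is exercised end-to-end against simulations whose ground truth is known.

## What it computes

**Stimuli.** Each base image yields 12 variants: intact, five isotropic
Butterworth band-pass versions R1–R5 (pass-bands 1–5, 5–10, 10–18, 18–45,
45–75 cycles/image), and a phase-scrambled counterpart of each.  The
band-pass gain at radial frequency *r* is

    B(r) = 1/(1 + (r/f_hi)^2n) · 1/(1 + (f_lo/r)^2n),      n = 4 by default

and every variant is brought to common moments by the linear map
*I*ₙₒᵣₘ = C·(I − μ)/σ + L with L = 0.5, C = 0.0314, so luminance and
contrast cannot confound SF.

**Responses.** Spike times become a neurons × trials × time tensor of
50-ms sliding-window rates (5-ms step), optionally z-scored against the
−50…50 ms baseline; a Wilcoxon signed-rank screen keeps visually responsive
neurons.

**Decoding.** Linear discriminant analysis (shared within-class
covariance, Ledoit–Wolf shrinkage) with leave-p-out resampling (30% test,
stratified, optional class balancing), per-class recall, decoding time
courses, and onset detection (baseline mean + 1 SD, five consecutive
significant windows).

**SF tuning.** Preferred SF `PSF = Σ f_Ri·c_Ri / Σ f_Ri` with coefficients
c = (−2, −1, 0, 1, 2); ANOVA-gated dominant band; SF profile labels
(LP, HP, U, IU, flat) from a quadratic fit over band index plus signed-rank
shape tests.

**Population structure.** Separability index `SI = ‖S_B‖/‖S_W‖` (between/
within scatter, Frobenius norm); single-neuron contribution (accuracy drop
under leave-one-neuron-out with shared splits); conditional mutual
information between neuron pairs given the label (10-bin plug-in estimate,
shuffle-corrected); decoder-weight sparseness `S = 1 − E(|w|)²/E(w²)`.

**Statistics.** Empirical run-distribution p-values (`p = r/M`, censored
at 1/M) for resampled quantities, plus Benjamini–Hochberg FDR.

## Worked example

```python
import numpy as np
from sfcode import simdata, responses, decoding, sfmetrics

rng = np.random.default_rng(0)
population = simdata.make_population(40, rng=rng)
stimuli = simdata.make_stimulus_manifest(
    n_base=15, include_intact=False, include_unscrambled=False
)
session = simdata.simulate_session(
    population, stimuli, simdata.SessionSpec(n_blocks=15), rng
)
tensor = responses.bin_rates(session)          # 50-ms window, 5-ms step
ztensor, _ = responses.zscore(tensor)

X = ztensor.window_mean(70, 170)               # trials x neurons at T1
y = ztensor.manifest["band"].to_numpy()
cv = decoding.decode_cv(X, y, runs=200, rng=rng)
print(f"five-way band accuracy: {cv.mean_accuracy:.3f} (chance 0.2)")
for band, recall in zip(cv.classes, cv.mean_recalls):
    print(f"  recall {band}: {recall:.2f}")

profiles = sfmetrics.classify_population_profiles(tensor)
print("profile counts:", profiles["label"].value_counts().to_dict())
```

Output:

```
five-way band accuracy: 0.618 (chance 0.2)
  recall R1: 0.89
  recall R2: 0.55
  recall R3: 0.60
  recall R4: 0.38
  recall R5: 0.66
profile counts: {'U': 11, 'LP': 10, 'flat': 9, 'IU': 8, 'HP': 2}
```

A 40-neuron simulated population decodes the five bands far above the 0.2
chance level; recall is highest for the lowest band (the generator's
low-SF bias plus shorter low-SF latencies — the coarse-to-fine signature),
and the profile classifier recovers the mixture of tuning shapes the
population was built from.

The same analyses run from the shell:

```bash
sfcode build-stimuli --n-base 15 --seed 1 --out stimuli/
sfcode all --seed 1 --out run1/        # simulate + every analysis as CSV
```

## Layout

```
src/sfcode/
  stimgen.py        # filters, phase scrambling, moment equalization
  simdata.py        # synthetic populations and Poisson sessions
  responses.py      # rate tensors, PSTH, z-score, responsiveness screen
  decoding.py       # LDA, leave-p-out CV, onsets, sub-populations
  sfmetrics.py      # preferred SF, dominant band, SF profiles
  codingmetrics.py  # SI, SNC, CMI, weight sparseness
  stats.py          # empirical p-values, FDR
  pipeline.py       # configured end-to-end runs
  cli.py            # `sfcode` command
```

See `docs/methods.md` for the modeling assumptions, parameter defaults,
and numerical conventions.
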