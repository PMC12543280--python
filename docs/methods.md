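# Methods

## The measurement and its model

A SiMPull stoichiometry experiment asks how many labeled prey subunits
(far-red channel) accompany one bait molecule (green channel) in an
immobilized complex. Under continuous excitation every fluorophore bleaches
irreversibly, so a spot's intensity trace is a descending staircase and the
number of downward steps estimates the number of labeled subunits. Two
systematic effects bias the raw step count low: incomplete dye labeling
(only a fraction *p* of tag sites carry a functional fluorophore) and
finite observation (a fluorophore that outlives the acquisition, or two
fluorophores bleaching within the temporal resolution, contribute fewer
countable steps).

The synthetic generator (`smstoich.simulate`) encodes exactly this model:

- true far-red copy number *n* per complex ~ `copy_number_dist`;
- labeled copies ~ Binomial(*n*, `labeling_prob`), independent per
  fluorophore (thinning);
- per-fluorophore bleach times i.i.d. exponential with channel half-time
  t½ (survival 2^(−t/t½));
- trace value at frame *f*: `baseline + step_height · survivors(f·dt) +
  N(0, noise_sd)`, fixed length `frames`.

Not modeled, by design: blinking and other dye photophysics,
partial-frame bleaching, drift, uneven illumination, non-Gaussian camera
noise, and any biological variance between replicates beyond sampling
(biological replicates differ only through finite counts). Passing tests
therefore demonstrate correctness of the analysis chain under this
idealization, not robustness to every artifact of real TIRF data.

## Default parameters

| parameter | default | rationale |
|---|---|---|
| `frames`, `frame_interval` | 1000, 0.05 s | 50 s at 20 frames/s, the acquisition this pipeline targets |
| `farred_half_time` | 10 s (T/5) | laser powers tuned so far-red bleaches with t½ ≈ 1/5 of imaging time |
| `green_half_time` | 5 s (T/10) | green t½ ≈ 1/10 of imaging time |
| `labeling_prob` | 0.4 | HaloTag/JF-dye labeling efficiency ≈ 40% |
| `step_height`, `noise_sd` | 50, 10 counts | raw count scales are instrument-specific and unpublished; chosen so one step is unambiguous against noise (SNR 5), a step clears the 25-count rubric threshold, and the plateau-variability rejection rule (pooled SD > 12.5 counts) does not fire on clean traces |
| `baseline` | 100 counts | arbitrary camera offset |
| `copy_number_dist` | {1: 0.229, 3: 0.771} | two-point mixture solved analytically so the *post-thinning observed* multimeric fraction is 0.39 at p = 0.4, the wild-type measurement; `copy_mixture_for_multimeric_fraction` does the algebra for any target |
| `green_labeling_prob` | 1.0 | the bait tag is a fluorescent protein, not a dye; the 40% dye efficiency must not thin the green channel |
| `n_bio`, `n_tech`, `spots_per_field` | 10, 7, 200 | the replicate structure of the quantified experiments |
| `psf_sd` | 1.2 px | diffraction-limited spot at typical pixel sampling |

With these defaults the step rubric rejects ≈ 33% of far-red traces
(dominated by complexes with zero labeled copies), bracketing the ≈ 42%
rejection rate of the manually labeled corpus; the real corpus adds
rejection modes (focus drift, aggregates) the generator does not emulate.

## Step-counting rubric (`smstoich.stepcount`)

Manual annotation is operationalized deterministically so it can label
synthetic training data and serve as an independent oracle for the CNNs:

1. **Segmentation** — recursive binary mean-shift segmentation; a split is
   accepted when both plateaus span ≥ `min_plateau_frames` (default 5,
   i.e. 0.25 s: "sustained") and the plateau mean difference exceeds
   `max(min_amplitude, 4·σ̂)`, with σ̂ a robust noise estimate from the
   median absolute first difference. The 4σ̂ term keeps a flat pure-noise
   trace at zero changepoints.
2. **Counting** — walk plateaus in time order; each mean decrease
   > 25 counts is one step; the first mean *increase* > 25 counts stops
   counting (`stopped_early`).
3. **Rejection** — no steps counted, or pooled within-plateau SD
   > 12.5 counts (half the step threshold: a step smaller than ~2 SD is not
   visually discrete).
4. **Binning** — far-red: 0 → rejected, 1, 2, ≥3 → `3plus`; green: exactly
   one event → `1-step`, otherwise rejected.

Thresholds act on raw counts; a trace that is already Z-scored
(mean ≈ 0, SD ≈ 1) is refused. The rubric is a stated operationalization
of visual counting, not a claim of equivalence to human annotators;
against generative ground truth (excluding unresolvable coincident-bleach
traces) it agrees ≥ 99% at noise = step/5.

## Classifiers (`smstoich.cnn`)

The two CNNs are implemented directly in numpy (`smstoich.nn`): conv
blocks (valid 1-D convolution → ReLU → non-overlapping max pool of 4), an
average-pooling head that reduces the time axis to ~32 bins, dense layers,
and a softmax. Training uses Adam on inverse-class-frequency-weighted
cross entropy (`w_c = N/(K·n_c)`, mean weight 1 — any positive rescaling
is loss-equivalent), fixed epoch budget, no early stopping. All
randomness (initialization, batch order, splits, folds) flows through the
config seed, giving bit-identical runs on the same platform; across BLAS
builds exact floating-point equality is not promised, so statistical
tests use tolerance bands.

The search protocol mirrors the development procedure: every candidate in
a declarative grid (default: kernel ∈ {5, 15, 31} × filters ∈ {8, 16} ×
dense ∈ {(32,), (64, 32)}) is trained on a stratified randomized 80/20
split and ranked by validation accuracy; the top five are re-scored by
stratified 5-fold cross-validation; the final pick maximizes CV mean
accuracy, then mean macro-F1. Splits are per-trace; grouped splitting by
replicate is available through the dataset metadata for leakage-sensitive
uses. Variable-length traces are rejected rather than padded — the
acquisition fixes L = 1000.

## Quantification and statistics (`smstoich.stats`)

A spot pair is analyzable iff its green trace is `1-step` and its far-red
trace is not rejected. Class percentages are computed per technical
replicate over {1-step, 2-step, 3plus}; the multimeric percentage is
2-step% + 3plus%. Each biological replicate is the **unweighted** mean of
its technical replicates (spot-count weighting is a caller-side option:
aggregate counts before `class_percentages`); the experiment reports the
grand mean ± SEM over biological replicates. Pooling technical replicates
before averaging is also computed in tests; the replicate-mean order is
primary.

Group comparisons use a nested one-way ANOVA: technical-replicate values
nested in biological replicates nested in groups, with
F = MS(group)/MS(bio within group) on (G−1, Σ(B_g−1)) degrees of freedom —
the biological replicate is the experimental unit. Tukey–Kramer pairwise
comparisons act on biological-replicate means with the
between-bio-within-group mean square as error term and the studentized
range distribution. Monomer/dimer/trimer+ segregation is the same
per-class output keyed by class; it is assumed the same nested model
applies per class.

Labeling efficiency is summarized as the mean ± SEM of per-replicate
colocalization percentages for stained samples, with the unstained
control reported alongside — not subtracted — and a flag raised if the
control exceeds the stained estimate. The thinning forward model maps a
true copy-number distribution to the observed labeled-copy distribution;
its inverse is non-negative least squares on the thinning matrix
(columns sum to 1, so an exactly consistent observed vector yields a
simplex solution; the result is renormalized against numerical drift).
The inverse is unavailable at p = 0.

## Numerical and degenerate-input choices

- Z-scoring uses the population SD (fixed-length signals, standard CNN
  preprocessing); zero-variance traces raise and are treated as rejected
  downstream (stored as all-zero vectors in labeled datasets).
- Half-time fits: 1-D survival counts → least squares on log counts
  (zero-count frames excluded); 2-D trace ensembles → `A·e^(−λt) + c` fit
  with a second, binomial-variance-weighted pass (floor 0.01 on the
  variance so the bleached tail cannot dominate). Non-positive fitted
  rates raise a no-bleaching error.
- Detection thresholds use median/MAD background statistics so sparse
  bright spots cannot inflate the threshold; a computed spot cap below 1
  (image far smaller than the sensor the `imgArea/3e5` formula targets)
  disables the cap, while an explicit `max_spots` is always honored.
- Colocalization is mutual nearest neighbor with an inclusive 2 px
  boundary; coordinate ties break toward the smallest spot index.
  A one-sided window can be emulated by relaxing the mutuality check;
  mutual NN is the default.
- Registration is translation-only, estimated as the mean matched-bead
  displacement with one re-matching refinement pass; < 3 matchable beads
  is an error.

## Problem sizes

Tests and the acceptance script run at reduced scale chosen as the
package's own verification budget: 2,000 traces for oracle validation,
8,000 for classifier cross-validation, one full 10 × 7 × 200 experiment
per condition for end-to-end recovery, and 50 class-level replicate
simulations for the ANOVA power sweep. Statistical acceptance bands are
Monte-Carlo-aware (e.g. multimeric recovery ± 3 percentage points,
labeling efficiency ± 3 points).

## Known limitations

- The rubric's step threshold (25 counts) is meaningful only on the raw
  count scale of the generator's defaults; data on other scales need the
  threshold rescaled.
- Step counting reads multimeric fractions ~2–3 percentage points below
  the generative post-thinning truth (window survival and coincident
  bleaches) — a real bias of the method, visible here because ground
  truth is known.
- The class-level fast path (`simulate_classified_pairs`) idealizes
  classification as error-free binning of labeled copies; it is intended
  for statistical power studies, not classifier evaluation.
- No biological between-replicate variance is simulated; nested-ANOVA
  error strata are exercised by sampling noise only.
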