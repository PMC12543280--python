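# smstoich

Single-molecule pull-down (SiMPull) photobleaching-step stoichiometry in
Python: how many copies of a prey protein sit in a complex with one bait
molecule?

In a SiMPull experiment, protein complexes from lysate are immobilized on an
antibody-functionalized coverslip and imaged by two-color TIRF microscopy
under continuous excitation. Each fluorophore photobleaches in a single,
discrete step, so the intensity trace of a diffraction-limited spot is a
descending staircase whose step count estimates the number of labeled
subunits. This package implements the full analysis chain for such data —
and a synthetic-data generator with known ground truth, so every stage is
testable without any microscope:

- **`smstoich.simulate`** — generative model: a complex carries one
  green-tagged bait and *n* far-red-tagged prey copies with
  *n* ~ a configurable copy-number distribution; incomplete dye labeling is
  independent Bernoulli(*p*) thinning; each labeled fluorophore bleaches at
  an exponential time (far-red half-time = 1/5 of the 50 s acquisition,
  green = 1/10, 1000 frames at 20 frames/s); traces are
  `baseline + step_height·(survivors) + N(0, noise_sd)`. Optional rendering
  to two-channel image stacks with a Gaussian PSF and a bead registration
  image pair.
- **`smstoich.registration`** — spot detection (local maxima over a robust
  background threshold, sub-pixel centroid refinement, brightness cap
  `floor(imgArea/3e5)`), translation registration from bead images, and
  mutual-nearest-neighbor colocalization within 2 px.
- **`smstoich.traces`** — ROI trace extraction, Z-score normalization
  (population SD), and exponential bleach half-time fits (`t½ = ln2/λ`).
- **`smstoich.stepcount`** — a deterministic step-counting rubric: recursive
  binary mean-shift segmentation into plateaus; each sustained decrease
  > 25 counts is one step; counting stops early at the first step-sized
  increase; traces with no steps or too-high plateau variability are
  rejected. Far-red traces bin into {rejected, 1-step, 2-step, 3plus},
  green into {rejected, 1-step}.
- **`smstoich.cnn`** — 1-D convolutional classifiers (numpy, CPU) for both
  channels with the full training protocol: inverse class frequency
  weighting `w_c = N/(K·n_c)`, stratified 80/20 split, architecture search
  ranked by validation accuracy with the top five re-scored by stratified
  5-fold cross-validation, final training on 100% of the data.
- **`smstoich.stats`** — the quantification: keep pairs with a 1-step green
  and non-rejected far-red trace; per-technical-replicate class
  percentages; multimeric % (= 2-step % + 3plus %) averaged into
  biological-replicate values, grand mean ± SEM; nested one-way ANOVA
  (group effect tested against the biological-replicate stratum) with
  Tukey-adjusted pairwise comparisons; and the binomial-thinning forward
  model `observed(k) = Σₙ true(n)·C(n,k)·pᵏ(1−p)ⁿ⁻ᵏ` with its
  simplex-constrained inverse for labeling-efficiency correction.

## Worked example

```python
import numpy as np
import smstoich as sm
from smstoich.pipeline import classify_pairs_oracle

# Default conditions: 10 biological x 7 technical replicates, 200 spots per
# field, labeling probability 0.4, copy-number mixture calibrated so the
# post-thinning observed multimeric fraction is 0.39.
cfg = sm.SimulationConfig()
traces, truth = sm.simulate_experiment(cfg, np.random.default_rng(104))

pairs = classify_pairs_oracle(traces)          # step-rubric classification
analyzable = sm.filter_pairs(pairs)            # green 1-step & far-red kept
summaries = sm.class_percentages(analyzable)   # per technical replicate
result = sm.percent_multimeric(summaries)
print(f"multimeric: {result.grand_mean:.1f}% +/- {result.sem:.1f} (SEM over "
      f"{len(result.bio_values)} biological replicates)")
```

prints

```
multimeric: 36.6% +/- 0.4 (SEM over 10 biological replicates)
```

i.e., 36.6% of analyzable complexes show two or more far-red photobleaching
steps. The generative truth is 39%; step counting reads slightly low
because a few percent of fluorophores survive the imaging window and
near-simultaneous bleach events merge into one step — the same physical
biases that make incomplete labeling an *underestimate* of true copy
number. `sm.invert_true_distribution` applies the binomial-thinning
correction when the labeling probability is known.

A `smstoich` console script exposes the same stages
(`simulate-traces`, `simulate-images`, `label`, `detect`, `register`,
`coloc`, `train`, `classify`, `quantify`, `halftime`); see
`smstoich --help`.

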