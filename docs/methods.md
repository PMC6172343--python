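# Methods

`lspdbn` decodes motor-imagery classes from EEG segments whose
artifact-contaminated or lost samples have been *deleted* rather than the
whole segment rejected. This note describes the models and procedures the
package implements, the choices made where the design was genuinely open,
and what the synthetic benchmarks do and do not demonstrate.

## Problem setting

A motor-imagery BCI discriminates imagined movements (left hand, right
hand, foot) from the power of sensorimotor rhythms: event-related
desynchronization (ERD) suppresses mu (8–13 Hz) and beta (18–26 Hz) power
over class-specific cortical areas. Extreme artifacts and acquisition
drop-outs are traditionally handled by rejecting the whole contaminated
segment, leaving the BCI silent for that period. The alternative
implemented here deletes only the affected samples. The retained samples
keep their original timestamps, so the segment becomes a *non-uniformly
sampled* series — which ordinary FFT/Welch spectral estimators handle
poorly but a least-squares spectral fit handles naturally.

## Processing chain

1. **Band-pass filtering.** Fifth-order Butterworth, pass band 8–35 Hz,
   output scaled by 1.5. Filtering is zero-phase (forward–backward,
   `sosfiltfilt`), chosen because the pipeline is offline; the applied
   magnitude response is therefore `|H(f)|²`, and the tests' oracles use
   that response. The gain is implemented as an explicit scalar multiply: a
   Butterworth prototype is unity-gain, so an output scale is the only
   consistent reading of a "filter with gain". Filtering precedes
   segmentation, on the trial-level record.
2. **Sliding-window segmentation.** 1-s windows every 0.2 s (80% overlap);
   a 4-s trial yields 16 segments. Windows are half-open sample ranges
   `[k·step, k·step + length)`; each segment restarts its clock at zero
   with timestamps `t_i = i/fs`.
3. **Data removal.**
   - *Point removal* (data-loss model): exactly `round(p·N)` sample
     indices drawn uniformly without replacement.
   - *Chunk removal* (extreme-artifact model): the segment is partitioned
     sequentially into chunks whose widths are drawn from Normal(10, 2),
     rounded and clipped to ≥ 1 sample, the last chunk truncated; randomly
     ordered chunks are deleted until the deleted count first reaches
     `p·N`, so the realized fraction overshoots by at most one chunk.
   - The same index set is deleted on every channel (loss hits whole
     frames), which is also what keeps a single timestamp vector per
     segment. Deleted samples are gone; retained samples keep their
     original timestamps.
4. **Spectral features.** Per channel, power is estimated on a frequency
   grid (default 1–35 Hz, 0.5 Hz spacing) and averaged within four
   sub-bands — alpha 8–13, sigma 13–18, low-beta 18–23, high-beta
   23–28 Hz, half-open intervals forming a partition of [8, 28). Features
   are concatenated channel-major: 4 bands × C channels (256 values for
   64 channels). Powers are divided by the retained fraction beforehand so
   different removal ratios sit on one scale.
5. **Normalization.** Per-dimension min–max scaling to [0, 1]. The
   statistics are fit on the training split only and reused on test data
   (no clipping; test values may leave [0, 1]); a dimension constant in
   training maps to 0. Fitting on train only avoids leakage; whether the
   original protocol normalized jointly is unknowable, and the joint
   variant would only shift both pipelines equally.

## Least-squares Lomb-Scargle periodogram

At each angular frequency ω the series x(t_i) is fit with
`a·cos(ωt) + b·sin(ωt)` by least squares:

    R(ω) = Σ_i [cos ωt_i, sin ωt_i]ᵀ[cos ωt_i, sin ωt_i]
    r(ω) = Σ_i [cos ωt_i, sin ωt_i]ᵀ x(t_i)
    P(ω) = (1/N) r(ω)ᵀ R(ω)⁻¹ r(ω)

implemented as the closed-form 2×2 solve, not the classical τ-offset
shortcut (the two coincide; the tests verify agreement with scipy's
τ-form up to its 2/N normalization). For a sinusoid of amplitude A,
P converges to A²/2 under dense sampling, so band averages are
amplitude-scale band powers. Numerical safeguards: if `det R ≤ 1e-10·N`,
a ridge `1e-10·N` is added to the diagonal; a still-degenerate frequency
returns zero power with a warning. There is no mean-centering beyond the
band-pass filter, which removes DC. Whole-dataset feature extraction uses
a vectorized path that exploits the fact that retained timestamps are
subsets of one uniform grid (masked trig tables); it is exactly equivalent
to the per-segment solve and is tested as such.

**FFT/Welch on gappy data.** A uniform-grid estimator needs a uniform
series, so the retained samples are concatenated and re-interpreted as
uniformly sampled at the original rate — the simplest treatment available,
and the source of these estimators' degradation: concatenation compresses
the timeline by the retention factor, shifting and smearing spectral
peaks. FFTs are zero-padded to the original segment length so the band
grid stays resolvable at high removal. Welch uses Hann windows of a
quarter of the retained length (min 32 samples), 50% overlap, and falls
back to a single window when data run short. Alternative treatments
(interpolation, zero-filling in place) exist; results for the baselines
depend on this choice and it is stated here for that reason.

## Deep belief network

Three stacked RBMs (default hidden sizes 60/50/35 on a 4·C input) with a
softmax output layer (3 classes).

- **Units.** Inputs are min–max-scaled features in [0, 1] treated as
  visible activation probabilities (mean-field); hidden units are
  stochastic binaries during contrastive divergence. This avoids an
  unparameterized Gaussian-visible variant while keeping the binary energy
  model. The negative-phase visibles are mean-field probabilities; the
  gradient statistics use probabilities throughout (lower variance, same
  expectation).
- **Pre-training.** Greedy CD-k (k = 1 default) per RBM, learning rate
  0.5 for weights and 0.25 for biases, upper RBMs consuming the lower
  layer's activation probabilities. Initialization: weights
  ~ Normal(0, 0.01), zero biases, no momentum.
- **Fine-tuning.** Full-network backpropagation on
  cross-entropy + (λ/2)·‖softmax weights‖² + β·Σ_layers mean-unit
  KL(ρ ‖ mean activation), with λ = 0.05, ρ = 0.1, β = 1. Two choices
  here were genuinely open and are deliberate: the weight decay applies to
  the softmax connection weights (the constraint terms belong to the
  softmax-regression cost), and the KL penalty is normalized per hidden
  unit so its strength does not grow with layer width. The alternative —
  decaying every weight and summing the KL over all units — makes the
  penalties dominate the data term by an order of magnitude and pins the
  network at chance; it was rejected on that ground. Gradients are
  verified against central finite differences (< 1e-5 relative).
- **Optimization schedules.** The default is 50 pre-training epochs per
  RBM and 200 fine-tuning epochs, batch 100, fine-tuning rate 0.1 decaying
  ×0.95/epoch — conservative, converges at any dataset size. The
  evaluation harness, which fits hundreds of DBNs on the canonical
  3600-segment training split, uses an equivalent-step shorter schedule
  (10 pre-train epochs, 25 fine-tune epochs, rate 0.5 ×0.93/epoch); on
  datasets much smaller than that it under-trains, so small examples use
  the default schedule.
- **Prediction.** Deterministic sigmoid forward pass + softmax; argmax
  with ties to the lowest class index.
- **Exact oracles.** For machines of ≤ 20 units the package enumerates the
  partition function, joint probabilities and exact log-likelihood
  gradients; the test suite holds conditionals and gradients to 1e-10 and
  requires the CD-50 update direction to track the exact gradient
  (mean cosine > 0.9 over 100 random machines).
- **Structure search.** Coordinate search over hidden widths
  ([15..90] × [10..60] × [25..85], one layer varied at a time around
  60/50/35) with seeded 5-fold cross-validation.

## SVM baseline

One binary RBF SVM per unordered class pair (three machines for three
classes), combined by majority vote with ties to the lowest class index.
Each machine grid-searches C and the kernel width σ over powers of two
(exponents −5..5; σ maps to sklearn's parameter as γ = 1/(2σ²)) with
seeded stratified 5-fold cross-validation. Whether the original grid was
log₂ or log₁₀, and whether σ or γ was gridded, is not stated anywhere;
base-2 over σ is the conventional choice and both are configurable.

## Synthetic data

No human EEG ships with the package; two generators stand in.

- **Two-tone probe:** `0.75·sin(2π·4t) + sin(2π·8t)`, 100 Hz, 10 s
  (rates/durations chosen to resolve the tones with ≤ 0.1 Hz grid
  spacing); the amplitude convention reads "amplitude ratio 0.75" as
  A₄/A₈ with the 8 Hz tone at unit amplitude.
- **Surrogate motor-imagery EEG:** per channel, 1/f background noise
  (exponent 1) mixed with a white floor (fraction 0.3), plus two
  random-frequency, random-phase sinusoids per rhythm band (mu 8–13 Hz at
  amplitude 1.0, beta 18–26 Hz at 0.7) with ~20% log-normal trial-to-trial
  amplitude jitter. Each class attenuates the rhythm amplitude by
  `1 − erd_depth` (default 0.6) on its own disjoint block of channels,
  with one block left unaffected as reference. Defaults are a desk-scale
  16 channels at 250 Hz with 4-s trials; `MotorImageryConfig.paper_scale()`
  switches to 64 channels at 1 kHz. Class sequences are balanced and
  seed-shuffled; every generator is a pure function of (config, seed).

What this emulates: the spectral signature the pipeline assumes (band-power
differences in mu/beta over 1/f noise). What it does not: volume
conduction and channel covariance, non-stationarity, real artifact
waveforms, inter-subject variability, or realistic class overlap — the
synthetic classes are far more separable than human EEG (intact decoding
accuracy saturates near 1.0, versus ~0.75 reported for real recordings).
Passing benchmarks therefore demonstrate the *mechanism* — that LSP
features degrade gracefully under removal while FFT/Welch features
collapse — not clinical-grade accuracy numbers.

## Evaluation harness

`run_removal_curve` applies removal independently per segment (training
and test sides alike, since each removal condition is trained and tested
within itself), extracts features per estimator, fits normalization on the
75% training split (segment-level by default; a trial-level mode keeps all
16 segments of a trial on one side to respect their correlation), trains
the classifier, and records segment-level test accuracy with trial-voted
accuracy alongside. Every random draw derives deterministically from one
base seed. The robustness statistic is the accuracy *spread* — max minus
min accuracy across removal ratios 0.1–0.8 — computed per seed and
averaged; "mean difference of accuracy" admits several readings and this
one is fixed here. The paired comparison across conditions uses the
classical paired t-test, with a degenerate-variance flag instead of a
statistic when all differences coincide.

Problem sizes used by the shipped benchmarks: 16 channels × 250 Hz ×
100 trials/class (4800 segments), ratios 0.1–0.8 in steps of 0.1, LSP and
FFT features, DBN classifier, 10 replicate seeds in the test suite and 3
in the acceptance script; the two-tone robustness sweep uses 100 removal
seeds per ratio.

### Point versus chunk removal under concatenation

An instructive property of the concatenation treatment: for the *LSP*
pipeline chunk removal is (mildly) harder than point removal at matched
ratios, as expected — deleting contiguous blocks removes whole stretches
of rhythm information while scattered single-sample losses average out.
For the *FFT* baseline the ordering inverts at high ratios: point-level
deletion destroys phase continuity sample by sample, so the concatenated
series whitens and FFT band powers collapse already around 30% removal,
whereas ~10-sample chunks remain internally intact oscillation snippets
whose band structure survives concatenation until roughly 50–60% removal.
Whether real recordings show this inversion depends on how gappy segments
are fed to the uniform-grid estimator, which is exactly the convention
this package had to fix by choice; the benchmark suite records the
directional check per estimator and the FFT direction fails under this
convention.

## Known limitations

- The FFT/Welch treatment of gaps (concatenation) is one of several
  defensible conventions; baseline numbers would differ under
  interpolation or in-place zero-filling.
- The chunk-partition policy (fresh Normal widths per segment, last chunk
  truncated) and the stop-at-first-overshoot deletion rule resolve details
  the underlying protocol leaves open.
- Whether reported accuracies should be segment-level or trial-voted is
  ambiguous in the source protocol; both are recorded, segment-level is
  primary.
- Artifact *detection* (deciding which chunks to remove in real data) is
  out of scope; removal is random by construction.
- EDF export is not provided (reading is available via the optional mne
  dependency); the tested interchange format is delimited matrices with a
  JSON sidecar.
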