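# Methods

## Problem setting

Single-channel EEG segments are classified into five states: healthy with
eyes open (A) or closed (B), interictal recordings from outside (C) or
inside (D) the epileptogenic zone, and ictal activity during seizure (E).
Long recordings (23.6 s, 4097 samples at 173.61 Hz) are cut into
non-overlapping one-second chunks of 178 samples; the classifier operates on
single chunks, so a deployed detector needs only one second of signal per
decision.  178 = ⌊4097/23⌋ is fixed by the network's input shape; the
trailing 3 samples of each segment are discarded.  Chunks inherit the label
of their source segment (A→0 … E→4).

By default the train/test split is stratified at the chunk level, so chunks
from one recording may appear on both sides — this matches the common
evaluation protocol for this corpus but is optimistic about
generalization to unseen recordings.  `split_dataset(..., by_segment=True)`
assigns whole segments to one side for a leakage-free alternative.

## The classifier

The network is a fixed-depth stack of six blocks of
[Conv1D → BatchNorm → Dropout → MaxPool] followed by [Flatten →
Dense(softmax)] — 4·6 + 2 = 26 layers.  Convolutions are stride-1 with
length-preserving ("same") padding; pooling uses a **ceiling** length
convention, out_len = ⌈L/m⌉ (so 45 → 23 with m = 2), implemented by
padding the tail with −∞ before the max.  Block filter counts follow the
schedule [δ, δ−10, δ−15, δ−20, δ−25, δ−30], clamped at one filter; the
schedule is a linear generalization read off the single reference
architecture (δ = 50 → 50, 40, 35, 30, 25, 20) and is the package's own
extrapolation for other δ.  With ceiling pooling the sequence length
saturates at 1 and can never reach 0, so depth never makes the architecture
unbuildable; the builder still validates input_len ≥ 1.

Training minimizes multi-class cross-entropy with Adam (β₁ = 0.9,
β₂ = 0.999).  Predicted probabilities are clamped at 10⁻¹² inside the
logarithm.  After every epoch, validation accuracy is compared with the
incumbent best and the best snapshot (weights plus batch-norm running
statistics) is retained; the returned model is the best-validation model,
not the last-epoch one.

The tensor arithmetic runs on a compact numpy engine (`mfocnn.nn`):
convolution as sliding-window im2col + BLAS matmul with hand-derived
backward passes, verified against central finite differences in the test
suite.  Shape inference (`mfocnn.model.infer_shapes`) is a separate pure
arithmetic path and is cross-checked layer-for-layer against the engine's
observed tensor shapes.

## Moth-flame hyperparameter search

Six hyperparameters are tuned inside the constraint box 40 ≤ δ ≤ 100,
1 ≤ s ≤ 20, a ∈ {0, 1, 2}, 0 ≤ d ≤ 0.6, 10⁻⁵ ≤ η < 1, 2 ≤ m ≤ 20.
The optimizer works on a continuous 6-vector; decoding clips to the box,
rounds δ, s, m and the activation code half-away-from-zero, and reads the
fifth coordinate as log₁₀η (the bound spans four decades, so searching η
linearly would waste almost the whole axis on large rates).

Per iteration: all moths are evaluated; the flame set is rebuilt as the k
best records pooled from current moths and previous flames (elitist — the
global best is never lost); k follows round(N − t(N−1)/T) clamped to ≥ 1,
with half-away-from-zero rounding to keep the schedule platform-independent;
each moth then moves along D·e^{bt}·cos(2πt) + F with t drawn i.i.d. uniform
on [−1, 1] per coordinate and is clipped back to the box.  Design choices
where the procedure is underdetermined:

- **Distance D**: the canonical coordinate-wise absolute distance |M − F|
  (symmetric spiral); a signed variant (M − F) is available via
  `signed_distance=True`.
- **Pairing**: moth i orbits flame i; moths with index ≥ flame count orbit
  the last retained flame.  Nearest-flame assignment is not used because it
  is not well defined for the shrinking flame set.
- **Spiral constant b = 1**: no value is conventionally fixed; b only
  rescales the radial envelope.
- Non-finite objective values are recorded as +∞ so a diverged training run
  can never become a flame.

The fitness of a candidate is the final validation cross-entropy after a
deliberately short training run (default 10 epochs, configurable), cached
on the *decoded* hyperparameters so rounding-equivalent positions never
retrain.  Full-budget training of every candidate (hundreds of evaluations ×
hundreds of epochs) is neither informative for ranking nor tractable; the
short-budget/final-retrain split is the package's design.  Reference study
conditions are 20 moths × 30 iterations for the search and batch 256 ×
500 epochs for final training; these are the defaults of
`MFOCNNClassifier`.  The validation set is carved out of the training
portion (default 10%, stratified, seeded), keeping the 80/20 train/test
split intact.

## Synthetic corpus

The generator is phenomenological — band-limited oscillations, Poisson
spikes and bursts on AR(1) colored noise — not a biophysical EEG model.
Default recipes (amplitudes in µV): A = weak alpha (8–13 Hz, 20) on noise
(σ 30); B = strong alpha (110); C = theta (4–7 Hz, 55) + 1 spike/s of 250;
D = theta (80) + 4 spikes/s of 350; E = rhythmic 3–7 Hz discharge with a
burst-suppression envelope peaking at 1300, reproducing the clinical fact
that ictal voltages exceed 1000 µV while other classes stay on a ~100 µV
scale.  Samples are rounded to integer microvolts (mirroring the ADC output
of real recordings), which makes ASCII export/re-import bit-lossless.  A
`separability` knob interpolates every recipe toward the A recipe: at 0 all
classes are statistically identical (a chance-level control), at 1 the full
structure is present.

What passing tests on this corpus do show: the pipeline's plumbing, the
optimizer's ability to find trainable configurations, and the classifier's
capacity to exploit amplitude and spectral class differences.  What they do
not show: performance on real EEG, whose within-class variability,
artifacts and inter-patient differences the recipes do not emulate.  Real
Bonn-layout data is supported through `mfocnn.bonn` but never required.

## Problem sizes and numerical choices

Desk-scale defaults used by the test suite: miniature corpora of 2–20
segments per class; the end-to-end tuning check runs 5 moths × 5 iterations
× 3 search-epochs followed by 20-epoch final training on a 20-segment
corpus (≈ 2300 chunks) — sizes chosen so the whole suite runs on one CPU in
minutes while every code path is exercised at full architecture depth.
The full-scale 100-segment corpus (11 500 chunks) is the generator default.

All computation is float32; determinism is exact for fixed seeds (one
`numpy` Generator per corpus, per optimizer run, and per training run; the
pipeline derives per-stage seeds from one global seed via CRC mixing).
Batch-norm uses ε = 10⁻⁵ and momentum 0.9; sigmoid inputs are clamped at
±60 to keep float32 exp finite; dropout is inverted (scaled at train time).
Stratified splits assign round(fraction × class size) rows per class, so
weighted proportions deviate from the target by less than one row per
class.

## Known limitations

- The numpy engine is single-threaded BLAS-bound; full study-scale search
  (600 trainings) is hours, not minutes.
- Chunk-level splitting (the default) leaks recording identity between
  train and test; use `by_segment=True` for honest generalization numbers.
- The filter schedule beyond the exhibited δ = 50 instance, and the
  treatment of the learning rate's published integer code, are documented
  package choices, not uniquely determined conventions.
- Multi-class precision/recall/F1 use support-weighted one-vs-rest
  averaging by default (macro available); accuracy is always
  100·trace/total of the confusion matrix.
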