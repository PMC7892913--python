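# Methods

## The problem

In a gaze-controlled interface, an on-screen action fires when the user's
gaze dwells on a target for longer than a threshold (here 500 ms).  Natural
visual exploration also produces long dwells, so the interface cannot tell a
deliberate selection from an accidental one from gaze alone.  This package
re-implements, against synthetic data, a single-trial MEG analysis that asks
whether the brain signal recorded in the first 700 ms of a dwell
(−0.2…0.5 s around fixation onset, before the interface feedback) carries
enough information to separate *voluntary* from *spontaneous* fixations —
and, as a positive control, whether the post-feedback interval (−0.2…1.0 s)
is much easier, as an evoked response to the visual feedback should make it.

## Trial taxonomy

A ball dwell is **voluntary** when it reached the 500 ms threshold
(feedback at onset + 500 ms), had a clear initial fixation onset within
50 ms of the dwell onset, ended with a saccade within 500 ms of the
feedback, and was followed by a confirmatory fixation within 200 ms.  A
sufficiently long dwell whose next fixation is *not* a confirmation is
**spontaneous**.  Everything else is **excluded** with a reason
(`below-threshold`, `late-onset`, `delayed-confirmation`).  The 200 ms
confirmation window is anchored at the dwell end by default: anchoring it at
the feedback would contradict the 500 ms saccade window (a dwell may
legitimately end later than 200 ms after feedback).  Both anchors are
supported via `confirm_anchor`.  Classes are balanced by randomly dropping
trials from the larger (spontaneous) class; participants with fewer than 70
voluntary trials are excluded from group analysis.

## Generative model of the synthetic data

Each epoch is a linear mixture `X = A S + ε` of `k_true` latent sources with
unit-norm spatial topographies (Gaussian bumps on a unit-disc head
projection of 102 gradiometer-pair positions, 204 channels) plus white
Gaussian sensor noise of standard deviation `noise_sd`:

- **slow deflection** (voluntary only): a quarter-period sine ramp from
  fixation onset to the 0.5 s feedback time, then held constant; loads over
  left central/parietal sensors.  This is the planted pre-feedback
  discriminative component.
- **evoked feedback response** (both classes, voluntary gain 1.0 vs
  spontaneous 0.5): a damped 5 Hz transient in 0.5–0.9 s; optional
  (`evoked_amplitude`, default 0).
- **frontal artifact** (voluntary only, optional): a step-like deflection at
  a random time in 0.1–0.6 s loading on the frontal band, emulating an
  oculomotor artifact.
- **oscillatory background**: 10 Hz sinusoids with a random phase per trial.
  The background belongs to the *noise* model: its amplitude is
  `background_amplitude × noise_sd`, so `noise_sd` is the single
  signal-to-noise dial and a `noise_sd = 0` simulation is exactly
  signal-only.

Background source centres are rejection-sampled to stay ≥ 0.55 map units
from every planted source so that each planted topography is identifiable —
without this, "recovering the slow source's pattern" would be ill-defined
whenever a background bump happened to overlap it.

Amplitude defaults (`slow_amplitude = 1`, `noise_sd = 1`) are free
parameters — the original study reports no effect size for the slow
component — chosen so that a 200-trial-per-class desk-scale dataset is
reliably decodable.  The synthetic effect is therefore deliberately
*stronger* than the real-data effect (where pre-feedback AUC was ~0.66):
passing tests show the pipeline detects a planted effect and stays at chance
without one, not that real MEG would behave this way.  Real-data features
the generator does not emulate: 1/f spectra, inter-trial covariance
structure, head movement, sensor drift, heartbeat/blink artifacts beyond the
single step source, and vendor interference suppression.

## Preprocessing

Crop (half-open sample window, `t = 0` at fixation onset) → zero-phase
lowpass below 45 Hz → per-trial normalization (subtract each channel's mean,
divide by one pooled SD over channels × time) → decimation to 125 Hz
(keep every 8th sample from index 0, output length floored).  A −0.2…0.5 s
epoch at 1000 Hz becomes 204 × 87; −0.2…1.0 s becomes 204 × 150.

The lowpass is an order-8 Butterworth applied forward–backward
(`sosfiltfilt`, edge padding beyond three filter lengths).  The order was
chosen for the anti-aliasing requirement of the subsequent 8× decimation:
the two-pass response is ≈ −46 dB at 62.5 Hz (the post-decimation Nyquist)
and ≈ 1 % amplitude at 60 Hz, while the 10 Hz passband is flat to < 0.1 %.
A lower-order design (e.g. order 4) would leave > 7 % amplitude at the new
Nyquist after two passes.  Zero-phase filtering avoids shifting the 0.5 s
feedback landmark.  Whether the original analysis filtered continuous or
epoched data is unstated; filtering the cropped epoch keeps the two window
analyses independent.

## Decoders

Both variants share: a spatial projection `S = WᵀX` onto `k` latent source
time courses (no bias, so `W` is a bank of spatial filters); a temporal
convolution of length `l_filt` with "same" padding; ReLU; non-overlapping
max-pooling over `pool` samples; dropout; one dense layer; softmax over two
classes.  **LF** uses one independent FIR filter per source;
**VAR** convolves all `k` inputs into each output (a vector-autoregressive
view).  Defaults: `k = 16`, `l_filt = 14` samples (112 ms at 125 Hz —
the sample count is taken as authoritative over the nominal "100 ms"),
`pool = 4` (stride 4; "4 adjacent samples" read as non-overlapping),
dropout 0.5 before the dense layer, l1 penalty 3 × 10⁻⁴ on both
convolutional layers, Adam with batch 100 and learning rate 3 × 10⁻⁴ on
binary cross-entropy.  "Same" temporal padding keeps 87 timepoints through
the convolution, giving ⌊87/4⌋ = 21 pooled samples and a 21 × 16 × 2 dense
weight tensor.

The implementation is plain NumPy with analytic gradients (verified against
central finite differences to ~10⁻⁹ relative error in float64) and a
deterministic seeded update/dropout stream.  Weights initialize as Gaussians
with sd `1/√fan_in`; training defaults to float32 (`ModelConfig.dtype`).

A "training iteration" is one mini-batch update.  With a validation set,
validation ROC AUC is recorded after every update, and training restores the
weights at the earliest validation maximum.  Without one (the "naive"
retraining), final weights are kept.

## Evaluation

Nested cross-validation: 5 stratified outer folds; within each outer
training set, 4 stratified inner folds (train:validation 3:1).  The optimal
iteration count is the mean over inner folds of the earliest
validation-AUC-maximum iteration, rounded to nearest, minimum 1.  Test
performance per outer fold: **naive** (fresh model retrained on the full
outer-training set for the optimal count) and **ensemble** (the four inner
models' voluntary-class probabilities averaged).  ROC AUC is the
Mann–Whitney concordance with ties credited ½ (cross-checked against
scikit-learn in the tests).  Per-fold significance: a label-permutation test
with 1000 permutations and the add-one estimator
`p = (1 + #{AUC_perm ≥ AUC_obs}) / (n_perm + 1)` (guarantees `p > 0`; a
tolerance of 10⁻¹² absorbs floating ties).  A participant is flagged `+`
when all five fold p-values are below 0.05 and `−` when none is.  Group
statistics: mean ± SD over participants, Pearson correlation of AUC with
trials-per-class, and a two-sided Wilcoxon signed-rank test between LF and
VAR per testing method (defined as p = 1 when all paired differences are
zero).  Stratified folds and the earliest-maximum tie-break are choices the
source protocol leaves open; both favour stability on small folds.

## Interpretation

Spatial filters are made interpretable through the covariance transform
`A = Σ_X W Σ_Ŝ⁻¹`, with `Σ_X` the channel covariance over concatenated
trials × time, `Σ_Ŝ` the latent covariance, and the inverse taken as a
pseudo-inverse with relative cutoff 10⁻¹⁰ (a condition number above 10¹⁰
raises a degenerate-latents warning).  Covariances are computed on the same
training split as the model to avoid test leakage.  Per-class source
importance is the normalized L1 norm of the dense weights per source; the
fraction of explained variance per channel is the squared Pearson
correlation between the recorded signal and its reconstruction `A Ŝ`
(aggregated as the unweighted mean over defined channels).  The frontal
diagnostic correlates, across sources, frontal pattern mass
`f_s = Σ_{i∈frontal}|A_{i,s}|` with voluntary output mass
`o_s = Σ_j |w_{j,s}|`; pattern columns (rather than raw filters) are used
because patterns are the source-projection estimates, with the raw-filter
variant available by passing a filter-built pattern set.

### Well-posedness of column-wise attribution

Two empirical findings shaped the reference studies and deserve emphasis:

1. **Single-column pattern recovery requires a non-redundant latent bank.**
   With `k = 16` and dropout, the trained filters are deliberately
   redundant — many filters carry the discriminative source, the latent
   time courses are collinear, and the `Σ_Ŝ⁻¹` partialling splits the
   planted topography across columns.  In simulation the best column then
   correlates only ~0.75 with the planted slow-source topography no matter
   how long training runs, whereas an oracle filter (`Σ⁻¹a` among 15 random
   columns) reaches 0.91–0.99 — the transform is fine; the attribution
   question is ill-posed under redundancy.  The pattern-recovery study
   therefore trains a compact two-source LF-CNN, where the best column
   reaches |r| ≈ 0.94–0.99 across seeds.

2. **The frontal-artifact correlation is intrinsically high-variance.**
   With a two-logit softmax, a discriminative feature can be encoded as
   positive voluntary weight or negative spontaneous weight; per-class L1
   attribution therefore splits artifact-detecting latents between the two
   classes essentially at random, and the per-participant frontal/output
   correlation fluctuates strongly across seeds even when the classifier is
   demonstrably artifact-driven.  (The original study's real-data scatter
   shows the same character: clearly positive correlations in a minority of
   participants.)  The diagnostic study plants a strong artifact as the sole
   class difference; the *null* centre (artifact-free runs) is the stable,
   reliable half of the check.

## Reference-study problem sizes

Claims about the full recording geometry use the 204-channel layout
(preprocessing shape; nested-CV structure on a 200-trial participant with 50
training iterations; decoding power at 200 trials/class, seeds 1–5, 150
iterations with a single outer split and the standard 4-model inner
ensemble; pattern recovery at 150 trials/class).  Scale-free statistical
claims run reduced: type-I control uses 16-channel null participants (200
repetitions, 199 permutations each); artifact-free diagnostic nulls use 64
channels.  The window-ordering study uses 100 trials/class and 100
iterations so the pre-feedback window does not saturate, keeping the
short-vs-long contrast informative.

## Known limitations

- The decoders are CPU-bound NumPy; they are intended for the desk-scale
  datasets here, not for large-scale training.
- The generator's linear instantaneous mixing cannot produce the
  propagation or nonstationarity of real MEG sources; FVE values on
  synthetic data are not comparable to real-data values.
- Per-class output-weight attribution (and hence the frontal diagnostic) is
  unstable for single participants, as discussed above.
- The gaze simulator emits dwell-level events only; no raw gaze coordinates
  and no online dispersion-based fixation detection.
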