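# Methods

This note documents the models, procedures, parameter choices, and
numerical decisions in `ecgscope`, and what the desk-scale experiments
do and do not demonstrate.

## Preprocessing

Order is fixed: resample → blind segment → band-pass → standardize.

- **Resampling** to 128 Hz uses anti-aliased polyphase rational
  resampling (`scipy.signal.resample_poly`); the rate ratio is
  approximated by a rational with denominator ≤ 1000, exact for all
  common ECG rates. A recording already at 128 Hz is returned
  unchanged.
- **Blind segmentation** cuts half-open windows [offset, offset+384) in
  samples at 128 Hz, 0-based. The signal content is never inspected.
- **Filtering** is a fifth-order Butterworth band-pass with critical
  frequencies 0.01·fN and 0.7·fN, fN = 64 Hz (0.64–44.8 Hz). It is
  applied per segment, after cutting, so the classifier sees the same
  end-of-window distortion it will see in deployment. Default
  application is zero-phase forward–backward (`filtfilt`), which
  concentrates the distortion at both window ends without phase shift;
  a causal single-pass mode is available via `FilterSpec(zero_phase=False)`.
- **Standardization** is the z-score with the population (1/N) standard
  deviation — the 1/N vs 1/(N−1) difference is immaterial at N = 384
  but is fixed for bit-stability. A flat segment (σ at rounding-noise
  level, relative threshold 1e−12·max(|μ|, 1)) raises
  `DegenerateSegmentError` rather than silently emitting zeros, which
  would poison training.

## Synthetic ECG generator

Each identity is five Gaussian bumps per beat (P, Q, R, S, T order)
with per-identity amplitudes, widths, and latencies, a mean RR interval
and Gaussian RR jitter. Priors (uniform, units of mV-like amplitude and
seconds):

| parameter | range |
|---|---|
| P, Q, R, S, T amplitude | (0.05, 0.30), (−0.30, −0.05), (0.8, 1.8), (−0.50, −0.10), (0.10, 0.65) |
| widths (σ of the bump) | (0.018, 0.050), (0.006, 0.018), (0.010, 0.028), (0.006, 0.018), (0.045, 0.110) |
| latencies vs beat center | (−0.28, −0.15), (−0.050, −0.022), (±0.004), (0.022, 0.050), (0.18, 0.35) |
| mean RR | (0.50, 1.20) s — prior mean 0.85 s |
| RR jitter sd | (0.010, 0.040) s |

Noise is additive white Gaussian plus a sinusoidal baseline wander
below 0.5 Hz. Two documented regimes: `EASY_NOISE` (white sd 0.01,
wander 0.03 at 0.25 Hz) — near-clean, used for learnability studies —
and `REALISTIC_NOISE` (0.06 / 0.20).

**Identity separation.** Continuous priors occasionally produce two
nearly identical morphologies; a registry therefore rejects an identity
draw whose prior-normalized parameter vector lies within distance 1.0
of an already-drawn identity (about 0.6% of pairs) and redraws
deterministically. Under the easy regime, nearest-template
classification by beat-aligned average morphology is then 100% correct
— the oracle the learnability experiments rely on.

**Time separation** is emulated by linear morphology drift: after t
hours, amplitudes scale by (1 ± drift_rate·t) along fixed per-identity
random directions (capped at ±40% total), widths at half rate,
latencies shift up to 40 ms, and the RR interval drifts at quarter
rate. Drift is evaluated at absolute time (session start plus position
in the recording), so both later sessions and late portions of very
long recordings show drifted waveforms.

What the generator does **not** model: pathology, 12-lead geometry,
electrode motion artifacts, heteroscedastic noise, respiratory
modulation of RR, or realistic HRV spectra. Passing tests on this data
shows the pipeline can learn and evaluate identity-bearing waveform
structure under controlled drift — not that it reaches any particular
accuracy on real ECG databases.

## Dataset generation

One example = scope J of h standardized segments, query Gq, and the
query's scope position as label. The generator draws the scope from one
uniformly chosen database, fills up one identity at a time from
uniformly chosen databases (skipping duplicates) when that database has
fewer than h identities, picks q uniformly, and for the true identity
cuts two windows from one uniformly chosen recording with
|Δoffset| ≥ 384 (sample-disjoint), retrying offsets up to 64 times and
the recording up to 16 times. Window starts are uniform over all valid
sample positions — not beat- or second-aligned, consistent with blind
segmentation. Scope order is the random insertion order; the ordinal
position is the class label. h = 32 for training-dataset generation;
the model itself accepts any h. Datasets persist provenance (database,
identity, recording, offset per window) for auditability, and are
stored as chunked `.npz` arrays with a JSON manifest.

## Model

Defaults are the full-scale architecture: d_model = 512, conv 512×33
stride 1 + ReLU + 16/16 max-pool (384 → 352 → 22 tokens), 4+4 encoder
layers, 8 heads, feed-forward 2048, dropout 0.1, verification head
[512, 512, 512, 512, 256, 128] with BatchNorm+ReLU after each layer and
a sigmoid output, identification head 256 → 1 shared across positions
with softmax. `ModelConfig.scaled(w)` multiplies all widths by w
(desk-scale: w = 1/8 → d_model 64, ff 256) while the token geometry
(22, 46) is unchanged.

Open choices made here (the upstream description is silent):

- **Positional information.** The pair encoder adds learned absolute
  position embeddings over the 46 composite positions (BERT-style).
  The ID encoder adds none — scope order is arbitrary, and the
  resulting permutation equivariance is both desirable and testable.
- **Attention geometry.** Heads = 8 and feed-forward = 2048 adopt the
  base transformer's companion values to d_model = 512.
- **BatchNorm statistics** come from the batch in training and from
  running estimates (momentum 0.1) at inference.
- **Initialization** is uniform fan-in U(±1/√fan_in) for weights and
  N(0, 0.02) for embeddings/tokens, from a single generator seeded by
  `ModelConfig.seed`, so construction is reproducible.
- **Numerics.** All model arithmetic is float32 on a small in-package
  reverse-mode autodiff engine (`ecgscope.autograd`); gradients are
  checked against finite differences in float64 in the test suite.
  Post-norm residual layers (attention → add & norm → feed-forward →
  add & norm) with dropout on each sub-layer output.

## Training

Adam with β1 = 0.9, β2 = 0.98, ε = 1e−9 and the epoch-indexed rate
lr(epoch) = 0.000012·e^(2−0.03·epoch) + 0.00008 (≈1.69e−4 at epoch 0,
floor 8e−5). The loss is the unweighted sum of (a) mean binary
cross-entropy of the h verification probabilities against smoothed
targets and (b) cross-entropy of the identification distribution
against the smoothed h-class target; weights are configurable. Label
smoothing ε = 0.1 gives 0.95/0.05 and, at h = 32, 0.903125/0.003125.
Training stops when validation loss fails to improve for 3 consecutive
epochs; the best-epoch parameters are returned. The monitored
"combined accuracy" is implemented literally as the mean of
verification TPR, verification FPR, and identification accuracy (the
raw-FPR mean is anomalous but is the stated monitoring quantity); a
corrected variant mean(TPR, 1−FPR, acc) sits behind a flag. Validation
TPR/FPR are computed at threshold 0.5. Gradient clipping is off by
default. The base learning rate is tied to the full-scale batch of
512; `TrainConfig.lr_scale` (default 1) scales it for small-batch desk
runs, which use lr_scale = 6 at batch 32.

### Desk-scale study conditions

The bundled learnability study trains the width-×1/8 model at scope
h = 8 on 2,000 easy-regime examples (48 identities in two databases at
128/256 Hz, split 36 training / 12 validation identities, 64 s per
identity), batch 32, 63 steps per epoch, at most 8 epochs, lr_scale 6,
patience 3. This fits in minutes on one CPU while leaving the
validation identities entirely unseen during training. The
time-separation study evaluates the trained model on drift-enabled
registries (drift_rate 2.0 per hour, capped) at t = 0 versus t = 600 s
across 5 registry seeds, with (r, t, p, n, v, h) = (12, ·, 32, 4, 2, 8).

## Voting and evaluation protocol

Enrollment windows are evenly spaced over [0, (r−3)·128] samples
(deterministic, maximal coverage; overlapping whenever (r−3)/(v−1) <
3 s). Vote j pairs the j-th enrollment window of every scope identity
with the query; the query segment itself is not varied across votes.
Majority identification with mean-probability tie-break; per-position
verification is the majority of 0.5-thresholded votes, an exact split
resolved by the mean probability; scope verification reads the winning
position's mean verification probability (the continuous score feeds
ROC sweeps).

The protocol carves [0, r) for enrollment and [r+t, r+t+p) for the
classification window (samples at 128 Hz, half-open), samples n query
starts uniformly inside the window, and reports: individual
verification ROC over genuine claims (true position's aggregated score)
versus impostor claims (every other position — h−1 impostors per
query); scope verification ROC over in-scope versus out-of-scope
queries (negatives drawn from held-out identities, count matched to
positives); and closed identification accuracy. EER is linearly
interpolated at the FPR = FNR crossing of the threshold-sweep ROC
(all thresholds retained), AUC is trapezoidal, TPR at a requested FPR
is linear interpolation. Multi-session registries use the earliest
session for enrollment and the second-earliest (short separation) or
latest (long separation) for classification.

## Known limitations

- The synthetic easy regime is intentionally benign; accuracy numbers
  from it say nothing quantitative about PhysioNet-scale performance.
- The full-scale configuration (2,580,480 examples, batch 512, 256
  steps/epoch) is supported as configuration but has not been run here.
- The WFDB codec covers single-signal format-16 records only.
- Voting varies only the enrollment windows; vote-level variation of
  the query segment is a plausible alternative reading and is not
  implemented.
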