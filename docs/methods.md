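# Methods

## Problem and pipeline

The package detects a driver's stress state from short windows (10 s or 30 s)
of three wearable-sensor channels: foot and hand galvanic skin response
(FGSR, HGSR, microsiemens) and heart rate (HR, bpm). Sessions follow a fixed
seven-period route — rest, city, highway, city, highway, city, rest — whose
periods carry low / high / medium stress levels respectively; a marker channel
delimits them. The binary task contrasts rest (relaxed) against city driving
(stressed); highway (medium) windows and windows containing a period
transition are excluded.

The pipeline, in execution order:

1. **Resampling to 16 Hz.** GSR channels (native ~33–35 Hz) are low-pass
   filtered (zero-phase 4th-order Butterworth at the new Nyquist) and linearly
   interpolated down; HR (native 0.5–1 Hz) is linearly interpolated up.
   Linear interpolation is chosen for reproducibility; both signal families
   vary slowly relative to 16 Hz, so the method has no practical effect on
   content. Output length is `round(duration * 16)`.
2. **Median filtering** (default kernel 5 samples ≈ 0.31 s, reflected edges)
   removes electrode-contact spikes. The kernel width is configurable; 5 is a
   conventional despiking width at this rate.
3. **Z-normalization** per channel, per recording, over the whole recording,
   with the population (n) denominator. Recording-level statistics remove
   between-subject amplitude differences without using any window label.
4. **Windowing**: fixed windows with 50 % overlap; trailing partial windows
   are dropped; windows get the label of the single period that contains them
   or are discarded.
5. **Continuous recurrence plots.** Each window is delay-embedded with
   dimension m = 3 and delay τ = 2 samples (0.125 s at 16 Hz), and the full
   pairwise Euclidean distance matrix of the embedded states is kept without
   thresholding. A 10-s window gives a 156×156 plot, a 30-s window 476×476.
6. **Three-branch CNN.** One branch per modality, weights independent:
   five convolution blocks with (2,2,3,3,3) convolution layers of 3×3 kernels
   (stride 1, same padding, ReLU) and filter counts (32,64,128,256,256),
   each block closed by 2×2 stride-2 max pooling; a global max pool turns the
   last feature map into a 256-vector per branch for any input side ≥ 32.
   The three vectors are concatenated (768) and a single dense sigmoid unit
   outputs P(stressed); P(relaxed) = 1 − P(stressed). Training uses plain SGD
   (no momentum), binary cross-entropy, defaults lr 0.001, batch 4, 15 epochs.
7. **Evaluation**: leave-one-recording-out cross-validation, training from
   scratch per fold with fold-derived seeds; per-fold confusion matrices are
   summed and accuracy / per-class precision / recall / F1 / AUC reported.
   Accuracy, precision and recall are percentages; F1 and AUC live on [0, 1].
   Undefined ratios (zero denominators) are reported as NaN, never as 0.

## Numerical and design choices

* **CNN implementation.** The network is written directly in numpy:
  convolutions are k²-tap shifted-slice im2col gathers followed by one batched
  GEMM, with explicit reverse-mode gradients; correctness is verified against
  central finite differences in the test suite. Arithmetic is float32 by
  default (a float64 mode exists and is used for gradient checking).
  Max-pool gradients split ties evenly among maxima.
* **Global max pooling instead of flattening.** The branch feature contract
  (256-dim for both 156×156 and 476×476 inputs) cannot be met by a fixed
  flatten; global pooling after block 5 satisfies it for any side ≥ 32 and
  makes the head input size-independent.
* **Raw distances, not per-plot rescaling.** Because channels are z-normalized
  per recording, the amplitude of phase-space distances is comparable across
  subjects and is itself the strongest stressed-vs-relaxed cue (stressed
  windows occupy a wider region of phase space). Per-plot min-max rescaling
  destroys exactly that information — measured on the synthetic task it drops
  the leave-one-recording-out linear-probe ceiling from 0.97 to ≈ 0.75 — so
  the pipeline feeds raw distances to the CNN by default; min-max rescaling
  to [0, 1] remains available (`rp_to_image(..., rescale=True)`) for display
  and as a config option.
* **Zero-initialized readout head.** With a randomly initialized head the
  logits start as an uninformative random projection; short training schedules
  then stall. A zero head starts at exactly P = 0.5 and the first SGD steps
  fit a logistic regression on the branch features. This also fixes the
  decision tie: p = 0.5 classifies as stressed.
* **Class balancing.** Random undersampling of the majority class, either
  inside each training fold (`fold`, leakage-safe default) or once before
  splitting (`global`, replicating a pre-CV balancing protocol). Both are
  implemented because pre-CV balancing lets class-ratio information cross
  fold boundaries; the report records which was used.
* **AUC aggregation** is reported as the mean of per-fold AUCs, with the
  pooled-over-folds AUC also emitted, since either convention is defensible.
* **Marker dialect.** The marker channel is piecewise-constant stress-level
  codes 0/1/2 (low/medium/high → rest/highway/city). Half-open intervals
  [start, end) in 0-based seconds. Channel rates are inferred from timestamps
  rather than declared, tolerating native-rate drift.

## Synthetic recordings

The generator emulates the driving protocol so the whole pipeline is testable
without external data. GSR = subject baseline + slow random walk +
state-dependent tonic shift + skin-conductance responses (difference of
exponentials, rise 0.75 s, decay 2.0 s, log-normal amplitudes) arriving as a
state-dependent Poisson process (defaults: rest 0.05/s, highway 0.15/s, city
0.30/s), plus Gaussian noise and sparse spike artifacts. Foot and hand GSR
share rates but draw independent event streams. HR = state-dependent baseline
(75 / 82 / 92 bpm) + 0.25 Hz, 3 bpm respiratory sinus modulation + AR(1)
noise whose stationary sd grows with stress (1 / 2 / 3.5 bpm). The marker
channel encodes the route; the default route is the seven-period protocol at
realistic one-hour scale. `stress_contrast` linearly scales every
state-dependent difference away from the rest value: 1 is the calibrated
default, 0 removes all separability. All randomness flows from one root seed
through numpy `SeedSequence` spawning; per-recording subject offsets emulate
the large between-subject baseline spread of real sessions.

The generator reproduces the ordering and rough scale of real city-vs-rest
contrasts (e.g. HR city mean exceeding rest by ~17 bpm at default contrast),
not validated electrodermal or cardiac dynamics. Passing tests on it show the
pipeline machinery is correct and can recover a planted state difference; they
do not certify performance on real recordings, where artifacts, non-Poisson
SCR timing and label noise are harsher.

## Desk-scale experiments

The published protocol (nine 60–90 min sessions, 15-epoch training of the
full-width branches per fold) is a full-scale replication target requiring
the real stress-recognition-in-automobile-drivers recordings and far more
compute; the originally reported headline numbers — 95.67 % accuracy /
AUC 0.9870 with 30-s windows and 92.33 % / 0.9619 with 10-s windows, plus
the modality ablations — are therefore *not* reproduced at desk scale and
serve only as optional full-scale targets for users with access to that
dataset. The package's reference experiment
(`contrp.experiments`) is a scaled-down stand-in chosen to run in minutes on
one CPU core: 4 synthetic recordings on a shortened route (rest 40 s /
city 30 s / highway 20 s), 10-s windows, filter widths (8,16,32,64,64),
5 epochs at lr 0.002 with momentum 0.9, batch 4, head-bias calibration,
global balancing. The last two are used only here, to compensate for the
short schedule: within a ~100-step budget, SGD ranks the held-out samples
correctly (per-fold AUC > 0.95) but cannot settle the sigmoid offset — on
some seeds even the *training-set* probabilities sit entirely on one side of
0.5, leaving whole folds predicted as one class. Momentum converges the
convex readout problem an order of magnitude faster at a learning rate the
convolutional stack tolerates, and `TrainConfig.calibrate_bias` then refits
the scalar head bias on the training set only: candidate biases are the
thresholds between consecutive sorted training logits plus the bias-only
cross-entropy optimum (a convex 1-D Newton fit), and the candidate with the
highest training accuracy wins, ties broken by lower cross-entropy — with
uninformative features this reduces exactly to the log-odds of the base
rate. The refit shifts every logit by one constant, so ranking and AUC are
untouched and no held-out information is used. The full-scale defaults
remain plain SGD (momentum 0) and no calibration, as published.

The easy variant uses `stress_contrast = 5` with low sensor noise, a near-zero
rest SCR rate, and the contrast expressed through SCR arrival rates and HR
variability rather than large tonic/mean shifts — recurrence plots are
translation invariant and the channels are z-normalized per recording, so mean
shifts contribute nothing to the windows while inflating the normalization
scale. The null variant sets `stress_contrast = 0` and must return the
pipeline to chance (binomial 95% band around 0.5 on the class-balanced pool).

## Known limitations

* No tonic/phasic electrodermal decomposition or adaptive artifact handling —
  a median filter is the only despiking step.
* The marker encoding is a definition of this artifact's file dialect, not a
  claim about the original waveform-bank format.
* Training determinism is exact under a fixed seed on a given BLAS; across
  BLAS builds bit-level results may differ while remaining statistically
  equivalent.
* Undefined metrics propagate as NaN; downstream consumers must expect NaN
  for degenerate folds (e.g. single-class held-out recordings when a fold has
  no stressed windows).
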