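# Methods

`fallaug` compares five families of data augmentation for wrist-worn IMU
fall detection — signal transforms (rotation, scaling, permutation),
SMOTE, a convolutional autoencoder, a variational autoencoder, and a
class-conditional denoising diffusion model — using a 1-D CNN detector
evaluated under leave-one-group-out cross-validation (LOGO-CV),
train-on-synthetic-test-on-real (TSTR) scoring, and within/between-class
dispersion ratios.  This note records the models, the choices made where
the design was open, and what the built-in synthetic cohort does and
does not establish.

## Data model and preprocessing

The unit of analysis is a 6-channel window (accelerometer x/y/z,
gyroscope x/y/z) of 100 samples at 18.4 Hz, about 5.43 s.  Fall
recordings are segmented with a sliding window of 50 % overlap, so a
recording of n samples yields floor((n−100)/50)+1 windows.  ADL
(activity of daily living) recordings shorter than 1000 samples
(~54.35 s) use the same rule; longer ones are split into ten equal
segments with one uniformly placed window per segment, capping the
contribution of long recordings.  Windows inherit their recording's
class label, so fall windows include stretches before and after the
impact — an intentional source of label difficulty that any detector
has to live with.

Channels are min–max normalized to [−1, 1].  The scaling is *global*
per channel, not per window: per-window scaling would erase the
amplitude difference that separates impacts from daily activity.  The
statistics are fitted on the training split of each CV fold only and
applied to train, test and synthetic windows alike; out-of-range test
values are clipped.  Fold-scoped fitting avoids test-set leakage; a
pipeline that normalized before splitting would produce slightly
different absolute numbers.  Degenerate channels (max = min) map to 0.

## Augmenters and the balancing plan

All augmenters implement one interface: fit on the (normalized) real
training windows of a fold, then draw per-class synthetic counts.  The
counts solve two constraints — the combined real+synthetic training set
is class-balanced, and the synthetic total equals the real training
size — giving `n_synth_fall = n_real_adl` and `n_synth_adl =
n_real_fall` (falls are assumed the minority; the code refuses
otherwise).

* **Transforms (DTF).**  Rotation premultiplies the accelerometer and
  gyroscope triplets by *independent* uniform random 3-D rotations
  (drawn with the invariant measure via quaternions); scaling
  multiplies all six channels by one factor ~ U(0, 2); permutation cuts
  the window into four 25-sample blocks and reorders them identically
  across channels.  Each transform is applied to real windows resampled
  with replacement, is evaluated as its own augmenter, and the reported
  DTF score is the arithmetic mean of the three.
* **SMOTE.**  x_new = x_chosen + (x_nearest − x_chosen)·δ with a scalar
  δ ~ U(0, 1) per sample, distances Euclidean on flattened
  channel-major 600-vectors, the neighbour drawn uniformly from the k=5
  nearest within the class, and base samples cycled so every class
  member is used.  Interpolation cannot leave the data range, so no
  clipping is needed.
* **Autoencoder.**  One model per class.  Valid (unpadded)
  convolutions shorten the signal (98, 49, 47, 23, 21, 10 along the
  encoder); the decoder interleaves linear upsampling (to 21, 47, 98)
  with transposed convolutions back to 6×100.  Trained with Adam
  (3e-4), MSE, batch 64.  A plain autoencoder has no sampling
  mechanism, so generation jitters the latent code of a random real
  window with Gaussian noise scaled by 0.1 × the per-dimension latent
  standard deviation before decoding.  This is the weakest-identified
  part of the design: pure reconstruction would duplicate inputs, and
  prior sampling is undefined for a deterministic autoencoder.
* **VAE.**  One model per class; length-preserving convolutions
  (kernels 5,5,3,3 down, 3,3,5,5 up), a single max-pool to (64, 50),
  and two parallel linear maps on the time axis to a (64, 128)
  Gaussian latent (mean and log-variance; parameterizing log-variance
  keeps σ > 0 by construction).  Loss = summed-squared reconstruction
  + β·KL(N(μ,σ²)‖N(0,1)) in closed form, β = 1, reparameterized
  sampling, Adam 5e-4.  Generation decodes prior draws z ~ N(0, I).
* **Conditional diffusion (DM).**  Forward chain with linear β from
  1e-4 to 0.02 over T = 1000 steps (the standard defaults of the
  original denoising-diffusion formulation), cumulative products computed in
  log space.  The noise predictor is a two-level 1-D U-Net: per level a
  length-preserving convolution (kernel 3) + group normalization (8
  groups) + GELU + single-head temporal self-attention; max-pool(2)
  down, linear-interpolation upsample(×2) with skip concatenation up;
  channel widths 64→128 mirrored (configurable — the audited surface is
  the shape contract, not the width).  Timesteps enter as sinusoidal
  embeddings summed with a learned 2-class embedding table and injected
  additively per level; classifier-free guidance is not used.  Training
  minimizes the simple noise-prediction MSE at per-sample uniform t.
  Sampling runs the ancestral reverse chain with σ_t = sqrt(β_t),
  clipping the implied clean signal to [−1, 1] at each step (the
  `clip_denoised` behaviour of standard diffusion implementations),
  which keeps the chain stable for lightly trained models; final outputs are
  clipped to [−1, 1].

## Detector and metrics

Three convolutional blocks (64 filters, kernel 3, length-preserving;
batch normalization; ReLU; max-pool 2; dropout 0.5 per block) followed
by fully connected layers 768→128→2 and softmax.  Adam 3e-4,
cross-entropy, batch 64.  The dropout rate, its per-block placement and
the hidden width are open design choices; the values above are recorded
in run metadata and configurable.  FALL
is the positive class everywhere.  Accuracy, precision, recall and F1
follow the standard confusion-matrix definitions; ratios with zero
denominators are reported as 0 and flagged.

## Evaluation protocols

LOGO-CV partitions subjects into 4 groups (17 subjects → 4,4,4,5,
larger group last; assignment is sorted-deterministic unless shuffling
is requested).  Per fold, the order is: subsample the real training
windows to the configured fraction (per-class totals exact via largest
remainder across subjects, so the subject structure survives); fit
normalization on that subset; fit the augmenter; draw the plan; train
the detector on real+synthetic (TSTR: synthetic only); evaluate on the
held-out subjects.  Folds whose training data collapse to one class are
skipped with a warning.  Fold metrics are averaged unweighted.

Dispersion statistics flatten windows to 600-vectors.  The
within-class scatter is the prior-weighted mean squared deviation from
class means and the between-class scatter the half prior-weighted sum
of pairwise squared mean distances; both are scalarized as trace
divided by dimension so values are comparable across feature sizes
(the scalarization of the printed matrix-valued definitions is not
uniquely determined; trace/d is used consistently here, so absolute
magnitudes need not match other implementations, though ratios of the
same quantity are comparable).  The ratio S_B/S_W over {synthetic
fall, synthetic ADL} scores class separation (higher better); over
{real, synthetic} after equal-size per-cell subsampling it scores
realism (lower better).  The subsample indices depend only on (class,
cell size), so a synthetic set that copies the real one verbatim
scores exactly 0.  If S_W = 0 the ratio is reported as +inf with a
flag.

The ratio sweep subsamples a fraction f of real training windows and
generates m × that many synthetic windows, split across classes to
balance the combined set when the budget allows; when it cannot
(m too small), the whole budget goes to the minority class and the
cell is flagged — "proportional" allocations that ignore the deficit
would never approach balance.

## The synthetic cohort

All tests and the acceptance script run on a built-in generative
cohort, since the real recordings cannot be redistributed.  The
generator emulates the statistical structure the analysis needs and no
more:

* ADL recordings are quasi-periodic: a 1 g gravity offset on
  accelerometer z plus 1–3 phase-random harmonics at a per-recording
  gait frequency (1.4–2.2 Hz), duration 600–1400 samples so that both
  the sliding-window and the ten-segment branches are exercised.
  Every third ADL recording is a vigorous activity (jumping-like):
  a train of half-sine bursts at 0.2 × the impact peak, echoing the
  vigorous activity types present in real ADL protocols and giving the
  classes a realistic amplitude overlap.
* Fall recordings are 300-sample clips: a quiet lead-in (30–180
  samples of low sway), a broadband loss-of-balance disturbance
  (three oscillations at 2.5–6 Hz, capped at 0.9 × peak), a single
  half-sine impact of ≤ 10 samples whose acceleration norm equals
  `impact_peak_g` (default 4.0 in normalized g units) exactly in the
  noiseless limit, with a correlated gyroscope burst.  Windows cut
  from the lead-in carry the FALL label while looking like
  low-activity ADL — the same label heterogeneity real fall clips
  have, and the main reason a scarce-data baseline underperforms.
* Subjects differ by lognormal amplitude (sd 0.15) and cadence
  multipliers drawn once per subject, making group-wise CV meaningful;
  channel noise is Gaussian (sd 0.15).
* Defaults (17 subjects, 6 ADL + 5 fall recordings each) yield ~25 %
  fall windows, matching the class imbalance of the emulated dataset,
  and a single amplitude threshold separates the classes with ≥ 95 %
  window accuracy — the task is learnable, not trivial.

What passing tests on this cohort shows: the pipeline arithmetic,
the architecture contracts, the statistics, and the *direction* of the
scarce-data augmentation effect.  What it does not show: absolute
performance on real wrist-sensor data, robustness to sensor drift or
saturation, or the relative ranking of augmenters at full scale —
the cohort has none of the hand-motion complexity that makes real
wrist data hard.

## Problem sizes and the tiny profile

The default ("paper") profile uses the full-scale training settings
(T = 1000, 300 detector epochs, widths as above).  The tiny profile —
used by the test suite, the CLI default and the acceptance script —
scales the study down to desk size as the package's own choice of
study conditions: an 8-subject cohort (3 ADL + 3 fall recordings per
subject, ~400 windows), T = 100 with β_end = 0.1 so the terminal
signal retention matches the T = 1000 chain (ᾱ_T < 0.01), U-Net width
32, diffusion training 600 epochs at batch 16 and learning rate 5e-4
(small batches trade gradient quality for optimizer steps, which the
small per-fold window counts make the binding resource), detector 40
epochs, autoencoder/VAE 20 epochs.  Under these conditions the
scarce-data comparison (25 % of real training windows) reproduces the
qualitative finding that conditional-diffusion augmentation raises
mean LOGO-CV F1 over the unaugmented baseline.  The margin is one to
two F1 points — the same order as seed-to-seed variability at this
scale, so individual training seeds can fall on either side of zero;
averaging over seeds, as the evaluation does, is essential, and the
effect grows with the diffusion model's optimization budget.

## Numerical choices

The neural components run on the package's own NumPy layer library
(`fallaug.nn`): manual backpropagation, float32 parameters and
activations, Adam with bias correction, exact-erf GELU, im2col
convolutions, interpolation-matrix upsampling (so the backward pass is
the exact transpose), and single-head scaled-dot-product attention.
Gradients of every layer are finite-difference checked in the test
suite at float64.  All randomness flows from a single master seed
through named child seeds (CRC-derived, < 2^31), so every stage is
independently reproducible; identical seeds give bit-identical models,
samples and reports.

## Known limitations

* The autoencoder generation mechanism (latent jitter) is a design
  choice where the published description is silent; AE-based scores
  are sensitive to the jitter scale.
* VAE prior sampling assumes the aggregate posterior matches N(0, I),
  which light training does not guarantee; VAE samples are the
  blurriest of the five families.
* Diffusion sample fidelity at the tiny profile is limited by the
  optimizer-step budget, not by the architecture; the absolute F1
  numbers reported by the acceptance script are specific to the tiny
  conditions.
* Parameter-count reconciliation against published totals is not
  attempted; the architecture acceptance surface is the activation
  shape audit.
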