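# Methods

## Problem and model

Motor imagery (MI) — mentally rehearsing a left- or right-hand movement —
modulates sensorimotor EEG rhythms over the motor cortex: mu-band
(6–13 Hz) power drops (event-related desynchronization, ERD) and beta-band
(here 17–30 Hz) power rises (event-related synchronization, ERS), both
lateralized contralaterally to the imagined hand. `mivae` classifies
two-class MI trials with a three-stage model:

1. **Input representation.** Each 2-s epoch (500 samples at 250 Hz) of
   each channel is turned into a magnitude spectrogram by an STFT with a
   64-sample Hamming window hopping by 14 samples: 32 frames over the
   first 498 samples (the last 2 samples are discarded) and, with a
   512-point zero-padded FFT, 257 one-sided frequency rows. The mu rows
   (16) and beta rows (23, cubically resized to 15) are stacked per
   channel (31 rows), and channels are stacked in anatomical order:
   a 93 × 32 image for the C3/Cz/C4 montage, 155 × 32 for
   C3/C1/Cz/C2/C4. For the 5-channel short-window protocol (window 32,
   hop 7) the raw frame count is 67; frames are truncated to the first 32
   so the image width the network expects is preserved.
2. **CNN feature extractor.** NF = 30 kernels of size Nh × 3 spanning the
   full image height slide along time only, giving one output row of
   length 30 per filter. The output function is f(a) = ln(1 + e^a)
   (softplus; a conventional max(0, a) is available by config), followed
   by factor-10 max-pooling (zero right-padding) and a two-way dense
   softmax head. Training is plain mini-batch SGD on the cross-entropy.
3. **VAE classifier.** The activated pre-pooling feature maps, flattened
   filter-major to 900 values, feed a variational autoencoder with five
   hidden layers (600–300–100–300–600 by default; the middle layer is a
   diagonal-Gaussian latent with mean μ(x) and variance θ(x)) and a
   Gaussian decoder with learned per-dimension output variance. The three
   (input, latent) stages are pretrained greedily as one-latent-layer VAEs
   by stochastic gradient ascent on the single-sample reparameterized
   ELBO, log p(x | z = μ + √θ·ε) − KL(q(z|x) ‖ N(0, I)), the deterministic
   hidden output softplus(μ(·)) of each stage feeding the next. A two-way
   softmax head on μ(x) is then fine-tuned jointly with the encoder by
   supervised cross-entropy; prediction uses μ(x) deterministically, so
   classification is reproducible. The CNN's own dense head shapes the
   kernels during stage-1 training but is discarded at prediction time;
   the VAE head is the sole classifier of the combined model.

Evaluation follows a chance-corrected protocol: Cohen's kappa
κ = (acc − rand)/(1 − rand) with rand = 0.5 for the balanced two-class
task, measured by 10 independent repetitions of a stratified random
10-fold (90%/10%) partition. Summaries report the mean kappa, the
standard deviation across the 10 repeat-means (the headline ± figure) and
across all 100 folds. Diagnostics include a Lilliefors-corrected
Kolmogorov–Smirnov normality test (Gaussian reference with
sample-estimated moments, via statsmodels) and one-way ANOVA across
methods with pairwise p-values.

## Synthetic data generator

Real MI recordings are not distributable with the package, so every stage
is exercised on a generator that reproduces the statistical structure the
model assumes: a zero-mean Gaussian broadband background (white noise
band-passed 0.5–100 Hz with a 4th-order zero-phase Butterworth filter,
matching a typical recording filter) carrying band-center mu (9.5 Hz) and
beta (23.5 Hz) sinusoids with uniformly random phase per trial and
channel. During the task window the mu amplitude on channels contralateral
to the cued hand is scaled by √(1 − erd_depth) and the beta amplitude by
√(1 + ers_gain); the midline Cz receives half the modulation depth;
ipsilateral channels are untouched. Sinusoids (rather than narrowband
noise) make ERD/ERS band-power ratios analytically exact, which the tests
exploit: the expected task/baseline mu-power ratio on a modulated channel
is (A²/2·(1−d) + P_n)/(A²/2 + P_n) with A the mu amplitude and P_n the
flat in-band background power sd²·bandwidth/(fs/2).

Defaults: fs 250 Hz, 6-s trials with the task in seconds 3–6, mu_amp
1.0 µV, beta_amp 0.7 µV, noise_sd 1.5 µV, erd_depth 0.6, ers_gain 0.5.
The amplitude/noise balance was fixed once so that (a) no-task segments
pass a Lilliefors normality test in well over 90% of seeds — as resting
EEG amplitude distributions do — and (b) the ERD contrast is strong
enough for band-power oracles to resolve. Per-trial seeds are derived as
master seed + trial index, so any subset regenerates independently.

What the generator does *not* emulate: eye-blink/EMG artifacts, 1/f
background spectra, inter-trial nonstationarity, volume-conduction
correlation between channels, or subject variability. Passing tests
therefore demonstrate that the implementation recovers the lateralized
band-power structure it was built for, not that it attains any particular
accuracy on recorded EEG.

## Numerical choices

* Networks are implemented in numpy with hand-derived analytic gradients;
  both stages are verified against central finite differences to relative
  error < 1e-4 (measured ~1e-8 in float64).
* Optimizer: plain SGD without momentum or weight decay, matching the
  stated update rule W ← W − η ∂E/∂W. Learning rate defaults are 0.05 for
  both stages, chosen by convergence experiments on synthetic data (with
  z-scored inputs, smaller rates fail to converge within the epoch
  budgets; larger ones diverge).
* Weight initialization: zero-mean Gaussian, sd 0.01, per-model seed.
* Posterior variance θ(x) = softplus(s(x)) + 1e-6 keeps θ strictly
  positive by construction; the decoder output variance is exp of a free
  per-dimension log-variance clipped to [ln 1e-6, 10].
* ELBO ascent with a free decoder variance is unstable near the variance
  floor (gradients scale as residual/variance), so the ELBO gradient is
  globally norm-clipped at 50 before each SGD step.
* Spectrogram pixels are linear magnitudes by default (power and
  log-magnitude by config). Input images are optionally z-scored with
  statistics computed on the training set only (the pipeline default),
  which conditions SGD without test-set leakage.
* Beta-band bin selection: the inclusive rule
  [floor(f_lo·nfft/fs), ceil(f_hi·nfft/fs)] yields 29 bins for 17–30 Hz;
  the block is trimmed symmetrically (extra bin from the top) to the
  configured 23 rows, pinning the cropped block to its nominal size. The
  same rule yields the mu block's 16 bins exactly.
* Ties at argmax resolve to class 0 (left). Epoch windows are half-open,
  sample indexing 0-based, image row 0 = top = lowest mu frequency of the
  first channel.
* The standalone-VAE ablation input is the Nh × Nt image average-pooled
  on an adaptive 30 × 30 grid (900 values), since no finer-grained
  down-sampling rule is canonical.

## Benchmark sizing

`mivae.benchmarks.run_benchmark` (used by `scripts/acceptance.py` and the
acceptance tests) cross-validates the CNN-VAE, CNN-only and VAE-only
models under identical seeds and partitions on 200 synthetic trials per
class — one 400-trial session — with the full 10×10 scheme. To keep the
benchmark at desk scale on one CPU the training schedules are shortened
to 30 epochs per phase (CNN, VAE pretraining, VAE fine-tuning) and the
VAE hidden sizes narrowed to 200/100/50/100/200; the synthetic task
saturates well before the production schedule (300-epoch CNN, 200+200
epoch VAE at 600/300/100) would add anything. The no-signal control
(erd_depth = ers_gain = 0) runs at 50 trials per class with a 5×5 scheme,
which is ample for a standard-error bound on a mean of zero.

## Known limitations

* The production-scale training schedule is not exercised by the test
  suite; it runs, but its behaviour on recorded EEG is unvalidated here.
* The greedy pretraining transfers decoder affine maps across stages as
  initialization only; the stage-wise ELBOs are not a bound on the full
  model's ELBO.
* GDF/EDF reading requires the optional `mne` dependency and cue
  annotations of the 769/770 (left/right) form; it is untested without
  real files.
* With linear-magnitude pixels the image scale depends on the recording
  amplitude; the optional z-scoring is recommended for any real data.
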