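# Methods

This note documents the models implemented in `neurotask`, the
numerical choices behind them, what the synthetic data generator does
and does not emulate, and the known limitations.

## Problem setting

Five mental tasks (word association, subtraction, navigation, hand and
feet motor imagery) are to be recognized from multichannel EEG without
any labeled training. The package casts the K-class problem as K
one-class problems: for each class a detector is fitted on that class's
trials only, and trials of every other class act as anomalies at test
time. Nothing in any fitting routine receives a label; labels are used
only to form splits and to score the result.

## Artifact removal (spatial MWF)

EEG artifacts (electrode glitches, blinks, movement) are spatially
focused and much stronger than the neural background. With `Ryy` the
channel covariance over artifact-contaminated samples and `Rvv` over
clean samples, the generalized eigenvalue problem `Ryy v = λ Rvv v`
jointly diagonalizes the pair; the filter retains components with
λ > 1 (`eig_gt_one`, artifact power above clean power) or a fixed rank,
and subtracts the artifact estimate `ŷ_art = W y` with
`W = V diag((λ−1)/λ) V⁻¹` on the retained components.

Choices:

* **Spatial-only filter (no delay taps).** Keeps the covariances
  `n_channels²`; temporal taps would square the size for modest gain at
  desk scale.
* **Covariances symmetrized and eigenvalue-floored at 1e-10** so the
  GEVD is always well posed; a singular clean covariance therefore
  degrades gracefully instead of erroring.
* **Automatic marking** is a per-channel robust z-score (median/MAD) of
  peak amplitude over non-overlapping 0.5-s windows, default threshold
  z = 5. Any externally supplied boolean mask is equally accepted —
  marking conventions vary between labs.
* The `eig_gt_one` rule keeps finite-sample components whose λ is only
  slightly above 1; their filter gains `(λ−1)/λ` are small but make the
  filter slightly non-idempotent. When the artifact rank is known
  (e.g., constructed fixtures), `fixed:r` is the cleaner choice.
* MWF is fitted per recording; per-trial fitting would starve the
  covariance estimates.

## Quadratic time-frequency features

Each segment is taken to its analytic signal (FFT Hilbert transform,
one-sided spectrum), then to a discrete pseudo Wigner–Ville
distribution: for time index `n` and integer lag `m`, the windowed
instantaneous autocorrelation `w[m]·a[n+m]·a*[n−m]` is Fourier
transformed over lag. Integer lags correspond to `τ = 2m/fs`, so
`n_fbins` DFT bins cover `[0, fs/2)` — valid for analytic input. The
Hann lag window (default 127 samples, centre weight 1) keeps the time
marginal exact: the frequency sum of every interior time slice equals
`|a(t)|²`.

The Choi–Williams distribution multiplies the ambiguity function (DFT
of the autocorrelation over time) by `exp(−(ϕτ)²/α²)` with doppler ϕ in
cycles/sample and lag τ in samples, then transforms to (t, f). The
kernel is 1 on the ambiguity axes (auto-terms preserved) and decays
away from them (cross-terms suppressed); as `α → ∞` the CWD recovers
the pseudo-WVD exactly (the kernel becomes 1, and the forward/inverse
DFT pair cancels). Default `α = 1` in these units suppresses two-tone
cross-terms at typical EEG band separations by well over half while
leaving single-component ridges untouched. The kernel is applied in the
ambiguity domain — the standard Choi–Williams construction; a
time-frequency-domain reading of the kernel's argument pair is not
implemented.

Feature reduction: per channel, the positive part of the TFR is
integrated over (band × time-bin) cells — default bands
0.5–4–8–12–18–26–40 Hz, 5 contiguous time bins — cells are averaged
over channels, `log(1+x)` compressed, and min-max scaled to [0, 1] for
the Bernoulli DBN input. 6 bands × 5 bins fixes the input width at 30.

**Scaling is global, not per-component.** A single min/max over the
training feature matrix scales all 30 cells jointly. Per-component
min-max (each cell to its own training range) was implemented and
rejected: it amplifies cells that carry only background noise to the
same [0, 1] range as signal cells, and after the 30 → 15 → 5 DBN
compression — which cannot learn the signal/noise distinction from a
few dozen one-class samples — the class contrast drowns in the
renormalized noise (pairwise AUC on the separable fixture collapsed to
0.2–0.8 regardless of the background-noise level, because per-component
scaling is scale-invariant). Global scaling preserves relative energies,
so separability is genuinely controlled by the generator's noise
amplitude. `FeatureScaler(mode="per_component")` remains available.
Scaling is always fitted on the target-class training split only and
reused (with clipping to [0, 1]) for all test data — no leakage.

Unstated protocol details resolved here: classification uses the
3–10 s imagery window by default; sliding windows default to 1 s with
1 s hop (1.5 s in the reduced test configuration).

## Deep belief network

Bernoulli RBMs with energy `E(v,h) = −vᵀWh − b_visᵀv − b_hidᵀh`,
factorized logistic conditionals, CD-k training (k = 5, learning rate
0.001, 1000 epochs, batch 250 by default; tests reduce epochs). The
negative chain samples binary units; the final negative statistics and
all between-layer propagation use probabilities (standard variance
reduction). Inputs in [0, 1] are treated as Bernoulli means. Weight
init N(0, 0.01²), zero biases, no momentum or weight decay. Greedy
layer-wise stacking, widths 30 → 15 → 5 (two RBMs); the forward
transform is deterministic and label-free. All randomness flows through
one seeded generator, so training is bitwise reproducible.

At the sample sizes of the synthetic experiments (~32 trials per class)
CD training moves the weights little; the latent map acts mostly as a
fixed random compression. The pipeline's discrimination then rests on
the features and the scaling preserving class contrast — which is why
the global-scaling choice above is load-bearing.

## Isolation Forest

Implemented from first principles. Trees grow on without-replacement
sub-samples of size ψ (default 256, clipped to the training size; 150
trees), splitting a uniformly drawn attribute at a uniform value within
the node's range, stopping at height `ceil(log₂ ψ)` or singleton
nodes; a constant attribute is re-drawn up to d times before the node
closes (guards against duplicate-heavy data). A point's path length is
the edge count to its external node plus `α(size)` — the average
unsuccessful-BST-search correction — and the score is
`A = 2^(−E[l]/α(ψ))` with `α(n) = 2(ln(n−1) + γ) − 2(n−1)/n`,
`α(0) = α(1) = 0`. `A ∈ [0, 1]`, decreasing in the expected path
length; `E[l] = α(ψ)` gives exactly 0.5, the decision threshold. The
uncertainty band around 0.5 defaults to width 0 (binary decisions);
`ln + γ` approximates the harmonic number to better than 0.01 only for
arguments ≳100, which covers practical sub-sample sizes.

The normalizer's `N` is the per-tree sub-sample size ψ, not the tree
count — the scoring formula normalizes by the training regime of a
single tree.

## Comparators and metrics

LOF (35 neighbors) and Elliptic Envelope (MCD, support fraction 0.9)
delegate to scikit-learn; both return higher-is-more-anomalous scores.
EE input is standardized on training statistics before the MCD fit
(Mahalanobis distance is affine-invariant; latent clouds can have
variances near 1e-8, which otherwise trips degenerate-covariance
guards). Decision thresholds: LOF > 1.5, EE robust distance above the
χ² 97.5% quantile; the headline comparison metric is AUC, which needs
no threshold.

Per (target, other) pair: predicted positive = decided *normal*,
actual positives = target inliers; accuracy `(TP+TN)/total`, recall
`TP/(TP+FN)`, precision `TP/(TP+FP)`, `F1 = 2TP/(2TP+FP+FN)`; zero
denominators return 0 with a warning. AUC is the Mann–Whitney rank
probability that a random outlier outscores a random inlier, ties ½.
The multiclass `predict_class` (argmin anomaly score over the detector
bank, ties to the lowest class id) is an extension beyond the pairwise
protocol and is labeled as such in reports.

## Synthetic data generator

The generator emulates the structure of a cue-based five-task
acquisition: 30 channels (10–20 montage scale) at 256 Hz, 10-s trials,
task signal gated on at the 3-s cue, 1/f^β background (β = 1, RMS
10 µV by default), optional Poisson-arriving spike (one-channel
exponential transient) and blink (frontal half-sine) artifacts. Each
class signature is a narrowband rhythm: a sinusoid whose frequency is
drawn per trial uniformly within the class band (default centers
6/10/14/20/26 Hz, width 2 Hz), random phase, 1-Hz sinusoidal amplitude
modulation, mixed through a class-specific nonnegative spatial pattern
at 5 µV. A tonal carrier was chosen over band-filtered noise because
its per-trial band energy is stable; with a noise carrier the band
energy is χ²-distributed with few effective degrees of freedom, adding
within-class feature variance that no noise dial controls.

What a green end-to-end test establishes: the pipeline recovers known
disjoint-band class structure through artifact filtering, CWD features,
DBN compression and isolation scoring, reproducibly and label-free.
What it does not establish: performance on real EEG — real task
signatures overlap spectrally, drift across sessions and subjects, and
ride on non-stationary backgrounds none of which the generator models.
The separable fixture used by the end-to-end tests is 6 channels,
40 trials/class, 0.5 µV noise (10:1 signal-to-noise amplitude), reduced
CWD grid (63-sample lag window, 128 bins) and 60 DBN epochs — sized for
a single CPU.

## Known limitations

* With ~30 one-class training vectors the DBN is close to a random
  projection; its benefit over feeding features directly to the
  detector is not demonstrable at this scale.
* The Choi–Williams α is dimensionless in (cycles/sample × samples)
  units; comparing values against implementations using physical
  (Hz × s) units requires rescaling.
* Isolation-forest scoring loops over trees in Python; at 150 trees ×
  ψ = 256 it is fast enough for trial-level features but not for
  sample-level streaming.
* EDF reading requires an optional backend (mne or pyedflib) and is
  untested here; CSV/HDF5 are the supported interchange formats.
* The accuracy/precision/F1 columns depend on each detector's decision
  threshold; only AUC is threshold-free, and comparisons across
  detectors should rest on it.
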