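# Methods

`virtustain` implements an AI-based label-free imaging workflow for
heterogeneous cell cultures (the motivating system is mesenchymal
stromal cells, MSCs): a conditional-GAN image translator that predicts
immunofluorescence-like marker images from phase-contrast input, an
evaluation layer built around pixel-level correlation statistics and an
analytic noise ceiling, single-cell morphology/intensity profiling, and
spatiotemporal analysis of expression fluctuations in time-lapse
predictions.  Because quantitative validation requires ground truth
that real micrographs cannot provide, the package ships a synthetic
microscopy simulator; every documented number below is recomputed by
the test suite or by `scripts/acceptance.py`, never quoted from
external data.

## Image translation model

The generator is a U-Net: an encoder/decoder with skip connections
joining features of equal resolution, single channel in and out.  With
depth *d* and base width *c* the encoder applies a 3×3 convolution
(1→c) followed by *d* stride-2 4×4 convolutions doubling the width each
level; the decoder mirrors this with nearest-neighbour upsampling, a
3×3 convolution halving the width, concatenation with the encoder skip,
and a 3×3 merge convolution; all hidden activations are leaky-ReLU
(slope 0.2).  The output layer is a linear 3×3 convolution.  We do
**not** use a saturating output nonlinearity: fluorescence targets are
sparse (mostly background), so with an L1 pixel loss the all-background
constant is a strong local attractor, and a tanh output makes it
gradient-dead — in our experiments training then collapses to constant
images.  With a linear output the same configuration escapes the
constant solution within a few hundred iterations.  Outputs are clipped
to the model range only at inference.

The discriminator is a patch-level convolutional classifier on the
2-channel concatenation of the phase input with a real or predicted
fluorescence image (4×4 stride-2 ×2, then 3×3), producing an
(H/4)×(W/4) grid of realism scores.  Training alternates least-squares
GAN updates (real pair → 1, fake pair → 0; generator pushed toward 1)
with the pixel loss:

    L_G = pixel_loss_weight · mean|G(x) − y| + ½ · adversarial_loss_weight · mean[(D(x, G(x)) − 1)²]

Defaults: pixel:adversarial = 100:1 (the standard paired-translation
weighting; L1 rather than L2 avoids over-smoothing), Adam with
β₁ = 0.5, β₂ = 0.999.  The default learning rate is 1e-3: at the small
iteration budgets this package targets (hundreds to ~2000 iterations on
a CPU) the conventional 2e-4 converges visibly more slowly (held-out
r_s ≈ 0.94 vs ≈ 0.98 at 600 iterations on the synthetic task); both
are configurable.  Setting `adversarial_loss_weight = 0` skips
discriminator construction entirely and yields exactly the supervised
U-Net regression baseline — the generator update path is bit-identical.

Inputs are normalized per image by a 0.1–99.9 percentile window to
[0, 1] and shifted to [−1, 1]; predictions are mapped back to the
[0, 1] intensity scale.  Background subtraction of targets, where
needed, is the caller's responsibility.  Inputs whose size is not a
multiple of 2^depth are reflect-padded and cropped after prediction.
Tile grids are predicted per tile and mosaicked with linear feathering
ramps whose weights sum to one, so constant fields are preserved.

The networks run on a small reverse-mode automatic-differentiation
engine written on NumPy (`virtustain.nn`): convolution is lowered to
BLAS matrix products over an im2col buffer, and every operation's
gradient is verified against central finite differences in the test
suite.  Training is deterministic for fixed (data, config, seed) on a
fixed platform.

## Evaluation metrics

* **Source Pearson correlation r_s** — the Pearson correlation of
  target and prediction pixel intensities,
  Σ(x−x̄)(y−ȳ)/[Σ(x−x̄)²Σ(y−ȳ)²]^{1/2}; captures the overall intensity
  distribution.
* **Laplacian Pearson correlation r_lap** — r_s applied to the
  Laplacian-filtered images; emphasises fine intensity variation.  The
  operator is a zero-sum Laplacian-of-Gaussian with a 31×31 aperture
  and scale σ = 2 px.  The scale matters: with σ grown proportionally
  to the aperture the filter becomes a band-pass centred near the
  signal's own scale and can *suppress* white target noise, making
  r_lap ≥ r_s; σ = 2 keeps the second-derivative (high-pass) character
  so r_lap is the more noise-sensitive statistic, as intended.
  Convolution uses reflect padding, and the correlation is evaluated on
  the interior of the field (excluding a half-kernel margin whenever at
  least 4 interior pixels per axis remain) so border reflection
  artefacts cannot contribute; by kernel symmetry the operator then
  annihilates affine ramps exactly.
* **Mean absolute error** — mean |x−y| on the normalized scale.
* **RMS SNR** — (S_signal − S_noise)/N_noise with the means and
  background standard deviation taken over caller-provided signal and
  background masks.
* **C_max** — for a noisy target T = G + ε with ε uncorrelated with the
  noise-free signal G, no prediction correlates with T better than G
  does, and corr(T, G) = √(SNR/(1+SNR)) with SNR = σ²_G/σ²_ε.  This is
  the ceiling against which measured r_s(SNR) curves are compared.
* **Prediction uncertainty** — empirical central quantiles (no
  parametric assumption) of the cell-level relative error
  (prediction − target)/target, reported as the half-width of the 60%
  interval in percent.

Constant images raise a typed `UndefinedStatisticError` instead of
propagating NaN into aggregate tables.

## Synthetic data generator

The simulator emulates the study conditions end to end:

* **Geometry.** Cells are placed without overlap by rejection sampling
  (400 attempts per cell before a `PlacementError`).  Three phenotypes
  follow the standard visual MSC classification: SS — high-aspect
  ellipses with tapered tips (aspect ≈ 3.6–5.2); RS — small five-point
  stars; FC — large, low-aspect blobs with prominent nuclei.  Nuclei
  are scaled copies of the outline (star-shaped about the centre, so
  containment is guaranteed).  Ground-truth area/axis/eccentricity
  values are computed analytically from the generating polygons via
  Green's-theorem moments.
* **Fluorescence.** Each marker has a localization pattern per cell —
  uniform, membrane (exponential decay from the boundary), perinuclear
  (ring around the nucleus) or punctate — scaled by a non-negative
  per-cell base expression, lightly band-limited (Gaussian σ = 1 px)
  on a dim background.  With base expression fixed at 1 the
  phase→fluorescence mapping is a deterministic function of geometry,
  which is what the translator-learnability checks rely on.
* **Phase contrast.** A deterministic halo-plus-gradient rendering:
  mid-grey background, slightly darker cytoplasm, darker nucleus, and
  a bright rim hugging the boundary.  It reproduces the optical cues a
  translator exploits; exact phase optics are out of scope.
* **Noise and impurities.** Additive zero-mean Gaussian noise with
  variance σ²_ε (matching the uncorrelated-noise assumption behind the
  C_max ceiling; shot noise is not modelled), with σ²_ε calibrated
  against the empirical variance of the rendered noise-free field to
  hit a requested SNR.  Impurity speckles (dust/non-specific blobs) are
  Poisson in number with configurable intensity.
* **Dynamics.** Per-cell scalar expression follows a stationary
  mean-reverting (Ornstein–Uhlenbeck) process with exact
  discretization, x_{t+Δ} = μ + (x_t − μ)e^{−Δ/τ} + σ√(1−e^{−2Δ/τ})ξ,
  so the lag-k autocorrelation is exactly e^{−kΔ/τ}.  Defaults mirror
  the live-imaging protocol: Δ = 2 min over 48 h (1441 frames),
  τ = 40 min, μ = 1, σ = 0.2 (negative excursions are then negligible
  and are not clipped).  Geometry is static over a movie.

What the simulator does **not** emulate: optical point-spread detail,
focus drift, cell migration/division, shot noise, uneven illumination,
or biological coupling between morphology and expression.  Passing
tests therefore demonstrate that the *procedures* are correct on data
whose ground truth is known — not that the specific published
quantities for real MSC cultures are reproduced, which requires the
original imaging data.

## Single-cell profiling

ROIs are polygons (canonical JSON schema; the common binary `.roi`
dialect is also read) rasterized by a pixel-centre-in-polygon test.
Per cell we record mean and integrated intensity per marker and 12
morphological features: cell area, perimeter, aspect ratio,
circularity (4πA/P²), solidity, eccentricity, major/minor axis lengths,
nucleus area, nucleus perimeter, nucleus-to-cell area ratio and nucleus
eccentricity.  Only five of these are fixed by the motivating study
(aspect ratio, nucleus-to-cell ratio, nucleus area, cell area,
perimeter); the other seven are standard shape descriptors chosen here
and documented as provisional.  Axes come from the second-moment
(inertia-equivalent) ellipse, perimeters from the boundary contour
length.

Standardization z-scores each variable; the per-variable relative
spread (sd/mean, %) annotates intensity distributions; zero-variance
variables are excluded with a warning record.  Hierarchical clustering
uses correlation distance (1 − Pearson) with average linkage
(configurable) and is deterministic; the displayed matrix is the fold
change of raw values against each variable's mean.  PCA operates on
the z-scored matrix; loadings are eigenvectors scaled by the explained
standard deviation (biplot convention), with the sign fixed so each
component's largest-magnitude loading is positive (row-order
invariant).

## Temporal analysis

Traces are total in-mask intensity per frame.  Two correlation summaries
distinguish population structure from single-cell dynamics: the
*overall* correlation (across cells at one time point, per marker pair)
and the *fluctuation* correlation (across time within one cell, after
linear detrending by default — detrending separates slow drift from
the stochastic fluctuation and can be disabled).  The ACF uses the
biased (divide-by-n) estimator, which is positive semidefinite, with
acf[0] = 1.  The correlation time τ is a least-squares fit of
exp(−lag/τ) to the ACF head, defined as lags up to the first zero
crossing and capped at a quarter of the available lags — the
anticorrelated tail expected from finite record length is excluded.
Note the known finite-record bias: estimating the mean from the same
trace depresses the ACF by ≈ 2τ/T (≈ 0.028 at τ = 40 min, T = 48 h);
ensemble checks account for it explicitly.

Intracellular heterogeneity is summarised kymograph-style: for each
frame, in-mask pixels are averaged over the image vertical axis to
give a 1-D profile across the cell's bounding box, resampled to 100
position bins so maps stay comparable as the outline changes; profiles
are stacked over time into a position × time matrix.  Its 2-D Fourier
magnitude spectrum (mean-subtracted, optional Hann window,
zero-frequency centred) is reported with physical axes — cycles/µm
from the pixel pitch and cycles/min from the frame interval.  The
unwindowed spectrum satisfies Parseval's identity, which the tests
verify to 1e-6 relative.

## Problem sizes and numerical choices

The shipped configurations are sized for a single CPU: translator
checks train a depth-3, 8-channel model on 64×64 fields (64 training
images, 700 adversarial iterations; data-efficiency sweeps use 20 vs
320 images at 350 supervised iterations), temporal ensembles use 200
cells × 1441 frames, profiling checks 90–100 cells.  The simulator's
condition parameters (2-min sampling over 48 h, τ = 40 min, SNR grid
0.5–32, impurity rates) are fixed properties of the emulated study
design, not tuning knobs.

Other numerical details: images are stored as 16-bit TIFF with a
linear [0, 1] convention recorded in the description tag; internal
computation is floating point.  Network parameters and activations are
float32 (gradient checks run the same engine in float64).  Clustering
and linkage tie-breaks follow SciPy's deterministic index order.
Checkpoints are single-file archives carrying parameters, config,
normalization convention and a format version that the loader refuses
to mismatch.

## Known limitations

* The translator is sized for small fields and CPU budgets; it is not a
  large-scale training framework (no GPU path, no data augmentation).
* The phase rendering is a caricature of phase optics; models trained
  on it will not transfer to real micrographs.
* Automatic segmentation is intentionally absent — ROIs are inputs, and
  phenotype labels are consumed, never computed.
* The 12-feature morphology set is provisional where the motivating
  study names only five features.
* Real-data headline values (e.g. mean r_s across real markers,
  real-culture correlation times) are out of scope without the original
  imaging data; the package reproduces and verifies the procedures on
  synthetic ground truth.
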