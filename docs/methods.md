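# Methods

This note documents the models, conventions, and design choices behind
`k2image`, in the spirit of a methods appendix: what is computed, under
which assumptions, and why the open choices were resolved the way they are.

## Radial trajectories

Spokes carry `n_samples` equidistant samples at radius `2πm/n_samples`
(radians/pixel), `m = −n_samples/2+1 … n_samples/2`, so every spoke passes
exactly through the k-space origin and the outermost sample reaches
`|k| = π`. Two angle schemes:

* **uniform** — `φ_k = k/n_spokes · 2π`. The fan spans the full circle
  rather than a half-turn; opposing spokes therefore sample conjugate
  positions, which is redundant for real-valued objects but not for the
  complex-valued images used here. The formula is implemented literally.
* **mrlinac** — the non-uniform distribution of a 0.35 T MR-Linac
  real-time sequence: a four-fold denser uniform fan of `4·n_spokes` base
  angles is subsampled with stride 4 (offset = `frame_index`, our reading
  of the scanner's four shifted spoke groups — the exact group-to-frame
  mapping is not documented and is an assumption), and each base angle θ is
  warped by `φ = arctan(2 tan θ)`. The arctangent is multivalued; we
  resolve it quadrant-preservingly as `atan2(2 sin θ, cos θ)` so the warped
  spokes stay distributed over the full circle, as the scanner's do.

Spoke-count rules: full sampling needs `round(w_img·π/2)` spokes
(Nyquist-equivalent angular sampling; 201 at `w_img = 128`). For an
undersampling factor `R`, the spoke count is the **odd integer nearest** to
`full/R`, rounding up at an exact even tie. Nearest-odd is the unique rule
that reproduces the canonical count list {101, 67, 51, 41, 33, 21} for
`R = {2, 3, 4, 5, 6, 10}` at 128×128; odd counts also avoid coincident
opposing spokes.

Point ordering is fixed package-wide: spoke-major, sample index ascending.
Every flattened model input uses this order, and it is recorded in saved
model containers.

## Fourier conventions

Pixel `i` has spatial coordinate `r = i − w/2`; k-space grid index `g` has
frequency `2π(g − w/2)/w`. All centered transforms are
fftshift/ifftshift sandwiches around the standard FFT. The learned model
uses the **orthonormal** centered pair, so the k-space-domain residual
equals the image-domain real/imaginary MSE (Parseval); training targets
use the exactly matching forward transform, making training and inference
self-consistent. Any self-consistent normalization reproduces the method —
absolute image scales under a different convention differ only by a
constant factor.

## Gridding NUFFT

Forward: apodization correction (division by the kernel's analytic Fourier
transform), zero-padding to a `wksp = 2·w_img` grid, centered unnormalized
FFT, and Kaiser-Bessel interpolation onto the trajectory points with a
6×6-cell kernel. The shape parameter β follows the standard
minimum-aliasing rule for kernel width `J` and oversampling ratio α
(`β = π·sqrt((J/α·(α−0.5))² − 0.8)`). The adjoint is the exact algebraic
adjoint (spreading, inverse FFT, deapodization, crop), so the pair passes
the dot test to machine precision by construction. Interpolation indices
wrap modulo the grid — exact for the periodic DFT spectrum of an
integer-pixel image, including the `|k| = π` boundary samples. Measured
accuracy against the exact direct-summation NDFT is ~1e−5 relative at
`w_img ≤ 64`, well inside the 1e−3 budget used in tests.

The zero-filled baseline weights each sample by the radial density
correction `(|k|⁴ + D⁴)^(1/4) ≈ |k|`, where `D > 0` keeps the k-space
center from being zeroed. Default `D = 0.0043` at `n_samples = 256`,
scaled as `0.0043·(256/n_samples)` for other sizes so that `D` stays a
fixed fraction of the radial sample spacing `2π/n_samples` — `D` is an
empirical constant and this scaling is our convention. The baseline's
output intensity is calibrated once per (trajectory, gridding, D): the
pipeline is applied to a constant-1 phantom and reconstructions are divided
by the resulting peak, so a unit phantom reconstructs to ≈1. Metrics
comparing methods on magnitude images rely on this calibration; the
convention is recorded in the evaluation metadata.

## Synthetic data generator

The generator emulates two properties of real complex MR images: a
non-negative, piecewise-smooth magnitude, and a phase dominated by smooth
spatial variation (field inhomogeneity, coil phase) with a weaker
structure-correlated component. Concretely:

* **magnitude** — random ellipses and rectangles of random intensity plus
  band-limited Gaussian texture, min-max normalized to [0, 1] exactly;
  alternatively any raster image via grayscale conversion, resize, and
  min-max normalization (constant inputs map to zeros).
* **phase** — `H + S`, where `H` is the magnitude minus its Gaussian blur
  (σ = `w_img/16` pixels — the simplest separable high-pass), rescaled to
  [−0.25, 0.25] rad, and `S` is white noise on a coarse `(w_img/8)²` grid,
  bilinearly upsampled and rescaled to [−π, π] rad. "Slowly varying" is
  otherwise underdetermined; the coarse-grid construction is our choice.
* **k-space** — forward gridding NUFFT at the trajectory points, divided
  by the global normalization `w_img²`.

What the generator does **not** emulate: sequence-specific contrast (bSSFP
vs gradient echo), correlated multi-coil noise, motion, off-resonance.
Passing tests therefore demonstrate that the method recovers
piecewise-smooth complex images from undersampled radial data under the
stated noise model — not scanner-grade generalization.

Measurement noise is complex Gaussian, independent per real/imaginary
component. The level is specified as a target PSNR (dB, peak 1) of the
fully sampled Cartesian reconstruction and converted analytically:
per-component image noise of std `σ_img = 10^(−PSNR/20)` corresponds to
k-space noise of std `σ = σ_img / w_img` on the normalized scale (the
inverse transform of white noise concentrates by one factor of `w_img`).
The default condition is 50 dB, interpreted as decibels; a Monte-Carlo
round-trip test verifies the calibration to 0.5 dB. Per-sample seeds are
derived from a global seed with NumPy seed sequences and recorded in each
sample.

## The learned model and its training

`A` has `n_spokes·n_samples·w_img²` parameters (423,624,704 at 101 spokes
× 256 samples × 128²), no bias, no activation; one real matrix serves both
channels, which makes the composite complex map commute with multiplication
by i — hence the magnitude output is invariant to a global input phase.
Weights initialize from a zero-mean Gaussian with std
`1/sqrt(n_spokes·n_samples)` (initialization is not otherwise constrained).

Training minimizes the MSE over the real and imaginary image planes with
Adam (defaults: lr 5e−6, β₁ = 0.9, β₂ = 0.98, ε = 1e−9, batch 128),
a reduce-on-plateau schedule on the **validation** loss (patience 5,
factor 0.8, absolute threshold 1e−10) and early stopping once the best
validation loss has not improved by more than `1e−4 × best` for 30 epochs;
the monitored quantity is our resolution of an ambiguity (train vs
validation loss), chosen because the augmentations make the training loss a
biased estimate. Weights are snapshotted at every new best validation loss
and the best snapshot is returned. Augmentations act on inputs only:
`floor(n_spokes/8)` spokes zeroed per sample per epoch (floor is our
rounding choice), and uniform [0.8, 1.2] multiplicative noise applied
**per element** (the stronger regularizer; a per-sample scalar is one
config switch away). Augmentation draws are keyed by (seed, epoch) and
consumed in sample-index order, so histories are bit-reproducible and
independent of batching.

Because the pipeline is linear, the training objective is linear least
squares and `closed_form_fit` computes its global optimum from the normal
equations. Radial sampling operators are often **structurally
rank-deficient** — every spoke samples the DC point, and the projection of
a `w`-wide image onto a spoke direction spans fewer than `n_samples`
degrees of freedom — so the unregularized normal equations can be exactly
singular. `ridge="auto"` uses `sqrt(machine ε) · λ_max`, the smallest
regularization that is numerically meaningful; smaller values resolve
directions dominated by the gridding operator's own ~1e−5 approximation
error, i.e. they fit numerical noise.

Desk-scale problem sizes are used throughout the test suite as the
package's own experimental design: the optimizer-equivalence check runs at
`w_img = 16`, `R = 4` with 2000 samples, where Adam (with a
size-appropriate lr 1e−2, batch 1000, and proportionally longer scheduler
patience — the full-scale defaults are tied to a 128² problem with 200k
samples) reaches the closed-form objective within 5%. The
learned-vs-conventional comparison runs at `w_img = 64` over
`R ∈ {2, 4, 6}` with 4000 training and 100 test samples, fitting each
model with the closed-form solver (the objective's global optimum, which
gradient training approaches by the equivalence result) to keep the full
protocol within minutes on one CPU.

## Compressed-sensing baseline

`argmin_x ½‖Ax − y‖² + λ‖Ψx‖₁` with `A` the normalized forward NUFFT
(no density correction inside the data term, matching standard practice; a
constant-1 sensitivity map, i.e. one effective coil), `Ψ` an orthogonal
Daubechies-4 wavelet with periodization boundary (level 4, capped so no
subband falls below the filter length), λ = 1e−5 by default, and at most
2000 iterations. The solver is FISTA with soft thresholding of all wavelet
coefficients and a monotone restart; the step is `1/λ_max(AᴴA)` with the
eigenvalue from power iteration (1e−4 relative tolerance). The stopping
tolerance (1e−8 relative objective change) is deliberately tight so the
iteration cap is usually binding. Absolute output scale follows the
package's operator normalization; comparisons use magnitude images and the
calibration conventions above.

## Evaluation protocol

MSE and SSIM (Gaussian window σ = 1.5, k₁ = 0.01, k₂ = 0.03, data range =
reference maximum) on magnitude images, summarized per (method, R, noise
condition) by median and lower/upper quartiles with the linear
interpolation convention (recorded in the output metadata). Display
windowing clips to intensity percentiles (default [0, 99]) and rescales to
[0, 1], with a guarded degenerate case for constant images. Timing
harness results are hardware-dependent and carry no acceptance weight.

## Known limitations

* The dense weight matrix is memory-hungry at full scale (≈1.7 GB in
  float32 at `R = 2`, 128²); the package targets desk-scale study of the
  method, not deployment.
* Gradient training at full scale is supported but slow in pure NumPy; the
  closed-form solver is exact only while the normal matrix
  (`n_in × n_in`) fits in memory.
* The generator's procedural magnitudes are simpler than natural-image or
  anatomical sources; absolute MSE/SSIM levels are therefore not
  comparable across data sources, only method orderings are.
* No scanner raw-data readers; real acquisitions must be converted to the
  package's HDF5 k-space layout by the user.
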