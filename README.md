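# k2image

Learned k-space-to-image reconstruction of radially undersampled 2D MRI
data, for low-latency real-time applications (MR-guided interventions,
MR-guided radiotherapy on MR-Linac systems) where images must be formed
from a handful of radial spokes in milliseconds.

## The problem and the model

Radial MRI acquires k-space along `n_spokes` straight lines ("spokes")
through the k-space center,

```
(kx, ky)(φ, m) = (2πm / n_samples) · (cos φ, sin φ),
      m = −n_samples/2 + 1, …, n_samples/2,
```

and accelerates imaging by acquiring fewer spokes than the
`round(w_img · π/2)` needed for full sampling (undersampling factor `R`).
Conventional reconstruction either regrids the samples with a zero-filled
density-corrected adjoint NUFFT — fast but heavily streaked — or solves an
iterative l1-wavelet compressed-sensing (CS) problem — clean but far too
slow for real time.

`k2image` implements a middle path: a **single bias-free linear layer**
with real weight matrix `A` (shape `w_img² × n_spokes·n_samples`, shared
between the real and imaginary channels) maps the flattened radial samples
to a `w_img × w_img` Cartesian k-space plane,

```
k_cartesian = A · k_radial ,      image = iFFT2(k_cartesian) ,
```

followed by an explicit centered 2D inverse FFT. Because the whole map is
linear and the loss is the MSE on the real/imaginary image parts, training
is a linear least-squares problem: the package offers both the gradient
recipe (Adam, reduce-on-plateau scheduler, early stopping, spoke-dropout
and multiplicative-noise augmentations) and an exact closed-form ridge
solver that serves as its oracle. At inference the magnitude image is
taken; multi-coil data are combined by root-sum-of-squares.

Training data are synthetic: procedurally generated grayscale magnitudes in
[0, 1] (or any user-supplied image folder) are combined with an MR-like
phase — a high-pass-filtered copy of the magnitude in [−0.25, 0.25] rad
plus a smooth random field in [−π, π] rad — as `M·exp(iP)`, and the radial
k-space is simulated with a Kaiser-Bessel gridding NUFFT and normalized by
`w_img²`. No scanner data are required.

## Worked example

Fit a model for `R = 4` at 64×64 and compare it with the adjoint-NUFFT
baseline on noisy held-out samples (complex Gaussian k-space noise
calibrated to a fully-sampled-Cartesian PSNR of 50 dB):

```python
import numpy as np
from k2image import (TrajectorySpec, build_trajectory, make_dataset,
                     KSpaceToImage, adjoint_recon, mse,
                     spokes_for_undersampling, calibrate_noise_sigma,
                     add_kspace_noise)

w = 64
spec = TrajectorySpec(w_img=w, n_samples=2 * w,
                      n_spokes=spokes_for_undersampling(w, 4))
train = make_dataset(4000, spec, seed=0)
test = make_dataset(5, spec, seed=1)

res = KSpaceToImage(train, spec=spec).fit(method="closed_form", ridge="auto")
print(res.summary())

traj = build_trajectory(spec)
sigma = calibrate_noise_sigma(w, 50.0)
for i, s in enumerate(test[:3]):
    noisy = add_kspace_noise(s.kspace, sigma, seed=100 + i)
    ml = res.infer_magnitude(noisy)
    nu = adjoint_recon(noisy, traj)
    print(f"sample {i}:  MSE(ML) = {mse(ml, s.image.magnitude):.5f}   "
          f"MSE(NUFFT) = {mse(nu, s.image.magnitude):.5f}")
```

Output:

```
R=4 at 64x64: 25 spokes x 128 samples
k-space-to-image linear reconstruction model
==============================================
trajectory        : uniform, 25 spokes x 128 samples
image size        : 64 x 64
parameters        : 13,107,200
fit method        : closed_form
ridge             : 0.000280168
sample 0:  MSE(ML) = 0.00121   MSE(NUFFT) = 0.04384
sample 1:  MSE(ML) = 0.00085   MSE(NUFFT) = 0.08537
sample 2:  MSE(ML) = 0.00100   MSE(NUFFT) = 0.06747
```

The learned interpolator suppresses the streaking that dominates the
zero-filled adjoint reconstruction, cutting the MSE against the ground
truth by more than an order of magnitude at this undersampling factor.
`k2image.experiments.undersampling_comparison` runs the full protocol —
one model per `R`, MSE/SSIM over a test set, median/quartile summaries.

## Command line

A thin CLI wraps the library for reproducible runs driven by a YAML
configuration (see `k2image.config.RunConfig`):

```sh
k2image gen-data  -c run.yaml     # synthetic train/val/test dataset (HDF5)
k2image train     -c run.yaml     # Adam training, model + history.csv
k2image recon     -c run.yaml --method ml|nufft|cs --input k.h5 --output img.h5
k2image eval      -c run.yaml --methods ml,nufft,cs --model model.h5
k2image bench-time -c run.yaml    # median wall-clock per method
```

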