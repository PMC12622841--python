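"""Synthetic MR-like training data.

Real complex-valued MR images combine a non-negative magnitude with a phase
that varies slowly across space (field inhomogeneity, coil phase) plus a
weak structure-correlated component.  The generator emulates this: a
grayscale magnitude in [0, 1] is combined with a phase built from

* a low-contrast high-pass-filtered copy of the magnitude, rescaled to
  [-0.25, 0.25] rad, and
* a spatially smooth random field, rescaled to [-pi, pi] rad,

as ``M * exp(i * P)``.  Radial k-space data are then simulated with the
forward NUFFT and divided by the global normalization factor ``w_img**2``.

Magnitudes come either from a procedural generator (random ellipses and
rectangles plus band-limited texture — the default, so the package is fully
self-contained) or from any user-supplied grayscale image folder via
:func:`load_magnitude`.

k-space noise for robustness experiments is complex Gaussian (independent
real/imaginary components); :func:`calibrate_noise_sigma` converts a target
image-domain PSNR (in dB, peak 1) into the per-component k-space standard
deviation on the normalized scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import ndimage

from .nufft import GriddingConfig, nufft_forward
from .trajectories import RadialTrajectory, TrajectorySpec, build_trajectory

__all__ = [
    "ComplexImage",
    "RadialKSpace",
    "Sample",
    "procedural_magnitude",
    "load_magnitude",
    "make_phase",
    "compose_complex",
    "simulate_radial_kspace",
    "add_kspace_noise",
    "calibrate_noise_sigma",
    "make_dataset",
]


@dataclass(frozen=True)
class ComplexImage:
    """A square complex-valued image (ground truth / reconstruction target)."""

    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError(f"expected a square 2D array, got shape {d.shape}")

    @property
    def w_img(self) -> int:
        return self.data.shape[0]

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)


@dataclass(frozen=True)
class RadialKSpace:
    """Non-Cartesian k-space samples, shape (n_spokes, n_samples).

    ``normalized`` records whether the values were divided by ``w_img**2``
    (always true for simulated data).
    """

    data: np.ndarray
    spec: TrajectorySpec = field(repr=False)
    normalized: bool = True

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.shape != (self.spec.n_spokes, self.spec.n_samples):
            raise ValueError(
                f"k-space shape {d.shape} inconsistent with spec "
                f"({self.spec.n_spokes}, {self.spec.n_samples})")


@dataclass(frozen=True)
class Sample:
    """One paired (ground-truth image, radial k-space) training sample."""

    image: ComplexImage
    kspace: RadialKSpace
    seed: int


def _minmax(x: np.ndarray, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    """Min-max rescale to [lo, hi]; a constant input maps to all-lo."""
    span = x.max() - x.min()
    if span == 0:
        return np.full_like(x, lo, dtype=float)
    return lo + (hi - lo) * (x - x.min()) / span


def procedural_magnitude(w_img: int, seed: int) -> np.ndarray:
    """Procedural grayscale magnitude in [0, 1]: piecewise-smooth shapes
    (random ellipses and rectangles) plus band-limited texture."""
    if w_img < 8:
        raise ValueError(f"w_img must be >= 8, got {w_img}")
    rng = np.random.default_rng(seed)
    img = np.zeros((w_img, w_img))
    yy, xx = np.mgrid[0:w_img, 0:w_img].astype(float)
    n_shapes = rng.integers(4, 9)
    for _ in range(n_shapes):
        inten = rng.uniform(-1.0, 1.0)
        cx, cy = rng.uniform(0.1 * w_img, 0.9 * w_img, size=2)
        if rng.random() < 0.5:  # ellipse
            a, b = rng.uniform(0.05 * w_img, 0.4 * w_img, size=2)
            th = rng.uniform(0, np.pi)
            xr = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
            yr = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
            mask = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
        else:  # axis-aligned rectangle
            hw, hh = rng.uniform(0.05 * w_img, 0.35 * w_img, size=2)
            mask = (np.abs(xx - cx) <= hw) & (np.abs(yy - cy) <= hh)
        img[mask] += inten
    texture = ndimage.gaussian_filter(rng.standard_normal((w_img, w_img)),
                                      sigma=max(1.0, w_img / 32.0))
    img += 0.3 * _minmax(texture, -1.0, 1.0)
    return _minmax(img)


def load_magnitude(path, w_img: int) -> np.ndarray:
    """Load a raster image, convert to grayscale, resize to (w_img, w_img),
    and min-max normalize to [0, 1]."""
    from skimage import io as skio
    from skimage.color import rgb2gray, rgba2rgb
    from skimage.transform import resize

    img = skio.imread(path)
    if img.ndim == 3:
        if img.shape[-1] == 4:
            img = rgba2rgb(img)
        img = rgb2gray(img)
    img = resize(img.astype(float), (w_img, w_img), anti_aliasing=True)
    return _minmax(img)


def make_phase(magnitude: np.ndarray, seed: int,
               highpass_sigma: Optional[float] = None,
               coarse_cells: Optional[int] = None) -> np.ndarray:
    """MR-like phase map: high-pass-filtered magnitude in [-0.25, 0.25] rad
    plus a smooth random field in [-pi, pi] rad.

    The high-pass filter is the magnitude minus its Gaussian blur
    (sigma = w_img/16 by default); the smooth field is coarse-grid white
    noise bilinearly upsampled (default (w_img/8)^2 grid cells).
    """
    mag = np.asarray(magnitude, dtype=float)
    w = mag.shape[0]
    if highpass_sigma is None:
        highpass_sigma = w / 16.0
    if coarse_cells is None:
        coarse_cells = max(2, w // 8)
    rng = np.random.default_rng(seed)
    high = mag - ndimage.gaussian_filter(mag, sigma=highpass_sigma)
    H = _minmax(high, -0.25, 0.25) if high.max() > high.min() else np.zeros_like(mag)
    coarse = rng.standard_normal((coarse_cells, coarse_cells))
    smooth = ndimage.zoom(coarse, w / coarse_cells, order=1, grid_mode=True,
                          mode="nearest")[:w, :w]
    S = _minmax(smooth, -np.pi, np.pi)
    return H + S


def compose_complex(M: np.ndarray, P: np.ndarray) -> ComplexImage:
    """Combine magnitude and phase as ``M * exp(i P)``."""
    M = np.asarray(M)
    P = np.asarray(P)
    if M.shape != P.shape:
        raise ValueError(f"shape mismatch: {M.shape} vs {P.shape}")
    return ComplexImage(data=M * np.exp(1j * P))


def simulate_radial_kspace(image: ComplexImage, traj: RadialTrajectory,
                           cfg: Optional[GriddingConfig] = None) -> RadialKSpace:
    """Forward NUFFT at the trajectory points, normalized by ``w_img**2``."""
    if image.w_img != traj.spec.w_img:
        raise ValueError(
            f"image width {image.w_img} != trajectory w_img {traj.spec.w_img}")
    samples = nufft_forward(image.data, traj, cfg) / traj.spec.w_img**2
    return RadialKSpace(
        data=samples.reshape(traj.spec.n_spokes, traj.spec.n_samples),
        spec=traj.spec, normalized=True)


def add_kspace_noise(kspace: RadialKSpace, sigma: float, seed: int) -> RadialKSpace:
    """Add zero-mean Gaussian noise of std ``sigma`` independently to the
    real and imaginary part of every sample."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return kspace
    rng = np.random.default_rng(seed)
    noise = rng.normal(scale=sigma, size=kspace.data.shape) \
        + 1j * rng.normal(scale=sigma, size=kspace.data.shape)
    return RadialKSpace(data=kspace.data + noise, spec=kspace.spec,
                        normalized=kspace.normalized)


def calibrate_noise_sigma(w_img: int, target_psnr_db: float) -> float:
    """Per-component k-space noise std (normalized scale) for a target
    image-domain PSNR in dB.

    For a fully sampled Cartesian k-space of a unit-peak image on the
    ``w_img**2``-normalized scale, inverting with the package FFT convention
    turns per-component k-space noise of std ``sigma`` into per-component
    image noise of std ``w_img * sigma``.  Setting PSNR = 20 log10(1/sigma_img)
    with peak 1 gives ``sigma = 10**(-PSNR/20) / w_img``.
    """
    if w_img < 8:
        raise ValueError(f"w_img must be >= 8, got {w_img}")
    if target_psnr_db <= 0:
        raise ValueError(f"target_psnr_db must be > 0, got {target_psnr_db}")
    return 10.0 ** (-target_psnr_db / 20.0) / w_img


def _sample_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)


def make_dataset(n: int, spec: TrajectorySpec, seed: int,
                 noise_sigma: float = 0.0,
                 cfg: Optional[GriddingConfig] = None,
                 traj: Optional[RadialTrajectory] = None) -> List[Sample]:
    """Generate ``n`` independent (image, radial k-space) samples.

    Per-sample seeds are derived from the global seed; noise (if any) is
    applied to the k-space only — the ground-truth image stays noise-free.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if traj is None:
        traj = build_trajectory(spec)
    seeds = _sample_seeds(seed, n)
    out: List[Sample] = []
    for s in seeds:
        s = int(s)
        mag = procedural_magnitude(spec.w_img, seed=s)
        phase = make_phase(mag, seed=s ^ 0x9E3779B9)
        image = compose_complex(mag, phase)
        ksp = simulate_radial_kspace(image, traj, cfg)
        if noise_sigma > 0:
            ksp = add_kspace_noise(ksp, noise_sigma, seed=s ^ 0x7F4A7C15)
        out.append(Sample(image=image, kspace=ksp, seed=s))
    return out
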