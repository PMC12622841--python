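"""Radial k-space sampling trajectories.

A radial trajectory consists of ``n_spokes`` straight lines ("spokes") through
the k-space center, each carrying ``n_samples`` equidistant samples.  The
sample at index ``m`` of a spoke with angle ``phi`` sits at

    (kx, ky) = (2*pi*m/n_samples) * (cos(phi), sin(phi)),

with ``m`` running from ``-n_samples/2 + 1`` to ``n_samples/2``, so the
outermost sample reaches exactly ``|k| = pi`` (radians per pixel) and every
spoke passes through the origin at ``m = 0``.

Two angle schemes are supported: ``uniform`` (equidistant angles over the full
circle) and ``mrlinac`` (the non-uniform angle distribution of a 0.35 T
MR-Linac real-time sequence, where four interleaved groups of spokes are
subsampled from a four-fold denser fan and warped by ``phi = arctan(2 tan
theta)``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrajectorySpec",
    "RadialTrajectory",
    "uniform_angles",
    "mrlinac_angles",
    "spokes_for_full_sampling",
    "spokes_for_undersampling",
    "build_trajectory",
]

_SCHEMES = ("uniform", "mrlinac")


@dataclass(frozen=True)
class TrajectorySpec:
    """Immutable description of a radial sampling pattern.

    Parameters
    ----------
    w_img : int
        Reconstructed image width in pixels (positive even integer).
    n_samples : int
        Samples per spoke (positive even integer); sample index m spans
        ``-n_samples/2 + 1 .. n_samples/2``.
    n_spokes : int
        Number of spokes (>= 1).
    scheme : {"uniform", "mrlinac"}
        Angle distribution.
    frame_index : int
        For the mrlinac scheme, which of the four interleaved spoke groups
        this frame uses (0..3).  Ignored for the uniform scheme.
    """

    w_img: int
    n_samples: int
    n_spokes: int
    scheme: str = "uniform"
    frame_index: int = 0

    def __post_init__(self) -> None:
        if self.w_img < 2 or self.w_img % 2:
            raise ValueError(f"w_img must be a positive even integer, got {self.w_img}")
        if self.n_samples < 2 or self.n_samples % 2:
            raise ValueError(
                f"n_samples must be a positive even integer, got {self.n_samples}"
            )
        if self.n_spokes < 1:
            raise ValueError(f"n_spokes must be >= 1, got {self.n_spokes}")
        if self.scheme not in _SCHEMES:
            raise ValueError(f"scheme must be one of {_SCHEMES}, got {self.scheme!r}")
        if not 0 <= self.frame_index <= 3:
            raise ValueError(f"frame_index must be in [0, 3], got {self.frame_index}")

    @property
    def n_points(self) -> int:
        return self.n_spokes * self.n_samples


@dataclass(frozen=True)
class RadialTrajectory:
    """Flattened (kx, ky) coordinates of a radial trajectory.

    Point ordering is spoke-major with the sample index m ascending within
    each spoke; this ordering is the package-wide flattening convention for
    model inputs.  Coordinates are in radians per pixel, |k| <= pi.
    """

    kx: np.ndarray
    ky: np.ndarray
    angles: np.ndarray
    spec: TrajectorySpec = field(repr=False)

    @property
    def radii(self) -> np.ndarray:
        return np.hypot(self.kx, self.ky)


def uniform_angles(n_spokes: int) -> np.ndarray:
    """Equidistant spoke angles ``phi_k = k/n_spokes * 2*pi``, k = 0..n-1."""
    if n_spokes < 1:
        raise ValueError(f"n_spokes must be >= 1, got {n_spokes}")
    return np.arange(n_spokes) * (2.0 * np.pi / n_spokes)


def mrlinac_angles(n_spokes: int, frame_index: int) -> np.ndarray:
    """Non-uniform MR-Linac spoke angles for one interleaved frame.

    The scanner subsamples ``n_spokes`` angles from a four-fold denser uniform
    fan of ``4*n_spokes`` base angles (stride 4, offset ``frame_index``) and
    warps each base angle theta through ``phi = arctan(2 tan theta)``.  The
    arctan branch is resolved quadrant-preservingly via
    ``atan2(2 sin theta, cos theta)`` so the warped spokes stay distributed
    over the full circle.  Results are reduced to [0, 2*pi).
    """
    if n_spokes < 1:
        raise ValueError(f"n_spokes must be >= 1, got {n_spokes}")
    if not 0 <= frame_index <= 3:
        raise ValueError(f"frame_index must be in [0, 3], got {frame_index}")
    base = np.arange(4 * n_spokes) * (2.0 * np.pi / (4 * n_spokes))
    theta = base[frame_index::4]
    phi = np.arctan2(2.0 * np.sin(theta), np.cos(theta))
    return np.mod(phi, 2.0 * np.pi)


def spokes_for_full_sampling(w_img: int) -> int:
    """Spokes needed for full radial sampling: round(w_img * pi / 2).

    Nyquist-equivalent angular sampling for a w_img-wide image; for
    w_img = 128 this gives 201 spokes.
    """
    if w_img < 2:
        raise ValueError(f"w_img must be >= 2, got {w_img}")
    return int(np.rint(w_img * np.pi / 2.0))


def spokes_for_undersampling(w_img: int, R: float) -> int:
    """Odd spoke count nearest to ``spokes_for_full_sampling(w_img) / R``.

    Undersampling factor R > 0; an exactly even quotient (equidistant between
    two odd integers) rounds up.  For w_img = 128 this reproduces
    {101, 67, 51, 41, 33, 21} for R = {2, 3, 4, 5, 6, 10}.
    """
    if R <= 0:
        raise ValueError(f"R must be > 0, got {R}")
    q = spokes_for_full_sampling(w_img) / R
    lo = 2 * math.floor((q - 1.0) / 2.0) + 1  # largest odd <= q (or q itself)
    hi = lo + 2
    if q - lo < hi - q:
        return max(lo, 1)
    return hi  # nearer to hi, or exact tie -> round up


def build_trajectory(spec: TrajectorySpec) -> RadialTrajectory:
    """Materialise the (kx, ky) sample coordinates for a trajectory spec."""
    if spec.scheme == "uniform":
        angles = uniform_angles(spec.n_spokes)
    else:
        angles = mrlinac_angles(spec.n_spokes, spec.frame_index)
    m = np.arange(-spec.n_samples // 2 + 1, spec.n_samples // 2 + 1)
    radius = 2.0 * np.pi * m / spec.n_samples  # (n_samples,)
    kx = np.outer(np.cos(angles), radius).ravel()
    ky = np.outer(np.sin(angles), radius).ravel()
    return RadialTrajectory(kx=kx, ky=ky, angles=angles, spec=spec)
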