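"""Image-quality evaluation: MSE/SSIM, distribution summaries, comparisons.

Metrics are computed on magnitude images against the ground-truth magnitude.
Distributions over a test set are summarized by the median and the lower /
upper quartiles (linear-interpolation convention), matching how undersampled
reconstruction quality is usually reported (boxplots rather than tests).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .synthetic import Sample, add_kspace_noise

__all__ = ["MetricSummary", "mse", "ssim", "summarize", "compare_methods",
           "window_display"]

QUARTILE_METHOD = "linear"  # numpy interpolation convention (type 7)


@dataclass(frozen=True)
class MetricSummary:
    """Median/quartile summary of one metric for one experiment cell."""

    method: str
    R: object
    noise: bool
    metric: str
    median: float
    q25: float
    q75: float
    n: int


def _check_pair(img: np.ndarray, ref: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    img = np.asarray(img, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if img.shape != ref.shape:
        raise ValueError(f"shape mismatch: {img.shape} vs {ref.shape}")
    return img, ref


def mse(img: np.ndarray, ref: np.ndarray) -> float:
    """Mean squared error over pixels."""
    img, ref = _check_pair(img, ref)
    return float(np.mean((img - ref) ** 2))


def ssim(img: np.ndarray, ref: np.ndarray,
         data_range: Optional[float] = None) -> float:
    """Structural similarity with a Gaussian window (sigma 1.5) and the
    standard constants k1=0.01, k2=0.03; data range defaults to the
    reference's maximum."""
    img, ref = _check_pair(img, ref)
    if data_range is None:
        data_range = float(ref.max()) or 1.0
    return float(structural_similarity(ref, img, data_range=data_range,
                                       gaussian_weights=True, sigma=1.5,
                                       use_sample_covariance=False))


def summarize(values: Sequence[float]) -> Tuple[float, float, float]:
    """(median, q25, q75) by the linear interpolation convention."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    q25, med, q75 = np.percentile(v, [25, 50, 75], method=QUARTILE_METHOD)
    return float(med), float(q25), float(q75)


def compare_methods(
    test_sets: Dict[object, Sequence[Sample]],
    methods: Dict[str, Dict[object, Callable[[object], np.ndarray]]],
    noise_flags: Sequence[bool] = (False,),
    noise_sigma: float = 0.0,
    noise_seed: int = 0,
    metrics: Tuple[str, ...] = ("mse", "ssim"),
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate reconstruction methods over undersampling factors.

    Parameters
    ----------
    test_sets : dict mapping R -> list of Sample
        One test set per undersampling factor (samples carry clean k-space).
    methods : dict mapping method name -> dict mapping R -> reconstructor
        Each reconstructor maps a ``RadialKSpace`` to a magnitude image.
    noise_flags : which noise conditions to run (False = clean input,
        True = complex Gaussian k-space noise of std ``noise_sigma``).
    noise_seed : base seed for the noise draws (per-sample seeds derive
        from it deterministically).

    Returns
    -------
    (summary, per_sample) : DataFrames — quartile summaries per
    (method, R, noise, metric) cell, and the raw per-sample metric values.
    """
    metric_fns = {"mse": mse, "ssim": ssim}
    records = []
    for name, by_R in methods.items():
        for R, test in test_sets.items():
            if R not in by_R:
                raise KeyError(
                    f"no reconstructor for method {name!r} at R={R!r}")
            recon = by_R[R]
            for noisy in noise_flags:
                for i, sample in enumerate(test):
                    ksp = sample.kspace
                    if noisy and noise_sigma > 0:
                        ksp = add_kspace_noise(
                            ksp, noise_sigma,
                            seed=(noise_seed * 1_000_003 + i) % 2**31)
                    out = recon(ksp)
                    ref = sample.image.magnitude
                    row = {"method": name, "R": R, "noise": noisy, "sample": i}
                    for m in metrics:
                        row[m] = metric_fns[m](out, ref)
                    records.append(row)
    per_sample = pd.DataFrame.from_records(records)
    summaries = []
    for (name, R, noisy), grp in per_sample.groupby(["method", "R", "noise"],
                                                    sort=False):
        for m in metrics:
            med, q25, q75 = summarize(grp[m].to_numpy())
            summaries.append(MetricSummary(method=name, R=R, noise=bool(noisy),
                                           metric=m, median=med, q25=q25,
                                           q75=q75, n=len(grp)))
    summary = pd.DataFrame([asdict(s) for s in summaries])
    return summary, per_sample


def window_display(img: np.ndarray, low_percentile: float = 0.0,
                   high_percentile: float = 99.0) -> np.ndarray:
    """Clip to the given intensity percentiles and rescale to [0, 1]."""
    if not 0 <= low_percentile < high_percentile <= 100:
        raise ValueError(
            f"invalid percentiles ({low_percentile}, {high_percentile})")
    img = np.asarray(img, dtype=float)
    lo, hi = np.percentile(img, [low_percentile, high_percentile])
    if hi <= lo:
        return np.zeros_like(img)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)
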