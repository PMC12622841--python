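"""Reproducible desk-scale experiments.

These drive the full pipeline — synthetic data generation, model fitting,
baseline reconstruction, metric evaluation — at sizes a single CPU handles
in minutes.  The undersampling comparison mirrors the canonical evaluation
of learned-vs-conventional radial reconstruction: one model per
undersampling factor, MSE/SSIM distributions over a noisy synthetic test
set, summarized by median and quartiles.

Models here are fitted with the closed-form ridge least-squares solver,
which computes the global optimum of the training objective directly;
gradient training reaches the same optimum (see the training module) but
needs far more wall time.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import nufft
from .evaluation import compare_methods
from .model import K2IModel, closed_form_fit
from .synthetic import (Sample, calibrate_noise_sigma, compose_complex,
                        make_phase, procedural_magnitude,
                        simulate_radial_kspace)
from .trajectories import (RadialTrajectory, TrajectorySpec, build_trajectory,
                           spokes_for_undersampling)

__all__ = ["make_images", "paired_dataset", "undersampling_comparison"]


def make_images(n: int, w_img: int, seed: int):
    """Generate n MR-like complex images (shared across trajectories)."""
    seeds = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    images = []
    for s in seeds:
        s = int(s)
        mag = procedural_magnitude(w_img, seed=s)
        phase = make_phase(mag, seed=s ^ 0x9E3779B9)
        images.append(compose_complex(mag, phase))
    return images, [int(s) for s in seeds]


def paired_dataset(images, seeds, traj: RadialTrajectory) -> List[Sample]:
    """Simulate radial k-space for pre-generated images."""
    return [Sample(image=img, kspace=simulate_radial_kspace(img, traj),
                   seed=s)
            for img, s in zip(images, seeds)]


def undersampling_comparison(
    w_img: int = 64,
    R_values: Sequence[float] = (2, 4, 6),
    n_train: int = 4000,
    n_test: int = 100,
    seed: int = 0,
    noise_psnr_db: Optional[float] = 50.0,
    n_samples: Optional[int] = None,
    ridge: object = "auto",
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[object, K2IModel]]:
    """Learned vs adjoint-NUFFT reconstruction across undersampling factors.

    Trains one linear model per undersampling factor R on ``n_train``
    synthetic samples (closed-form ridge fit), then reconstructs ``n_test``
    held-out samples with both methods — with calibrated complex Gaussian
    k-space noise when ``noise_psnr_db`` is set — and returns the
    median/quartile summary table, the per-sample metrics, and the fitted
    models.
    """
    ns = n_samples or 2 * w_img
    train_imgs, train_seeds = make_images(n_train, w_img, seed)
    test_imgs, test_seeds = make_images(n_test, w_img, seed + 1)

    test_sets: Dict[object, List[Sample]] = {}
    methods: Dict[str, Dict[object, object]] = {"ml": {}, "nufft": {}}
    models: Dict[object, K2IModel] = {}
    for R in R_values:
        spec = TrajectorySpec(w_img=w_img, n_samples=ns,
                              n_spokes=spokes_for_undersampling(w_img, R))
        traj = build_trajectory(spec)
        train = paired_dataset(train_imgs, train_seeds, traj)
        model = closed_form_fit(train, spec, ridge=ridge)
        models[R] = model
        test_sets[R] = paired_dataset(test_imgs, test_seeds, traj)
        methods["ml"][R] = model.infer_magnitude
        methods["nufft"][R] = (
            lambda k, _t=traj: nufft.adjoint_recon(k, _t))

    sigma = (calibrate_noise_sigma(w_img, noise_psnr_db)
             if noise_psnr_db is not None else 0.0)
    flags = (True,) if sigma > 0 else (False,)
    summary, per_sample = compare_methods(
        test_sets, methods, noise_flags=flags, noise_sigma=sigma,
        noise_seed=seed + 2)
    return summary, per_sample, models
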