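"""Gradient training of the k-space-to-image model.

Mini-batch Adam on the MSE between the predicted and ground-truth complex
images (evaluated on real and imaginary parts).  With the package's
orthonormal FFT convention the image-domain loss equals the k-space-domain
residual mean square, so the trainer operates directly on the linear layer's
input/output planes — the inverse FFT never has to be differentiated.

Training augmentations (both applied to the input only; targets stay clean):

* spoke dropout — ``floor(n_spokes/8)`` randomly chosen spokes zeroed per
  sample per epoch, teaching the interpolator robustness to missing data;
* multiplicative noise — each k-space element scaled by an independent
  uniform factor in [0.8, 1.2] (switchable to one scalar per sample).

Learning-rate schedule: reduce-on-plateau on the validation loss (patience
5, factor 0.8, threshold 1e-10).  Early stopping: training ends once the
best validation loss has not improved by more than ``1e-4 * best`` for 30
epochs.  The returned model carries the weights of the best validation epoch.

All randomness (init, shuffling, augmentation) derives from ``TrainConfig
.seed``; augmentation draws are keyed by (seed, epoch) and consumed in
sample-index order, so histories are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import K2IModel, design_matrices
from .synthetic import RadialKSpace, Sample
from .trajectories import TrajectorySpec

__all__ = ["TrainConfig", "spoke_dropout", "multiplicative_noise",
           "loss", "train"]


@dataclass
class TrainConfig:
    """Optimizer, scheduler, augmentation, and stopping hyperparameters.

    Defaults follow the published training recipe for the full-scale model
    (Adam lr 5e-6, betas (0.9, 0.98), eps 1e-9, batch 128; plateau scheduler
    patience 5 / factor 0.8 / threshold 1e-10; early stop after 30 epochs
    without a 1e-4-relative improvement; spoke dropout n_spokes/8;
    multiplicative input noise U(0.8, 1.2)).  For small desk-scale problems
    a larger learning rate is usually appropriate.
    """

    learning_rate: float = 5e-6
    beta1: float = 0.9
    beta2: float = 0.98
    opt_epsilon: float = 1e-9
    batch_size: int = 128
    plateau_patience: int = 5
    plateau_factor: float = 0.8
    plateau_threshold: float = 1e-10
    early_stop_delta: float = 1e-4
    early_stop_patience: int = 30
    dropout_spokes: Optional[int] = None  # None -> floor(n_spokes / 8)
    mult_noise_range: Tuple[float, float] = (0.8, 1.2)
    noise_per_element: bool = True
    max_epochs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.plateau_factor < 1:
            raise ValueError("plateau_factor must be in (0, 1)")
        if self.plateau_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patience values must be >= 1")
        lo, hi = self.mult_noise_range
        if not 0 <= lo <= hi:
            raise ValueError(f"invalid mult_noise_range ({lo}, {hi})")

    def resolved_dropout(self, n_spokes: int) -> int:
        if self.dropout_spokes is None:
            return n_spokes // 8
        return self.dropout_spokes


def spoke_dropout(kspace: RadialKSpace, n_drop: int, seed: int) -> RadialKSpace:
    """Zero all samples of ``n_drop`` distinct, uniformly chosen spokes."""
    n_spokes = kspace.spec.n_spokes
    if not 0 <= n_drop <= n_spokes:
        raise ValueError(f"n_drop must be in [0, {n_spokes}], got {n_drop}")
    if n_drop == 0:
        return kspace
    rng = np.random.default_rng(seed)
    drop = rng.choice(n_spokes, size=n_drop, replace=False)
    data = kspace.data.copy()
    data[drop] = 0.0
    return RadialKSpace(data=data, spec=kspace.spec, normalized=kspace.normalized)


def multiplicative_noise(kspace: RadialKSpace, noise_range: Tuple[float, float],
                         seed: int) -> RadialKSpace:
    """Scale every complex sample by an independent uniform real factor."""
    lo, hi = noise_range
    if lo > hi:
        raise ValueError(f"invalid range ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    factors = rng.uniform(lo, hi, size=kspace.data.shape)
    return RadialKSpace(data=kspace.data * factors, spec=kspace.spec,
                        normalized=kspace.normalized)


def loss(prediction, target) -> float:
    """MSE over the stacked real and imaginary image planes."""
    p = np.asarray(getattr(prediction, "data", prediction))
    t = np.asarray(getattr(target, "data", target))
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    d = p - t
    return float(0.5 * (np.mean(d.real**2) + np.mean(d.imag**2)))


def _augment_epoch(K: np.ndarray, n_drop: int,
                   noise_range: Tuple[float, float], per_element: bool,
                   rng: np.random.Generator) -> np.ndarray:
    """Apply spoke dropout + multiplicative noise to the whole epoch's
    complex inputs K of shape (N, n_spokes, n_samples); draws are made in
    sample-index order."""
    N, n_spokes, _ = K.shape
    out = K
    if n_drop > 0:
        # per-sample uniform choice without replacement via argpartition
        u = rng.random((N, n_spokes))
        drop = np.argpartition(u, n_drop - 1, axis=1)[:, :n_drop]
        out = out.copy()
        rows = np.repeat(np.arange(N), n_drop)
        out[rows, drop.ravel()] = 0.0
    lo, hi = noise_range
    if (lo, hi) != (1.0, 1.0):
        if per_element:
            f = rng.uniform(lo, hi, size=K.shape)
        else:
            f = rng.uniform(lo, hi, size=(N, 1, 1))
        out = out * f
    return out


def _stack_real(x: np.ndarray) -> np.ndarray:
    return np.concatenate([x.real, x.imag])


def train(spec: TrajectorySpec, train_samples: Sequence[Sample],
          val_samples: Sequence[Sample],
          cfg: TrainConfig) -> Tuple[K2IModel, pd.DataFrame]:
    """Mini-batch Adam training; returns the best-validation model + history.

    Raises ``RuntimeError`` (with the epoch index) if the loss diverges.
    """
    if not train_samples or not val_samples:
        raise ValueError("train and validation datasets must be non-empty")
    n_in = spec.n_points
    w2 = spec.w_img**2
    n_drop = cfg.resolved_dropout(spec.n_spokes)

    Ktr = np.stack([s.kspace.data for s in train_samples])  # (N, spokes, samp)
    _, Ytr = design_matrices(train_samples)                 # (2N, w2)
    Xval, Yval = design_matrices(val_samples)

    rng_init = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA11]))
    A = rng_init.normal(scale=1.0 / np.sqrt(n_in), size=(w2, n_in))
    mom = np.zeros_like(A)
    vel = np.zeros_like(A)
    t_step = 0
    lr = cfg.learning_rate

    N = len(train_samples)
    best_val = np.inf          # for weight snapshots
    best_early = np.inf        # for the early-stopping criterion
    best_A = A.copy()
    since_improve = 0
    sched_best = np.inf
    sched_bad = 0
    rows = []

    for epoch in range(cfg.max_epochs):
        rng_epoch = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 1, epoch]))
        Kaug = _augment_epoch(Ktr, n_drop, cfg.mult_noise_range,
                              cfg.noise_per_element, rng_epoch)
        Xa = _stack_real(Kaug.reshape(N, n_in))             # (2N, n_in)
        order = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 2, epoch])).permutation(2 * N)
        ep_loss = 0.0
        n_batches = 0
        for start in range(0, 2 * N, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            Xb, Yb = Xa[idx], Ytr[idx]
            resid = Xb @ A.T - Yb
            bloss = np.mean(resid**2)
            grad = (2.0 / resid.size) * (resid.T @ Xb)
            t_step += 1
            mom = cfg.beta1 * mom + (1 - cfg.beta1) * grad
            vel = cfg.beta2 * vel + (1 - cfg.beta2) * grad**2
            mhat = mom / (1 - cfg.beta1**t_step)
            vhat = vel / (1 - cfg.beta2**t_step)
            A -= lr * mhat / (np.sqrt(vhat) + cfg.opt_epsilon)
            ep_loss += bloss
            n_batches += 1
        train_loss = ep_loss / n_batches
        val_loss = float(np.mean((Xval @ A.T - Yval) ** 2))
        if not np.isfinite(train_loss) or not np.isfinite(val_loss):
            raise RuntimeError(f"training diverged at epoch {epoch}")
        rows.append({"epoch": epoch, "train_loss": train_loss,
                     "val_loss": val_loss, "lr": lr})

        if val_loss < best_val:
            best_val = val_loss
            best_A = A.copy()

        # reduce-on-plateau (validation loss, absolute threshold)
        if val_loss < sched_best - cfg.plateau_threshold:
            sched_best = val_loss
            sched_bad = 0
        else:
            sched_bad += 1
            if sched_bad > cfg.plateau_patience:
                lr *= cfg.plateau_factor
                sched_bad = 0

        # early stopping on relative improvement of the best loss
        if val_loss < best_early * (1.0 - cfg.early_stop_delta):
            best_early = val_loss
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= cfg.early_stop_patience:
                break

    history = pd.DataFrame(rows)
    meta = {"method": "adam", "epochs_run": len(history),
            "best_val_loss": best_val, "seed": cfg.seed,
            "learning_rate": cfg.learning_rate}
    return K2IModel(A=best_A, spec=spec, training_meta=meta), history
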