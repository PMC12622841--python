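"""Iterative l1-wavelet compressed-sensing baseline.

Solves  argmin_x  1/2 ||A x - y||^2 + lambda * ||Psi x||_1  where A is the
(w_img**2-normalized) forward NUFFT restricted to the radial trajectory, Psi
an orthogonal wavelet transform (Daubechies-4, 4 levels, periodization
boundary), and y the acquired radial k-space.  A single constant-1
sensitivity map is assumed (one effective coil).  The solver is FISTA with
soft-thresholding in the wavelet domain and an optional monotone restart;
the step size is 1/L with L the largest eigenvalue of A^H A estimated by
power iteration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np
import pywt

from .nufft import GriddingConfig, nufft_adjoint, nufft_forward
from .trajectories import RadialTrajectory

__all__ = ["CSConfig", "power_iteration", "max_eigenvalue", "cs_recon"]


@dataclass
class CSConfig:
    """Regularization weight, iteration budget, and wavelet choice."""

    lam: float = 1e-5
    max_iters: int = 2000
    wavelet: str = "db4"
    level: int = 4
    tol: float = 1e-8
    monotone: bool = True

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if self.max_iters < 1:
            raise ValueError(f"max_iters must be >= 1, got {self.max_iters}")


def power_iteration(normal_op: Callable[[np.ndarray], np.ndarray],
                    shape: Tuple[int, ...], seed: int = 0,
                    tol: float = 1e-4, max_iters: int = 500) -> float:
    """Largest eigenvalue of a self-adjoint PSD operator by power iteration."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    x /= np.linalg.norm(x)
    ev = 0.0
    for _ in range(max_iters):
        y = normal_op(x)
        ev_new = float(np.real(np.vdot(x.ravel(), y.ravel())))
        ny = np.linalg.norm(y)
        if ny == 0:
            return 0.0
        x = y / ny
        if abs(ev_new - ev) <= tol * max(abs(ev_new), 1e-30):
            return ev_new
        ev = ev_new
    raise RuntimeError(
        f"power iteration did not converge in {max_iters} iterations")


def _operators(traj: RadialTrajectory, grid_cfg: Optional[GriddingConfig]):
    w = traj.spec.w_img
    cfg = grid_cfg or GriddingConfig.for_image(w)
    scale = 1.0 / w**2

    def A(x: np.ndarray) -> np.ndarray:
        return nufft_forward(x, traj, cfg) * scale

    def AH(y: np.ndarray) -> np.ndarray:
        return nufft_adjoint(y, traj, cfg) * scale

    return A, AH


def max_eigenvalue(traj: RadialTrajectory,
                   grid_cfg: Optional[GriddingConfig] = None,
                   seed: int = 0, tol: float = 1e-4,
                   max_iters: int = 500) -> float:
    """Largest eigenvalue of A^H A for the trajectory's forward operator."""
    A, AH = _operators(traj, grid_cfg)
    w = traj.spec.w_img
    return power_iteration(lambda x: AH(A(x)), (w, w), seed=seed, tol=tol,
                           max_iters=max_iters)


def _soft_threshold(c: np.ndarray, t: float) -> np.ndarray:
    mag = np.abs(c)
    return np.where(mag > t, c * (1.0 - t / np.maximum(mag, 1e-300)), 0.0)


def _eff_level(x: np.ndarray, cfg: CSConfig) -> int:
    """Decomposition level capped so no subband is smaller than the filter."""
    return max(1, min(cfg.level,
                      pywt.dwt_max_level(min(x.shape), cfg.wavelet)))


def _wavelet_l1(x: np.ndarray, cfg: CSConfig) -> float:
    arr, _ = pywt.coeffs_to_array(
        pywt.wavedec2(x, cfg.wavelet, mode="periodization",
                      level=_eff_level(x, cfg)))
    return float(np.abs(arr).sum())


def _prox_wavelet(x: np.ndarray, t: float, cfg: CSConfig) -> np.ndarray:
    coeffs = pywt.wavedec2(x, cfg.wavelet, mode="periodization",
                           level=_eff_level(x, cfg))
    arr, slices = pywt.coeffs_to_array(coeffs)
    arr = _soft_threshold(arr, t)
    return pywt.waverec2(pywt.array_to_coeffs(arr, slices, output_format="wavedec2"),
                         cfg.wavelet, mode="periodization")


def cs_recon(kspace, traj: RadialTrajectory,
             cfg: Optional[CSConfig] = None,
             grid_cfg: Optional[GriddingConfig] = None,
             return_info: bool = False):
    """FISTA l1-wavelet reconstruction; returns the magnitude image.

    With ``return_info=True`` also returns a dict with the per-iteration
    objective values, the step size, and the iteration count.
    """
    cfg = cfg or CSConfig()
    y = np.asarray(getattr(kspace, "data", kspace)).ravel()
    if y.size != traj.spec.n_points:
        raise ValueError("k-space size does not match trajectory")
    A, AH = _operators(traj, grid_cfg)
    w = traj.spec.w_img
    L = max_eigenvalue(traj, grid_cfg)
    step = 1.0 / L

    def objective(x: np.ndarray) -> float:
        r = A(x) - y
        f = 0.5 * float(np.real(np.vdot(r, r)))
        if cfg.lam > 0:
            f += cfg.lam * _wavelet_l1(x, cfg)
        return f

    x = np.zeros((w, w), dtype=complex)
    z = x
    t_mom = 1.0
    obj = objective(x)
    objs = [obj]
    for it in range(cfg.max_iters):
        grad = AH(A(z) - y)
        x_new = _prox_wavelet(z - step * grad, step * cfg.lam, cfg)
        obj_new = objective(x_new)
        if cfg.monotone and obj_new > obj:
            # restart momentum from the best iterate
            z = x
            t_mom = 1.0
            grad = AH(A(z) - y)
            x_new = _prox_wavelet(z - step * grad, step * cfg.lam, cfg)
            obj_new = objective(x_new)
            if obj_new > obj:   # no further progress possible at this step
                break
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        z = x_new + ((t_mom - 1.0) / t_new) * (x_new - x)
        x, t_mom = x_new, t_new
        objs.append(obj_new)
        if abs(obj - obj_new) <= cfg.tol * max(obj, 1e-30):
            obj = obj_new
            break
        obj = obj_new
    result = np.abs(x)
    if return_info:
        return result, {"objective": np.array(objs), "step": step,
                        "iterations": len(objs) - 1, "max_eig": L}
    return result
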