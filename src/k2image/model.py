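"""The learned k-space-to-image model.

A single bias-free linear layer maps flattened radial k-space samples
(``n_spokes * n_samples`` values, spoke-major, sample index ascending) to a
flattened ``w_img x w_img`` Cartesian k-space plane; a centered orthonormal
2D inverse FFT then yields the complex image.  The real weight matrix ``A``
is shared between the real and imaginary channels, which makes the composite
map complex-linear (it commutes with multiplication by i), so the magnitude
output is invariant to a global phase of the input.

Because the whole pipeline is linear and the training loss is a plain MSE,
the training problem is linear least squares; :func:`closed_form_fit` solves
it exactly (optionally ridge-regularized) and serves both as a fast fitting
route for small problems and as the oracle against which gradient training
is validated.

The statsmodels-style entry points are :class:`KSpaceToImage` (model bound to
data) and the :class:`K2IResults` object its ``fit`` returns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .fourier import fft2c, ifft2c
from .synthetic import ComplexImage, RadialKSpace, Sample
from .trajectories import TrajectorySpec

__all__ = [
    "K2IModel",
    "KSpaceToImage",
    "K2IResults",
    "parameter_count",
    "forward",
    "infer_magnitude",
    "infer_multicoil",
    "closed_form_fit",
    "design_matrices",
    "save_model",
    "load_model",
]

FLATTEN_ORDER = "spoke-major, sample index ascending"
FFT_CONVENTION = "centered orthonormal 2D iFFT"
_FORMAT_VERSION = 1


def parameter_count(spec: TrajectorySpec) -> int:
    """Trainable parameters of the linear map: n_spokes * n_samples * w_img**2."""
    return spec.n_spokes * spec.n_samples * spec.w_img**2


@dataclass
class K2IModel:
    """Trained weights of the k-space-to-image map.

    ``A`` has shape (w_img**2, n_spokes * n_samples); the map is
    ``k_cartesian = A @ k_radial_flat`` followed by the centered orthonormal
    inverse FFT.
    """

    A: np.ndarray
    spec: TrajectorySpec
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = (self.spec.w_img**2, self.spec.n_points)
        if self.A.shape != expected:
            raise ValueError(f"A has shape {self.A.shape}, expected {expected}")

    @property
    def n_parameters(self) -> int:
        return parameter_count(self.spec)

    def forward(self, kspace: RadialKSpace) -> ComplexImage:
        return forward(self, kspace)

    def infer_magnitude(self, kspace: RadialKSpace) -> np.ndarray:
        return infer_magnitude(self, kspace)

    def infer_multicoil(self, coil_kspace: Sequence[RadialKSpace]) -> np.ndarray:
        return infer_multicoil(self, coil_kspace)

    def save(self, path) -> None:
        save_model(self, path)


def _check_kspace(model: K2IModel, kspace: RadialKSpace) -> np.ndarray:
    data = np.asarray(kspace.data)
    if data.shape != (model.spec.n_spokes, model.spec.n_samples):
        raise ValueError(
            f"k-space shape {data.shape} does not match model spec "
            f"({model.spec.n_spokes}, {model.spec.n_samples})")
    return data.ravel()


def forward(model: K2IModel, kspace: RadialKSpace) -> ComplexImage:
    """Apply the linear map and the inverse FFT; returns the complex image.

    The real matrix acts identically on the real and imaginary channels,
    which is algebraically identical to applying it to the complex vector.
    """
    x = _check_kspace(model, kspace)
    w = model.spec.w_img
    k_cart = (model.A @ x).reshape(w, w)
    return ComplexImage(data=ifft2c(k_cart))


def infer_magnitude(model: K2IModel, kspace: RadialKSpace) -> np.ndarray:
    """Magnitude image |forward(model, kspace)|."""
    return np.abs(forward(model, kspace).data)


def infer_multicoil(model: K2IModel,
                    coil_kspace: Sequence[RadialKSpace]) -> np.ndarray:
    """Root-sum-of-squares combination of per-coil magnitude images."""
    coils = list(coil_kspace)
    if not coils:
        raise ValueError("coil_kspace must contain at least one coil")
    mags = np.stack([infer_magnitude(model, c) for c in coils])
    return np.sqrt((mags**2).sum(axis=0))


def design_matrices(samples: Sequence[Sample]) -> Tuple[np.ndarray, np.ndarray]:
    """Stack a dataset into real design/target matrices (X, Y).

    X has one row per real channel and one per imaginary channel of each
    sample's flattened radial k-space (2N x n_in); Y holds the matching
    channels of the centered orthonormal FFT of the ground-truth image
    (2N x w_img**2).  With the orthonormal convention, the k-space residual
    mean square equals the image-domain real/imaginary MSE (Parseval), so
    least squares on (X, Y) is exactly the training objective.
    """
    if not samples:
        raise ValueError("empty dataset")
    xs = np.stack([s.kspace.data.ravel() for s in samples])
    ys = np.stack([fft2c(s.image.data).ravel() for s in samples])
    X = np.concatenate([xs.real, xs.imag])
    Y = np.concatenate([ys.real, ys.imag])
    return X, Y


def _gram_lambda_max(gram: np.ndarray, iters: int = 50) -> float:
    """Largest eigenvalue of the (PSD) normal matrix by power iteration."""
    rng = np.random.default_rng(0)
    v = rng.standard_normal(gram.shape[0])
    v /= np.linalg.norm(v)
    ev = 0.0
    for _ in range(iters):
        w = gram @ v
        ev_new = float(v @ w)
        nw = np.linalg.norm(w)
        if nw == 0:
            return 0.0
        v = w / nw
        if abs(ev_new - ev) <= 1e-6 * max(ev_new, 1e-300):
            break
        ev = ev_new
    return ev_new


def closed_form_fit(samples: Sequence[Sample], spec: TrajectorySpec,
                    ridge=0.0) -> K2IModel:
    """Exact (ridge) least-squares solution of the training objective.

    Minimizes ``||X A^T - Y||^2 + ridge * ||A||^2`` over the weight matrix
    via the normal equations.  Intended for small problems (the normal
    matrix is n_in x n_in).

    Radial sampling operators are often structurally rank-deficient (all
    spokes share the DC sample; line projections of a w-wide image carry
    fewer than n_samples degrees of freedom), so the unregularized normal
    equations can be exactly singular; pass ridge > 0 then, or
    ``ridge="auto"`` for ``sqrt(machine eps) * lambda_max`` — the smallest
    numerically meaningful regularization.
    """
    import scipy.linalg

    X, Y = design_matrices(samples)
    gram = X.T @ X
    if isinstance(ridge, str):
        if ridge != "auto":
            raise ValueError(f"ridge must be a number or 'auto', got {ridge!r}")
        ridge = float(np.sqrt(np.finfo(float).eps) * _gram_lambda_max(gram))
    if ridge < 0:
        raise ValueError(f"ridge must be >= 0, got {ridge}")
    if ridge > 0:
        gram[np.diag_indices_from(gram)] += ridge
    rhs = X.T @ Y
    try:
        c, low = scipy.linalg.cho_factor(gram)
        At = scipy.linalg.cho_solve((c, low), rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "normal equations are singular (rank-deficient sampling "
            "operator); pass ridge > 0 or ridge='auto'") from exc
    # Cholesky can succeed on a numerically singular matrix; verify the solve.
    if ridge == 0:
        resid = np.linalg.norm(gram @ At - rhs) / max(np.linalg.norm(rhs), 1e-300)
        if resid > 1e-6:
            raise np.linalg.LinAlgError(
                "normal equations are numerically singular (relative solve "
                f"residual {resid:.2e}); pass ridge > 0 or ridge='auto'")
    return K2IModel(A=np.ascontiguousarray(At.T), spec=spec,
                    training_meta={"method": "closed_form", "ridge": ridge,
                                   "n_samples": len(samples)})


def save_model(model: K2IModel, path) -> None:
    """Persist weights + spec + metadata to an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("A", data=model.A)
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["flatten_order"] = FLATTEN_ORDER
        f.attrs["fft_convention"] = FFT_CONVENTION
        for k in ("w_img", "n_samples", "n_spokes", "scheme", "frame_index"):
            f.attrs[f"spec_{k}"] = getattr(model.spec, k)
        f.attrs["training_meta"] = json.dumps(model.training_meta)


def load_model(path) -> K2IModel:
    """Load a model container written by :func:`save_model`."""
    import h5py

    try:
        with h5py.File(path, "r") as f:
            if "A" not in f or "spec_w_img" not in f.attrs:
                raise ValueError(f"{path}: not a k2image model container")
            spec = TrajectorySpec(
                w_img=int(f.attrs["spec_w_img"]),
                n_samples=int(f.attrs["spec_n_samples"]),
                n_spokes=int(f.attrs["spec_n_spokes"]),
                scheme=str(f.attrs["spec_scheme"]),
                frame_index=int(f.attrs["spec_frame_index"]))
            meta = json.loads(f.attrs.get("training_meta", "{}"))
            return K2IModel(A=f["A"][...], spec=spec, training_meta=meta)
    except OSError as exc:
        raise ValueError(f"{path}: unreadable or truncated model file") from exc


class KSpaceToImage:
    """k-space-to-image reconstruction model bound to a training dataset.

    Parameters
    ----------
    train_samples : sequence of Sample
        Paired (complex image, radial k-space) training data.
    val_samples : sequence of Sample, optional
        Validation split monitored by the scheduler/early stopping.
    spec : TrajectorySpec, optional
        Defaults to the spec of the first training sample.
    """

    def __init__(self, train_samples: Sequence[Sample],
                 val_samples: Optional[Sequence[Sample]] = None,
                 spec: Optional[TrajectorySpec] = None):
        if not train_samples:
            raise ValueError("train_samples must not be empty")
        self.train_samples = list(train_samples)
        self.val_samples = list(val_samples) if val_samples else []
        self.spec = spec or self.train_samples[0].kspace.spec
        for s in self.train_samples + self.val_samples:
            if s.kspace.spec != self.spec:
                raise ValueError("all samples must share the model spec")

    def fit(self, method: str = "adam", config=None,
            ridge: float = 0.0) -> "K2IResults":
        """Fit the weight matrix.

        method="adam" runs mini-batch gradient training with the full
        augmentation/scheduler/early-stopping recipe (see
        :class:`k2image.training.TrainConfig`); method="closed_form" solves
        the least-squares objective directly.
        """
        if method == "closed_form":
            mod = closed_form_fit(self.train_samples, self.spec, ridge=ridge)
            return K2IResults(model=mod, history=None, config=None)
        if method == "adam":
            from .training import TrainConfig, train

            cfg = config or TrainConfig()
            mod, history = train(self.spec, self.train_samples,
                                 self.val_samples or self.train_samples, cfg)
            return K2IResults(model=mod, history=history, config=cfg)
        raise ValueError(f"unknown fit method {method!r}")


@dataclass
class K2IResults:
    """Fit results: trained weights, training history, diagnostics."""

    model: K2IModel
    history: Optional["pandas.DataFrame"] = None  # noqa: F821
    config: Optional[object] = None

    def predict(self, kspace: RadialKSpace) -> ComplexImage:
        return forward(self.model, kspace)

    def infer_magnitude(self, kspace: RadialKSpace) -> np.ndarray:
        return infer_magnitude(self.model, kspace)

    def infer_multicoil(self, coil_kspace: Sequence[RadialKSpace]) -> np.ndarray:
        return infer_multicoil(self.model, coil_kspace)

    def save(self, path) -> None:
        save_model(self.model, path)

    def summary(self) -> str:
        """Human-readable fit summary."""
        s = self.model.spec
        meta = self.model.training_meta
        lines = [
            "k-space-to-image linear reconstruction model",
            "=" * 46,
            f"trajectory        : {s.scheme}, {s.n_spokes} spokes x "
            f"{s.n_samples} samples",
            f"image size        : {s.w_img} x {s.w_img}",
            f"parameters        : {self.model.n_parameters:,}",
            f"fit method        : {meta.get('method', 'unknown')}",
        ]
        if self.history is not None and len(self.history):
            best = self.history["val_loss"].min()
            lines += [
                f"epochs run        : {len(self.history)}",
                f"best val loss     : {best:.6e}",
                f"final lr          : {self.history['lr'].iloc[-1]:.3e}",
            ]
        if "ridge" in meta:
            lines.append(f"ridge             : {meta['ridge']:g}")
        return "\n".join(lines)
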