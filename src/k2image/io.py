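"""HDF5 persistence for datasets, trajectories, and images.

Single array-container layout (all complex data as complex64 on disk):

* dataset file — one group per split with datasets ``images`` (n, w, w) and
  ``kspace`` (n, n_spokes, n_samples) plus ``seeds``; trajectory-spec fields
  and the generator seed as attributes.
* trajectory file — datasets ``kx``, ``ky``, ``angles``; spec attributes.
* k-space / image files — a single dataset plus spec attributes.
"""

from __future__ import annotations

import hashlib
import json
from typing import Dict, List, Sequence

import h5py
import numpy as np

from .synthetic import ComplexImage, RadialKSpace, Sample
from .trajectories import RadialTrajectory, TrajectorySpec

__all__ = [
    "save_dataset", "load_dataset", "dataset_manifest",
    "save_trajectory", "load_trajectory",
    "save_kspace", "load_kspace", "save_image", "load_image",
]

_SPEC_KEYS = ("w_img", "n_samples", "n_spokes", "scheme", "frame_index")


def _write_spec(obj, spec: TrajectorySpec) -> None:
    for k in _SPEC_KEYS:
        obj.attrs[f"spec_{k}"] = getattr(spec, k)


def _read_spec(obj) -> TrajectorySpec:
    return TrajectorySpec(
        w_img=int(obj.attrs["spec_w_img"]),
        n_samples=int(obj.attrs["spec_n_samples"]),
        n_spokes=int(obj.attrs["spec_n_spokes"]),
        scheme=str(obj.attrs["spec_scheme"]),
        frame_index=int(obj.attrs["spec_frame_index"]))


def save_dataset(path, splits: Dict[str, Sequence[Sample]],
                 seed: int = 0) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["generator_seed"] = seed
        for name, samples in splits.items():
            if not samples:
                raise ValueError(f"split {name!r} is empty")
            g = f.create_group(name)
            g.create_dataset("images", data=np.stack(
                [s.image.data for s in samples]).astype(np.complex64))
            g.create_dataset("kspace", data=np.stack(
                [s.kspace.data for s in samples]).astype(np.complex64))
            g.create_dataset("seeds", data=np.array(
                [s.seed for s in samples], dtype=np.int64))
            _write_spec(g, samples[0].kspace.spec)


def load_dataset(path) -> Dict[str, List[Sample]]:
    out: Dict[str, List[Sample]] = {}
    with h5py.File(path, "r") as f:
        for name, g in f.items():
            spec = _read_spec(g)
            images = g["images"][...]
            kspace = g["kspace"][...]
            seeds = g["seeds"][...]
            out[name] = [
                Sample(image=ComplexImage(data=images[i]),
                       kspace=RadialKSpace(data=kspace[i], spec=spec),
                       seed=int(seeds[i]))
                for i in range(images.shape[0])]
    return out


def dataset_manifest(path) -> dict:
    """Checksums and spec of each split, for reproducibility manifests."""
    manifest: dict = {"file": str(path), "splits": {}}
    with h5py.File(path, "r") as f:
        for name, g in f.items():
            h = hashlib.sha256()
            h.update(g["images"][...].tobytes())
            h.update(g["kspace"][...].tobytes())
            spec = _read_spec(g)
            manifest["splits"][name] = {
                "n": int(g["images"].shape[0]),
                "sha256": h.hexdigest(),
                "spec": {k: getattr(spec, k) for k in _SPEC_KEYS},
            }
    return manifest


def save_trajectory(path, traj: RadialTrajectory) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("kx", data=traj.kx)
        f.create_dataset("ky", data=traj.ky)
        f.create_dataset("angles", data=traj.angles)
        _write_spec(f, traj.spec)


def load_trajectory(path) -> RadialTrajectory:
    with h5py.File(path, "r") as f:
        return RadialTrajectory(kx=f["kx"][...], ky=f["ky"][...],
                                angles=f["angles"][...], spec=_read_spec(f))


def save_kspace(path, kspace_coils: Sequence[RadialKSpace]) -> None:
    """Save one or more coils of radial k-space ((n_coils, spokes, samples))."""
    coils = list(kspace_coils)
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=np.stack(
            [c.data for c in coils]).astype(np.complex64))
        f.attrs["normalized"] = bool(coils[0].normalized)
        _write_spec(f, coils[0].spec)


def load_kspace(path) -> List[RadialKSpace]:
    with h5py.File(path, "r") as f:
        spec = _read_spec(f)
        norm = bool(f.attrs.get("normalized", True))
        data = f["kspace"][...]
        return [RadialKSpace(data=data[i], spec=spec, normalized=norm)
                for i in range(data.shape[0])]


def save_image(path, img: np.ndarray, meta: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("image", data=np.asarray(img))
        if meta:
            f.attrs["meta"] = json.dumps(meta)


def load_image(path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["image"][...]
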