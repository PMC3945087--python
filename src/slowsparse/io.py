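"""Persistence for pair sets, whiteners and filter banks.

Pair sets are written as HDF5 (datasets ``x_t``, ``x_t1``, attribute group
``process``) or NPZ, with a JSON sidecar duplicating the generation
metadata.  Whiteners and filter banks round-trip bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np

from .preprocessing import PatchWhitener
from .synthetic import PatchPairSet, TransformProcess

__all__ = [
    "save_pairs",
    "load_pairs",
    "save_whitener",
    "load_whitener",
    "save_filterbank",
    "load_filterbank",
]


def _process_to_attrs(process: TransformProcess) -> dict:
    d = dataclasses.asdict(process)
    d["angle_range"] = list(d["angle_range"])
    d["scale_factor_range"] = list(d["scale_factor_range"])
    return d


def _process_from_attrs(attrs: dict) -> TransformProcess:
    return TransformProcess(
        kind=str(attrs["kind"]),
        n_pairs=int(attrs["n_pairs"]),
        seed=int(attrs["seed"]),
        max_shift=float(attrs["max_shift"]),
        angle_range=tuple(float(v) for v in attrs["angle_range"]),
        scale_factor_range=tuple(float(v) for v in attrs["scale_factor_range"]),
    )


def save_pairs(path: str | Path, pairs: PatchPairSet) -> None:
    """Write a pair set to ``.h5``/``.hdf5`` or ``.npz`` plus a JSON sidecar."""
    path = Path(path)
    proc = _process_to_attrs(pairs.process)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("x_t", data=pairs.x_t)
            f.create_dataset("x_t1", data=pairs.x_t1)
            f.attrs["patch_side"] = pairs.patch_side
            grp = f.create_group("process")
            for k, v in proc.items():
                grp.attrs[k] = v
            meta = f.create_group("metadata")
            for k, v in pairs.metadata.items():
                if v is None:
                    continue
                meta.create_dataset(k, data=np.asarray(v))
    elif path.suffix == ".npz":
        meta_arrays = {
            f"meta_{k}": np.asarray(v) for k, v in pairs.metadata.items() if v is not None
        }
        np.savez(
            path,
            x_t=pairs.x_t,
            x_t1=pairs.x_t1,
            patch_side=pairs.patch_side,
            process_json=json.dumps(proc),
            **meta_arrays,
        )
    else:
        raise ValueError(f"unsupported pair-set format {path.suffix!r}")
    sidecar = {
        "patch_side": int(pairs.patch_side),
        "n_pairs": int(pairs.n_pairs),
        "dim": int(pairs.dim),
        "process": proc,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_pairs(path: str | Path) -> PatchPairSet:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            process = _process_from_attrs(dict(f["process"].attrs))
            metadata = {k: np.asarray(v) for k, v in f["metadata"].items()}
            return PatchPairSet(
                x_t=np.asarray(f["x_t"]),
                x_t1=np.asarray(f["x_t1"]),
                process=process,
                patch_side=int(f.attrs["patch_side"]),
                metadata=metadata,
            )
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as f:
            process = _process_from_attrs(json.loads(str(f["process_json"])))
            metadata = {
                k[len("meta_") :]: f[k] for k in f.files if k.startswith("meta_")
            }
            return PatchPairSet(
                x_t=f["x_t"],
                x_t1=f["x_t1"],
                process=process,
                patch_side=int(f["patch_side"]),
                metadata=metadata,
            )
    raise ValueError(f"unsupported pair-set format {path.suffix!r}")


def save_whitener(path: str | Path, p: PatchWhitener) -> None:
    """Persist a fitted whitener (HDF5) with a JSON summary sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for name in ("ac_basis_", "whitener_", "dewhitener_", "mean_", "eigenvalues_"):
            f.create_dataset(name, data=getattr(p, name))
        f.attrs["regularization"] = p.regularization
        f.attrs["stationary"] = p.stationary
        f.attrs["n_features_in"] = p.n_features_in_
    summary = {
        "n_pixels": int(p.n_features_in_),
        "n_components": int(p.n_components_),
        "eigenvalue_min": float(p.eigenvalues_[0]),
        "eigenvalue_max": float(p.eigenvalues_[-1]),
        "stationary": bool(p.stationary),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(summary, indent=2))


def load_whitener(path: str | Path) -> PatchWhitener:
    with h5py.File(path, "r") as f:
        p = PatchWhitener(
            regularization=float(f.attrs["regularization"]),
            stationary=bool(f.attrs["stationary"]),
        )
        for name in ("ac_basis_", "whitener_", "dewhitener_", "mean_", "eigenvalues_"):
            setattr(p, name, np.asarray(f[name]))
        p.n_features_in_ = int(f.attrs["n_features_in"])
        p.n_components_ = p.n_features_in_ - 1
    return p


def save_filterbank(
    path: str | Path, w: np.ndarray, subspace_dim: int = 2, attrs: dict | None = None
) -> None:
    """Persist a filter bank with its subspace grouping (HDF5 or NPZ)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("W", data=np.asarray(w))
            f.attrs["subspace_dim"] = subspace_dim
            for k, v in (attrs or {}).items():
                f.attrs[k] = v
    elif path.suffix == ".npz":
        np.savez(path, W=np.asarray(w), subspace_dim=subspace_dim, **(attrs or {}))
    else:
        raise ValueError(f"unsupported filter-bank format {path.suffix!r}")


def load_filterbank(path: str | Path) -> tuple[np.ndarray, int]:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return np.asarray(f["W"]), int(f.attrs["subspace_dim"])
    if path.suffix == ".npz":
        with np.load(path) as f:
            return f["W"], int(f["subspace_dim"])
    raise ValueError(f"unsupported filter-bank format {path.suffix!r}")
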