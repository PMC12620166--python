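"""File I/O: HDF5 k-space containers, NIfTI maps, CSV masks/curves, YAML configs.

The HDF5 container stores ``/kspace`` (complex64, [echo, coil, slice, pe,
ro]), ``/csm`` (complex64, [coil, slice, pe, ro]), ``/brain_mask`` (uint8)
and ``/sg_map`` (float32, μT/m) with attributes ``te_ms``, ``tr_ms`` and
``packages``; phantom ground-truth maps and clean images are optional extra
datasets so a full :class:`~phimo.phantom.PhantomDataset` round-trips
losslessly.  Exclusion/reference masks use a CSV dialect with one row per
PE line and columns ``line_index, weight_odd, weight_even``; motion curves
use ``time_s, tx_mm, ty_mm, tz_mm, rx_deg, ry_deg, rz_deg``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .forward import CoilSensitivityMaps, ExclusionMask, KSpaceVolume, RigidState
from .motion import MotionCurve, ReferenceMask
from .phantom import PhantomDataset

__all__ = [
    "SchemaError",
    "write_kspace_container",
    "read_kspace_container",
    "write_phantom",
    "read_phantom",
    "write_masks_csv",
    "read_masks_csv",
    "write_curve_csv",
    "read_curve_csv",
    "write_nifti_map",
    "read_nifti_map",
    "load_config",
    "write_manifest",
]


class SchemaError(ValueError):
    """A required dataset or attribute is missing from a container."""


_REQUIRED_DATASETS = ("kspace", "csm", "brain_mask", "sg_map")
_REQUIRED_ATTRS = ("te_ms", "tr_ms", "packages")


def write_kspace_container(
    path,
    kspace: KSpaceVolume,
    csm: CoilSensitivityMaps,
    brain_mask: np.ndarray,
    sg_map: np.ndarray,
    packages: str = "odd,even",
    extra: dict[str, np.ndarray] | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=kspace.data.astype(np.complex64))
        f.create_dataset("csm", data=csm.csm.astype(np.complex64))
        f.create_dataset("brain_mask", data=np.asarray(brain_mask, dtype=np.uint8))
        f.create_dataset("sg_map", data=np.asarray(sg_map, dtype=np.float32))
        f.attrs["te_ms"] = [float(t) for t in kspace.te_ms]
        f.attrs["tr_ms"] = float(kspace.tr_ms)
        f.attrs["packages"] = packages
        for name, arr in (extra or {}).items():
            f.create_dataset(name, data=arr)


def read_kspace_container(path):
    """Read the container; returns (KSpaceVolume, CoilSensitivityMaps, brain_mask, sg_map, extras)."""
    with h5py.File(path, "r") as f:
        for name in _REQUIRED_DATASETS:
            if name not in f:
                raise SchemaError(f"container is missing dataset {name!r}")
        for name in _REQUIRED_ATTRS:
            if name not in f.attrs:
                raise SchemaError(f"container is missing attribute {name!r}")
        kspace = KSpaceVolume(f["kspace"][()], np.asarray(f.attrs["te_ms"]),
                              float(f.attrs["tr_ms"]))
        csm = CoilSensitivityMaps(f["csm"][()])
        brain = f["brain_mask"][()].astype(bool)
        sg = f["sg_map"][()].astype(float)
        extras = {
            k: f[k][()] for k in f.keys() if k not in _REQUIRED_DATASETS
        }
        extras["packages"] = str(f.attrs["packages"])
    return kspace, csm, brain, sg, extras


def write_phantom(path, phantom: PhantomDataset) -> None:
    extra = {
        "s0_map": phantom.s0_map.astype(np.float64),
        "t2star_map": phantom.t2star_map.astype(np.float64),
        "b0_map": phantom.b0_map.astype(np.float64),
        "clean_images": phantom.clean_images.astype(np.complex128),
        "voxel_mm": np.float64(phantom.voxel_mm),
        "seed": np.int64(phantom.seed),
    }
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=phantom.clean_kspace.data)
        f.create_dataset("csm", data=phantom.csm.csm)
        f.create_dataset("brain_mask", data=phantom.brain_mask.astype(np.uint8))
        f.create_dataset("sg_map", data=phantom.sg_map.astype(np.float64))
        f.attrs["te_ms"] = [float(t) for t in phantom.te_ms]
        f.attrs["tr_ms"] = float(phantom.tr_ms)
        f.attrs["packages"] = "odd,even"
        for name, arr in extra.items():
            f.create_dataset(name, data=arr)


def read_phantom(path) -> PhantomDataset:
    with h5py.File(path, "r") as f:
        needed = _REQUIRED_DATASETS + ("s0_map", "t2star_map", "b0_map", "clean_images")
        for name in needed:
            if name not in f:
                raise SchemaError(f"phantom container is missing dataset {name!r}")
        for name in _REQUIRED_ATTRS:
            if name not in f.attrs:
                raise SchemaError(f"phantom container is missing attribute {name!r}")
        te = np.asarray(f.attrs["te_ms"])
        tr = float(f.attrs["tr_ms"])
        return PhantomDataset(
            s0_map=f["s0_map"][()],
            t2star_map=f["t2star_map"][()],
            b0_map=f["b0_map"][()],
            csm=CoilSensitivityMaps(f["csm"][()]),
            brain_mask=f["brain_mask"][()].astype(bool),
            sg_map=f["sg_map"][()],
            clean_images=f["clean_images"][()],
            clean_kspace=KSpaceVolume(f["kspace"][()], te, tr),
            te_ms=te,
            tr_ms=tr,
            voxel_mm=float(f["voxel_mm"][()]),
            seed=int(f["seed"][()]),
        )


# ---------------------------------------------------------------------------
# CSV masks and curves
# ---------------------------------------------------------------------------


def _mask_weights(mask) -> np.ndarray:
    if isinstance(mask, ExclusionMask):
        return mask.line_weights
    if isinstance(mask, ReferenceMask):
        return mask.line_labels.astype(float)
    return np.asarray(mask, dtype=float)


def write_masks_csv(path, mask_odd, mask_even) -> None:
    """One row per PE line: line_index, weight_odd, weight_even."""
    w_odd = _mask_weights(mask_odd)
    w_even = _mask_weights(mask_even)
    if w_odd.size != w_even.size:
        raise ValueError("package masks must have equal length")
    pd.DataFrame(
        {
            "line_index": np.arange(w_odd.size),
            "weight_odd": np.round(w_odd, 6),
            "weight_even": np.round(w_even, 6),
        }
    ).to_csv(path, index=False)


def read_masks_csv(path) -> tuple[ExclusionMask, ExclusionMask]:
    df = pd.read_csv(path)
    for col in ("line_index", "weight_odd", "weight_even"):
        if col not in df.columns:
            raise SchemaError(f"mask CSV is missing column {col!r}")
    df = df.sort_values("line_index")
    return (
        ExclusionMask(df["weight_odd"].to_numpy(), package="odd"),
        ExclusionMask(df["weight_even"].to_numpy(), package="even"),
    )


_CURVE_COLUMNS = ("time_s", "tx_mm", "ty_mm", "tz_mm", "rx_deg", "ry_deg", "rz_deg")


def write_curve_csv(path, curve: MotionCurve) -> None:
    params = curve.params_matrix()
    df = pd.DataFrame(
        np.column_stack([curve.times_s, params]), columns=list(_CURVE_COLUMNS)
    )
    df.to_csv(path, index=False)


def read_curve_csv(path) -> MotionCurve:
    df = pd.read_csv(path)
    for col in _CURVE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"curve CSV is missing column {col!r}")
    states = [
        RigidState(t=row[1:4], r=row[4:7])
        for row in df[list(_CURVE_COLUMNS)].to_numpy()
    ]
    return MotionCurve(df["time_s"].to_numpy(), states)


# ---------------------------------------------------------------------------
# NIfTI maps, configs, manifests
# ---------------------------------------------------------------------------


def write_nifti_map(path, map_data: np.ndarray, voxel_mm: float = 2.0,
                    dtype=np.float32) -> None:
    """Store a [slice, pe, ro] map as NIfTI (reordered to pe, ro, slice)."""
    arr = np.asarray(map_data).astype(dtype)
    arr = np.moveaxis(arr, 0, -1)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def read_nifti_map(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.moveaxis(np.asarray(img.dataobj), -1, 0)


def load_config(path, known_keys: set[str] | None = None) -> dict:
    """Load a YAML config; unknown keys raise instead of being ignored."""
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    if not isinstance(cfg, dict):
        raise SchemaError("config must be a YAML mapping")
    if known_keys is not None:
        unknown = set(cfg) - known_keys
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_path, config: dict, seed: int | None,
                   inputs: list | None = None) -> Path:
    """Write a JSON run manifest (resolved config, seed, version, input hashes)."""
    from . import __version__

    out_path = Path(out_path)
    manifest = {
        "config": config,
        "seed": seed,
        "phimo_version": __version__,
        "numpy_version": np.__version__,
        "inputs": {str(p): _sha256(p) for p in (inputs or []) if Path(p).exists()},
    }
    manifest_path = out_path.with_suffix(out_path.suffix + ".manifest.json")
    with open(manifest_path, "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True, default=str)
    return manifest_path
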