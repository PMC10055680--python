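"""File formats: NIfTI-1 parameter maps, HDF5 signal containers, YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .matcher import ParameterMaps
from .phantom import SimulatedSignals
from .sequence import SequenceConfig

__all__ = [
    "write_maps",
    "read_map",
    "save_signals",
    "load_signals",
    "save_label_map",
    "load_config",
    "save_config",
]

_MS_PARAMS = ("t1", "t2", "t1rho")


def _affine(voxel_size) -> np.ndarray:
    return np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])


def write_maps(maps: ParameterMaps, out_dir) -> list:
    """One NIfTI-1 file per parameter (pd, t1, t2, t1rho, b1, score).

    Voxel size goes into pixdim; ms units are recorded in the header
    description for the relaxation maps.  Masked voxels are NaN.
    Returns the list of written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, vol in maps.as_dict().items():
        img = nib.Nifti1Image(np.asarray(vol, dtype=np.float64), _affine(maps.voxel_size))
        unit = "ms" if name in _MS_PARAMS else "a.u."
        img.header["descrip"] = f"mrf3d {name} [{unit}]".encode()
        p = out_dir / f"{name}.nii"
        nib.save(img, p)
        written.append(p)
    return written


def read_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)


def save_label_map(label_map: np.ndarray, voxel_size, path) -> None:
    img = nib.Nifti1Image(np.asarray(label_map, dtype=np.int16), _affine(voxel_size))
    nib.save(img, str(path))


def save_signals(sig: SimulatedSignals, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=sig.signals)
        f.create_dataset("voxel_index", data=sig.voxel_index)
        f.create_dataset("labels", data=sig.labels)
        f.attrs["shape"] = sig.shape
        f.attrs["schedule_hash"] = sig.schedule_hash
        f.attrs["noise_sigma"] = sig.noise_sigma
        f.attrs["n_shots"] = sig.n_shots
        f.attrs["seed"] = sig.seed


def load_signals(path) -> SimulatedSignals:
    with h5py.File(path, "r") as f:
        return SimulatedSignals(
            signals=f["signals"][:],
            voxel_index=f["voxel_index"][:],
            labels=f["labels"][:],
            shape=tuple(int(v) for v in f.attrs["shape"]),
            schedule_hash=str(f.attrs["schedule_hash"]),
            noise_sigma=float(f.attrs["noise_sigma"]),
            n_shots=int(f.attrs["n_shots"]),
            seed=int(f.attrs["seed"]),
        )


def save_config(config: SequenceConfig, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=True)


def load_config(path) -> SequenceConfig:
    with open(path) as f:
        d = yaml.safe_load(f)
    return SequenceConfig.from_dict(d or {})


def write_json(obj, path) -> None:
    with open(path, "w") as f:
        json.dump(obj, f, indent=2, sort_keys=True, default=float)
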