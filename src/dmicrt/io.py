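"""File I/O: NIfTI maps, HDF5 k-space containers and run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

import h5py
import nibabel as nib
import numpy as np
import yaml

from .params import SequenceParams
from .simulate import KSpaceData
from .trajectory import CRTrajectory

_TRAJ_FIELDS = (
    "ring_index",
    "point_index",
    "kx",
    "ky",
    "kz",
    "time_offset_ms",
    "n_averages",
    "density_weights",
    "hamming_weights",
)


def affine_from_geometry(
    voxel_mm: Sequence[float], matrix: Sequence[int]
) -> np.ndarray:
    """RAS affine of an FOV-centred isotropic-grid volume."""
    affine = np.diag([voxel_mm[0], voxel_mm[1], voxel_mm[2], 1.0])
    affine[:3, 3] = [-(m // 2) * v for m, v in zip(matrix, voxel_mm)]
    return affine


def save_maps_nifti(
    maps: Mapping[str, np.ndarray],
    voxel_mm: Sequence[float],
    out_dir: Path,
    prefix: str = "map",
) -> Dict[str, Path]:
    """Write one NIfTI volume per named map; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}
    for name, vol in maps.items():
        vol = np.asarray(vol, dtype=float)
        affine = affine_from_geometry(voxel_mm, vol.shape)
        path = out_dir / f"{prefix}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(vol, affine), str(path))
        written[name] = path
    return written


def load_map_nifti(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_kspace_h5(
    path: Path,
    datasets: Mapping[float, KSpaceData],
    config_json: Optional[str] = None,
) -> None:
    """Store simulated k-space per dynamic time point in one HDF5 file.

    Trajectory arrays and the protocol (as JSON) are stored once; each time
    point gets a complex values dataset under ``timepoints/<minutes>``.
    """
    if not datasets:
        raise ValueError("no k-space datasets to save")
    first = next(iter(datasets.values()))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as fh:
        fh.attrs["params_json"] = first.params.model_dump_json()
        if config_json is not None:
            fh.attrs["config_json"] = config_json
        tgrp = fh.create_group("trajectory")
        for name in _TRAJ_FIELDS:
            tgrp.create_dataset(name, data=getattr(first.traj, name))
        tgrp.attrs["n_points_per_ring"] = first.traj.n_points_per_ring
        tgrp.attrs["revolution_time_ms"] = first.traj.revolution_time_ms
        grp = fh.create_group("timepoints")
        for t_min, data in sorted(datasets.items()):
            if data.params != first.params:
                raise ValueError("all time points must share one protocol")
            grp.create_dataset(f"{float(t_min):.4f}", data=data.values)


def load_kspace_h5(path: Path) -> Tuple[Dict[float, KSpaceData], Optional[str]]:
    """Load the datasets written by :func:`save_kspace_h5`."""
    with h5py.File(Path(path), "r") as fh:
        params = SequenceParams.model_validate_json(fh.attrs["params_json"])
        config_json = fh.attrs.get("config_json")
        tgrp = fh["trajectory"]
        traj = CRTrajectory(
            ring_index=np.asarray(tgrp["ring_index"]),
            point_index=np.asarray(tgrp["point_index"]),
            kx=np.asarray(tgrp["kx"]),
            ky=np.asarray(tgrp["ky"]),
            kz=np.asarray(tgrp["kz"]),
            time_offset_ms=np.asarray(tgrp["time_offset_ms"]),
            n_averages=np.asarray(tgrp["n_averages"]),
            n_points_per_ring=int(tgrp.attrs["n_points_per_ring"]),
            revolution_time_ms=float(tgrp.attrs["revolution_time_ms"]),
            density_weights=np.asarray(tgrp["density_weights"]),
            hamming_weights=np.asarray(tgrp["hamming_weights"]),
        )
        out: Dict[float, KSpaceData] = {}
        for key in fh["timepoints"]:
            out[float(key)] = KSpaceData(
                values=np.asarray(fh["timepoints"][key]), traj=traj, params=params
            )
    return out, (str(config_json) if config_json is not None else None)


def save_yaml(obj, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def load_yaml(path: Path):
    with open(Path(path)) as fh:
        return yaml.safe_load(fh)


def file_sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(Path(path), "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(paths: Sequence[Path], out_path: Path) -> None:
    """Write a JSON manifest with the SHA-256 checksum of each output file."""
    entries = [
        {"path": str(Path(p)), "sha256": file_sha256(p), "bytes": Path(p).stat().st_size}
        for p in paths
    ]
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text(json.dumps({"files": entries}, indent=2) + "\n")
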