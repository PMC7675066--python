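"""Disk containers: HDF5 RF scans, NIfTI/MetaImage volumes, JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .geometry import VoxelGrid
from .optics import FluenceVolume
from .reconstruct import ReconVolume
from .simulate import RFPlane

__all__ = ["save_scan", "load_scan", "save_volume", "load_volume", "save_json"]


def save_scan(path, planes: list[RFPlane], meta: dict | None = None) -> None:
    """Write a scan: one dataset per pose with pose/energy/sampling attributes."""
    with h5py.File(path, "w") as f:
        g = f.create_group("planes")
        for i, p in enumerate(planes):
            d = g.create_dataset(f"{i:04d}", data=p.samples, compression="gzip")
            d.attrs["pose_angle"] = p.pose_angle
            d.attrs["pulse_energy"] = p.pulse_energy
            d.attrs["sampling_rate"] = p.sampling_rate
        if meta:
            f.attrs["meta"] = json.dumps(meta)


def load_scan(path) -> tuple[list[RFPlane], dict]:
    with h5py.File(path, "r") as f:
        planes = []
        for key in sorted(f["planes"]):
            d = f["planes"][key]
            planes.append(
                RFPlane(
                    pose_angle=float(d.attrs["pose_angle"]),
                    samples=d[()],
                    pulse_energy=float(d.attrs["pulse_energy"]),
                    sampling_rate=float(d.attrs["sampling_rate"]),
                )
            )
        meta = json.loads(f.attrs["meta"]) if "meta" in f.attrs else {}
    return planes, meta


def _grid_affine(grid: VoxelGrid) -> np.ndarray:
    # NIfTI stores mm; the toolkit works in cm
    aff = np.eye(4)
    aff[:3, :3] *= grid.spacing * 10.0
    aff[:3, 3] = np.asarray(grid.origin) * 10.0
    return aff


def save_volume(path, volume, sidecar: dict | None = None) -> None:
    """Write a ReconVolume/FluenceVolume as NIfTI (plus an optional JSON sidecar)."""
    if isinstance(volume, (ReconVolume, FluenceVolume)):
        grid, values = volume.grid, volume.values
    else:
        raise TypeError("expected a ReconVolume or FluenceVolume")
    img = nib.Nifti1Image(np.asarray(values, np.float64), _grid_affine(grid))
    nib.save(img, str(path))
    if sidecar is not None:
        save_json(Path(str(path)).with_suffix("").with_suffix(".json"), sidecar)


def load_volume(path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    aff = img.affine
    spacing = float(aff[0, 0]) / 10.0
    origin = tuple(aff[:3, 3] / 10.0)
    return data, VoxelGrid(origin=origin, spacing=spacing, shape=data.shape)


def save_json(path, obj: dict) -> None:
    def clean(o):
        if isinstance(o, dict):
            return {k: clean(v) for k, v in o.items() if not str(k).startswith("_")}
        if isinstance(o, (list, tuple)):
            return [clean(v) for v in o]
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return o

    Path(path).write_text(json.dumps(clean(obj), indent=2))
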