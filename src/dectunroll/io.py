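"""File formats: geometry YAML, sinogram/volume HDF5, NIfTI volumes,
dataset directories.

Sinograms are stored as HDF5 datasets ``sino_L`` / ``sino_H`` shaped
(rows, channels, views) with the geometry embedded as a JSON attribute;
in memory they are flat ``(2, n_rays)`` with ray index ordered
(view, row, channel).  Volumes go to NIfTI (mm-scaled affine) or HDF5.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .geometry import ScanGeometry
from .spectral import BasisImage, SinogramSet

__all__ = [
    "load_geometry", "save_geometry",
    "sino_to_stack", "stack_to_sino",
    "save_sinograms", "load_sinograms",
    "save_volume", "load_volume",
    "save_sample", "load_sample", "write_dataset_index",
]


# -- geometry -----------------------------------------------------------------

def load_geometry(path) -> ScanGeometry:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return ScanGeometry.from_dict(cfg["geometry"] if "geometry" in cfg else cfg)


def save_geometry(path, geom: ScanGeometry) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"geometry": geom.to_dict()}, fh, sort_keys=False)


# -- sinogram layout ----------------------------------------------------------

def sino_to_stack(flat: np.ndarray, geom: ScanGeometry) -> np.ndarray:
    """(n_rays,) flat ray order -> (rows, channels, views)."""
    v, r, ch = geom.n_views_total, geom.effective_rows, geom.n_channels
    return flat.reshape(v, r, ch).transpose(1, 2, 0)


def stack_to_sino(stack: np.ndarray, geom: ScanGeometry) -> np.ndarray:
    return np.ascontiguousarray(stack.transpose(2, 0, 1)).reshape(-1)


def save_sinograms(path, d: SinogramSet, geom: ScanGeometry,
                   extra_attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("sino_L", data=sino_to_stack(d.d[0], geom))
        f.create_dataset("sino_H", data=sino_to_stack(d.d[1], geom))
        f.attrs["geometry"] = json.dumps(geom.to_dict())
        for k, v in (extra_attrs or {}).items():
            f.attrs[k] = v


def load_sinograms(path) -> tuple[SinogramSet, ScanGeometry]:
    with h5py.File(path, "r") as f:
        geom = ScanGeometry.from_dict(json.loads(f.attrs["geometry"]))
        d = np.stack([stack_to_sino(f["sino_L"][()], geom),
                      stack_to_sino(f["sino_H"][()], geom)])
    return SinogramSet(d), geom


# -- volumes ------------------------------------------------------------------

def save_volume(path, img: BasisImage, geom: ScanGeometry | None = None):
    """Write component images; .nii/.nii.gz via nibabel, else HDF5."""
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        spacing = (1.0, 1.0, 1.0) if geom is None else geom.voxel_spacing
        affine = np.diag(list(spacing) + [1.0])
        data = np.moveaxis(img.c, 0, -1)  # components as the last axis
        nib.save(nib.Nifti1Image(data, affine), str(path))
    else:
        with h5py.File(path, "w") as f:
            f.create_dataset("c", data=img.c)
            if geom is not None:
                f.attrs["geometry"] = json.dumps(geom.to_dict())


def load_volume(path) -> BasisImage:
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        data = np.asanyarray(nib.load(str(path)).dataobj)
        return BasisImage(np.moveaxis(data, -1, 0))
    with h5py.File(path, "r") as f:
        return BasisImage(f["c"][()])


# -- dataset directories ------------------------------------------------------

def save_sample(path, sample, geom: ScanGeometry) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("sino_L", data=sino_to_stack(sample.d.d[0], geom))
        f.create_dataset("sino_H", data=sino_to_stack(sample.d.d[1], geom))
        f.create_dataset("target_c", data=sample.target.c)
        f.create_dataset("init_c", data=sample.init.c)
        f.attrs["seed"] = sample.seed
        f.attrs["geometry"] = json.dumps(geom.to_dict())


def load_sample(path):
    from .phantoms import SimSample
    with h5py.File(path, "r") as f:
        geom = ScanGeometry.from_dict(json.loads(f.attrs["geometry"]))
        d = np.stack([stack_to_sino(f["sino_L"][()], geom),
                      stack_to_sino(f["sino_H"][()], geom)])
        return SimSample(d=SinogramSet(d),
                         target=BasisImage(f["target_c"][()]),
                         init=BasisImage(f["init_c"][()]),
                         seed=int(f.attrs["seed"])), geom


def write_dataset_index(dirpath, filenames, geom: ScanGeometry,
                        seed: int) -> None:
    index = {"samples": list(filenames), "seed": seed,
             "geometry": geom.to_dict()}
    with open(Path(dirpath) / "index.json", "w") as fh:
        json.dump(index, fh, indent=1)
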