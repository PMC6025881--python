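"""Field and model serialization: NIfTI-1, HDF5 and JSON model specs.

Fields are written as NIfTI-1 (3D for scalar fields, 4D for temporal fields,
voxel spacing in mm and the time step in the 4th pixdim) and as a portable
HDF5 container carrying the full grid metadata and units.  Random-field model
specifications round-trip through plain JSON dictionaries.
"""

from __future__ import annotations

import json

import h5py
import nibabel as nib
import numpy as np

from .fields import (
    GaussianFieldModel,
    Grid,
    LognormalFieldModel,
    LumpyFieldModel,
    ScalarField,
    TemporalField,
)

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_hdf5",
    "load_hdf5",
    "model_to_dict",
    "model_from_dict",
]


def _affine(grid: Grid) -> np.ndarray:
    aff = np.diag([*grid.spacing, 1.0])
    aff[:3, 3] = np.asarray(grid.origin) + 0.5 * np.asarray(grid.spacing)
    return aff


def save_nifti(field, path) -> None:
    if isinstance(field, TemporalField):
        data = np.moveaxis(field.values, 0, -1)
        img = nib.Nifti1Image(data, _affine(field.grid))
        img.header["pixdim"][4] = field.dt
        img.header["toffset"] = field.times[0]
    else:
        img = nib.Nifti1Image(field.values, _affine(field.grid))
    img.header.set_xyzt_units(xyz="mm")
    if field.units:
        img.header["descrip"] = field.units.encode()[:79]
    nib.save(img, str(path))


def load_nifti(path):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    aff = img.affine
    spacing = tuple(float(np.linalg.norm(aff[:3, a])) for a in range(3))
    origin = tuple(float(aff[a, 3] - 0.5 * spacing[a]) for a in range(3))
    units = bytes(img.header["descrip"]).split(b"\x00")[0].decode(errors="ignore")
    if data.ndim == 4:
        grid = Grid(data.shape[:3], spacing, origin)
        dt = float(img.header["pixdim"][4]) or 1.0
        t0 = float(img.header["toffset"])
        times = t0 + dt * np.arange(data.shape[3])
        return TemporalField(grid, times, np.moveaxis(data, -1, 0), units=units)
    grid = Grid(data.shape, spacing, origin)
    return ScalarField(grid, data, units=units)


def save_hdf5(field, path, name: str = "field") -> None:
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        g = f.create_group(name)
        g.create_dataset("values", data=field.values)
        g.attrs["shape"] = field.grid.shape
        g.attrs["spacing"] = field.grid.spacing
        g.attrs["origin"] = field.grid.origin
        g.attrs["units"] = field.units
        g.attrs["nonnegative"] = field.nonnegative
        if isinstance(field, TemporalField):
            g.create_dataset("times", data=field.times)


def load_hdf5(path, name: str = "field"):
    with h5py.File(path, "r") as f:
        g = f[name]
        grid = Grid(
            tuple(int(s) for s in g.attrs["shape"]),
            tuple(float(s) for s in g.attrs["spacing"]),
            tuple(float(s) for s in g.attrs["origin"]),
        )
        vals = np.asarray(g["values"])
        units = str(g.attrs["units"])
        nonneg = bool(g.attrs["nonnegative"])
        if "times" in g:
            return TemporalField(grid, np.asarray(g["times"]), vals, units, nonneg)
        return ScalarField(grid, vals, units, nonneg)


def model_to_dict(model) -> dict:
    if isinstance(model, GaussianFieldModel):
        d = {"type": "gaussian", "mean": model.mean if not hasattr(model.mean, "grid") else None}
        if model.stationary:
            d.update(sigma2=model.sigma2, corr_length=model.corr_length)
        else:
            d["cov_matrix"] = model.cov_matrix.tolist()
        return d
    if isinstance(model, LumpyFieldModel):
        return {
            "type": "lumpy",
            "kbar": model.kbar,
            "amplitude": model.amplitude,
            "width": model.width,
            "offset": model.offset,
        }
    if isinstance(model, LognormalFieldModel):
        return {"type": "lognormal", "log_model": model_to_dict(model.log_model)}
    raise TypeError(f"cannot serialize model type {type(model).__name__}")


def model_from_dict(d: dict):
    kind = d.get("type")
    if kind == "gaussian":
        if "cov_matrix" in d:
            return GaussianFieldModel(d.get("mean", 0.0), cov_matrix=np.asarray(d["cov_matrix"]))
        return GaussianFieldModel(
            d.get("mean", 0.0), sigma2=d["sigma2"], corr_length=d["corr_length"]
        )
    if kind == "lumpy":
        return LumpyFieldModel(d["kbar"], d["amplitude"], d["width"], d.get("offset", 0.0))
    if kind == "lognormal":
        return LognormalFieldModel(model_from_dict(d["log_model"]))
    raise ValueError(f"unknown model type {kind!r}")


def write_json(obj, path) -> None:
    with open(path, "w") as f:
        json.dump(obj, f, indent=2, sort_keys=True, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
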