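"""File I/O: NIfTI volumes, DICOM series, measurement CSVs, YAML configs.

NIfTI is the native on-disk form for HU volumes and occupancy grids;
the affine carries the voxel spacing and places voxel centers at
``origin + (index + 0.5) * spacing`` (the package's corner-based origin
convention).  DICOM series are read-only, with RescaleSlope/Intercept
applied to recover HU.
"""

from __future__ import annotations

import os
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .phantom import AcquisitionConfig, CTVolume
from .volumetry import SliceROIMeasurement

__all__ = [
    "read_volume",
    "write_volume",
    "read_dicom_series",
    "read_measurements_csv",
    "write_measurements_csv",
    "load_config",
    "save_config",
]

MEASUREMENT_COLUMNS = ["slice_index", "area_mm2", "mean_hu", "sd_hu"]


# --------------------------------------------------------------------------
# NIfTI
# --------------------------------------------------------------------------

def write_volume(volume: CTVolume, path) -> None:
    """Write a CTVolume (or an occupancy grid wrapped in one) to NIfTI."""
    dx, dy, dz = volume.spacing
    ox, oy, oz = volume.origin
    affine = np.diag([dx, dy, dz, 1.0])
    affine[:3, 3] = [ox + dx / 2.0, oy + dy / 2.0, oz + dz / 2.0]
    # NIfTI is x-fastest: store as (x, y, z)
    data = np.transpose(volume.hu, (2, 1, 0))
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((dx, dy, dz))
    nib.save(img, os.fspath(path))


def read_volume(path) -> CTVolume:
    """Read a NIfTI volume written by :func:`write_volume` (or any 3-D
    NIfTI with a diagonal affine)."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got {data.ndim}-D")
    dx, dy, dz = (float(z) for z in img.header.get_zooms()[:3])
    t = img.affine[:3, 3]
    origin = (float(t[0]) - dx / 2.0, float(t[1]) - dy / 2.0,
              float(t[2]) - dz / 2.0)
    return CTVolume(hu=np.transpose(data, (2, 1, 0)).astype(float),
                    spacing=(dx, dy, dz), origin=origin)


# --------------------------------------------------------------------------
# DICOM (read-only)
# --------------------------------------------------------------------------

def read_dicom_series(directory) -> CTVolume:
    """Read a single-series axial DICOM directory into a CTVolume.

    Slices are ordered by their z position; RescaleSlope/Intercept map
    stored values to HU.  Inconsistent in-plane spacing or irregular
    slice spacing raises ``ValueError``.
    """
    import pydicom

    directory = os.fspath(directory)
    files = sorted(
        os.path.join(directory, f) for f in os.listdir(directory)
        if not f.startswith("."))
    if not files:
        raise FileNotFoundError(f"no files in {directory}")
    datasets = [pydicom.dcmread(f) for f in files]
    datasets.sort(key=lambda d: float(d.ImagePositionPatient[2]))

    pix = [tuple(float(v) for v in d.PixelSpacing) for d in datasets]
    if len(set(pix)) != 1:
        raise ValueError("inconsistent PixelSpacing across the series")
    row_mm, col_mm = pix[0]  # PixelSpacing is (row, col) = (dy, dx)

    zs = np.array([float(d.ImagePositionPatient[2]) for d in datasets])
    if len(zs) > 1:
        dzs = np.diff(zs)
        if np.ptp(dzs) > 1e-3 or dzs[0] <= 0:
            raise ValueError("irregular slice spacing in the series")
        dz = float(dzs[0])
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0))

    slices = []
    for d in datasets:
        arr = d.pixel_array.astype(float)
        slope = float(getattr(d, "RescaleSlope", 1.0))
        intercept = float(getattr(d, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    hu = np.stack(slices, axis=0)
    x0, y0, z0 = (float(v) for v in datasets[0].ImagePositionPatient)
    origin = (x0 - col_mm / 2.0, y0 - row_mm / 2.0, zs[0] - dz / 2.0)
    return CTVolume(hu=hu, spacing=(col_mm, row_mm, dz), origin=origin)


# --------------------------------------------------------------------------
# measurement CSV
# --------------------------------------------------------------------------

def write_measurements_csv(measurements: Sequence[SliceROIMeasurement],
                           path) -> None:
    pd.DataFrame([
        {
            "slice_index": m.slice_index,
            "area_mm2": m.area_mm2,
            "mean_hu": m.mean_hu,
            "sd_hu": m.sd_hu,
        }
        for m in measurements
    ])[MEASUREMENT_COLUMNS].to_csv(path, index=False)


def read_measurements_csv(path) -> list[SliceROIMeasurement]:
    df = pd.read_csv(path)
    missing = set(MEASUREMENT_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"measurement CSV missing columns: {sorted(missing)}")
    if "sd_hu" not in df.columns:
        df["sd_hu"] = 0.0
    return [
        SliceROIMeasurement(
            slice_index=int(r.slice_index),
            area_mm2=float(r.area_mm2),
            mean_hu=float(r.mean_hu),
            sd_hu=float(r.sd_hu),
        )
        for r in df.itertuples()
    ]


# --------------------------------------------------------------------------
# YAML configs
# --------------------------------------------------------------------------

def save_config(config: AcquisitionConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_config(path) -> AcquisitionConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ValueError(f"config file {path} does not hold a mapping")
    return AcquisitionConfig.from_dict(d)
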