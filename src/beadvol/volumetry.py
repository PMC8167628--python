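"""Two-material partial-volume volumetry.

A voxel (or ROI) spanning two materials reports the occupancy-weighted
average of their densities.  For a region containing only an object
material (mean density ``hu_object``) embedded in a background material
(``hu_background``), the object's area fraction is recovered by inverting
the two-material mixture::

    f = (mean_hu - hu_background) / (hu_object - hu_background)

and the object volume follows from per-slice ROI areas and the slice
thickness::

    V [cm^3] = T/1000 * sum_i A_i * f_i

with ``T`` in mm and ``A_i`` in mm^2.  No boundary detection is involved,
which is the point: the method is insensitive to partial-volume blurring
of convoluted interfaces.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "MaterialPair",
    "SliceROIMeasurement",
    "VolumetryResult",
    "object_fraction",
    "total_volume",
    "relative_error",
    "measure_roi",
    "calibrate_materials",
    "cnr",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MaterialPair:
    """Reference densities (HU) of the two compartments.

    ``hu_object`` is the contained material (the beads), ``hu_background``
    the surrounding material (the jelly).  SDs are diagnostic only; they do
    not enter the volume computation.
    """

    hu_object: float
    hu_background: float
    sd_object: Optional[float] = None
    sd_background: Optional[float] = None

    def __post_init__(self) -> None:
        if self.hu_object == self.hu_background:
            raise ValueError(
                "hu_object and hu_background must differ "
                f"(both are {self.hu_object} HU); the mixture inversion "
                "divides by their contrast"
            )
        for name in ("sd_object", "sd_background"):
            sd = getattr(self, name)
            if sd is not None and sd < 0:
                raise ValueError(f"{name} must be >= 0, got {sd}")

    @property
    def contrast(self) -> float:
        """HU difference between object and background."""
        return self.hu_object - self.hu_background

    def shifted(self, delta_object: float = 0.0, delta_background: float = 0.0
                ) -> "MaterialPair":
        """Return a copy with offset reference densities."""
        return MaterialPair(
            hu_object=self.hu_object + delta_object,
            hu_background=self.hu_background + delta_background,
            sd_object=self.sd_object,
            sd_background=self.sd_background,
        )


@dataclass(frozen=True)
class SliceROIMeasurement:
    """Per-slice ROI record: what a PACS workstation displays.

    ``area_mm2`` is the ROI area, ``mean_hu``/``sd_hu`` the density mean
    and standard deviation over the ROI pixels.
    """

    slice_index: int
    area_mm2: float
    mean_hu: float
    sd_hu: float = 0.0

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0:
            raise ValueError(f"area_mm2 must be > 0, got {self.area_mm2}")


@dataclass
class VolumetryResult:
    """Per-slice fractions/volumes and their total.

    ``n_out_of_range`` counts slices whose fraction fell outside [0, 1]
    (legal under noise; fractions are propagated unclamped).
    """

    slice_indices: list[int]
    per_slice_fraction: np.ndarray
    per_slice_volume_cm3: np.ndarray
    total_volume_cm3: float
    slice_thickness_mm: float
    materials: MaterialPair
    n_out_of_range: int = 0
    relative_error_pct: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "slice_indices": list(map(int, self.slice_indices)),
            "per_slice_fraction": [float(f) for f in self.per_slice_fraction],
            "per_slice_volume_cm3": [float(v) for v in self.per_slice_volume_cm3],
            "total_volume_cm3": float(self.total_volume_cm3),
            "slice_thickness_mm": float(self.slice_thickness_mm),
            "n_out_of_range": int(self.n_out_of_range),
            "materials": {
                "hu_object": self.materials.hu_object,
                "hu_background": self.materials.hu_background,
                "sd_object": self.materials.sd_object,
                "sd_background": self.materials.sd_background,
            },
        }
        if self.relative_error_pct is not None:
            d["relative_error_pct"] = float(self.relative_error_pct)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "VolumetryResult":
        with open(path) as fh:
            d = json.load(fh)
        mat = d["materials"]
        return cls(
            slice_indices=list(d["slice_indices"]),
            per_slice_fraction=np.asarray(d["per_slice_fraction"], dtype=float),
            per_slice_volume_cm3=np.asarray(d["per_slice_volume_cm3"], dtype=float),
            total_volume_cm3=float(d["total_volume_cm3"]),
            slice_thickness_mm=float(d["slice_thickness_mm"]),
            materials=MaterialPair(
                hu_object=mat["hu_object"],
                hu_background=mat["hu_background"],
                sd_object=mat.get("sd_object"),
                sd_background=mat.get("sd_background"),
            ),
            n_out_of_range=int(d.get("n_out_of_range", 0)),
            relative_error_pct=d.get("relative_error_pct"),
        )


# --------------------------------------------------------------------------
# core operations
# --------------------------------------------------------------------------

def object_fraction(mean_hu, materials: MaterialPair):
    """Object area fraction from the mean ROI density.

    Inverts the two-material mixture.  Not clamped to [0, 1]: under noise
    a measured mean can stray slightly past either pure-material density,
    and clamping would bias the summed volume upward.  Accepts scalars or
    arrays.
    """
    mean_hu = np.asarray(mean_hu, dtype=float)
    f = (mean_hu - materials.hu_background) / materials.contrast
    return float(f) if f.ndim == 0 else f


def total_volume(
    measurements: Sequence[SliceROIMeasurement],
    materials: MaterialPair,
    slice_thickness_mm: float,
    reference_cm3: Optional[float] = None,
) -> VolumetryResult:
    """Object volume (cm^3) from per-slice ROI measurements.

    V = T/1000 * sum_i A_i * f_i, with f_i from :func:`object_fraction`.
    Slices whose ROI contains no object contribute f ~ 0, so including
    extra slices is harmless.  If ``reference_cm3`` is given the signed
    relative error (%) is attached to the result.
    """
    measurements = list(measurements)
    if not measurements:
        raise ValueError("measurement set is empty")
    if slice_thickness_mm <= 0:
        raise ValueError(
            f"slice_thickness_mm must be > 0, got {slice_thickness_mm}")
    indices = [m.slice_index for m in measurements]
    if len(set(indices)) != len(indices):
        raise ValueError("slice_index values must be unique")

    areas = np.array([m.area_mm2 for m in measurements], dtype=float)
    means = np.array([m.mean_hu for m in measurements], dtype=float)
    fractions = object_fraction(means, materials)
    fractions = np.atleast_1d(fractions)
    volumes = slice_thickness_mm * areas * fractions / 1000.0
    total = float(volumes.sum())
    n_oob = int(np.count_nonzero((fractions < 0) | (fractions > 1)))

    err = None
    if reference_cm3 is not None:
        err = relative_error(total, reference_cm3)
    return VolumetryResult(
        slice_indices=indices,
        per_slice_fraction=fractions,
        per_slice_volume_cm3=volumes,
        total_volume_cm3=total,
        slice_thickness_mm=slice_thickness_mm,
        materials=materials,
        n_out_of_range=n_oob,
        relative_error_pct=err,
    )


def relative_error(calculated_cm3: float, actual_cm3: float) -> float:
    """Signed relative error (%) of a calculated volume vs the truth."""
    if actual_cm3 <= 0:
        raise ValueError(f"actual volume must be > 0, got {actual_cm3}")
    return 100.0 * (calculated_cm3 - actual_cm3) / actual_cm3


def cnr(materials: MaterialPair, noise_sd: float) -> float:
    """Contrast-to-noise ratio: material contrast over the image noise SD."""
    if noise_sd <= 0:
        raise ValueError(f"noise_sd must be > 0, got {noise_sd}")
    return abs(materials.contrast) / noise_sd


# --------------------------------------------------------------------------
# ROI statistics and calibration
# --------------------------------------------------------------------------

def measure_roi(volume, slice_index: int, roi_mask: np.ndarray
                ) -> SliceROIMeasurement:
    """Mean/SD density and area of a binary ROI on one slice.

    ``volume`` is a :class:`beadvol.phantom.CTVolume` (or anything with
    ``hu[z, y, x]`` and ``spacing=(dx, dy, dz)``).  Area is the masked
    pixel count times the in-plane pixel area; SD is the population SD
    (ddof=0), matching what workstations report.
    """
    hu = volume.hu
    if not 0 <= slice_index < hu.shape[0]:
        raise IndexError(
            f"slice_index {slice_index} outside stack of {hu.shape[0]}")
    sl = hu[slice_index]
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != sl.shape:
        raise ValueError(
            f"mask shape {roi_mask.shape} != slice shape {sl.shape}")
    n = int(roi_mask.sum())
    if n == 0:
        raise ValueError("ROI mask is empty")
    vals = sl[roi_mask]
    dx, dy, _ = volume.spacing
    return SliceROIMeasurement(
        slice_index=int(slice_index),
        area_mm2=n * dx * dy,
        mean_hu=float(vals.mean()),
        sd_hu=float(vals.std(ddof=0)),
    )


def calibrate_materials(
    volume,
    background_roi,
    object_rois: Iterable,
    occupancy: Optional[np.ndarray] = None,
) -> MaterialPair:
    """Estimate the reference densities from calibration ROIs.

    ``background_roi`` is one (slice_index, mask) pair — a large region of
    pure background; ``object_rois`` are small masks each fully interior
    to one object on the slice where it appears largest.  The object
    density is the unweighted mean of the per-ROI means (mirroring the
    ten-bead procedure); its SD is the unweighted mean of the per-ROI SDs.
    If a ground-truth ``occupancy`` grid is supplied, object ROIs that
    touch background voxels trigger a warning.
    """
    object_rois = list(object_rois)
    if not object_rois:
        raise ValueError("at least one object calibration ROI is required")

    def _as_pair(roi):
        # accept (slice_index, mask) tuples or SliceROI-like objects
        if hasattr(roi, "slice_index") and hasattr(roi, "mask"):
            return int(roi.slice_index), np.asarray(roi.mask, dtype=bool)
        idx, mask = roi
        return int(idx), np.asarray(mask, dtype=bool)

    bg_idx, bg_mask = _as_pair(background_roi)
    bg = measure_roi(volume, bg_idx, bg_mask)

    means, sds = [], []
    for roi in object_rois:
        idx, mask = _as_pair(roi)
        if occupancy is not None and np.any(occupancy[idx][mask] < 1.0):
            warnings.warn(
                f"object calibration ROI on slice {idx} includes voxels "
                "not fully interior to an object; its mean is biased "
                "toward the background",
                stacklevel=2,
            )
        m = measure_roi(volume, idx, mask)
        means.append(m.mean_hu)
        sds.append(m.sd_hu)

    return MaterialPair(
        hu_object=float(np.mean(means)),
        hu_background=bg.mean_hu,
        sd_object=float(np.mean(sds)),
        sd_background=bg.sd_hu,
    )
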