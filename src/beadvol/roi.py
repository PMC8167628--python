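"""Region-of-interest construction, rasterization, and perturbation.

Emulates the freehand mixture ROIs a radiologist draws around the bead
cluster on each slice (all object pixels plus a rim of background and
nothing else), the area-doubled variant, and the calibration ROIs
(a large pure-background region; small disks interior to individual
beads).  Polygon ROIs are rasterized by the pixel-center even-odd rule
before any statistics are taken, matching what a PACS workstation
reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from matplotlib.path import Path as _MplPath
from scipy import ndimage

__all__ = [
    "SliceROI",
    "auto_mixture_roi",
    "mixture_roi_stack",
    "scale_roi",
    "rasterize",
    "background_calibration_roi",
    "object_calibration_rois",
    "save_roi_set",
    "load_roi_set",
]

ROI_KINDS = ("mixture", "background_cal", "object_cal")


@dataclass
class SliceROI:
    """One per-slice ROI: a binary raster and/or a closed polygon (mm).

    ``polygon`` is an (n, 2) array of in-plane (x, y) vertices of a
    simple closed ring; ``mask`` is a 2-D boolean raster on the slice
    grid.  At least one of the two must be present.
    """

    slice_index: int
    kind: str = "mixture"
    mask: Optional[np.ndarray] = None
    polygon: Optional[np.ndarray] = None
    achieved_area_factor: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ROI_KINDS:
            raise ValueError(f"kind must be one of {ROI_KINDS}, got {self.kind!r}")
        if self.mask is None and self.polygon is None:
            raise ValueError("SliceROI needs a mask or a polygon")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if not self.mask.any():
                raise ValueError("ROI raster is empty")
        if self.polygon is not None:
            self.polygon = np.asarray(self.polygon, dtype=float).reshape(-1, 2)
            if len(self.polygon) < 3:
                raise ValueError("polygon needs at least 3 vertices")

    @property
    def n_pixels(self) -> int:
        if self.mask is None:
            raise ValueError("ROI has no raster; rasterize it first")
        return int(self.mask.sum())


# --------------------------------------------------------------------------
# rasterization
# --------------------------------------------------------------------------

def rasterize(roi: SliceROI, grid_shape: tuple[int, int],
              spacing: tuple[float, float],
              origin: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Rasterize a polygon ROI: a pixel belongs to the ROI iff its
    center lies inside the polygon (even-odd rule).

    ``grid_shape`` is (ny, nx), ``spacing`` (dx, dy) mm, ``origin`` the
    mm position of the corner of pixel (0, 0).  Deterministic; returns a
    boolean mask.
    """
    if roi.polygon is None:
        if roi.mask is not None:
            return roi.mask
        raise ValueError("ROI has no polygon to rasterize")
    poly = roi.polygon
    if len(poly) < 3:
        raise ValueError("degenerate polygon: fewer than 3 vertices")
    ny, nx = grid_shape
    dx, dy = spacing
    ox, oy = origin
    xs = ox + (np.arange(nx) + 0.5) * dx
    ys = oy + (np.arange(ny) + 0.5) * dy
    xx, yy = np.meshgrid(xs, ys)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    # close the ring explicitly: Path(..., closed=True) consumes the last
    # vertex as the CLOSEPOLY slot
    ring = np.vstack([poly, poly[:1]])
    inside = _MplPath(ring, closed=True).contains_points(pts)
    return inside.reshape(ny, nx)


# --------------------------------------------------------------------------
# automatic mixture ROIs
# --------------------------------------------------------------------------

def _elliptic_footprint(radius_mm: float, spacing: tuple[float, float]
                        ) -> np.ndarray:
    """Binary footprint of mm radius on a possibly anisotropic grid."""
    dx, dy = spacing
    rx = max(int(np.ceil(radius_mm / dx)), 0)
    ry = max(int(np.ceil(radius_mm / dy)), 0)
    yy, xx = np.mgrid[-ry:ry + 1, -rx:rx + 1]
    return (xx * dx) ** 2 + (yy * dy) ** 2 <= radius_mm ** 2 + 1e-12


def auto_mixture_roi(
    occupancy: np.ndarray,
    slice_index: int,
    margin_mm: float = 2.0,
    spacing: tuple[float, float] = (1.0, 1.0),
    occ_threshold: float = 1e-9,
) -> SliceROI:
    """Freehand-like mixture ROI for one slice of a simulated phantom.

    Dilates the slice's ground-truth object support (occupancy above
    ``occ_threshold``) by ``margin_mm``, so the ROI contains every
    object pixel plus a background rim only — the two-material premise.
    Rejects slices without object and ROIs that would touch the grid
    edge (pixels beyond the grid are not guaranteed to be phantom).
    """
    occ = np.asarray(occupancy)
    if not 0 <= slice_index < occ.shape[0]:
        raise IndexError(f"slice_index {slice_index} outside stack")
    support = occ[slice_index] > occ_threshold
    if not support.any():
        raise ValueError(
            f"slice {slice_index} contains no object; a margin-only ROI "
            "is not a mixture ROI")
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    if margin_mm == 0:
        mask = support
    else:
        mask = ndimage.binary_dilation(
            support, structure=_elliptic_footprint(margin_mm, spacing))
    edge = (mask[0, :].any() or mask[-1, :].any()
            or mask[:, 0].any() or mask[:, -1].any())
    if edge:
        raise ValueError(
            "ROI touches the grid edge; enlarge the grid margin so the "
            "ROI contains only the two phantom materials")
    return SliceROI(slice_index=int(slice_index), kind="mixture", mask=mask)


def mixture_roi_stack(
    occupancy: np.ndarray,
    margin_mm: float = 2.0,
    spacing: tuple[float, float] = (1.0, 1.0),
    occ_threshold: float = 1e-9,
) -> list[SliceROI]:
    """Mixture ROIs for every slice that contains any object."""
    occ = np.asarray(occupancy)
    out = []
    for k in range(occ.shape[0]):
        if np.any(occ[k] > occ_threshold):
            out.append(auto_mixture_roi(occ, k, margin_mm, spacing,
                                        occ_threshold))
    if not out:
        raise ValueError("no slice contains any object")
    return out


def scale_roi(
    roi: SliceROI,
    area_factor: float,
    occupancy: Optional[np.ndarray] = None,
    occ_threshold: float = 1e-9,
) -> SliceROI:
    """Grow an ROI by iterative one-pixel dilation until its raster area
    reaches ``area_factor`` times the original.

    The grown rim must be pure background when ground truth is supplied
    (it is by construction when the original ROI already contains all
    object pixels of the slice).  The achieved factor — at least the
    requested one, overshooting by at most one dilation ring — is
    recorded on the returned ROI.
    """
    if area_factor < 1:
        raise ValueError("area_factor must be >= 1")
    if roi.mask is None:
        raise ValueError("ROI must be rasterized before scaling")
    mask = roi.mask
    target = area_factor * mask.sum()
    while mask.sum() < target:
        grown = ndimage.binary_dilation(mask)
        if (grown[0, :].any() or grown[-1, :].any()
                or grown[:, 0].any() or grown[:, -1].any()):
            raise ValueError(
                f"cannot grow ROI to x{area_factor} without touching the "
                "grid edge")
        if occupancy is not None:
            rim = grown & ~mask
            if np.any(occupancy[roi.slice_index][rim] > occ_threshold):
                raise ValueError(
                    "ROI growth would swallow object pixels outside the "
                    "original ROI")
        mask = grown
    return SliceROI(
        slice_index=roi.slice_index,
        kind=roi.kind,
        mask=mask,
        achieved_area_factor=float(mask.sum() / roi.mask.sum()),
    )


# --------------------------------------------------------------------------
# calibration ROIs
# --------------------------------------------------------------------------

def background_calibration_roi(
    occupancy: np.ndarray,
    spacing: tuple[float, float],
    area_mm2: float = 1000.0,
    edge_margin_px: int = 2,
) -> SliceROI:
    """A large disk of pure background, emulating the ~10 cm^2 jelly ROI.

    Searches every slice for the background pixel with the greatest
    clearance from any object or grid edge and centers the disk there.
    """
    occ = np.asarray(occupancy)
    dx, dy = spacing
    radius_mm = float(np.sqrt(area_mm2 / np.pi))
    best = None  # (clearance_mm, slice, iy, ix)
    pad = 1 + edge_margin_px
    for k in range(occ.shape[0]):
        bg = occ[k] <= 0
        if not bg.any():
            continue
        # padding with non-background makes the transform measure
        # clearance from objects AND the grid edge at once
        bgp = np.pad(bg, pad, constant_values=False)
        dist = ndimage.distance_transform_edt(bgp, sampling=(dy, dx))[
            pad:-pad, pad:-pad]
        iy, ix = np.unravel_index(np.argmax(dist), dist.shape)
        if best is None or dist[iy, ix] > best[0]:
            best = (float(dist[iy, ix]), k, iy, ix)
    if best is None or best[0] < radius_mm:
        raise ValueError(
            f"no background region large enough for a {area_mm2} mm^2 "
            "calibration ROI")
    _, k, iy, ix = best
    ny, nx = occ.shape[1:]
    yy, xx = np.mgrid[0:ny, 0:nx]
    mask = ((xx - ix) * dx) ** 2 + ((yy - iy) * dy) ** 2 <= radius_mm ** 2
    return SliceROI(slice_index=int(k), kind="background_cal", mask=mask)


def object_calibration_rois(
    pack,
    grid_shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float],
    n_rois: int = 10,
    roi_radius_fraction: float = 0.5,
    min_radius_mm: float = 1.8,
    seed: int = 0,
) -> list[SliceROI]:
    """Small disks interior to randomly selected beads.

    For each selected bead, a disk of ``roi_radius_fraction`` times the
    bead radius is placed at the bead center on the slice where the bead
    cross-section is largest — the slice nearest the center — keeping
    the ROI clear of any partial-volume rim.  Beads smaller than
    ``min_radius_mm`` are excluded so the disk spans several pixels.
    """
    dx, dy, dz = spacing
    ox, oy, oz = origin
    nz, ny, nx = grid_shape
    eligible = np.flatnonzero(pack.radii >= min_radius_mm)
    if eligible.size == 0:
        raise ValueError("no bead large enough for an interior ROI")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(eligible, size=min(n_rois, eligible.size),
                        replace=False)
    rois = []
    yy, xx = np.mgrid[0:ny, 0:nx]
    for b in chosen:
        cx, cy, cz = pack.centers[b]
        r_roi = pack.radii[b] * roi_radius_fraction
        k = int(np.clip(round((cz - oz) / dz - 0.5), 0, nz - 1))
        # shrink so the disk stays interior despite the slice offset
        z_off = abs(oz + (k + 0.5) * dz - cz) + dz / 2.0
        r_eff = np.sqrt(max(pack.radii[b] ** 2 - z_off ** 2, 0.0))
        r_roi = min(r_roi, r_eff - max(dx, dy))
        if r_roi < max(dx, dy):
            continue
        mask = (((xx + 0.5) * dx + ox - cx) ** 2
                + ((yy + 0.5) * dy + oy - cy) ** 2) <= r_roi ** 2
        if mask.any():
            rois.append(SliceROI(slice_index=k, kind="object_cal", mask=mask))
    if not rois:
        raise ValueError("could not place any interior bead ROI")
    return rois


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def save_roi_set(rois: Iterable[SliceROI], path) -> None:
    """Write polygon ROIs as JSON ({slice_index, kind, polygon} records)."""
    records = []
    for r in rois:
        if r.polygon is None:
            raise ValueError(
                "only polygon ROIs serialize to JSON; raster ROIs should "
                "be written as NIfTI label masks")
        records.append({
            "slice_index": int(r.slice_index),
            "kind": r.kind,
            "polygon": np.asarray(r.polygon, dtype=float).tolist(),
        })
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2)


def load_roi_set(path) -> list[SliceROI]:
    with open(path) as fh:
        records = json.load(fh)
    return [
        SliceROI(slice_index=int(r["slice_index"]), kind=r.get("kind", "mixture"),
                 polygon=np.asarray(r["polygon"], dtype=float))
        for r in records
    ]
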