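"""Digital bead-in-jelly phantom and CT acquisition emulation.

Builds a random non-overlapping pack of PMMA-like spheres (object,
~120 HU) settled into a petroleum-jelly-like background (~-150 HU),
voxelizes it with sub-voxel partial-volume averaging, and emulates the
acquisition variations a scanner would produce: through-plane slice
averaging, additive image noise, an edge-enhancing reconstruction
kernel (unsharp mask), multiplanar reformats, and in-plane pixel
coarsening.  No sinogram/back-projection physics: each voxel's HU is
the exact occupancy-weighted mixture of the two materials, which is
the regime the volumetry method assumes.

Conventions: arrays are indexed ``[z, y, x]`` with z the stacking axis;
``spacing`` is ``(dx, dy, dz)`` in mm; ``origin`` is the mm position of
the corner of voxel (0, 0, 0), so voxel centers sit at
``origin + (index + 0.5) * spacing``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "HU_BEADS",
    "HU_JELLY",
    "DEFAULT_SIZE_MIX",
    "BeadPack",
    "CTVolume",
    "AcquisitionConfig",
    "PackingError",
    "pack_beads",
    "analytic_volume",
    "voxelize",
    "air_pocket_pack",
    "reslice",
    "add_noise",
    "edge_enhance",
    "reformat",
    "resample_pixels",
    "nearest_thickness",
    "crop_slices_to_multiple",
]

#: Measured reference densities of the physical phantom materials (HU).
HU_BEADS = 119.9
HU_JELLY = -149.7

#: Default bead diameter mixture (mm -> probability).  Nominal sizes span
#: 3.2-6.4 mm; the weights skew small so that a 750-bead pack has an
#: expected analytic volume of 35.5 cm^3 (47.34 mm^3 per bead).
DEFAULT_SIZE_MIX = {3.2: 0.32, 4.0: 0.28, 4.8: 0.22, 5.6: 0.11, 6.4: 0.07}

#: Tangency tolerance for the non-overlap constraint (mm).
EPS_CONTACT = 1e-6


class PackingError(RuntimeError):
    """Raised when the sphere packer cannot place enough beads."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class BeadPack:
    """Non-overlapping spheres inside an axis-aligned box.

    ``centers`` are (n, 3) mm coordinates (x, y, z) with the container
    spanning ``[0, L]`` on each axis; ``radii`` are mm.  The analytic
    sphere-volume sum is the simulation ground truth, standing in for the
    physical phantom's water-displacement measurement.
    """

    centers: np.ndarray
    radii: np.ndarray
    container: tuple[float, float, float]
    seed: int = 0

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        if len(self.centers) != len(self.radii):
            raise ValueError("centers and radii length mismatch")

    def __len__(self) -> int:
        return len(self.radii)

    @property
    def analytic_volume_cm3(self) -> float:
        return analytic_volume(self)

    def validate(self) -> None:
        """Check non-overlap and containment (O(n^2); used by tests)."""
        c, r = self.centers, self.radii
        lo = c - r[:, None]
        hi = c + r[:, None]
        if np.any(lo < -EPS_CONTACT) or np.any(
                hi > np.asarray(self.container) + EPS_CONTACT):
            raise ValueError("sphere extends outside the container")
        for i in range(len(r)):
            d = np.linalg.norm(c[i + 1:] - c[i], axis=1)
            if np.any(d < r[i + 1:] + r[i] - EPS_CONTACT):
                raise ValueError(f"sphere {i} overlaps a later sphere")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "centers_mm": self.centers.tolist(),
                    "radii_mm": self.radii.tolist(),
                    "container_mm": list(self.container),
                    "seed": int(self.seed),
                    "analytic_volume_cm3": self.analytic_volume_cm3,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "BeadPack":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            centers=np.asarray(d["centers_mm"], dtype=float),
            radii=np.asarray(d["radii_mm"], dtype=float),
            container=tuple(d["container_mm"]),
            seed=int(d.get("seed", 0)),
        )


@dataclass
class CTVolume:
    """A 3-D HU grid with voxel spacing.

    ``hu`` is ``[z, y, x]``; ``spacing`` is ``(dx, dy, dz)`` mm.
    """

    hu: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=float)
        if self.hu.ndim != 3:
            raise ValueError(f"hu grid must be 3-D, got {self.hu.ndim}-D")
        if min(self.hu.shape) < 1:
            raise ValueError("grid dimensions must all be >= 1")
        if min(self.spacing) <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape

    @property
    def n_slices(self) -> int:
        return self.hu.shape[0]

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing[0] * self.spacing[1]

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def slice_thickness_mm(self) -> float:
        return self.spacing[2]

    def copy(self) -> "CTVolume":
        return CTVolume(self.hu.copy(), tuple(self.spacing), tuple(self.origin))


@dataclass
class AcquisitionConfig:
    """Emulated scan/reconstruction parameters.

    Tube current, kVp and iterative reconstruction are represented only
    through ``noise_sd_hu``; ``supersampling`` is the per-axis sub-voxel
    sampling used for partial-volume averaging.  The default pixel size
    is a 14 cm FOV over a 512 matrix.
    """

    hu_object: float = HU_BEADS
    hu_background: float = HU_JELLY
    in_plane_pixel_mm: float = 140.0 / 512.0
    thin_slice_mm: float = 0.625
    noise_sd_hu: float = 4.6
    kernel: str = "standard"
    supersampling: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.in_plane_pixel_mm <= 0 or self.thin_slice_mm <= 0:
            raise ValueError("pixel and slice sizes must be > 0")
        if self.supersampling < 1:
            raise ValueError("supersampling must be >= 1")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be >= 0")
        if self.kernel not in ("standard", "edge_enhanced"):
            raise ValueError(f"unknown kernel {self.kernel!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionConfig":
        return cls(**d)


# --------------------------------------------------------------------------
# sphere packing
# --------------------------------------------------------------------------

def _sample_diameters(rng, n, diameter_range, size_mix):
    lo, hi = diameter_range
    if size_mix == "uniform":
        return rng.uniform(lo, hi, size=n)
    mix = DEFAULT_SIZE_MIX if size_mix is None else dict(size_mix)
    sizes = np.array([d for d in mix if lo - 1e-9 <= d <= hi + 1e-9])
    if sizes.size == 0:
        raise ValueError("no mixture diameters inside diameter_range")
    w = np.array([mix[d] for d in sizes], dtype=float)
    return rng.choice(sizes, size=n, p=w / w.sum())


def pack_beads(
    count_target: int,
    diameter_range: tuple[float, float] = (3.2, 6.4),
    container: tuple[float, float, float] = (70.0, 70.0, 45.0),
    seed: int = 0,
    size_mix=None,
    max_attempts_per_bead: int = 4000,
) -> BeadPack:
    """Random sequential addition of non-overlapping spheres.

    Candidate positions are biased toward the lower center of the box,
    emulating beads settled into a concave scoop; tangency between beads
    is allowed.  Deterministic given ``seed``.  Raises
    :class:`PackingError` if fewer than half the requested beads can be
    placed within the attempt budget.

    ``size_mix`` is a {diameter_mm: weight} dict, ``"uniform"``, or None
    for the default small-skewed nominal mix.
    """
    if count_target < 1:
        raise ValueError("count_target must be >= 1")
    lo, hi = diameter_range
    if lo <= 0 or hi < lo or hi > min(container):
        raise ValueError(
            f"diameter_range {diameter_range} must lie in "
            f"(0, {min(container)}]")

    rng = np.random.default_rng(seed)
    box = np.asarray(container, dtype=float)
    diams = _sample_diameters(rng, count_target, diameter_range, size_mix)
    # place large beads first: improves packing density and mimics big
    # beads reaching the scoop bottom
    diams = np.sort(diams)[::-1]

    centers: list[np.ndarray] = []
    radii: list[float] = []
    placed = np.empty((0, 3))
    placed_r = np.empty(0)
    for d in diams:
        r = d / 2.0
        free = box - 2 * r
        for attempt in range(max_attempts_per_bead):
            # relax the settling bias as attempts accumulate so a crowded
            # bottom does not stall the packer
            relax = attempt / max_attempts_per_bead
            u = rng.random(3)
            xy_bias = rng.beta(1.6, 1.6, size=2) if relax < 0.5 else u[:2]
            z_bias = u[2] ** (1.6 - relax) if relax < 0.8 else u[2]
            pos = np.array([
                r + free[0] * xy_bias[0],
                r + free[1] * xy_bias[1],
                r + free[2] * z_bias,
            ])
            if placed.shape[0]:
                d2 = np.sum((placed - pos) ** 2, axis=1)
                min_d = placed_r + r - EPS_CONTACT
                if np.any(d2 < min_d * min_d):
                    continue
            centers.append(pos)
            radii.append(r)
            placed = np.vstack([placed, pos])
            placed_r = np.append(placed_r, r)
            break

    if len(radii) < max(1, count_target // 2):
        raise PackingError(
            f"placed only {len(radii)}/{count_target} beads; "
            "use a larger container or smaller beads")
    return BeadPack(
        centers=np.asarray(placed),
        radii=np.asarray(placed_r),
        container=tuple(box),
        seed=int(seed),
    )


def analytic_volume(pack: BeadPack) -> float:
    """Exact sphere-volume sum of a pack, in cm^3."""
    return float(np.sum(4.0 / 3.0 * np.pi * pack.radii ** 3) / 1000.0)


# --------------------------------------------------------------------------
# voxelization (partial-volume averaging)
# --------------------------------------------------------------------------

def _sphere_occupancy(
    centers: np.ndarray,
    radii: np.ndarray,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float],
    supersampling: int,
) -> np.ndarray:
    """Per-voxel occupancy of a set of spheres by regular sub-voxel
    sampling at ``supersampling**3`` points per voxel."""
    nz, ny, nx = shape
    dx, dy, dz = spacing
    ox, oy, oz = origin
    s = supersampling
    occ = np.zeros(shape, dtype=float)
    # sub-voxel sample offsets (voxel units, centered)
    off = (np.arange(s) + 0.5) / s - 0.5
    for (cx, cy, cz), r in zip(centers, radii):
        # voxel index ranges covering the sphere
        jx0 = max(int(np.floor((cx - r - ox) / dx)), 0)
        jx1 = min(int(np.ceil((cx + r - ox) / dx)), nx)
        jy0 = max(int(np.floor((cy - r - oy) / dy)), 0)
        jy1 = min(int(np.ceil((cy + r - oy) / dy)), ny)
        jz0 = max(int(np.floor((cz - r - oz) / dz)), 0)
        jz1 = min(int(np.ceil((cz + r - oz) / dz)), nz)
        if jx0 >= jx1 or jy0 >= jy1 or jz0 >= jz1:
            continue
        # fine-grid coordinates relative to the sphere center
        fx = (ox + (np.arange(jx0, jx1)[:, None] + 0.5 + off) * dx - cx).ravel()
        fy = (oy + (np.arange(jy0, jy1)[:, None] + 0.5 + off) * dy - cy).ravel()
        fz = (oz + (np.arange(jz0, jz1)[:, None] + 0.5 + off) * dz - cz).ravel()
        inside = (
            fz[:, None, None] ** 2 + fy[None, :, None] ** 2
            + fx[None, None, :] ** 2
        ) <= r * r
        nzf, nyf, nxf = jz1 - jz0, jy1 - jy0, jx1 - jx0
        frac = (
            inside.reshape(nzf, s, nyf, s, nxf, s)
            .mean(axis=(1, 3, 5))
        )
        occ[jz0:jz1, jy0:jy1, jx0:jx1] += frac
    np.clip(occ, 0.0, 1.0, out=occ)
    return occ


def voxelize(
    pack: BeadPack,
    config: Optional[AcquisitionConfig] = None,
    margin_mm: float = 3.0,
    nz_multiple: int = 8,
    shape: Optional[tuple[int, int, int]] = None,
    origin: Optional[tuple[float, float, float]] = None,
    air_pack: Optional[BeadPack] = None,
    hu_air: float = -1000.0,
) -> tuple[CTVolume, np.ndarray]:
    """Voxelize a bead pack into an HU volume plus an occupancy grid.

    Each voxel's occupancy ``o`` in [0, 1] — the fraction of the voxel
    inside any sphere — is estimated by regular sub-voxel sampling at
    ``supersampling**3`` points; the voxel's HU is the mixture
    ``o*hu_object + (1-o)*hu_background``, noise-free.  Spheres never
    overlap, so per-sphere occupancies add.

    By default the grid covers the container plus ``margin_mm`` of pure
    background on every side (the jelly fills the whole grid), with the
    slice count rounded up to a multiple of ``nz_multiple`` so the stack
    reslices evenly to 2.5 and 5.0 mm.  Pass ``shape``/``origin`` for an
    explicit grid instead; spheres outside the grid raise ``ValueError``.

    ``air_pack`` (see :func:`air_pocket_pack`) injects tiny air pockets
    that displace *background only*, lowering ROI means without
    changing the object ground truth — an artifact model, off unless
    supplied.
    """
    config = config or AcquisitionConfig()
    dx = dy = config.in_plane_pixel_mm
    dz = config.thin_slice_mm

    if shape is None:
        nx = int(np.ceil((pack.container[0] + 2 * margin_mm) / dx))
        ny = int(np.ceil((pack.container[1] + 2 * margin_mm) / dy))
        nz = int(np.ceil((pack.container[2] + 2 * margin_mm) / dz))
        nz = int(np.ceil(nz / nz_multiple) * nz_multiple)
        # center the container in the grid
        ox = (pack.container[0] - nx * dx) / 2.0
        oy = (pack.container[1] - ny * dy) / 2.0
        oz = (pack.container[2] - nz * dz) / 2.0
        origin = (ox, oy, oz)
    else:
        nz, ny, nx = shape
        origin = origin or (0.0, 0.0, 0.0)
    ox, oy, oz = origin

    lo = pack.centers - pack.radii[:, None]
    hi = pack.centers + pack.radii[:, None]
    grid_lo = np.array([ox, oy, oz])
    grid_hi = grid_lo + np.array([nx * dx, ny * dy, nz * dz])
    if np.any(lo < grid_lo - 1e-9) or np.any(hi > grid_hi + 1e-9):
        raise ValueError("a sphere extends outside the voxel grid; the "
                         "mixture model requires full containment")

    spacing = (dx, dy, dz)
    occ = _sphere_occupancy(pack.centers, pack.radii, (nz, ny, nx),
                            spacing, origin, config.supersampling)
    # convex-combination form keeps pure voxels at exactly the material HU
    hu = occ * config.hu_object + (1.0 - occ) * config.hu_background
    if air_pack is not None and len(air_pack):
        o_air = _sphere_occupancy(air_pack.centers, air_pack.radii,
                                  (nz, ny, nx), spacing, origin,
                                  config.supersampling)
        # air displaces background only; bead occupancy (the ground
        # truth) is untouched
        o_air = np.minimum(o_air, 1.0 - occ)
        hu += o_air * (hu_air - config.hu_background)
    vol = CTVolume(hu=hu, spacing=spacing, origin=(ox, oy, oz))
    return vol, occ


def air_pocket_pack(
    pack: BeadPack,
    radius_mm: float = 0.3,
    fraction: float = 0.5,
    contact_tol_mm: float = 0.5,
    seed: int = 0,
) -> BeadPack:
    """Tiny air spheres at bead-bead contact points.

    Sequentially packed spheres rarely touch exactly, so any pair whose
    surface gap is at most ``contact_tol_mm`` counts as a contact.

    Models air adherent to bead surfaces where beads touch — a
    plausible source of a small negative volumetry bias: the pockets
    lower nearby ROI means (pulling the estimated object fraction
    down) while the true bead volume is unchanged.  ``fraction``
    selects a random subset of the contact points.
    """
    c, r = pack.centers, pack.radii
    contacts = []
    for i in range(len(r)):
        d = np.linalg.norm(c[i + 1:] - c[i], axis=1)
        touching = np.flatnonzero(d <= r[i + 1:] + r[i] + contact_tol_mm)
        for j in touching:
            k = i + 1 + j
            # point on the line between centers, at the surface of bead i
            p = c[i] + (c[k] - c[i]) * (r[i] / (r[i] + r[k]))
            contacts.append(p)
    if not contacts:
        return BeadPack(np.empty((0, 3)), np.empty(0), pack.container,
                        seed=seed)
    contacts = np.asarray(contacts)
    rng = np.random.default_rng(seed)
    n_keep = max(1, int(round(fraction * len(contacts))))
    keep = rng.choice(len(contacts), size=n_keep, replace=False)
    return BeadPack(contacts[keep], np.full(n_keep, radius_mm),
                    pack.container, seed=seed)


# --------------------------------------------------------------------------
# acquisition emulation
# --------------------------------------------------------------------------

def _thickness_factor(volume: CTVolume, new_thickness_mm: float) -> int:
    dz = volume.spacing[2]
    factor = new_thickness_mm / dz
    if abs(factor - round(factor)) > 1e-6 or round(factor) < 1:
        raise ValueError(
            f"new thickness {new_thickness_mm} mm is not an integer "
            f"multiple of the native spacing {dz} mm")
    return int(round(factor))


def reslice(volume: CTVolume, new_thickness_mm: float) -> CTVolume:
    """Thicker slices by non-overlapping averaging of native slices.

    The new thickness must be an integer multiple of the native z
    spacing and divide the stack evenly (no slice-sensitivity-profile
    interpolation is modelled); the volume-wide HU mean is preserved.
    """
    factor = _thickness_factor(volume, new_thickness_mm)
    if factor == 1:
        return volume.copy()
    nz = volume.hu.shape[0]
    if nz % factor:
        raise ValueError(
            f"stack of {nz} slices does not divide evenly into blocks of "
            f"{factor}; crop background slices first "
            "(crop_slices_to_multiple)")
    hu = volume.hu.reshape(nz // factor, factor, *volume.hu.shape[1:]).mean(axis=1)
    dx, dy, dz = volume.spacing
    return CTVolume(hu=hu, spacing=(dx, dy, dz * factor), origin=volume.origin)


def nearest_thickness(volume: CTVolume, desired_mm: float) -> float:
    """Closest reslice-able thickness to ``desired_mm`` (>= 1 slice)."""
    dz = volume.spacing[2]
    return max(1, round(desired_mm / dz)) * dz


def crop_slices_to_multiple(
    volume: CTVolume,
    factor: int,
    occupancy: Optional[np.ndarray] = None,
):
    """Trim edge slices so the stack length is a multiple of ``factor``.

    Slices are removed as evenly as possible from both ends.  If a
    ground-truth ``occupancy`` grid is supplied, it is cropped alongside
    and the removed slices are required to be object-free.
    """
    nz = volume.hu.shape[0]
    excess = nz % factor
    if excess == 0:
        return (volume, occupancy) if occupancy is not None else volume
    front = excess // 2
    back = excess - front
    if occupancy is not None and (
        np.any(occupancy[:front] > 0) or (back and np.any(occupancy[nz - back:] > 0))
    ):
        raise ValueError("cannot crop: edge slices contain object voxels")
    sl = slice(front, nz - back)
    dx, dy, dz = volume.spacing
    ox, oy, oz = volume.origin
    out = CTVolume(
        hu=volume.hu[sl].copy(),
        spacing=volume.spacing,
        origin=(ox, oy, oz + front * dz),
    )
    if occupancy is not None:
        return out, occupancy[sl].copy()
    return out


def add_noise(volume: CTVolume, sd_hu: float, seed: int = 0) -> CTVolume:
    """Add zero-mean i.i.d. Gaussian noise (white; real CT noise is
    spatially correlated, which is deliberately not modelled)."""
    if sd_hu < 0:
        raise ValueError(f"sd_hu must be >= 0, got {sd_hu}")
    if sd_hu == 0:
        return volume.copy()
    rng = np.random.default_rng(seed)
    hu = volume.hu + rng.normal(0.0, sd_hu, size=volume.hu.shape)
    return CTVolume(hu=hu, spacing=volume.spacing, origin=volume.origin)


def edge_enhance(volume: CTVolume, strength: float = 1.5,
                 radius_mm: float = 0.8) -> CTVolume:
    """Edge-enhancing ("Lung"-like) kernel emulated as an in-plane
    unsharp mask: ``out = in + strength * (in - G_radius(in))``.

    Flat regions are unchanged; edges overshoot/undershoot, altering HU
    and noise texture near boundaries the way sharp reconstruction
    kernels do.
    """
    if strength < 0:
        raise ValueError(f"strength must be >= 0, got {strength}")
    if strength == 0:
        return volume.copy()
    dx, dy, _ = volume.spacing
    blurred = ndimage.gaussian_filter(
        volume.hu, sigma=(0.0, radius_mm / dy, radius_mm / dx),
        mode="nearest")
    hu = volume.hu + strength * (volume.hu - blurred)
    return CTVolume(hu=hu, spacing=volume.spacing, origin=volume.origin)


def reformat(volume: CTVolume, plane: str,
             out_thickness_mm: Optional[float] = None) -> CTVolume:
    """Multiplanar reformat: make the coronal or sagittal plane the
    slicing plane, optionally followed by a reslice.

    Coronal stacks along the original y axis (slices contain z, x);
    sagittal stacks along x (slices contain z, y).  The transposition is
    lossless, so the global HU mean is preserved exactly.
    """
    dx, dy, dz = volume.spacing
    ox, oy, oz = volume.origin
    if plane == "coronal":
        # [z, y, x] -> [y, z, x]; in-plane axes (x, z), stack spacing dy
        hu = np.transpose(volume.hu, (1, 0, 2))
        out = CTVolume(hu=hu.copy(), spacing=(dx, dz, dy), origin=(ox, oz, oy))
    elif plane == "sagittal":
        # [z, y, x] -> [x, z, y]; in-plane axes (y, z), stack spacing dx
        hu = np.transpose(volume.hu, (2, 0, 1))
        out = CTVolume(hu=hu.copy(), spacing=(dy, dz, dx), origin=(oy, oz, ox))
    elif plane == "axial":
        out = volume.copy()
    else:
        raise ValueError(f"unknown plane {plane!r}")
    if out_thickness_mm is not None:
        out = reslice(out, out_thickness_mm)
    return out


def resample_pixels(volume: CTVolume, new_pixel_mm: float) -> CTVolume:
    """Coarsen the in-plane pixel size by area-weighted averaging,
    emulating a larger reconstruction FOV at a fixed matrix.

    Only coarsening is supported.  For integer ratios this is exact
    block averaging; for non-integer ratios the output covers the
    largest whole number of new pixels and any sub-pixel remainder at
    the high-index edge is dropped.
    """
    dx, dy, dz = volume.spacing
    if new_pixel_mm < dx - 1e-12 or new_pixel_mm < dy - 1e-12:
        raise ValueError(
            f"new pixel {new_pixel_mm} mm is finer than the native "
            f"({dx}, {dy}) mm; only coarsening is emulated")
    if abs(new_pixel_mm - dx) < 1e-12 and abs(new_pixel_mm - dy) < 1e-12:
        return volume.copy()

    def _weights(n_in: int, d_in: float) -> np.ndarray:
        n_out = int(np.floor(n_in * d_in / new_pixel_mm + 1e-9))
        if n_out < 1:
            raise ValueError("volume too small for the requested pixel size")
        w = np.zeros((n_out, n_in))
        for i in range(n_out):
            a, b = i * new_pixel_mm, (i + 1) * new_pixel_mm
            j0, j1 = int(np.floor(a / d_in)), int(np.ceil(b / d_in - 1e-12))
            for j in range(j0, min(j1, n_in)):
                w[i, j] = (min(b, (j + 1) * d_in) - max(a, j * d_in)) / new_pixel_mm
        return w

    wy = _weights(volume.hu.shape[1], dy)
    wx = _weights(volume.hu.shape[2], dx)
    hu = np.einsum("ij,zjk->zik", wy, volume.hu)
    hu = np.einsum("kl,zjl->zjk", wx, hu)
    return CTVolume(hu=hu, spacing=(new_pixel_mm, new_pixel_mm, dz),
                    origin=volume.origin)
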