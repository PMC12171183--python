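"""Volume containers and I/O: fat-fraction maps, muscle masks, point clouds.

Fat fraction (FF) is fat / (fat + water) per voxel and is stored in [0, 1];
all human-facing reports print percent. Masks are binary on the same grid as
their FF volume. Point clouds place one point at each foreground voxel center
((index + 0.5) * spacing, 0-based indices) in physical mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class FFVolume:
    """3D fat-fraction grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Fat fraction in [0, 1]; NaN allowed (e.g. where fat + water == 0).
    spacing : tuple of float
        Voxel size (dx, dy, dz) in mm, all strictly positive.
    slice_axis : int
        Index of the anatomical long axis (the slice-stacking axis).
    distal_to_proximal : bool
        True if increasing slice index runs distal -> proximal.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    slice_axis: int = 2
    distal_to_proximal: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"FFVolume requires a 3D array, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive floats")
        if not 0 <= self.slice_axis <= 2:
            raise ValueError("slice_axis must be 0, 1 or 2")
        finite = self.data[np.isfinite(self.data)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("finite fat-fraction values must lie in [0, 1]")

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass
class MuscleMask:
    """Binary segmentation mask for one muscle, on the grid of its FFVolume."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    muscle_label: str = "muscle"
    slice_axis: int = 2
    distal_to_proximal: bool = True

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"MuscleMask requires a 3D array, got {arr.ndim}D")
        uniq = np.unique(arr[np.isfinite(arr.astype(float))])
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be binary 0/1")
        self.data = arr.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def volume_mm3(self) -> float:
        """Muscle volume: foreground voxel count times voxel volume."""
        return float(self.data.sum()) * self.voxel_volume


@dataclass
class BoundingDomain:
    """Axis-aligned box (mm), optionally backed by the voxel mask for
    CSR simulation restricted to the muscle shape."""

    low: np.ndarray
    high: np.ndarray
    mask: np.ndarray | None = None
    spacing: tuple[float, float, float] | None = None

    @property
    def box_volume(self) -> float:
        return float(np.prod(self.high - self.low))


@dataclass
class MusclePointCloud:
    """IMF voxel centers in mm with the enclosing muscle volume.

    ``points`` has one row per foreground voxel of the source IMF mask;
    ``muscle_volume`` (mm^3) is the normalisation constant for the
    tessellation metrics; ``bounding_domain`` is the support for CSR
    simulation in Ripley's K analysis.
    """

    points: np.ndarray
    muscle_volume: float
    bounding_domain: BoundingDomain = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def compute_ff_map(
    fat_signal: np.ndarray,
    water_signal: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    slice_axis: int = 2,
    distal_to_proximal: bool = True,
) -> FFVolume:
    """Fat-fraction map from separate fat and water signal volumes.

    FF = fat / (fat + water) voxelwise; voxels where fat + water == 0 are NaN.
    """
    fat = np.asarray(fat_signal, dtype=float)
    water = np.asarray(water_signal, dtype=float)
    if fat.shape != water.shape:
        raise ValueError(f"shape mismatch: fat {fat.shape} vs water {water.shape}")
    if np.nanmin(fat) < 0 or np.nanmin(water) < 0:
        raise ValueError("signal volumes must be non-negative")
    total = fat + water
    with np.errstate(invalid="ignore", divide="ignore"):
        ff = np.where(total > 0, fat / np.where(total > 0, total, 1.0), np.nan)
    return FFVolume(ff, spacing, slice_axis, distal_to_proximal)


def _nifti_spacing(img: nib.Nifti1Image) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def load_volume(
    path: str | Path,
    kind: str = "ff",
    slice_axis: int = 2,
    distal_to_proximal: bool = True,
    muscle_label: str = "muscle",
) -> FFVolume | MuscleMask:
    """Load a NIfTI volume as an FF map or a binary muscle mask.

    FF stored as percent (max > 1.5) is rescaled to [0, 1] with a warning.
    Masks are binarized at 0.5 and must be 0/1 afterwards.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
    spacing = _nifti_spacing(img)
    if kind == "ff":
        finite = data[np.isfinite(data)]
        if finite.size and finite.max() > 1.5:
            logger.warning("%s: values look like percent (max=%.3g); rescaling to [0,1]",
                           path, finite.max())
            data = data / 100.0
        return FFVolume(data, spacing, slice_axis, distal_to_proximal)
    if kind == "mask":
        binar = (data >= 0.5).astype(np.uint8)
        # values not close to 0 or 1 indicate a non-mask volume
        resid = np.abs(data - binar)
        if np.nanmax(resid) > 0.5:
            raise ValueError(f"{path}: volume is not a binary mask")
        return MuscleMask(binar, spacing, muscle_label, slice_axis, distal_to_proximal)
    raise ValueError(f"unknown kind {kind!r}; expected 'ff' or 'mask'")


def save_volume(vol: FFVolume | MuscleMask, path: str | Path) -> None:
    """Write a volume as NIfTI, encoding spacing in a diagonal affine."""
    data = vol.data.astype(np.uint8) if isinstance(vol, MuscleMask) else vol.data
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def voxel_centers_mm(mask: np.ndarray, spacing: tuple[float, float, float]) -> np.ndarray:
    """Physical coordinates of foreground voxel centers: (index + 0.5) * spacing."""
    idx = np.argwhere(mask)
    return (idx + 0.5) * np.asarray(spacing, dtype=float)


def mask_to_point_cloud(imf_mask: np.ndarray, muscle_mask: MuscleMask) -> MusclePointCloud:
    """Convert a binary IMF mask into a point cloud for spatial analysis.

    One point per foreground voxel at the voxel center in mm; the muscle
    volume and bounding domain come from the enclosing muscle mask.
    """
    imf = np.asarray(imf_mask).astype(bool)
    if imf.shape != muscle_mask.data.shape:
        raise ValueError("IMF mask and muscle mask must share a grid")
    if not imf.any():
        raise ValueError("no IMF clusters: the IMF mask is empty")
    pts = voxel_centers_mm(imf, muscle_mask.spacing)
    midx = np.argwhere(muscle_mask.data)
    sp = np.asarray(muscle_mask.spacing)
    domain = BoundingDomain(
        low=midx.min(axis=0) * sp,
        high=(midx.max(axis=0) + 1) * sp,
        mask=muscle_mask.data,
        spacing=muscle_mask.spacing,
    )
    return MusclePointCloud(pts, muscle_mask.volume_mm3, domain)
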