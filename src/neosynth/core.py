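"""Core containers: label maps, intensity images, cortical surface pairs.

Volumes live on a regular 3D grid with a physical voxel size in mm. World
coordinates put the origin at the volume centre, so mm-denominated parameters
(translations, displacements, surface offsets) keep their meaning across grid
sizes. NIfTI-1 is the on-disk format for everything (integer label maps,
float32 images and signed-distance volumes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

#: Canonical tissue palette: the nine brain tissue classes of the target
#: objective plus air background, with all extra-cerebral tissue collapsed
#: into a single ``head`` class.
PALETTE: dict[int, str] = {
    0: "background",
    1: "head",
    2: "csf",
    3: "gm",
    4: "wm",
    5: "ventricles",
    6: "deepgm",
    7: "cerebellum",
    8: "brainstem",
    9: "hipamy",
}

LABEL_IDS: dict[str, int] = {name: lid for lid, name in PALETTE.items()}

#: Structures that the surface-derived ground-truth fusion must never touch.
PROTECTED_LABELS: tuple[str, ...] = (
    "background", "head", "ventricles", "deepgm", "cerebellum",
    "brainstem", "hipamy",
)


def _affine_from_geometry(shape, voxel_size) -> np.ndarray:
    """World affine with the origin at the volume centre (RAS, mm)."""
    shape = np.asarray(shape, dtype=float)
    voxel_size = np.asarray(voxel_size, dtype=float)
    aff = np.diag(np.append(voxel_size, 1.0))
    aff[:3, 3] = -(shape - 1) / 2.0 * voxel_size
    return aff


def _as_voxel_size(voxel_size) -> tuple[float, float, float]:
    arr = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    if np.any(arr <= 0):
        raise ValueError(f"voxel_size must be positive, got {tuple(arr)}")
    return tuple(float(v) for v in arr)


@dataclass
class LabelMap:
    """3D integer tissue map with voxel geometry.

    Parameters
    ----------
    voxels
        Integer array of label ids, shape (nx, ny, nz).
    voxel_size
        Physical voxel size in mm per axis (scalar broadcasts).
    palette
        Mapping from label id to tissue name. Every voxel value must be a
        key of the palette.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    palette: Mapping[int, str] = field(default_factory=lambda: dict(PALETTE))
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("LabelMap requires a 3D array")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("LabelMap voxels must be integer-typed")
        self.voxel_size = _as_voxel_size(self.voxel_size)
        present = np.unique(self.voxels)
        unknown = [int(v) for v in present if int(v) not in self.palette]
        if unknown:
            raise ValueError(f"voxel values {unknown} not in palette")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def affine(self) -> np.ndarray:
        return _affine_from_geometry(self.shape, self.voxel_size)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def id_of(self, name: str) -> int:
        for lid, lname in self.palette.items():
            if lname == name:
                return lid
        raise KeyError(f"label {name!r} not in palette")

    def mask(self, label: int | str) -> np.ndarray:
        lid = self.id_of(label) if isinstance(label, str) else int(label)
        return self.voxels == lid

    def volume_mm3(self, label: int | str) -> float:
        return float(self.mask(label).sum()) * self.voxel_volume

    def present_labels(self) -> list[int]:
        return [int(v) for v in np.unique(self.voxels)]

    def with_voxels(self, voxels: np.ndarray, palette=None) -> "LabelMap":
        return LabelMap(voxels, self.voxel_size,
                        dict(palette if palette is not None else self.palette),
                        dict(self.meta))

    def copy(self) -> "LabelMap":
        return self.with_voxels(self.voxels.copy())

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.voxels.astype(np.int16), self.affine)
        img.header.set_zooms(self.voxel_size)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path, palette=None) -> "LabelMap":
        img = nib.load(str(path))
        voxels = np.asarray(img.dataobj).astype(np.int32)
        voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(voxels, voxel_size,
                   dict(palette) if palette is not None else dict(PALETTE))


@dataclass
class Image:
    """3D scalar intensity volume sharing the geometry of a LabelMap."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("Image requires a 3D array")
        self.voxel_size = _as_voxel_size(self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def affine(self) -> np.ndarray:
        return _affine_from_geometry(self.shape, self.voxel_size)

    def with_voxels(self, voxels: np.ndarray) -> "Image":
        return Image(voxels, self.voxel_size)

    def copy(self) -> "Image":
        return self.with_voxels(self.voxels.copy())

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.voxels.astype(np.float32), self.affine)
        img.header.set_zooms(self.voxel_size)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path) -> "Image":
        img = nib.load(str(path))
        voxels = np.asarray(img.dataobj, dtype=np.float64)
        voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(voxels, voxel_size)


@dataclass
class SurfacePair:
    """Signed-distance volumes (mm, negative inside) of the two cortical
    boundaries: inner (white) and outer (pial).

    Invariant: the interior of the inner surface is nested in the interior of
    the outer surface, i.e. ``{inner_sdf < 0} ⊆ {outer_sdf < 0}``.
    """

    inner_sdf: np.ndarray
    outer_sdf: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.inner_sdf = np.asarray(self.inner_sdf, dtype=np.float64)
        self.outer_sdf = np.asarray(self.outer_sdf, dtype=np.float64)
        if self.inner_sdf.shape != self.outer_sdf.shape:
            raise ValueError("inner and outer SDF shapes differ")
        self.voxel_size = _as_voxel_size(self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.inner_sdf.shape

    def check_nested(self) -> bool:
        """True when {inner < 0} is a subset of {outer < 0}."""
        return bool(np.all(self.outer_sdf[self.inner_sdf < 0] < 0))

    def offset(self, bias_mm: float) -> "SurfacePair":
        """Displace the outer boundary outward and the inner inward by
        ``bias_mm`` (thickening the enclosed shell)."""
        return SurfacePair(self.inner_sdf + bias_mm,
                           self.outer_sdf - bias_mm, self.voxel_size)

    def save(self, inner_path: str | Path, outer_path: str | Path) -> None:
        aff = _affine_from_geometry(self.shape, self.voxel_size)
        for arr, path in ((self.inner_sdf, inner_path),
                          (self.outer_sdf, outer_path)):
            img = nib.Nifti1Image(arr.astype(np.float32), aff)
            img.header.set_zooms(self.voxel_size)
            nib.save(img, str(path))

    @classmethod
    def load(cls, inner_path: str | Path, outer_path: str | Path
             ) -> "SurfacePair":
        inner = nib.load(str(inner_path))
        outer = nib.load(str(outer_path))
        voxel_size = tuple(float(z) for z in inner.header.get_zooms()[:3])
        return cls(np.asarray(inner.dataobj, dtype=np.float64),
                   np.asarray(outer.dataobj, dtype=np.float64), voxel_size)


def world_coordinates(shape, voxel_size) -> tuple[np.ndarray, ...]:
    """Per-axis 1D world coordinates (mm, origin at the volume centre),
    shaped for broadcasting over the grid."""
    voxel_size = np.broadcast_to(np.asarray(voxel_size, float), (3,))
    axes = []
    for d, (n, vs) in enumerate(zip(shape, voxel_size)):
        c = (np.arange(n) - (n - 1) / 2.0) * vs
        shp = [1, 1, 1]
        shp[d] = n
        axes.append(c.reshape(shp))
    return tuple(axes)
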