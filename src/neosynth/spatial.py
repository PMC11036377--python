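"""Random affine and elastic spatial augmentation.

Label maps are resampled with nearest-neighbour interpolation (a deformation
can never invent a label) and images with trilinear interpolation. Both share
identical geometry semantics: rotations are about the volume centre in world
coordinates, translations and displacements are in mm, and out-of-field
voxels are filled with the background label / zero intensity.

Default sampling ranges: per-axis scaling U[0.9, 1.1], rotation U[-20°, 20°],
translation U[-10, 10] mm; elastic deformation on a 12-point-per-axis control
grid with per-component displacements U[-8, 8] mm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import ndimage

from .core import Image, LabelMap

Volume = Union[LabelMap, Image]

SCALE_RANGE: tuple[float, float] = (0.9, 1.1)
MAX_ROTATION_DEG: float = 20.0
MAX_TRANSLATION_MM: float = 10.0
ELASTIC_CONTROL_POINTS: int = 12
ELASTIC_MAX_DISPLACEMENT_MM: float = 8.0


@dataclass
class AffineParams:
    """Per-axis scale, rotation (degrees) and translation (mm)."""

    scale: np.ndarray
    rotation_deg: np.ndarray
    translation_mm: np.ndarray

    def __post_init__(self):
        self.scale = np.broadcast_to(np.asarray(self.scale, float), (3,)).copy()
        self.rotation_deg = np.broadcast_to(
            np.asarray(self.rotation_deg, float), (3,)).copy()
        self.translation_mm = np.broadcast_to(
            np.asarray(self.translation_mm, float), (3,)).copy()

    @classmethod
    def identity(cls) -> "AffineParams":
        return cls(np.ones(3), np.zeros(3), np.zeros(3))

    def is_identity(self) -> bool:
        return (np.all(self.scale == 1.0) and np.all(self.rotation_deg == 0.0)
                and np.all(self.translation_mm == 0.0))

    def to_config(self) -> dict:
        return {"scale": self.scale.tolist(),
                "rotation_deg": self.rotation_deg.tolist(),
                "translation_mm": self.translation_mm.tolist()}


@dataclass
class ElasticParams:
    """Coarse displacement grid: one mm-denominated 3-vector per control
    point, densified over the voxel grid with a cubic B-spline."""

    displacement_mm: np.ndarray  # (3, nc, nc, nc)
    max_displacement_mm: float = ELASTIC_MAX_DISPLACEMENT_MM

    def __post_init__(self):
        self.displacement_mm = np.asarray(self.displacement_mm, float)
        if self.displacement_mm.ndim != 4 or self.displacement_mm.shape[0] != 3:
            raise ValueError("displacement grid must have shape (3, nc, nc, nc)")

    @property
    def control_points(self) -> int:
        return self.displacement_mm.shape[1]

    @classmethod
    def zero(cls, control_points: int = ELASTIC_CONTROL_POINTS
             ) -> "ElasticParams":
        n = control_points
        return cls(np.zeros((3, n, n, n)))


def sample_affine(rng: np.random.Generator,
                  scale_range=SCALE_RANGE,
                  max_rotation_deg=MAX_ROTATION_DEG,
                  max_translation_mm=MAX_TRANSLATION_MM) -> AffineParams:
    """Uniform, per-axis-independent affine parameters within the ranges."""
    return AffineParams(
        scale=rng.uniform(*scale_range, size=3),
        rotation_deg=rng.uniform(-max_rotation_deg, max_rotation_deg, size=3),
        translation_mm=rng.uniform(-max_translation_mm, max_translation_mm,
                                   size=3),
    )


def sample_elastic(rng: np.random.Generator, grid_shape=None,
                   control_points: int = ELASTIC_CONTROL_POINTS,
                   max_displacement_mm: float = ELASTIC_MAX_DISPLACEMENT_MM
                   ) -> ElasticParams:
    """Draw every control-point displacement component from
    U[-max_displacement, max_displacement] mm.

    ``grid_shape`` is accepted for interface symmetry with ``apply_elastic``
    but the control grid itself is resolution-independent.
    """
    n = int(control_points)
    disp = rng.uniform(-max_displacement_mm, max_displacement_mm,
                       size=(3, n, n, n))
    return ElasticParams(disp, max_displacement_mm)


def _rotation_matrix(rotation_deg: np.ndarray) -> np.ndarray:
    """R = Rz @ Ry @ Rx, angles in degrees."""
    rx, ry, rz = np.deg2rad(rotation_deg)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _resolve(volume: Volume, interpolation: str | None):
    """Common checks; returns (array, order, cval, is_labels)."""
    if isinstance(volume, LabelMap):
        if interpolation is None:
            interpolation = "nearest"
        if interpolation != "nearest":
            raise ValueError(
                "label maps must be resampled with nearest-neighbour "
                f"interpolation, got {interpolation!r}")
        return volume.voxels, 0, 0, True
    if isinstance(volume, Image):
        if interpolation is None:
            interpolation = "linear"
        order = {"nearest": 0, "linear": 1}.get(interpolation)
        if order is None:
            raise ValueError(f"unknown interpolation {interpolation!r}")
        return volume.voxels, order, 0.0, False
    raise TypeError(f"expected LabelMap or Image, got {type(volume).__name__}")


def _rebuild(volume: Volume, out: np.ndarray) -> Volume:
    if isinstance(volume, LabelMap):
        return volume.with_voxels(out.astype(volume.voxels.dtype))
    return volume.with_voxels(out)


def apply_affine(volume: Volume, params: AffineParams,
                 interpolation: str | None = None) -> Volume:
    """Resample ``volume`` under the affine map y = R S (x - c) + c + t
    (world mm coordinates, c the volume centre)."""
    arr, order, cval, _ = _resolve(volume, interpolation)
    if params.is_identity():
        return _rebuild(volume, arr.copy())
    vs = np.asarray(volume.voxel_size)
    centre = (np.asarray(arr.shape) - 1) / 2.0
    fwd = _rotation_matrix(params.rotation_deg) @ np.diag(params.scale)
    inv = np.linalg.inv(fwd)
    # ndimage pulls: input_voxel = M @ output_voxel + offset
    M = np.diag(1.0 / vs) @ inv @ np.diag(vs)
    offset = centre - M @ centre - (np.diag(1.0 / vs) @ inv
                                    @ params.translation_mm)
    out = ndimage.affine_transform(arr, M, offset=offset, order=order,
                                   mode="constant", cval=cval,
                                   prefilter=False)
    return _rebuild(volume, out)


def densify_displacement(params: ElasticParams, grid_shape,
                         voxel_size=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Densify the control grid to a per-voxel displacement field (mm).

    The control displacements are used directly as cubic B-spline
    coefficients (no prefilter), so the dense field is a convex-weighted
    blend of control values and every component stays within the sampled
    bounds.
    """
    nc = params.control_points
    shape = tuple(int(n) for n in grid_shape)
    coords = np.meshgrid(
        *[np.arange(n) / max(n - 1, 1) * (nc - 1) for n in shape],
        indexing="ij")
    coords = np.stack(coords)
    field = np.empty((3,) + shape)
    for axis in range(3):
        field[axis] = ndimage.map_coordinates(
            params.displacement_mm[axis], coords, order=3,
            mode="nearest", prefilter=False)
    return field


def apply_elastic(volume: Volume, params: ElasticParams,
                  interpolation: str | None = None) -> Volume:
    """Warp ``volume`` by the densified field: output(x) = input(x + d(x))."""
    arr, order, cval, _ = _resolve(volume, interpolation)
    if not np.any(params.displacement_mm):
        return _rebuild(volume, arr.copy())
    field = densify_displacement(params, arr.shape, volume.voxel_size)
    vs = np.asarray(volume.voxel_size)
    coords = np.meshgrid(*[np.arange(n, dtype=float) for n in arr.shape],
                         indexing="ij")
    sample = [coords[a] + field[a] / vs[a] for a in range(3)]
    out = ndimage.map_coordinates(arr, sample, order=order, mode="constant",
                                  cval=cval, prefilter=False)
    return _rebuild(volume, out)
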