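"""Surface-derived cortical ground truth.

Given signed-distance volumes of the inner (white) and outer (pial) cortical
boundaries, the cortical GM partial-volume fraction of each voxel is
estimated by supersampling: the voxel is split into ``supersample``^3
sub-voxels and the fraction of sub-voxel centres falling between the two
surfaces (outer_sdf < 0 and inner_sdf >= 0) is counted, with the SDFs
evaluated by trilinear interpolation. Thresholding the partial-volume map at
0.5 gives a binary GM which is fused back into an existing label map:
voxels that lose their GM label are reassigned to the nearest of WM / CSF,
voxels that gain GM overwrite WM / CSF only, and every other structure is
left bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import Image, LabelMap, SurfacePair

DEFAULT_SUPERSAMPLE: int = 4
GM_THRESHOLD: float = 0.5


@dataclass
class PartialVolumeMap:
    """Per-voxel GM fraction in [0, 1] on the label-map grid."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.min() < -1e-9 or self.voxels.max() > 1 + 1e-9:
            raise ValueError("partial-volume fractions must lie in [0, 1]")

    @property
    def shape(self):
        return self.voxels.shape

    def to_image(self) -> Image:
        return Image(self.voxels, self.voxel_size)


@dataclass
class FusionDiagnostics:
    """Bookkeeping from ``binarize_and_fuse``."""

    n_gm_lost: int = 0
    n_gm_gained: int = 0
    n_protected_conflicts: int = 0


def partial_volume_gm(surfaces: SurfacePair, grid=None,
                      supersample: int = DEFAULT_SUPERSAMPLE
                      ) -> PartialVolumeMap:
    """GM partial-volume map from a nested surface pair.

    ``grid`` defaults to the SDF grid itself (a LabelMap may be passed to
    assert geometric agreement).
    """
    if supersample < 2:
        raise ValueError("supersample must be >= 2")
    if not surfaces.check_nested():
        raise ValueError("surface pair violates nesting: {inner_sdf < 0} "
                         "must be a subset of {outer_sdf < 0}")
    shape = surfaces.shape
    if grid is not None and tuple(grid.shape) != tuple(shape):
        raise ValueError("grid shape does not match the surface volumes")

    s = int(supersample)
    offsets = (np.arange(s) + 0.5) / s - 0.5
    base = np.meshgrid(*[np.arange(n, dtype=float) for n in shape],
                       indexing="ij")
    count = np.zeros(shape, dtype=np.int64)
    for ox in offsets:
        for oy in offsets:
            for oz in offsets:
                coords = [base[0] + ox, base[1] + oy, base[2] + oz]
                inner = ndimage.map_coordinates(surfaces.inner_sdf, coords,
                                                order=1, mode="nearest")
                outer = ndimage.map_coordinates(surfaces.outer_sdf, coords,
                                                order=1, mode="nearest")
                count += (outer < 0) & (inner >= 0)
    return PartialVolumeMap(count / float(s ** 3), surfaces.voxel_size)


def binarize_and_fuse(label_map: LabelMap, pv: PartialVolumeMap,
                      threshold: float = GM_THRESHOLD,
                      return_diagnostics: bool = False):
    """Replace the GM of ``label_map`` by the thresholded partial volume.

    GM := {pv >= threshold} (closed comparison, so exact 0.5 ties are
    deterministic). Former GM voxels outside the new GM are propagated to
    the nearest adjacent label among WM / CSF (Euclidean distance to those
    masks, ties to WM); new GM voxels overwrite WM / CSF only. A protected
    structure (ventricles, deep GM, cerebellum, brainstem,
    hippocampus-amygdala, head, background) is never altered; conflicts are
    counted in the diagnostics.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if pv.shape != label_map.shape:
        raise ValueError("partial-volume map grid does not match label map")

    lab = label_map.voxels
    gm, wm, csf = (label_map.id_of(n) for n in ("gm", "wm", "csf"))
    editable = (lab == gm) | (lab == wm) | (lab == csf)
    gm_raw = pv.voxels >= threshold
    gm_new = gm_raw & editable

    out = lab.copy()
    lost = (lab == gm) & ~gm_new
    gained = gm_new & (lab != gm)
    diag = FusionDiagnostics(
        n_gm_lost=int(lost.sum()),
        n_gm_gained=int(gained.sum()),
        n_protected_conflicts=int((gm_raw & ~editable).sum()),
    )

    if lost.any():
        sampling = label_map.voxel_size
        wm_mask = lab == wm
        csf_mask = lab == csf
        d_wm = (ndimage.distance_transform_edt(~wm_mask, sampling=sampling)
                if wm_mask.any() else np.full(lab.shape, np.inf))
        d_csf = (ndimage.distance_transform_edt(~csf_mask, sampling=sampling)
                 if csf_mask.any() else np.full(lab.shape, np.inf))
        if np.isinf(d_wm).all() and np.isinf(d_csf).all():
            raise ValueError("cannot propagate lost GM: no WM or CSF present")
        out[lost & (d_wm <= d_csf)] = wm
        out[lost & (d_wm > d_csf)] = csf
    out[gained] = gm
    out[gm_new] = gm

    fused = label_map.with_voxels(out)
    if return_diagnostics:
        return fused, diag
    return fused
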