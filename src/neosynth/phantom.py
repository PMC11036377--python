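"""Seeded neonatal-like label phantoms.

A phantom is a nested head geometry on a voxel grid: air background, a head
shell, a CSF compartment, a cortical GM shell bounded by an inner (white)
and outer (pial) surface, a WM interior, and five deep structures carved out
of the WM (lateral-ventricle-like, deep GM, cerebellum, brainstem and
hippocampus-amygdala blobs). A ``folding`` parameter in [0, 1] perturbs both
cortical boundaries with a common band-limited radial displacement --- a
stand-in for the increase of cortical folding with gestational age (the
cohort helper maps folding linearly onto 26-45 weeks postconception).

The phantom also provides paired ground-truth variants for the cortical GM:
a ``tight`` one thresholding the surface partial volume at 0.5 and a
``large`` one built from boundaries displaced outward/inward by a bias, with
the bias calibrated so the GM volume ratio large/tight hits a target
(default 1.25, i.e. a 25% GM over-segmentation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LABEL_IDS, PALETTE, LabelMap, SurfacePair, world_coordinates
from .surface_gt import GM_THRESHOLD, binarize_and_fuse, partial_volume_gm

#: Target over-segmentation ratio of GM volume, large / tight.
GM_VOLUME_RATIO_TARGET: float = 1.25

#: Gestational age range (weeks postconception) that folding stands in for.
AGE_RANGE_WEEKS: tuple[float, float] = (26.0, 45.0)

# Deep structures: name -> (per-side centre, semi-axes), in units of the safe
# interior radius; entries with a mirrored twin are voxelized on both sides.
_DEEP_BLOBS: dict[str, tuple[tuple[float, float, float],
                             tuple[float, float, float], bool]] = {
    "ventricles": ((0.20, 0.10, 0.15), (0.11, 0.28, 0.11), True),
    "deepgm": ((0.50, 0.00, 0.08), (0.13, 0.16, 0.13), True),
    "cerebellum": ((0.0, -0.45, -0.35), (0.30, 0.18, 0.16), False),
    "brainstem": ((0.0, -0.10, -0.55), (0.11, 0.11, 0.28), False),
    "hipamy": ((0.35, -0.28, -0.18), (0.10, 0.14, 0.10), True),
}

_N_FOLD_WAVES = 6
_FOLD_AMPLITUDE_MM = 2.2
_FOLD_FREQ_RANGE = (3.0, 10.0)


@dataclass
class PhantomSpec:
    """Geometry and seeding of one phantom."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    folding: float = 0.5
    cortical_thickness: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.grid_shape, int):
            self.grid_shape = (self.grid_shape,) * 3
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if len(self.grid_shape) != 3 or any(n < 32 for n in self.grid_shape):
            raise ValueError("grid_shape must be 3 integers, each >= 32")
        vs = np.broadcast_to(np.asarray(self.voxel_size, float), (3,))
        if np.any(vs <= 0):
            raise ValueError("voxel_size must be positive")
        self.voxel_size = tuple(float(v) for v in vs)
        if not 0.0 <= self.folding <= 1.0:
            raise ValueError("folding must lie in [0, 1]")
        if self.cortical_thickness <= 0:
            raise ValueError("cortical_thickness must be positive")

    @property
    def half_extent_mm(self) -> float:
        return min(n * v for n, v in zip(self.grid_shape, self.voxel_size)) / 2

    def radii(self) -> dict[str, float]:
        """Deterministic shell radii (mm) implied by the grid geometry."""
        H = self.half_extent_mm
        r_out = 0.70 * H
        return {
            "head": 0.92 * H,
            "csf": 0.80 * H,
            "outer": r_out,
            "inner": r_out - self.cortical_thickness,
        }

    @property
    def pseudo_age_weeks(self) -> float:
        lo, hi = AGE_RANGE_WEEKS
        return lo + self.folding * (hi - lo)

    @property
    def fold_amplitude_mm(self) -> float:
        """Peak radial displacement of the folded cortical boundaries,
        capped so the folds stay clear of the CSF/head interface on small
        grids."""
        radii = self.radii()
        gap = radii["csf"] - radii["outer"]
        return self.folding * min(_FOLD_AMPLITUDE_MM, 0.55 * gap)


def _folding_perturbation(spec: PhantomSpec, rng: np.random.Generator,
                          nx, ny, nz, r) -> np.ndarray:
    """Band-limited radial displacement p(direction), |p| <= amplitude."""
    amplitude = spec.fold_amplitude_mm
    lo, hi = _FOLD_FREQ_RANGE
    omega = lo + (hi - lo) * spec.folding
    # draw the phases/directions even at folding=0 so the rng stream (and
    # hence the deep-structure jitter) does not depend on the folding value
    dirs = np.stack([rng.standard_normal(3) for _ in range(_N_FOLD_WAVES)])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    phases = rng.uniform(0, 2 * np.pi, size=_N_FOLD_WAVES)
    weights = rng.uniform(0.5, 1.0, size=_N_FOLD_WAVES)
    if amplitude == 0.0:
        return np.zeros_like(r)
    weights = amplitude * weights / weights.sum()
    safe_r = np.maximum(r, 1e-9)
    ux, uy, uz = nx / safe_r, ny / safe_r, nz / safe_r
    p = np.zeros_like(r)
    for w, d, ph in zip(weights, dirs, phases):
        p += w * np.sin(omega * (d[0] * ux + d[1] * uy + d[2] * uz) + ph)
    return p


def make_phantom(spec: PhantomSpec) -> tuple[LabelMap, SurfacePair]:
    """Generate one phantom; deterministic for a fixed spec (bit-exact).

    Returns the label map (all ten palette labels present) and the cortical
    surface pair as signed-distance volumes. Raises if the grid is too small
    to host all structures.
    """
    rng = np.random.default_rng(spec.seed)
    radii = spec.radii()
    amplitude = spec.fold_amplitude_mm

    margin_csf = radii["csf"] - (radii["outer"] + amplitude)
    if margin_csf <= 0.5:
        raise ValueError(
            f"grid too small: the folded pial boundary (<= "
            f"{radii['outer'] + amplitude:.1f} mm) leaves only "
            f"{margin_csf:.2f} mm of CSF below the head shell at "
            f"{radii['csf']:.1f} mm; increase the grid or reduce folding")
    r_safe = radii["inner"] - amplitude - 1.0
    if r_safe < 6.0:
        raise ValueError(
            f"grid too small: safe WM interior radius {r_safe:.1f} mm < 6 mm "
            "cannot host the deep structures; increase grid_shape, reduce "
            "folding or cortical_thickness")

    x, y, z = world_coordinates(spec.grid_shape, spec.voxel_size)
    r = np.sqrt(x ** 2 + y ** 2 + z ** 2)
    p = _folding_perturbation(spec, rng, x, y, z, r)

    inner_sdf = r - (radii["inner"] + p)
    outer_sdf = r - (radii["outer"] + p)

    lab = np.zeros(spec.grid_shape, dtype=np.int16)  # background
    lab[r <= radii["head"]] = LABEL_IDS["head"]
    lab[r <= radii["csf"]] = LABEL_IDS["csf"]
    lab[(outer_sdf < 0) & (inner_sdf >= 0)] = LABEL_IDS["gm"]
    lab[inner_sdf < 0] = LABEL_IDS["wm"]

    min_semi = 1.2 * max(spec.voxel_size)
    wm_id = LABEL_IDS["wm"]
    for name, (centre, semi, mirrored) in _DEEP_BLOBS.items():
        sides = (1.0, -1.0) if mirrored else (1.0,)
        jitter = rng.uniform(-0.02, 0.02, size=3)
        for side in sides:
            c = (np.asarray(centre) + jitter) * r_safe
            c[0] *= side
            a = np.maximum(np.asarray(semi) * r_safe, min_semi)
            inside = (((x - c[0]) / a[0]) ** 2 + ((y - c[1]) / a[1]) ** 2
                      + ((z - c[2]) / a[2]) ** 2) <= 1.0
            if not inside.any():
                raise ValueError(f"grid too small: structure {name!r} "
                                 "voxelizes to an empty set")
            if np.any(lab[inside] != wm_id):
                raise ValueError(
                    f"grid too small: structure {name!r} would overlap a "
                    "non-WM region; deep blobs must stay disjoint inside WM")
            lab[inside] = LABEL_IDS[name]

    label_map = LabelMap(lab, spec.voxel_size, dict(PALETTE))
    label_map.meta.update(
        radii=radii, folding=spec.folding, seed=spec.seed,
        pseudo_age_weeks=spec.pseudo_age_weeks,
        fold_amplitude_mm=amplitude,
    )
    surfaces = SurfacePair(inner_sdf, outer_sdf, spec.voxel_size)
    return label_map, surfaces


def gm_volume_from_surfaces(label_map: LabelMap, surfaces: SurfacePair,
                            bias_mm: float, supersample: int = 2) -> int:
    """Voxel count of the thresholded, bias-displaced surface GM restricted
    to the editable (gm/wm/csf) region -- the quantity the bias calibration
    drives."""
    pv = partial_volume_gm(surfaces.offset(bias_mm) if bias_mm else surfaces,
                           supersample=supersample)
    lab = label_map.voxels
    editable = ((lab == LABEL_IDS["gm"]) | (lab == LABEL_IDS["wm"])
                | (lab == LABEL_IDS["csf"]))
    return int(((pv.voxels >= GM_THRESHOLD) & editable).sum())


def make_gt_variants(label_map: LabelMap, surfaces: SurfacePair,
                     bias_mm: float, supersample: int = 2
                     ) -> tuple[LabelMap, LabelMap]:
    """Paired ground truths: ``tight`` from the surfaces as given, ``large``
    from boundaries displaced outward (pial) / inward (white) by ``bias_mm``
    before thresholding. Only GM/WM/CSF may differ between the two."""
    if bias_mm < 0:
        raise ValueError("bias_mm must be >= 0")
    head = label_map.mask("head") | label_map.mask("background")
    if bias_mm > 0 and np.any((surfaces.outer_sdf - bias_mm < 0) & head):
        raise ValueError("bias_mm too large: displaced GM touches the head "
                         "label")
    pv_tight = partial_volume_gm(surfaces, supersample=supersample)
    tight = binarize_and_fuse(label_map, pv_tight)
    if bias_mm == 0:
        return tight, tight.copy()
    pv_large = partial_volume_gm(surfaces.offset(bias_mm),
                                 supersample=supersample)
    large = binarize_and_fuse(label_map, pv_large)
    return tight, large


def calibrate_gt_bias(label_map: LabelMap, surfaces: SurfacePair,
                      target_ratio: float = GM_VOLUME_RATIO_TARGET,
                      supersample: int = 2, tol: float = 0.01,
                      max_bias_mm: float = 4.0) -> float:
    """Bisection for the boundary bias that makes volume(large GM) /
    volume(tight GM) hit ``target_ratio``.

    The GM volume is non-decreasing in the bias, so plain bisection on the
    ratio converges; the returned bias achieves the target within ``tol``
    (up to voxelization granularity).
    """
    if target_ratio < 1.0:
        raise ValueError("target_ratio must be >= 1")
    v0 = gm_volume_from_surfaces(label_map, surfaces, 0.0, supersample)
    if v0 == 0:
        raise ValueError("tight GM is empty; cannot calibrate")
    if target_ratio == 1.0:
        return 0.0

    def ratio(b):
        return gm_volume_from_surfaces(label_map, surfaces, b,
                                       supersample) / v0

    lo, hi = 0.0, 0.5
    while ratio(hi) < target_ratio:
        hi *= 2.0
        if hi > max_bias_mm:
            raise ValueError("target ratio not reachable before the GM "
                             "touches the head label")
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        rmid = ratio(mid)
        if abs(rmid - target_ratio) <= tol:
            return mid
        if rmid < target_ratio:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-4:
            break
    return 0.5 * (lo + hi)


def boundary_face_count(label_map: LabelMap, label_a: str, label_b: str
                        ) -> int:
    """Number of voxel faces between two labels (6-connectivity) -- a
    discrete proxy for interface surface area."""
    a = label_map.mask(label_a)
    b = label_map.mask(label_b)
    faces = 0
    for axis in range(3):
        for sign in (1, -1):
            faces += int((a & np.roll(b, sign, axis=axis)).sum())
    return faces
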