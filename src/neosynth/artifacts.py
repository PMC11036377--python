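"""MR acquisition artifacts: bias field, noise, gamma, and k-space motion.

The motion simulator reproduces the mechanism by which subject movement
corrupts an MRI acquisition: k-space is acquired line by line over time, so a
rigid-body movement during the acquisition mixes the spectra of inconsistent
object poses. Each k-space segment (by default a contiguous chunk of
phase-encode lines) is taken from the Fourier transform of the object under
that segment's rigid transform; translations enter as exact linear phase
ramps, rotations by resampling the object before the FFT. The trajectory
model is a single transient movement: identity pose until a random event
time, a short smooth ramp, then a constant plateau whose translation /
rotation magnitudes equal the sampled maxima.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage

from .core import Image

BIAS_ORDER: int = 3
BIAS_MAX_MAGNITUDE: float = 0.5
NOISE_STD_RANGE: tuple[float, float] = (5e-3, 0.1)
MOTION_AMPLITUDE_RANGE: tuple[float, float] = (3.0, 8.0)
LOG_GAMMA_RANGE: tuple[float, float] = (-0.3, 0.3)


# --------------------------------------------------------------------------
# Bias field
# --------------------------------------------------------------------------

def polynomial_exponents(order: int) -> list[tuple[int, int, int]]:
    """All 3-variable monomial exponents with total degree <= order."""
    return [(a, b, c) for a, b, c in product(range(order + 1), repeat=3)
            if a + b + c <= order]


@dataclass
class BiasFieldParams:
    """Coefficients of an order-``order`` polynomial over coordinates
    normalized to [-1, 1]^3; the field applied is exp(P(x))."""

    coefficients: np.ndarray
    order: int = BIAS_ORDER
    max_magnitude: float = BIAS_MAX_MAGNITUDE

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, float)
        n = len(polynomial_exponents(self.order))
        if self.coefficients.shape != (n,):
            raise ValueError(
                f"order-{self.order} bias field needs {n} coefficients, "
                f"got shape {self.coefficients.shape}")


def sample_bias_field(rng: np.random.Generator, order: int = BIAS_ORDER,
                      max_magnitude: float = BIAS_MAX_MAGNITUDE
                      ) -> BiasFieldParams:
    n = len(polynomial_exponents(order))
    coeffs = rng.uniform(-max_magnitude, max_magnitude, size=n)
    return BiasFieldParams(coeffs, order, max_magnitude)


def _normalized_coords(shape, frame=None):
    """Per-axis coordinates in [-1, 1], broadcastable over the grid.

    ``frame`` optionally maps voxel indices to the normalized frame of a
    larger parent grid as ``(offset_vox, parent_shape)`` so a bias field can
    be evaluated consistently on crops.
    """
    axes = []
    for d, n in enumerate(shape):
        idx = np.arange(n, dtype=float)
        if frame is not None:
            off, parent = frame
            idx = idx + off[d]
            m = parent[d]
        else:
            m = n
        half = (m - 1) / 2.0
        c = (idx - half) / half if half > 0 else idx * 0.0
        shp = [1, 1, 1]
        shp[d] = n
        axes.append(c.reshape(shp))
    return axes


def bias_field(params: BiasFieldParams, shape, frame=None) -> np.ndarray:
    """Evaluate the multiplicative field exp(P(x)) on a grid."""
    x, y, z = _normalized_coords(shape, frame)
    P = np.zeros(shape)
    for coeff, (a, b, c) in zip(params.coefficients,
                                polynomial_exponents(params.order)):
        P += coeff * (x ** a) * (y ** b) * (z ** c)
    return np.exp(P)


def apply_bias(image: Image, params: BiasFieldParams, frame=None) -> Image:
    """Multiply by the strictly positive field exp(P(x))."""
    if not np.all(np.isfinite(image.voxels)):
        raise ValueError("apply_bias requires a finite image")
    return image.with_voxels(image.voxels * bias_field(params, image.shape,
                                                       frame))


# --------------------------------------------------------------------------
# Noise and gamma
# --------------------------------------------------------------------------

@dataclass
class NoiseParams:
    std: float
    mean: float = 0.0


def sample_noise(rng: np.random.Generator,
                 std_range=NOISE_STD_RANGE) -> NoiseParams:
    return NoiseParams(std=float(rng.uniform(*std_range)))


def apply_noise(image: Image, params: NoiseParams,
                rng: np.random.Generator) -> Image:
    if params.std == 0.0 and params.mean == 0.0:
        return image.copy()
    noise = params.mean + params.std * rng.standard_normal(image.shape)
    return image.with_voxels(image.voxels + noise)


def sample_log_gamma(rng: np.random.Generator,
                     log_gamma_range=LOG_GAMMA_RANGE) -> float:
    return float(rng.uniform(*log_gamma_range))


def apply_gamma(image: Image, log_gamma: float) -> Image:
    """Power-law contrast perturbation: out = in ** exp(log_gamma).

    Requires a non-negative image (rescale to [0, 1] first); the power
    function is monotone there, so voxel ordering is preserved.
    """
    v = image.voxels
    if v.min() < 0:
        raise ValueError("apply_gamma requires non-negative intensities; "
                         "normalize the image to [0, 1] first")
    return image.with_voxels(v ** np.exp(log_gamma))


# --------------------------------------------------------------------------
# Motion
# --------------------------------------------------------------------------

@dataclass
class MotionParams:
    """Peak amplitudes of the simulated movement."""

    max_translation_mm: float
    max_rotation_deg: float


def sample_motion_params(rng: np.random.Generator,
                         amplitude_range=MOTION_AMPLITUDE_RANGE
                         ) -> MotionParams:
    return MotionParams(
        max_translation_mm=float(rng.uniform(*amplitude_range)),
        max_rotation_deg=float(rng.uniform(*amplitude_range)),
    )


@dataclass
class MotionTrajectory:
    """Time-ordered rigid transforms, one per k-space segment."""

    translations_mm: np.ndarray  # (n_segments, 3)
    rotations_deg: np.ndarray    # (n_segments, 3)
    event_segment: int | None = None
    ramp_segments: int | None = None

    def __post_init__(self):
        self.translations_mm = np.atleast_2d(
            np.asarray(self.translations_mm, float))
        self.rotations_deg = np.atleast_2d(
            np.asarray(self.rotations_deg, float))
        if self.translations_mm.shape != self.rotations_deg.shape:
            raise ValueError("translation/rotation arrays must match")
        if self.translations_mm.shape[1] != 3:
            raise ValueError("each transform needs 3 translations and "
                             "3 rotations")

    @property
    def n_segments(self) -> int:
        return self.translations_mm.shape[0]

    @classmethod
    def identity(cls, n_segments: int) -> "MotionTrajectory":
        return cls(np.zeros((n_segments, 3)), np.zeros((n_segments, 3)))

    @classmethod
    def constant(cls, n_segments: int, translation_mm=(0, 0, 0),
                 rotation_deg=(0, 0, 0)) -> "MotionTrajectory":
        return cls(np.tile(np.asarray(translation_mm, float), (n_segments, 1)),
                   np.tile(np.asarray(rotation_deg, float), (n_segments, 1)))

    def peak_translation(self) -> float:
        return float(np.linalg.norm(self.translations_mm, axis=1).max())

    def peak_rotation(self) -> float:
        return float(np.linalg.norm(self.rotations_deg, axis=1).max())


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
        if n > 1e-12:
            return v / n


def sample_trajectory(params: MotionParams, n_segments: int,
                      rng: np.random.Generator) -> MotionTrajectory:
    """Single-event step trajectory.

    Identity pose until a uniformly drawn event segment, a linear ramp over a
    small random window, then a plateau at the peak transform. The plateau
    translation norm equals ``max_translation_mm`` and the rotation norm
    ``max_rotation_deg`` exactly; directions are uniform on the sphere. The
    ramp is truncated so the peak is always reached within the acquisition.
    """
    if n_segments < 2:
        raise ValueError("motion simulation needs at least 2 k-space segments")
    event = int(rng.integers(0, n_segments))
    max_ramp = max(2, n_segments // 8)
    ramp = int(rng.integers(1, max_ramp + 1))
    ramp = min(ramp, n_segments - event)
    t_dir = _random_unit_vector(rng)
    r_dir = _random_unit_vector(rng)
    alpha = np.clip((np.arange(n_segments) - event + 1) / ramp, 0.0, 1.0)
    trans = alpha[:, None] * (params.max_translation_mm * t_dir)
    rot = alpha[:, None] * (params.max_rotation_deg * r_dir)
    return MotionTrajectory(trans, rot, event_segment=event,
                            ramp_segments=ramp)


def _segment_lines(n_lines: int, n_segments: int, line_order: str
                   ) -> list[np.ndarray]:
    if not 1 <= n_segments <= n_lines:
        raise ValueError(
            f"trajectory length {n_segments} does not match the number of "
            f"k-space segments available ({n_lines} phase-encode lines)")
    if line_order == "linear":
        order = np.arange(n_lines)
    elif line_order == "centric":
        centre = (n_lines - 1) / 2.0
        order = np.argsort(np.abs(np.arange(n_lines) - centre),
                           kind="stable")
    else:
        raise ValueError(f"unknown line order {line_order!r}")
    return np.array_split(order, n_segments)


def _rotate_volume(arr: np.ndarray, rotation_deg: np.ndarray,
                   voxel_size) -> np.ndarray:
    from .spatial import _rotation_matrix  # shared rotation convention
    vs = np.asarray(voxel_size, float)
    centre = (np.asarray(arr.shape) - 1) / 2.0
    inv = np.linalg.inv(_rotation_matrix(rotation_deg))
    M = np.diag(1.0 / vs) @ inv @ np.diag(vs)
    offset = centre - M @ centre
    return ndimage.affine_transform(arr, M, offset=offset, order=1,
                                    mode="constant", cval=0.0,
                                    prefilter=False)


def apply_motion(image: Image, traj: MotionTrajectory,
                 segment_axis: int = 1, line_order: str = "linear",
                 background_mask: np.ndarray | None = None,
                 return_complex: bool = False) -> Image:
    """Corrupt an image with rigid motion during a line-by-line acquisition.

    Phase-encode lines along ``segment_axis`` are partitioned (in
    ``line_order`` acquisition order) into ``traj.n_segments`` contiguous
    chunks. For every segment, the object is rigidly transformed to that
    segment's pose -- rotation by linear resampling in image space,
    translation as an exact linear phase ramp -- and the segment's lines are
    copied from the transformed object's spectrum. The composite k-space is
    inverted and the magnitude returned (complex output via
    ``return_complex``).

    ``background_mask`` voxels are forced to zero beforehand so background
    intensity is not mixed into the object by the acquisition model.
    """
    data = np.asarray(image.voxels, dtype=np.float64)
    if background_mask is not None:
        data = np.where(background_mask, 0.0, data)
    n_lines = data.shape[segment_axis]
    segments = _segment_lines(n_lines, traj.n_segments, line_order)
    vs = np.asarray(image.voxel_size, float)

    freqs = [np.fft.fftfreq(n) for n in data.shape]
    k_out = np.zeros(data.shape, dtype=np.complex128)

    # group segments sharing a pose so each distinct pose costs one FFT
    keys = np.round(np.hstack([traj.translations_mm, traj.rotations_deg]), 9)
    _, inverse = np.unique(keys, axis=0, return_inverse=True)
    for gid in np.unique(inverse):
        seg_ids = np.nonzero(inverse == gid)[0]
        trans = traj.translations_mm[seg_ids[0]]
        rot = traj.rotations_deg[seg_ids[0]]
        obj = data
        if np.any(rot):
            obj = _rotate_volume(data, rot, vs)
        spectrum = np.fft.fftn(obj)
        if np.any(trans):
            shift_vox = trans / vs
            for d in range(3):
                if shift_vox[d]:
                    shp = [1, 1, 1]
                    shp[d] = data.shape[d]
                    ramp = np.exp(-2j * np.pi * freqs[d] * shift_vox[d])
                    spectrum = spectrum * ramp.reshape(shp)
        lines = np.concatenate([segments[s] for s in seg_ids])
        index = [slice(None)] * 3
        index[segment_axis] = lines
        k_out[tuple(index)] = spectrum[tuple(index)]

    out = np.fft.ifftn(k_out)
    if return_complex:
        return out
    return image.with_voxels(np.abs(out))
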