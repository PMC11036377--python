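"""Random-contrast image synthesis from label maps.

The generative model assumes the MR signal is homogeneous within each tissue:
a synthetic image is produced by drawing, per label, a Gaussian intensity
distribution whose mean ~ U[0, 1] and standard deviation ~ U[0.02, 0.1], and
sampling every voxel of that label independently from it. One contrast sample
is drawn per generated volume. A final min-max normalization maps each
generated volume onto [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .core import Image, LabelMap

#: Sampling ranges of the per-tissue Gaussian parameters.
MEAN_RANGE: tuple[float, float] = (0.0, 1.0)
STD_RANGE: tuple[float, float] = (0.02, 0.1)


@dataclass
class ContrastSample:
    """Per-label Gaussian intensity parameters (mean, std)."""

    means: dict[int, float]
    stds: dict[int, float]

    def labels(self) -> set[int]:
        return set(self.means)

    def covers(self, labels: Iterable[int]) -> bool:
        return set(labels) <= self.labels()

    @classmethod
    def from_table(cls, table: Mapping[int, tuple[float, float]]
                   ) -> "ContrastSample":
        return cls({int(k): float(m) for k, (m, _) in table.items()},
                   {int(k): float(s) for k, (_, s) in table.items()})

    def to_config(self) -> dict:
        return {int(k): [float(self.means[k]), float(self.stds[k])]
                for k in sorted(self.means)}

    def save(self, path: str | Path) -> None:
        """Plain-text key-value serialization: ``label mean std`` per line."""
        lines = [f"{k} {self.means[k]!r} {self.stds[k]!r}"
                 for k in sorted(self.means)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ContrastSample":
        means, stds = {}, {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            k, m, s = line.split()
            means[int(k)] = float(m)
            stds[int(k)] = float(s)
        return cls(means, stds)


def sample_contrast(labels: Iterable[int], rng: np.random.Generator,
                    mean_range=MEAN_RANGE, std_range=STD_RANGE
                    ) -> ContrastSample:
    """Draw one (mean, std) pair per label, independently across labels.

    Means are uniform on ``mean_range`` and standard deviations uniform on
    ``std_range``; iteration order is the sorted label id order so a fixed
    seed yields an identical sample.
    """
    labels = sorted(int(l) for l in set(labels))
    if not labels:
        raise ValueError("sample_contrast requires a non-empty label set")
    means = rng.uniform(*mean_range, size=len(labels))
    stds = rng.uniform(*std_range, size=len(labels))
    return ContrastSample(dict(zip(labels, means.tolist())),
                          dict(zip(labels, stds.tolist())))


def render_image(label_map: LabelMap, contrast: ContrastSample,
                 rng: np.random.Generator) -> Image:
    """Render a random-contrast image: each voxel of label ``l`` is an
    independent draw from Normal(mean_l, std_l).

    Negative intensities are kept; the final normalization rescales them.
    """
    present = label_map.present_labels()
    missing = [l for l in present if l not in contrast.means]
    if missing:
        raise ValueError(
            f"contrast sample missing labels {missing}; present={present}")
    max_id = max(contrast.means)
    mean_lut = np.zeros(max_id + 1)
    std_lut = np.zeros(max_id + 1)
    for lid in contrast.means:
        mean_lut[lid] = contrast.means[lid]
        std_lut[lid] = contrast.stds[lid]
    lab = label_map.voxels
    noise = rng.standard_normal(lab.shape)
    voxels = mean_lut[lab] + std_lut[lab] * noise
    return Image(voxels, label_map.voxel_size)


def normalize_intensity(image: Image) -> Image:
    """Affinely rescale so the minimum maps to 0 and the maximum to 1.

    The rescale is strictly monotone, hence idempotent once the range is
    [0, 1]. A constant image has no contrast to preserve: it is mapped to
    all zeros and a warning is emitted.
    """
    v = image.voxels
    if not np.all(np.isfinite(v)):
        raise ValueError("normalize_intensity requires a finite image")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        warnings.warn("constant image: normalization returns all zeros",
                      RuntimeWarning, stacklevel=2)
        return image.with_voxels(np.zeros_like(v))
    return image.with_voxels((v - lo) / (hi - lo))
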