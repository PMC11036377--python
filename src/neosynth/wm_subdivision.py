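"""White-matter intensity subdivision.

During the developmental period the WM is not homogeneous: myelination
produces intra-WM intensity variation that a single-Gaussian generative
tissue cannot reproduce. The remedy is to split the WM label into N
sub-labels by clustering the reference (T2-like) intensities within the WM
mask with a 1D Gaussian-mixture EM; each sub-region then acts as a distinct
tissue in the generative model (its own random contrast) while the
segmentation objective regroups all sub-labels back to a single WM class.

The EM is written out explicitly so its behaviour is fully specified:
quantile-based initialization, responsibilities by log-sum-exp, ties broken
toward the lower-mean component, convergence when the relative
log-likelihood change drops below ``tol`` (the per-iteration trace is kept
and is non-decreasing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .core import Image, LabelMap

MAX_CLUSTERS: int = 6
_VAR_FLOOR = 1e-10


@dataclass
class GaussianMixture1D:
    """Fitted 1D mixture, components sorted by ascending mean."""

    means: np.ndarray
    stds: np.ndarray
    weights: np.ndarray
    log_likelihood_trace: list[float] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.means)

    def _log_resp(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)[:, None]
        log_pdf = (-0.5 * ((x - self.means) / self.stds) ** 2
                   - np.log(self.stds) - 0.5 * np.log(2 * np.pi))
        return np.log(self.weights) + log_pdf

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Maximum-responsibility component per sample; exact ties go to the
        lower-mean component (argmax returns the first maximum and the
        components are mean-sorted)."""
        return np.argmax(self._log_resp(x), axis=1)

    def log_likelihood(self, x: np.ndarray) -> float:
        return float(logsumexp(self._log_resp(x), axis=1).sum())


def fit_gmm_1d(x: np.ndarray, n_components: int, max_iter: int = 200,
               tol: float = 1e-6) -> GaussianMixture1D:
    """EM fit of a 1D Gaussian mixture with deterministic quantile init."""
    x = np.asarray(x, float).ravel()
    if x.size < n_components:
        raise ValueError("fewer samples than mixture components")
    qs = (2 * np.arange(n_components) + 1) / (2 * n_components)
    means = np.quantile(x, qs)
    spread = max(float(x.std()), 1e-6)
    stds = np.full(n_components, spread / n_components + 1e-6)
    weights = np.full(n_components, 1.0 / n_components)
    model = GaussianMixture1D(means, stds, weights)

    prev_ll = -np.inf
    for _ in range(max_iter):
        log_r = model._log_resp(x)
        norm = logsumexp(log_r, axis=1)
        ll = float(norm.sum())
        model.log_likelihood_trace.append(ll)
        r = np.exp(log_r - norm[:, None])
        nk = r.sum(axis=0) + 1e-12
        model.weights = nk / nk.sum()
        model.means = (r * x[:, None]).sum(axis=0) / nk
        var = (r * (x[:, None] - model.means) ** 2).sum(axis=0) / nk
        model.stds = np.sqrt(np.maximum(var, _VAR_FLOOR))
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * max(abs(ll), 1.0):
            break
        prev_ll = ll

    order = np.argsort(model.means, kind="stable")
    model.means = model.means[order]
    model.stds = model.stds[order]
    model.weights = model.weights[order]
    return model


@dataclass
class SubdivisionResult:
    """WM replaced by N intensity sub-labels, plus the grouping that maps
    every generation label to its target class."""

    relabeled: LabelMap
    grouping: dict[int, int]
    n_clusters: int
    mixture: GaussianMixture1D | None = None


def subdivide_wm(label_map: LabelMap, intensity: Image, n_clusters: int,
                 rng: np.random.Generator | None = None) -> SubdivisionResult:
    """Split the WM label into ``n_clusters`` intensity clusters.

    The sub-labels partition the original WM mask exactly; every other voxel
    is untouched (bit-exact). ``rng`` is accepted for interface uniformity;
    the quantile-initialized EM is deterministic. If the WM carries fewer
    distinct intensities than clusters, the cluster count is reduced with a
    warning.
    """
    if not 1 <= n_clusters <= MAX_CLUSTERS:
        raise ValueError(f"n_clusters must be in 1..{MAX_CLUSTERS}")
    wm_id = label_map.id_of("wm")
    wm_mask = label_map.voxels == wm_id
    if not wm_mask.any():
        raise ValueError("label map has no WM voxels")
    if intensity.shape != label_map.shape:
        raise ValueError("intensity grid does not match the label map")

    identity = {int(l): int(l) for l in label_map.palette}
    if n_clusters == 1:
        return SubdivisionResult(label_map.copy(), identity, 1)

    values = intensity.voxels[wm_mask]
    n_distinct = np.unique(values).size
    if n_distinct < n_clusters:
        warnings.warn(
            f"only {n_distinct} distinct WM intensities; reducing "
            f"n_clusters from {n_clusters} to {n_distinct}", RuntimeWarning,
            stacklevel=2)
        n_clusters = int(n_distinct)
        if n_clusters == 1:
            return SubdivisionResult(label_map.copy(), identity, 1)

    mixture = fit_gmm_1d(values, n_clusters)
    assignment = mixture.predict(values)

    base = max(label_map.palette) + 1
    voxels = label_map.voxels.copy()
    voxels[wm_mask] = base + assignment
    palette = {lid: name for lid, name in label_map.palette.items()
               if lid != wm_id}
    grouping = {int(l): int(l) for l in palette}
    for k in range(n_clusters):
        palette[base + k] = f"wm_{k + 1}"
        grouping[base + k] = wm_id
    grouping[wm_id] = wm_id  # harmless if a plain-WM map is regrouped

    relabeled = label_map.with_voxels(voxels, palette)
    return SubdivisionResult(relabeled, grouping, n_clusters, mixture)


def regroup(prediction: LabelMap, grouping: dict[int, int]) -> LabelMap:
    """Collapse generation labels to target classes; idempotent when the
    grouping maps target ids to themselves."""
    present = prediction.present_labels()
    unknown = [l for l in present if l not in grouping]
    if unknown:
        raise ValueError(f"labels {unknown} missing from the grouping")
    max_id = max(max(grouping), max(present))
    lut = np.arange(max_id + 1, dtype=prediction.voxels.dtype)
    for src, dst in grouping.items():
        lut[src] = dst
    palette = {}
    for lid in sorted(set(grouping.values())):
        palette[int(lid)] = _target_name(prediction, grouping, int(lid))
    return prediction.with_voxels(lut[prediction.voxels], palette)


def _target_name(prediction: LabelMap, grouping: dict[int, int],
                 target_id: int) -> str:
    if target_id in prediction.palette:
        name = prediction.palette[target_id]
        if not name.startswith("wm_"):
            return name
    from .core import PALETTE
    return PALETTE.get(target_id, f"class_{target_id}")
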