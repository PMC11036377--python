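"""Patch sampling, dice-loss training and full-volume inference.

Training follows the reference protocol at configurable scale: from every
generated volume a fixed number of patches is drawn with a structure-
balanced sampler (first a target structure uniform among those present,
then a centre voxel uniform within that structure), batches are optimized
with Adam on the average soft-dice loss, and inference runs on the entire
volume (padded to the pooling factor) with dropout off.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .core import Image, LabelMap, PALETTE
from .unet import UNet3d, UNetConfig, build_unet


@dataclass
class TrainConfig:
    patch_size: int = 128
    patches_per_volume: int = 8
    batch_size: int = 4
    learning_rate: float = 1e-4
    max_iterations: int = 100
    seed: int = 0
    #: size of the shuffle pool (in patches) from which batches are drawn;
    #: mixing patches of several generated volumes (hence several contrast
    #: draws) in one batch stabilizes randomized-contrast training. 0
    #: disables shuffling (strictly sequential consumption).
    shuffle_pool: int = 64
    #: "constant" or "cosine" (5% linear warmup then cosine decay to 0);
    #: cosine speeds up convergence of short desk-scale runs.
    lr_schedule: str = "constant"

    def learning_rate_at(self, iteration: int) -> float:
        if self.lr_schedule == "constant":
            return self.learning_rate
        if self.lr_schedule != "cosine":
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")
        warmup = max(1, int(0.05 * self.max_iterations))
        if iteration < warmup:
            return self.learning_rate * (iteration + 1) / warmup
        frac = (iteration - warmup) / max(1, self.max_iterations - warmup)
        return self.learning_rate * 0.5 * (1 + np.cos(np.pi * frac))


def _crop_with_padding(arr: np.ndarray, centre, size: int, fill):
    """Crop a cube of side ``size`` around ``centre``; outside-of-field
    voxels are filled (background label / zero intensity)."""
    out = np.full((size,) * 3, fill, dtype=arr.dtype)
    starts = [int(c) - size // 2 for c in centre]
    src, dst = [], []
    for d in range(3):
        s0 = max(starts[d], 0)
        s1 = min(starts[d] + size, arr.shape[d])
        if s1 <= s0:
            return out
        src.append(slice(s0, s1))
        dst.append(slice(s0 - starts[d], s1 - starts[d]))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def sample_patches(label_map: LabelMap, image: Image, cfg: TrainConfig,
                   rng: np.random.Generator,
                   background_label: int = 0) -> list[tuple[np.ndarray,
                                                            np.ndarray]]:
    """Structure-balanced patch sampling.

    For each of ``cfg.patches_per_volume`` patches a structure is drawn
    uniformly from those present in the volume, then a centre voxel uniform
    within that structure; the image/label patch pair is cropped around it
    with background padding at the borders, so every patch contains at
    least one voxel of its drawn structure.

    The centre voxel is drawn by inverse-CDF over the structure's voxel
    list (lexicographic order): one uniform variate indexes the list, so
    paired trainings that share a seed but differ slightly in a
    structure's extent (e.g. two ground-truth variants of the same
    anatomy) sample patches at matched locations — the common-random-
    numbers coupling that controlled model comparisons rely on.
    """
    if image.shape != label_map.shape:
        raise ValueError("image and label map grids differ")
    size = cfg.patch_size
    if size > min(label_map.shape):
        warnings.warn(
            f"patch_size {size} exceeds the volume extent "
            f"{label_map.shape}; using the full volume", RuntimeWarning,
            stacklevel=2)
        size = min(label_map.shape)

    structures = label_map.present_labels()
    coords = {s: np.argwhere(label_map.voxels == s) for s in structures}
    patches = []
    for _ in range(cfg.patches_per_volume):
        s = structures[int(rng.integers(len(structures)))]
        pts = coords[s]
        centre = pts[int(rng.random() * len(pts))]
        img_patch = _crop_with_padding(image.voxels, centre, size, 0.0)
        lab_patch = _crop_with_padding(label_map.voxels, centre, size,
                                       background_label)
        patches.append((img_patch, lab_patch))
    return patches


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """(B, X, Y, Z) integer labels -> (B, C, X, Y, Z) one-hot float."""
    labels = np.asarray(labels)
    if labels.ndim == 3:
        labels = labels[None]
    out = np.zeros((labels.shape[0], n_classes) + labels.shape[1:],
                   dtype=nn.DTYPE)
    for c in range(n_classes):
        out[:, c] = labels == c
    return out


def dice_loss(soft_prediction: np.ndarray, one_hot_target: np.ndarray
              ) -> float:
    """Average soft-dice loss (see :func:`neosynth.nn.soft_dice_loss`)."""
    return nn.soft_dice_loss(soft_prediction, one_hot_target)


@dataclass
class TrainResult:
    network: UNet3d
    loss_trace: list[float]
    config: TrainConfig
    unet_config: UNetConfig


def train(sample_generator, unet_cfg: UNetConfig, train_cfg: TrainConfig,
          checkpoint_path: str | Path | None = None,
          log_every: int = 0) -> TrainResult:
    """Train a UNet on a stream of generated volumes.

    ``sample_generator`` is a callable ``(rng) -> (Image, LabelMap)``
    producing one training volume per call (typically a recipe closure over
    a subject cohort). Patches are buffered and consumed in batches; the
    per-iteration loss trace is recorded; a non-finite loss aborts with a
    diagnostic. Fully seeded through ``train_cfg.seed``.
    """
    rng = np.random.default_rng(train_cfg.seed)
    net = build_unet(unet_cfg, rng)
    opt = nn.Adam(net.params(), lr=train_cfg.learning_rate)
    n_classes = unet_cfg.n_classes

    pool_size = max(train_cfg.shuffle_pool, train_cfg.batch_size)
    buffer: list[tuple[np.ndarray, np.ndarray]] = []
    trace: list[float] = []
    for it in range(train_cfg.max_iterations):
        while len(buffer) < pool_size:
            image, labels = sample_generator(rng)
            buffer.extend(sample_patches(labels, image, train_cfg, rng))
        if train_cfg.shuffle_pool:
            picks = rng.choice(len(buffer), size=train_cfg.batch_size,
                               replace=False)
            batch = [buffer[i] for i in picks]
            for i in sorted(picks, reverse=True):
                buffer.pop(i)
        else:
            batch = [buffer.pop(0) for _ in range(train_cfg.batch_size)]
        x = np.stack([b[0] for b in batch])[:, None]
        y = one_hot(np.stack([b[1] for b in batch]), n_classes)
        probs = net.forward(x, train=True)
        loss, dprobs = nn.soft_dice_loss(probs, y, return_grad=True)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged at iteration {it}: loss={loss!r}")
        trace.append(loss)
        opt.zero_grad()
        net.backward(dprobs)
        opt.lr = train_cfg.learning_rate_at(it)
        opt.step()
        if log_every and (it + 1) % log_every == 0:
            print(f"iter {it + 1:5d}  dice loss {loss:.4f}")

    result = TrainResult(net, trace, train_cfg, unet_cfg)
    if checkpoint_path is not None:
        save_checkpoint(result, checkpoint_path)
    return result


def save_checkpoint(result: TrainResult, path: str | Path) -> None:
    """Checkpoint with the full configuration embedded (npz + json)."""
    net = result.network
    arrays = {f"param_{i}": p.value for i, p in enumerate(net.params())}
    idx = 0
    for layer in _iter_layers(net):
        if isinstance(layer, nn.BatchNorm3d):
            arrays[f"bn_mean_{idx}"] = layer.running_mean
            arrays[f"bn_var_{idx}"] = layer.running_var
            idx += 1
    meta = {"unet_config": asdict(result.unet_config),
            "train_config": asdict(result.config),
            "loss_trace": result.loss_trace}
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path) -> TrainResult:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    ucfg_d = dict(meta["unet_config"])
    ucfg_d["kernel"] = tuple(ucfg_d["kernel"])
    unet_cfg = UNetConfig(**ucfg_d)
    train_cfg = TrainConfig(**meta["train_config"])
    net = build_unet(unet_cfg, np.random.default_rng(train_cfg.seed))
    for i, p in enumerate(net.params()):
        p.value[...] = data[f"param_{i}"]
    idx = 0
    for layer in _iter_layers(net):
        if isinstance(layer, nn.BatchNorm3d):
            layer.running_mean = data[f"bn_mean_{idx}"]
            layer.running_var = data[f"bn_var_{idx}"]
            idx += 1
    return TrainResult(net, list(meta["loss_trace"]), train_cfg, unet_cfg)


def _iter_layers(net: UNet3d):
    yield from net.iter_layers()


def predict_full_volume(network: UNet3d, image: Image,
                        palette=None) -> LabelMap:
    """Segment an entire volume at native resolution.

    The volume is zero-padded to the next pooling-compatible shape, passed
    through the network in evaluation mode (dropout off, batch-norm running
    statistics), argmaxed over the class axis and cropped back.
    """
    pf = network.config.pool_factor
    shape = image.shape
    padded = [int(np.ceil(n / pf) * pf) for n in shape]
    pad = [(0, p - n) for p, n in zip(padded, shape)]
    x = np.pad(image.voxels, pad)[None, None]
    probs = network.forward(x, train=False)
    labels = probs[0].argmax(axis=0).astype(np.int16)
    labels = labels[:shape[0], :shape[1], :shape[2]]
    if palette is None:
        palette = {c: PALETTE.get(c, f"class_{c}")
                   for c in range(network.config.n_classes)}
    return LabelMap(labels, image.voxel_size, palette)
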