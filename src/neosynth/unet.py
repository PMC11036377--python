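"""3D UNet: configuration, construction, parameter counting.

The reference architecture has five resolution levels separated by 2x max
pooling (encoder) and 2x upsampling (decoder); every level stacks three
3x3x3 convolutions, each followed by batch normalization, ReLU and 10%
dropout; feature maps start at 24 and double after each pooling / halve
after each upsampling; skip connections concatenate encoder features into
the decoder; the classifier is a final 1x1x1 convolution followed only by a
softmax. Residual shortcuts run inside each level's convolution stack.

Two conventions are left open by that description and are exposed as
config toggles, because they change the trainable parameter count:

* ``upsample``: ``"interp"`` (nearest-neighbour upsampling + 1x1x1
  convolution halving the features, decoder block input 2f) or
  ``"transposed"`` (2x2x2 stride-2 transposed convolution preserving the
  feature count, decoder block input 3f).
* ``residual_mode`` / ``decoder_residual_mode``: ``"none"``, ``"tail"``
  (identity shortcut spanning the channel-constant tail of the stack, i.e.
  after the first, channel-setting convolution) or ``"full"`` (shortcut
  spanning the whole stack, with a 1x1x1 projection when channels differ).

``reference_config`` pins the convention whose trainable parameter count
reproduces the published 21.6 million figure: transposed-conv upsampling
with tail residuals in the encoder and full (projected) residuals in the
decoder — 21,585,418 parameters at 10 classes. ``convention_sweep``
enumerates the candidate conventions with their counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from . import nn

VALID_RESIDUAL_MODES = ("none", "tail", "full")
VALID_UPSAMPLE = ("interp", "transposed")


@dataclass
class UNetConfig:
    levels: int = 5
    convs_per_level: int = 3
    kernel: tuple[int, int, int] = (3, 3, 3)
    base_features: int = 24
    dropout: float = 0.1
    n_classes: int = 10
    residual_skips: bool = True
    residual_mode: str = "tail"
    decoder_residual_mode: str | None = None
    upsample: str = "interp"
    #: normalization statistics at inference: "instance" recomputes batch
    #: statistics from the input volume itself (contrast-agnostic, matches
    #: the single-volume batches seen in training); "running" uses the
    #: averaged training statistics.
    eval_norm: str = "instance"

    def __post_init__(self):
        if self.levels < 1 or self.convs_per_level < 1:
            raise ValueError("levels and convs_per_level must be >= 1")
        if tuple(self.kernel) != (3, 3, 3):
            raise ValueError("only 3x3x3 convolution kernels are supported")
        if self.residual_mode not in VALID_RESIDUAL_MODES:
            raise ValueError(f"residual_mode must be one of "
                             f"{VALID_RESIDUAL_MODES}")
        if (self.decoder_residual_mode is not None
                and self.decoder_residual_mode not in VALID_RESIDUAL_MODES):
            raise ValueError("bad decoder_residual_mode")
        if self.upsample not in VALID_UPSAMPLE:
            raise ValueError(f"upsample must be one of {VALID_UPSAMPLE}")
        if self.eval_norm not in ("instance", "running"):
            raise ValueError("eval_norm must be 'instance' or 'running'")
        if not self.residual_skips:
            self.residual_mode = "none"
            self.decoder_residual_mode = "none"

    @property
    def effective_decoder_residual(self) -> str:
        return (self.decoder_residual_mode
                if self.decoder_residual_mode is not None
                else self.residual_mode)

    @property
    def pool_factor(self) -> int:
        return 2 ** (self.levels - 1)

    def features(self) -> list[int]:
        return [self.base_features * 2 ** i for i in range(self.levels)]


def reference_config(n_classes: int = 10) -> UNetConfig:
    """The convention that reproduces the published parameter count."""
    return UNetConfig(n_classes=n_classes, upsample="transposed",
                      residual_mode="tail", decoder_residual_mode="full")


def toy_config(levels: int = 2, convs_per_level: int = 1,
               base_features: int = 4, n_classes: int = 2,
               dropout: float = 0.0) -> UNetConfig:
    """A desk-scale configuration for tests and examples."""
    return UNetConfig(levels=levels, convs_per_level=convs_per_level,
                      base_features=base_features, n_classes=n_classes,
                      dropout=dropout)


class _ConvBlock:
    """``n`` conv(+BN+ReLU+dropout) units with an optional residual
    shortcut added after the stack."""

    def __init__(self, in_ch, out_ch, n_convs, dropout, residual_mode, rng,
                 name):
        self.residual_mode = residual_mode
        self.units: list[list[nn.Layer]] = []
        c = in_ch
        for i in range(n_convs):
            unit: list[nn.Layer] = [nn.Conv3d(c, out_ch, 3, rng,
                                              f"{name}.conv{i}")]
            unit.append(nn.BatchNorm3d(out_ch, name=f"{name}.bn{i}"))
            unit.append(nn.ReLU())
            if dropout > 0:
                unit.append(nn.Dropout(dropout, rng))
            self.units.append(unit)
            c = out_ch
        self.projection = None
        if residual_mode == "full" and in_ch != out_ch:
            self.projection = nn.Conv3d(in_ch, out_ch, 1, rng,
                                        f"{name}.proj")

    def params(self):
        ps = [p for unit in self.units for layer in unit
              for p in layer.params()]
        if self.projection is not None:
            ps += self.projection.params()
        return ps

    def forward(self, x, train):
        if self.residual_mode == "none" or len(self.units) == 1 and \
                self.residual_mode == "tail":
            h = x
            for unit in self.units:
                for layer in unit:
                    h = layer.forward(h, train)
            self._mode_used = "none"
            return h
        if self.residual_mode == "tail":
            h = x
            for layer in self.units[0]:
                h = layer.forward(h, train)
            shortcut = h
            for unit in self.units[1:]:
                for layer in unit:
                    h = layer.forward(h, train)
            self._mode_used = "tail"
            return h + shortcut
        # full
        h = x
        for unit in self.units:
            for layer in unit:
                h = layer.forward(h, train)
        s = x if self.projection is None else \
            self.projection.forward(x, train)
        self._mode_used = "full"
        return h + s

    def backward(self, grad):
        if self._mode_used == "none":
            g = grad
            for unit in reversed(self.units):
                for layer in reversed(unit):
                    g = layer.backward(g)
            return g
        if self._mode_used == "tail":
            g = grad
            for unit in reversed(self.units[1:]):
                for layer in reversed(unit):
                    g = layer.backward(g)
            g = g + grad  # shortcut
            for layer in reversed(self.units[0]):
                g = layer.backward(g)
            return g
        # full
        g = grad
        for unit in reversed(self.units):
            for layer in reversed(unit):
                g = layer.backward(g)
        if self.projection is not None:
            g = g + self.projection.backward(grad)
        else:
            g = g + grad
        return g


class UNet3d:
    """Fully-convolutional 3D UNet mapping (B, 1, X, Y, Z) to per-voxel
    class probabilities (B, n_classes, X, Y, Z); X, Y, Z must be divisible
    by ``config.pool_factor``."""

    def __init__(self, config: UNetConfig, rng: np.random.Generator | None
                 = None):
        self.config = config
        rng = rng if rng is not None else np.random.default_rng(0)
        feats = config.features()
        enc_res = config.residual_mode
        dec_res = config.effective_decoder_residual

        self.enc_blocks = []
        cin = 1
        for li, f in enumerate(feats):
            self.enc_blocks.append(_ConvBlock(
                cin, f, config.convs_per_level, config.dropout, enc_res,
                rng, f"enc{li}"))
            cin = f
        self.pools = [nn.MaxPool3d() for _ in range(config.levels - 1)]

        self.up_ops = []
        self.dec_blocks = []
        for li in range(config.levels - 2, -1, -1):
            f = feats[li]
            if config.upsample == "interp":
                self.up_ops.append((nn.Upsample3d(),
                                    nn.Conv3d(cin, f, 1, rng, f"up{li}")))
                block_in = 2 * f
            else:
                self.up_ops.append((nn.ConvTranspose3d(cin, cin, rng,
                                                       f"upT{li}"), None))
                block_in = cin + f
            self.dec_blocks.append(_ConvBlock(
                block_in, f, config.convs_per_level, config.dropout,
                dec_res, rng, f"dec{li}"))
            cin = f
        self.classifier = nn.Conv3d(cin, config.n_classes, 1, rng, "cls")
        self._probs = None
        if config.eval_norm == "instance":
            for layer in self.iter_layers():
                if isinstance(layer, nn.BatchNorm3d):
                    layer.force_batch_stats = True

    def iter_layers(self):
        for block in self.enc_blocks + self.dec_blocks:
            for unit in block.units:
                yield from unit
            if block.projection is not None:
                yield block.projection
        for up, conv in self.up_ops:
            yield up
            if conv is not None:
                yield conv
        yield self.classifier

    # ------------------------------------------------------------------
    def params(self) -> list[nn.Param]:
        ps = []
        for b in self.enc_blocks:
            ps += b.params()
        for up, conv in self.up_ops:
            ps += up.params()
            if conv is not None:
                ps += conv.params()
        for b in self.dec_blocks:
            ps += b.params()
        ps += self.classifier.params()
        return ps

    def check_input_shape(self, spatial_shape) -> None:
        pf = self.config.pool_factor
        bad = [n for n in spatial_shape if n % pf]
        if bad:
            need = [int(np.ceil(n / pf) * pf) - n for n in spatial_shape]
            raise ValueError(
                f"input spatial shape {tuple(spatial_shape)} is not "
                f"divisible by the pooling factor {pf}; pad by {need} "
                "voxels (or use predict_full_volume, which pads for you)")

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 5 or x.shape[1] != 1:
            raise ValueError("input must be shaped (batch, 1, X, Y, Z)")
        self.check_input_shape(x.shape[2:])
        skips = []
        h = x
        for li, block in enumerate(self.enc_blocks):
            h = block.forward(h, train)
            if li < len(self.pools):
                skips.append(h)
                h = self.pools[li].forward(h, train)
        self._skip_channels = [s.shape[1] for s in skips]
        for (up, conv), block, skip in zip(self.up_ops, self.dec_blocks,
                                           reversed(skips)):
            h = up.forward(h, train)
            if conv is not None:
                h = conv.forward(h, train)
            h = np.concatenate([h, skip], axis=1)
            h = block.forward(h, train)
        z = self.classifier.forward(h, train)
        self._probs = nn.softmax_channels(z)
        return self._probs

    def backward(self, dprobs: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the output probabilities."""
        g = nn.softmax_backward(self._probs, dprobs)
        g = self.classifier.backward(g)
        skip_grads = []
        for idx in range(len(self.dec_blocks) - 1, -1, -1):
            up, conv = self.up_ops[idx]
            g = self.dec_blocks[idx].backward(g)
            n_up = g.shape[1] - self._skip_channels[
                len(self.enc_blocks) - 2 - idx]
            g_up, g_skip = g[:, :n_up], g[:, n_up:]
            skip_grads.append(g_skip)
            if conv is not None:
                g_up = conv.backward(g_up)
            g = up.backward(g_up)
        # skip_grads[j] carries the gradient entering encoder level j
        for li in range(len(self.enc_blocks) - 1, -1, -1):
            if li < len(self.pools):
                g = self.pools[li].backward(g)
                g = g + skip_grads[li]
            g = self.enc_blocks[li].backward(g)

    def zero_grad(self):
        for p in self.params():
            p.zero_grad()


def build_unet(config: UNetConfig,
               rng: np.random.Generator | None = None) -> UNet3d:
    return UNet3d(config, rng)


def count_parameters(network, only_trainable: bool = True) -> int:
    """Exact count of (trainable) scalar parameters."""
    params = network.params() if hasattr(network, "params") else network
    return int(sum(p.size for p in params
                   if p.trainable or not only_trainable))


def count_parameters_config(config: UNetConfig) -> int:
    """Closed-form parameter count for a configuration (no allocation)."""

    def conv(cin, cout, k=3):
        return k ** 3 * cin * cout + cout

    def block(cin, cout, n, mode):
        t = 0
        c = cin
        for _ in range(n):
            t += conv(c, cout, 3) + 2 * cout  # conv + BN affine pair
            c = cout
        if mode == "full" and cin != cout:
            t += conv(cin, cout, 1)
        return t

    feats = config.features()
    enc_res = config.residual_mode
    dec_res = config.effective_decoder_residual
    total, cin = 0, 1
    for f in feats:
        total += block(cin, f, config.convs_per_level, enc_res)
        cin = f
    for f in reversed(feats[:-1]):
        if config.upsample == "interp":
            total += conv(cin, f, 1)
            bin_ = 2 * f
        else:
            total += 2 ** 3 * cin * cin + cin
            bin_ = cin + f
        total += block(bin_, f, config.convs_per_level, dec_res)
        cin = f
    total += conv(cin, config.n_classes, 1)
    return total


def convention_sweep(n_classes_options=(9, 10, 19)) -> list[dict]:
    """Enumerate the documented convention variants with their counts."""
    rows = []
    for ncls, up, enc, dec in product(
            n_classes_options, VALID_UPSAMPLE,
            ("none", "tail", "full"), ("none", "tail", "full")):
        cfg = UNetConfig(n_classes=ncls, upsample=up, residual_mode=enc,
                         decoder_residual_mode=dec)
        rows.append({
            "n_classes": ncls, "upsample": up, "encoder_residual": enc,
            "decoder_residual": dec,
            "parameters": count_parameters_config(cfg),
            "config": cfg,
        })
    return rows


def select_reference_convention(target_millions: float = 21.6,
                                tolerance: float = 0.05) -> dict:
    """Pick the swept convention matching the published count."""
    rows = convention_sweep()
    best = min(rows, key=lambda r: abs(r["parameters"] / 1e6
                                       - target_millions))
    if abs(best["parameters"] / 1e6 - target_millions) > tolerance:
        raise RuntimeError(
            "no documented convention matches the published parameter "
            f"count within {tolerance} M; closest is {best}")
    return best
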