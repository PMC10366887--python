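"""2D U-net denoisers built from the NumPy layer framework.

Two variants are used:

* ``UnetwFBP`` style — residual connection from input to output, trained
  with plain MSE in the reconstruction domain;
* ``UnetU`` style — no residual, Tanhshrink output activation, operating
  in the normalized high-pass singular-vector domain.

Architecture (canonical encoder-decoder): ``levels`` resolution levels
with two 3x3 conv + batch-norm + ReLU blocks per level, 2x2 max-pool
downsampling, 2x2 transposed-conv upsampling, skip concatenation between
matching levels, and a final 1x1 projection to the output channels.
Filter count doubles per level from ``base_filters``.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .containers import SpectralVolume
from . import nn

__all__ = ["NetConfig", "UNet2D", "build_unet", "predict_volume", "predict_slices"]


@dataclass
class NetConfig:
    levels: int = 4
    convs_per_level: int = 2
    in_channels: int = 4
    out_channels: int = 4
    base_filters: int = 64
    residual: bool = False
    output_activation: str = "identity"  # "identity" | "tanhshrink"
    batch_norm: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if min(self.in_channels, self.out_channels, self.base_filters) < 1:
            raise ValueError("channel counts must be >= 1")
        if self.output_activation not in ("identity", "tanhshrink"):
            raise ValueError(f"unknown output activation {self.output_activation!r}")

    @property
    def min_divisor(self) -> int:
        """Input spatial size must be divisible by this power of two."""
        return 2 ** (self.levels - 1)

    def n_parameters(self) -> int:
        """Analytic parameter count (convs + 1x1 head + batch norms)."""
        total = 0
        cin = self.in_channels
        widths = [self.base_filters * 2**i for i in range(self.levels)]
        enc_out = []
        for w in widths:
            for _ in range(self.convs_per_level):
                total += 9 * cin * w + w  # conv
                if self.batch_norm:
                    total += 2 * w
                cin = w
            enc_out.append(cin)
        for i in range(self.levels - 2, -1, -1):
            w = widths[i]
            total += 4 * cin * w + w  # transposed conv
            cin = w + enc_out[i]
            for _ in range(self.convs_per_level):
                total += 9 * cin * w + w
                if self.batch_norm:
                    total += 2 * w
                cin = w
        total += cin * self.out_channels + self.out_channels  # 1x1 head
        return total


class _ConvBlock:
    """conv -> (BN) -> ReLU, repeated."""

    def __init__(self, cin, cout, n, batch_norm, rng):
        self.layers = []
        for _ in range(n):
            self.layers.append(nn.Conv2d(cin, cout, 3, rng))
            if batch_norm:
                self.layers.append(nn.BatchNorm2d(cout))
            self.layers.append(nn.ReLU())
            cin = cout

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class UNet2D:
    """Encoder-decoder network over (B, C, H, W) float32 tensors."""

    def __init__(self, cfg: NetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        widths = [cfg.base_filters * 2**i for i in range(cfg.levels)]
        self.enc = []
        self.pools = []
        cin = cfg.in_channels
        for i, w in enumerate(widths):
            self.enc.append(_ConvBlock(cin, w, cfg.convs_per_level, cfg.batch_norm, rng))
            cin = w
            if i < cfg.levels - 1:
                self.pools.append(nn.MaxPool2d())
        self.ups = []
        self.dec = []
        for i in range(cfg.levels - 2, -1, -1):
            w = widths[i]
            self.ups.append(nn.ConvTranspose2d(cin, w, rng))
            self.dec.append(
                _ConvBlock(w + widths[i], w, cfg.convs_per_level, cfg.batch_norm, rng)
            )
            cin = w
        self.head = nn.Conv2d(cin, cfg.out_channels, 1, rng)
        if cfg.residual:
            # start exactly at the identity map; with the residual path the
            # network then learns a correction from zero, which converges far
            # faster than washing out a random initial output
            self.head.w[...] = 0.0
        self.out_act = nn.Tanhshrink() if cfg.output_activation == "tanhshrink" else None

    # ---- parameter plumbing -------------------------------------------------
    def _layers(self):
        for block in self.enc:
            yield from block.layers
        yield from self.pools
        for up, block in zip(self.ups, self.dec):
            yield up
            yield from block.layers
        yield self.head
        if self.out_act is not None:
            yield self.out_act

    @property
    def params(self):
        return [p for layer in self._layers() for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self._layers() for g in layer.grads]

    def zero_grad(self):
        for layer in self._layers():
            layer.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)

    def state_dict(self) -> dict:
        state = {"params": [p.copy() for p in self.params], "bn": []}
        for layer in self._layers():
            if isinstance(layer, nn.BatchNorm2d):
                state["bn"].append(
                    (layer.running_mean.copy(), layer.running_var.copy())
                )
        return state

    def load_state_dict(self, state: dict) -> None:
        for p, saved in zip(self.params, state["params"]):
            p[...] = saved
        bn = iter(state["bn"])
        for layer in self._layers():
            if isinstance(layer, nn.BatchNorm2d):
                mean, var = next(bn)
                layer.running_mean[...] = mean
                layer.running_var[...] = var

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as f:
            pickle.dump({"config": asdict(self.cfg), "state": self.state_dict()}, f)

    @classmethod
    def load(cls, path: str | Path) -> "UNet2D":
        with open(path, "rb") as f:
            blob = pickle.load(f)
        net = cls(NetConfig(**blob["config"]))
        net.load_state_dict(blob["state"])
        return net

    # ---- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Input and output are channels-first (B, C, H, W); the layers
        themselves run channels-last for speed."""
        cfg = self.cfg
        if x.shape[1] != cfg.in_channels:
            raise ValueError(
                f"network expects {cfg.in_channels} channels, got {x.shape[1]}"
            )
        if x.shape[2] % cfg.min_divisor or x.shape[3] % cfg.min_divisor:
            raise ValueError(
                f"spatial size {x.shape[2:]} not divisible by {cfg.min_divisor}"
            )
        self._skips = []
        h = np.ascontiguousarray(x.transpose(0, 2, 3, 1), dtype=np.float32)
        x_in = h
        for i, block in enumerate(self.enc):
            h = block.forward(h, train)
            if i < cfg.levels - 1:
                self._skips.append(h)
                h = self.pools[i].forward(h, train)
        self._concat_channels = []
        for up, block, skip in zip(self.ups, self.dec, reversed(self._skips)):
            h = up.forward(h, train)
            self._concat_channels.append(skip.shape[-1])
            h = block.forward(np.concatenate([skip, h], axis=-1), train)
        h = self.head.forward(h, train)
        if self.out_act is not None:
            h = self.out_act.forward(h, train)
        if cfg.residual:
            h = h + x_in
        return np.ascontiguousarray(h.transpose(0, 3, 1, 2))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        """Gradients are channels-first at the boundary, like `forward`."""
        cfg = self.cfg
        g = np.ascontiguousarray(gout.transpose(0, 2, 3, 1))
        g_residual = g if cfg.residual else None
        if self.out_act is not None:
            g = self.out_act.backward(g)
        g = self.head.backward(g)
        # decoder runs levels L-2..0 top-down in self.ups/self.dec order, so
        # backward walks them in reverse; skip_grads[i] ends up holding the
        # gradient flowing into the level-i skip connection
        skip_grads = [None] * (cfg.levels - 1)
        for j in range(len(self.ups) - 1, -1, -1):
            level = cfg.levels - 2 - j
            g = self.dec[j].backward(g)
            csk = self._concat_channels[j]
            skip_grads[level] = g[..., :csk]
            g = self.ups[j].backward(np.ascontiguousarray(g[..., csk:]))
        g = self.enc[cfg.levels - 1].backward(g)
        for i in range(cfg.levels - 2, -1, -1):
            g = self.pools[i].backward(g)
            g = g + skip_grads[i]
            g = self.enc[i].backward(g)
        if cfg.residual and g_residual is not None:
            g = g + g_residual
        return np.ascontiguousarray(g.transpose(0, 3, 1, 2))


def build_unet(cfg: NetConfig) -> UNet2D:
    return UNet2D(cfg)


def _pad_to_divisor(x: np.ndarray, d: int):
    h, w = x.shape[-2:]
    ph, pw = (-h) % d, (-w) % d
    if ph == 0 and pw == 0:
        return x, (0, 0, 0, 0)
    pads = (ph // 2, ph - ph // 2, pw // 2, pw - pw // 2)
    x = np.pad(x, ((0, 0), (0, 0), (pads[0], pads[1]), (pads[2], pads[3])))
    return x, pads


def predict_slices(net: UNet2D, stack: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Deterministic (eval-mode) slice-wise inference on a (C, Z, H, W) stack.

    Inputs whose in-plane size is not divisible by the network's required
    power of two are symmetrically zero-padded, then cropped back.
    """
    c, z, h, w = stack.shape
    x = stack.transpose(1, 0, 2, 3).astype(np.float32)  # (Z, C, H, W)
    x, pads = _pad_to_divisor(x, net.cfg.min_divisor)
    outs = []
    for start in range(0, z, batch_size):
        outs.append(net.forward(x[start:start + batch_size], train=False))
    out = np.concatenate(outs, axis=0)
    t, b_, l, r = pads
    out = out[:, :, t:out.shape[2] - b_ or None, l:out.shape[3] - r or None]
    return out.transpose(1, 0, 2, 3)


def predict_volume(net: UNet2D, volume: SpectralVolume, batch_size: int = 8) -> SpectralVolume:
    """Slice-by-slice axial inference in the reconstruction domain."""
    out = predict_slices(net, volume.data, batch_size)
    return SpectralVolume(out, list(volume.energies), volume.voxel_size_mm)
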