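"""A simple 3D U-net for patch-based binary lesion segmentation.

The default configuration follows the reference architecture: encoder
levels of 32, 64, 128 and 256 kernels of size 3x3x3, each a single
convolution followed by ReLU and group normalisation (groups of 8
channels), with max pooling of size 2 between levels; the decoder uses
parameter-free x2 upsampling, concatenation skip connections and one
convolution (+ReLU+group norm) per level; a final 1x1x1 convolution emits a
single-channel logit map.  With two input channels this network has exactly
2,906,913 trainable parameters — the printed count is what pins the decoder
topology, the parameter-free upsampler and the 2-channel input.

The forward pass maps a (B, C, D, H, W) patch to a (B, 1, D, H, W) logit
map for any spatial extent divisible by 8 (three poolings of size 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .nnops import F32, Adam, Conv3d, GroupNorm, Layer, MaxPool3d, ReLU, Upsample3d

__all__ = ["UnetSpec", "UNet3D", "build_unet", "count_parameters",
           "save_checkpoint", "load_checkpoint", "REFERENCE_PARAMETER_COUNT"]

REFERENCE_PARAMETER_COUNT = 2_906_913


@dataclass(frozen=True)
class UnetSpec:
    """Architectural hyperparameters of the U-net."""

    in_channels: int = 2
    widths: Tuple[int, int, int, int] = (32, 64, 128, 256)
    kernel: int = 3
    group_channels: int = 8
    out_channels: int = 1

    def __post_init__(self) -> None:
        if self.in_channels not in (1, 2):
            raise ValueError("in_channels must be 1 or 2")
        for a, b in zip(self.widths, self.widths[1:]):
            if b != 2 * a:
                raise ValueError("widths must increase strictly by factor 2")
        for w in self.widths:
            if w % self.group_channels != 0:
                raise ValueError("every width must be divisible by the group size")


class _ConvBlock:
    """conv -> ReLU -> GroupNorm."""

    def __init__(self, cin: int, cout: int, kernel: int, group_channels: int,
                 rng: np.random.Generator) -> None:
        self.conv = Conv3d(cin, cout, kernel, rng)
        self.relu = ReLU()
        self.norm = GroupNorm(cout, group_channels)
        self.layers: List[Layer] = [self.conv, self.relu, self.norm]

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.norm.forward(self.relu.forward(self.conv.forward(x)))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.relu.backward(self.norm.backward(dy)))


class UNet3D:
    """Three-pool encoder/decoder with concatenation skips (numpy engine)."""

    def __init__(self, spec: UnetSpec, seed: int) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        w1, w2, w3, w4 = spec.widths
        k, g = spec.kernel, spec.group_channels
        self.enc = [
            _ConvBlock(spec.in_channels, w1, k, g, rng),
            _ConvBlock(w1, w2, k, g, rng),
            _ConvBlock(w2, w3, k, g, rng),
        ]
        self.bottleneck = _ConvBlock(w3, w4, k, g, rng)
        self.pools = [MaxPool3d() for _ in range(3)]
        self.ups = [Upsample3d() for _ in range(3)]
        self.dec = [
            _ConvBlock(w4 + w3, w3, k, g, rng),
            _ConvBlock(w3 + w2, w2, k, g, rng),
            _ConvBlock(w2 + w1, w1, k, g, rng),
        ]
        self.head = Conv3d(w1, spec.out_channels, 1, rng)

    # -- plumbing ----------------------------------------------------------

    def layers(self) -> List[Layer]:
        out: List[Layer] = []
        for blk in [*self.enc, self.bottleneck, *self.dec]:
            out.extend(blk.layers)
        out.append(self.head)
        return out

    def parameter_vector(self) -> np.ndarray:
        """All trainable scalars concatenated (for checksums/equality)."""
        return np.concatenate([
            layer.params[name].ravel()
            for layer in self.layers() for name in sorted(layer.params)
        ])

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=F32)
        if x.ndim == 4:
            x = x[None]
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"expected {self.spec.in_channels} input channels, got {x.shape[1]}"
            )
        if any(s % 8 for s in x.shape[2:]):
            raise ValueError("spatial extents must be divisible by 8")
        skips = []
        h = x
        for blk, pool in zip(self.enc, self.pools):
            h = blk.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        self._skip_channels = []
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h)
            self._skip_channels.append((h.shape[1], skip.shape[1]))
            h = np.concatenate([h, skip], axis=1)
            h = blk.forward(h)
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(np.asarray(dlogits, dtype=F32))
        dskips = []
        for up, blk, (c_up, c_skip) in zip(
            reversed(self.ups), reversed(self.dec), reversed(self._skip_channels)
        ):
            d = blk.backward(d)
            dskips.append(d[:, c_up:])
            d = up.backward(d[:, :c_up])
        # dskips collected shallowest-first; encoder unwinds deepest-first
        d = self.bottleneck.backward(d)
        for blk, pool, dskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(dskips)
        ):
            d = pool.backward(d)
            d = blk.backward(d + dskip)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Forward pass followed by a sigmoid, without caching gradients."""
        logits = self.forward(x).astype(np.float64)
        return 1.0 / (1.0 + np.exp(-logits))

    def make_optimizer(self, lr: float = 1e-3) -> Adam:
        return Adam(self.layers(), lr=lr)


def build_unet(spec: UnetSpec | None = None, seed: int = 0) -> UNet3D:
    """Instantiate the U-net with weights drawn deterministically from seed."""
    return UNet3D(spec or UnetSpec(), seed)


def save_checkpoint(model: UNet3D, path, **manifest) -> None:
    """Save weights plus a run manifest (loss name, seed, fold, epoch, ...)."""
    import json

    arrays = {}
    for i, layer in enumerate(model.layers()):
        for name, p in layer.params.items():
            arrays[f"{i}:{name}"] = p
    spec = model.spec
    manifest = dict(manifest,
                    in_channels=spec.in_channels, widths=list(spec.widths),
                    group_channels=spec.group_channels)
    np.savez(path, __manifest__=np.frombuffer(
        json.dumps(manifest).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> Tuple[UNet3D, dict]:
    """Rebuild a model from a checkpoint; returns (model, manifest)."""
    import json

    with np.load(path) as data:
        manifest = json.loads(bytes(data["__manifest__"]).decode())
        spec = UnetSpec(in_channels=manifest["in_channels"],
                        widths=tuple(manifest["widths"]),
                        group_channels=manifest["group_channels"])
        model = UNet3D(spec, seed=0)
        for i, layer in enumerate(model.layers()):
            for name in layer.params:
                layer.params[name] = data[f"{i}:{name}"].copy()
    return model, manifest


def count_parameters(model: UNet3D) -> int:
    """Total number of trainable scalars in the model."""
    return sum(layer.n_parameters() for layer in model.layers())
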