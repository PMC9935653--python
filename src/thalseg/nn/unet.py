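"""Patch-based 3D encoder-decoder (U-net) with residual blocks.

The full-size configuration mirrors a clinical thalamus-segmentation
network: 160^3 input patches at 1-mm voxels, four resolution reductions,
instance normalization, five output classes (background, left thalamus,
right thalamus, other deep gray matter, remaining intracranial volume).
Depth, patch size and channel width are configurable so the same
architecture runs at desk scale (e.g. 32^3 patches, two reductions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import AvgPool2, Conv3d, InstanceNorm3d, ReLU, ResBlock, Sequential, Upsample2


@dataclass
class NetConfig:
    patch_size: int = 160
    depth: int = 4  # number of resolution reductions
    base_channels: int = 8
    n_classes: int = 5
    normalization: str = "instance"
    res_blocks_per_level: int = 1

    def __post_init__(self) -> None:
        if self.patch_size % (2**self.depth):
            raise ValueError(
                f"patch size {self.patch_size} must be divisible by "
                f"2^depth = {2**self.depth}"
            )
        if self.normalization != "instance":
            raise ValueError("only instance normalization is supported")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.res_blocks_per_level < 1:
            raise ValueError("res_blocks_per_level must be >= 1")


def _level(c_in, c_out, n_blocks, rng, dtype):
    blocks = [ResBlock(c_in, c_out, rng, dtype)]
    blocks += [ResBlock(c_out, c_out, rng, dtype) for _ in range(n_blocks - 1)]
    return Sequential(*blocks)


class UNet3D:
    """Encoder-decoder over single-sample (C, D, H, W) tensors."""

    def __init__(self, config: NetConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.base_channels
        nb = config.res_blocks_per_level
        self.enc = []
        self.pools = []
        ch_in = 1
        for lvl in range(config.depth):
            ch_out = c * 2**lvl
            self.enc.append(_level(ch_in, ch_out, nb, rng, dtype))
            self.pools.append(AvgPool2())
            ch_in = ch_out
        self.bottleneck = _level(ch_in, c * 2**config.depth, nb, rng, dtype)
        self.ups = []
        self.dec = []
        for lvl in reversed(range(config.depth)):
            skip_ch = c * 2**lvl
            up_ch = c * 2 ** (lvl + 1)
            self.ups.append(Upsample2())
            self.dec.append(_level(up_ch + skip_ch, skip_ch, nb, rng, dtype))
        self.head = Conv3d(c, config.n_classes, 1, rng, dtype)
        self._skip_channels = [c * 2**l for l in range(config.depth)]

    def params(self):
        ps = []
        for m in self.enc + [self.bottleneck] + self.dec + [self.head]:
            ps += m.params()
        return ps

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (1, D, H, W) with D, H, W divisible by 2^depth -> logits (C, D, H, W)."""
        if x.ndim != 4 or x.shape[0] != 1:
            raise ValueError(f"expected (1, D, H, W) input, got {x.shape}")
        skips = []
        for enc, pool in zip(self.enc, self.pools):
            x = enc.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            x = np.concatenate([x, skip], axis=0)
            x = dec.forward(x)
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.head.backward(dlogits)
        dskips = []
        for up, dec, skip_ch in zip(
            reversed(self.ups), reversed(self.dec), self._skip_channels
        ):
            dy = dec.backward(dy)
            up_ch = dy.shape[0] - skip_ch
            dskips.append(dy[up_ch:])
            dy = up.backward(dy[:up_ch])
        dy = self.bottleneck.backward(dy)
        for enc, pool, dskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(dskips)
        ):
            dy = pool.backward(dy)
            dy = enc.backward(dy + dskip)

    def state_dict(self):
        return {f"p{i}": p.value for i, p in enumerate(self.params())}

    def load_state_dict(self, state):
        for i, p in enumerate(self.params()):
            v = np.asarray(state[f"p{i}"])
            if v.shape != p.value.shape:
                raise ValueError("checkpoint does not match the configured network")
            p.value = v.astype(p.value.dtype)
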