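"""Training-time augmentation: bias fields, noise, rotation, left-right flip.

Geometric transforms are applied identically to the image (linear
interpolation) and the label map (nearest neighbour). A left-right flip
mirrors anatomy, so it swaps the left/right thalamus labels. Intensity
transforms (multiplicative bias field, additive noise) never touch labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import LabelMap, VolumeImage
from .phantom import smooth_random_field

#: axis index of the left-right (x) direction on the canonical RAS+ grid
LR_AXIS = 0
#: label swap applied together with a midsagittal flip
FLIP_SWAP = {1: 2, 2: 1}


@dataclass
class AugmentParams:
    """Ranges from which each per-sample augmentation is drawn."""

    bias_amplitude_range: tuple = (0.0, 0.4)
    bias_correlation_mm: float = 40.0
    noise_std_range: tuple = (0.0, 6.0)
    rotation_deg_range: tuple = (-10.0, 10.0)  # per rotation plane
    flip_probability: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bias_amplitude_range", "noise_std_range", "rotation_deg_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} has lower > upper: ({lo}, {hi})")
        if not 0.0 <= self.flip_probability <= 1.0:
            raise ValueError("flip_probability must be in [0, 1]")
        if self.bias_correlation_mm <= 0:
            raise ValueError("bias_correlation_mm must be > 0")

    @classmethod
    def identity(cls) -> "AugmentParams":
        return cls((0.0, 0.0), 40.0, (0.0, 0.0), (0.0, 0.0), 0.0)


def random_bias_field(shape, amplitude, correlation_mm, seed, spacing=1.0) -> np.ndarray:
    """Smooth, strictly positive multiplicative field with spatial mean ~1.

    The field is the exponential of a smoothed, zero-mean, peak-normalized
    Gaussian random field, scaled so that the peak deviation from 1 equals
    ``amplitude``, then renormalized to unit spatial mean. Amplitude 0
    returns an all-ones field.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0:
        return np.ones(shape, dtype=np.float32)
    rng = np.random.default_rng(seed)
    g = smooth_random_field(shape, spacing, correlation_mm, rng)
    field = np.exp(np.log1p(amplitude) * g)
    field /= field.mean()
    return field.astype(np.float32)


_ROT_PLANES = ((1, 2), (0, 2), (0, 1))  # rotation plane per axis


def _rotate(data, angles_deg, order):
    """Rotate about the volume center, one plane at a time.

    Angles that are exact multiples of 90 degrees use lossless quarter-turns
    so label counts are preserved bit-exactly.
    """
    out = data
    for axes, angle in zip(_ROT_PLANES, angles_deg):
        if angle == 0:
            continue
        if angle % 90 == 0 and out.shape[axes[0]] == out.shape[axes[1]]:
            out = np.rot90(out, k=int(angle // 90), axes=axes)
        else:
            out = ndimage.rotate(
                out, angle, axes=axes, reshape=False, order=order,
                mode="constant", cval=0.0,
            )
    return out


def flip_lr(labels: np.ndarray) -> np.ndarray:
    """Midsagittal flip of a label array with the left/right thalamus swap."""
    flipped = np.flip(labels, axis=LR_AXIS).copy()
    out = flipped.copy()
    for src, dst in FLIP_SWAP.items():
        out[flipped == src] = dst
    return out


def augment_pair(v: VolumeImage, l: LabelMap, p: AugmentParams, seed: int):
    """Apply one random augmentation draw to an image/label pair.

    Order: rotation -> flip (geometric, shared) -> bias field -> noise
    (intensity, image only). Deterministic in ``seed``.
    """
    if v.data.shape != l.data.shape or not np.allclose(v.affine, l.affine):
        raise ValueError("image and label map must share a grid")
    rng = np.random.default_rng(seed)

    angles = rng.uniform(*p.rotation_deg_range, size=3)
    if p.rotation_deg_range == (0.0, 0.0):
        angles = np.zeros(3)
    do_flip = rng.random() < p.flip_probability
    amplitude = rng.uniform(*p.bias_amplitude_range)
    noise_std = rng.uniform(*p.noise_std_range)
    bias_seed = int(rng.integers(2**31))
    noise_seed = int(rng.integers(2**31))

    img = np.asarray(v.data, dtype=np.float32)
    lab = np.asarray(l.data)
    if np.any(angles != 0):
        img = _rotate(img, angles, order=1)
        lab = _rotate(lab, angles, order=0)
    if do_flip:
        img = np.flip(img, axis=LR_AXIS).copy()
        lab = flip_lr(lab)

    if amplitude > 0:
        spacing = float(np.mean(v.spacing))
        img = img * random_bias_field(
            img.shape, amplitude, p.bias_correlation_mm, bias_seed, spacing
        )
    if noise_std > 0:
        img = img + np.random.default_rng(noise_seed).standard_normal(
            img.shape
        ).astype(np.float32) * noise_std

    return (
        VolumeImage(img.astype(np.float32), v.affine.copy()),
        LabelMap(lab.astype(l.data.dtype), l.affine.copy(), dict(l.codebook)),
    )
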