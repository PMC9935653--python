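"""Segmentation agreement metrics: Dice, Hausdorff distance, Bland-Altman.

Dice and Hausdorff compare a test mask against a reference mask on the same
grid; Hausdorff is the classic symmetric maximum of directed boundary-to-
boundary distances, reported in physical mm via the voxel spacing.
Bland-Altman statistics summarize volume agreement over a set of paired
measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff
from scipy.stats import pearsonr


@dataclass
class AgreementStats:
    """Bland-Altman summary of paired volume measurements (test - reference)."""

    mean_diff: float  # mL
    std_diff: float  # mL
    loa_lower: float  # mL, mean - 1.96*std
    loa_upper: float  # mL, mean + 1.96*std
    r_diff_vs_ref: float  # Pearson r between difference and reference
    p_value: float


def _as_mask(m) -> np.ndarray:
    m = np.asarray(m)
    if m.ndim != 3:
        raise ValueError(f"masks must be 3D, got shape {m.shape}")
    return m.astype(bool)


def dice(test, reference) -> float:
    """Dice similarity coefficient 2|A & B| / (|A| + |B|).

    Defined as 1.0 when both masks are empty (perfect agreement on
    nothingness), with a warning.
    """
    a, b = _as_mask(test), _as_mask(reference)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        warnings.warn("Dice of two empty masks defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one face neighbour outside the mask."""
    mask = _as_mask(mask)
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    eroded = ndimage.binary_erosion(mask, structure, border_value=0)
    return np.argwhere(mask & ~eroded)


def hausdorff(test, reference, spacing=(1.0, 1.0, 1.0)) -> float:
    """Symmetric Hausdorff distance between mask boundaries, in mm."""
    a, b = _as_mask(test), _as_mask(reference)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        raise ValueError("Hausdorff distance is undefined for an empty mask")
    spacing = np.asarray(spacing, dtype=float)
    pa = boundary_voxels(a) * spacing
    pb = boundary_voxels(b) * spacing
    return max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])


def bland_altman(test_volumes, reference_volumes) -> AgreementStats:
    """Bland-Altman agreement of paired volumes (differences = test - ref).

    The correlation is computed between the differences and the reference
    volumes, i.e. whether the offset depends on the true volume.
    """
    t = np.asarray(test_volumes, dtype=float)
    r = np.asarray(reference_volumes, dtype=float)
    if t.shape != r.shape or t.ndim != 1:
        raise ValueError("test and reference must be 1D arrays of equal length")
    if t.size < 3:
        raise ValueError("need at least 3 paired measurements")
    d = t - r
    mean_diff = float(d.mean())
    std_diff = float(d.std(ddof=1))
    if np.allclose(d, d[0]) or np.allclose(r, r[0]):
        corr, p = 0.0, 1.0  # constant offset or constant reference: no trend
    else:
        corr, p = pearsonr(d, r)
    return AgreementStats(
        mean_diff=mean_diff,
        std_diff=std_diff,
        loa_lower=mean_diff - 1.96 * std_diff,
        loa_upper=mean_diff + 1.96 * std_diff,
        r_diff_vs_ref=float(corr),
        p_value=float(p),
    )
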