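"""NIfTI volume and label-map I/O on a canonical 1-mm working grid.

All downstream computation assumes volumes in closest-canonical (RAS+)
orientation resampled to isotropic voxels, so that a structure volume in mL
is exactly ``voxel count * edge^3 / 1000`` and "left"/"right" refer to
anatomical sides (x axis), not array index order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

#: Label codebook shared by the whole package.
CODEBOOK = {
    0: "background",
    1: "left_thalamus",
    2: "right_thalamus",
    3: "other_deep_gm",
    4: "remaining_tiv",
}

#: Classes counted toward total intracranial volume.
TIV_LABELS = (1, 2, 3, 4)


class FormatError(ValueError):
    """Raised for structurally invalid image files (wrong dimensionality etc.)."""


@dataclass
class VolumeImage:
    """A 3D scalar intensity grid with geometry metadata.

    Parameters
    ----------
    data
        3D float array of intensities (arbitrary units).
    affine
        4x4 voxel-index -> world (mm) affine, NIfTI convention (RAS+ after
        canonicalization).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise FormatError(
                f"expected a 3D volume, got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.any(self.spacing <= 0):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def origin(self) -> np.ndarray:
        """World coordinates (mm) of voxel (0, 0, 0)."""
        return self.affine[:3, 3]

    def voxel_volume_ml(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3]))) / 1000.0


@dataclass
class LabelMap:
    """Integer-coded segmentation sharing a grid with its VolumeImage."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    codebook: dict = field(default_factory=lambda: dict(CODEBOOK))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(
                f"expected a 3D label map, got shape {self.data.shape}"
            )
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise ValueError("label map has non-integer values")
            self.data = rounded.astype(np.int16)
        extra = set(np.unique(self.data)) - set(self.codebook)
        if extra:
            raise ValueError(f"labels outside the codebook: {sorted(extra)}")

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_volume_ml(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3]))) / 1000.0


def _load_canonical(path):
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt header, wrong magic, ...
        raise FormatError(f"cannot read {path!s} as NIfTI: {exc}") from exc
    img = nib.as_closest_canonical(img)
    if len(img.shape) == 4 and img.shape[3] == 1:
        img = img.slicer[..., 0]
    if len(img.shape) != 3:
        raise FormatError(
            f"{path!s}: expected a 3D image, header reports shape {img.shape}"
        )
    return img


def read_volume(path) -> VolumeImage:
    """Read a NIfTI-1/2 volume, reoriented to closest-canonical (RAS+)."""
    img = _load_canonical(path)
    return VolumeImage(np.asarray(img.get_fdata(), dtype=np.float32), img.affine)


def read_labels(path) -> LabelMap:
    """Read an integer-coded NIfTI label map, reoriented to RAS+."""
    img = _load_canonical(path)
    data = np.asarray(img.get_fdata())
    return LabelMap(np.rint(data).astype(np.int16), img.affine)


def write_volume(v: VolumeImage, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(v.data, dtype=np.float32), v.affine), str(path))


def write_labels(l: LabelMap, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(l.data, dtype=np.int16), l.affine), str(path))


def _resample(data, affine, edge, order):
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    zoom = spacing / edge
    out_shape = np.maximum(1, np.rint(np.asarray(data.shape) * zoom)).astype(int)
    # exact scale implied by the rounded shape keeps the field of view within
    # one voxel of the input
    out = ndimage.zoom(
        np.asarray(data, dtype=np.float32),
        out_shape / np.asarray(data.shape),
        order=order,
        mode="nearest",
        grid_mode=True,
    )
    actual_zoom = out_shape / np.asarray(data.shape)
    new_affine = affine.copy()
    new_affine[:3, :3] = affine[:3, :3] / actual_zoom[np.newaxis, :]
    # grid_mode aligns cell edges: centre of output voxel 0 sits at input
    # continuous index 1/(2*zoom) - 1/2 along each axis
    shift = 0.5 / actual_zoom - 0.5
    new_affine[:3, 3] = affine[:3, 3] + affine[:3, :3] @ shift
    return out, new_affine


def resample_isotropic(v: VolumeImage, edge: float = 1.0, mode: str = "linear") -> VolumeImage:
    """Resample to cubic voxels of the given edge length (mm).

    ``linear`` interpolates intensities; ``nearest`` is for label-valued
    data and never invents new values.
    """
    if edge <= 0:
        raise ValueError(f"voxel edge must be positive, got {edge}")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    if np.allclose(v.spacing, edge):
        return replace(v, data=v.data.copy(), affine=v.affine.copy())
    data, affine = _resample(v.data, v.affine, edge, order=1 if mode == "linear" else 0)
    return VolumeImage(data, affine)


def resample_labels_isotropic(l: LabelMap, edge: float = 1.0) -> LabelMap:
    """Nearest-neighbour resampling of a label map to an isotropic grid."""
    if edge <= 0:
        raise ValueError(f"voxel edge must be positive, got {edge}")
    if np.allclose(l.spacing, edge):
        return LabelMap(l.data.copy(), l.affine.copy(), dict(l.codebook))
    data, affine = _resample(l.data.astype(np.float32), l.affine, edge, order=0)
    return LabelMap(np.rint(data).astype(np.int16), affine, dict(l.codebook))
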