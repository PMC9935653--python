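"""Synthetic labeled head phantoms and simulated volumetry cohorts.

The phantom generator is the package's stand-in for T1w head MRI: a set of
ellipsoidal structures (left/right thalamus, other deep gray matter,
surrounding intracranial tissue) rendered under a parameterized scanner
appearance (bias field, noise, global scale, gamma-like contrast). Anatomy
(the label map) is a pure function of the geometry spec and the seed;
appearance additionally depends on the scanner profile — this separation is
what lets scanner-robustness be measured against exact ground truth.

Cohort simulation produces tabular records with the three variance
components of multi-scanner volumetry: between-subject (sigma_between),
inter-scanner (sigma_inter) and intra-scanner / test-retest (sigma_intra),
around a quadratic volume-TIV-age trend.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import CODEBOOK, LabelMap, VolumeImage

COHORT_COLUMNS = [
    "subject_id",
    "scanner_id",
    "session_id",
    "repeat",
    "age_years",
    "tiv_ml",
    "thalv_ml",
]


class GeometryError(ValueError):
    """A phantom structure does not fit inside the grid."""


@dataclass
class Ellipsoid:
    """Axis-aligned ellipsoid in world mm, centered relative to the grid center."""

    center: tuple  # mm offset from grid center (x=L->R, y=P->A, z=I->S)
    semi_axes: tuple  # mm

    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c


@dataclass
class PhantomSpec:
    """Geometry and tissue appearance of the synthetic head.

    Thalami are mirror images about the midsagittal (x = 0) plane. Mean
    intensities roughly order like T1w tissue: CSF/mixed intracranial
    darkest, deep gray matter brighter, thalamus brightest; the absolute
    units are arbitrary.
    """

    shape: tuple = (64, 64, 64)
    spacing: float = 1.0  # mm, isotropic working grid
    intracranial: Ellipsoid = field(
        default_factory=lambda: Ellipsoid((0.0, 0.0, 0.0), (28.0, 30.0, 26.0))
    )
    left_thalamus: Ellipsoid = field(
        default_factory=lambda: Ellipsoid((-9.0, -2.0, 0.0), (6.0, 9.0, 5.0))
    )
    other_deep_gm: tuple = field(
        default_factory=lambda: (
            Ellipsoid((-13.0, 10.0, 4.0), (4.0, 7.0, 4.0)),
            Ellipsoid((13.0, 10.0, 4.0), (4.0, 7.0, 4.0)),
            Ellipsoid((-16.0, -4.0, -4.0), (3.5, 4.5, 6.0)),
            Ellipsoid((16.0, -4.0, -4.0), (3.5, 4.5, 6.0)),
        )
    )
    # mean intensity and within-structure std per label
    mean_intensity: dict = field(
        default_factory=lambda: {0: 0.0, 1: 135.0, 2: 135.0, 3: 120.0, 4: 100.0}
    )
    intensity_std: dict = field(
        default_factory=lambda: {0: 0.0, 1: 2.0, 2: 2.0, 3: 2.0, 4: 4.0}
    )
    smoothing_mm: float = 1.0  # partial-volume emulation
    center_jitter_mm: float = 1.5  # per-seed anatomical variability
    axis_jitter_frac: float = 0.12

    def right_thalamus(self, left: Ellipsoid) -> Ellipsoid:
        cx, cy, cz = left.center
        return Ellipsoid((-cx, cy, cz), left.semi_axes)


@dataclass
class ScannerProfile:
    """Scanner-specific appearance transform applied to the clean phantom."""

    scanner_id: str = "scanner_0"
    bias_amplitude: float = 0.2  # max multiplicative deviation from 1
    bias_smoothness_mm: float = 40.0  # correlation length of the bias field
    noise_std: float = 4.0  # additive noise, intensity units
    intensity_scale: float = 1.0
    contrast_gamma: float = 1.0
    noise_model: str = "gaussian"  # or "rician"

    def __post_init__(self) -> None:
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        if self.bias_smoothness_mm <= 0:
            raise ValueError("bias_smoothness_mm must be > 0")
        if self.intensity_scale <= 0:
            raise ValueError("intensity_scale must be > 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    def param_digest(self) -> int:
        """Stable integer digest of the numeric appearance parameters."""
        payload = np.array(
            [
                self.bias_amplitude,
                self.bias_smoothness_mm,
                self.noise_std,
                self.intensity_scale,
                self.contrast_gamma,
                float(self.noise_model == "rician"),
            ],
            dtype=np.float64,
        ).tobytes()
        return zlib.crc32(payload + self.scanner_id.encode())


def scaled_spec(shape, reference=64) -> "PhantomSpec":
    """A PhantomSpec with the default geometry scaled to fit a smaller grid."""
    s = min(shape) / reference
    base = PhantomSpec()

    def scale(e: Ellipsoid) -> Ellipsoid:
        return Ellipsoid(
            tuple(c * s for c in e.center), tuple(a * s for a in e.semi_axes)
        )

    return PhantomSpec(
        shape=tuple(shape),
        intracranial=scale(base.intracranial),
        left_thalamus=scale(base.left_thalamus),
        other_deep_gm=tuple(scale(e) for e in base.other_deep_gm),
        smoothing_mm=base.smoothing_mm * s,
        center_jitter_mm=base.center_jitter_mm * s,
        axis_jitter_frac=base.axis_jitter_frac,
    )


def random_scanner_profile(rng_or_seed, scanner_id: str = "scanner") -> ScannerProfile:
    """Draw a plausible scanner appearance at random (for cohort rendering)."""
    rng = np.random.default_rng(rng_or_seed) if not isinstance(
        rng_or_seed, np.random.Generator
    ) else rng_or_seed
    return ScannerProfile(
        scanner_id=scanner_id,
        bias_amplitude=float(rng.uniform(0.0, 0.4)),
        bias_smoothness_mm=float(rng.uniform(25.0, 60.0)),
        noise_std=float(rng.uniform(1.0, 8.0)),
        intensity_scale=float(rng.uniform(0.8, 1.25)),
        contrast_gamma=float(rng.uniform(0.85, 1.2)),
    )


def _jitter_ellipsoid(e: Ellipsoid, rng, center_jitter, axis_frac) -> Ellipsoid:
    center = np.asarray(e.center) + rng.uniform(-center_jitter, center_jitter, 3)
    axes = np.asarray(e.semi_axes) * (1.0 + rng.uniform(-axis_frac, axis_frac, 3))
    return Ellipsoid(tuple(center), tuple(axes))


def _ellipsoid_mask(shape, spacing, e: Ellipsoid) -> np.ndarray:
    coords = [
        (np.arange(n) - (n - 1) / 2.0) * spacing for n in shape
    ]  # mm, relative to grid center
    x, y, z = np.meshgrid(*coords, indexing="ij")
    cx, cy, cz = e.center
    ax, ay, az = e.semi_axes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _check_inside(name, e: Ellipsoid, shape, spacing) -> None:
    half_extent = (np.asarray(shape) - 1) / 2.0 * spacing
    lo = np.asarray(e.center) - np.asarray(e.semi_axes)
    hi = np.asarray(e.center) + np.asarray(e.semi_axes)
    if np.any(lo < -half_extent) or np.any(hi > half_extent):
        raise GeometryError(
            f"structure {name!r} (center {e.center}, semi-axes {e.semi_axes}) "
            f"exceeds the {shape} grid at {spacing} mm"
        )


def build_label_map(spec: PhantomSpec, seed: int) -> LabelMap:
    """Anatomy only: label map as a pure function of (spec, seed)."""
    rng = np.random.default_rng([int(seed), 0])
    left = _jitter_ellipsoid(
        spec.left_thalamus, rng, spec.center_jitter_mm, spec.axis_jitter_frac
    )
    right = spec.right_thalamus(left)
    deep = tuple(
        _jitter_ellipsoid(e, rng, spec.center_jitter_mm, spec.axis_jitter_frac)
        for e in spec.other_deep_gm
    )
    icc = spec.intracranial

    for name, e in [("intracranial", icc), ("left_thalamus", left),
                    ("right_thalamus", right)] + [
        (f"other_deep_gm[{i}]", e) for i, e in enumerate(deep)
    ]:
        _check_inside(name, e, spec.shape, spec.spacing)

    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[_ellipsoid_mask(spec.shape, spec.spacing, icc)] = 4
    for e in deep:
        labels[_ellipsoid_mask(spec.shape, spec.spacing, e)] = 3
    labels[_ellipsoid_mask(spec.shape, spec.spacing, left)] = 1
    labels[_ellipsoid_mask(spec.shape, spec.spacing, right)] = 2

    affine = np.diag([spec.spacing] * 3 + [1.0])
    affine[:3, 3] = -(np.asarray(spec.shape) - 1) / 2.0 * spec.spacing
    return LabelMap(labels, affine, dict(CODEBOOK))


def smooth_random_field(shape, spacing, correlation_mm, rng) -> np.ndarray:
    """Zero-mean, unit-max-normalized smooth Gaussian random field."""
    sigma_vox = correlation_mm / (2.0 * np.asarray(spacing, dtype=float))
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox, mode="reflect")
    f -= f.mean()
    peak = np.abs(f).max()
    if peak > 0:
        f /= peak
    return f


def render_appearance(
    labels: np.ndarray,
    spec: PhantomSpec,
    profile: ScannerProfile,
    rng: np.random.Generator,
) -> np.ndarray:
    """Clean tissue intensities -> smoothing -> bias -> scale/contrast -> noise."""
    img = np.zeros(labels.shape, dtype=np.float64)
    for k, mu in spec.mean_intensity.items():
        mask = labels == k
        sd = spec.intensity_std.get(k, 0.0)
        img[mask] = mu + (rng.standard_normal(int(mask.sum())) * sd if sd > 0 else 0.0)

    if spec.smoothing_mm > 0:
        img = ndimage.gaussian_filter(img, spec.smoothing_mm / spec.spacing)

    if profile.bias_amplitude > 0:
        # exponential of a smooth zero-mean field: strictly positive,
        # peak deviation == amplitude
        g = smooth_random_field(labels.shape, spec.spacing, profile.bias_smoothness_mm, rng)
        img = img * np.exp(np.log1p(profile.bias_amplitude) * g)
    else:
        rng.standard_normal(labels.shape)  # keep stream aligned across amplitudes

    ref = max(spec.mean_intensity.values()) or 1.0
    img = profile.intensity_scale * ref * np.power(
        np.clip(img, 0.0, None) / ref, profile.contrast_gamma
    )

    if profile.noise_std > 0:
        if profile.noise_model == "rician":
            n1 = rng.standard_normal(labels.shape) * profile.noise_std
            n2 = rng.standard_normal(labels.shape) * profile.noise_std
            img = np.sqrt((img + n1) ** 2 + n2**2)
        else:
            img = img + rng.standard_normal(labels.shape) * profile.noise_std
    return img.astype(np.float32)


def make_phantom(spec: PhantomSpec, profile: ScannerProfile, seed: int):
    """Render one phantom.

    Returns
    -------
    (VolumeImage, LabelMap, dict)
        The image under the given scanner appearance, the ground-truth label
        map (independent of the profile), and per-structure true volumes in
        mL (label voxel count x voxel volume), keyed by codebook name plus
        ``THALV`` and ``TIV``.
    """
    label_map = build_label_map(spec, seed)
    rng = np.random.default_rng([int(seed), 1, profile.param_digest()])
    img = render_appearance(label_map.data, spec, profile, rng)
    vol = VolumeImage(img, label_map.affine.copy())

    vv = label_map.voxel_volume_ml()
    volumes = {
        name: float((label_map.data == k).sum()) * vv
        for k, name in CODEBOOK.items()
        if k != 0
    }
    volumes["THALV"] = volumes["left_thalamus"] + volumes["right_thalamus"]
    volumes["TIV"] = sum(volumes[CODEBOOK[k]] for k in (1, 2, 3, 4))
    return vol, label_map, volumes


# --------------------------------------------------------------------------
# Tabular cohort simulation
# --------------------------------------------------------------------------

#: Generating coefficients of the quadratic THALV-TIV-age trend,
#: THALV = a*TIV^2 + b*age^2 + c*TIV*age + d*TIV + e*age + f  (mL; TIV in mL,
#: age in years). Chosen to give bilateral thalamus volumes of ~8-18 mL with
#: mild age-related decline over a TIV range of ~1000-1800 mL.
DEFAULT_COEFFS = (-1.0e-6, -2.0e-4, -5.0e-6, 0.01, -0.03, 4.1)


def quadratic_thalv(tiv, age, coeffs=DEFAULT_COEFFS):
    """Evaluate the quadratic normative trend (vectorized)."""
    a, b, c, d, e, f = coeffs
    tiv = np.asarray(tiv, dtype=float)
    age = np.asarray(age, dtype=float)
    return a * tiv**2 + b * age**2 + c * tiv * age + d * tiv + e * age + f


@dataclass
class CohortParams:
    """Simulation parameters for a multi-scanner volumetry cohort."""

    n_subjects: int = 4872
    n_scanners: int = 160
    repeats: tuple = (1, 1)  # inclusive range of repeat scans per session
    age_bounds: tuple = (20.0, 90.0)  # years, uniform
    tiv_mean: float = 1400.0  # mL
    tiv_std: float = 130.0  # mL
    coeffs: tuple = DEFAULT_COEFFS
    sigma_between: float = 0.88  # mL, between-subject residual spread
    sigma_inter: float = 0.28  # mL, inter-scanner offset spread
    sigma_intra: float = 0.08  # mL, test-retest spread
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_between, self.sigma_inter, self.sigma_intra) < 0:
            raise ValueError("variance components must be >= 0")
        lo, hi = self.age_bounds
        if not (0 <= lo <= hi <= 120):
            raise ValueError("age bounds must lie within [0, 120]")
        if self.n_subjects < 1 or self.n_scanners < 1:
            raise ValueError("need at least one subject and one scanner")
        if self.repeats[0] < 1 or self.repeats[0] > self.repeats[1]:
            raise ValueError("repeats range must be 1 <= lo <= hi")


def make_cohort(params: CohortParams) -> pd.DataFrame:
    """Simulate a cohort under THALV_ijk = model(TIV_i, age_i) + b_i + s_j + eps_ijk.

    b_i ~ N(0, sigma_between^2) per subject, s_j ~ N(0, sigma_inter^2) per
    scanner, eps_ijk ~ N(0, sigma_intra^2) per scan. Each subject is scanned
    in one session on one scanner with a repeat count drawn uniformly from
    the configured range.
    """
    rng = np.random.default_rng(params.seed)
    p = params
    age = rng.uniform(*p.age_bounds, p.n_subjects)
    tiv = np.clip(rng.normal(p.tiv_mean, p.tiv_std, p.n_subjects), 900.0, None)
    b = rng.normal(0.0, p.sigma_between, p.n_subjects) if p.sigma_between else np.zeros(p.n_subjects)
    s = rng.normal(0.0, p.sigma_inter, p.n_scanners) if p.sigma_inter else np.zeros(p.n_scanners)
    scanner_of = rng.integers(0, p.n_scanners, p.n_subjects)
    n_rep = rng.integers(p.repeats[0], p.repeats[1] + 1, p.n_subjects)

    base = quadratic_thalv(tiv, age, p.coeffs) + b + s[scanner_of]
    rows = []
    for i in range(p.n_subjects):
        for r in range(int(n_rep[i])):
            eps = rng.normal(0.0, p.sigma_intra) if p.sigma_intra else 0.0
            rows.append(
                (
                    f"sub_{i:05d}",
                    f"scanner_{scanner_of[i]:03d}",
                    f"ses_{i:05d}",
                    r,
                    age[i],
                    tiv[i],
                    base[i] + eps,
                )
            )
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    if (df["thalv_ml"] <= 0).any() or (df["thalv_ml"] >= df["tiv_ml"]).any():
        raise ValueError("simulated THALV outside (0, TIV); check coefficients")
    return df


def make_travel_sessions(
    n_scanners: int,
    repeats: tuple,
    sigma_intra: float,
    sigma_inter: float,
    base_thalv: float = 13.5,
    seed: int = 0,
    age: float = 50.0,
    tiv: float = 1450.0,
) -> pd.DataFrame:
    """Simulate a frequently-traveling-human-phantom study.

    One subject, one session per scanner, ``repeats`` (inclusive range)
    repeat scans without repositioning per session:
    THALV_jk = base + s_j + eps_jk.
    """
    if n_scanners < 2:
        raise ValueError("a traveling-phantom study needs >= 2 scanners")
    lo, hi = int(repeats[0]), int(repeats[1])
    if lo < 1 or lo > hi:
        raise ValueError("repeats range must be 1 <= lo <= hi")
    rng = np.random.default_rng(seed)
    s = rng.normal(0.0, sigma_inter, n_scanners) if sigma_inter else np.zeros(n_scanners)
    rows = []
    for j in range(n_scanners):
        for r in range(int(rng.integers(lo, hi + 1))):
            eps = rng.normal(0.0, sigma_intra) if sigma_intra else 0.0
            rows.append(
                (
                    "fthp_subject",
                    f"scanner_{j:03d}",
                    f"ses_{j:03d}",
                    r,
                    age,
                    tiv,
                    base_thalv + s[j] + eps,
                )
            )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
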