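# Methods

## Problem and scope

`thalseg` implements a complete, desk-scale pipeline for scanner-robust
MRI thalamus volumetry:

1. a **synthetic phantom generator** producing labeled 3D head phantoms
   under parameterized scanner appearance, and tabular cohorts with
   explicit variance components;
2. a **patch-based 3D encoder–decoder segmentation network** with
   bias-field/noise/rotation/flip augmentation, trained and run entirely
   in numpy;
3. **segmentation agreement metrics** (Dice, Hausdorff, Bland–Altman);
4. **intra-/inter-scanner stability analysis** of volume estimates;
5. a **normative quadratic THALV–TIV–age model** with two-step outlier
   exclusion and a two-sample rule for flagging reduced thalamus volume in
   a single subject.

All computation happens on a canonical working grid: closest-canonical
(RAS+) axis order, isotropic voxels (1 mm by default), so that a structure
volume in mL is exactly `voxel count × edge³ / 1000` and left/right refer
to anatomical sides rather than array order. Linear interpolation is used
for intensities and nearest-neighbour for labels; how sub-millimetre or
anisotropic clinical acquisitions are best brought to this grid is an open
choice, and linear/nearest is the conventional default.

## Phantom generator

A phantom is a set of axis-aligned ellipsoids inside an intracranial
ellipsoid: mirror-symmetric left/right thalami, a few deep-gray-matter
blobs, and the remaining intracranial compartment. Geometry is jittered
per seed (centres ±1.5 mm, semi-axes ±12%) to emulate anatomical
variability. Rendering follows

    tissue means (+ within-structure Gaussian texture)
      → Gaussian smoothing (partial-volume emulation, 1 mm)
      → × bias field → global scale, gamma-like contrast → + noise.

The bias field is the exponential of a smoothed, zero-mean, peak-normalized
Gaussian random field, which guarantees positivity and makes the peak
deviation equal the configured amplitude. Noise is additive Gaussian by
default with an optional Rician mode for magnitude-MRI realism.

**Anatomy/appearance separation** is the load-bearing invariant: the label
map is a pure function of (geometry spec, seed) and never of the scanner
profile, so ground truth is exact no matter how harsh the appearance.

Tissue means (thalamus 135, other deep GM 120, remaining intracranial 100,
background 0, arbitrary units) give a T1w-like contrast ordering with a
deliberately modest thalamus/deep-GM contrast, because distinguishing
adjacent deep gray structures is the hard part of the real task.

### Cohort simulation

Tabular cohorts follow

    THALV_ijk = a·TIV² + b·age² + c·TIV·age + d·TIV + e·age + f
                + b_i + s_j + ε_ijk,

with subject effects `b_i ~ N(0, σ_between²)`, scanner offsets
`s_j ~ N(0, σ_inter²)` and repeat noise `ε_ijk ~ N(0, σ_intra²)`. Default
sizes and spreads mirror the reference study conditions: a normal database
of 4872 subjects over 160 scanners with σ_between = 0.88 mL, and a
traveling-subject study of 123 scanners with 3–5 repeats per session and
σ_inter = 0.28 mL, σ_intra = 0.08 mL. Ages are uniform in [20, 90] years;
TIV is Gaussian (1400 ± 130 mL, floored at 900 mL). The generating
coefficients `(-1e-6, -2e-4, -5e-6, 0.01, -0.03, 4.1)` yield bilateral
thalamus volumes of roughly 8–18 mL with mild age-related decline — chosen
once as a physiologically plausible surface; no distributional detail of
the real cohorts beyond the stated spreads is claimed.

What the generator does **not** emulate: cortical folding, lesions, pulse
sequence physics, scanner drift over time, or any TIV–age correlation.
Passing tests therefore demonstrate correctness of the algorithms under
the stated generative model, not clinical performance.

## Segmentation network

A fully convolutional encoder–decoder (U-net) over single-sample
`(C, D, H, W)` tensors:

- per resolution level, a residual block `conv3³–IN–ReLU–conv3³–IN` plus
  a (projected) shortcut with ReLU on the sum;
- 2× average pooling between encoder levels, nearest-neighbour upsampling
  and skip concatenation in the decoder;
- **instance normalization** throughout (per-sample, per-channel,
  ε = 1e-5), appropriate for batch size 1;
- a 1³ convolution head to 5 classes (background, left thalamus, right
  thalamus, other deep gray matter, remaining intracranial volume), with
  channel-axis softmax.

The clinical-scale configuration is 160³ patches with four reductions
(bottleneck 10³); the desk-scale configuration used everywhere in the
tests is 32³ patches, two reductions, 8 base channels (~120k parameters).
The architecture is identical up to these dials, and all shape/
normalization contracts are tested at the reduced scale.

The network is implemented directly in numpy: im2col convolutions (the
heavy products go through BLAS), hand-derived backward passes (verified
against central finite differences at 1e-5 relative tolerance in the
tests), and Adam. On one CPU core a 32³ forward+backward pass takes
~0.4 s.

### Loss and training schedule

The loss is an equal-weighted sum of voxel-wise cross-entropy and a soft
Dice term `1 − mean_c D_c` over the four foreground classes
(`D_c = (2Σp·t + ε)/(Σp + Σt + ε)`, ε = 1e-6). Cross-entropy anchors the
dominant background/TIV classes; the Dice term keeps gradients alive for
the small thalamic structures (~0.4% of the volume).

Training is a two-stage schedule: stage 1 with full augmentation at
lr 1e-3, stage 2 fine-tuning at lr 2e-4 (both Adam, β = (0.9, 0.999)).
Samples are augmented on the fly with a seed derived per (epoch, sample),
making runs bit-reproducible. Patches are random crops: 75% centred near
the foreground bounding box with jitter of ± half a patch, 25% uniform
over the grid — the uniform fraction is essential so that
background-dominant tiles at the volume rim stay in-distribution for
whole-volume inference. Inputs are z-scored per volume, which removes the
global intensity scale (the augmentation and scanner profiles still vary
bias, contrast and noise).

### Augmentation

Per sample: rotation (±10° per plane; exact quarter-turns use lossless
axis permutations), a midsagittal flip with probability 0.5 — which swaps
the left/right thalamus labels, the only anatomically valid flip — a
multiplicative bias field (amplitude uniform in [0, 0.4], correlation
length 40 mm) and additive Gaussian noise (std uniform in [0, 6] intensity
units). Geometric transforms are applied identically to image (linear) and
labels (nearest); intensity transforms never touch labels. The exact
bias-field family and parameter ranges are design choices of this package.

The random intensity fields are sampled in the array frame; consequently
flip-equivariance is exact for the label pathway and for geometric
transforms, but image-side equality of "flip then augment" and "augment
then flip" would require mirror-symmetric noise fields and holds only in
distribution. The tests assert the exact parts.

### Inference

Patches tile the volume with 50% overlap (plus a final patch flush with
each edge); overlapping softmax scores are blended with a Gaussian window
(σ = patch/4, floored at 1e-4) before the argmax. Ties in the argmax
resolve to the lowest class index for determinism. Volumes smaller than
one patch are symmetrically padded and the padding is recorded in the
result log. Volumes: `volume_k = count(label k) × voxel volume / 1000`,
`THALV = left + right thalamus`, `TIV = Σ_{k≥1} volume_k`.

## Agreement metrics

- **Dice**: `2|A∩B|/(|A|+|B|)`; defined as 1 with a warning when both
  masks are empty. Verified against a brute-force set-count oracle on
  random 8³ masks.
- **Hausdorff**: classic symmetric maximum of directed distances between
  boundary voxel sets (boundary = mask voxels with a face neighbour
  outside), in mm via the voxel spacing; the 95th-percentile variant is
  deliberately not substituted. Undefined (error) for empty masks.
- **Bland–Altman**: mean and std (ddof 1) of differences test−reference,
  limits of agreement mean ± 1.96·std, and the Pearson correlation of the
  differences against the reference volumes (volume-dependence of the
  offset).

## Stability analysis

For a single subject scanned on many scanners: intra-scanner residuals are
deviations from the mean of the same scanner's repeats, pooled over all
scans (length = total scans; singleton groups contribute an exact zero,
keeping the bookkeeping length); inter-scanner residuals are per-scanner
means minus the grand mean of scanner means (length = number of
scanners). Both are zero-mean by construction (asserted to 1e-9 mL).

Group-mean subtraction makes the raw pooled intra std biased low by
`√(1−1/m)` for m repeats, and the spread of scanner means contains an
`σ_intra²/m` leakage term. The report therefore carries both the raw
construction and corrected estimators: the pooled unbiased within-group
std (ddof = N − #groups) and `√(max(var(means) − σ̂_intra²·mean(1/m), 0))`.
The recovery tests use the corrected estimators; the raw values are what
the classic residual-vector construction prints.

Dispersion comparisons use the classic mean-centred Levene W with an F
reference (via scipy), with two documented degeneracies: both groups
constant → (0, 1) with a warning; within-group deviations constant but
unequal between groups → (∞, 0). Pairwise comparisons are reported against
a Bonferroni threshold α/#comparisons (0.05/3 ≈ 0.017 for three methods).
Percentiles of absolute residuals (50th, 95th) use linear interpolation
between order statistics, and the method is recorded in the report.

The dimensionless ratio inter-scanner std / between-subject std summarizes
how much of a normative band is consumed by scanner effects (e.g.
0.28/0.88 ≈ 0.32 versus 0.62/1.09 ≈ 0.57 and 0.63/1.15 ≈ 0.55 for the
three volumetry methods' published spreads).

## Normative model and detection

The normative fit is ordinary least squares on the 6-column design
`(TIV², age², TIV·age, TIV, age, 1)` — age and TIV enter untransformed so
the coefficients stay in the conventional parameterization. Exactly two
fits are performed: after the first, records with residuals outside the
Tukey fences (quartiles ± 1.5·IQR, linear-interpolation quartiles) are
excluded, and the model is refitted once on the rest. σ_norm is the std
(ddof 1) of the second fit's residuals over retained records. The design
is collinear in its raw parameterization, so tests compare fitted surfaces
(predictions), not raw coefficients, against a direct normal-equations
oracle; rank deficiency (e.g. constant age) raises a named error.

Detection is one-sided (volume *reduction*): with `z = 1.96` (the quoted
95% convention; no t-quantile is substituted),

    reduced  ⇔  resTHALV + z·σ_scanner < −z·σ_norm   (strict inequality).

`σ_scanner` is supplied by the caller — typically the inter-scanner std
from a traveling-subject study — rather than hard-coded, so the rule
generalizes to any measurement pipeline. The two-sample form is strictly
more conservative than the one-sample rule (σ_scanner = 0), is monotone in
both arguments, and on healthy cohorts flags at most the one-sided tail
`P(Z < −z − z·σ_scanner/σ_norm)` ≈ 1% at the default spreads (≤ 2.5%
asserted over replicates). Only the upper edge of the patient CI is
compared against the lower normal bound (the literal one-sided reading).

## Reference experiment and problem sizes

The package's accuracy benchmark trains the reduced network (32³ patches,
depth 2, 8 base channels, 14 + 4 epochs, ~5–6 min on one CPU) on 40
phantoms (64³, 1 mm) rendered under random scanner profiles with full
augmentation, then evaluates mean bilateral-thalamus Dice on 10 held-out
phantoms with unseen anatomy seeds *and* unseen scanner profiles. These
sizes are the package's desk-scale reference configuration; the same code
scales to the clinical configuration by changing the dials.

## Known limitations

- The ellipsoidal anatomy gives the network a strong positional cue that
  is inherently robust to intensity transforms. A consequence: the
  across-profile THALV spread of an augmentation-trained network is not
  reliably lower than that of a geometrically-augmented-only network at
  desk scale — `run_robustness_experiment` reports both spreads, and the
  test suite asserts only the well-posed contracts of that experiment. On
  real anatomy, where intensity cues matter more, the augmentation benefit
  is expected to be larger; the synthetic setting cannot demonstrate it.
- Dice on structures of ~1100 voxels saturates well below 1 even for
  sub-voxel-accurate boundaries; held-out values of ~0.9 at this scale are
  near the discretization ceiling.
- The corrected inter-scanner estimator clips at zero when the intra
  leakage exceeds the raw spread (small-sample effect).
- Training-time held-out Dice in the history log is evaluated on a single
  centred patch per validation sample (cheap proxy); final evaluation
  always uses full tiled inference.
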