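# thalseg

Scanner-robust thalamus volumetry for T1w-like 3D MRI, end to end and
fully testable without any data downloads.

Thalamus atrophy is an early, clinically meaningful imaging marker (for
example in multiple sclerosis), but automatic volumetry pipelines are
sensitive to the MRI scanner and protocol: the same head yields different
volumes on different scanners, which erodes the usable range of any
normative database shared across sites. `thalseg` implements the full
chain needed to build and evaluate a scanner-robust pipeline:

- **`thalseg.phantom`** — labeled synthetic head phantoms (left/right
  thalamus, other deep gray matter, intracranial compartment) rendered
  under parameterized scanner appearance (bias field, noise, scale,
  contrast), plus tabular cohort simulation with explicit between-subject,
  inter-scanner and intra-scanner variance components.
- **`thalseg.segmenter`** — `ThalamusSegmenter`, a scikit-learn-style
  estimator wrapping a patch-based 3D residual encoder–decoder
  (instance normalization, five-class output) with a cross-entropy +
  soft-Dice loss, two-stage training, and overlapping-patch inference
  with Gaussian score blending. The network and its backpropagation are
  implemented in pure numpy — no deep-learning framework required.
- **`thalseg.augment`** — training-time augmentation: random
  multiplicative bias fields, additive noise, small rotations, and the
  midsagittal flip with the left/right label swap.
- **`thalseg.metrics`** — Dice, Hausdorff distance (mm), Bland–Altman
  agreement statistics.
- **`thalseg.stability`** — intra-/inter-scanner residual analysis for
  traveling-subject studies: pooled residual vectors, stds and
  percentiles, Levene variance tests with Bonferroni thresholds.
- **`thalseg.normative`** — `NormativeThalamusModel`: the quadratic
  THALV–TIV–age normative fit with two-step Tukey outlier exclusion,
  and the two-sample rule flagging significantly reduced thalamus volume
  in a single subject.

## The model in brief

Normative volumetry regresses bilateral thalamus volume (THALV, mL) on
total intracranial volume (TIV, mL) and age (years):

    THALV = a·TIV² + b·age² + c·TIV·age + d·TIV + e·age + f

fitted by least squares in a normal database; after a first fit, records
outside the Tukey fences (quartiles ± 1.5·IQR of the residuals) are
dropped and the model refitted once. With σ_norm the residual std of the
final fit and σ_scanner the inter-scanner std of the measurement (from a
traveling-subject study), a patient's residual resTHALV is called
**reduced** when

    resTHALV + 1.96·σ_scanner < −1.96·σ_norm ,

i.e. the patient's own 95% CI lies entirely below the normal 95% band —
a two-sample rule, deliberately more conservative than comparing the
point estimate. The ratio σ_scanner/σ_norm measures how much of the
normative band scanner effects consume; lowering it is the whole point of
scanner-robust segmentation.

## Worked example

```python
from thalseg import (CohortParams, make_cohort, make_travel_sessions,
                     fit_normative, stability_report, variability_ratio)

# a traveling-subject study: 123 scanners, 3-5 repeats each
travel = make_travel_sessions(123, (3, 5), sigma_intra=0.08,
                              sigma_inter=0.28, seed=1)
rep = stability_report(travel)

# a normal database: 4872 subjects on 160 scanners
normals = make_cohort(CohortParams(seed=2))
model = fit_normative(normals)

d = model.detect_reduced(-2.5, sigma_scanner=rep.inter_std_corrected)
```

prints (via the obvious format strings):

```
485 scans on 123 scanners
intra-scanner std 0.069 mL (corrected 0.079)
inter-scanner std 0.250 mL (corrected 0.247)
sigma_norm 0.898 mL from 4834 records (38 outliers removed)
normal band (-1.760, 1.760) mL
variability ratio 0.27
patient resTHALV -2.5 mL -> reduced: True (margin 0.257 mL)
```

Reading this: the pooled intra-scanner residual std (0.069 mL) is biased
low by the group-mean subtraction; the corrected estimator recovers the
configured 0.08 mL. The fitted normative spread (0.898 mL) recovers the
configured between-subject 0.88 mL up to the outlier trim. A patient
2.5 mL below the normative surface is flagged as reduced even after
granting the measurement its full inter-scanner uncertainty.

The segmentation side has the same shape:

```python
from thalseg import PhantomSpec, ScannerProfile, make_phantom, ThalamusSegmenter
from thalseg.benchmark import default_augment

pairs = [make_phantom(PhantomSpec(), ScannerProfile(), seed=s) for s in range(40)]
est = ThalamusSegmenter(augment=default_augment(), random_state=0)
est.fit([v for v, _, _ in pairs], [l for _, l, _ in pairs])
result = est.predict(pairs[0][0])
print(result.volumes["THALV"])   # mL, from label counts on the 1-mm grid
```

A command-line interface mirrors the library:
`thalseg phantom`, `thalseg cohort`, `thalseg convert`, `thalseg train`,
`thalseg segment`, `thalseg evaluate`, `thalseg stability`,
`thalseg normative fit/detect`. Run `thalseg --help` for details.

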