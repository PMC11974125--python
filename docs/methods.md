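# Methods

This note records the models, parameter choices and numerical conventions
behind `ctoam`, and what the synthetic validation does and does not
establish about real data.

## The measurement model

CTOAM treats the subchondral bone plate as a thin shell whose mineral
density field is observed through CT attenuation. The chain is:

```
HU volume ──segment──> bone mask ──ray cast──> surface + plate (≤ depth)
          ──project──> MIP / mean maps ──quantize──> 8-bit, 8 bins, 10 colours
          ──calibrate──> mg HA/cm³ summaries ──pair──> cohort statistics
```

Assumptions: attenuation is affine in mineral density over the calibrated
range (standard single-energy QCT); the plate is at least as thick as the
projection depth, so plate samples do not leak into trabecular bone at
normal incidence; views are axis-aligned so ray casting along a volume axis
is exact.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| segmentation threshold | 200 | HU | floor of the densitogram display window; well above soft tissue (≈ 40 HU), below all mineralised classes |
| MIP depth | 1.5 | mm | the subchondral plate thickness being projected |
| display window | 200–1200 | HU | the densitogram's dynamic range; quantization and colours operate inside it |
| bins | 8 × 32 levels | — | density maxima are the top two bins (≥ level 192) |
| grid | 30 × 30 | — | standardised maxima coordinates across individuals |
| alpha | 0.05 | — | significance level of the paired *t*-test |

Depth is measured in mm along the ray from the surface-voxel centre,
inclusively: with 0.3 mm sampling, 1.5 mm keeps the surface sample plus
five beyond it; at 0.5 mm spacing it keeps four layers. Depth is computed
in native grid steps per axis (exact for axis-aligned views at any
spacing, isotropic or not); no trilinear resampling is performed.

### Quantization conventions

8-bit level = `round(255 · clip((HU − 200)/1000, 0, 1))`, rounding half
away from zero; out-of-window values clip to the end levels. Level 255
stays in bin 7, so the bins are {0–31, …, 224–255}. Colour class =
`floor((HU − 200)/100)` after clipping HU into `[200, 1200)`, giving ten
classes; class 9 (1100–1200 HU) renders black and class 0 (200–300 HU)
white. MAR is an exact integer count ratio. The 30 × 30 grid cell is
`1 + floor(30 · (pixel − bbox_min)/bbox_extent)` per axis over the tight
bounding box of the joint surface, clipped to 30.

### Which "mean density" is reported

A MIP pixel is the maximum of several noisy samples, so the surface mean of
the MIP map is biased upward by construction (≈ +1.3 σ of the HU noise for
4–6 samples per ray). The package therefore reports **two** surface means
per view: `mean_density`, the surface average of the per-ray *mean* map
(unbiased for plate density under symmetric noise; the headline endpoint
used in paired tests and parameter recovery), and `mip_mean_density`, the
surface average of the MIP map (the projection's traditional readout).
Both appear in every summary and report table, along with the calibrated
maximum of the MIP map.

## The synthetic phantom

### Geometry

A block base carries two parallel half-capsule ridges (axis dorsoplantar,
spherical cap at the dorsal end) standing in for the medial and lateral
trochlear ridges. Defaults: 6 mm ridge radius, 14 mm separation, 24 mm
length, on a 64³ grid at 0.5 mm isotropic spacing. The plate is the bone
shell within 2.0 mm (Euclidean distance) of the background — deliberately
thicker than the 1.5 mm projection depth so that plate rays do not dip
into trabecular bone. Cylindrical calibration inserts (0, 400,
800 mg HA/cm³) sit in the soft-tissue background below the bone.

### Densities (mg HA/cm³) and the study conditions

| structure | default | source of the value |
|---|---|---|
| contralateral plate base | 780.7 ± 39.8 between dogs | cohort result for the contralateral trochlear ridge |
| affected plate base | 720.7 (= 780.7 − 60) | not printed in the study; chosen once so the affected joint is globally less dense, as observed |
| lesion core | 612.6 ± 88.4 between dogs | cohort result for the lesion mean |
| lesion rim | 1000 | sclerotic rim; must reach the two highest bins (> ≈ 951 HU under identity calibration) to reproduce the "ring of increased density" phenotype |
| physiological peaks | +200 amplitude, σ = 2 mm | focal maxima at the proximal-medial and distal-lateral ridge positions; σ kept small so the peaks perturb the surface mean by ≈ +15 HU while remaining detectable density maxima |
| trabecular interior | 400 | typical cancellous bone |
| soft-tissue background | 40 HU | water-adjacent soft tissue |
| HU noise | 15 HU SD, additive Gaussian | plausible CT noise; a config knob, not a claim |

The density field is converted to HU by inverting the configured affine
calibration (default identity), so applying the true calibration to the
noiseless HU field recovers the density field exactly — the basis of the
calibration-exactness tests. Lesion densities override peak contributions
inside the lesion (the affected medial peak site is where the lesion
sits). Between-dog variation is Normal on the contralateral plate base and
the lesion core; the affected plate base tracks the contralateral minus the
bilateral offset. Per-volume and per-dog random streams are keyed by
(dog, side, timepoint) CRC32 into `numpy.random.SeedSequence` substreams,
so cohorts are reproducible and stable under reordering.

Follow-up timepoints raise the contralateral plate by 30 mg HA/cm³ and
shrink the lesion core–rim contrast (+40 core / −40 rim per step),
emulating the longitudinal pattern after treatment; the magnitudes are
package choices, as the study reports directions, not magnitudes.

### What the phantom does *not* emulate

Real talar shape, cartilage, beam hardening, scatter, metal or motion
artifacts, scanner point-spread blurring, and spatially correlated noise.
Passing tests show the *operators* are correct (projection depths, bin
arithmetic, calibration recovery, paired statistics) and that the pipeline
recovers known densities through realistic noise; they do not certify
segmentation quality on anatomically complex scans, where threshold choice
and bone separation are the operator's responsibility.

## Numerical and degenerate-case policy

- Segmentation: 26-connectivity; component-size ties break to the lowest
  label; holes ≤ 3 voxels are filled; an all-sub-threshold volume raises.
- Calibration: exact two-point solution for two inserts, OLS beyond;
  coincident insert HU or a non-positive fitted slope raises; negative
  calibrated densities are allowed numerically and logged.
- Quantization on an empty surface is rejected; an empty density maximum is
  valid (MAR 0, no regions).
- Paired test: differences with zero variance are reported as degenerate
  (t = 0, p = 1 for identical lists; t = ±∞, p = 0 otherwise) with a flag
  rather than raising; Shapiro–Wilk requires n ≥ 3 and non-constant
  differences, otherwise its fields are null; non-normality sets a warning
  flag but never switches the test.
- All pipeline randomness flows from one seed; CSV/JSON outputs are
  byte-identical across reruns of the same config.

## Validation problem sizes

Parameter recovery uses 20 replicate 8-dog cohorts of 64³ phantoms
(320 volumes, ≈ 25 s total); the power/type-I properties use 200
summary-level simulated cohorts; the density-maximum extractor is checked
against a brute-force flood-fill oracle on 100 random ≤ 32 × 32 maps. The
8-dog, two-group conditions (612.6 ± 88.4 vs 780.7 ± 39.8) give the paired
*t*-test essentially full power, consistent with the strongly significant
difference the cohort reported.

## Known limitations

- The dorsal view of the stylised phantom sees the ridge end-caps and base
  wall; its surface is less informative than a real dorsal trochlear view,
  so dorsal-view behaviour is exercised structurally rather than
  anatomically.
- `read_dicom_series` assumes a single axial series with uniform slice
  spacing and applies rescale slope/intercept only.
- Arbitrary oblique views (beyond the two axis-aligned standard views) are
  not implemented; the "approximately 90°" dorsal rotation is exact here.
- Which scalar (per-ray mean vs MIP mean, which view) entered the study's
  printed *t*-test is not stated; the package defaults to the per-ray mean
  averaged over both views and reports all variants.
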