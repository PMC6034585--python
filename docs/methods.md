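# Methods

## Scientific setting

After unilateral perinatal arterial ischemic stroke, white matter (WM) in the
lesioned hemisphere myelinates less than in the healthy hemisphere. Because
myelin brightens T1-weighted MRI, the inter-hemispheric difference in raw
T1 WM intensity is a usable myelination biomarker — provided intensities are
*not* bias-corrected (automated correction alters voxel values), and scanner
inhomogeneity is instead controlled by comparing the two hemispheres within
each subject. `myelomap` implements two complementary quantifications plus the
cohort statistics around them, and a phantom generator that plants known
regional intensities so every estimate can be validated against ground truth.

## Region classification

Given an integer parcellation, a lookup table with per-region hemisphere and
homologue, and a binary lesion mask on the same grid, regions are classed as:

- **perilesional** — at least one region voxel *outside* the lesion is a
  voxel-space neighbour of a lesion voxel. "Directly touching" is
  operationalized as 26-connectivity by default (face, edge or corner contact
  — the most inclusive reading), configurable to 6 or 18. Perilesional extent
  is the full parcel: no dilation ring or distance band is applied, so the
  distal border comes from the segmentation itself.
- **lesion_overlap** — ≥ 50% of the region's voxels fall inside the lesion
  (`overlap_fraction`, tunable). These parcels are mostly destroyed and are
  excluded from intensity scoring. Below the cutoff, the surviving voxels are
  scored and the region is perilesional (it necessarily touches the lesion).
- **ipsilesional_remote** — same hemisphere, no contact.
- **contralesional_homologue** — the mirror counterpart of each remote region
  (exact bijection, asserted on every run).
- **contralesional_other** — the residue (homologues of perilesional or
  overlapped parcels), kept so region sets always partition each hemisphere.

The lesion hemisphere is taken from the lesion centroid relative to the
midline; a lesion with voxels on both sides of the midsagittal plane is an
error, as is an empty lesion (controls bypass classification). The midline
convention everywhere: axis 0 is left–right and the midsagittal plane sits
between the two central voxel columns, so reflection is exact on even grids.
When a lookup table supplies a hemisphere for a label it takes precedence
over voxel position (logged when they disagree).

## Regional intensity and asymmetry ratios

Per region, the mean and SD of raw intensity over (region ∩ WM mask) \ lesion.
The WM restriction comes from the tissue mask, not from assuming the
parcellation is WM-only. Regions with no surviving WM voxels are dropped with
a warning, never reported as zero.

The hemispheric asymmetry ratio is

    ratio = mean WM intensity (contralesional) / mean WM intensity (ipsilesional)

with lesion and lesion-overlap parcels excluded; ratio > 1 means the lesioned
hemisphere is darker, i.e. hypomyelinated. A secondary ratio divides the
contralesional-homologue class mean by the ipsilesional-remote class mean.
Hemisphere aggregation is voxel-weighted by default (equivalent to pooling
all scored voxels — an identity asserted in the tests); an unweighted
parcel-mean variant is available behind `weighted=False` because the choice
is not determined by the design. Controls run the same machinery as
right / left. Ratios are scale-invariant and strictly monotone in
ipsilesional attenuation (property-tested).

## Threshold sweep

The parcellation-free score. Intensities are first linearly quantized over
brain voxels to integer levels 1–255 (per volume, not per slice; a constant
volume maps to 128). Lesion voxels are removed from the WM masks *and* from
the quantization range — otherwise editing lesion intensities would shift
every level, violating lesion-exclusion exactness.

Starting from the most inferior axial slice with at least
`min_visible_pixels` WM pixels in each hemisphere, each slice is swept: the
bilateral threshold T* is the highest level t such that at least
`min_bilateral_pixels` WM pixels in *each* hemisphere satisfy I ≥ t; the
cutoff is T* + 1 and every WM pixel at or above it counts as positive. The
comparison at the threshold is inclusive (ImageJ-style boundary inclusion),
which is why the cutoff is exactly one level above T*. With
`min_bilateral_pixels = 1` (the default — positives "first appear"
bilaterally at T*) the count equals the number of WM pixels strictly brighter
than the dimmer hemisphere's maximum, a closed form used as an oracle; the
general case is checked against enumeration of all 255 levels. The default of
1 is noise-sensitive (a single hot voxel moves T*), hence the flag.

Slices where one hemisphere has too few WM pixels above the start slice score
0 with a warning; the total score is the sum of per-slice counts from the
start slice to the top of the volume (no superior stopping rule). Scores are
raw pixel counts, not normalized by brain volume (a normalization flag exists
for cross-resolution use). Lesion and brain volumetry use mask voxel counts ×
voxel volume over every slice; anisotropic voxels affect volumetry only.
Re-running on the same volume is bit-identical — the computational analogue
of intra-rater repeat scoring, whose agreement the ICC quantifies.

## Phantom generator

The generator emulates exactly what the analysis consumes: two mirrored
hemispheres of parcellated WM (axis-aligned blocks stacked along the axial
axis — adjacency to a lesion is then fully controllable), a grey-matter shell
and CSF rim, an optional spherical lesion confined to one hemisphere, and WM
intensity planted per region as base + hemisphere offset + region delta −
class attenuation on a 0–255 scale. A planted intensity outside [0, 255]
raises rather than clipping silently. Degradations: i.i.d. additive Gaussian
noise on brain voxels (`noise_sd`) and an optional smooth multiplicative
quadratic bias field, modelling B1/coil inhomogeneity. With both disabled,
region means equal their planted values exactly and a lesion-free phantom is
exactly mirror-symmetric.

Presets encode the observed group structure:

- control: WM base 117.13, right-hemisphere offset +5.11 → planted hemisphere
  means 122.24 / 117.13; `noise_sd = 5`.
- stroke: left-hemisphere sphere (radius 9 mm) with attenuations planting
  class means 86.33 (perilesional), 94.06 (remote), 100.96 (contralesional);
  lesion intensity 45 (dark infarct); `noise_sd = 5`.

GM (80), CSF (40) and lesion (45) intensities, the lesion radius, and
`noise_sd = 5` are modelling choices, not reported quantities: they give
T1-plausible tissue contrast and an SNR at which the planted ordering is
comfortably but not trivially recoverable at the studied cohort sizes
(n = 20 stroke / 27 control). Between-subject variance defaults to voxel
noise only; a per-subject WM offset (`subject_offset_sd`) exists because the
real variance decomposition (region- vs subject-level) is unknown, and
defaults to 0.

What the phantom does **not** emulate: cortical folding, partial-volume
effects, MR acquisition physics, spatially structured lesions, or the joint
distribution linking the two scores to clinical outcomes. A green
planted-recovery test therefore establishes that the pipeline measures what
was planted — not that the biological effect sizes are reproduced from real
images.

## Statistics

- Mixed-design repeated-measures ANOVA (between = group, within = region
  class) via pingouin, with Greenhouse–Geisser correction applied when
  sphericity is rejected; falls back to one-way RM-ANOVA for a single group.
  Shapiro–Wilk is screened per cell and violations warn rather than abort.
  Pairwise location contrasts are Bonferroni-adjusted.
- Two-sample t-tests with mean difference and 95% CI; Welch fallback when a
  group variance degenerates; two identical groups report p = 1 rather than
  a 0/0 statistic.
- Pearson/Spearman correlations; the partial variant correlates residuals of
  (rank-)regressions on the covariates with n − 2 − k degrees of freedom.
  This matches `pingouin.partial_corr` exactly (cross-checked in tests). Note
  the rank-residual partial Spearman carries a small positive finite-sample
  bias under a shared-covariate null (≈ +0.04 at n = 20, shrinking with n).
- Intra-rater reliability: ICC(A,1) — two-way mixed, absolute agreement,
  single measure — a convention fixed here because the study design does not
  pin down the ICC form.
- Bonferroni: p_adj = min(1, m·p), with the family size logged.
- Missing outcomes are handled complete-case per test, with n reported.

All implemented tests are calibration-checked: simulated type-I error at
α = 0.05 within ±0.02 over 1000 null replicates.

## Outcome scores

Melbourne Assessment: MA% = achieved / possible × 100 (possible defaults to
the instrument's 122 points). Non-motor PSOM = language production +
language comprehension + cognitive/behavioural subscores (each 0–2, total
0–6), dichotomized *poor* iff the total is strictly greater than 1. Robotic
sensorimotor parameters, AHA logits, neuropsychology percentiles and EEG
classifications are consumed as ready-made columns; their computation is out
of scope.

## Numerical and design notes

- Sweep direction: the score counts the *brightest* pixels — those above the
  highest level the dimmer hemisphere reaches — consistent with "values near
  zero ⇒ no asymmetry" and with positives appearing in the brighter
  (typically contralesional) WM. The closed-form oracle makes this choice
  fully testable.
- Quantization is per volume by default; per-slice rescaling would decouple
  slices from a common brightness scale.
- Seeds: cohort-level seeds spawn per-subject seeds deterministically;
  identical spec + seed gives byte-identical outputs, including written CSVs.
- Group comparison uses the raw ratio; a log-ratio analysis is left to the
  caller (ratios near 1, the difference is negligible at these effect sizes).
- All grids of a subject must be voxel-aligned; no resampling is performed.

## Known limitations

Axial-block parcels are geometrically unlike gyral parcellations (fewer,
larger contact surfaces with a lesion). The sweep's bilateral threshold with
`min_bilateral_pixels = 1` is driven by hemisphere maxima and hence
noise-sensitive; raising the floor trades sensitivity for robustness. The
cross-method association between the regional ratio and the sweep score on
phantoms reflects only the shared planted asymmetry, not the empirical
correlation structure of clinical images.
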