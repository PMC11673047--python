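# Methods

`ctharmony` studies a practical problem in quantitative imaging: radiomics
features extracted from CT scans change when the same acquisition is
reconstructed differently (filtered back projection vs. iterative
reconstruction, virtual monoenergetic images at different energies), which
undermines their use as stable biomarkers.  The package implements the full
evaluation loop — synthetic aligned multi-protocol cohorts, a GAN-based
harmonizer that maps every reconstruction toward a reference protocol, a
455-feature radiomics extractor, and ICC-based reproducibility analyses —
so that every stage can be exercised and verified without patient data.

## Synthetic phantom cohorts

Dual-energy CT reconstructions of one acquisition are voxel-aligned by
construction.  The phantom module emulates this: each subject is a labeled
2D abdominal phantom (liver, spleen, kidneys, paraspinal muscles, an aortic
vessel, bowel gas, fat rim, soft-tissue background) rendered once per
protocol as

```
image = blur(base_HU + contrast_gain * enhancement_HU, psf_sigma)
        + noise_sd * filter(shared_noise_field)
```

All protocols of a subject share one noise realisation (re-filtered per
protocol to emulate kernel-dependent noise texture), so pixel-wise
correspondence holds exactly, as in real same-raw-data reconstructions.

Default protocol parameters encode the orderings radiomics actually sees:

| protocol | contrast gain | PSF σ (mm) | noise SD (HU) | noise corr. σ (mm) |
|----------|---------------|------------|----------------|---------------------|
| FBP      | 1.0           | 0.6        | 16             | 0.5                 |
| IR       | 1.0           | 0.9        | 7              | 0.9                 |
| M40      | 2.2           | 0.8        | 13             | 0.7                 |
| M70      | 1.0           | 0.8        | 8              | 0.7                 |

FBP is noisier and sharper than IR; the 40 keV monoenergetic image
amplifies iodine attenuation roughly two-fold relative to 70 keV, modelled
as a gain on the iodine-attributable enhancement map only (no spectral
physics).  Typical portal-phase attenuations are used (liver 60 HU, spleen
50, kidney 40 + 100 enhancement, vessel 50 + 150, muscle 55, fat −100,
air −1000), all configurable.

Between-subject variability has two components: geometric jitter of organ
position/size, and biological spread — each soft-tissue compartment's
attenuation is drawn with SD 8 HU around its mean and the subject's global
iodine level with SD 15 % around unity.  The latter matters: the ICC's
numerator is between-subject variance, so a cohort of identical phantoms
would make every reproducibility analysis degenerate no matter how well
harmonization works.

What the phantom does **not** emulate: anatomical texture heterogeneity
(lesions, vascular trees), beam hardening, scatter, partial-volume effects
at organ boundaries, 3D structure, and inter-scanner geometry differences.
Passing tests therefore demonstrate that the pipeline's machinery behaves
correctly and that harmonization works in the directions expected on
aligned data; they do not certify effect sizes on clinical images.

The default ROI roster mirrors the evaluation design: two liver, two
spleen, two kidney, two muscle ROIs (240 mm² each), one vessel ROI
(120 mm²) and one air ROI, identical in structure across subjects.

## Radiomics features

The 91-feature core follows the IBSI reference definitions in 2D: 18
first-order, 22 co-occurrence (GLCM), 16 run-length (GLRLM), 16 size-zone
(GLSZM), 14 dependence (GLDM) and 5 neighbouring grey-tone difference
(NGTDM) features.  Applying the core to the original image and the four
subbands of a single-level stationary wavelet transform (LL/LH/HL/HH,
default `coif1`) gives 455 features in 30 (image type × class) groups.
Because several co-occurrence rosters of 22–24 features circulate, the
roster here is frozen in `radiomics.MATRIX_CLASSES` as the single source
of truth; deprecated duplicates (sum-average and variants) are omitted to
reach 22.

Numerical conventions, chosen where the field has no single standard and
documented here so results are reproducible:

* **Discretization** — fixed bin width, default 25 HU, with
  `bin(x) = floor(x/w) − floor(min/w) + 1`; the dominant CT convention.
* **First order** — computed on raw HU values; entropy and uniformity use
  the discretized histogram.  Skewness/kurtosis of constant ROIs are 0.
* **GLCM** — four in-plane offsets (0°, 45°, 90°, 135°), symmetric,
  normalized per offset; features computed per offset and averaged.
  Degenerate correlation (zero variance) is defined as 1.
* **GLRLM** — same four directions, runs broken by the mask, features
  averaged over directions.
* **GLSZM** — zones by 8-connectivity.  **GLDM** — dependence size is 1 +
  the number of 8-neighbours with identical grey level (α = 0).
  **NGTDM** — neighbour means over the in-mask 8-neighbourhood.
* **Wavelets** — undecimated transform so subbands keep the image size and
  ROI masks need no resampling; odd dimensions are symmetrically padded
  and cropped back.
* ROIs below 9 pixels yield explicit missing markers, never silent zeros.

Texture builders are verified against independent brute-force enumeration
oracles (plain-loop pair/run/zone/dependence recounting) on random small
ROIs, exactly.

## Harmonization network

The generator is a residual encoder–decoder with hierarchical feature
synthesis at three scales.  Downsampling uses pixel unshuffling — a
lossless space-to-depth permutation — instead of average pooling, so no
spatial information is discarded; each scale's residual blocks apply
spatial attention (a sigmoid gate from the channel-pooled map) followed by
channel attention (squeeze-and-excite), sequentially; features from every
scale are pixel-shuffled back to full resolution, concatenated and fused
before a zero-initialized output head.  The generator therefore starts as
an exact identity and learns a correction — the natural parameterisation
for a near-identity mapping.  The discriminator is U-Net-style, returning
a global realness scalar from the bottleneck and a per-pixel realness map
from a skip-connected decoder; both heads enter least-squares adversarial
terms with equal weight.

Training pairs a random non-target protocol patch with the
iterative-reconstruction patch at the same location.  Loss weights default
to 100·L1 + 100·L2 + 1·adversarial.  The quadratic term is deliberate: the
L1 gradient has constant magnitude per pixel, so the rare, large errors
that define the monoenergetic iodine mapping (a few hundred HU over ~1 %
of pixels) would be corrected too slowly within a short training budget.
Patch sampling is likewise biased: half the patches are centred on
enhancing tissue (source intensity > 150 HU) and the rest are drawn from
the body, because uniform sampling spends most patches on air.

Inference is tiled at the training patch size with half-patch overlap and
raised-cosine blending of the predicted *corrections*.  Tiling is not an
optimisation: the attention gates pool over their input window, so the
generator must see inference inputs with training-patch statistics —
whole-image inputs (half air) measurably break the learned mapping.
Blending corrections rather than outputs preserves the exact-identity
property of an untrained generator.  Outputs are clamped to
[−1100, 3000] HU.

Desk-scale defaults: 64×64 patches, batch 4, 500 alternating steps, Adam
at 2.5·10⁻³, HU scaled by 1/400.  All randomness flows from the spec seed;
training is bit-reproducible on CPU.  No pretrained weights are shipped.

## Reproducibility analyses

Protocols act as raters.  For each feature an n×k matrix feeds a two-way
ANOVA ICC; the default form is two-way random, single measurement,
**absolute agreement** (ICC(2,1)) — harmonization targets equality of
values across protocols, not mere rank agreement — with two-way
consistency (ICC(3,1)) as a config option.  95 % confidence intervals use
the standard F-based constructions (exact for consistency; the
Satterthwaite approximation for agreement).  The implementation is checked
against a brute-force ANOVA oracle and against `pingouin` where available.
All-identical matrices (possible for constant features on synthetic air)
return a "degenerate, reproducible" sentinel of 1: identical measurements
are perfectly reproducible by any reading.  A feature is reproducible when
ICC ≥ 0.85.

* **Region-based analysis** — subjects are patients; one ICC per (ROI,
  feature).  For organs with two ROIs a feature counts only if it passes
  in both.  Output mirrors a per-organ table of counts/percentages for the
  original and harmonized arms and the increase.
* **Patient-based analysis** — each patient's ROIs are the subjects; one
  ICC per (patient, feature).  Reported as per-patient reproducible-feature
  counts (mean ± SD), the mean per-patient gain, and patients × features
  ICC heatmaps.
* **Redundancy exclusion** — a group (image type × class) is flagged in
  stage 1 if, in the training cohort, more than half of its features reach
  ICC ≥ 0.85 in every ROI (such features do not sense protocol differences
  and would inflate reproducibility claims); stage 2 excludes a flagged
  group if more than half of external patients individually satisfy the
  same majority rule.  Both comparisons are strict.  Summary percentages
  use the retained-feature denominator.

A note on the two ICC forms: agreement ≤ consistency holds whenever the
rater mean-square is at least the residual mean-square; with negligible
rater bias and negative numerators the order can flip, so the package does
not assert the inequality unconditionally.

## Standard-deviation maps

For a k-protocol stack, all C(k,2) signed pairwise difference images are
formed in fixed lexicographic order and the per-pixel standard deviation
across them is the disagreement map; four protocols give six differences.
The population convention (divide by the number of pairs) is the default
since the pairs are a complete enumeration, not a sample; a config switch
selects the sample convention.  Display windowing defaults to width 300 /
level 40 HU.  Maps are computed on the full image with an optional body
mask; the pipeline reports body-masked means (outside the body every
protocol agrees on air, which would dilute the statistic).

## Experiment driver and problem sizes

`run_experiment` chains simulate → train → harmonize → extract →
redundancy exclusion → region and patient analyses → std maps → report,
persisting every stage's artifacts (CSV/JSON/PNG) so each report value is
recomputable from disk.  The default desk-scale configuration is 8
training and 8 external subjects at 256×256 / 1 mm with 500 training
steps — small enough to run in minutes on one CPU core while leaving every
directional effect (lower held-out L1 against the target protocol, positive
mean per-patient ICC gain, lower std-map means) clearly measurable.  A
512×512 / 3 mm preset mirrors full-resolution geometry for real data.

## Known limitations

* The harmonizer is trained per cohort at desk scale; no claim is made
  that its weights transfer across scanners or match any published model.
* Effect sizes on synthetic cohorts are not comparable to clinical
  percentages; only directions are meaningful, and single-ROI organs
  (vessel, air) give noisy region-based counts at n = 8–20.
* 2D only; no shape features; no resampling machinery beyond the ROI crop;
  DICOM input must already be pixel-aligned (no registration).
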