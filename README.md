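# ctharmony

Radiomics features — the hundreds of intensity and texture descriptors
extracted from CT images for predictive modelling — are notoriously
sensitive to how a scan is reconstructed.  The same dual-energy abdominal
acquisition reconstructed with filtered back projection (FBP), iterative
reconstruction (IR), or as 40/70 keV virtual monoenergetic images (M40,
M70) yields systematically different feature values, which breaks
cross-protocol and cross-site studies.  `ctharmony` is a tested pipeline
for quantifying that problem and for evaluating a deep-learning fix: a
GAN harmonizer that maps every reconstruction toward the IR reference, so
features extracted afterwards agree across protocols.

It is intended for imaging researchers who want a fully verifiable,
CPU-scale testbed for protocol-harmonization experiments: every stage runs
on built-in synthetic phantom cohorts whose ground truth is known exactly,
and the same interfaces accept real NIfTI/DICOM stacks.

The pipeline:

1. **Phantom cohorts** — pixel-aligned multi-protocol abdominal slices
   (one shared noise realisation per subject, protocol-specific contrast
   gain, kernel blur and noise magnitude) with a 10-ROI roster: 2 liver,
   2 spleen, 2 kidney, 2 muscle, 1 vessel, 1 air.
2. **Harmonizer** — a hierarchical-feature-synthesis generator (pixel
   unshuffling instead of pooling, sequential spatial→channel attention,
   residual output) against a U-Net discriminator with scalar and
   per-pixel realness heads, trained with L1+L2 reconstruction and
   least-squares adversarial losses toward the IR image.
3. **Radiomics** — 455 features = 91 IBSI-style core features (18
   first-order, 22 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM) ×
   {original image + 4 stationary-wavelet subbands}, i.e. 30 feature
   groups.
4. **Reproducibility** — two-way ANOVA intraclass correlation with
   protocols as raters:
   `ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE))`,
   threshold 0.85; region-based (subjects = patients, both-ROI rule for
   paired organs) and patient-based (subjects = each patient's ROIs)
   analyses, plus a two-stage redundancy-group exclusion (the four
   canonical redundant groups leave 387 of 455 features).
5. **Std maps** — per-pixel standard deviation over the C(k,2)=6 pairwise
   protocol differences, the visual measure of residual disagreement.

## Worked example

```python
from ctharmony import ExperimentConfig, run_experiment

bundle = run_experiment(ExperimentConfig(n_train=8, n_external=8, seed=1),
                        out_dir="results/demo")
print(bundle.region.table[["organ", "pct_original", "pct_harmonized"]])
print(f"mean per-patient reproducible features: "
      f"{bundle.patient.mean_original:.1f} -> {bundle.patient.mean_harmonized:.1f} "
      f"(gain {bundle.patient.mean_gain:+.1f})")
print(f"std-map mean: {bundle.stdmap_mean_original:.2f} -> "
      f"{bundle.stdmap_mean_harmonized:.2f} HU")
```

On the fixed-seed desk-scale run above this prints:

```
 organ  pct_original  pct_harmonized
 liver      0.219780        0.439560
spleen      0.439560        0.439560
vessel      0.219780        0.000000
kidney      0.219780        0.439560
muscle      2.637363        5.494505
   air      9.230769       13.186813
mean per-patient reproducible features: 37.9 -> 73.9 (gain +36.0)
std-map mean: 14.26 -> 5.37 HU
```

Reading the numbers: with only eight synthetic patients the per-organ
percentages are coarse (each feature is ±0.22 %), but the aggregate
effects are unambiguous — harmonization roughly doubles the number of
reproducible (ICC ≥ 0.85) features per patient and cuts the mean
inter-protocol disagreement map by more than half.  Magnitudes are
specific to the synthetic conditions; the directions are the result.

The same stages are available as a CLI for on-disk workflows:

```bash
ctharmony simulate --n-subjects 8 --seed 1 --out-dir cohort/
ctharmony train --cohort-dir cohort/ --target IR --model-out model.pkl
ctharmony harmonize --model model.pkl --stack-dir cohort/subject_000 --out-dir harm/
ctharmony extract --stack-dir cohort/subject_000 --roi-file cohort/subject_000/rois.json --out feats.csv
ctharmony stdmap --stack-dir cohort/subject_000 --out sd.png --window 300 --level 40
ctharmony run-all --n-train 8 --n-external 8 --seed 1 --out-dir results/
```

## Layout

```
src/ctharmony/
  phantom.py          synthetic aligned multi-protocol cohorts + ROIs
  radiomics.py        455-feature schema, wavelets, texture matrices
  reproducibility.py  ICC, region/patient analyses, redundancy exclusion
  nn.py               numpy reverse-mode autodiff (conv, attention ops, Adam)
  harmonizer.py       generator/discriminator, training, tiled inference
  stdmap.py           pairwise-difference std maps, display windowing
  io.py               NIfTI/DICOM/CSV/JSON I/O
  pipeline.py         end-to-end experiment driver
  cli.py              click command-line interface
docs/methods.md       model, conventions, parameter rationale, limitations
```
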