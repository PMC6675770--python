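# chromosep

Objective, endoscopist-independent assessment of chromoendoscopy modalities
for early gastric cancer, based purely on color.

Endoscopic diagnosis of early gastric cancer rests on subtle color
differences between the lesion and the surrounding mucosa, and dye-spray
techniques — indigo carmine (Indigo) and acetic acid plus indigo carmine
(AIM) — exist to enhance that contrast over plain white-light endoscopy
(WL). Whether they actually do has traditionally been judged by eye.
`chromosep` implements the computational alternative: given still images
paired with binary masks of the cancerous area (one lesion imaged under all
three modalities), it measures per image

- the **Mahalanobis color-separation distance** between the cancerous and
  non-cancerous RGB distributions,

  D = √((μ₁ − μ₂)ᵀ Σp⁻¹ (μ₁ − μ₂)),  Σp = (Σ₁ + Σ₂)/2,

  estimated from 2000 luminance-matched random pixels per class (matching
  removes brightness as a confounder, so only chromatic differences
  remain), and
- the **SVM diagnosability**: an RBF support vector machine trained on 100
  RGB samples per class classifies the held-out 1900 per class, scored by
  the F1 measure (harmonic mean of sensitivity and positive predictive
  value),

then aggregates across lesions into per-modality means and paired
Wilcoxon signed-rank comparisons. Because no public image corpus exists for
this protocol, the package ships a first-class synthetic study generator
with known ground-truth color structure — every stage is validated against
closed-form oracles. See `docs/methods.md` for the full model and its
assumptions.

Intended users: researchers in endoscopic image analysis who want an
objective modality comparison pipeline, and anyone needing a tested
reference implementation of luminance-matched region-color separability
scoring.

## Worked example

Simulate an 18-lesion study (54 images) and run the full pipeline:

```sh
chromosep simulate --config study.yaml --out images/ --seed 1
chromosep run --manifest images/manifest.csv --out results/ --seed 1
```

with `study.yaml` containing `n_lesions: 18`. Output:

```
Study of 18 lesions x 3 modalities

Mean Mahalanobis distance:
      WL: 1.636 (sd 0.212)
  Indigo: 1.408 (sd 0.184)
     AIM: 2.701 (sd 0.358)

Mean F1 measure:
      WL: 0.786 (sd 0.029)
  Indigo: 0.753 (sd 0.031)
     AIM: 0.906 (sd 0.033)

Paired Wilcoxon signed-rank (two-sided), uncorrected p:
  mahalanobis_distance     WL-Indigo: p=0.000 (Holm 0.000)
  mahalanobis_distance        WL-AIM: p=0.000 (Holm 0.000)
  mahalanobis_distance    Indigo-AIM: p=0.000 (Holm 0.000)
                    f1     WL-Indigo: p=0.000 (Holm 0.000)
                    f1        WL-AIM: p=0.000 (Holm 0.000)
                    f1    Indigo-AIM: p=0.000 (Holm 0.000)
```

Reading this: the generator's default per-modality separation scales are
{WL: 1.52, Indigo: 1.32, AIM: 2.53}, and the pipeline recovers both the
magnitudes (mean distance, slightly above the scales because of per-lesion
variation) and the ordering AIM > WL > Indigo in distance *and* in SVM
diagnosability — AIM's enhanced color contrast translates directly into a
higher F1. With 18 paired lesions and effect sizes this large, all pairwise
Wilcoxon tests reject (p < 0.0005). `results/` also contains
`per_image_results.csv` (per-image distance, confusion counts, sensitivity,
PPV, F1) and `study_report.json` (full precision); `chromosep report`
re-aggregates an existing CSV.

The same pipeline runs on real data: point the manifest CSV
(`lesion_id,modality,image_path,mask_path`) at your own 8-bit RGB
PNG/TIFF images and 0/255 mask PNGs.

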