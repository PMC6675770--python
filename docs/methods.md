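# Methods

## Problem and model

`chromosep` quantifies how well an endoscopic imaging modality separates
cancerous from non-cancerous gastric mucosa *by color alone*. The unit of
analysis is a still image of one lesion under one of three modalities —
white-light endoscopy (WL), indigo carmine dye spray (Indigo), and acetic
acid plus indigo carmine (AIM) — with a binary mask tracing the cancerous
area. Each pixel is a 3-vector of 8-bit RGB intensities; the two tissue
regions are treated as two class-conditional distributions of such vectors.

Two per-image measurements are made on luminance-matched random pixel
samples (2000 per class):

1. **Color-separation distance.** The Mahalanobis distance between class
   mean colors,

   D = sqrt( (μ₁ − μ₂)ᵀ Σp⁻¹ (μ₁ − μ₂) ),  Σp = (Σ₁ + Σ₂) / 2,

   with μᵢ, Σᵢ the sample mean and unbiased covariance of class *i*'s RGB
   samples. The unweighted covariance average is symmetric in the classes
   and coincides with count-weighted pooling at equal class sizes; an
   alternative which covariance to pool is not identifiable from the
   protocol, so both are exposed (`pooled_weighting`). The reported
   quantity is D, not D².

2. **SVM diagnosability.** A soft-margin RBF support vector machine is
   trained on 100 samples per class and classifies the remaining 1900 per
   class; diagnosability is the F1 measure, the harmonic mean of
   sensitivity (recall of the cancer class) and positive predictive value.

Because every lesion is imaged under all three modalities, modality effects
are compared **paired at the lesion level**: per-modality means/SDs of D and
F1, and per-pair two-sided Wilcoxon signed-rank tests (primary — no
normality assumption at n = 18) with paired t-tests alongside. P-values are
uncorrected by default (matching the simple three-comparison design), with a
Holm-adjusted column emitted for transparency.

## Luminance matching

Brightness is a confounder: regions under different illumination could be
separated on luminance alone. Matching is implemented as equal-width
histogram matching on luma Y = 0.299 R + 0.587 G + 0.114 B (ITU-R BT.601;
BT.709 selectable). The [0, 255] range is split into `n_bins = 32` bins;
each bin's joint capacity is min(cancer count, non-cancer count); the
per-class quota `n_per_class = 2000` is allocated across bins proportionally
to joint capacity with largest-remainder rounding (ties to the lower bin,
making allocation deterministic), then drawn uniformly without replacement
within each class and bin. Both classes therefore receive bin-identical
luminance histograms, which bounds the mean-luminance gap by one bin width
(255/32 ≈ 8 intensity levels). "Equivalent luminance" has no canonical
quantification; bin width is the knob standing in for it. If total joint
capacity falls below the quota (e.g. disjoint luminance supports), sampling
fails loudly and reports the achievable maximum.

## SVM settings

The protocol fixes the training design (100 per class, single fixed split
per image, no cross-validation) but not the kernel or hyperparameters. We
use the long-standing soft-margin defaults: RBF kernel, C = 1, kernel width
γ = 1/(d·Var(X)) with d = 3 (`gamma="scale"`), features rescaled from
[0, 255] to [0, 1]. Unscaled RGB with an RBF kernel makes results fragile in
the hyperparameters; all three knobs are exposed in the config, and modality
rankings should be checked for robustness across them. Scoring defines
sensitivity, PPV and F1 as 0 when tp = 0, so degenerate classifiers score
worst rather than erroring.

## Synthetic data generator

No image corpus accompanies the protocol, so the generator is the study
stand-in and the oracle supplier. It renders, per lesion × modality, an
image whose cancerous blob and surrounding mucosa are i.i.d. draws from two
3-D Gaussian RGB distributions, clipped to [0, 255] and rounded to 8 bits:

- **Mask geometry** — a star-convex blob: an ellipse whose radius is
  modulated by a radial sinusoid (`r(θ) ∝ 1 + a·sin(kθ + φ)`), giving
  simple, reproducible, area-controllable lesion shapes. Specs whose
  regions fall below 2000 pixels (the sampling floor) are rejected.
- **Modality axis** — with Σ = σ²I on both classes, the population
  separation is D = |Δμ|/σ, so each modality's mean separation is set to
  σ·(scale × lesion factor) along a fixed unit direction. Default scales
  {WL: 1.52, Indigo: 1.32, AIM: 2.53} reproduce the magnitudes reported for
  the three modalities in the clinical setting this emulates. The direction
  (0.8165, −0.4082, −0.4082)/‖·‖ is nearly luminance-neutral (luma
  component ≈ −0.04), so class signal is chromatic, as intended.
- **Per-lesion variation** — a Gaussian baseline color offset (s.d. 8 per
  channel) shifts both class means equally, and a log-normal factor
  (σ = 0.12) scales all three modalities' separations of that lesion
  equally, preserving the ground-truth modality ordering within every
  lesion, as in a paired design.
- **Luminance gradient** — an optional radial additive gradient on all
  channels (default amplitude 0) exercises the matching stage.
- **Defaults** — 18 lesions × 3 modalities (54 images) of 256×256 pixels,
  noise σ = 12, base mean (140, 90, 85): a reddish mucosa tone with regions
  ≥ 5σ from the clip bounds, keeping the clipped-pixel fraction below 10⁻³.

All randomness flows from one master seed through
`SeedSequence((master, lesion ordinal, modality ordinal, stage))` with stage
codes 0 = render, 1 = sampling, 2 = split, 3 = per-lesion perturbation —
identical seeds give byte-identical images, samples and reports, and
per-image seeds are logged for exact replay.

**What the generator does not emulate:** spatial correlation of color noise
(pixels are exchangeable, matching how the analysis treats them; a
correlated-noise mode is deliberately out of scope), specular highlights and
halation, dye-diffusion texture, registration error between modalities, and
non-Gaussian color distributions — Gaussianity is an assumption of
convenience, not an empirical claim. Passing tests therefore establish that
the *pipeline* recovers known structure, not that real endoscopic images
satisfy these assumptions.

## Numerical choices

- Covariance estimates use the n−1 denominator; class statistics require
  n ≥ 4.
- If the pooled covariance's condition number exceeds 10⁸, a ridge
  ε·I with ε = 10⁻⁶·trace(Σp)/3 is added and flagged in the result
  (`regularized`), never silently. A pooled covariance that is identically
  zero with unequal means is an error; with equal means the distance is 0.
- Largest-remainder allocation resolves rounding deterministically (stable
  sort, ties to the lower bin).
- Masks are written canonically as 0/255 single-channel PNG and read with
  0/nonzero semantics; 16-bit rasters are rejected; RGBA alpha is dropped.
- Wilcoxon uses `zero_method="wilcox"`; an all-zero difference vector is
  reported as the degenerate case (statistic 0, p = 1).
- No mask erosion at the tumor boundary by default (`boundary_erode = 0`);
  boundary handling in the original protocol is unspecified, so the default
  keeps every pixel and the knob exists for sensitivity analysis.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run the full default study
(18 lesions × 3 modalities, 256×256 images, 2000 samples/class), repeated
over 10 master seeds for the ranking-recovery check; estimator-consistency
and F1 benchmarks use 2000 samples/class over 20 and 10 seeded replicates
respectively. These sizes make the whole suite complete in well under a
minute on one CPU while keeping every check at the protocol's own sample
sizes.

## Known limitations

- The SVM hyperparameters of the original protocol are unrecoverable; the
  defaults here are the most probable unstated setting, not a calibration.
- F1 ≈ accuracy only at the balanced, symmetric operating point; the
  Gaussian benchmark 1 − Φ(−D/2) is an approximation for that regime.
- The Mahalanobis estimate from luminance-matched (stratified) samples is
  very slightly inflated relative to the unconditional population value,
  because stratification shrinks within-class luminance variance; with a
  near-luminance-neutral separation direction the effect is small compared
  with sampling noise.
- Subjective (endoscopist) assessment and any inter-rater statistics are
  out of scope; the report states numbers, not diagnostic recommendations.
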