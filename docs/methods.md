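# Methods

## Problem and pipeline

Acute ischaemia-reperfusion injury (IRI) in the mouse kidney is read out
histologically. The classical readout grades ten microscope fields of view
(FOVs) from the cortex and outer stripe of the outer medulla on a 0-4 scale
and averages them; it is ordinal, observer-dependent and samples roughly a
tenth of the section. The pipeline implemented here replaces it with dense
semantic segmentation of the whole section followed by pixel counting:

1. tile the section into patches;
2. segment every position into one of ten classes with an encoder-only
   convolutional network (8×-downsampled output);
3. sum all non-background pixels as the kidney surface and report each
   class as a percentage of it; the injury score is the summed percentage
   of the configured pathological classes (intratubular casts + tubular
   necrosis by default);
4. map each pathological class spatially as a per-512×512-patch percentage
   heatmap (deep blue 0% → red 100%);
5. evaluate pixel-wise against annotated ground truth (confusion matrix,
   precision / recall / specificity / F1 per class);
6. compare the pixel score with the traditional FOV score across a cohort
   (Spearman by default).

## Segmentation model

The network is the descending half of a U-Net with no decoder: four 3×3
convolution / batch-norm / ReLU blocks, the first three with stride 2
(output stride 8), default channel widths (16, 32, 64, 64), spatial dropout
before a final 1×1 projection to K = 10 score channels. Per position the
class is the softmax argmax, ties broken by the lowest class id. Because no
autodiff framework is assumed, the layers and their gradients are
implemented directly on numpy (im2col convolutions); this caps the model at
desk scale but makes the package dependency-light and fully deterministic
given a seed.

Training minimises pixel-wise multinomial cross-entropy on annotated
output-grid positions. Ground truth reaches the output grid by per-8×8-block
majority vote; blocks in which unannotated pixels outnumber all annotated
ones are excluded from the loss, preserving the semantics of sparse region
annotation. With class balancing enabled (default), the loss is weighted by
median-frequency / class-frequency (clipped to [0.2, 10]) and batch tiles
are drawn per class among tiles containing that class. The optimiser is
momentum SGD (momentum 0.99 by default; 0.9 supported). The learning rate
starts at `lr_max` = 5e-4 and halves whenever an exponentially smoothed loss
stops improving for a patience window, never leaving [5e-7, 5e-4]. One
"epoch" is one optimizer step on one freshly sampled batch (the adaptive,
monitor-on-the-fly regime); the desk-scale default is 500 steps.
Augmentations: horizontal/vertical flips, 90° rotations (square patches),
mild brightness and saturation jitter — stand-ins for section-orientation
and staining-intensity variation.

## Synthetic sections

No real cohort is deposited, so the generator is the test bed. It emits a
kidney-shaped silhouette (ellipse with a hilar notch) on a near-white
background, stamps glomeruli as compact round blobs, tessellates the rest of
the foreground into tubule-scale Voronoi cells, and assigns cells to classes
greedily — splitting the final cell pixel-by-pixel — so every targeted class
fraction of the non-background area is realised to within integer rounding.
Rendering is stylised, not photorealistic: per-class base colours from the
schema palette plus class-specific texture (homogeneous strongly-stained
casts, high-variance fragmented necrosis, punctate brush border on proximal
tubules) and a faint illumination gradient. The contract is only that
classes are chromatically/texturally separable so a small network can learn
them; a green segmentation test therefore establishes that the pipeline
learns and measures correctly at desk scale, *not* that the architecture
reaches any particular accuracy on real PAS histology (no stain variation,
no artefacts, no anatomical zonation are modelled).

Defaults (documented choices where no published value exists): sections
1024×1024 px at a nominal 0.504 µm/px; healthy composition of the kidney
surface 45% proximal tubules, 28% distal tubules/collecting ducts, 5%
glomeruli, 14% stroma, 5% transitional epithelium, 3% adipose tissue; an
injury fraction f is split 60% casts / 40% necrosis and healthy classes are
scaled down to make room; regenerating epithelium appears only on injured
sections at 0.4% of surface — deliberately rare (< 1%) so the
class-imbalance path that degrades this class in practice is exercised.
Texture noise SD defaults to 8 grey levels. Cohort generation derives
per-section seeds from a master seed via a seed sequence and cycles the
requested injury grades, forcing one healthy control into any cohort of ≥ 3
sections.

## Quantification conventions

Two denominators coexist on purpose. The injury score divides by
non-background pixels only (the kidney surface); heatmap patch percentages
divide by all pixels of the patch, background included, so edge patches with
little tissue read low. Grids use 0-based, half-open pixel intervals and a
"clip" edge policy for quantification (edge patches shrink; every pixel is
counted exactly once). Counts from an 8× mask are scaled by 8² when reported
as full-resolution-equivalent areas; the injury score is exactly invariant
under nearest-neighbour upsampling of the 8× mask.

The FOV grade bins are 0 ⇔ exactly 0, then (0,.25] → 1, (.25,.50] → 2,
(.50,.75] → 3, (.75,1] → 4; the published bin edges overlap ("26-59" vs
"51-75") and this is the only disjoint, exhaustive resolution. FOV damage is
area-based (score-class pixels / non-background pixels in the field), FOV
centres are drawn uniformly from the tissue footprint (an optional region
mask emulates the pathologist's restriction to specific zones), and the FOV
edge defaults to 512 px, configurable since "200× magnification" is
hardware-dependent. Evaluation aligns grids by majority-downsampling the
ground truth to the prediction's 8× grid (consistent with training; avoids
counting replicated predictions as independent pixels); upsampling the
prediction instead is available. Undefined metrics (zero denominators) are
reported as absent and excluded from macro means. Spearman correlation is
the default cohort statistic (Pearson available), computed by scipy with
mean ranks for ties and the t-approximation p-value.

## Numerical and design choices

* Loss/optimiser/normalisation are unspecified upstream; the package uses
  class-weighted cross-entropy, momentum SGD and batch normalisation as the
  smallest standard choices consistent with the stated hyperparameter
  ranges.
* Background is stored explicitly as class id 0 by the generator, never
  inferred from colour.
* The UNANNOTATED sentinel is 255 and is excluded everywhere (loss,
  confusion counts, class areas).
* Rasterization uses the pixel-centre convention (a pixel belongs to a
  polygon iff its centre does); later-listed polygons win overlaps.
* Annotation balancing subsamples by region count (matching a fixed
  per-class budget), not by pixel count.
* Softmax scores sum to 1 within 1e-5 per position; argmax ties go to the
  lowest class id for determinism.

## Desk-scale benchmark

`nephroseg.benchmark.desk_scale_f1` generates 40 training and 10 held-out
256×256 tiles (injury cycling 0-0.4), trains the default encoder for 500
steps with batch 8, and reports held-out per-class F1 at the 8× grid. On one
CPU this takes ≈ 3-4 minutes. The acceptance gate is min(F1 casts, F1
necrosis) > 0.75; at this scale the pathological classes typically reach
F1 ≈ 0.9, while tiny round structures (glomeruli, shrunk proportionally with
the section) and the deliberately rare regenerating-epithelium class remain
poor — mirroring at miniature scale the class-scarcity failure mode seen in
real cohorts.

## Known limitations

* The renderer is not photorealistic; colour is the dominant class cue, so
  desk-scale F1 overstates what the same architecture would achieve on real
  tissue.
* The encoder is numpy-bound: full-slide (≥ 20k px) training is out of
  reach; inference tiles arbitrarily large sections but at CPU speed.
* No anatomical parcellation (cortex / OSOM / medulla): the heatmap
  localises damage visually, and the FOV region mask must be supplied by the
  caller.
* Inter-observer variability of the manual score is not modelled; the
  synthetic "pathologist" applies the bin rule exactly.
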