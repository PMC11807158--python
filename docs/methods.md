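# Methods

This note documents the models, the synthetic phantom, the numerical
choices and the known limitations of the package. It states nothing that
the test suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

Spectral-domain OCT volumes of the macula are stacks of 2-D B-scans
(nominally 1024×496 px, 49 per volume). In Stargardt disease the outer
retina degenerates: the outer nuclear layer and the photoreceptor inner
and outer segments thin and, in severely affected areas, disappear, often
leaving hyper-reflective debris. Sublayer boundaries are undefined where a
layer is absent, so the pipeline splits every scan into a *severely
affected region* — a single orthogonal box enclosing all columns where at
least one sublayer is undetectable — and the *relatively unaffected
region* outside it. Only the total retina is annotated and segmented
inside the box; the five sublayers (IR, ONL, PR-IS, PR-OS, RPE) are
segmented outside it.

## Masked losses

The combined objective is cross-entropy plus soft Dice. The
pathology-aware form multiplies every sum by a binary exclusion mask that
is zero on the box's columns, extended over the full image height. Two
conventions required a decision:

* **0·log 0.** The literal masked cross-entropy contains `log(m·ŷ)`,
  undefined at `m = 0`. We adopt 0·log 0 := 0 and implement it by
  restricting the sum to unmasked pixels, which also makes the gradient
  of every masked pixel exactly zero (asserted by finite differences and
  by training-twice equivalence tests).
* **Normalization.** The literal form divides by the total pixel count N,
  so the loss shrinks as the box grows. This is the default
  (`masked_norm="literal"`); `masked_norm="unmasked"` divides by Σm
  instead. The choice does not affect the zero-gradient property.
* **Multi-class Dice.** The published form is binary; we compute
  one-vs-rest Dice per class and average over classes present, excluding
  background from the Dice average (it is included in the cross-entropy).
  A class absent from both prediction and truth is skipped rather than
  scored.
* Probabilities are clamped at ε = 1e-7 inside logarithms.

## Default segmenter

The segmenter contract is `forward(image) -> (H, W, C)` probabilities with
C = 2 (total retina) or 6 (sublayers); any trainable model can stand
behind it. The default is a **pixel-wise MLP classifier** (one tanh hidden
layer, 16 units) over ten engineered, strictly column-local features:
raw and axially smoothed intensity (σ = 2, 6), the axial gradient,
absolute row, depth below the estimated retina top, fractional depth
within the band, band thickness, mean band intensity, and a
cumulative-reflectance depth coordinate. The retina band per column is
found by thresholding the axially smoothed profile between its low decile
and 99th percentile.

Why not a convolutional encoder-decoder? Three reasons, in order:

1. **Provable exclusion.** Because every feature of a pixel depends only
   on its own column, altering anything inside a box's column band cannot
   change any feature, prediction or gradient outside it. Together with
   the masked loss this makes the exclusion guarantee exact at the level
   of learned parameters — a property the tests verify bit-for-bit, and
   which holds only approximately for models with 2-D receptive fields.
2. **Closed-form gradients.** The exact combined CE + Dice objective
   (masked or not) is differentiated by hand, so training is transparent,
   deterministic and dependency-light.
3. **CPU budget.** The model trains in seconds on one core, which lets the
   test suite train many models (reduction, corruption-equivalence,
   determinism, overfitting and comparison experiments) rather than one.

Because layered retinal anatomy is essentially a column-wise stack whose
class is nearly determined by fractional depth and reflectance, this
compact model reaches overall sublayer Dice ≥ 0.9 on held-out phantoms
(a property test) and ~1.0 for the 2-class total-retina task. The
contract deliberately leaves room for registering stronger 2-D
architectures where the exact-exclusion property can be relaxed.

### Training schedule

Adam; batches of 15 images with 2000 sampled pixels per image per epoch in
minibatches of 4096 pixels; 15 epochs per loop for total retina, 30 for
sublayers; validation overall Dice (background excluded, box interiors
excluded when masks exist) is monitored once per epoch; the best
checkpoint is kept; a plateau scheduler halves the learning rate after 15
epochs without improvement. The published schedule used a learning rate
of 5e-4 with large pretrained convolutional backbones; the compact MLP
needs a larger step to converge within the same epoch budget, so the
default here is 0.02 (configurable). Sampling pixels rather than whole
images keeps per-epoch cost flat while the per-pixel loss is unbiased for
the image-level cross-entropy; the Dice term is computed per minibatch,
the usual soft-Dice-on-batch approximation.

## Box detection

The ground-truth rule is: a column is severely affected iff some sublayer
has thickness below `t_min` in it; all affected columns merge into one
box (min..max affected column × the retina band rows), whose confidence is
the flagged fraction of its span. On ground-truth masks `t_min = 1 px` is
exact and is the default of `column_integrity_profile`.

The **rule-based detector** applies the same audit to a trained
segmenter's argmax output. A trained classifier smears a few pixels of
every class into lesion columns, so an absolute 1 px threshold never
fires; the detector therefore defaults to `t_min="auto"` = max(2, 2.5% of
image height) and suppresses flagged runs shorter than 8 columns
(segmentation noise). With these defaults, box presence/absence on the
phantom test sets is essentially perfect and AP50 is high, while AP75 is
low: the merged box's exact edges depend on where smearing stops, which a
thickness audit localizes only to a few columns. The **learned detector**
is a per-column logistic regression on band thickness, band intensity and
a 12-bin fractional-depth intensity profile, following the same
single-box merge; it overfits small fixtures to AP50 = 100 and respects
the published iteration schedule (2000 iterations in loop 0 rising to
3000 by loop 10). Both emit at most one box; the pipeline keeps the top
detection with confidence ≥ 0.5.

## Synthetic phantom

The phantom emulates what the method needs from real data, not OCT
physics:

* six smooth boundaries delimiting five sublayers: a shared sinusoidal
  undulation, a Gaussian foveal dip of the inner surface (decaying with
  depth), and a shared multiplicative thickness modulation so fractional
  layer depths are constant across columns in lesion-free scans;
* per-class mean reflectance (dark background and ONL; bright
  photoreceptor bands and RPE), unit-mean gamma speckle (10 looks) and
  additive Gaussian noise (σ = 0.01), clipped to [0, 1];
* disease severity s ∈ [0, 1]: global thinning of ONL/PR-IS/PR-OS/RPE
  (slopes 0.45/0.50/0.40/0.15), ONL brightening (+0.3·s, the
  hyper-reflective change), and above an onset of 0.45 a focal lesion
  whose span grows with s, inside which the listed layers collapse
  completely and hyper-reflective debris is painted into the band;
* lesion collapse rebuilds each column from the band top, so the total
  retina remains one connected (thinner) band — continuity holds by
  construction rather than by redistributing thickness to neighbours;
* cohorts: per-patient baseline severity ~ U(0.15, 0.60) and per-visit
  progression ~ U(0.02, 0.10), so severity rises monotonically across the
  five visits; severity is weighted toward central slices; healthy
  cohorts are severity 0 throughout. Geometry is drawn per scan —
  longitudinal shape coherence of a given eye is out of scope.

Because debris appearance is not quantitatively characterized in the
clinical literature available to us, its parameters (gray level 0.75,
density 0.15 within the band) are free choices. What passing tests show:
the masked-loss machinery, box semantics, metrics and cohort logic are
exact, and the *ordering* of methods (pathology-aware > standard on
diseased scans, parity on healthy) is reproduced. What they do not show:
absolute Dice or AP values transfer to clinical scans, where texture,
vessel shadows, motion artifacts and grader variability dominate.

## Evaluation

Dice is computed per class; sublayer evaluation on diseased scans is
restricted to outside the ground-truth box, where sublayer truth exists;
total-retina evaluation uses the full image. Reports give per-layer
mean ± sd (sample sd, ddof = 1) over images, and an overall score that
averages layers within each image first, then over images (stated in the
report header; pooling pixels instead is the other defensible choice).
Undefined per-class Dice values are excluded from averages rather than
scored 1. Detection AP uses greedy one-to-one matching by descending
confidence and 101-point interpolated precision, with mAP averaged over
IoU 0.50:0.05:0.95 — the COCO conventions. Method comparison is a
two-sided paired t-test on per-image overall Dice; zero-variance
differences are reported explicitly as degenerate (t = 0 for identical
vectors) rather than NaN.

## Cohort logic

Patients are split 8:1:1 within each site; validation and test each take
`floor(n/10)` patients (at least 1 when the site has ≥ 3; smaller sites
train-only with a warning), the remainder trains. The middle 11 slices of
a volume are central (floor offset for even remainders; 49 slices give
indices 19..29), the rest peripheral. Per patient, scans pool across all
visits and both eyes; `round(0.3·n)` (half-up) are drawn from the central
pool and the rest peripheral, without replacement — 3 per training
patient, 16 per validation/test patient. The iterative loop transfers
exactly 200 random pool scans per loop (phantom ground truth stands in
for the annotator), keeps validation/test fixed (hash-checked), and
optionally stops once the validation metric improves by < 0.5 percentage
points for two consecutive loops.

## Reduced scale

The reference experiments run on 320×160 phantoms (~1/3 nominal
resolution), 50 healthy + 50 diseased training scans, 10 epochs — sizes
chosen so the full comparison, detection evaluation and bookkeeping run
end to end in tens of seconds while every qualitative property of the
full-scale design is preserved. The bookkeeping cohort uses nine sites of
90/80/40/20/10/10/3/3/3 patients — a realistic enrollment spread whose
8:1:1 per-site split yields 203/28/28 patients and hence 609 initial
training and 448 validation/test B-scans.

## Known limitations

* The default segmenter cannot exploit lateral context; real-scan
  performance would need a 2-D architecture behind the same contract.
* The rule-based detector localizes box edges only to within a few
  columns (low AP75 by construction).
* One box per scan: separate lesions are merged, discarding any intact
  anatomy between them — a multi-box extension is deliberately excluded.
* The phantom's speckle is uncorrelated; real OCT speckle is structured.
* Image-quality grading of real scans (field of view, tilt, noise) is a
  stub hook only.
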