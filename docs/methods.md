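# Methods

## Problem setting

A segmentation model trained on one microscopy domain (a cell type, an
imaging modality, an illumination setup) degrades on another. Annotating the
new domain is expensive, so this package adapts the trained model *at test
time*, using only the unlabelled target images, and then reuses the adapted
feature extractor for joint cell detection, re-identification (ReID) and
lineage tracking.

## Segmentation unit

The unit is a compact encoder–decoder with batch normalization (BN) after
every convolution. Downsampling uses 2×2 stride-2 convolutions without
padding, so an encoder tap at ratio r has spatial size exactly
⌊H/r⌋ × ⌊W/r⌋; taps at 1/8, 1/16 and 1/32 form the feature pyramid consumed
by the tracking heads. The decoder upsamples (nearest-neighbour, exact
target size) with skip connections back to full resolution and emits a
single foreground-probability channel; the two-class form (p, 1−p) is used
wherever a loss consumes explicit class distributions. We use plain skip
connections rather than densely nested ones: at the model sizes this
package targets (4–8 base channels) the nested variant adds cost without
changing any tested behaviour. Source training minimizes a soft Dice loss
(ε = 1e-6 guards empty masks) with Adam; no augmentation, so a fixed seed
reproduces training bit-for-bit on one CPU.

The whole network stack (convolution, BN, attention, the losses) runs on a
small reverse-mode autodiff engine over numpy arrays written for this
package; float64 everywhere, im2col convolutions, SVD-based nuclear-norm
gradient (∂‖A‖*/∂A = UVᵀ).

## Two-stage test-time adaptation

Only the BN affine parameters (γ, β) are optimized during adaptation; BN
normalization statistics are re-estimated from target batches (a full
replacement pass before each stage); every other weight is bit-frozen. This
is the standard BN-modulation argument: convolutional weights carry feature
knowledge, normalization statistics carry the domain.

**Stage 1 (entire image).** Minimize L_E = L_s + α·L_bnm over target
batches, where L_s is the mean per-pixel Shannon entropy (natural log) of
the two-class prediction and L_bnm = −(1/B)‖A‖* is the negative mean
nuclear norm of the batch response matrix (rows: pixels of the batch,
columns: the two classes). Entropy sharpens per-pixel decisions; the
nuclear-norm term maintains prediction diversity near the decision
boundary, which matters most for dense scenes. α defaults to 0.5.

**Stage 2 (patches).** Each target image is tiled into overlapping patches
(default 128 px with 32 px overlap at full scale; the desk-scale harness
uses 48/16). For each patch, a center δ is the median (or mean) of the
patch pixels that Stage 1 predicted as background; if a patch has no
predicted background, the global-frame background statistic substitutes and
the event is logged. Pixel similarity is φ(i, j) = 1/(1 + ‖i−j‖²) on
intensities normalized to [0, 1]. The central-metric contrastive (CMC)
objective in its hard-set form is

    L_CMC = −log [ Σ_{i∈P⁺} e^{φ(i,δ)} / (Σ_{i∈P⁺} e^{φ(i,δ)} + Σ_{i∈P⁻} e^{φ(i,δ)}) ]

with P⁺/P⁻ the cell/background pixel sets from the binarized (0.5) Stage-1
prediction. With both the sets and δ frozen, this quantity has no gradient
path to the model, so optimization uses the soft-membership relaxation: the
current model's foreground probability q_i weights each pixel's term,
S⁺ = Σ q_i e^{φ_i}, S⁻ = Σ (1−q_i) e^{φ_i}. The relaxation recovers the
printed value for binary q and is exposed separately (`cmc_loss` vs
`cmc_loss_soft`). The orientation of the printed form rewards cell pixels
for resembling the *background* center; a `cmc_orientation="flipped"`
switch swaps the roles for experimentation, and the default remains the
printed orientation. Stage-2 predictions are stitched with cosine-ramp
weights normalized to a partition of unity, so stitching crops of a map
reproduces the map exactly.

The final mask is the weighted average w·pred1 + (1−w)·pred2 (w = 0.5)
binarized at 0.5. Adaptation budgets default to 3 + 3 epochs (< 10 total)
at the source learning rate.

## Joint detection and ReID heads

The heads consume the (adapted) pyramid with the backbone frozen — the
adaptation stage owns the shared trunk, so head training touches only head
parameters. Per resolution r ∈ {8, 16, 32}, stacked 1×1 convolutions emit
a 5-vector (tx, ty, tw, th, logit p) per location; the anchor at
(⌊x/r⌋, ⌊y/r⌋) is positive for a ground-truth box centred at (x, y)
(collisions keep the larger box, logged). Decoding is YOLO-style with one
anchor per location: centre = (grid + sigmoid(t))·r, size = anchor·e^t with
anchor side 1.5r. Classification uses the focal term
−α_c(1−p_t)^{γ_c} log p_t with α_c = 0.25, γ_c = 2 applied to positives
and negatives alike (a `standard_alpha` flag restores the conventional
α/1−α split); regression uses 1 − CIOU at positives; the detection loss is
their sum over resolutions and locations, weighted β_c = 0.05 for
regression and normalized by the positive count. The objectness bias is
initialized to −3 so an untrained head predicts background nearly
everywhere (the usual focal-loss prior).

All three resolutions are supervised, but inference decodes the finest
grid only (configurable): at desk scale a cell spans roughly one stride-8
anchor, and the coarser grids cannot localize below their stride, so their
boxes only add poorly-localized duplicates. The deployed operating point
for tracking is score ≥ 0.45 with NMS at IoU 0.5 (the permissive 0.3/0.5
pair remains the constructor default for exploratory use).

The ReID branch upsamples the 1/16 and 1/32 maps to 1/8, encodes each with
a 3×3 conv + BN + ReLU, applies a spatial attention module (channel mean
and max maps, concatenated, 7×7 convolution, sigmoid), fuses as
f + f⊙attention, concatenates the three scales and maps to D-dimensional
embeddings with a final 3×3 convolution (D = 128 by default; the harness
uses 32). A training-only linear classifier over the C identities provides
the cross-entropy ReID objective; the printed ReID quantity (1/N)ΣΣ Y log p
(which is the negative of that cross-entropy) is reported alongside. The
joint objective is L_det + η·L_id with η = 0.05. An ablation branch
replaces the attention module with plain stacked convolutions.

## Online association and lineage

JDE-style two-pass matching per frame: (1) cosine distance between the
exponentially smoothed tracklet embedding (momentum 0.9) and detection
embeddings, gated by a constant-velocity Kalman prediction (24 px centre
gate, cosine ≤ 0.5); (2) IoU ≥ 0.5 fallback; both solved as optimal
bipartite assignments. Unmatched detections open tracklets; unmatched
tracklets survive 10 frames before finishing. The lineage table uses CTC
semantics (label, begin, end, parent). Division is recovered heuristically:
a new track is linked to a track that ended the previous frame nearby, or
to a nearby live track whose box area roughly halved at that frame — in
the latter case the live track is split so parents end before children
begin. The association stage does not model division explicitly, so this
remains best-effort.

## Metrics

Dice and IOU at pixel level (both-empty masks score 1); AJI at object
level, with each ground-truth object matched to its Jaccard-maximizing
prediction (ties: lower label) and never-matched predictions inflating the
denominator. Tracking uses CLEAR-style persistent matching at IoU ≥ 0.5
(configurable): MOTA = 1 − (FN+FP+IDSW)/GT; CT is the share of reference
tracks covered on every frame of their span by a single predicted
identity; TF averages, over references detected at least once, the longest
single-identity run divided by the span; MT/ML are the percentages of
references covered ≥ 80% / < 20% of their frames. The cell-imaging-density
statistic is reported in both readings — effective area per cell, and
cells per 1000 px of effective area — because the first (the printed
definition) *decreases* with crowding while the crowding interpretation
requires the reciprocal; neither is asserted canonical. The effective area
defaults to the frame minus a one-cell-radius margin, an explicit
algorithmic stand-in for "excluding marginal sections".

## Synthetic study conditions

The generator renders elliptical cells (area-preserving eccentricity) on a
lightly textured background, with additive Gaussian noise, an optional
illumination ramp, Gaussian per-frame motion, and divisions that terminate
the parent and start two offset children the next frame (a newborn waits
one frame before it may divide). Later-drawn cells own overlapping pixels.
Photometric domain shift (gamma, contrast, brightness, inversion,
illumination, fresh noise) alters images only, never masks.

Fixed study conditions used by the tests and the acceptance script:

- *Adaptation*: source 96×96, 6 cells of radius 5–8 px, fg/bg intensity
  0.8/0.2, noise σ 0.02, 10 frames; target 18 cells (3× density), 6 frames,
  shifted by gamma 2.5, contrast 0.45, brightness −0.18, illumination 0.3,
  noise σ 0.06 — strong enough that the unadapted model visibly degrades.
- *Easy tracking*: 128×128, 10 cells of radius 7–10 px, ≥ 26 px apart,
  motion σ 0.8 px/frame, 20 frames.
- *Crowded tracking* (ReID ablation): 12 cells, ≥ 17 px apart, motion σ
  2.5, 15 frames — close enough encounters that embedding quality decides
  identity preservation.

Tracking experiments use the one-shot deployment protocol: the
segmentation unit and joint head are fitted on the annotated recording,
and that recording is then tracked and scored. The association stage never
sees labels, so MOTA/CT/TF on this protocol measure detection coherence,
embedding quality and the matching logic — deliberately not detector
generalization to unseen recordings, which at these model and data sizes
is limited (the ReID classifier's identity space is per-recording by
construction, and a stride-8 detection head trained on a dozen frames
does not localize reliably in configurations it has not seen).
`cross_validate` retains a held-out protocol for the segmentation unit,
which does generalize across same-domain videos.

Model sizes in the harness (6 base channels, 32-dim embeddings, 10 source
epochs, 60 head epochs) are chosen so a full experiment runs in about a
minute per seed on one CPU; they are the package's desk-scale defaults, not
statements about converged large-scale behaviour.

What the synthetic conditions do **not** emulate: real microscope
point-spread functions, intensity heterogeneity inside cells, cell-shape
dynamics, apoptosis, dense overlapping in 3D, or modality-specific artefacts
(phase halos, DIC shadows). Passing these tests therefore demonstrates the
mechanics and the claimed directional effects (adaptation helps under
photometric shift and density increase; the patch stage helps object-level
separation; attention helps identity preservation), not performance on any
real dataset.

## Numerical choices and degenerate inputs

Probabilities are clamped at 1e-12 (entropy) / 1e-7 (focal) before logs.
The CIOU aspect-ratio trade-off coefficient is treated as a constant in the
gradient, as is standard. Binarization threshold is 0.5 everywhere. Empty
P⁺ makes the CMC loss undefined: the patch is skipped and logged, and a
target whose Stage-1 prediction is empty everywhere aborts Stage 2 with an
explicit error. Zero ground-truth objects make AJI/MOTA undefined (errors),
and an empty TF consideration set reports NaN. Assignment ties and NMS
order are deterministic (stable sorts, fixed tie-breaks), so every
experiment is a pure function of its configuration and seed.

## Known limitations

- The stride-8 feature grid bounds detection localization; cells much
  smaller than ~8 px would need a finer tap than the pyramid provides.
- The ID classifier's identity space is the training video's; across
  videos only the embedding geometry transfers.
- The division heuristic links parents by proximity and area halving; it
  cannot distinguish division from a passing near-collision.
- BN-only adaptation assumes the domain gap is largely photometric; it
  cannot recover from semantic shifts (different cell morphology classes).
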