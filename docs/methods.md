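# Methods

This note records the models, conventions and numerical choices behind
`echoseg`, and what the phantom-based validation does and does not show.

## Segmentation network

The model is a reference-guided two-stream detector-segmenter.  Both
streams take two-channel 128×256 inputs (grayscale frame + guidance
mask); "Siamese" is implemented as literal weight sharing of the encoder
and of the per-stream feature pyramids — the streams differ only in their
inputs.  The encoder is a five-stage residual network; the `full` preset
uses bottleneck blocks of widths 64/128/256/512 with 3/4/6/3 blocks per
stage (outputs 256–2048 channels), the `reduced` preset basic blocks of
widths 16/32/64/128, one per stage.  No normalization layers are used:
the desk-scale experiments train with small effective batches where batch
statistics are unreliable, and careful He initialization with a
down-weighted final conv per block proved sufficient.

Stage 3/4/5 outputs feed a feature pyramid producing P3–P7 (strides
8–128) at 256 channels (`reduced`: 32).  P6 is a stride-2 3×3 conv on C5
and P7 a stride-2 conv on ReLU(P6).  The two streams' pyramids are fused
per level by channel concatenation + 1×1 reduction, *after* the pyramids
and before the subnets; fusing earlier (at the encoder) would discard the
reference stream's multi-scale detail, and fusing later would double the
head cost.

Heads are shared across levels.  Classification: four 3×3 conv+ReLU
layers and a final conv with A = 9 outputs per location + sigmoid.
Regression: identical with 4A outputs, predicting (dx, dy, dw, dh)
normalized by (0.1, 0.1, 0.2, 0.2).  Segmentation: RoIAlign (14×14, one
bilinear sample per bin, sampled from fused P3) followed by four 3×3
conv+ReLU layers, a ×2 nearest upsample, one 3×3 conv+ReLU and a final
1×1 conv + sigmoid, giving a 28×28 probability map that is resized into
the detected box and thresholded at 0.5.

Anchors use aspect ratios {0.5, 1, 2} (width/height) and scale
multipliers {1, 2^(1/3), 2^(2/3)} on base areas 32²–512², the canonical
single-stage-detector configuration; the template order is ratio-major
and the flattening order (level, row, col, anchor) is shared between the
anchor generator and the head reshapes.  Assignment bands: max-IoU ≥ 0.5
positive, < 0.4 background, the rest ignored.  Filtering keeps the top
1000 candidates per level, applies the 0.5 score threshold, then greedy
NMS at IoU 0.5 with ties broken toward the lower box index.  Anchors
partially outside the image are kept; clipping happens after regression.

### Training

One sequence per iteration: the first frame + its mask feed the reference
stream once (features are tiled across the batch), the remaining frames
form the main-stream batch.  Guidance masks use teacher forcing (the
previous frame's *ground-truth* mask); propagating the model's own
prediction during training is not implemented.  The mask head is trained
on RoIAligned crops of the ground-truth boxes, so its loss is independent
of detection quality early in training.  The loss is the unweighted sum
of the focal classification loss (α_t = 0.25, γ = 2, uniform α_t,
normalized by the positive-anchor count), the mean smooth-L1 regression
loss over positive anchors (σ = 3), and the average binary cross-entropy
of the 28×28 mask against the box-cropped ground truth.  Probabilities
are clipped to [1e-7, 1 − 1e-7] before any logarithm.

The optimizer is SGD; `TrainConfig` defaults to the full-scale setting
(learning rate 1e-5, read from the stated "10e-5" as 1e-5 — the
configuration field exists precisely because the notation is ambiguous).
The CPU-scale experiments in the test suite and acceptance script use
the `reduced` preset with learning rate 0.01 and momentum 0.9 for 200
iterations on five phantom sequences — hyperparameters chosen for that
problem scale (≈ 5×10⁵ parameters, 64×128 inputs, no normalization
layers; 0.05 diverges, 0.003 underfits within the 200-iteration budget).
The classification head's final bias is initialized at prior 0.5 in the
reduced preset (0.01 in `full`) so that detection works from the first
iterations of a short schedule.

At inference there is no fine-tuning.  If no detection survives
filtering, the guidance mask is reused verbatim and the frame is flagged
(`fallback_used`); the first output mask of a sequence is always the
user's annotation, bit-exact.

## Quantification

LV landmarks come from the mask's convex hull with the basal side at the
image top: the mitral chord is the longest hull edge whose midpoint lies
in the top 30 % of the mask's row extent (on any chamber with a roughly
flat mitral plane this is that plane's edge), and the apex is the hull
vertex farthest from the chord line.  The detector is a function argument
of `quantify_lv_sequence`, so alternative strategies can be swapped in.
L = |apex − chord midpoint| · spacing, S = pixel count · spacing²,
V = 8S²/(3πL) (single-plane area-length; assumes rotational symmetry
about the long axis — biplane volumes are out of scope).  ED/ES are the
volume argmax/argmin with ties to the earliest frame; a constant curve
yields (0, 0) with a warning.  Empty-mask frames are flagged and their
measures linearly interpolated from neighbours so a segmentation dropout
cannot masquerade as ES.  EF and FAC are spacing-invariant by
construction.  RV phase frames must be operator-supplied; the package
deliberately refuses to infer them from the area curve.

Quantification runs on masks at the acquisition resolution (predictions
made at network resolution are upsampled with nearest-neighbour first),
so `pixel_spacing` always refers to original pixels.

## Phantom

The phantom emulates a four-chamber LV: a bullet-shaped chamber — an
ellipse with long axis along image rows truncated by a flat basal
(mitral) plane at fraction t = 0.6 of the long semi-axis above the
centre — rendered as a dark cavity inside a bright wall ring on a
mid-gray background, multiplied by (1 + s·U[−1, 1]) speckle-like noise
and clipped to [0, 1].  The truncated shape (rather than a full ellipse)
is deliberate: it gives the chamber an actual mitral plane, which is what
the hull-based landmark detector — and a real LV — has.  Closed forms:
S = ab(π/2 + t√(1−t²) + asin t), L = a(1+t), V by the area-length rule;
EF depends only on the axis ratios, so truncation does not change it.

Semi-axes follow a piecewise half-cosine contraction weight (0 at ED,
1 at ES at `es_frame_fraction`, back to 0), one cycle per sequence.  The
clip covers 90 % of the cycle (`cycle_coverage`), ending before full
relaxation as single-beat cine clips do; with full coverage the last
frame ties with frame 0 within pixel rounding and the discrete ED frame
becomes ill-defined.  The random-spec sampler draws ED semi-axes of
135–175 × 70–105 px at 0.025–0.04 cm/px (lengths 7–10 cm, ED volumes
roughly 60–140 mL), longitudinal/radial shortening 12–20 %/20–30 %
(EF ≈ 40–60 %), speckle strength 0.2–0.5, and 10–14 frames per clip with
the ES position snapped onto the frame grid.  These ranges were fixed so
that the smallest adjacent-frame volume gap near ES exceeds worst-case
pixel-rounding noise in the hull-derived length (±2 px on L ≥ 215 px),
making exact discrete ED/ES recovery well-posed for any seed.

What the phantom does *not* emulate: papillary muscles, valves and
trabeculation, probe-sector geometry and shadowing, Rayleigh speckle
statistics, out-of-plane motion, multi-chamber scenes, annotation
variability.  Passing phantom tests therefore demonstrates the
correctness of the machinery (losses, anchors, propagation, geometry,
statistics) at a small scale — not clinical-grade accuracy on hospital
data, which would require the full preset, a pretrained backbone and real
annotated sequences.

## Numerical conventions

- Boxes are (x1, y1, x2, y2) float pixel coordinates with continuous
  areas (x2−x1)(y2−y1); IoU of zero-area boxes is 0.
- RoIAlign samples one point per output bin at the bin centre, with
  feature pixel centres at integer coordinates + 0.5; a box covering the
  whole map at matching output size is an identity crop.
- Images are resized bilinearly, masks with nearest-neighbour (masks stay
  strictly binary); min–max normalization maps a constant frame to zeros
  with a warning.
- Mask binarization uses `value >= threshold`.
- The engine computes in float32; gradient-check tests switch it to
  float64.
- Sample statistics use ddof = 1 throughout (Cronbach's α, Bland–Altman
  SD).  R² is 1 − SS_res/SS_tot (not squared Pearson).  Two empty masks
  score 1 on all overlap metrics so truth-vs-truth evaluation is perfect.
- Degenerate statistics (constant reference for R², zero total variance
  for α, constant input for Pearson) are reported as NaN with a warning
  rather than raising.

## Problem sizes used in validation

The acceptance studies run 50 randomized inputs per formula oracle, 200
random assignment cases and 40 NMS cases against brute force, 20 random
phantoms for EF/FAC recovery, and one training experiment (5 training
phantoms, 200 SGD iterations, one held-out phantom) — sizes at which the
whole suite completes in a few minutes on a single CPU core while still
exercising every code path end to end.
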