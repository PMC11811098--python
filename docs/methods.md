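# Methods

## The blink wave and its analysis

The object of study is the per-frame interpalpebral height percentage
(IPH%): the maximum vertical extent of the segmented interpalpebral region,
divided by the image height. Plotted over a 20-s recording this gives the
blink wave; every blink is a trough.

**Event detection.** With Δ[t] = IPH%[t−1] − IPH%[t] (positive while the eye
closes), a run of k = 5 strictly positive Δ opens a candidate blink at the
first frame spanned by that run, i.e. the last frame at the pre-blink
height. Ties (Δ = 0) break a run, so two blinks separated by at least one
steady frame can never merge. A subsequent run of k strictly negative Δ
confirms the reopening. Two design choices deserve note:

* **Sign convention.** The rule is oriented so that positive Δ means the
  lid is descending. The convention is forced by the geometry of a blink
  wave: the closing phase is the falling limb, and the "five consecutive
  increments" that open a blink must be decrements of IPH%.
* **Event end.** The first k-length falling run after the start confirms
  that the eye is reopening, but the event does not end there: it ends at
  the last frame of that maximal falling run — where the reopening stops,
  normally the return to the open-eye height. Ending at the fifth frame of
  the run would clip every opening phase at 5/fps ≈ 0.17 s, which
  contradicts observed opening durations (≈ 0.3–0.4 s) and would make the
  opening-phase duration a constant rather than a measurement.

A start with no confirmed end before the recording finishes is dropped; a
second start arriving before any end supersedes the first (keep-latest),
which keeps candidate intervals disjoint and ordered. k is configurable
because at 30 fps a 5-Δ run requires the closing ramp to span ≥ 6 frames
(0.2 s); fast real blinks can violate this, and a 3-frame median pre-filter
(off by default) is available for noisy waves.

**Classification.** With baseline b = IPH% at the start frame and trough
m = min over the event: m = 0 is a complete blink, 0 < m ≤ 0.8·b an
incomplete blink, m > 0.8·b a rejected dip (not a blink, excluded from all
counts). The complete-blink test uses exact zero — no epsilon — because the
classifier correction guarantees closed frames carry IPH = 0.

**Phases.** For a complete blink the closed phase is the zero-run containing
the trough: closing ends at its first frame, opening starts at its last.
For an incomplete blink the boundary is the first frame attaining the
trough and the closed phase has zero length. The three durations always
telescope to (end − start)/fps exactly.

**Summary metrics.** IB and CB count non-rejected events; TB = IB + CB;
IBR = IB/TB (undefined when TB = 0); relative IPH% = mean/max of the wave,
in [0, 1], undefined for an all-zero wave. Relative IPH% is reported as
defined; note that on mostly-open recordings it sits near 1 by construction.

## Frame-state correction

A segmenter leaves occasional foreground residue on fully closed eyes; since
any nonzero IPH reads as an open eye, segmentation alone under-detects
closure (low sensitivity for the "disappearance" state at high specificity).
The frame classifier arbitrates: frames classified as palpebral fissure
disappearance have their IPH forced to zero, all others keep the segmented
value. The rule is idempotent. For all frame-state metrics the positive
class is "disappearance" — the convention under which segmentation-alone
sensitivity is the quantity the correction improves.

## Models

**Segmenter.** A U-Net: four encoder levels of (3×3 conv, batch norm, ReLU)
× 2 followed by 2×2 max-pooling with channel doubling; a two-conv
bottleneck; a mirrored decoder using ×2 nearest-neighbour upsampling and
skip concatenation; a 1×1 per-pixel head. Batch normalization in the conv
blocks follows standard U-Net practice and is what makes small-batch Dice
training stable — without it the optimizer reliably slides into the
all-background Dice minimum, where gradients vanish. Training minimizes the
soft Dice loss (per-sample, smoothing 1.0) with SGD (lr 0.01, momentum 0.9,
×0.1 decay every 20 epochs, batch 4, up to 100 epochs, early stop after 20
epochs without validation-DSC improvement); the best-validation checkpoint
is returned. Default protocol: 512×512 nearest-neighbour-resized grayscale
inputs, base width 64. Desk-scale runs (tests, acceptance) use 128×128 or
64×64 inputs with base width 8–16, where the synthetic task trains to
DSC > 0.95 in a few minutes on one CPU. Predicted masks are
nearest-neighbour-resized back to the frame resolution before any IPH is
computed, with a 0.5 probability threshold.

**Classifier.** A four-stage hierarchical windowed-attention transformer:
4×4 patch embedding, stages of transformer blocks with window attention
(alternate blocks use cyclically shifted windows with the standard boundary
attention mask), patch merging (2× spatial reduction, 2× width) between
stages, global average pooling and a 2-way head. Relative-position bias is
omitted — attention is plain scaled dot-product — which at the scales used
here has no measurable effect on the binary open/closed task. Default
protocol: 224×224×3 inputs (grayscale replicated), embed 96, depths
2/2/6/2, window 7, AdamW (lr 1e-4, weight decay 5e-2), batch 8, 10 epochs,
cross-entropy; the common channel normalization constants
(0.485/0.456/0.406, 0.229/0.224/0.225) are defaults and recorded in the run
config. Desk-scale: 64×64 inputs, embed 16, depths 1/1/1/1, window 4,
lr 1e-3, where validation accuracy reaches 1.0 within 4 epochs. Training
augmentation is a random 70–100% crop plus horizontal flip; inference is a
deterministic full-frame resize.

**Splits.** All datasets are split 8:1:1 (train/validation/test) by a seeded
shuffle with largest-remainder rounding, so 1,440 frames give 1152/144/144
and all three sets are non-empty from n = 10. Flips/crops augment the
training split only. One explicit seed drives split, initialization and
augmentation; identical data + seed reproduce training histories exactly.

## Synthetic recordings

The generator emulates a 20-s, 30-fps, 800×600 acquisition of a single eye.
Blink schedules are drawn with per-event phase durations quantized to the
frame grid: closing 0.2–0.4 s, closed 0.07–0.2 s (complete blinks only),
opening 0.23–0.5 s, incomplete-blink troughs at 10–70% of baseline, events
separated by at least one baseline frame. The ranges bracket reported group
means for the phases (closing ≈ 0.15–0.18 s, opening ≈ 0.28–0.35 s) while
keeping both ramps ≥ 6 frames so the k = 5 run rule can resolve them; the
quantization makes ground-truth start/trough/end frames, phase durations
and closed-frame labels exact by construction. The blink profile is
piecewise-linear (descend, hold, ascend) — a deliberate idealization that
makes phase boundaries exact for testing rather than a claim about lid
kinematics. The open-eye baseline defaults to 35% of the image height
(geometric maximum 50%).

Rendering draws the aperture between two parabolic lid arcs meeting at
fixed canthi; closure moves the upper arc down, the lower arc is fixed.
The mask equals the rendered aperture exactly, its maximum column extent is
round(IPH%·image_height) within one pixel, and IPH% = 0 gives an empty
mask. Optional Gaussian noise is added to the waveform (clipped to [0, 1])
and to pixel intensities; masks and ground truth stay noise-free.

What the generator does **not** emulate: eyelashes, iris/pupil texture,
specular highlights, camera motion, illumination drift, partial occlusion,
asymmetric or double-peaked blinks. Passing tests therefore demonstrate the
correctness of the algorithms and the trainability of the architectures on
controlled geometry, not clinical-grade segmentation accuracy on real
videos.

## Statistics

Bland-Altman differences default to percent-of-pair-mean
(d = (a−b)/mean(a,b)·100, pairs with zero mean excluded; 95% limits of
agreement mean ± 1.96 × sample sd), matching how device-agreement results
are usually quoted in percent; a raw-difference mode is available. The ICC
is fixed to the two-way random-effects, absolute-agreement, single-measure
form ICC(2,1) — the form appropriate for "do two devices give the same
number" — computed via pingouin and cross-checked against the closed-form
ANOVA expression in the tests. Cohen's kappa errors on degenerate marginals
(expected agreement 1). The two-group comparison screens both groups with
Shapiro-Wilk at α = 0.05 and applies Student's t-test when both pass,
Mann-Whitney U otherwise, reporting which test ran.

## Numerical and scale choices

* All computation is float32 in the networks; the autograd engine is a
  reverse-mode tape over numpy with im2col convolutions (stride 1) and
  reshape-based pooling/upsampling.
* Empty-vs-empty masks score DSC = IOU = 1 (agreement on absence avoids
  0/0); sensitivity and specificity default to 1 when their denominator is
  empty.
* Probability-to-mask threshold 0.5; segmentation metrics are reported as
  mean ± sd over frames.
* Desk-scale problem sizes used by the test suite and acceptance script —
  64-pair / 128×128 / width-16 segmentation runs, 120-frame / 64×64
  classifier runs, 100 synthetic recordings, 1,000 random waves — are the
  package's own validation sizes, chosen so the full validation completes
  in minutes on one CPU while still exercising every code path end to end.

## Known limitations

* At 30 fps phase boundaries are quantized to 33 ms; no sub-frame
  interpolation is attempted, and blink-speed estimation is out of scope.
* The k = 5 run rule cannot resolve blinks whose closing ramp spans fewer
  than 6 frames; real fast blinks may need k = 3–4.
* The synthetic renderer is geometric, not photometric; models trained on
  it will not transfer to clinical video without retraining.
* Whether an opening phase should end at the return to baseline or at the
  run-rule end frame is observable only at the wave level; this package
  uses the end of the falling run (see above).
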