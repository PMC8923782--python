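# Methods

## Problem and model

Tongue segmentation is binary pixel classification: label 1 (tongue)
versus label 0 (everything else — lips, teeth, skin, background). The
failure mode that motivates the two-stage design is boundary error where
the tongue color is close to the adjoining lip region: a CNN alone
produces masks that spill past or stop short of the true margin
(over-/under-segmentation).

**Stage 1 — UrNet.** A UNet-shaped encoder-decoder whose encoder is built
from ResNet18-style basic units. The exact reconciliation of "ResNet18 as
encoder" with "UNet skip connections" is under-determined, so the builder
commits to one layout and emits an architecture table
(`UrNet.architecture_table()`) so the choice is inspectable:

- stem: 7×7 conv stride 2 + BN + ReLU (no max-pool, so skip features
  exist at 1/2, 1/4, 1/8 and 1/16 resolution);
- four stages of two basic units each, channels (64, 128, 256, 512)
  scaled by `width_multiplier`; the first unit of stages 2–4 downsamples
  by stride 2 with a 1×1-conv projection shortcut;
- decoder: per level, 2× bilinear upsampling, concatenation of the
  same-resolution encoder feature map, then two 3×3 conv+BN+ReLU; a final
  upsample returns to full resolution and a 1×1 conv produces the two
  class scores;
- dropout (rate 0.6) at the bottleneck only — the rate is prescribed, the
  placement was open and the bottleneck is the conventional spot;
- weights are randomly initialized (He normal); no pretraining.

Training: Adam on mean pixelwise cross-entropy; learning rate
`lr(t) = lr₀/(1 + decay·t)` with lr₀ = 1e−3 and decay = 1e−4, where the
iteration counter t is **optimizer steps**, not epochs (with decay 1e−4
the schedule is only meaningful at step granularity). Early stopping halts
training after `patience = 10` consecutive epochs in which the monitored
loss was not *strictly* below the best seen so far; the weights of the
best epoch are restored. The monitored quantity is the training loss by
default (`TrainConfig.monitor = "val"` switches to validation loss; which
one the original protocol used is not stated).

Prediction: per-pixel argmax of the two scores, exact ties resolved to
background so a zero network yields an empty mask rather than a full one.

**Stage 2 — superpixel coverage refinement.** SLIC superpixels are
computed on the input image (not on the mask):

1. seeds on a regular grid with step `S = sqrt(N²/K)`; the grid uses
   spacing ⌊S⌋ with offset ⌊S/2⌋, so the realized count K′ = ⌊N/⌊S⌋⌋² can
   differ from the request K;
2. each seed moves to the minimum-gradient pixel in its 3×3 neighborhood
   (gradient = sum over channels of squared central differences; ties
   keep the original position);
3. windowed assignment: each seed claims pixels in a 2S×2S window by
   minimizing `D′ = sqrt((d_c/m)² + (d_s/S)²)`; `d_c` is Euclidean
   distance in CIELAB (raw RGB available as an ablation), `m` defaults to
   10 on the Lab scale; argmin ties go to the lowest seed id, pixels in
   no window fall back to a global nearest-seed pass;
4. seeds move to their blocks' mean position/color; steps 3–4 iterate up
   to 10 times with early exit when no label changes;
5. labels are made consecutive, and connectivity is enforced (below).

Refinement: per block, coverage = fraction of member pixels the coarse
mask labels tongue. If coverage > θ (strictly — "more than θ") the block
survives, otherwise all its pixels become background. Two survival
semantics are provided because "retained" is genuinely ambiguous:
`retain` keeps the coarse labels inside surviving blocks (refined tongue
⊆ coarse tongue; removes spill only) and `fill` sets surviving blocks
entirely to tongue (can also repair under-segmentation). The default is
`retain`, the literal reading; the sweep can select either.

## Connectivity enforcement (a deliberate design choice)

After the SLIC iterations a block can consist of several connected
components. The component containing the block's seed (or the largest
one, if the seed drifted off-block) is canonical; every other fragment is
merged into the **adjacent block with which it shares the longest
boundary**. An earlier variant that merged fragments into the *largest*
adjacent block by area was measured to be harmful: large background
blocks kept swallowing thin tongue-rim fragments (a rich-get-richer
effect), creating blocks that straddle the color boundary — precisely the
blocks the coverage rule then zeroes wholesale. With boundary-length
merging, the refined-minus-coarse MIoU difference on corrupted synthetic
masks moved from −0.026 to +0.004 (50 seeds), and every block is a single
connected component afterwards. The merge is iterated to a fixed point
(≤ 5 passes) because a fragment's chosen neighbor may itself move.

## Metrics

From pooled confusion counts (TP, FP, FN, TN):

| metric | `formula_mode="paper"` | `formula_mode="standard"` |
|---|---|---|
| PA | (TP+TN)/total | same |
| MPA | ½·[TP/(TP+FP) + TN/(TN+FN)] (precision-like) | ½·[TP/(TP+FN) + TN/(TN+FP)] (recall-based) |
| MIoU | ½·[TP/(TP+FP+FN) + TN/(TN+FN+FP)] | same |
| FWIoU | (TP+FN)/total · TP/(TP+FP+FN) (tongue term only) | Σ_c freq_c·IoU_c |

Paper mode reproduces the printed equations verbatim — including their
quirks: paper MPA uses precision rather than recall, and paper FWIoU
contains only the tongue-class term, so a *perfect* prediction scores the
tongue frequency, not 1. Standard mode provides the conventional
definitions. The accompanying prose definition of FP/FN in the source
protocol is internally inconsistent (it swaps the two and calls
all-background "false negative"); the standard contingency definitions
are used, which make the equations coherent. A 0/0 per-class term (class
absent from both prediction and truth) is dropped from the average and
recorded in `MetricsReport.dropped_terms`.

Cross-validation uses sklearn's shuffled KFold (seeded). Within a fold
the confusion counts of all held-out images are pooled (micro-average)
before metrics are computed; across folds the mean and *sample* (n−1)
standard deviation are reported, matching the mean ± std presentation of
segmentation benchmarks.

The (K, θ) sweep computes the SLIC labeling once per (K, scene) and
reuses it for every θ; the argmax breaks ties toward smaller K, then
smaller θ (cheaper superpixels, gentler threshold).

## Preprocessing and augmentation

Resize to 256×256 (bilinear for images, nearest for masks so labels stay
binary), then normalize `v ↦ 2v/255 − 1`. Augmentation (training only)
applies one random similarity transform per pair — rotation uniform in
±10°, horizontal/vertical shifts uniform in ±0.2 of the side (the bare
0.2 is read as a side fraction, the common convention), horizontal and
vertical flips each with probability 0.5 when enabled — identically to
image and mask, plus an additive per-channel shift uniform in ±0.2 of the
value range on the image only. Pixels exposed by the geometric transform
are filled with the nearest edge value in the image and with background
in the mask, so augmentation cannot create phantom tongue pixels. A
degenerate all-zero configuration is an exact identity.

## Synthetic scenes

`generate_scene` renders, at 256×256 by default: a noisy skin-toned
background; an axis-aligned elliptical tongue (semi-axes 0.22/0.17 of the
side, center at (0.58, 0.50), reddish mean color) with Gaussian texture
noise (sd 8 on the 8-bit scale); and a lip crescent — the ring
1 < ρ ≤ 1.3 of the tongue ellipse restricted to the upper half — whose
mean color sits a controlled Euclidean distance (`lip_tongue_color_gap`,
default 40) from the tongue color. The ground-truth mask is the exact set
of pixel centers with ρ ≤ 1, so a perfect predictor scores exactly 1.0 on
PA/MPA/MIoU. The ellipse is axis-aligned on purpose: the mask then equals
a closed-form point-in-ellipse test, which the tests use as an oracle.

`corrupt_mask` emulates coarse-CNN errors: the boundary is displaced by
thresholding (signed distance transform + smooth Gaussian-filtered noise
field), with the field rescaled so its peak magnitude equals the jitter
bound — hence no flipped pixel lies farther than `boundary_jitter_px`
(default 3) from the original boundary; then `speckle_count` (default 5)
disks of radius 2 are label-flipped. All randomness is seed-derived.

What the generator does **not** emulate: lighting and camera variation,
teeth and specular highlights, anatomical shape variability, fuzzy
margins. Passing tests therefore demonstrate the pipeline's mechanics and
the refinement's direction of effect, not clinical-grade accuracy.

A documented limitation found while validating the generator: the
intended difficulty knob (`lip_tongue_color_gap`) does not measurably
reduce a trained network's held-out MIoU at fixture scale. The scenes are
geometrically stereotyped enough that the CNN learns the tongue shape and
position, so color ambiguity at the lip barely registers in the overall
score (measured 0.988 vs 0.990 mean MIoU for gap 60 vs gap 0 over 5
seeds). The knob still controls the *pixel-level* color separability by
construction; it just does not translate into a monotone end-to-end
difficulty gradient on small stereotyped fixtures.

## Numerical and scale choices

- The CNN runs on a small numpy autodiff engine (`spurnet/nn.py`):
  im2col convolution, batch norm with running statistics, inverted
  dropout, align-corners-false bilinear upsampling, softmax
  cross-entropy; Adam with per-step learning rate. Gradients are verified
  against central finite differences in the test suite. Everything is
  CPU, float32 parameters, deterministic for a fixed seed.
- Test/experiment problem sizes: tiny networks use
  `width_multiplier = 1/8 or 1/16` and 32–64 px scenes (the 7×7 stem and
  the 16× total downsampling are unchanged, so 32 px is the smallest
  legal input). The overfit experiment uses 8 scenes at 64 px and ≤ 200
  epochs with batch size 1 — on an 8-image fixture per-image steps are
  needed for the optimizer to take enough updates within the epoch
  budget; refinement experiments use 50 full-size (256 px) scenes; the
  sweep uses 6 scenes and K ∈ {50, 100, 200, 400}. These sizes were
  chosen so every experiment runs in seconds-to-minutes on one CPU while
  still exercising the full-resolution superpixel stage.
- Tie-breaks are fixed everywhere (argmax/argmin to the lowest index,
  prediction ties to background, coverage strictly greater than θ) so
  identical inputs give identical outputs with no RNG outside the seeded
  generators.
- Degenerate inputs: empty blocks keep their previous seed; 0/0 metric
  terms follow the dropped-term policy; an empty training set, shape
  mismatches, non-binary masks, double normalization and out-of-range
  parameters raise validation errors; NaN loss raises a
  training-diverged error.

## Known limitations

- The numpy engine is single-threaded and orders of magnitude slower
  than a GPU framework; full-size (256 px, width 1.0) training is
  possible but impractical — the package targets method correctness and
  desk-scale experiments.
- `retain` mode can only remove tongue pixels; repairing
  under-segmentation requires `fill` mode, and neither mode can fix a
  coarse mask that misses an entire region no block survives in.
- The FCN/DeepLab baselines of the original comparison are out of scope;
  the evaluation harness accepts any external mask source instead
  (`spurnet refine --masks <dir>`).
- Real clinical images were not available; all quantitative statements
  produced by the tests and `scripts/acceptance.py` are on synthetic
  scenes.
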