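# Methods

## Problem and pipeline

`blinkdetect` detects eye blinks — rapid eyelid closure/reopening
events — in pre-cropped single-eye grayscale video (48×48 pixels,
nominally 25 fps) and reports each blink as an inclusive 1-based
`[start_frame, end_frame]` interval. The pipeline has four stages:

1. **Subsequence classification.** A classifier `C` maps each
   `Ns`-frame window (default `Ns = 12` ≈ 300 ms, the median blink
   duration at 25 fps) to a blink probability in [0, 1]. Every window
   position is scored: starts 1 … N − Ns + 1, step 1, so each interior
   frame is covered by `Ns` windows.
2. **Prediction accumulator.** Window scores are binarized at 0.5 and
   each positive window adds one vote to every frame it covers. The
   accumulator `A` is therefore integer-valued in `[0, Ns]`. The point
   of the dense overlap is robustness to blink splitting: the 3–4
   closed-core frames (`M`) of a blink are fully contained in
   `Ns − M + 1` windows, so a correct classifier drives `A` to a peak
   of 8–10 at the core regardless of how any fixed segmentation would
   have cut the video.
3. **Segmentation.** Grayscale closing (flat structuring element,
   length 3) removes one/two-frame dips that would over-segment. A 1D
   watershed on `−A` partitions frames into basins, one per regional
   maximum of the closed signal, separating consecutive blinks whose
   accumulator values never drop to zero between them. Per basin, if
   the peak reaches the threshold `T` (default `6 = Ns/2`, about half
   the expected blink duration), the maximal contiguous supra-threshold
   run containing the peak becomes one blink interval.
4. **Event-level evaluation.** Predicted and true intervals are matched
   by interval IOU (inclusive frame counting) at a cutoff of 0.2 into a
   binary correspondence matrix `R` (rows = truth, columns =
   predictions). From `R`: `FN` = empty rows; row excess
   `a = Σ_{rows>1}(row−1)`; column excess `b = Σ_{cols>1}(col−1)`;
   double-count correction `c` = entries whose row and column sums both
   exceed 1; `FP = a + b − c + (empty columns)`; `TP = ΣR − FP`.
   Summary scores are `accuracy = 100·TP/(TP+FP+FN)` and
   `F1 = 100·2TP/(2TP+FP+FN)` (true negatives are undefined for event
   detection). These score formulas are not unique to this package but
   were locked by verifying that they reproduce the published
   accuracy/F1 pairs of six detectors from their event counts
   (`tests/test_acceptance.py`).

## Classifiers

Three architectures share the window-in/probability-out contract. No
deep-learning framework is used: the layers (3D convolution via
im2col + GEMM, transposed 3D convolution as its exact adjoint, dense,
ReLU, clipped ReLU, inverted dropout) and Adam are implemented in
numpy with explicit backpropagation, float32 throughout. Gradients are
validated against central differences and the conv/transposed-conv
adjoint identity in `tests/test_nn.py`.

* **cnn3d** — four conv blocks (conv + ReLU + dropout 0.3):
  16 filters 5³ stride (2,2,2) → 32 filters 5³ stride (2,2,2) →
  32 filters 5³ stride 1 → 32 filters 5³ stride (2,2,1 in H,W,D),
  giving the feature-map chain 48×48×12×1 → 24×24×6×16 → 12×12×3×32 →
  12×12×3×32 → 6×6×3×32, flattened into a 2048-unit latent layer, then
  a fully-connected head (256, 64 with ReLU + dropout, 2-way softmax
  read as a blink probability). The head sizes are the smallest
  configuration consistent with "repeated fully-connected blocks".
* **ae3d** — the same encoder and head, plus a decoder of three
  transposed-conv blocks (32, 32, 16 filters, strides inverting the
  encoder) with skip connections concatenating encoder blocks 4, 2
  and 1 onto the decoder inputs, and a final conv + clipped ReLU with
  ceiling 255 so reconstructions are valid 8-bit intensities. Trained
  on `0.9·L_cls + 0.1·L_rec` (binary cross-entropy + voxel MSE); equal
  weights are available but non-default, as the reconstruction term
  otherwise converges first and starves the classifier.
* **resnet3d** — stem conv (64 filters, 3×5×5, stride (2,4,4) in
  D,H,W) + one stack of four 64-filter residual blocks with identity
  shortcuts (first block 3×3×3, the rest 1×3×3 to keep the network
  compact), global average pooling, 2-way head; ≈ 2.3 × 10⁵
  parameters, logged at build time.

Inputs stay in raw 0–255 intensity on disk and in the data containers;
networks scale by 1/255 at entry, while reconstruction targets remain
on the raw scale to match the clipped-ReLU-255 output. Checkpoints are
a numpy `.npz` of parameters plus a YAML architecture manifest.

Training uses Adam (lr 1e-3), batch 16, 30 epochs by default, 20 %
validation split, fully deterministic given the config seed (which
also reseeds dropout masks). Training refuses single-class data.

## Synthetic data

The generator supplies the study conditions for every test: it
emulates the *temporal* statistics of clinical blink video, not its
appearance. Blink durations are discretized normal (mean 12, sd 2,
min 6 frames; median 12 by construction), closed cores 3 or 4 frames
with equal probability, onset gaps exponential with configurable mean.
The scene is a bright sclera ellipse with a dark iris disk on a skin
background; a skin-colored eyelid follows a piecewise-linear
close–hold–open aperture profile; nuisances are additive Gaussian
pixel noise (sd 4) and sub-pixel translational jitter (sd 0.8 px). All
generation is bit-reproducible per seed.

Because the fixture claims only temporal realism, passing tests
demonstrate the correctness of the accumulator/segmentation/metrics
machinery and the trainability of the architectures — not performance
on clinical video, which depends on appearance variation (glasses,
reflections, illumination, head pose) the renderer does not model.

Two oracle classifiers decouple stage testing: a perfect oracle voting
1 exactly when a window fully contains a blink's closed core (so the
accumulator peak on an isolated blink is provably `Ns − M + 1`), and a
noisy oracle flipping votes with a seeded probability. Direct
enumeration gives `Ns − M + 1` windows fully containing an `M`-frame
core, and enumeration is treated as ground truth throughout.

Training sets take one positive window per annotated blink (starting
at the annotated start frame) and negatives sampled uniformly from
blink-free stretches, count-matched 1:1 (class balance is a package
choice).

## Numerical and design choices

* **Window starts run 1 … N − Ns + 1** so every frame receives at least
  one vote. Edge frames receive fewer than `Ns` votes and no
  normalization is applied; blinks within `Ns` frames of the sequence
  ends are therefore harder to detect (known limitation; the generator
  keeps a margin by default).
* **Binarized votes.** Scores are thresholded at 0.5 before
  accumulation, keeping the accumulator integer; soft accumulation of
  raw probabilities exists behind `SegmentationConfig.soft_votes`
  (off by default).
* **Morphology boundary handling.** Dilation pads with the signal
  minimum, erosion with the dilated signal's maximum, so closing is
  extensive, idempotent, order-preserving, and cannot hallucinate edge
  peaks.
* **1D watershed determinism.** Basins are delimited at the
  minimal-value region between consecutive regional maxima; frames of
  a boundary minimum plateau are assigned to the earlier (left) basin,
  processed left to right. Constant or monotone signals yield a single
  segment. The segment count always equals the number of regional
  maxima (cross-checked against `skimage.segmentation.watershed`).
* **Threshold applied to the closed accumulator** — the same signal
  that was watershed-segmented — keeping the two stages consistent.
* **Multiple supra-threshold runs in one segment** (possible for
  jagged classifiers): the run containing the segment peak wins, with
  the earliest peak on ties.
* **Eyes are independent.** No left/right fusion; totals are sums of
  per-eye counts.
* **Negative TP floor.** `TP = ΣR − FP` taken literally goes negative
  when predictions exist but nothing matches (e.g. no true blinks);
  the raw operation warns and returns the literal value, while
  aggregate reporting floors TP at zero.
* **Degenerate inputs.** Sequences shorter than one window raise a
  dedicated error; classifier outputs outside [0, 1] raise a contract
  violation; undefined scores (no events at all) raise rather than
  return NaN silently.

## Problem sizes used in tests

The scaled-down learning check trains the cnn3d on ~390 windows from
two simulated sequences (3600 frames each, mean gap 24 frames), 8
epochs, then requires held-out window accuracy > 0.9 and detection
F1 > 90 on a fresh 1500-frame video — sizes chosen so the full suite
runs on a single desktop CPU core. The clinical-scale results the
architecture family was designed for are represented only by the
published event-count derivations, which the metrics module reproduces
exactly.
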