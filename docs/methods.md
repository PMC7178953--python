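# Methods

This note documents the modelling choices, parameter defaults, numerical
conventions, and known limitations of the package. It states nothing the
test suite or `scripts/acceptance.py` does not itself compute.

## Network

The D2FC-DN is an encoder–decoder segmentation CNN. The encoder applies an
initial 7×7 convolution (16 channels), then three stages of dilated dense
block + transition down; a fourth dilated dense block forms the bottleneck.
The decoder applies three transition-up stages and two final 3×3
convolutions (32, then 1 channel). The dense-block layer counts are
4/5/6/7 with growth rates 8/16/32/64; transition-down widths are 32/64/128
and transition-up widths 448/192/96 at a 384×192 input.

Conventions the architecture description leaves open, and how this package
resolves them:

- **Skip connections and decoder widths.** The tensor forwarded from each
  encoder level is the concatenation of the level input with its dense-block
  output (48/112/256 channels); each transition-up output is concatenated
  with the skip at its resolution before the next transition-up. This is the
  only composition consistent with the stated per-stage output widths and
  yields 4,976,052 trainable parameters (4.98 M), matching the ≈ 4.97 M
  design figure. The dense-block output itself concatenates only the
  per-layer outputs (`n_layers × growth_rate` channels).
- **Dilated convolution** is implemented as true discrete convolution
  `(F *_l k)(p) = Σ_{s+lt=p} F(s)k(t)` (taps applied through the spatially
  flipped kernel), stride 1, zero padding `r·l` per axis so resolution is
  preserved; at `l = 1` it reduces exactly to standard convolution. The
  parameter count is independent of `l`.
- **Transposed convolution**: 3×3, stride 2, with the padding/output-padding
  convention that exactly doubles both spatial dimensions.
- **Output nonlinearity**: sigmoid on the main output and every supervision
  head (binary task trained with Dice on probabilities). Threshold 0.5,
  ties counting as foreground.
- **Supervision heads**: one 1×1 convolution after each transition-up
  stage, followed by sigmoid and bilinear upsampling (half-pixel-centre
  convention) to the input resolution. Heads are used only in the training
  objective.
- **Biases** are included on all convolutions; batch-norm contributes scale
  and shift parameters per channel.

The network runs on an in-package numpy reverse-mode autodiff engine
(`tendonseg.autograd`). Float32 is used for network weights and
activations; the functional ops preserve float64 when tests require
reference precision. All ops are verified against finite-difference
gradients and, for convolution, against direct double-sum evaluation.

## Training

- Initialisation: zero-mean Gaussian with `std = sqrt(2/((2r+1)² c_in))`
  per convolution; biases zero.
- Optimiser: RMSProp (decay 0.9, epsilon 1e-8, no momentum), batch size 4.
- Learning rate: `l_n = l₀ (1 − n/N_e)^α` with `l₀ = 5e-4`, `α = 1.5`,
  updated once per epoch; `N_e` defaults to 50 (20 is the convention for
  series data).
- Loss: each term is `1 −` the soft Dice coefficient
  `2Σpq / (Σp² + Σq² + ε)` with `ε = 1e-6` defining the empty–empty case;
  the printed coefficient form is a similarity, so the minimised loss is its
  complement — maximising it directly would drive the network to degenerate
  masks. Supervision weights `(1/16, 1/8, 1/4)` are indexed coarsest head
  first, so the lowest-resolution level carries the lowest weight. Ground
  truth is compared at full resolution for every term (heads are upsampled
  before the loss).
- Batch normalisation uses batch statistics in training and running
  statistics at inference. The running-average momentum is **0.9**: with the
  short CPU-scale schedules this package targets (hundreds of updates), a
  0.99 momentum leaves the running statistics dominated by early-training
  activations and measurably degrades inference (≈ 0.05 held-out Dice on
  the recovery experiment below); 0.9 tracks the converged statistics while
  remaining a standard convention.
- Inputs are normalised to [0, 1]. Warm-starting from a checkpoint is
  supported (`tendonseg train --warm-start`), which is how cross-dataset
  pre-training is expressed.
- Determinism: given (architecture seed, data, training seed) a run is
  bit-reproducible; all randomness flows through `numpy.random.default_rng`.

## Augmentation

Offline expansion is exactly 10× per image: original, vertical flip, four
random translations (independent axis shifts in [−32, 32] px), and four
random field-of-view scalings (independent margins of 10–50 px cropped from
the borders, then resampled to the native size). The protocol wording also
mentions rotation for the offline stage; the parameter table lists scaling,
which is taken as canonical, and rotation is available via
`AugmentSpec(offline_variant="rotation")`.

Online augmentation applies each of rotation (±10°), shrinking (0–10 %),
translation (±16 px), additive Gaussian noise (σ ≤ 5 intensity levels), and
gamma transformation (γ ∈ [0.7, 1.3]) independently with probability 1/2,
re-drawn every epoch. These ranges are package defaults (the protocol does
not state them) and are configurable. Geometric operations transform image
and mask identically (bilinear vs nearest-neighbour resampling, zero border
fill); intensity operations touch the image only. Every draw is logged so a
transform can be replayed.

## Evaluation measures

Masks are (row, col) boolean arrays, origin top-left. A contour is the
inner boundary: foreground pixels with at least one background 4-neighbour,
image borders counting as adjacent to background. Distances are Euclidean
between pixel centres, in pixels; physical spacing (0.07–0.075 mm/px for
the clinical scanners this targets) is metadata only.

- DSC `2|X∩Y|/(|X|+|Y|)`; MAD (symmetric mean nearest-point distance);
  HD (symmetric Hausdorff); Yasnoff `(100/W)·sqrt(Σ_a min_b d(a,b)²)` — as
  defined it is asymmetric, summing over the predicted contour only, and is
  kept that way.
- CHD: Hausdorff distance between a region's contour and the contour of its
  filled convex hull (computed with `skimage.morphology.convex_hull_image`
  and re-contoured with the same boundary convention, so like is compared
  with like). Convex regions score ≤ 1 px (rasterization tolerance); the
  measure grows with concavity depth.
- Artifact filtering retains the largest 8-connected component (ties break
  to the first component in scan order, deterministically). It is applied
  to HD and CHD only; DSC, MAD and Yasnoff use raw masks.
- Empty predictions: DSC 0, contour measures NaN and flagged, excluded from
  aggregate means.

All five measures are validated against independent brute-force oracles
(O(nm) distance scans, pure-python monotone-chain hull) on random masks.

## Synthetic phantoms

The generator emulates the structure of a transverse A1-pulley scan: a
hyperechoic elliptical tendon, a hypoechoic sheath ring around it (sheath
mask = filled outer ellipse, enclosing the tendon; a ring-only reading can
be derived by subtraction), a bright volar-plate curve below, textured
background, and multiplicative Rayleigh speckle (the standard first-order
speckle approximation), clipped to 8-bit. `bottom_contrast` sets the
intensity step across the tendon's bottom boundary and drives the
clear/fuzzy appearance.

The clear/fuzzy classifier compares the mean intensities of two 15×15
windows centred 8 px above and below the bottom-most tendon boundary row
(on that row's column centroid); an image is clear iff the difference
strictly exceeds 30. The 8-px offset keeps the windows clear of the
boundary itself and is exposed as a parameter; window size and offset scale
proportionally on reduced canvases. Default sampling draws clear phantoms
at contrast 45–90 and fuzzy at 0–18, well separated from the threshold so
intended and realized labels agree (verified ≥ 95 %). Series mode perturbs
the geometry by a small random walk (≤ ~2 px/slice) to emulate a continuous
acquisition group.

What the phantoms do **not** reproduce: real speckle correlation, shadowing
and reverberation artifacts, neighbouring tissues, probe-pressure
deformation, and anatomical variability. Passing the recovery experiment
therefore demonstrates that the architecture, loss, and pipeline are
implemented correctly and can learn this segmentation geometry — not that
clinical-grade accuracy would be reached on real scans.

## Scaled-down recovery experiment

The end-to-end check trains on 64 phantoms at 96×48 and evaluates on 16
held-out phantoms after 20 epochs, passing at mean held-out Dice ≥ 0.9 in
at least 2 of 3 seeds. It uses a width-reduced preset
(`NetworkSpec.reduced()`: initial 8 channels, levels (2,2)/(3,4)/(4,8)/(5,16),
transitions 8/16/32 down and 80/32/16 up, ~164 k parameters) with the same
topology as the full network — three down/up levels, per-layer dilation
schedules, deep supervision. The problem sizes were chosen so the whole
experiment runs in minutes on a single CPU core with the numpy engine; the
full 5 M-parameter network at native resolution is built and shape-verified
(and trainable through the same code path) but is not trained in the test
suite.

## Known limitations

- The numpy engine is single-threaded BLAS-bound; full-scale training at
  384×192 is possible but slow, and no GPU path exists.
- `convex_hull_image` uses half-pixel offset coordinates, so CHD can differ
  from a pixel-centre hull rasterization by up to ~1 px; all CHD contracts
  are stated with that tolerance.
- The classifier requires both windows to fit inside the image and raises
  otherwise rather than shrinking them.
- Checkpoints embed the architecture specification; loading re-builds the
  network, so files are portable but not backward-compatible across
  architecture-spec schema changes.
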