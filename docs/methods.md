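# Methods

## Problem and approach

Coherent fiber bundles relay an image through ~30,000 individual cores;
the cladding between cores transmits no light, so every frame carries a
dark quasi-hexagonal mesh — the honeycomb artifact. `debundle` removes it
with a small convolutional network that maps a raw bundle image directly
to an artifact-free image, and ships everything needed to train, evaluate
and stress that network without hardware: a bundle simulator, the
training-pair synthesis scheme, three classical baselines, the field's
quality metrics, and a minimal mosaicking pipeline.

## Training-pair synthesis

Supervised restoration needs aligned (bundle image, clean image) pairs.
Instead of a dual-sensor rig, pairs are synthesized: an ordinary image is
converted to grayscale (luminance weights 0.299/0.587/0.114), resized to
the acquisition resolution, masked to the circular field of view, and
multiplied pixel-wise by the white reference normalized to [0, 1].
Normalization divides by the global maximum — not min–max — so the
brightest core transmits exactly 1 and the synthetic bundle image never
exceeds the scene: core-pixel intensities are preserved, cladding pixels
are attenuated toward zero. The network is trained against the masked
ground truth; outside-FOV pixels carry no information either way.

## Network

Three convolution layers: 9×9 → 64 maps (patch extraction, sized to
enclose one honeycomb cell at a core pitch of 5–6 px), 1×1 → 32 maps
(nonlinear mapping), 5×5 → 1 (reconstruction); ReLU after the first two.
Training minimizes MSE over 33×33 sub-images cut on a stride-14 grid with
a boundary-aligned final start per axis — the only simple convention that
yields 72 starts per 1024-px axis and hence 5184 patches per image.
Inference is a single forward pass at any image size; the cost is
(f1²n1 + n1f2²n2 + n2f3²)·H·W multiply–accumulates, linear in pixels.

Numerical choices:

- **Padding.** Replicate ("same") padding in both training and inference.
  This keeps the loss defined on full patches and makes restoration
  shape-preserving; the alternative (valid-region crops) complicates
  full-image inference for no measurable gain at this kernel size.
- **Implementation.** Forward and backward passes are numpy: narrow
  layers go through an explicit im2col matrix laid out so BLAS consumes
  its transpose directly; the wide reconstruction layer uses a
  register-blocked direct convolution (numba when available, with an
  equivalent pure-numpy path). The adjoint of replicate padding folds
  boundary gradients back onto edge pixels, rows then columns. The
  forward pass is verified against a naive triple-loop convolution to
  1e-5, the backward pass against central finite differences.
- **Initialization.** `init="gaussian"` draws N(0, 0.001²) weights (the
  SRCNN convention); `init="he"` scales by fan-in. Biases start at zero.
- **Optimizer.** Plain SGD (lr 1e-4, batch 128) is the library default,
  mirroring the published recipe at full scale. "10,000 epochs" is read
  as optimizer steps; a literal epoch over 518,400 patches at batch 128
  would mean ~4×10⁷ updates. True epochs are expressible through
  `iterations`.
- **Determinism.** Initialization and batch order derive from one seed;
  a fixed seed reproduces a run bitwise on the same platform.
- **Failure modes.** A non-finite loss aborts with a diagnostic. Note
  that all-positive inputs make ReLU stacks prone to dying-unit collapse
  (the net degenerates to predicting the mean) when the learning rate is
  near the stability edge or the width is very small — visible as the
  loss plateauing at the target variance.

## Desk-scale study conditions

The full protocol (130 ILSVRC images at 1024², tens of thousands of
steps) is scaled to a single-CPU benchmark that preserves the
architecture, loss, patch geometry and method set:

- 20 synthetic pairs at 256² (16 train / 4 validation), scenes drawn as
  smooth random textures at correlation lengths {2, 3, 4, 6} px,
  contrast-stretched to [0, 1] the way photographs span their range.
- Simulated bundle: hexagonal lattice, core pitch 5.5 px, core width
  σ = 1.1 px, position jitter 0.3 px RMS (real bundles are only
  quasi-hexagonal), per-core transmission spread ±20% (typical of
  leached/fused bundles).
- Training: 2000 steps, batch 64, He initialization, SGD with momentum
  0.9 and lr 0.05. The learning rate and momentum were selected by a
  sweep on training loss (0.15 diverges; 0.1 with momentum 0.95 is
  unstable); batch 64 keeps one benchmark run around four minutes on one
  CPU. The paper-faithful settings remain the `ModelConfig` defaults.

PSNR/SSIM are computed on the held-out pairs exactly as synthesized —
the restoration benchmark evaluates the synthesis model itself, so no
acquisition effects are added there.

## Bar-target acquisition model

Smoothness s = 1 − σ_restored/σ_raw (flat region) and line separation
r = (max Sl − min Sl)/max Sl (profile averaged along the bars) are
measured on a simulated resolution target imaged *through* the bundle.
Unlike training synthesis, a physical acquisition sees three first-order
effects, and all three matter for these metrics:

- **Core-aperture integration**: the scene is pre-blurred by a Gaussian
  of the core width (σ = 1.1 px) before reference multiplication.
- **Stray light**: a diffuse floor of 0.05 inside the FOV.
- **Sensor noise**: additive Gaussian, σ = 0.015 full scale (a typical
  sCMOS figure at video rate).

Without them the r measurement degenerates: exact-zero dark bars pin
min(Sl) = 0, so r saturates at 1 for any method that preserves zeros and
cannot discriminate. The bar period is 6 px ≈ the core pitch, i.e. the
resolution limit of the core lattice — the regime a Rayleigh-type
separation criterion is designed to probe (a resolution chart is read at
its finest resolvable group). This is also the regime that separates the
method families: filters trade detail for smoothness; barycentric
interpolation cannot represent bars below its core-sampling Nyquist
period (2×pitch = 11 px); the learned restoration exploits sub-core
information that the synthesis model preserves. At coarser, fully
resolvable periods the *idealized* simulated interpolation baseline
(perfect core detection on a clean synthetic reference) attains the best
weighted quality — its real-world deficit comes from core-detection and
transmission irregularities the simulator idealizes away, which is worth
keeping in mind when transferring these numbers to real data.

## Baselines

Median 7×7 and Gaussian σ = 3 (kernel truncated at radius ⌈3σ⌉,
normalized), both with replicate borders. The published description is
ambiguous about the Gaussian — "3 × 3" in the text, "standard deviation 3"
in the table footnote; σ = 3 is adopted as the more specific statement.
The interpolation baseline detects cores as local maxima of the lightly
smoothed white reference (non-maximum suppression at 3 px, subpixel
quadratic refinement — integer-grid centers visibly bias sampling at a
5-px pitch), samples the raw image bilinearly at the centers, and fills
the convex hull by barycentric interpolation over a Delaunay
triangulation; linear precision is verified to 1e-6.

## Metrics

PSNR uses the 0–255 convention (`20·log10(255/√MSE)`); unit-interval
rasters are rescaled internally. SSIM uses the standard 11×11
Gaussian-weighted window (σ 1.5, c1 = (0.01L)², c2 = (0.03L)², L = 255),
with a global single-window mode for the bare formula. q(γ) = γs + (1−γ)r
is exact arithmetic; s is offset-invariant while r is max-normalized and
deliberately not. Published-table reproduction uses half-away-from-zero
rounding at 4 decimals, matching how such tables are printed.

## Mosaicking

Shi–Tomasi corners (structure-tensor minimum eigenvalue) with the FOV
mask eroded so the rim contributes no spurious responses. Matching is
block matching: each descriptor patch is NCC-correlated densely over the
next frame within the search radius, the peak refined to subpixel by a
parabolic fit, and the shift taken as the inlier-median of the votes
(inliers at 1 px). Corner-to-corner matching was measurably insufficient:
corner localization on restored frames wobbles ±1–2 px under residual
lattice interference, bounding the error near 1.5 px regardless of the
estimator. Motion is translation-only; frames are averaged onto the
canvas at rounded offsets; a matching failure truncates the mosaic, which
is exactly how the stationary-pattern pathology manifests on unrestored
frames — on raw honeycomb frames the matcher locks onto the (stationary)
lattice and reports near-zero motion.

The simulated scan uses 10 frames of a fine fibrous texture
(correlation length 2 px) translating 8 px per frame, detection at scale
σ = 2 with 21-px descriptors. Per-frame shifts are configurable; the
8-px step keeps the scene's correlation peak separated from the residual
lattice's zero-shift peak by more than the peak width.

## What the simulator does and does not show

The simulator reproduces the geometry and first-order radiometry of a
fiber-bundle system: quasi-hexagonal core lattice, per-core transmission
spread, circular FOV, and (for acquisitions) aperture blur, stray floor
and sensor noise. It does not model inter-core coupling, chromatic
effects, the objective's PSF, nonuniform illumination, or real scene
statistics; scenes are Gaussian random fields and bar patterns. Passing
benchmarks here therefore demonstrates the machinery end to end under
controlled conditions — not performance on clinical imagery. The
interpolation baseline in particular is flattered by the simulator's
clean reference, and the absolute PSNR/SSIM/s/r values depend on every
simulator setting; only identities, counts and method orderings are
treated as conclusions.

## Known limitations

- The network is trained per bundle geometry; a very different core
  pitch needs retraining (the multi-scale extension is out of scope).
- Plain SGD at the published 1e-4 learning rate needs far more than the
  desk-scale budget to converge; the benchmark recipe (He init, momentum)
  exists because of that and is documented where used.
- Mosaicking assumes pure translation and averages overlaps; rotation,
  affine drift and exposure changes are out of scope.
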