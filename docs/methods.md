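# Methods

## Problem

Raman and infrared hyperspectral images (HSIs) of tissue hold a full
vibrational spectrum at every pixel.  Spectral k-means — clustering pixels by
their spectra alone — can separate tissue *compositions*, but two regions
built from the same molecules arranged differently are indistinguishable to
it.  `hsiseg` segments HSIs spatio-spectrally: overlapping image patches are
compressed by a convolutional autoencoder (CAE) into low-dimensional latent
vectors that encode both what spectra are present and how they are arranged,
and a clustering head groups patches with similar latents into tissue
classes.  Feature extraction and clustering can be trained jointly
(end-to-end), so the learned features are tuned for the segmentation rather
than for reconstruction alone.

## Pipeline

1. **Patch decomposition.**  The H x W x B cube is cut into p x p x B
   patches on a raster scan with step s (defaults p = 20, s = 4; a
   240 x 240 cube gives 3136 patches).  Negative intensities are zeroed and
   every patch is divided by the single global maximum of the cube, so
   values lie in [0, 1] and relative amplitudes between patches are
   preserved.
2. **Feature mining.**  A CAE encoder maps each patch to a latent vector
   l̄ of length D (default 100) and a decoder maps it back; pretraining
   minimises mean-squared reconstruction error.
3. **Clustering.**  Soft assignments use a Student's-t kernel around k
   cluster centres μ_j in latent space,

       q_ij = (1 + ||z_i − μ_j||²/α)^(−(α+1)/2) / Σ_j' (…),   α = 1,

   and joint training minimises  L = L_rec + γ · KL(P ‖ Q)  where the target
   distribution sharpens the assignments:

       p_ij = (q_ij²/f_j) / Σ_j' (q_ij'²/f_j'),   f_j = Σ_i q_ij.

   Gradients flow into the centres and, through the encoder, the CAE
   weights.  Centres are initialised by k-means on the pretrained latents.
   Hard labels are the row argmax of Q (ties to the lowest index).

   One conditioning step matters here: the latent scale of a
   reconstruction-trained CAE on [0, 1]-normalised patches is of order
   1e-2, so raw squared distances (~1e-3) are negligible against the
   kernel's unit bandwidth and every soft assignment is near-uniform,
   leaving the sharpening loss inert.  At initialisation the latents are
   therefore rescaled by one scalar — the initial within-cluster RMS
   distance, fixed thereafter — so distances entering the kernel are O(1).
   k-means itself is scale-invariant, so this affects only the soft
   assignments and their gradients.
4. **Reconstruction.**  Patch labels are painted back over their footprints
   in raster order (later patches overwrite earlier ones), reproducing the
   characteristic p-wide smear band at the bottom and right edges, which is
   cropped (plus an s-wide alignment margin) before scoring.  A
   majority-vote reconstruction and an (s, s) shift correction are available
   as alternatives but are off by default so the default output matches the
   protocol the scores refer to.

Scores are pixel-level normalised mutual information (NMI, arithmetic-mean
normalisation; min/geometric/max selectable) and adjusted Rand score (ARS)
against the ground-truth image, both permutation invariant.

## Architectures

All three CAEs share a front / branch / tail skeleton and rectified-linear
hidden activations with a small negative slope (0.01); outputs are linear.
The leaky slope matters: with hard rectifiers the encoder can collapse to a
constant latent early in training (the decoder bias then reconstructs the
mean patch) and never recover.

- **uwu2d** (default): the front is a 1 x 1 spectral-compression
  convolution (B -> 16 channels) followed by a 3 x 3 stride-2 spatial
  convolution producing M activation maps (M = 4 « B).  Each map feeds its
  own branch — two stride-2 3 x 3 convolutions (8, 16 filters) and a dense
  map to the D/M = 25 branch latent.  Branch decoders mirror with
  nearest-neighbour upsampling and end linearly (again to avoid dead
  branches); the tail restores p x p resolution and maps back to B bands
  with a 3 x 3 then a 1 x 1 convolution.  An optional *texture* readout
  (``filter_budget={"texture": t}``) replaces t of the branch-latent dims
  with projected per-channel spatial moments (mean and standard deviation)
  of the conv features: these are translation-invariant, which compacts
  pattern classes whose layout codes vary with stripe phase or globule
  placement.  On the phantom benchmark the default dense readout performed
  at least as well once the clustering kernel was conditioned (below), so
  the option is off by default.
- **generic2d**: a plain stack (1 x 1 spectral, two stride-2 3 x 3 convs,
  dense bottleneck D, same optional texture readout) with filter counts
  chosen so its parameter count matches uwu2d within 20% (measured ratio
  ≈ 0.91), isolating the effect of branching.
- **generic3d**: the patch as a single-channel p x p x B volume through two
  3-D convolutions (kernels 3 x 3 x 7 and 3 x 3 x 5, band-axis strides 4
  and 5, 4 and 8 filters) and a dense bottleneck; deliberately smaller,
  since 3-D filters are costlier per parameter.

The factorised front (point-wise spectral mixing before spatial
convolution) replaces a full 3 x 3 x B convolution; it is the standard
spectral-then-spatial design for HSI feature extraction and is ~3x cheaper
on CPU at equal output shape.

## Training protocol

Adam, learning rate 0.001, batch size 58 throughout.  Pretraining holds out
a 10% validation split and stops when validation loss has not improved for
5 epochs (cap 50); the 3-D architecture instead pretrains a fixed 40 epochs
and caps joint training at 20 epochs.  Joint training refreshes the target
distribution once per epoch and stops when fewer than 0.1% of hard
assignments change after an epoch, or at 50 epochs.  Non-finite losses
trigger a re-initialised restart (at most 3).  The clustering weight γ
defaults to 0.1; k is user-chosen (default 3 for the phantom study, one
class per fat pattern).  All randomness (weights, batch order, k-means
restarts, phantom geometry) flows from explicit seeds.

## Synthetic phantoms

The generator emulates Raman maps of porcine muscle with embedded fat:
a H x W canvas (default 240 x 240) is partitioned into three horizontal
sections — solid fat, striped fat (10-px stripes on a 20-px period), and
randomly placed fat globules (disk radii uniform in [3, 8] px, filled to a
30% area fraction) — and every fat pixel receives one fat spectrum, every
muscle pixel one muscle spectrum.  Spectra are sums of Lorentzian lines over
a linear baseline on a wavenumber axis starting at 444.2 cm⁻¹ with step
1.98 cm⁻¹ for 800 points (the quoted instrument endpoint of 2035.2 cm⁻¹ is
arithmetically inconsistent with that start/step/count — 444.2 + 799 · 1.98
= 2026.22 — so the axis is generated from start, step and count).  The
line lists follow the strong bands of adipose (acyl-chain CH₂ 1301/1440,
ester carbonyl 1746, C=C 1655 cm⁻¹) and muscle tissue (amide I/III,
phenylalanine 1004 cm⁻¹); the measured reference spectra are not tabulated
anywhere, so these synthetic presets stand in for them.  Their correlation
is ≈ 0.59, far below the 0.95 cap required for spectral separability.
Because exactly two pixel spectra exist, fat-vs-muscle separation is trivial
by construction and the only hard task is telling the *patterns* apart —
which requires spatial context and is what the benchmark measures.

What the phantoms do **not** model: instrument noise (optional additive
Gaussian noise exists but defaults to 0), baseline drift, cosmic rays,
spectral mixing at boundaries, or intra-class spectral variability.  Passing
the benchmark therefore shows the machinery works on idealised data; it does
not predict scores on real tissue.

Pattern ground truth labels each section's whole footprint by its pattern
kind (muscle between stripes/globules belongs to its section): the
clustering is expected to group *regions*, not pixels.  A per-section truth
mode exists for sensitivity checks.

## Benchmark sizes

The phantom study runs at 240 x 240 pixels with a 100-point band axis
(default 800 retained for full-scale generation), p = 20, s = 4, k = 3,
three replicate seeds, each drawing a fresh phantom and fresh weights.  The
band count is the main memory/time lever and spectral information is vastly
redundant here (two spectra); the patch geometry and optimiser protocol are
at full scale.  Benchmark pretraining is capped at 40 epochs: on noiseless
phantoms the validation loss decays slowly without plateauing, so the cap,
not the patience rule, sets the length.  One replicate takes a few minutes
on one CPU.

## Numerical choices

- float32 throughout the network; losses accumulated in float64.
- He-style initialisation scaled by fan-in, seeded per architecture config.
- Soft-assignment rows and target rows are exactly normalised; KL uses a
  1e-12 floor under the log to guard empty clusters, and columns with zero
  soft count are excluded from target normalisation with a warning.
- k-means (centre initialisation, CAE+k-means, spectral baseline) uses 10
  restarts and a fixed seed; best inertia wins.
- Equidistant centres give exactly uniform assignments; argmax ties break
  to the lowest cluster index.
- 'Same' convolution padding with output size ceil(n/stride), so encoder
  and decoder shapes mirror exactly for any patch size.

## Known limitations

- Patterns whose defining scale exceeds the patch size cannot be separated;
  patch size is the relevant spatial context window.
- Heavy class imbalance degrades the k-means centre initialisation and
  hence the final segmentation.
- The raster-overwrite reconstruction translates objects by roughly the
  step size and smears the bottom/right edges; cropping (and optionally the
  shift correction) mitigates but does not remove the translation's effect
  on scores.
- Scores on the phantom benchmark vary by a few hundredths across seeds;
  single-seed comparisons between methods are not meaningful.
- In this implementation the end-to-end gain over CAE+k-means is modest and
  seed-dependent: the sharpening step mostly consolidates the k-means
  initialisation rather than repairing it, so both arms are limited by the
  quality of the pretrained latents (and, as the initialisation is k-means,
  by class balance).  Pattern classes are multimodal in latent space —
  stripe-phase and globule-placement variation spread each class over
  several modes — which caps what a k-cluster Euclidean partition of these
  latents can recover.
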