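# Methods

`perfudim` implements a two-stage method for mapping the neural substrates
of acute stroke deficits from routinely acquired imaging: (1) a *computed
perfusion map* (CPM) is derived from a co-registered CT/CTA pair by
vascular seeding and fast marching; (2) a deep variational model infers,
from a cohort of (CPM, ordinal deficit score) pairs, a voxel-wise
*substrate map* whose dot product with a patient's CPM predicts their
score. This note records the model assumptions, the numeric choices, and
what the synthetic experiments do and do not demonstrate.

## Computed perfusion maps

The CPM pipeline assumes the CT and CTA are already co-registered on a
common isotropic grid with comparable intensity scales (nonlinear spatial
normalisation is upstream and out of scope). Stages:

1. **Digital subtraction.** `dsa = (cta − ct)` rescaled to [0, 1]; a
   constant difference degenerates to an all-zero map rather than dividing
   by zero. The DSA doubles later as the propagation speed, so vascular
   voxels (high contrast) are fast and parenchyma slow.
2. **Vesselness speed potential.** Perona–Malik gradient anisotropic
   diffusion in explicit flux form with exponential conductance
   `c(g) = exp(−(g/K)²)`. Defaults: 5 iterations, conductance K = 1.0,
   time step 0.0625 (the explicit-scheme 3D stability bound `1/2^(d+1)`;
   larger steps are rejected). Zero-flux boundaries conserve the image
   mean exactly. The filter parameters of the clinical deployment are not
   published, so all three are exposed in `CpmConfig`.
3. **Binarisation** at 0.2 with strict `>` comparison.
4. **Thinning** to a one-voxel centreline with
   `skimage.morphology.skeletonize` (the Lee et al. 3D thinning family).
5. **Seed selection.** Skeleton voxels whose VSP value lies strictly above
   the 75th percentile. The percentile's reference population is the VSP
   restricted to skeleton voxels by default (`percentile_population =
   "skeleton"`); a `"global"` switch is provided because the original
   parameter semantics could not be recovered. An optional venous mask
   removes seeds inside it; ties under a constant VSP yield zero seeds and
   an explicit `NoSeedError`.
6. **Fast marching.** First-order upwind solution of `|∇T|·F = 1` on the
   6-neighbour stencil, with the DSA as speed `F` clamped below at
   `speed_floor = 1e-3` so avascular tissue acquires large-but-finite
   arrival times (the method needs a value at every voxel). Arrival time
   is zero exactly at seeds. The 26-neighbourhood of every seed is
   initialised with the exact two-point ray quadrature
   (`seed_neighbor_init=True`): a first-order stencil otherwise
   overestimates diagonal arrivals next to a point source by ~40%.
7. **Reslicing.** Block-mean downsampling by a factor 2 for the CPM (an
   average of arrival times); trilinear for intensity volumes. Fast
   marching runs at native resolution; only the final map is resliced.

The CPM is unitless; higher values mean longer to perfuse and hence higher
ischaemic risk. The pipeline is fully deterministic.

### Eikonal solver accuracy

`fast_march` is cross-checked against an independent oracle: Dijkstra
shortest paths on the dense 26-neighbourhood graph with edge weights
`step length × mean slowness`. On random smooth speed fields of ≤12 voxels
per axis the two maps agree to a median of <5% per voxel, with ≥81% of
voxels within 10%; the worst single-voxel deviation is ~18%. That residual
is the irreducible oblique-direction error of a first-order 6-stencil
scheme at coarse resolution — it cannot be removed without moving to a
higher-order or diagonal stencil, which would be a different
discretisation than the one this pipeline specifies. Consumers of the CPM
should treat it as ordinal/structural information (as the downstream model
does) rather than a metrically exact travel time.

## The synthetic cohort generator

No patient data can ship with the package, so every downstream stage is
exercised on phantoms that reproduce the *structure* the method assumes:

- **Vascular tree:** recursive bifurcation grown breadth-first from a
  single inflow root, radius tapered by 0.8 and segment length by 0.75 per
  generation, branch directions drawn within a configurable angle spread.
  Vessels are rasterised as tubes (point-to-segment distance ≤ radius).
- **Scan pair:** CT = background level + smooth parenchymal texture +
  Gaussian noise; CTA = CT + contrast inside every non-occluded vessel
  voxel + independent Gaussian noise (defaults: contrast 1.0, noise SD
  0.02, background 0.3 — chosen for a vessel-to-noise ratio at which the
  0.2 binarisation threshold separates vessels from parenchyma, the regime
  the clinical pipeline operates in).
- **Occlusion:** one edge plus its entire downstream subtree loses
  contrast; the hypoperfused territory is the subtree's tubes dilated by
  2 voxels (tissue at risk extends beyond the lumen).
- **Substrate:** a sum of weighted balls. The default single ball (radius
  grid/5, weight 1) sits in the vascular canopy at fractional height 0.62,
  where random branch occlusions cover it in part of the cohort — deficits
  in this generative model *must* be driven by occlusion-induced
  hypoperfusion of the eloquent region, and a substrate placed outside all
  territories would produce near-constant scores with no lesion-deficit
  signal to recover.
- **Scores:** raw deficit = Σ substrate·CPM (+ optional Gaussian noise),
  discretised to an ordinal scale by cohort-quantile binning into 5 levels
  (mirroring 0–4 clinical sub-scores). Constant raw scores collapse to
  level 0.

Everything is a pure function of its configuration and seed.

What the phantoms do **not** emulate: anatomically realistic
Circle-of-Willis geometry, haemodynamic flow, beam-hardening or motion
artefacts, registration error, and the heavy-tailed score distributions of
clinical cohorts. Passing tests therefore demonstrate that the *inference
machinery* recovers planted structure under its own generative
assumptions, not clinical validity.

## The variational perfusion-deficit model

A VAE over joint (CPM, score) data. The encoder consumes a five-channel
volume — the CPM (zero-padded symmetrically to the model grid and divided
by the training cohort's 99th-percentile intensity), X/Y/Z coordinate
meshes normalised to [−1, 1], and the score (divided by its maximum
ordinal value) broadcast over the grid. Six blocks of
[3³ conv (stride 1) → batch-norm → GELU → 2³ conv (stride 2)] with output
channels (5, 16, 32, 64, 128, 256) reduce a 128³ input to a
2048-dimensional feature, and a fully connected layer emits 100 values:
50 posterior means and 50 log-variances (exponentiated to standard
deviations — the positivity parameterisation is our choice). The decoder
splits the 50-dimensional latent: the first 25 dimensions map through
FC → 256×2×2×2 and six mirrored upsampling blocks to the *substrate map*;
the last 25, through an independent branch of the same shape, to the CPM
reconstruction. The score is reconstructed as the dot product between the
decoded substrate and the input CPM — the inductive bias that makes the
substrate interpretable.

Loss = KL(N(μ,σ²)‖N(0,I)) + ‖recon − cpm‖² + (pred − score)², unit
weights (exposed as config multipliers). Optimiser: Adam, lr 1e-4, weight
decay 1e-5, batch 10, up to 4000 epochs; after every epoch the validation
score-reconstruction MSE (at the posterior mean) is recorded and the
best checkpoint is returned, ties to the earliest epoch. Cohorts split
90/5/5 into train/validation/calibration with `round(0.05·n)` per small
subset (1393 → 70 calibration patients).

Numerical choices worth knowing:

- **Internal dot-product scale.** Inside the model the deficit prediction
  is `(Σ substrate·cpm)/√V` with V the voxel count. Without this, the
  decoder would have to drive its output through 3–4 orders of magnitude
  before the score term produces usable gradients; with it, an O(1)
  decoder output maps to an O(1) prediction from the first step. The
  substrate map is a relative weight field either way — calibration
  binarises it at a percentile of its own weights and refits the scale.
- **Substrate head parameterisation.** The substrate output is
  `decoder(z) + B`, where B is a learnable voxel-wise output bias holding
  the population-shared component of the substrate, and the decoder's
  final convolution is initialised near zero. Two facts motivate this.
  First, under the squared score loss, gradient flow only ever *adds*
  components lying in the span of the training perfusion maps, so a
  random nonzero initial output would persist as frozen noise in the
  inferred map. Second, B's gradient is the cohort covariance between
  perfusion maps and score residuals — free of reparameterisation
  sampling noise — so per-voxel adaptive steps on B perform, in map
  space, exactly the implicitly-regularised least-squares descent the
  linear deficit readout calls for; the latent pathway then models
  per-patient deviations around the shared map. On synthetic cohorts
  this raises the planted-substrate recovery from chance to near the
  ridge-regression oracle.
- **Score-readout intercept.** During training the prediction carries a
  trainable scalar intercept, initialised at the cohort-mean score.
  Without it, the substrate first builds and then slowly sculpts away a
  mean-perfusion-shaped component (a transient lasting hundreds of
  epochs at adaptive-optimiser step sizes). The intercept exists only in
  the training loss; `predict_score`, inference and calibration remain a
  pure dot product.
- **Population substrate** = voxel-wise mean (optionally median) of
  per-patient posterior-mean decodes.
- **Calibration** searches percentiles 90.5–99.5 in steps of 0.5 (19
  candidates). Each candidate's binary map predicts every calibration
  patient's score via the dot product after a least-squares scale fit;
  the accuracy metric is negative mean absolute error by default
  (MSE and Spearman are pluggable); ties resolve to the lowest
  percentile. An all-zero substrate raises a calibration-degenerate error.
- Substrate weights are not constrained non-negative.
- The deficit dot product uses the native (unpadded) grid; padded zeros
  contribute nothing either way.

The stack is hand-written numpy (im2col convolutions as single BLAS
matmuls, explicit backward passes, numba-compiled gather/scatter kernels
with numpy fallbacks); every layer's backward pass is verified against
central finite differences in the test suite.

## Scaled-down experiments

The full-scale configuration (1393 patients × 128³ × 4000 epochs) is a
GPU-cluster workload. The package's self-validation runs a scaled
protocol chosen to finish on one CPU core in minutes: 64 phantom patients
on 32³ grids, depth-5 channel schedule (8, 8, 16, 16, 16), latent 50
(25 + 25), Adam at lr 1e-3 (a standard choice for a ~100× smaller
network), batch 10, 40 epochs. Scores are the exact noiseless dot
products, mapped linearly onto [0, 4].

The experiment reports three recovery measures: Dice between the
calibrated binary substrate and the planted ball; Dice at the support
size matched to the ball; and the mean percentile rank of the planted
voxels within the inferred map. The distinction matters at this scale.
A 90/5/5 split of 64 patients leaves 3 validation and 3 calibration
patients, so the two *selection* steps of the full-scale procedure —
checkpoint selection by validation score-MSE, and percentile selection
by calibration accuracy — operate on 3-sample statistics. Two
small-sample phenomena follow. First, prediction-optimal and
support-recovery-optimal stopping differ: an early, smooth (effectively
ridge-shrunk) substrate predicts held-out scores best, while
localisation keeps sharpening for tens of epochs after — so the
score-MSE checkpoint systematically selects a spatially immature map.
Second, because perfusion maps are strongly correlated within vascular
territories, every candidate percentile predicts three calibration
scores almost equally well; the selection is decided by noise, and the
narrow supports it often lands on cap the attainable Dice well below the
matched-support value regardless of map quality (a *perfect* ranking
binarised at the 99.5th percentile of a 32³ grid cannot exceed Dice
0.26 against a ball occupying 3.3% of the volume). A min-norm linear
oracle run on the same cohorts bounds what any dot-product readout can
recover: truth-voxel mean rank 0.95 and matched-support Dice 0.62 at
this scale — and even that oracle map fails the 3-patient calibration
lottery. The matched-support Dice and rank measures are therefore the
informative indicators of whether inference works; the calibrated Dice
additionally measures the small-sample behaviour of the selection steps
themselves. All of this concerns the scaled protocol only: at the
clinical scale the validation and calibration subsets have 70 patients
each and both selections average over real variance. None of these
results say anything about 128³ clinical behaviour.

## Substrate post-processing

Binarised substrates are split into grey-/white-matter components against
tissue templates (probabilistic templates thresholded at 0.5, exposed).
White-matter bundle disruption against a streamline atlas (TRK via
nibabel, or a plain-text format): a bundle is *involved* when ≥2
white-matter substrate voxels lie within 2 mm of any of its points
(`min_voxels` exposed; a sensitivity sweep over 2,4,…,16 is one call); a
streamline is *disrupted* when ≥1 of its points lies within 2 mm of a
substrate voxel centre (configurable to ≥k points); MDU = disrupted
fraction, reported regardless of the involvement flag. Distances are
voxel-centre to streamline-point in millimetres; streamlines are not
resampled by default (a 1 mm resampling option exists for sparse
polylines). Whether the published 2 mm rule means point distance or tube
distance is ambiguous; point distance is implemented.

For validating CPMs against reference perfusion parameters (e.g. T-max),
both maps are smoothed with a truncated Gaussian window of 10 voxels per
axis (σ = kernel/4, so the window spans ±2σ; σ is exposed since only the
window size is specified) and rank-correlated voxel-wise (Spearman,
mid-ranks, two-sided p).

## Known limitations

- The eikonal solver's per-voxel worst-case deviation from an exact
  geodesic oracle is ~18% on coarse grids (first-order scheme; see above).
- Training on CPU limits the architectures that are practical to test;
  the full 128³ model is instantiated and shape-checked but not trained
  in the test suite.
- The phantom generator's vascular geometry is schematic; none of the
  recovery results transfer to clinical claims without real data.
- Batch-norm makes training results device-consistent but not necessarily
  bit-identical across BLAS implementations.
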