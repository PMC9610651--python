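# Methods

`octdr` implements a computer-aided detection pipeline for diabetic
retinopathy (DR) from 3D macular OCT volumes with co-registered 12-layer
segmentations (NFL through RPE). The pipeline has four stages: per-scan
reflectivity normalization, Laplace-equation layer thickness, first-order
per-layer descriptors, and a two-stage neural-network classifier evaluated
with subject-level cross-validation. A synthetic layered-retina phantom
supplies ground-truthed inputs for every stage.

## Reflectivity normalization

Raw OCT intensity is not comparable across eyes (pupil dilation, media
opacity, scanner gain). Each scan is rescaled affinely using two anatomical
anchors measured on the same scan:

    I_norm = (I − R_V) / (R_12 − R_V)

where `R_V` is the mean intensity over the vitreous voxels (label 13) and
`R_12` the mean over the RPE voxels (label 12). The vitreous then maps to 0
and the RPE to 1 exactly, and the result is invariant to any positive affine
transform of the raw intensities. Values outside [0, 1] are preserved:
hyper-/hypo-reflectivity relative to the anchors carries diagnostic signal.
Anchor contrast below `1e-9 × max(I)` is rejected as degenerate.

Per-layer reflectivity is summarized by first-order statistics of the
normalized intensities pooled over the layer's full 3D extent (all B-scans
together). Pooling over 3D rather than summarizing per B-scan is an
interpretation choice; it weighs every voxel equally and keeps the
descriptor independent of the slice count.

## Laplace-equation layer thickness

Thickness is geometric, not intensity-based. For each layer the potential
γ solves ∇²γ = 0 on the layer's voxels with γ = 0 clamped on the reference
boundary (voxels 6-adjacent to the preceding region) and γ = 1 on the target
boundary (adjacent to the following region). Gradient streamlines of γ
establish a one-to-one correspondence between boundary surfaces, and the
thickness at a boundary voxel is the Euclidean arc length of its streamline
— a measurement that remains perpendicular to the layer where it tilts or
curves, unlike voxel counting along an A-scan column.

Solver details:

- **Stencil.** Jacobi iteration; each interior voxel is replaced by the
  inverse-square-spacing-weighted mean of its six neighbors, which reduces to
  the plain six-neighbor average for isotropic voxels. Anisotropy matters
  because clinical scans are strongly anisotropic along the slice axis.
- **Free faces.** Neighbors outside the layer mask are mirrored (zero-flux),
  so no potential leaks through the open lateral faces or the thin slice
  axis. In 2D (single-slice) mode the slice axis degenerates to this
  reflection and the stencil is effectively 4-neighbor.
- **Initialization.** Interior voxels start at 0.5. This is unbiased between
  the clamped extremes, and because the initial error is then orthogonal to
  the slowest (symmetric) Jacobi mode it roughly halves the iteration count
  relative to a zero start.
- **Convergence test.** Iteration stops when the sup-norm per-iteration
  change `res` *and* the geometric-tail estimate of the remaining error,
  `res·ρ̂/(1−ρ̂)` with ρ̂ the observed ratio of consecutive residuals, both
  fall below `tol` (default 1e-6, `max_iter` 20 000). A bare sup-change
  threshold is not a convergence test on large masks: on a 96³ slab the
  Jacobi rate is ≈ 1 − 7e-4, and stopping at change < 1e-6 leaves a ~1.4e-3
  error; the corrected rule leaves ~1.4e-6. Mask components touching
  neither boundary are rejected (their potential is undetermined).
- **Maximum principle.** The update is a convex average, so γ stays within
  [0, 1] by construction; tests assert it after convergence.

Streamlines are seeded at every target-boundary voxel center and integrated
downhill through the normalized gradient (central differences in physical
coordinates, trilinear interpolation, explicit steps of 0.25·min(spacing)).
Because the clamped boundary voxels corrupt both γ and its discrete gradient
within about one voxel of either surface, the arc length is assembled from
the smooth interior of the field:

1. record the arc positions where the path crosses the γ = 0.9 and γ = 0.1
   iso-levels (sub-step linear interpolation), and the directional
   derivative of γ along the path at each crossing;
2. extrapolate linearly from each crossing to the 1 and 0 levels using that
   slope — this reaches the *effective* discrete boundary (the surface
   through the clamped voxel centers) without crawling along its jagged
   staircase;
3. add a half-voxel boundary-offset cap at each end,
   `0.5·max_a(|n̂_a|·Δ_a)` with `n̂` the local streamline direction, which
   converts center-of-voxel to anatomical-surface thickness.

On an axis-aligned slab of separation 10 this yields exactly 10.0; on a 45°
tilted slab it returns the perpendicular distance (≈10.25, not the 14.1
axial run); on a spherical shell of radii (20, 26) it returns ≈5.96. Traces
that stall on a zero-gradient plateau or exceed 10× a slab-estimate length
are recorded as failures; more than 20% failures in a layer is a hard error.

The thickness descriptor applies the same first-order statistics to the
distribution of streamline lengths of the layer.

## First-order descriptors

Both markers use the same 9-statistic vector: mean, sd, median, p10, p25,
p75, p90, skewness, kurtosis. Conventions are fixed: population (n)
variance, linear interpolation between order statistics, Fisher (excess)
kurtosis; zero-spread samples report 0 for sd/skewness/kurtosis. The set is
configurable; "first-order" means marginal-histogram statistics only — no
spatial co-occurrence features.

## Two-stage classifier

Stage 1 is one multilayer perceptron per layer and marker: 12 reflectivity
networks (67 hidden units), 12 thickness networks (72 hidden units), each
mapping a 9-dim descriptor to a DR probability. Stage 2 fuses the 24
stage-1 DR probabilities with a 6-hidden-unit network. Every network has
exactly one hidden layer, tanh hidden activation and a 2-unit softmax
output; stage-1 outputs feeding the fusion are the DR-class softmax
probabilities. Weights initialize from a seeded zero-mean normal scaled by
1/√fan_in; biases start at zero.

Training is full-batch gradient descent with momentum on mean cross-entropy:
learning rate 0.01, momentum 0.9, epoch cap 2 000, with early stop when the
sup-norm of the parameter update over an epoch drops below 1e-5 ("weights
stable"). These hyperparameters are package defaults chosen to converge
reliably on descriptor-scale inputs; features are standardized (center/scale
learned on the training split only) because raw thickness magnitudes
saturate tanh. Non-finite loss raises with advice to lower the rate.

Stacked classifiers fit naively are optimistically biased: a fusion network
trained on stage-1 resubstitution outputs learns to trust overconfident
probabilities. By default the fusion training matrix is built out-of-fold
from an inner stratified 3-fold split of the training subjects, after which
stage-1 networks are trained on all training subjects ("oof" mode); a
"naive" mode is retained for comparison. Ties at p = 0.5 classify as DR
(screening favors sensitivity); the threshold is configurable.

Everything is seeded and deterministic: identical records and configuration
reproduce byte-identical serialized models.

## Evaluation

DR is the positive class. Splits are always by subject id; k-fold splits
(k = 5, 10) are class-stratified because an 88/100 imbalance risks folds
with a missing class. k-fold results report mean ± sd across folds; LOSO
results are pooled over all subjects, since per-fold sensitivity/specificity
is undefined for a single-subject test set. Reports round to 2 decimals.
The ablation suite reruns the cross-validation for each single layer and
marker (the lone network thresholded at 0.5), each single-marker fusion, and
the combined system — 27 rows per scheme.

`evaluation.REFERENCE_LOSO_RESULTS` holds the published reference study's
LOSO sensitivity/specificity/accuracy triples on its private 100-normal /
88-DR cohort. They are used only for internal-consistency arithmetic checks
of `metrics()` against the implied integer confusion counts; no attempt is
made to reproduce those absolute accuracies, which belong to inaccessible
clinical data.

## Phantom

The phantom emulates a macular OCT volume: twelve stacked layers between
vitreous and background, boundary surfaces depressed by a Gaussian foveal
pit that attenuates linearly with depth (the RPE stays flat), per-layer mean
reflectivity, and multiplicative Gamma speckle (mean 1, CV `noise_cv`) —
Gamma so the first-order statistics stay analytically checkable through the
CV. Between-subject variability is independent multiplicative Gamma jitter
(CV `subject_jitter_cv`) on every layer thickness and reflectivity. The DR
condition applies configurable signed fractional deltas per layer; defaults
thin layer 1 (NFL) by 30% and raise its reflectivity by 15%, which together
with jitter CV 5% and noise CV 10% define the package's standard end-to-end
study. Defaults: 96×96×16 grid at unit spacing (large enough for a
well-posed 3D solve, small enough for minutes-scale experiments; the
clinical 1024×1024×5 geometry is available via configuration), layer
thicknesses 4–7 units, reflectivities between a dark vitreous (40) and a
bright RPE (220).

Realized (post-delta, post-jitter) parameters are recorded as ground truth.
Any layer realized at ≤ 1 voxel (pit included) is rejected with the layer
named. Per-subject generation is keyed by `(spec.seed, subject_seed)`, so
cohorts are reproducible with independent subjects.

What the phantom does *not* model: vasculature and vessel shadows, motion
artifacts, scanner point-spread, spatially correlated speckle, eye-specific
anatomy beyond the pit, or any claim about *which* layers DR truly affects
most. Passing end-to-end tests therefore demonstrates that the pipeline
recovers known, localized effects through the full measurement chain — not
clinical performance.

## Problem sizes and numerical choices in the shipped experiments

The standard end-to-end experiment uses 30 normal + 30 DR subjects at
96×96×16 with LOSO cross-validation, and trains with `max_epochs = 300`
(descriptor-scale inputs with strong effects converge well within this
budget; the package default of 2 000 is kept for harder data). Solver
oracle tests use a full 96³ slab, a (30, 45) spherical shell for the
potential profile (the two free constants of the 1/r profile are fitted
because voxelization blurs the effective radii by a fraction of a voxel;
agreement is tested ≥ 5 voxels clear of the jagged clamped surfaces), and a
(20, 26) shell plus flat/45°-tilted slabs for thickness.

## Known limitations

- Plain Jacobi (no SOR/multigrid) is kept deliberately for transparency; at
  1024×1024 B-scan resolution a solve would take far longer than at the
  phantom's working resolution.
- Streamline thickness near the open lateral faces of a tilted layer bends
  with the zero-flux field and can overshoot; layer-wide summaries absorb
  this (it affects a thin margin of seeds).
- A layer anywhere thinner than 2 voxels has overlapping boundary sets and
  is rejected rather than partially measured.
- The 2D central-slice mode changes the thickness definition (in-plane
  streamlines); its results are comparable between runs of the same mode,
  not directly against 3D values.
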