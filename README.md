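# octdr

3D OCT retinal-layer analysis for diabetic-retinopathy (DR) screening:
per-layer reflectivity, Laplace-equation 3D thickness, and a two-stage
neural-network classifier, exercised end to end on a synthetic
layered-retina phantom with known ground truth.

## The problem

DR damages the retina before vision degrades, and depth-resolved OCT shows
the earliest changes layer by layer. Given a 3D OCT volume and a
co-registered segmentation of the retina into its 12 anatomical layers
(NFL through RPE), this package quantifies each layer with two markers and
classifies the eye:

1. **First-order reflectivity.** Intensities are normalized per scan by
   anchoring the mean vitreous intensity to 0 and the mean RPE intensity
   to 1, `I' = (I − R_V)/(R_12 − R_V)`, making scans comparable across eyes
   and scanners; each layer is then summarized by nine first-order
   statistics of its normalized intensity distribution.
2. **3D thickness.** The Laplace equation ∇²γ = 0 is solved between each
   layer's two boundary surfaces (γ clamped to 0 and 1) by Jacobi
   iteration; gradient streamlines of γ pair corresponding boundary voxels,
   and the streamline arc length is the local layer thickness — a tilt- and
   curvature-robust alternative to counting voxels down an A-scan.
3. **Two-stage classification.** One small MLP per layer and marker
   (12 reflectivity nets with 67 hidden units, 12 thickness nets with 72)
   each emit a DR probability; a fusion net (6 hidden units) combines the
   24 probabilities into the final diagnosis. All nets are tanh/softmax,
   trained by backpropagation with momentum until the weights stabilize,
   with anti-leakage out-of-fold construction of the fusion training
   matrix. Evaluation is subject-level 5-fold, 10-fold, or
   leave-one-subject-out (LOSO) cross-validation reporting sensitivity,
   specificity and accuracy (DR positive).

Clinical OCT datasets of this kind are private, so the package ships a
phantom generator producing cohorts of layered volumes with a foveal pit,
speckle-like noise, between-subject jitter, and configurable DR effects —
every stage is testable against analytic ground truth.

## Worked example

```python
from octdr import (PhantomSpec, generate_phantom, compute_normalization_stats,
                   normalize_reflectivity, compute_layer_thickness,
                   layer_reflectivity_features)

spec = PhantomSpec(seed=1)                        # 96x96x16 default grid
vol, labels, gt = generate_phantom(spec, "DR", subject_seed=3)

stats = compute_normalization_stats(vol, labels)
norm = normalize_reflectivity(vol, stats)
refl = layer_reflectivity_features(norm, labels, layer_id=1)
tmap = compute_layer_thickness(labels, layer_id=1, spacing=vol.spacing)

print(f"layer 1 mean reflectivity {refl.values[0]:.3f}")
print(f"layer 1 mean thickness    {tmap.valid_lengths.mean():.2f} "
      f"(ground truth {gt.true_layer_thickness[0]:.2f})")
```

prints

```
layer 1 mean reflectivity 0.737
layer 1 mean thickness    4.75 (ground truth 4.87)
```

— the DR subject's NFL is thinned (base 7.0 units, −30% DR delta plus
subject jitter) and the streamline thickness recovers the realized value to
a few percent; its reflectivity sits at 0.74 on the vitreous(0)–RPE(1)
scale after the +15% DR shift.

The full experiment — cohort simulation, feature extraction, training,
cross-validation — runs from one config file:

```bash
octdr simulate --config config.yaml
octdr features --config config.yaml          # add --mode 2d for central-slice
octdr train    --config config.yaml
octdr evaluate --config config.yaml --scheme loso
```

A LOSO evaluation of the default phantom study (30 normal + 30 DR subjects,
layer-1 thinning −30%, layer-1 reflectivity +15%, 5% subject jitter) emits:

```
loso cross-validation over 60 subjects
  sensitivity: 100.00%
  specificity: 100.00%
     accuracy: 100.00%
  pooled counts: tp=30 fp=0 tn=30 fn=0
```

with single-marker fusions at 91.67% (reflectivity) and 100% (thickness) —
the configured effects are strong and localized, and the pipeline recovers
them through the full measurement chain.

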