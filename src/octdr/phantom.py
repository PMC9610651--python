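"""Synthetic layered-retina phantoms with known thickness and reflectivity.

The phantom emulates macular OCT volumes: twelve stacked, gently curved
retinal layers between vitreous above and background below, a Gaussian
foveal pit depressing the inner surfaces, per-layer mean reflectivity, and
multiplicative speckle-like noise.  A "DR" condition applies configurable
signed fractional changes to selected layers' thickness and reflectivity;
between-subject biological variability enters as independent multiplicative
jitter on every layer parameter.

Because both the geometry and the intensity model are analytic, every
downstream stage (normalization, Laplace-equation thickness, classification)
can be tested against known ground truth without any real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volio import (CLASS_DR, CLASS_NORMAL, CLASSES, N_LAYERS, GridSpacing,
                    LayerLabelMap, OCTVolume, SubjectRecord)

# Defaults chosen to look like a macular scan at the package's working
# resolution: 12 layers totalling 58 length units under 14 units of vitreous,
# NFL moderately bright, the EZ and RPE bands the brightest, vitreous dark.
DEFAULT_THICKNESS = (7.0, 5.0, 4.0, 4.0, 6.0, 5.0, 4.0, 4.0, 5.0, 4.0, 4.0, 6.0)
DEFAULT_REFLECTIVITY = (160.0, 110.0, 120.0, 90.0, 115.0, 70.0,
                        100.0, 95.0, 180.0, 120.0, 140.0, 220.0)
# DR condition: thin the innermost (NFL) layer by 30% and raise its
# reflectivity by 15%.  These are the study conditions of the package's
# end-to-end experiments, not a biological claim; both vectors are fully
# configurable per layer.
DEFAULT_DR_THICKNESS_DELTA = (-0.30,) + (0.0,) * 11
DEFAULT_DR_REFLECTIVITY_DELTA = (0.15,) + (0.0,) * 11


class PhantomError(ValueError):
    """Raised when a phantom specification cannot produce a valid volume."""


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of the phantom population.

    Lengths are in arbitrary physical units (voxel spacing converts them to
    voxels); intensities are in arbitrary raw scanner units.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 16)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    layer_thickness: tuple[float, ...] = DEFAULT_THICKNESS
    layer_reflectivity: tuple[float, ...] = DEFAULT_REFLECTIVITY
    vitreous_reflectivity: float = 40.0
    background_reflectivity: float = 25.0
    retina_top: float = 14.0          # mean depth of the inner retinal surface
    pit_depth: float = 3.0            # foveal pit depth; 0 disables the pit
    pit_radius: float = 15.0          # Gaussian radius of the pit
    noise_cv: float = 0.10            # CV of multiplicative speckle factor
    dr_thickness_delta: tuple[float, ...] = DEFAULT_DR_THICKNESS_DELTA
    dr_reflectivity_delta: tuple[float, ...] = DEFAULT_DR_REFLECTIVITY_DELTA
    subject_jitter_cv: float = 0.05   # between-subject CV on layer parameters
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(int(s) < 4 for s in self.grid_shape):
            raise PhantomError(f"grid_shape components must be >= 4, got {self.grid_shape}")
        for name in ("layer_thickness", "layer_reflectivity",
                     "dr_thickness_delta", "dr_reflectivity_delta"):
            if len(getattr(self, name)) != N_LAYERS:
                raise PhantomError(f"{name} must have {N_LAYERS} entries")
        if any(t <= 0 for t in self.layer_thickness):
            raise PhantomError("all base layer thicknesses must be > 0")
        if any(t * (1 + d) <= 0 for t, d in
               zip(self.layer_thickness, self.dr_thickness_delta)):
            raise PhantomError("dr_thickness_delta drives a layer thickness <= 0")
        if not 0 <= self.noise_cv < 1:
            raise PhantomError(f"noise_cv must be in [0, 1), got {self.noise_cv}")
        if self.subject_jitter_cv < 0:
            raise PhantomError("subject_jitter_cv must be >= 0")
        if self.pit_depth < 0 or self.pit_radius <= 0:
            raise PhantomError("pit_depth must be >= 0 and pit_radius > 0")
        GridSpacing.from_any(self.spacing)  # validates positivity


@dataclass(frozen=True)
class GroundTruth:
    """Realized (post-jitter, post-delta) per-subject layer parameters."""

    true_layer_thickness: tuple[float, ...]
    true_layer_reflectivity: tuple[float, ...]
    class_label: str

    def __post_init__(self):
        if any(t <= 0 for t in self.true_layer_thickness):
            raise PhantomError("ground-truth thicknesses must be positive")
        if self.class_label not in CLASSES:
            raise PhantomError(f"class_label must be one of {CLASSES}")


def _jitter_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Multiplicative mean-1 Gamma factors with the requested CV."""
    if cv == 0:
        return np.ones(n)
    shape = 1.0 / cv ** 2
    return rng.gamma(shape, 1.0 / shape, size=n)


def generate_phantom(spec: PhantomSpec, class_label: str, subject_seed: int
                     ) -> tuple[OCTVolume, LayerLabelMap, GroundTruth]:
    """Generate one subject's volume, label map and realized ground truth.

    Deterministic in ``(spec.seed, subject_seed)``: the same inputs always
    yield bit-identical outputs.
    """
    if class_label not in CLASSES:
        raise PhantomError(f"class_label must be one of {CLASSES}")
    if subject_seed < 0:
        raise PhantomError("subject_seed must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed) & 0x7FFFFFFF,
                                                        int(subject_seed)]))
    nx, ny, nz = (int(s) for s in spec.grid_shape)
    spacing = GridSpacing.from_any(spec.spacing)

    thick = np.asarray(spec.layer_thickness, dtype=float)
    refl = np.asarray(spec.layer_reflectivity, dtype=float)
    if class_label == CLASS_DR:
        thick = thick * (1.0 + np.asarray(spec.dr_thickness_delta))
        refl = refl * (1.0 + np.asarray(spec.dr_reflectivity_delta))
    thick = thick * _jitter_factors(rng, spec.subject_jitter_cv, N_LAYERS)
    refl = refl * _jitter_factors(rng, spec.subject_jitter_cv, N_LAYERS)

    # The pit thins each layer by pit_depth/12 at the foveal center; account
    # for it in the minimum-thickness guard.
    min_thick_vox = (thick - spec.pit_depth / N_LAYERS) / spacing.dx
    too_thin = np.where(min_thick_vox <= 1.0)[0]
    if too_thin.size:
        k = int(too_thin[0]) + 1
        raise PhantomError(
            f"layer {k}: realized thickness {thick[k - 1]:.3f} is <= 1 voxel "
            "after jitter/delta/pit; too thin to segment features from"
        )

    # Boundary depth surfaces B_0..B_12 (physical units).  The Gaussian pit
    # depresses the inner boundaries and attenuates linearly with depth so the
    # outer retina (RPE) stays flat, as in a real fovea.
    y = (np.arange(ny) - (ny - 1) / 2.0) * spacing.dy
    z = (np.arange(nz) - (nz - 1) / 2.0) * spacing.dz
    r2 = y[:, None] ** 2 + z[None, :] ** 2
    pit = spec.pit_depth * np.exp(-r2 / (2.0 * spec.pit_radius ** 2))
    cum = np.concatenate([[0.0], np.cumsum(thick)])            # (13,)
    atten = 1.0 - np.arange(N_LAYERS + 1) / N_LAYERS           # 1 -> 0
    bounds = (spec.retina_top + cum[:, None, None]
              + pit[None, :, :] * atten[:, None, None])        # (13, ny, nz)

    bounds_vox = bounds / spacing.dx
    if bounds_vox[0].min() < 1.0:
        raise PhantomError("retina_top too small: no vitreous above the retina")
    if bounds_vox[-1].max() > nx - 1.0:
        raise PhantomError(
            f"retina bottom ({bounds_vox[-1].max():.1f} voxels) exceeds the "
            f"axial extent ({nx}); enlarge the grid or shrink the layers"
        )

    depth = np.arange(nx)[:, None, None] + 0.5                 # voxel centers
    region = (depth[None] >= bounds_vox[:, None, :, :]).sum(axis=0)  # 0..13
    code_lut = np.array([13] + list(range(1, N_LAYERS + 1)) + [0], dtype=np.int16)
    labels = code_lut[region]

    mean_lut = np.array([spec.vitreous_reflectivity, *refl,
                         spec.background_reflectivity])
    intensities = mean_lut[region]
    if spec.noise_cv > 0:
        shape = 1.0 / spec.noise_cv ** 2
        intensities = intensities * rng.gamma(shape, 1.0 / shape,
                                              size=intensities.shape)

    vol = OCTVolume(intensities, spacing, subject_id=f"S{subject_seed:04d}")
    labmap = LayerLabelMap(labels)
    gt = GroundTruth(tuple(float(t) for t in thick),
                     tuple(float(r) for r in refl), class_label)
    return vol, labmap, gt


def generate_cohort(spec: PhantomSpec, n_normal: int, n_dr: int
                    ) -> list[SubjectRecord]:
    """Deterministically enumerate a labeled cohort of subject records.

    Records carry identity, class and a per-subject seed; volumes are
    materialized on demand with :func:`realize_subject` so large cohorts never
    need to be held in memory at once.
    """
    if n_normal < 1 or n_dr < 1:
        raise PhantomError("need at least one subject per class")
    records = []
    for i in range(n_normal + n_dr):
        label = CLASS_NORMAL if i < n_normal else CLASS_DR
        prefix = "N" if label == CLASS_NORMAL else "D"
        records.append(SubjectRecord(
            subject_id=f"{prefix}{i:04d}", class_label=label, seed=i))
    return records


def realize_subject(spec: PhantomSpec, record: SubjectRecord
                    ) -> tuple[OCTVolume, LayerLabelMap, GroundTruth]:
    """Generate the volume/labels/ground truth for one cohort record."""
    vol, labels, gt = generate_phantom(spec, record.class_label, record.seed)
    vol.subject_id = record.subject_id
    return vol, labels, gt
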