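"""Reflectivity normalization against vitreous/RPE anchors and per-layer features.

Raw OCT intensity depends on pupil dilation, media opacity and scanner gain,
so intensities are made comparable across eyes by an affine rescaling that
maps the mean vitreous intensity to 0 and the mean retinal-pigment-epithelium
(RPE, layer 12) intensity to 1:

    I_norm = (I - R_V) / (R_12 - R_V)

where ``R_V`` and ``R_12`` are the arithmetic means over the vitreous and RPE
voxels of the same scan.  The transform is invariant to any positive affine
rescaling of the raw intensities, and values outside [0, 1] are deliberately
preserved: hyper- or hypo-reflectivity relative to the anchors is signal.

Per-layer reflectivity features are first-order statistics of the normalized
intensities pooled over the full 3D layer (see :mod:`octdr.descriptors`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .descriptors import DescriptorConfig, LayerFeatureVector, descriptor_from_sample
from .volio import KIND_REFLECTIVITY, N_LAYERS, RPE, VITREOUS, LayerLabelMap, OCTVolume


class NormalizationError(ValueError):
    """Raised for missing anchor regions or degenerate anchor contrast."""


@dataclass(frozen=True)
class NormalizationStats:
    """Anchor means used by the normalization, in raw intensity units."""

    rv: float            # mean vitreous intensity
    r12: float           # mean RPE intensity
    n_vitreous: int
    n_rpe: int

    def __post_init__(self):
        if self.n_vitreous < 1 or self.n_rpe < 1:
            raise NormalizationError("anchor regions must contain >= 1 voxel")


def compute_normalization_stats(vol: OCTVolume, labels: LayerLabelMap,
                                epsilon: float | None = None
                                ) -> NormalizationStats:
    """Arithmetic anchor means over the vitreous (code 13) and RPE (code 12).

    ``epsilon`` is the minimum acceptable anchor contrast ``|R12 - RV|``;
    the default is ``1e-9 * max(intensity)``.
    """
    if vol.shape != labels.shape:
        raise NormalizationError(
            f"volume shape {vol.shape} != label shape {labels.shape}")
    arr = vol.intensities
    vit = arr[labels.labels == VITREOUS]
    rpe = arr[labels.labels == RPE]
    for name, region in (("vitreous (code 13)", vit), ("RPE (code 12)", rpe)):
        if region.size == 0:
            raise NormalizationError(f"no {name} voxels to anchor the normalization")
    rv = float(vit.mean())
    r12 = float(rpe.mean())
    if epsilon is None:
        epsilon = 1e-9 * float(np.abs(arr).max() or 1.0)
    if abs(r12 - rv) <= epsilon:
        raise NormalizationError(
            f"degenerate anchor contrast |R12 - RV| = {abs(r12 - rv):.3g} <= "
            f"{epsilon:.3g}; vitreous and RPE intensities are indistinguishable"
        )
    return NormalizationStats(rv=rv, r12=r12,
                              n_vitreous=int(vit.size), n_rpe=int(rpe.size))


def normalize_reflectivity(vol: OCTVolume, stats: NormalizationStats) -> OCTVolume:
    """Apply ``(I - RV) / (R12 - RV)`` voxelwise; output is dimensionless.

    Values outside [0, 1] are preserved, not clipped.
    """
    if stats.r12 == stats.rv:
        raise NormalizationError("degenerate stats: R12 == RV")
    out = (vol.intensities - stats.rv) / (stats.r12 - stats.rv)
    return OCTVolume(out, vol.spacing, subject_id=vol.subject_id, eye=vol.eye,
                     normalized=True)


def layer_reflectivity_features(normvol: OCTVolume, labels: LayerLabelMap,
                                layer_id: int,
                                descriptor_config: DescriptorConfig | None = None
                                ) -> LayerFeatureVector:
    """First-order statistics of one layer's normalized intensities.

    The layer's voxels are pooled over the full 3D extent (all B-scans).
    """
    if not 1 <= layer_id <= N_LAYERS:
        raise NormalizationError(f"layer_id must be in 1..12, got {layer_id}")
    if normvol.shape != labels.shape:
        raise NormalizationError(
            f"volume shape {normvol.shape} != label shape {labels.shape}")
    sample = normvol.intensities[labels.labels == layer_id]
    if sample.size == 0:
        raise NormalizationError(f"layer {layer_id} has no voxels")
    return descriptor_from_sample(sample, layer_id, KIND_REFLECTIVITY,
                                  descriptor_config)
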