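"""End-to-end feature extraction: volume + labels -> per-layer descriptors.

Binds the normalization, reflectivity-descriptor and Laplace-thickness stages
into a single call per subject, in either full-3D mode or a 2D mode that
keeps only the central B-scan (for like-for-like comparison of 2D versus 3D
analysis of the same cohort).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import phantom as ph
from .descriptors import DescriptorConfig
from .reflectivity import (compute_normalization_stats, layer_reflectivity_features,
                           normalize_reflectivity)
from .thickness import (extract_boundaries, layer_thickness_features,
                        layer_thickness_map, solve_laplace)
from .volio import (KIND_REFLECTIVITY, KIND_THICKNESS, N_LAYERS, GridSpacing,
                    LayerLabelMap, OCTVolume, SubjectRecord)


@dataclass(frozen=True)
class SolverConfig:
    """Laplace-solver settings shared by every layer of a run."""

    tol: float = 1e-6
    max_iter: int = 20_000
    mode: str = "3d"          # "3d" or "2d" (central slice only)

    def __post_init__(self):
        if self.mode not in ("3d", "2d"):
            raise ValueError(f"mode must be '3d' or '2d', got {self.mode!r}")


def _central_slice(vol: OCTVolume, labels: LayerLabelMap
                   ) -> tuple[OCTVolume, LayerLabelMap]:
    mid = vol.shape[2] // 2
    v = OCTVolume(vol.intensities[:, :, mid:mid + 1], vol.spacing,
                  subject_id=vol.subject_id, eye=vol.eye,
                  normalized=vol.normalized)
    return v, LayerLabelMap(labels.labels[:, :, mid:mid + 1])


def extract_subject_features(vol: OCTVolume, labels: LayerLabelMap,
                             descriptor: DescriptorConfig | None = None,
                             solver: SolverConfig | None = None) -> dict:
    """Both markers for all 12 layers of one subject.

    Returns a dict mapping ``(kind, layer_id)`` to a LayerFeatureVector.
    """
    descriptor = descriptor or DescriptorConfig()
    solver = solver or SolverConfig()
    if solver.mode == "2d":
        vol, labels = _central_slice(vol, labels)
    stats = compute_normalization_stats(vol, labels)
    norm = normalize_reflectivity(vol, stats)
    features = {}
    for layer in range(1, N_LAYERS + 1):
        features[(KIND_REFLECTIVITY, layer)] = layer_reflectivity_features(
            norm, labels, layer, descriptor)
        ref, tgt, mask = extract_boundaries(labels, layer)
        fld = solve_laplace(mask, ref, tgt, vol.spacing, tol=solver.tol,
                            max_iter=solver.max_iter, layer_id=layer)
        tmap = layer_thickness_map(fld)
        features[(KIND_THICKNESS, layer)] = layer_thickness_features(
            tmap, descriptor)
    return features


def build_cohort_records(spec: ph.PhantomSpec, n_normal: int, n_dr: int,
                         descriptor: DescriptorConfig | None = None,
                         solver: SolverConfig | None = None,
                         progress: bool = False) -> list[SubjectRecord]:
    """Generate a phantom cohort and extract every subject's features.

    Volumes are materialized one at a time and discarded; only the feature
    vectors and ground truth are kept on the records.
    """
    records = ph.generate_cohort(spec, n_normal, n_dr)
    for i, rec in enumerate(records):
        vol, labels, gt = ph.realize_subject(spec, rec)
        rec.ground_truth = gt
        rec.features = extract_subject_features(vol, labels, descriptor, solver)
        if progress and (i + 1) % 10 == 0:
            print(f"  extracted features for {i + 1}/{len(records)} subjects")
    return records
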