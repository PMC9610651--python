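import numpy as np
import pytest

from octdr.descriptors import DEFAULT_STATS, LayerFeatureVector
from octdr.phantom import PhantomSpec
from octdr.volio import KINDS, SubjectRecord

# compact spec used wherever full resolution is unnecessary: 12 thin-but-
# resolvable layers in a 64-voxel axial extent
SMALL_THICKNESS = (4.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 3.0, 4.0)


@pytest.fixture
def small_spec():
    return PhantomSpec(grid_shape=(64, 48, 8), retina_top=8.0,
                       layer_thickness=SMALL_THICKNESS, pit_depth=1.5,
                       pit_radius=10.0, seed=7)


@pytest.fixture
def clean_spec():
    """Noise-free, jitter-free, pit-free spec: geometry is exactly the base."""
    return PhantomSpec(grid_shape=(96, 48, 8), noise_cv=0.0, pit_depth=0.0,
                       subject_jitter_cv=0.0, seed=0)


def synthetic_records(n_per_class=20, shift=2.0, seed=0,
                      affected=(("reflectivity", 1), ("thickness", 1))):
    """Feature-level records with a class shift on the affected (kind, layer)s.

    Bypasses the imaging pipeline: useful for classifier/evaluation tests
    that only need records with known separability.
    """
    rng = np.random.default_rng(seed)
    records = []
    for i in range(2 * n_per_class):
        is_dr = i >= n_per_class
        feats = {}
        for kind in KINDS:
            for layer in range(1, 13):
                mu = shift if (is_dr and (kind, layer) in affected) else 0.0
                feats[(kind, layer)] = LayerFeatureVector(
                    layer, kind, rng.normal(mu, 1.0, len(DEFAULT_STATS)),
                    DEFAULT_STATS)
        records.append(SubjectRecord(
            subject_id=f"{'D' if is_dr else 'N'}{i:03d}",
            class_label="DR" if is_dr else "normal", seed=i, features=feats))
    return records


@pytest.fixture
def feature_records():
    return synthetic_records()
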