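"""First-order (histogram) descriptors of per-layer value distributions.

Both markers — a layer's normalized reflectivity and its streamline thickness
— are summarized by the same fixed-length vector of first-order statistics of
the pooled value distribution.  "First-order" means statistics of the marginal
histogram only; no spatial co-occurrence information enters.

Conventions are fixed rather than inherited from library defaults: population
(``n``-denominator) variance, linear interpolation between order statistics
for percentiles, and Fisher (excess) kurtosis.  Degenerate samples (a single
value, or zero spread) report 0 for sd/skewness/kurtosis with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

DEFAULT_STATS = ("mean", "sd", "median", "p10", "p25", "p75", "p90",
                 "skewness", "kurtosis")


@dataclass(frozen=True)
class DescriptorConfig:
    """Which first-order statistics make up a layer feature vector."""

    stats: tuple[str, ...] = DEFAULT_STATS

    def __post_init__(self):
        unknown = set(self.stats) - set(DEFAULT_STATS)
        if unknown:
            raise ValueError(f"unknown statistics: {sorted(unknown)}")
        if len(self.stats) == 0:
            raise ValueError("descriptor needs at least one statistic")

    @property
    def length(self) -> int:
        return len(self.stats)


@dataclass
class LayerFeatureVector:
    """Fixed-length first-order descriptor of one layer's marker distribution."""

    layer_id: int
    kind: str
    values: np.ndarray
    stat_names: tuple[str, ...]

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or len(vals) != len(self.stat_names):
            raise ValueError("values and stat_names must be 1D and equally long")
        if not np.all(np.isfinite(vals)):
            raise ValueError(
                f"non-finite descriptor for layer {self.layer_id} ({self.kind})"
            )
        self.values = vals
        self.stat_names = tuple(self.stat_names)


def first_order_stats(sample: np.ndarray,
                      config: DescriptorConfig | None = None) -> dict[str, float]:
    """Compute the configured first-order statistics of a 1D sample."""
    config = config or DescriptorConfig()
    x = np.asarray(sample, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    mean = float(np.mean(x))
    var = float(np.mean((x - mean) ** 2))  # population convention
    sd = float(np.sqrt(var))
    if x.size == 1:
        warnings.warn("single-value sample: sd/skewness/kurtosis reported as 0",
                      stacklevel=2)
    if sd > 0:
        z = (x - mean) / sd
        skew = float(np.mean(z ** 3))
        kurt = float(np.mean(z ** 4) - 3.0)  # excess kurtosis
    else:
        skew = kurt = 0.0
    out = {
        "mean": mean,
        "sd": sd,
        "median": float(np.median(x)),
        "p10": float(np.percentile(x, 10)),
        "p25": float(np.percentile(x, 25)),
        "p75": float(np.percentile(x, 75)),
        "p90": float(np.percentile(x, 90)),
        "skewness": skew,
        "kurtosis": kurt,
    }
    return {name: out[name] for name in config.stats}


def descriptor_from_sample(sample: np.ndarray, layer_id: int, kind: str,
                           config: DescriptorConfig | None = None
                           ) -> LayerFeatureVector:
    config = config or DescriptorConfig()
    stats = first_order_stats(sample, config)
    return LayerFeatureVector(layer_id=layer_id, kind=kind,
                              values=np.array(list(stats.values())),
                              stat_names=tuple(stats.keys()))
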