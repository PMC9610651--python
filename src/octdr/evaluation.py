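"""Subject-level cross-validation and sensitivity/specificity/accuracy reporting.

The positive class is DR throughout.  Splits are always by subject id, so no
subject contributes to both sides of any fold; k-fold splits are additionally
class-stratified (with a 100/88 class balance, unstratified folds risk a
training split with one class missing).  Leave-one-subject-out (LOSO) results
are pooled over all subjects, since per-fold sensitivity/specificity is
undefined for a single-subject test set; k-fold results are reported as
mean +/- sd across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .classifier import (TrainConfig, fit_single_feature, fit_two_stage)
from .volio import (CLASS_DR, KIND_REFLECTIVITY, KIND_THICKNESS, KINDS,
                    N_LAYERS, SubjectRecord)

SCHEMES = ("kfold5", "kfold10", "loso")


class EvaluationError(ValueError):
    """Raised for undefined metrics or invalid fold requests."""


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with DR as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvaluationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)

    @classmethod
    def from_predictions(cls, y_true: Sequence[int], y_pred: Sequence[int]
                         ) -> "ConfusionCounts":
        yt = np.asarray(y_true, dtype=int)
        yp = np.asarray(y_pred, dtype=int)
        return cls(tp=int(((yt == 1) & (yp == 1)).sum()),
                   fp=int(((yt == 0) & (yp == 1)).sum()),
                   tn=int(((yt == 0) & (yp == 0)).sum()),
                   fn=int(((yt == 1) & (yp == 0)).sum()))


class Metrics(NamedTuple):
    sensitivity: float
    specificity: float
    accuracy: float

    def rounded(self, ndigits: int = 2) -> "Metrics":
        return Metrics(*(round(v, ndigits) for v in self))


def metrics(c: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity and accuracy in percent.

    sens = 100 tp / (tp + fn);  spec = 100 tn / (tn + fp);
    acc = 100 (tp + tn) / total.  Reports round to 2 decimals.
    """
    if c.tp + c.fn < 1:
        raise EvaluationError("no positive (DR) subjects: sensitivity undefined")
    if c.tn + c.fp < 1:
        raise EvaluationError("no negative (normal) subjects: specificity undefined")
    return Metrics(sensitivity=100.0 * c.tp / (c.tp + c.fn),
                   specificity=100.0 * c.tn / (c.tn + c.fp),
                   accuracy=100.0 * (c.tp + c.tn) / c.total)


def counts_from_rates(sensitivity: float, specificity: float,
                      n_dr: int, n_normal: int) -> ConfusionCounts:
    """Integer confusion counts implied by printed percentage rates."""
    tp = int(round(sensitivity / 100.0 * n_dr))
    tn = int(round(specificity / 100.0 * n_normal))
    return ConfusionCounts(tp=tp, fn=n_dr - tp, tn=tn, fp=n_normal - tn)


# Reported leave-one-subject-out sensitivity/specificity/accuracy triples (%)
# of the reference clinical CAD study on its 100-normal / 88-DR cohort, keyed
# by (marker, row).  Used only for internal-consistency arithmetic checks of
# `metrics`; the underlying scans are private and are not consumed here.
REFERENCE_LOSO_RESULTS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("reflectivity", "layer1"): (77.27, 80.00, 78.72),
    ("reflectivity", "layer2"): (82.95, 82.00, 82.45),
    ("reflectivity", "layer3"): (84.09, 81.00, 82.45),
    ("reflectivity", "layer4"): (81.82, 78.00, 79.79),
    ("reflectivity", "layer5"): (81.82, 78.00, 79.79),
    ("reflectivity", "layer6"): (71.59, 67.00, 69.15),
    ("reflectivity", "layer7"): (61.36, 68.00, 64.89),
    ("reflectivity", "layer8"): (82.95, 44.00, 62.23),
    ("reflectivity", "layer9"): (77.27, 80.00, 78.72),
    ("reflectivity", "layer10"): (62.50, 55.00, 58.51),
    ("reflectivity", "layer11"): (53.41, 54.00, 53.72),
    ("reflectivity", "layer12"): (50.00, 74.00, 62.77),
    ("reflectivity", "fusion"): (84.09, 86.00, 85.11),
    ("thickness", "layer1"): (90.91, 88.00, 89.36),
    ("thickness", "layer2"): (67.05, 83.00, 75.53),
    ("thickness", "layer3"): (70.45, 78.00, 74.47),
    ("thickness", "layer4"): (76.14, 75.00, 75.53),
    ("thickness", "layer5"): (72.73, 43.00, 56.91),
    ("thickness", "layer6"): (59.09, 49.00, 53.72),
    ("thickness", "layer7"): (84.09, 44.00, 62.77),
    ("thickness", "layer8"): (69.32, 59.00, 63.83),
    ("thickness", "layer9"): (88.64, 39.00, 62.23),
    ("thickness", "layer10"): (65.91, 82.00, 74.47),
    ("thickness", "layer11"): (64.77, 55.00, 59.57),
    ("thickness", "layer12"): (75.00, 70.00, 72.34),
    ("thickness", "fusion"): (92.05, 95.00, 93.62),
    ("combined", "fusion"): (95.45, 98.00, 96.81),
}
REFERENCE_COHORT = {"n_normal": 100, "n_dr": 88}


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def make_folds(records: Sequence[SubjectRecord], scheme: str, seed: int = 0
               ) -> list[tuple[list[str], list[str]]]:
    """Subject-level train/test id splits for the requested scheme.

    Deterministic given the seed and invariant to the input record order
    (records are sorted by subject id before splitting).
    """
    if scheme not in SCHEMES:
        raise EvaluationError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    recs = sorted(records, key=lambda r: r.subject_id)
    ids = [r.subject_id for r in recs]
    if len(set(ids)) != len(ids):
        raise EvaluationError("duplicate subject ids")
    y = np.array([1 if r.is_dr else 0 for r in recs])
    if scheme == "loso":
        if len(recs) < 2:
            raise EvaluationError("LOSO needs >= 2 subjects")
        return [([i for i in ids if i != test], [test]) for test in ids]
    k = 5 if scheme == "kfold5" else 10
    if min(np.bincount(y, minlength=2)) < 2:
        raise EvaluationError("k-fold needs >= 2 subjects per class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for train_idx, test_idx in skf.split(np.zeros(len(ids)), y):
        if len(np.unique(y[train_idx])) < 2:
            raise EvaluationError(
                "a class is absent from a training split; reduce k or add subjects")
        folds.append(([ids[i] for i in train_idx], [ids[i] for i in test_idx]))
    return folds


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-fold and aggregate metrics of one cross-validated experiment."""

    scheme: str
    per_fold: list[Metrics]
    pooled: ConfusionCounts
    seed: int
    n_subjects: int

    @property
    def pooled_metrics(self) -> Metrics:
        return metrics(self.pooled)

    @property
    def mean_sensitivity(self) -> float:
        return self._agg(0)

    @property
    def mean_specificity(self) -> float:
        return self._agg(1)

    @property
    def mean_accuracy(self) -> float:
        return self._agg(2)

    def _agg(self, i: int) -> float:
        if self.scheme == "loso":
            return float(self.pooled_metrics[i])
        return float(np.mean([m[i] for m in self.per_fold]))

    def sd(self, i: int) -> float:
        if self.scheme == "loso":
            return float("nan")
        return float(np.std([m[i] for m in self.per_fold], ddof=1))

    def summary(self) -> str:
        m = (self.mean_sensitivity, self.mean_specificity, self.mean_accuracy)
        lines = [f"{self.scheme} cross-validation over {self.n_subjects} subjects"]
        for name, i in (("sensitivity", 0), ("specificity", 1), ("accuracy", 2)):
            if self.scheme == "loso":
                lines.append(f"  {name:>11}: {m[i]:6.2f}%")
            else:
                lines.append(f"  {name:>11}: {m[i]:6.2f}% +/- {self.sd(i):.2f}%")
        c = self.pooled
        lines.append(f"  pooled counts: tp={c.tp} fp={c.fp} tn={c.tn} fn={c.fn}")
        return "\n".join(lines)


def cross_validate(records: Sequence[SubjectRecord], scheme: str,
                   model_builder: Callable[[Sequence[SubjectRecord]], object],
                   cfg: TrainConfig | None = None, seed: int = 0) -> CVResult:
    """Fit on the training subjects of each fold, predict the held-out ones.

    ``model_builder(train_records)`` must return an object with a
    ``predict_record(record) -> (p_dr, label)`` method.  All fitting —
    feature scaling included — happens inside each fold.
    """
    recs = sorted(records, key=lambda r: r.subject_id)
    by_id = {r.subject_id: r for r in recs}
    folds = make_folds(recs, scheme, seed)
    per_fold: list[Metrics] = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for train_ids, test_ids in folds:
        if set(train_ids) & set(test_ids):
            raise EvaluationError("subject appears on both sides of a split")
        model = model_builder([by_id[i] for i in train_ids])
        y_true, y_pred = [], []
        for tid in test_ids:
            _, label = model.predict_record(by_id[tid])
            y_true.append(1 if by_id[tid].is_dr else 0)
            y_pred.append(1 if label == CLASS_DR else 0)
        counts = ConfusionCounts.from_predictions(y_true, y_pred)
        pooled = pooled + counts
        if scheme != "loso":
            per_fold.append(metrics(counts))
    if pooled.total != len(recs):
        raise EvaluationError("folds do not partition the subjects")
    return CVResult(scheme=scheme, per_fold=per_fold, pooled=pooled,
                    seed=seed, n_subjects=len(recs))


# ---------------------------------------------------------------------------
# ablations
# ---------------------------------------------------------------------------

def _single_builder(kind, layer, cfg):
    def build(train_records):
        return fit_single_feature(train_records, kind, layer, cfg)
    return build


def _fusion_builder(kinds, cfg, fusion_mode):
    def build(train_records):
        return fit_two_stage(train_records, cfg, kinds=kinds,
                             fusion_mode=fusion_mode)
    return build


def ablation_suite(records: Sequence[SubjectRecord], scheme: str,
                   cfg: TrainConfig | None = None, seed: int = 0,
                   fusion_mode: str = "oof") -> pd.DataFrame:
    """Single-layer and fusion experiments in one long-format table.

    Rows: 12 reflectivity-only single-layer results, 12 thickness-only,
    then reflectivity fusion, thickness fusion, and the combined
    two-marker fusion (27 rows per scheme).
    """
    cfg = cfg or TrainConfig()
    rows = []

    def run(feature: str, layer_label: str, builder):
        res = cross_validate(records, scheme, builder, cfg, seed=seed)
        rows.append({
            "feature": feature, "layer": layer_label, "scheme": scheme,
            "sensitivity": res.mean_sensitivity,
            "specificity": res.mean_specificity,
            "accuracy": res.mean_accuracy,
            "sensitivity_sd": res.sd(0), "specificity_sd": res.sd(1),
            "accuracy_sd": res.sd(2),
        })

    for kind in KINDS:
        for layer in range(1, N_LAYERS + 1):
            run(kind, str(layer), _single_builder(kind, layer, cfg))
    run(KIND_REFLECTIVITY, "fusion",
        _fusion_builder((KIND_REFLECTIVITY,), cfg, fusion_mode))
    run(KIND_THICKNESS, "fusion",
        _fusion_builder((KIND_THICKNESS,), cfg, fusion_mode))
    run("combined", "fusion", _fusion_builder(KINDS, cfg, fusion_mode))
    return pd.DataFrame(rows)
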