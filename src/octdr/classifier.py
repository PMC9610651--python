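"""Two-stage backpropagation neural-network classifier.

Stage 1 is a bank of per-layer multilayer perceptrons: one network per
retinal layer and marker kind — reflectivity networks with 67 hidden units
and thickness networks with 72 hidden units, each mapping that layer's
feature vector to a DR probability.  Stage 2 is a fusion network (6 hidden
units) that consumes the stage-1 DR probabilities (24 of them for the full
12-layer, two-marker system) and emits the final diagnosis.  All networks
have exactly one hidden layer with tanh activation and a two-unit softmax
output, and are trained by full-batch gradient descent with momentum on the
cross-entropy loss until the weights stabilize or an epoch cap is reached.

Stacked classifiers trained naively are optimistically biased: if the fusion
network is fit on stage-1 probabilities produced by networks that already saw
the same subjects, it learns to trust overconfident resubstitution outputs.
By default the fusion training matrix is therefore built out-of-fold via an
inner 3-fold split of the training subjects ("oof" mode); a "naive" mode is
kept for comparison.

Everything is deterministic given the seeds: the same records and
configuration always reproduce bit-identical trained models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .volio import (CLASS_DR, KIND_REFLECTIVITY, KIND_THICKNESS, KINDS,
                    N_LAYERS, SubjectRecord)

DEFAULT_HIDDEN = {KIND_REFLECTIVITY: 67, KIND_THICKNESS: 72}
DEFAULT_FUSION_HIDDEN = 6


class ClassifierError(ValueError):
    """Raised for invalid inputs, untrained models, or divergent training."""


@dataclass(frozen=True)
class TrainConfig:
    """Gradient-descent hyperparameters; see docs/methods.md for rationale."""

    learning_rate: float = 0.01
    momentum: float = 0.9
    max_epochs: int = 2000
    batch_size: int | None = None          # None = full batch
    weight_stability_tol: float = 1e-5     # sup-norm of per-epoch weight update
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or not 0 <= self.momentum < 1:
            raise ClassifierError("learning_rate > 0 and 0 <= momentum < 1 required")
        if self.max_epochs < 1:
            raise ClassifierError("max_epochs must be >= 1")
        if self.weight_stability_tol <= 0:
            raise ClassifierError("weight_stability_tol must be > 0")


@dataclass
class MLPParams:
    """One single-hidden-layer tanh/softmax network's parameters."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    init_seed: int
    trained: bool = False
    epochs_run: int = 0
    final_loss: float = np.nan

    @property
    def input_dim(self) -> int:
        return self.W1.shape[0]

    @property
    def hidden_dim(self) -> int:
        return self.W1.shape[1]

    def copy(self) -> "MLPParams":
        return MLPParams(self.W1.copy(), self.b1.copy(), self.W2.copy(),
                         self.b2.copy(), self.init_seed, self.trained,
                         self.epochs_run, self.final_loss)


def init_network(input_dim: int, hidden_dim: int, seed: int) -> MLPParams:
    """Random zero-mean weights scaled by 1/sqrt(fan_in); zero biases."""
    if input_dim < 1 or hidden_dim < 1:
        raise ClassifierError("dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    W1 = rng.normal(0.0, 1.0 / np.sqrt(input_dim), size=(input_dim, hidden_dim))
    W2 = rng.normal(0.0, 1.0 / np.sqrt(hidden_dim), size=(hidden_dim, 2))
    return MLPParams(W1=W1, b1=np.zeros(hidden_dim), W2=W2, b2=np.zeros(2),
                     init_seed=int(seed))


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def forward(net: MLPParams, x: np.ndarray) -> np.ndarray:
    """Class probabilities ``(P(normal), P(DR))`` for one or many inputs."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ClassifierError("non-finite input features")
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != net.input_dim:
        raise ClassifierError(
            f"input dimension {X.shape[1]} != network input {net.input_dim}")
    hidden = np.tanh(X @ net.W1 + net.b1)
    probs = _softmax(hidden @ net.W2 + net.b2)
    return probs[0] if single else probs


def loss_and_grads(net: MLPParams, X: np.ndarray, Y: np.ndarray
                   ) -> tuple[float, dict[str, np.ndarray]]:
    """Mean cross-entropy and its analytic gradients (backpropagation)."""
    n = len(X)
    H = np.tanh(X @ net.W1 + net.b1)
    P = _softmax(H @ net.W2 + net.b2)
    with np.errstate(divide="ignore"):
        logP = np.log(P)  # -inf for an underflowed class flags divergence
    loss = float(-np.mean(np.sum(Y * np.where(Y > 0, logP, 0.0), axis=1)))
    dlogits = (P - Y) / n
    dW2 = H.T @ dlogits
    db2 = dlogits.sum(axis=0)
    dH = dlogits @ net.W2.T
    dpre = dH * (1.0 - H ** 2)
    dW1 = X.T @ dpre
    db1 = dpre.sum(axis=0)
    return loss, {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2}


def _one_hot(y: np.ndarray) -> np.ndarray:
    Y = np.zeros((len(y), 2))
    Y[np.arange(len(y)), y] = 1.0
    return Y


def train_backprop(net: MLPParams, X: np.ndarray, y: np.ndarray,
                   cfg: TrainConfig) -> MLPParams:
    """Gradient descent with momentum until the weights stabilize.

    Training stops when the sup-norm of the parameter update over a full
    epoch falls below ``cfg.weight_stability_tol``, or at ``cfg.max_epochs``.
    ``y`` holds class indices (0 = normal, 1 = DR).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ClassifierError("X must be (n, d) with one label per row")
    if not np.all(np.isfinite(X)):
        raise ClassifierError("non-finite training features")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ClassifierError(
            f"need >= 2 examples of each class, got counts {counts.tolist()}")
    Y = _one_hot(y)
    net = net.copy()
    params = {"W1": net.W1, "b1": net.b1, "W2": net.W2, "b2": net.b2}
    vel = {k: np.zeros_like(v) for k, v in params.items()}
    n = len(X)
    batch = n if cfg.batch_size is None else min(cfg.batch_size, n)
    loss = np.nan
    epochs = 0
    for epoch in range(cfg.max_epochs):
        epochs = epoch + 1
        sup_update = 0.0
        for start in range(0, n, batch):
            sl = slice(start, start + batch)
            loss, grads = loss_and_grads(net, X[sl], Y[sl])
            if not np.isfinite(loss):
                raise ClassifierError(
                    "training diverged (non-finite loss); lower the learning rate")
            for k in params:
                vel[k] = cfg.momentum * vel[k] - cfg.learning_rate * grads[k]
                params[k] += vel[k]
                sup_update = max(sup_update, float(np.abs(vel[k]).max()))
        if sup_update < cfg.weight_stability_tol:
            break
    net.trained = True
    net.epochs_run = epochs
    net.final_loss = float(loss_and_grads(net, X, Y)[0])
    return net


# ---------------------------------------------------------------------------
# feature scaling and record handling
# ---------------------------------------------------------------------------

@dataclass
class FeatureScaler:
    """Per-feature center/scale learned on training data only."""

    center: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureScaler":
        center = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(center=center, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) / self.scale


def _stack_features(records: Sequence[SubjectRecord], kind: str,
                    layer: int) -> np.ndarray:
    try:
        return np.stack([r.feature_vector(kind, layer) for r in records])
    except KeyError as exc:
        raise ClassifierError(
            f"record missing features for ({kind}, layer {layer})") from exc


def _labels(records: Sequence[SubjectRecord]) -> np.ndarray:
    return np.array([1 if r.is_dr else 0 for r in records], dtype=int)


def _net_seed(base_seed: int, *ids: int) -> int:
    ss = np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, *ids])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# two-stage model
# ---------------------------------------------------------------------------

@dataclass
class TwoStageModel:
    """All 2 x 12 per-layer networks plus the fusion network and scalers."""

    stage1: dict                     # (kind, layer) -> MLPParams
    scalers: dict                    # (kind, layer) -> FeatureScaler
    fusion: MLPParams
    kinds: tuple[str, ...]
    layers: tuple[int, ...]
    cfg: TrainConfig
    fusion_mode: str = "oof"
    decision_threshold: float = 0.5  # ties go to DR (screening favors recall)

    @property
    def fusion_input_dim(self) -> int:
        return len(self.kinds) * len(self.layers)

    def stage1_probabilities(self, record: SubjectRecord) -> np.ndarray:
        """DR probabilities of every stage-1 network, kind-major order."""
        probs = []
        for kind in self.kinds:
            for layer in self.layers:
                net = self.stage1[(kind, layer)]
                x = self.scalers[(kind, layer)].transform(
                    record.feature_vector(kind, layer))
                probs.append(forward(net, x)[1])
        return np.array(probs)

    def predict_record(self, record: SubjectRecord) -> tuple[float, str]:
        if not self.fusion.trained:
            raise ClassifierError("model is not trained")
        p = forward(self.fusion, self.stage1_probabilities(record))[1]
        label = CLASS_DR if p >= self.decision_threshold else "normal"
        return float(p), label


def _train_stage1(records, kinds, layers, hidden, cfg):
    nets, scalers = {}, {}
    for ki, kind in enumerate(kinds):
        for layer in layers:
            X = _stack_features(records, kind, layer)
            scaler = FeatureScaler.fit(X)
            net = init_network(X.shape[1], hidden[kind],
                               _net_seed(cfg.seed, ki, layer))
            nets[(kind, layer)] = train_backprop(
                net, scaler.transform(X), _labels(records), cfg)
            scalers[(kind, layer)] = scaler
    return nets, scalers


def _inner_folds(y: np.ndarray, n_folds: int, seed: int) -> list[np.ndarray]:
    """Stratified index folds for the out-of-fold fusion matrix."""
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in (0, 1):
        idx = np.where(y == cls)[0]
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % n_folds].append(int(j))
    return [np.array(sorted(f), dtype=int) for f in folds]


def fit_two_stage(train_records: Sequence[SubjectRecord],
                  cfg: TrainConfig | None = None,
                  kinds: Sequence[str] = KINDS,
                  layers: Sequence[int] = tuple(range(1, N_LAYERS + 1)),
                  hidden: dict | None = None,
                  fusion_hidden: int = DEFAULT_FUSION_HIDDEN,
                  fusion_mode: str = "oof") -> TwoStageModel:
    """Train the full two-stage model on a set of subject records.

    Feature scaling, all stage-1 networks and the fusion network are learned
    from ``train_records`` only.  In the default ``"oof"`` mode the fusion
    training matrix holds out-of-fold stage-1 probabilities from an inner
    stratified 3-fold split; in ``"naive"`` mode it holds resubstitution
    probabilities.
    """
    cfg = cfg or TrainConfig()
    hidden = dict(DEFAULT_HIDDEN, **(hidden or {}))
    kinds = tuple(kinds)
    layers = tuple(layers)
    if fusion_mode not in ("oof", "naive"):
        raise ClassifierError(f"fusion_mode must be 'oof' or 'naive', got {fusion_mode}")
    records = list(train_records)
    y = _labels(records)
    if np.bincount(y, minlength=2).min() < 2:
        raise ClassifierError("need >= 2 training subjects of each class")

    nets, scalers = _train_stage1(records, kinds, layers, hidden, cfg)

    n = len(records)
    fusion_X = np.zeros((n, len(kinds) * len(layers)))
    if fusion_mode == "naive":
        tmp = TwoStageModel(nets, scalers, init_network(1, 1, 0), kinds,
                            layers, cfg)
        for i, rec in enumerate(records):
            fusion_X[i] = tmp.stage1_probabilities(rec)
    else:
        for fold_idx, test_idx in enumerate(
                _inner_folds(y, 3, _net_seed(cfg.seed, 999, 0))):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            inner = [records[i] for i in train_idx]
            inner_nets, inner_scalers = _train_stage1(
                inner, kinds, layers, hidden, cfg)
            tmp = TwoStageModel(inner_nets, inner_scalers,
                                init_network(1, 1, 0), kinds, layers, cfg)
            for i in test_idx:
                fusion_X[i] = tmp.stage1_probabilities(records[i])

    fusion = init_network(fusion_X.shape[1], fusion_hidden,
                          _net_seed(cfg.seed, 999, 1))
    fusion = train_backprop(fusion, fusion_X, y, cfg)
    return TwoStageModel(stage1=nets, scalers=scalers, fusion=fusion,
                         kinds=kinds, layers=layers, cfg=cfg,
                         fusion_mode=fusion_mode)


def predict(model: TwoStageModel, record: SubjectRecord) -> tuple[float, str]:
    """DR probability and label for one subject (ties at 0.5 go to DR)."""
    return model.predict_record(record)


# ---------------------------------------------------------------------------
# single-network convenience model (used by per-layer ablations)
# ---------------------------------------------------------------------------

@dataclass
class SingleFeatureModel:
    """A lone stage-1 network used directly as the classifier."""

    net: MLPParams
    scaler: FeatureScaler
    kind: str
    layer: int
    decision_threshold: float = 0.5

    def predict_record(self, record: SubjectRecord) -> tuple[float, str]:
        x = self.scaler.transform(record.feature_vector(self.kind, self.layer))
        p = float(forward(self.net, x)[1])
        return p, (CLASS_DR if p >= self.decision_threshold else "normal")


def fit_single_feature(train_records: Sequence[SubjectRecord], kind: str,
                       layer: int, cfg: TrainConfig | None = None,
                       hidden: dict | None = None) -> SingleFeatureModel:
    cfg = cfg or TrainConfig()
    hidden = dict(DEFAULT_HIDDEN, **(hidden or {}))
    X = _stack_features(train_records, kind, layer)
    scaler = FeatureScaler.fit(X)
    ki = KINDS.index(kind)
    net = init_network(X.shape[1], hidden[kind], _net_seed(cfg.seed, ki, layer))
    net = train_backprop(net, scaler.transform(X), _labels(train_records), cfg)
    return SingleFeatureModel(net=net, scaler=scaler, kind=kind, layer=layer)


# ---------------------------------------------------------------------------
# architecture search
# ---------------------------------------------------------------------------

def default_search_space() -> dict:
    """Hyperparameter ranges explored when selecting the architecture."""
    return {"n_hidden_layers": range(1, 6), "hidden_units": range(4, 201)}


def grid_search_architecture(records: Sequence[SubjectRecord],
                             search_space: Iterable[dict],
                             cv_scheme: str = "kfold5",
                             cfg: TrainConfig | None = None,
                             seed: int = 0):
    """Evaluate candidate architectures by cross-validated accuracy.

    ``search_space`` is an iterable of dicts with keys ``refl_hidden``,
    ``thick_hidden`` and ``fusion_hidden``.  Returns a DataFrame ranked
    best-first; fully deterministic given the seeds.
    """
    import pandas as pd

    from .evaluation import cross_validate

    cfg = cfg or TrainConfig()
    space = list(search_space)
    if not space:
        raise ClassifierError("empty architecture search grid")
    rows = []
    for arch in space:
        hidden = {KIND_REFLECTIVITY: arch.get("refl_hidden", DEFAULT_HIDDEN[KIND_REFLECTIVITY]),
                  KIND_THICKNESS: arch.get("thick_hidden", DEFAULT_HIDDEN[KIND_THICKNESS])}
        fusion_hidden = arch.get("fusion_hidden", DEFAULT_FUSION_HIDDEN)

        def builder(train_records, _cfg=cfg, _h=hidden, _f=fusion_hidden):
            return fit_two_stage(train_records, _cfg, hidden=_h,
                                 fusion_hidden=_f)

        result = cross_validate(records, cv_scheme, builder, cfg, seed=seed)
        rows.append({**arch, "accuracy": result.mean_accuracy,
                     "sensitivity": result.mean_sensitivity,
                     "specificity": result.mean_specificity})
    table = pd.DataFrame(rows).sort_values("accuracy", ascending=False,
                                           kind="stable").reset_index(drop=True)
    return table


# ---------------------------------------------------------------------------
# serialization: flat array container + JSON metadata
# ---------------------------------------------------------------------------

def save_model(model: TwoStageModel, path) -> None:
    """Write a model to a flat ``.npz`` container (names -> arrays + JSON)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    meta = {
        "kinds": list(model.kinds),
        "layers": list(model.layers),
        "fusion_mode": model.fusion_mode,
        "decision_threshold": model.decision_threshold,
        "cfg": {"learning_rate": model.cfg.learning_rate,
                "momentum": model.cfg.momentum,
                "max_epochs": model.cfg.max_epochs,
                "batch_size": model.cfg.batch_size,
                "weight_stability_tol": model.cfg.weight_stability_tol,
                "seed": model.cfg.seed},
        "nets": {},
    }

    def pack(prefix: str, net: MLPParams):
        for p in ("W1", "b1", "W2", "b2"):
            arrays[f"{prefix}_{p}"] = getattr(net, p)
        meta["nets"][prefix] = {"init_seed": net.init_seed,
                                "trained": net.trained,
                                "epochs_run": net.epochs_run,
                                "final_loss": net.final_loss}

    for (kind, layer), net in model.stage1.items():
        prefix = f"{kind}_{layer:02d}"
        pack(prefix, net)
        arrays[f"{prefix}_center"] = model.scalers[(kind, layer)].center
        arrays[f"{prefix}_scale"] = model.scalers[(kind, layer)].scale
    pack("fusion", model.fusion)
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path) -> TwoStageModel:
    path = Path(path)
    if not path.exists():
        raise ClassifierError(f"model file not found: {path}")
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode("utf-8"))

    def unpack(prefix: str) -> MLPParams:
        m = meta["nets"][prefix]
        return MLPParams(W1=data[f"{prefix}_W1"], b1=data[f"{prefix}_b1"],
                         W2=data[f"{prefix}_W2"], b2=data[f"{prefix}_b2"],
                         init_seed=m["init_seed"], trained=m["trained"],
                         epochs_run=m["epochs_run"],
                         final_loss=m["final_loss"])

    stage1, scalers = {}, {}
    for kind in meta["kinds"]:
        for layer in meta["layers"]:
            prefix = f"{kind}_{layer:02d}"
            stage1[(kind, layer)] = unpack(prefix)
            scalers[(kind, layer)] = FeatureScaler(
                center=data[f"{prefix}_center"], scale=data[f"{prefix}_scale"])
    cfg = TrainConfig(**meta["cfg"])
    return TwoStageModel(stage1=stage1, scalers=scalers, fusion=unpack("fusion"),
                         kinds=tuple(meta["kinds"]),
                         layers=tuple(meta["layers"]), cfg=cfg,
                         fusion_mode=meta["fusion_mode"],
                         decision_threshold=meta["decision_threshold"])
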