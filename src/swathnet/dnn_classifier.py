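"""Small fully-connected neural classifier over per-scan window features.

The default architecture is three dense layers — two rectifier hidden layers
and a sigmoid (binary) or softmax (multiclass) output. On the canonical
1024-window input with binary output the hidden sizes are (56, 41), giving
59,779 trainable parameters (1024·56+56 + 56·41+41 + 41·1+1). Training uses
minibatch adaptive-moment gradient descent on a cross-entropy loss; all
stochastic choices (weight init, shuffling) are fixed by the config seed.

The optimizer and backprop machinery are provided by scikit-learn's
multilayer perceptron; this module owns the architecture, the parameter
accounting, the determinism contract and the prediction rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from .feature_swath import IntensityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "TrainingConfig",
    "TrainedModel",
    "default_model_spec",
    "count_parameters",
    "train_model",
    "predict_scans",
    "save_model",
    "load_model",
]

# canonical hidden sizes for a 1024-feature binary model
_BASE_INPUT = 1024
_BASE_HIDDEN = (56, 41)


@dataclass(frozen=True)
class ModelSpec:
    """Architecture of the feed-forward classifier.

    ``hidden_layers`` lists (units, activation) per hidden layer; the output
    layer has one sigmoid unit for binary problems and ``n_classes`` softmax
    units otherwise.
    """

    input_dim: int
    hidden_layers: tuple[tuple[int, str], ...]
    n_classes: int

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not self.hidden_layers:
            raise ValueError("at least one hidden layer required")
        if any(u < 1 for u, _ in self.hidden_layers):
            raise ValueError("hidden layer unit counts must be positive")

    @property
    def output_units(self) -> int:
        return 1 if self.n_classes == 2 else self.n_classes

    @property
    def output_activation(self) -> str:
        return "sigmoid" if self.n_classes == 2 else "softmax"

    @property
    def layer_sizes(self) -> list[int]:
        return [self.input_dim, *[u for u, _ in self.hidden_layers], self.output_units]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation settings; ``seed`` fixes every stochastic choice."""

    epochs: int = 30
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0
    validation_fraction: float = 0.1
    balance_classes: bool = False  # deterministic minority oversampling

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if not 0.0 <= self.validation_fraction < 0.5:
            raise ValueError("validation_fraction must be in [0, 0.5)")


@dataclass
class TrainedModel:
    spec: ModelSpec
    config: TrainingConfig
    classes: np.ndarray
    training_log: dict
    _clf: MLPClassifier = field(repr=False)


def default_model_spec(input_dim: int, n_classes: int) -> ModelSpec:
    """The library's default three-dense-layer architecture.

    For 1024 inputs the hidden sizes are (56, 41); other input widths scale
    both hidden sizes proportionally (rounded, floored at 1 unit).
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    scale = input_dim / _BASE_INPUT
    hidden = tuple(
        (max(1, round(u * scale)), "relu") for u in _BASE_HIDDEN
    )
    return ModelSpec(input_dim=input_dim, hidden_layers=hidden, n_classes=n_classes)


def count_parameters(spec: ModelSpec) -> int:
    """Trainable parameters: Σ over consecutive layers of n_in·n_out + n_out."""
    sizes = spec.layer_sizes
    return int(sum(a * b + b for a, b in zip(sizes, sizes[1:])))


def _as_feature_array(features) -> np.ndarray:
    if isinstance(features, IntensityMatrix):
        if not features.normalized:
            raise ValueError("features must be row-normalized before training/prediction")
        return features.values
    return np.asarray(features, dtype=np.float64)


def _oversample(X: np.ndarray, y: np.ndarray, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Duplicate minority-class rows until all classes match the majority count."""
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    parts_X, parts_y = [X], [y]
    for cls, cnt in zip(classes, counts):
        if cnt < target:
            pool = np.flatnonzero(y == cls)
            extra = rng.choice(pool, size=target - cnt, replace=True)
            parts_X.append(X[extra])
            parts_y.append(y[extra])
    return np.vstack(parts_X), np.concatenate(parts_y)


def train_model(
    features,
    labels,
    spec: ModelSpec | None = None,
    config: TrainingConfig | None = None,
) -> TrainedModel:
    """Fit the classifier; deterministic given (data, spec, config).

    ``features`` may be a normalized :class:`IntensityMatrix` or a plain
    array. Errors on single-class labels and on NaN loss.
    """
    X = _as_feature_array(features)
    y = np.asarray(labels, dtype=np.int64)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} feature rows but {y.shape[0]} labels")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class; need >= 2")
    config = config or TrainingConfig()
    spec = spec or default_model_spec(X.shape[1], classes.size)
    if X.shape[1] != spec.input_dim:
        raise ValueError(f"feature dim {X.shape[1]} != spec.input_dim {spec.input_dim}")

    rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    n_val = int(round(config.validation_fraction * n))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if np.unique(y[train_idx]).size < 2:  # tiny-data fallback: train on all rows
        train_idx, val_idx = perm, perm[:0]
    X_tr, y_tr = X[train_idx], y[train_idx]
    if config.balance_classes:
        X_tr, y_tr = _oversample(X_tr, y_tr, config.seed)

    activations = {a for _, a in spec.hidden_layers}
    if activations - {"relu"}:
        raise NotImplementedError(f"unsupported hidden activations: {activations}")
    clf = MLPClassifier(
        hidden_layer_sizes=tuple(u for u, _ in spec.hidden_layers),
        activation="relu",
        solver="adam",
        alpha=0.0,
        batch_size=min(config.batch_size, X_tr.shape[0]),
        learning_rate_init=config.learning_rate,
        max_iter=config.epochs,
        shuffle=True,
        random_state=int(config.seed) % (2**32),
        tol=0.0,
        n_iter_no_change=config.epochs + 1,
        early_stopping=False,
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X_tr, y_tr)
    loss_curve = [float(v) for v in clf.loss_curve_]
    if any(np.isnan(v) or np.isinf(v) for v in loss_curve):
        raise FloatingPointError(
            f"non-finite training loss (curve: {loss_curve[:5]}...); "
            "lower the learning rate or check the input scaling"
        )
    log = {
        "loss": loss_curve,
        "train_accuracy": float(clf.score(X_tr, y_tr)),
        "val_accuracy": float(clf.score(X[val_idx], y[val_idx])) if val_idx.size else None,
        "n_train": int(X_tr.shape[0]),
        "n_val": int(val_idx.size),
    }
    logger.info(
        "trained %s model: %d params, final loss %.4f, train acc %.3f",
        "binary" if classes.size == 2 else f"{classes.size}-class",
        count_parameters(spec), loss_curve[-1], log["train_accuracy"],
    )
    return TrainedModel(spec=spec, config=config, classes=clf.classes_.copy(),
                        training_log=log, _clf=clf)


def predict_scans(model: TrainedModel, features) -> tuple[np.ndarray, np.ndarray]:
    """Per-scan (predicted label, class-probability row) for each feature row.

    Binary rule: positive class iff its probability >= 0.5 (a tie goes to the
    positive class). Multiclass: argmax of the softmax probabilities.
    Probability columns follow ``model.classes`` order.
    """
    X = _as_feature_array(features)
    if X.ndim != 2 or X.shape[1] != model.spec.input_dim:
        raise ValueError(
            f"feature dim {X.shape[1] if X.ndim == 2 else X.shape} "
            f"!= model input_dim {model.spec.input_dim}"
        )
    probs = model._clf.predict_proba(X)
    if model.classes.size == 2:
        labels = np.where(probs[:, 1] >= 0.5, model.classes[1], model.classes[0])
    else:
        labels = model.classes[np.argmax(probs, axis=1)]
    return labels.astype(np.int64), probs


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize spec + config + weights to a single archive file."""
    joblib.dump(
        {"spec": model.spec, "config": model.config, "classes": model.classes,
         "training_log": model.training_log, "clf": model._clf},
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    return TrainedModel(spec=payload["spec"], config=payload["config"],
                        classes=payload["classes"],
                        training_log=payload["training_log"], _clf=payload["clf"])
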