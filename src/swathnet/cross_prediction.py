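"""Leave-one-out cross prediction with scan-level majority voting.

Each iteration holds out one run (sample) as the independent test set, trains
a fresh classifier on the scans of all remaining runs, predicts every test
scan, and issues a sample-level verdict: for binary problems the sample is
predicted correctly when the fraction of its scans whose predicted label
matches the true label is >= 0.5; for multiclass problems the sample label is
the argmax of the scan-averaged class probabilities. Per-scan probabilities
are pooled across iterations for ROC analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np

from .dnn_classifier import ModelSpec, TrainingConfig, predict_scans, train_model
from .feature_swath import (
    IntensityMatrix,
    WindowGrid,
    concat_matrices,
    extract_feature_swath,
    make_label_vector,
    normalize_rows,
)
from .spectra_io import SpectraRun

logger = logging.getLogger(__name__)

__all__ = [
    "SamplePrediction",
    "CohortResult",
    "SingleClassTrainingError",
    "loo_split",
    "evaluate_sample",
    "run_loo",
]

# predictor signature: (X_train, y_train, X_test, classes, seed) -> (labels, probs)
Predictor = Callable[
    [np.ndarray, np.ndarray, np.ndarray, np.ndarray, int],
    tuple[np.ndarray, np.ndarray],
]


class SingleClassTrainingError(ValueError):
    """A training fold collapsed to one class (e.g. one run per class)."""


@dataclass
class SamplePrediction:
    """Outcome of one held-out run."""

    run_id: str
    original_label: int
    per_scan_labels: np.ndarray
    per_scan_probs: np.ndarray  # (n_scans, n_classes), columns follow `classes`
    classes: np.ndarray
    correct_ratio: float = field(init=False)
    mean_probs: np.ndarray = field(init=False)
    predicted_label: int = field(init=False)
    verdict: str = field(init=False)  # "correct" | "wrong"


@dataclass
class CohortResult:
    """Aggregated leave-one-out outcome for a cohort."""

    predictions: list[SamplePrediction]
    classes: np.ndarray
    pooled_true: np.ndarray  # per-scan true labels across all iterations
    pooled_probs: np.ndarray  # per-scan class probabilities, columns = classes

    @property
    def n_total(self) -> int:
        return len(self.predictions)

    @property
    def n_predicted(self) -> int:
        return sum(p.verdict == "correct" for p in self.predictions)

    @property
    def accuracy(self) -> float:
        return self.n_predicted / self.n_total


def loo_split(
    runs: Sequence[SpectraRun],
) -> Iterator[tuple[SpectraRun, list[SpectraRun]]]:
    """Yield (test_run, training_runs) with each run held out exactly once."""
    if len(runs) < 2:
        raise ValueError("leave-one-out needs at least 2 runs")
    if len({r.sample_label for r in runs}) < 2:
        raise ValueError("cohort holds a single class; nothing to classify")
    for k in range(len(runs)):
        yield runs[k], [r for i, r in enumerate(runs) if i != k]


def evaluate_sample(
    per_scan_labels: np.ndarray,
    original_label: int,
    mean_probs: np.ndarray | None = None,
    mode: str = "binary",
    classes: np.ndarray | None = None,
    run_id: str = "",
    per_scan_probs: np.ndarray | None = None,
) -> SamplePrediction:
    """Majority-vote verdict for one held-out sample.

    Binary: ``correct_ratio`` is the fraction of scans predicted as the true
    label; the sample is "correct" iff the ratio >= 0.5 (boundary counted
    correct). Multiclass: the sample label is the argmax of the scan-averaged
    class probabilities and the verdict compares it with the true label.
    """
    per_scan_labels = np.asarray(per_scan_labels, dtype=np.int64)
    if per_scan_labels.size == 0:
        raise ValueError(f"sample {run_id or '?'}: no scans to vote over")
    if classes is None:
        classes = np.unique(np.append(per_scan_labels, original_label))
    classes = np.asarray(classes)
    if per_scan_probs is None:
        # degenerate probabilities from hard labels (used by injected predictors)
        per_scan_probs = (per_scan_labels[:, None] == classes[None, :]).astype(float)
    if mean_probs is None:
        mean_probs = per_scan_probs.mean(axis=0)
    mean_probs = np.asarray(mean_probs, dtype=np.float64)

    pred = SamplePrediction(
        run_id=run_id,
        original_label=int(original_label),
        per_scan_labels=per_scan_labels,
        per_scan_probs=per_scan_probs,
        classes=classes,
    )
    pred.mean_probs = mean_probs
    pred.correct_ratio = float(np.mean(per_scan_labels == original_label))
    if mode == "binary":
        if classes.size != 2:
            raise ValueError(f"binary mode needs 2 classes, got {classes.size}")
        correct = pred.correct_ratio >= 0.5
        others = classes[classes != original_label]
        pred.predicted_label = int(original_label) if correct else int(others[0])
    elif mode == "multiclass":
        pred.predicted_label = int(classes[int(np.argmax(mean_probs))])
        correct = pred.predicted_label == original_label
    else:
        raise ValueError(f"unknown mode {mode!r}")
    pred.verdict = "correct" if correct else "wrong"
    return pred


def _default_predictor(
    spec: ModelSpec | None, config: TrainingConfig
) -> Predictor:
    def predictor(X_train, y_train, X_test, classes, seed):
        cfg = TrainingConfig(
            epochs=config.epochs,
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            seed=seed,
            validation_fraction=config.validation_fraction,
            balance_classes=config.balance_classes,
        )
        model = train_model(X_train, y_train, spec=spec, config=cfg)
        return predict_scans(model, X_test)

    return predictor


def _features_for(run: SpectraRun, grid: WindowGrid) -> IntensityMatrix:
    return normalize_rows(extract_feature_swath(run, grid))


def run_loo(
    runs: Sequence[SpectraRun],
    grid: WindowGrid,
    spec: ModelSpec | None = None,
    config: TrainingConfig | None = None,
    predictor: Predictor | None = None,
) -> CohortResult:
    """Full leave-one-out cross prediction over a cohort sharing one grid.

    A fresh model is trained per iteration with seed ``config.seed + k`` for
    iteration k, so the whole protocol is reproducible from one master seed.
    ``predictor`` may replace the train+predict stage (e.g. for oracles in
    tests); it receives (X_train, y_train, X_test, classes, seed).
    """
    config = config or TrainingConfig()
    classes = np.array(sorted({r.sample_label for r in runs}))
    mode = "binary" if classes.size == 2 else "multiclass"
    predictor = predictor or _default_predictor(spec, config)

    # features are extracted once per run and reused across iterations
    feats = {r.run_id: _features_for(r, grid) for r in runs}
    predictions: list[SamplePrediction] = []
    pooled_true: list[np.ndarray] = []
    pooled_probs: list[np.ndarray] = []

    for k, (test_run, train_runs) in enumerate(loo_split(runs)):
        train_labels = np.concatenate(
            [make_label_vector(r, r.n_scans) for r in train_runs]
        )
        if np.unique(train_labels).size < 2:
            raise SingleClassTrainingError(
                f"iteration {k} (test={test_run.run_id}): training runs are "
                "single-class; provide at least two runs per class"
            )
        X_train = concat_matrices([feats[r.run_id] for r in train_runs]).values
        X_test = feats[test_run.run_id].values
        try:
            scan_labels, scan_probs = predictor(
                X_train, train_labels, X_test, classes, config.seed + k
            )
        except Exception as exc:
            raise RuntimeError(
                f"iteration {k} (test={test_run.run_id}) failed: {exc}"
            ) from exc
        scan_probs = _align_probs(np.asarray(scan_probs, float),
                                  np.unique(train_labels), classes)
        pred = evaluate_sample(
            per_scan_labels=np.asarray(scan_labels),
            original_label=test_run.sample_label,
            mode=mode,
            classes=classes,
            run_id=test_run.run_id,
            per_scan_probs=scan_probs,
        )
        predictions.append(pred)
        pooled_true.append(np.full(X_test.shape[0], test_run.sample_label))
        pooled_probs.append(scan_probs)
        logger.info("iteration %d: test=%s ratio=%.3f verdict=%s",
                    k, test_run.run_id, pred.correct_ratio, pred.verdict)

    return CohortResult(
        predictions=predictions,
        classes=classes,
        pooled_true=np.concatenate(pooled_true),
        pooled_probs=np.vstack(pooled_probs),
    )


def _align_probs(probs: np.ndarray, train_classes: np.ndarray,
                 all_classes: np.ndarray) -> np.ndarray:
    """Map probability columns from the fold's class order onto the cohort's.

    A class absent from a training fold gets probability 0 for that fold.
    """
    if probs.ndim != 2:
        raise ValueError("probabilities must be 2-D (scans × classes)")
    if probs.shape[1] == all_classes.size:
        return probs
    if probs.shape[1] != train_classes.size:
        raise ValueError(
            f"probability columns ({probs.shape[1]}) match neither the cohort "
            f"({all_classes.size}) nor the fold ({train_classes.size}) class count"
        )
    out = np.zeros((probs.shape[0], all_classes.size))
    col = {int(c): j for j, c in enumerate(all_classes)}
    for j_src, c in enumerate(train_classes):
        out[:, col[int(c)]] = probs[:, j_src]
    return out
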