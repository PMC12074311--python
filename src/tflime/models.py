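"""Black-box classifier contract and the reference MLP.

The explanation engine only needs a batch probability function: an array of
series in, one probability row per series out.  :func:`wrap_model` adapts any
such callable and validates the contract on first use.  :func:`train_mlp`
provides the reference black box for the 64-class detection benchmark: a
two-hidden-layer ReLU perceptron on the raw 1000-sample series.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from sklearn.neural_network import MLPClassifier

__all__ = [
    "BlackBoxModel",
    "MlpSpec",
    "wrap_model",
    "train_mlp",
    "samples_to_arrays",
    "save_model",
    "load_model",
]

_ROW_SUM_TOL = 1e-6


@dataclass
class BlackBoxModel:
    """Batch probability predictor: (n, T) array -> (n, n_classes) simplex rows."""

    predict_fn: Callable[[np.ndarray], np.ndarray]
    n_classes: int
    _validated: bool = field(default=False, repr=False)

    def predict(self, batch: np.ndarray) -> np.ndarray:
        batch = np.atleast_2d(np.asarray(batch, dtype=float))
        probs = np.asarray(self.predict_fn(batch), dtype=float)
        if not self._validated:
            if probs.shape != (batch.shape[0], self.n_classes):
                raise ValueError(
                    f"model returned shape {probs.shape}, expected "
                    f"{(batch.shape[0], self.n_classes)}"
                )
            if np.any(probs < -_ROW_SUM_TOL) or np.any(
                np.abs(probs.sum(axis=1) - 1.0) > _ROW_SUM_TOL
            ):
                raise ValueError("model output rows are not probability simplexes")
            self._validated = True
        return probs

    def predicted_class(self, series: np.ndarray) -> int:
        return int(np.argmax(self.predict(series[None, :])[0]))


def wrap_model(
    predict_fn: Callable[[np.ndarray], np.ndarray], n_classes: int
) -> BlackBoxModel:
    """Adapt an arbitrary batch probability function to the contract."""
    return BlackBoxModel(predict_fn=predict_fn, n_classes=n_classes)


@dataclass(frozen=True)
class MlpSpec:
    """Architecture and optimisation settings of the reference perceptron."""

    hidden_sizes: tuple[int, int] = (256, 128)
    n_epochs: int = 30
    learning_rate: float = 1e-3
    batch_size: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_sizes) != 2:
            raise ValueError("the reference model has exactly two hidden layers")


def samples_to_arrays(samples) -> tuple[np.ndarray, np.ndarray]:
    """Stack detection-benchmark samples into (X, y) arrays."""
    X = np.stack([s.series.values for s in samples])
    y = np.array([s.label.class_index for s in samples], dtype=int)
    return X, y


def _expand_classes(estimator, n_classes: int) -> Callable[[np.ndarray], np.ndarray]:
    """Map an estimator's predict_proba onto the full class alphabet.

    Classes absent from training get probability exactly 0; a degenerate
    single-class fit predicts its class with certainty.
    """
    classes = np.asarray(estimator.classes_, dtype=int)

    def predict_fn(batch: np.ndarray) -> np.ndarray:
        if classes.size == 1:
            full = np.zeros((batch.shape[0], n_classes))
            full[:, classes[0]] = 1.0
            return full
        probs = estimator.predict_proba(batch)
        if classes.size == n_classes:
            return probs
        full = np.zeros((batch.shape[0], n_classes))
        full[:, classes] = probs
        return full

    return predict_fn


def train_mlp(
    X: np.ndarray,
    y: np.ndarray,
    spec: MlpSpec | None = None,
    n_classes: int = 64,
) -> BlackBoxModel:
    """Fit the reference MLP (ReLU, adaptive-moment optimiser, cross-entropy).

    Training is reproducible from ``spec.seed``.  Raises if the optimiser
    diverges to a non-finite loss.
    """
    spec = spec or MlpSpec()
    clf = MLPClassifier(
        hidden_layer_sizes=spec.hidden_sizes,
        activation="relu",
        solver="adam",
        learning_rate_init=spec.learning_rate,
        batch_size=spec.batch_size,
        max_iter=spec.n_epochs,
        random_state=spec.seed,
        alpha=1e-4,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warning at a fixed epoch count
        clf.fit(X, y)
    if not np.isfinite(clf.loss_):
        raise RuntimeError("training diverged to a non-finite loss")

    classes = np.asarray(clf.classes_, dtype=int)

    model = wrap_model(_expand_classes(clf, n_classes), n_classes)
    model.estimator = clf  # type: ignore[attr-defined]
    return model


def save_model(model: BlackBoxModel, path: str | Path) -> None:
    """Persist a trained reference model (pickle of the sklearn estimator)."""
    est = getattr(model, "estimator", None)
    if est is None:
        raise ValueError("only models trained by train_mlp can be saved")
    with open(path, "wb") as fh:
        pickle.dump({"estimator": est, "n_classes": model.n_classes}, fh)


def load_model(path: str | Path) -> BlackBoxModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    est, n_classes = payload["estimator"], payload["n_classes"]
    model = wrap_model(_expand_classes(est, n_classes), n_classes)
    model.estimator = est  # type: ignore[attr-defined]
    return model
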