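"""Time-binned feature vectors and the linear-classifier harness.

Feature maps (or raw cochlear spike streams for the baseline) are
reduced to fixed-length vectors by counting spikes in equal-width time
bins per (channel, neuron); vectors from several scales are
concatenated.  Evaluation fits a linear-kernel SVM with the
regularization constant chosen by cross-validation on the training set
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .feast import FeatureMap
from .spikes import EventStream


@dataclass
class BinnedFeature:
    """Flattened spike-count vector for one utterance.

    Ordering is C-contiguous over (bin, channel, neuron): the neuron
    index varies fastest, then channel, then time bin.
    """

    vector: np.ndarray
    n_bins: int
    n_channels: int
    n_neurons: int
    label: Optional[int] = None
    utterance_id: Optional[str] = None

    def counts(self) -> np.ndarray:
        """View as (n_bins, n_channels, n_neurons)."""
        return self.vector.reshape(self.n_bins, self.n_channels, self.n_neurons)


def time_bin(fmap: Union[FeatureMap, EventStream], n_bins: int,
             duration: Optional[int] = None, label=None,
             utterance_id=None) -> BinnedFeature:
    """Count spikes in ``n_bins`` equal time bins per (channel, neuron).

    ``duration`` defaults to the map's recorded source length in
    samples; bins partition [0, duration).  A spike exactly at the
    duration boundary lands in the last bin.
    """
    if duration is None:
        duration = fmap.duration
    if duration <= 0:
        raise ValueError("utterance duration must be positive")
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    if isinstance(fmap, FeatureMap):
        neuron = fmap.winner
        n_neurons = fmap.m
    else:
        neuron = np.zeros(len(fmap), dtype=np.int64)
        n_neurons = 1
    n_ch = fmap.n_channels
    bins = np.minimum((fmap.t * n_bins) // duration, n_bins - 1).astype(np.int64)
    flat = (bins * n_ch + fmap.channel.astype(np.int64)) * n_neurons + neuron
    vector = np.bincount(flat, minlength=n_bins * n_ch * n_neurons).astype(float)
    return BinnedFeature(vector, n_bins, n_ch, n_neurons,
                         label=label, utterance_id=utterance_id)


def baseline_features(stream: EventStream, n_bins: int, duration=None,
                      label=None, utterance_id=None) -> BinnedFeature:
    """Time-binned raw cochlear spikes (no feature extraction)."""
    return time_bin(stream, n_bins, duration=duration, label=label,
                    utterance_id=utterance_id)


def concat_features(parts: Sequence[BinnedFeature]) -> BinnedFeature:
    """Concatenate per-scale vectors for one utterance (labels must agree)."""
    if not parts:
        raise ValueError("nothing to concatenate")
    labels = {p.label for p in parts}
    if len(labels) != 1:
        raise ValueError("label mismatch across parts")
    vec = np.concatenate([p.vector for p in parts])
    return BinnedFeature(vec, parts[0].n_bins, parts[0].n_channels,
                         sum(p.n_neurons for p in parts),
                         label=parts[0].label, utterance_id=parts[0].utterance_id)


@dataclass
class EvalReport:
    """Held-out evaluation result."""

    accuracy: float
    confusion: np.ndarray  # rows: true class, cols: predicted
    classes: np.ndarray
    best_c: float
    config: dict = field(default_factory=dict)

    def to_yaml(self, path):
        import yaml

        data = {
            "accuracy": float(self.accuracy),
            "best_c": float(self.best_c),
            "classes": [int(c) for c in self.classes],
            "confusion": [[int(v) for v in row] for row in self.confusion],
            "config": self.config,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


def _stack(features: Sequence[BinnedFeature], normalize: bool):
    X = np.stack([f.vector for f in features])
    if normalize:
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        X = X / norms
    y = np.array([f.label for f in features])
    return X, y


def evaluate(train_features: Sequence[BinnedFeature],
             test_features: Sequence[BinnedFeature],
             c_grid: Sequence[float] = (0.01, 0.1, 1.0, 10.0, 100.0),
             seed: int = 0, cv_folds: int = 5, normalize: bool = True,
             config: Optional[dict] = None) -> EvalReport:
    """Linear-SVM evaluation with CV-selected regularization.

    The regularization constant is chosen by ``cv_folds``-fold
    cross-validation on the training set only; accuracy and the
    confusion matrix are reported on the held-out test set.  Shared
    utterance ids across the split raise (label leakage).
    """
    from sklearn.model_selection import GridSearchCV, StratifiedKFold
    from sklearn.svm import SVC

    train_ids = {f.utterance_id for f in train_features if f.utterance_id}
    test_ids = {f.utterance_id for f in test_features if f.utterance_id}
    shared = train_ids & test_ids
    if shared:
        raise ValueError(f"utterance ids shared across split: {sorted(shared)[:5]}")
    X_tr, y_tr = _stack(train_features, normalize)
    X_te, y_te = _stack(test_features, normalize)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("need at least two classes")
    folds = min(cv_folds, int(np.min(np.bincount(y_tr.astype(int)))))
    cv = StratifiedKFold(n_splits=max(2, folds), shuffle=True, random_state=seed)
    search = GridSearchCV(SVC(kernel="linear"), {"C": list(c_grid)}, cv=cv)
    search.fit(X_tr, y_tr)
    best_c = float(search.best_params_["C"])
    model = SVC(kernel="linear", C=best_c)
    model.fit(X_tr, y_tr)
    pred = model.predict(X_te)
    classes = np.unique(np.concatenate([y_tr, y_te]))
    index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((classes.size, classes.size), dtype=np.int64)
    for yt, yp in zip(y_te, pred):
        confusion[index[yt], index[yp]] += 1
    acc = float(np.mean(pred == y_te))
    return EvalReport(accuracy=acc, confusion=confusion, classes=classes,
                      best_c=best_c, config=dict(config or {}, seed=seed))
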