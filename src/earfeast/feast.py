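"""Competitive feature learning with adaptive selection thresholds.

A bank of m neurons, each holding a weight vector the shape of the event
contexts it consumes and an individual similarity threshold in [0, 1].
During learning, the most similar neuron whose cosine similarity clears
its own threshold wins: its threshold rises by delta_i and its weights
move toward the context by a convex mixing step.  If no neuron clears
its threshold, every threshold drops by delta_e.  The opposing
adjustments equalize win rates across the bank.  During extraction
thresholds are ignored: the argmax-similarity neuron emits one feature
spike per event.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import yaml

from ._kernels import feast_train_epochs
from .context import ECBatch
from .spikes import EventStream


@dataclass
class FeastParams:
    m: int = 16
    delta_i: float = 0.001
    delta_e: float = 0.003
    eta: float = 0.001
    epochs: int = 10
    seed: int = 0
    early_stop_dw: Optional[float] = None  # stop when mean |dW| drops below

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("need at least one neuron")
        if min(self.delta_i, self.delta_e, self.eta) <= 0:
            raise ValueError("delta_i, delta_e and eta must be positive")
        if self.eta >= 1:
            raise ValueError("eta must be < 1")


@dataclass
class FeastNeuron:
    weights: np.ndarray
    vth: float
    win_count: int = 0


class NeuronBank:
    """m neurons for one context scale, plus training diagnostics."""

    def __init__(self, weights: np.ndarray, vth: np.ndarray, scale: int,
                 params: FeastParams, trained: bool = False):
        self.weights = np.asarray(weights, dtype=float)
        self.vth = np.asarray(vth, dtype=float)
        if self.weights.ndim != 2 or self.vth.shape != (self.weights.shape[0],):
            raise ValueError("weights must be (m, dim) with matching thresholds")
        self.scale = int(scale)
        self.params = params
        self.trained = trained
        self.dw_log: list = []
        self.win_counts = np.zeros(self.weights.shape[0], dtype=np.int64)

    @property
    def m(self):
        return self.weights.shape[0]

    @property
    def dim(self):
        return self.weights.shape[1]

    def neurons(self) -> List[FeastNeuron]:
        return [FeastNeuron(self.weights[i].copy(), float(self.vth[i]),
                            int(self.win_counts[i])) for i in range(self.m)]

    @classmethod
    def initialize(cls, dim: int, scale: int, params: FeastParams) -> "NeuronBank":
        """Seeded random init: uniform(0,1) weights L2-normalized, uniform thresholds."""
        rng = np.random.default_rng(params.seed)
        w = rng.uniform(0.0, 1.0, size=(params.m, dim))
        w /= np.linalg.norm(w, axis=1, keepdims=True)
        vth = rng.uniform(0.0, 1.0, size=params.m)
        return cls(w, vth, scale, params, trained=False)

    # -- serialization: YAML metadata + CSV weight matrix --------------

    def save(self, stem):
        stem = Path(stem)
        np.savetxt(stem.with_suffix(".weights.csv"), self.weights, delimiter=",")
        meta = {
            "scale": self.scale,
            "m": self.m,
            "dim": self.dim,
            "vth": [float(v) for v in self.vth],
            "trained": bool(self.trained),
            "win_counts": [int(v) for v in self.win_counts],
            "dw_log": [float(v) for v in self.dw_log],
            "params": {
                "m": self.params.m, "delta_i": self.params.delta_i,
                "delta_e": self.params.delta_e, "eta": self.params.eta,
                "epochs": self.params.epochs, "seed": self.params.seed,
            },
        }
        with open(stem.with_suffix(".bank.yaml"), "w") as fh:
            yaml.safe_dump(meta, fh)

    @classmethod
    def load(cls, stem) -> "NeuronBank":
        stem = Path(stem)
        with open(stem.with_suffix(".bank.yaml")) as fh:
            meta = yaml.safe_load(fh)
        w = np.loadtxt(stem.with_suffix(".weights.csv"), delimiter=",", ndmin=2)
        bank = cls(w, np.asarray(meta["vth"], dtype=float), meta["scale"],
                   FeastParams(**meta["params"]), trained=meta["trained"])
        bank.win_counts = np.asarray(meta["win_counts"], dtype=np.int64)
        bank.dw_log = list(meta["dw_log"])
        return bank


def similarity(ec: np.ndarray, weights: np.ndarray) -> float:
    """Cosine similarity between a flattened context and one weight vector."""
    ec = np.asarray(ec, dtype=float).ravel()
    w = np.asarray(weights, dtype=float).ravel()
    if ec.shape != w.shape:
        raise ValueError("shape mismatch")
    n_ec = np.linalg.norm(ec)
    n_w = np.linalg.norm(w)
    if n_ec == 0.0 or n_w == 0.0:
        raise ValueError("zero-norm vector: degenerate context or weights")
    return float(np.dot(ec, w) / (n_ec * n_w))


def learn_step(ec: np.ndarray, bank: NeuronBank,
               params: Optional[FeastParams] = None) -> Optional[int]:
    """One competitive update; mutates the bank, returns winner index or None.

    Candidates are neurons whose similarity clears their own threshold
    (inclusive); the winner is the argmax among them (ties to the lowest
    index).  Winner: threshold += delta_i (clamped at 1), weights mixed
    toward the context.  No candidate: all thresholds -= delta_e
    (clamped at 0).
    """
    p = params or bank.params
    ec = np.asarray(ec, dtype=float).ravel()
    sims = np.array([similarity(ec, bank.weights[i]) for i in range(bank.m)])
    eligible = sims >= bank.vth
    if not eligible.any():
        bank.vth = np.clip(bank.vth - p.delta_e, 0.0, 1.0)
        return None
    masked = np.where(eligible, sims, -np.inf)
    w = int(np.argmax(masked))  # argmax ties -> lowest index
    bank.vth[w] = min(1.0, bank.vth[w] + p.delta_i)
    bank.weights[w] = (1.0 - p.eta) * bank.weights[w] + p.eta * ec
    bank.win_counts[w] += 1
    return w


def train(ecs, params: FeastParams, scale: int = 1) -> NeuronBank:
    """Train a neuron bank on a batch of event contexts.

    Parameters
    ----------
    ecs : ECBatch or ndarray
        Flattened contexts, one per row.
    params : FeastParams
    scale : int
        Channel count of the contexts (bookkeeping only).

    Returns
    -------
    NeuronBank
        Trained bank with per-epoch mean |dW| in ``dw_log`` and
        final-epoch win counts in ``win_counts``.
    """
    values = ecs.values if isinstance(ecs, ECBatch) else np.asarray(ecs, dtype=float)
    if values.ndim != 2 or values.shape[0] == 0:
        raise ValueError("need a non-empty 2-D batch of flattened contexts")
    if isinstance(ecs, ECBatch):
        scale = ecs.scale
    n, dim = values.shape
    if n < params.m:
        import warnings

        warnings.warn(f"batch of {n} contexts is smaller than m={params.m}; "
                      "features will be underdetermined", stacklevel=2)
    bank = NeuronBank.initialize(dim, scale, params)
    if params.epochs == 0:
        bank.trained = True
        return bank
    rng = np.random.default_rng(params.seed + 1)
    order = np.stack([rng.permutation(n) for _ in range(params.epochs)]).astype(np.int64)
    values = np.ascontiguousarray(values)
    norms = np.linalg.norm(values, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm context in batch")
    if params.early_stop_dw is None:
        dw, wins = feast_train_epochs(values, norms, bank.weights, bank.vth,
                                      order, params.delta_i, params.delta_e,
                                      params.eta)
        bank.dw_log = list(dw)
        bank.win_counts = wins
    else:
        for ep in range(params.epochs):
            dw, wins = feast_train_epochs(values, norms, bank.weights, bank.vth,
                                          order[ep:ep + 1], params.delta_i,
                                          params.delta_e, params.eta)
            bank.dw_log.append(float(dw[0]))
            bank.win_counts = wins
            if dw[0] < params.early_stop_dw:
                break
    bank.trained = True
    return bank


class FeatureMap:
    """Feature-space spike stream: one winner neuron per consumed event."""

    def __init__(self, t, channel, winner, scale, m, fs, n_channels, duration):
        self.t = np.asarray(t, dtype=np.int64)
        self.channel = np.asarray(channel, dtype=np.int32)
        self.winner = np.asarray(winner, dtype=np.int32)
        self.scale = int(scale)
        self.m = int(m)
        self.fs = float(fs)
        self.n_channels = int(n_channels)
        self.duration = int(duration)

    def __len__(self):
        return self.t.size

    def __eq__(self, other):
        return (isinstance(other, FeatureMap)
                and (self.scale, self.m, self.fs, self.n_channels, self.duration)
                == (other.scale, other.m, other.fs, other.n_channels, other.duration)
                and np.array_equal(self.t, other.t)
                and np.array_equal(self.channel, other.channel)
                and np.array_equal(self.winner, other.winner))

    def to_csv(self, path):
        import pandas as pd

        df = pd.DataFrame({"t_sample": self.t, "channel": self.channel,
                           "winner_id": self.winner, "scale": self.scale})
        df.to_csv(path, index=False)
        meta = {"fs": self.fs, "n_channels": self.n_channels, "m": self.m,
                "scale": self.scale, "duration": self.duration}
        with open(Path(path).with_suffix(Path(path).suffix + ".yaml"), "w") as fh:
            yaml.safe_dump(meta, fh)

    @classmethod
    def from_csv(cls, path):
        import pandas as pd

        path = Path(path)
        df = pd.read_csv(path)
        with open(path.with_suffix(path.suffix + ".yaml")) as fh:
            meta = yaml.safe_load(fh)
        return cls(df["t_sample"], df["channel"], df["winner_id"],
                   meta["scale"], meta["m"], meta["fs"], meta["n_channels"],
                   meta["duration"])


def extract_from_batch(batch: ECBatch, bank: NeuronBank) -> FeatureMap:
    """Winner-take-all extraction over a pre-built context batch."""
    if not bank.trained:
        raise ValueError("bank is not trained")
    if batch.values.shape[1] != bank.dim:
        raise ValueError("context/bank dimension mismatch")
    stream = batch.stream
    if batch.n_built == 0:
        winners = np.zeros(0, dtype=np.int32)
    else:
        vals = batch.values / np.linalg.norm(batch.values, axis=1, keepdims=True)
        w = bank.weights / np.linalg.norm(bank.weights, axis=1, keepdims=True)
        winners = np.argmax(vals @ w.T, axis=1).astype(np.int32)
    return FeatureMap(stream.t[batch.anchor_index],
                      stream.channel[batch.anchor_index], winners,
                      bank.scale, bank.m, stream.fs, stream.n_channels,
                      stream.duration)


def extract(stream: EventStream, banks: Sequence[NeuronBank],
            ec_params) -> List[FeatureMap]:
    """Build contexts at each bank's scale and extract one feature map per bank.

    Thresholds play no role here; every event with a valid context
    yields exactly one feature spike per bank.
    """
    from .context import ec_batch

    maps = []
    for bank in banks:
        batch = ec_batch(stream, ec_params, scale=bank.scale)
        maps.append(extract_from_batch(batch, bank))
    return maps
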