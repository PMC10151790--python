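"""Leaky integrate-and-fire spike encoding of cochlear output.

Each cochlear channel drives one or more LIF neurons.  A neuron's
membrane follows a first-order leaky recurrence toward the drive; when
it exceeds its threshold it emits a spike and resets.  Several firing
thresholds per channel (optionally replicated neurons per threshold)
give a population code of response amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

from ._kernels import lif_count_spikes, lif_fill_spikes


@dataclass
class LIFConfig:
    """LIF population configuration.

    The leak coefficient is ``c_lif = 1 / (fs * tau_lif)``; with the
    defaults (fs=16 kHz, tau=10 ms) this is 1/160.  ``thresholds`` is an
    ordered (strictly increasing) list; the default single medium value
    is 4e-4.  ``neurons_per_threshold=3`` with three thresholds gives a
    nine-neuron layout per channel.
    """

    tau_lif: float = 0.01
    fs: float = 16000.0
    thresholds: Sequence[float] = (0.0004,)
    neurons_per_threshold: int = 1
    v_reset: float = 0.0

    def __post_init__(self):
        if self.tau_lif <= 0:
            raise ValueError("tau_lif must be positive")
        thr = np.asarray(self.thresholds, dtype=float)
        if thr.ndim != 1 or thr.size == 0 or np.any(np.diff(thr) <= 0):
            raise ValueError("thresholds must be a strictly increasing sequence")
        if self.neurons_per_threshold < 1:
            raise ValueError("neurons_per_threshold must be positive")
        if not 0.0 < self.c_lif <= 1.0:
            raise ValueError("c_lif = 1/(fs*tau_lif) must lie in (0, 1]")
        self.thresholds = tuple(float(v) for v in thr)

    @property
    def c_lif(self) -> float:
        return 1.0 / (self.fs * self.tau_lif)

    def initial_potentials(self) -> np.ndarray:
        """Deterministic per-neuron initial membrane offsets.

        Shape (n_thresholds, neurons_per_threshold).  Replicated neurons
        sharing a threshold start at staggered fractions of it so they
        desynchronize; the first neuron starts at v_reset.
        """
        thr = np.asarray(self.thresholds)
        n = self.neurons_per_threshold
        frac = 0.5 * np.arange(n) / n  # 0, 1/2n, 2/2n, ...
        return self.v_reset + np.outer(thr - self.v_reset, frac)


def lif_step(v_prev: float, drive: float, c_lif: float) -> float:
    """One step of the leaky membrane recurrence."""
    return v_prev + c_lif * (drive - v_prev)


class SpikeEvent(NamedTuple):
    """A single spike: sample time, frequency channel and neuron identity."""

    t: int
    channel: int
    threshold_id: int = 0
    neuron_id: int = 0


class EventStream:
    """Time-ordered spike records stored as column arrays.

    Attributes
    ----------
    t, channel, threshold_id, neuron_id : ndarray
        Parallel columns, sorted by ``t`` (stable).
    fs : float
        Sampling rate the sample times refer to.
    n_channels : int
    duration : int
        Length of the source signal in samples (bins span [0, duration)).
    """

    COLUMNS = ("t_sample", "channel", "threshold_id", "neuron_id")

    def __init__(self, t, channel, threshold_id=None, neuron_id=None, *,
                 fs, n_channels, duration=None, source=""):
        self.t = np.asarray(t, dtype=np.int64)
        self.channel = np.asarray(channel, dtype=np.int32)
        n = self.t.size
        self.threshold_id = (
            np.zeros(n, dtype=np.int32) if threshold_id is None
            else np.asarray(threshold_id, dtype=np.int32)
        )
        self.neuron_id = (
            np.zeros(n, dtype=np.int32) if neuron_id is None
            else np.asarray(neuron_id, dtype=np.int32)
        )
        if not (self.channel.size == n == self.threshold_id.size == self.neuron_id.size):
            raise ValueError("column length mismatch")
        if n and np.any(np.diff(self.t) < 0):
            raise ValueError("event times must be non-decreasing")
        if n and (self.t.min() < 0 or self.channel.max() >= n_channels):
            raise ValueError("event out of range")
        self.fs = float(fs)
        self.n_channels = int(n_channels)
        self.duration = int(duration) if duration is not None else (
            int(self.t.max()) + 1 if n else 0)
        self.source = source

    def __len__(self):
        return self.t.size

    def __iter__(self) -> Iterator[SpikeEvent]:
        for i in range(len(self)):
            yield SpikeEvent(int(self.t[i]), int(self.channel[i]),
                             int(self.threshold_id[i]), int(self.neuron_id[i]))

    def __eq__(self, other):
        return (
            isinstance(other, EventStream)
            and self.fs == other.fs
            and self.n_channels == other.n_channels
            and self.duration == other.duration
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.channel, other.channel)
            and np.array_equal(self.threshold_id, other.threshold_id)
            and np.array_equal(self.neuron_id, other.neuron_id)
        )

    def times_seconds(self) -> np.ndarray:
        return self.t / self.fs

    def channel_times(self, merge_thresholds: bool = True):
        """Per-channel sorted spike-time arrays (float, in samples)."""
        out = []
        for ch in range(self.n_channels):
            mask = self.channel == ch
            out.append(np.sort(self.t[mask]).astype(float))
        return out

    def restrict_channel(self, ch) -> "EventStream":
        mask = self.channel == ch
        return EventStream(self.t[mask], self.channel[mask],
                           self.threshold_id[mask], self.neuron_id[mask],
                           fs=self.fs, n_channels=self.n_channels,
                           duration=self.duration, source=self.source)

    def shifted(self, dt: int) -> "EventStream":
        """Copy with all timestamps shifted by a constant (for invariance tests)."""
        return EventStream(self.t + int(dt), self.channel,
                           self.threshold_id, self.neuron_id,
                           fs=self.fs, n_channels=self.n_channels,
                           duration=self.duration + int(dt), source=self.source)

    # -- I/O: CSV body + YAML sidecar ---------------------------------

    def to_csv(self, path):
        path = Path(path)
        df = pd.DataFrame({
            "t_sample": self.t, "channel": self.channel,
            "threshold_id": self.threshold_id, "neuron_id": self.neuron_id,
        })
        df.to_csv(path, index=False)
        meta = {"fs": self.fs, "n_channels": self.n_channels,
                "duration": self.duration, "source": self.source}
        with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
            yaml.safe_dump(meta, fh)

    @classmethod
    def from_csv(cls, path):
        path = Path(path)
        df = pd.read_csv(path)
        with open(path.with_suffix(path.suffix + ".yaml")) as fh:
            meta = yaml.safe_load(fh)
        return cls(df["t_sample"].to_numpy(), df["channel"].to_numpy(),
                   df["threshold_id"].to_numpy(), df["neuron_id"].to_numpy(),
                   fs=meta["fs"], n_channels=meta["n_channels"],
                   duration=meta.get("duration"), source=meta.get("source", ""))


def encode(cochleagram, config: LIFConfig, drive=None) -> EventStream:
    """Encode lateral-inhibited IHC output into a spike stream.

    Parameters
    ----------
    cochleagram : Cochleagram or None
        Source of drive values; its ``ihc_li`` array is used.  May be
        None when ``drive`` is given directly.
    config : LIFConfig
    drive : ndarray, optional
        Explicit (time x channel) drive matrix overriding the cochleagram.

    Returns
    -------
    EventStream
        Globally time-sorted; at most one spike per (channel,
        threshold_id, neuron_id, t).
    """
    if drive is None:
        drive = cochleagram.ihc_li
    drive = np.ascontiguousarray(drive, dtype=float)
    if drive.ndim != 2:
        raise ValueError("drive must be (time x channel)")
    if drive.shape[0] == 0:
        return EventStream([], [], fs=config.fs, n_channels=drive.shape[1],
                           duration=0, source="lif")
    thr = np.asarray(config.thresholds, dtype=float)
    v_init = np.ascontiguousarray(config.initial_potentials())
    n = lif_count_spikes(drive, config.c_lif, thr, v_init, config.v_reset)
    out_t = np.empty(n, dtype=np.int64)
    out_ch = np.empty(n, dtype=np.int32)
    out_thr = np.empty(n, dtype=np.int32)
    out_nrn = np.empty(n, dtype=np.int32)
    filled = lif_fill_spikes(drive, config.c_lif, thr, v_init, config.v_reset,
                             out_t, out_ch, out_thr, out_nrn)
    assert filled == n
    return EventStream(out_t, out_ch, out_thr, out_nrn, fs=config.fs,
                       n_channels=drive.shape[1], duration=drive.shape[0],
                       source="lif")
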