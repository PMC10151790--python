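"""Exponential time surfaces and fixed-size event contexts.

Every spike leaves an exponentially decaying trace in its channel.  The
event context (EC) of a spike is a fixed-size snapshot of those traces
in a neighborhood ending at the spike: 1-D (the spike's own channel, its
k most recent spikes) or 2-D (an odd number of adjacent channels, k
spikes each).  Because spike windows have varying durations, each
context is resampled onto a fixed grid: spike positions are normalized
to the window and the decay runs in grid samples, which makes a context
invariant to uniform time rescaling while preserving the relative
inter-spike-interval pattern.  The anchor cell always holds 1.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from ._kernels import ec_1d_batch, ec_2d_batch
from .spikes import EventStream, SpikeEvent


@dataclass
class TimeSurfaceParams:
    """Raw time-surface decay: tau_v in samples, default fs * 1e-3."""

    fs: float = 16000.0
    tau_v: Optional[float] = None

    def __post_init__(self):
        if self.tau_v is None:
            self.tau_v = self.fs * 1e-3
        if self.tau_v <= 0:
            raise ValueError("tau_v must be positive")


def time_surface_value(t_now, t_last, tau_v) -> float:
    """Exponential trace of the previous event, evaluated at t_now.

    Returns ``exp(-(t_now - t_last)/tau_v)``; 1.0 at the event itself.
    """
    if t_now < t_last:
        raise ValueError("t_now must not precede t_last")
    return math.exp(-(t_now - t_last) / tau_v)


@dataclass
class ECParams:
    """Event-context geometry.

    k : spikes per channel in a context (anchor included).
    n_samples : resampled grid length per channel.
    scales : channel counts for 2-D contexts (each odd).
    tau_grid : decay constant on the resampled grid, in grid samples
        (default n_samples / 4).
    min_history_policy : 'skip' drops events whose own channel lacks k
        spikes of history; rows of other channels are always zero-filled
        when short.
    """

    k: int = 4
    n_samples: int = 32
    scales: Sequence[int] = (5, 13, 25, 37)
    tau_grid: Optional[float] = None
    min_history_policy: str = "skip"

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_samples < self.k:
            raise ValueError("n_samples must be >= k")
        if any(s % 2 == 0 or s < 1 for s in self.scales):
            raise ValueError("every 2-D scale must be a positive odd channel count")
        if self.min_history_policy not in ("skip", "pad"):
            raise ValueError("min_history_policy must be 'skip' or 'pad'")
        if self.tau_grid is None:
            self.tau_grid = self.n_samples / 4.0
        if self.tau_grid <= 0:
            raise ValueError("tau_grid must be positive")


@dataclass
class EventContext:
    """Fixed-size context: (n_samples,) for 1-D, (scale, n_samples) for 2-D."""

    values: np.ndarray
    anchor: SpikeEvent
    scale: int = 1

    def flat(self) -> np.ndarray:
        return self.values.ravel()


class ECBatch:
    """Dense batch of contexts built from one stream.

    Attributes
    ----------
    values : ndarray, (n_built, scale * n_samples)
        Flattened contexts, in stream order of their anchors.
    anchor_index : ndarray
        Index of each built context's anchor within the source stream.
    n_skipped : int
        Events dropped for insufficient own-channel history.
    """

    def __init__(self, values, anchor_index, stream, scale, params):
        self.values = values
        self.anchor_index = anchor_index
        self.stream = stream
        self.scale = scale
        self.params = params

    @property
    def n_built(self):
        return self.values.shape[0]

    @property
    def n_skipped(self):
        return len(self.stream) - self.n_built

    def anchor_times(self):
        return self.stream.t[self.anchor_index]

    def anchor_channels(self):
        return self.stream.channel[self.anchor_index]

    def contexts(self) -> List[EventContext]:
        out = []
        n = self.params.n_samples
        for row, idx in zip(self.values, self.anchor_index):
            vals = row if self.scale == 1 else row.reshape(self.scale, n)
            anchor = SpikeEvent(int(self.stream.t[idx]), int(self.stream.channel[idx]),
                                int(self.stream.threshold_id[idx]),
                                int(self.stream.neuron_id[idx]))
            out.append(EventContext(values=vals, anchor=anchor, scale=self.scale))
        return out

    def to_csv(self, path):
        import pandas as pd

        df = pd.DataFrame(self.values)
        df.insert(0, "anchor_t", self.anchor_times())
        df.insert(1, "anchor_channel", self.anchor_channels())
        df.insert(2, "scale", self.scale)
        df.to_csv(path, index=False)


def _stream_arrays(stream: EventStream):
    """Flattened per-channel spike times plus each event's in-channel index."""
    n_ch = stream.n_channels
    counts = np.bincount(stream.channel, minlength=n_ch)
    offsets = np.zeros(n_ch + 1, dtype=np.int64)
    np.cumsum(counts, out=offsets[1:])
    times_flat = np.empty(len(stream), dtype=float)
    idx_in_ch = np.empty(len(stream), dtype=np.int64)
    cursor = offsets[:-1].copy()
    for i in range(len(stream)):
        ch = stream.channel[i]
        idx_in_ch[i] = cursor[ch] - offsets[ch]
        times_flat[cursor[ch]] = stream.t[i]
        cursor[ch] += 1
    return times_flat, offsets, idx_in_ch


def ec_batch(stream: EventStream, params: ECParams, scale: int = 1) -> ECBatch:
    """Build the context of every event in the stream.

    ``scale=1`` builds 1-D contexts; an odd ``scale>1`` builds 2-D
    contexts over that many adjacent channels.  Events without k spikes
    of history in their own channel are skipped (counted, not built).
    """
    times_flat, offsets, idx_in_ch = _stream_arrays(stream)
    ev_ch = stream.channel.astype(np.int64)
    if len(stream) == 0:
        dim = params.n_samples * scale
        return ECBatch(np.zeros((0, dim)), np.zeros(0, dtype=np.int64),
                       stream, scale, params)
    if scale == 1:
        ecs, built = ec_1d_batch(times_flat, offsets, ev_ch, idx_in_ch,
                                 params.k, params.n_samples, params.tau_grid)
    else:
        if scale % 2 == 0:
            raise ValueError("2-D scale must be odd")
        ev_t = stream.t.astype(float)
        ecs, built = ec_2d_batch(times_flat, offsets, ev_t, ev_ch, idx_in_ch,
                                 stream.n_channels, scale, params.k,
                                 params.n_samples, params.tau_grid)
        ecs = ecs.reshape(ecs.shape[0], -1)
    mask = built.astype(bool)
    return ECBatch(ecs[mask], np.nonzero(mask)[0].astype(np.int64),
                   stream, scale, params)


def build_ec_1d(anchor_index: int, stream: EventStream,
                params: ECParams) -> Optional[EventContext]:
    """Context of a single event (by stream index); None if skipped."""
    batch = ec_batch(stream, params, scale=1)
    where = np.nonzero(batch.anchor_index == anchor_index)[0]
    if where.size == 0:
        return None
    return batch.contexts()[int(where[0])]


def build_ec_2d(anchor_index: int, stream: EventStream, scale: int,
                params: ECParams) -> Optional[EventContext]:
    """2-D context of a single event (by stream index); None if skipped."""
    batch = ec_batch(stream, params, scale=scale)
    where = np.nonzero(batch.anchor_index == anchor_index)[0]
    if where.size == 0:
        return None
    return batch.contexts()[int(where[0])]


def row_profile(times_in_channel, t_anchor, k, n_samples, tau_grid,
                window_start=None) -> np.ndarray:
    """Reference construction of one context row (plain numpy, no JIT).

    Selects the k latest spikes at or before ``t_anchor`` in the given
    channel, normalizes their positions to the window
    ``[window_start or earliest selected, t_anchor]`` and evaluates the
    grid-domain exponential decay at ``n_samples`` uniform points.
    Returns zeros when fewer than k spikes are available.
    """
    times = np.asarray(times_in_channel, dtype=float)
    sel = times[times <= t_anchor]
    if sel.size < k:
        return np.zeros(n_samples)
    sel = np.sort(sel)[-k:]
    w0 = sel[0] if window_start is None else float(window_start)
    dur = t_anchor - w0
    if dur <= 0:
        return np.ones(n_samples)
    rho = (sel - w0) / dur
    grid = np.linspace(0.0, 1.0, n_samples)
    out = np.zeros(n_samples)
    for p, u in enumerate(grid):
        past = rho[rho <= u + 1e-12]
        if past.size:
            out[p] = math.exp(-(u - past[-1]) * (n_samples - 1) / tau_grid)
    return out
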