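"""Cascaded asymmetric-resonator cochlear filterbank.

A software cochlea: a cascade of second-order asymmetric resonators whose
characteristic frequencies follow the Greenwood frequency-position map,
with an optional fast-acting-compression (FAC) loop (outer-hair-cell
nonlinearity plus a multi-stage AGC), inner-hair-cell detection and
lateral inhibition between neighboring channels.

Channel 0 sits at the base (highest CF); CF decreases with channel index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import yaml

from ._kernels import car_fac_cascade

GREENWOOD_A = 165.4
GREENWOOD_ALPHA = 2.1

#: AGC smoothing-stage time constants in seconds (fast to slow).
DEFAULT_AGC_TAUS = (0.002, 0.008, 0.032, 0.128)


def greenwood_cf(x):
    """Map normalized cochlear position to characteristic frequency.

    Parameters
    ----------
    x : float or array-like
        Normalized position along the cochlea, 0 at the apex to 1 at the
        base.

    Returns
    -------
    float or ndarray
        Characteristic frequency in Hz: ``165.4 * (10**(2.1*x) - 1)``.
        Monotonically increasing in ``x``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("normalized cochlear position must lie in [0, 1]")
    f = GREENWOOD_A * (10.0 ** (GREENWOOD_ALPHA * x) - 1.0)
    return float(f) if f.ndim == 0 else f


def greenwood_position(f):
    """Analytic inverse of :func:`greenwood_cf` (frequency -> position)."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be nonnegative")
    x = np.log10(f / GREENWOOD_A + 1.0) / GREENWOOD_ALPHA
    return float(x) if x.ndim == 0 else x


@dataclass
class CochleaConfig:
    """Filterbank design: per-channel coefficients plus FAC/LI parameters."""

    n_channels: int
    fs: float
    cf: np.ndarray  # strictly decreasing, Hz
    fac_enabled: bool = False
    zeta: float = 0.10  # pole damping ratio of the linear CAR
    pole_shift: float = 0.91  # pole freq / CF; offsets the cascade peak shift
    zeta_min: float = 0.04  # FAC: minimum damping (quiet, high gain)
    zeta_max: float = 0.30  # FAC: maximum damping (loud, compressed)
    v_scale: float = 8.0  # OHC velocity-nonlinearity scale
    agc_taus: tuple = DEFAULT_AGC_TAUS
    agc_weights: tuple = (0.25, 0.25, 0.25, 0.25)
    agc_gain: float = 12.0
    ihc_tau: float = 0.0005  # IHC smoothing time constant, s
    li_kernel: tuple = (-0.5, 1.0, -0.5)  # center-minus-neighbors

    # derived per-channel arrays
    theta: np.ndarray = field(default=None, repr=False)
    a0: np.ndarray = field(default=None, repr=False)
    c0: np.ndarray = field(default=None, repr=False)
    h: np.ndarray = field(default=None, repr=False)
    r_lin: np.ndarray = field(default=None, repr=False)
    g_lin: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.cf = np.asarray(self.cf, dtype=float)
        if self.cf.shape != (self.n_channels,):
            raise ValueError("cf must have length n_channels")
        if np.any(np.diff(self.cf) >= 0):
            raise ValueError("cf must be strictly decreasing with channel index")
        if np.any(self.cf <= 0) or np.any(self.cf >= self.fs / 2):
            raise ValueError("all cf must lie in (0, fs/2)")
        # pole slightly below nominal CF: gain accumulated along the
        # cascade pushes the net response peak a couple of channels past
        # each stage's own resonance, so the poles are pre-shifted to
        # land the measured best frequency on the nominal CF
        pole = np.minimum(self.cf * self.pole_shift, 0.475 * self.fs)
        self.theta = 2.0 * np.pi * pole / self.fs
        self.a0 = np.cos(self.theta)
        self.c0 = np.sin(self.theta)
        # zeros placed above the pole frequency -> asymmetric (steep
        # high-side) resonance, as in the coupled-form cochlear cascade
        self.h = self.c0.copy()
        self.r_lin = 1.0 - self.zeta * self.theta
        a = self.r_lin * self.a0
        c = self.r_lin * self.c0
        num_dc = 1.0 - 2.0 * a + self.r_lin**2
        self.g_lin = num_dc / (num_dc + self.h * c)

    # -- serialization -------------------------------------------------

    def to_yaml(self, path):
        data = {
            "n_channels": int(self.n_channels),
            "fs": float(self.fs),
            "cf": [float(v) for v in self.cf],
            "fac_enabled": bool(self.fac_enabled),
            "zeta": float(self.zeta),
            "pole_shift": float(self.pole_shift),
            "zeta_min": float(self.zeta_min),
            "zeta_max": float(self.zeta_max),
            "v_scale": float(self.v_scale),
            "agc_taus": [float(v) for v in self.agc_taus],
            "agc_weights": [float(v) for v in self.agc_weights],
            "agc_gain": float(self.agc_gain),
            "ihc_tau": float(self.ihc_tau),
            "li_kernel": [float(v) for v in self.li_kernel],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def stage_ba(self, ch):
        """Biquad (b, a) of one cascade stage, for analytic checks."""
        r = self.r_lin[ch]
        a_ = r * self.a0[ch]
        c_ = r * self.c0[ch]
        b = self.g_lin[ch] * np.array([1.0, self.h[ch] * c_ - 2.0 * a_, r**2])
        a = np.array([1.0, -2.0 * a_, r**2])
        return b, a


def design_filterbank(n_channels=64, fs=16000.0, cf_range=(100.0, 8000.0), **kwargs):
    """Design a filterbank with Greenwood-spaced characteristic frequencies.

    CFs are sampled at ``n_channels`` equally spaced cochlear positions
    spanning ``cf_range`` and ordered base to apex, i.e. decreasing with
    channel index.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    lo, hi = float(cf_range[0]), float(cf_range[1])
    if not (0.0 < lo < hi):
        raise ValueError("cf_range must be increasing and positive")
    if hi >= fs / 2:
        raise ValueError(f"cf_range upper edge {hi} Hz reaches Nyquist ({fs / 2} Hz)")
    x = np.linspace(greenwood_position(lo), greenwood_position(hi), n_channels)
    cf = greenwood_cf(x)[::-1].copy()  # channel 0 = highest CF
    return CochleaConfig(n_channels=n_channels, fs=fs, cf=cf, **kwargs)


@dataclass
class CochleagramFrame:
    """One output sample: per-channel BM output and inhibited IHC output."""

    t: int
    bm: np.ndarray
    ihc_li: np.ndarray


class Cochleagram:
    """Dense (time x channel) cochlear output, iterable as frames."""

    def __init__(self, bm, ihc_li, fs):
        self.bm = bm
        self.ihc_li = ihc_li
        self.fs = fs

    @property
    def n_samples(self):
        return self.bm.shape[0]

    @property
    def n_channels(self):
        return self.bm.shape[1]

    def __len__(self):
        return self.n_samples

    def __getitem__(self, t) -> CochleagramFrame:
        return CochleagramFrame(t=t, bm=self.bm[t], ihc_li=self.ihc_li[t])

    def __iter__(self) -> Iterator[CochleagramFrame]:
        for t in range(self.n_samples):
            yield self[t]

    def to_csv(self, path):
        import pandas as pd

        cols = {f"ihc_li_{c}": self.ihc_li[:, c] for c in range(self.n_channels)}
        pd.DataFrame(cols).to_csv(path, index=False)


def lateral_inhibition(ihc, kernel=(-0.5, 1.0, -0.5)):
    """Sharpen spectral contrast by subtracting neighboring channels.

    ``kernel`` is centered on the channel itself; negative side weights
    subtract the neighbors.  At the edges the kernel is truncated and its
    side weights renormalized so edge channels see the same total
    inhibition.  Output is floored at zero.

    Works on a single frame (1-D, n_channels) or a full cochleagram
    (2-D, time x channel).
    """
    ihc = np.asarray(ihc, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 1 or kernel.size % 2 == 0:
        raise ValueError("kernel must be 1-D with odd length")
    single = ihc.ndim == 1
    x = ihc[None, :] if single else ihc
    n_ch = x.shape[1]
    half = kernel.size // 2
    side_total = np.sum(np.abs(kernel)) - np.abs(kernel[half])
    out = kernel[half] * x.copy()
    for off in range(-half, half + 1):
        if off == 0:
            continue
        w = kernel[half + off]
        if w == 0.0:
            continue
        lo_dst = max(0, -off)
        hi_dst = min(n_ch, n_ch - off)
        contrib = np.zeros_like(x)
        contrib[:, lo_dst:hi_dst] = w * x[:, lo_dst + off : hi_dst + off]
        out += contrib
    if side_total > 0:
        # renormalize edge channels whose kernel was truncated
        for ch in range(n_ch):
            avail = 0.0
            for off in range(-half, half + 1):
                if off != 0 and 0 <= ch + off < n_ch:
                    avail += np.abs(kernel[half + off])
            if 0.0 < avail < side_total:
                scale = side_total / avail
                extra = np.zeros(x.shape[0])
                for off in range(-half, half + 1):
                    if off != 0 and 0 <= ch + off < n_ch:
                        extra += kernel[half + off] * x[:, ch + off]
                out[:, ch] = kernel[half] * x[:, ch] + scale * extra
    np.maximum(out, 0.0, out=out)
    return out[0] if single else out


def process(signal, config: CochleaConfig) -> Cochleagram:
    """Run a waveform through the cochlear cascade.

    Parameters
    ----------
    signal : array-like
        Mono waveform samples.
    config : CochleaConfig
        Filterbank design from :func:`design_filterbank`.

    Returns
    -------
    Cochleagram
        BM output and lateral-inhibited IHC output per channel.
    """
    x = np.ascontiguousarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be mono (1-D)")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains NaN or Inf")
    agc_coeffs = 1.0 - np.exp(-1.0 / (config.fs * np.asarray(config.agc_taus)))
    ihc_coeff = 1.0 - np.exp(-1.0 / (config.fs * config.ihc_tau))
    bm, ihc = car_fac_cascade(
        x,
        config.a0,
        config.c0,
        config.h,
        config.r_lin,
        config.g_lin,
        config.fac_enabled,
        config.theta,
        config.zeta_min,
        config.zeta_max,
        config.v_scale,
        agc_coeffs,
        np.asarray(config.agc_weights, dtype=float),
        config.agc_gain,
        ihc_coeff,
    )
    ihc_li = lateral_inhibition(ihc, config.li_kernel)
    return Cochleagram(bm=bm, ihc_li=ihc_li, fs=config.fs)


def read_wav(path):
    """Read a mono PCM WAV file, returning (samples in [-1, 1], fs)."""
    from scipy.io import wavfile

    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: stereo WAV not supported; supply mono audio")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return data, float(fs)


def write_wav(path, samples, fs):
    """Write samples in [-1, 1] as 16-bit mono PCM."""
    from scipy.io import wavfile

    pcm = np.clip(np.asarray(samples, dtype=float), -1.0, 1.0)
    wavfile.write(path, int(fs), (pcm * 32767.0).astype(np.int16))
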