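"""Synthetic speech-like audio for end-to-end testing.

Generates isolated "utterances" with the statistical structure real
speech presents to a cochlear front end: a harmonic source (stacked
harmonics of a drifting fundamental) shaped by formant resonances whose
center frequencies follow class-specific trajectories, multiplied by a
syllabic-rate amplitude envelope, with optional additive noise.
"Speakers" are multiplicative jitters of the fundamental and formants,
so train/test splits can be made speaker-disjoint.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass
class AudioSignal:
    samples: np.ndarray
    fs: float

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


def synth_tone(freq, amp, duration, fs, am_rate=0.0, am_depth=0.0,
               phase=0.0) -> AudioSignal:
    """Amplitude-modulated sinusoid; with am_depth=0, a constant tone."""
    if freq >= fs / 2:
        raise ValueError(f"tone at {freq} Hz aliases at fs={fs}")
    if not 0.0 <= am_depth <= 1.0:
        raise ValueError("am_depth must lie in [0, 1]")
    t = np.arange(int(round(duration * fs))) / fs
    env = (1.0 - am_depth) + am_depth * 0.5 * (1.0 - np.cos(2 * np.pi * am_rate * t))
    x = amp * env * np.sin(2 * np.pi * freq * t + phase)
    return AudioSignal(x, fs)


@dataclass
class UtteranceSpec:
    """Parameters of one synthetic utterance."""

    class_id: int
    duration: float  # seconds
    f0: Tuple[float, float]  # fundamental start/end, Hz
    formants: Sequence[Tuple[float, float]]  # per formant: (start, end) Hz
    formant_bw: float = 120.0  # resonance bandwidth, Hz
    env_rate: float = 4.0  # syllabic AM rate, Hz
    env_depth: float = 0.6
    snr_db: Optional[float] = 30.0  # None = noiseless
    amplitude: float = 0.15  # peak amplitude target
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if min(self.f0) <= 0:
            raise ValueError("f0 must be positive")


def _resonance_gain(f, center, bw):
    """Lorentzian-style formant gain at frequency f."""
    return 1.0 / (1.0 + ((f - center) / (bw / 2.0)) ** 2)


def synth_utterance(spec: UtteranceSpec, fs: float = 16000.0) -> AudioSignal:
    """Render one utterance: harmonic source x formant filter x envelope.

    The source is a sum of harmonics of the (linearly drifting)
    fundamental, each harmonic weighted per sample by the summed formant
    resonance gains at its instantaneous frequency, plus a gentle
    spectral tilt.  Phases accumulate the instantaneous frequency so
    drifting trajectories stay smooth.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    u = t / spec.duration  # normalized time
    f0 = spec.f0[0] + (spec.f0[1] - spec.f0[0]) * u
    max_f0 = max(spec.f0)
    n_harm = max(1, int((fs / 2 - 200.0) / max_f0))
    x = np.zeros(n)
    centers = [(f1 + (f2 - f1) * u) for (f1, f2) in spec.formants]
    for h in range(1, n_harm + 1):
        fh = h * f0
        valid = fh < fs / 2
        gain = np.zeros(n)
        for c in centers:
            gain += _resonance_gain(fh, c, spec.formant_bw)
        gain *= (1.0 / h) * valid  # source tilt ~1/harmonic number
        phase = 2 * np.pi * np.cumsum(fh) / fs
        x += gain * np.sin(phase + rng.uniform(0, 2 * np.pi))
    env = (1.0 - spec.env_depth) + spec.env_depth * 0.5 * (
        1.0 - np.cos(2 * np.pi * spec.env_rate * t))
    ramp = np.minimum(1.0, np.minimum(t, spec.duration - t) / 0.02)  # 20 ms edges
    x *= env * ramp
    peak = np.max(np.abs(x))
    if peak > 0:
        x *= spec.amplitude / peak
    if spec.snr_db is not None and np.any(x):
        p_sig = np.mean(x**2)
        p_noise = p_sig / (10.0 ** (spec.snr_db / 10.0))
        x = x + rng.normal(0.0, np.sqrt(p_noise), size=n)
    np.clip(x, -1.0, 1.0, out=x)
    return AudioSignal(x, fs)


#: Class templates: (f0 range, formant-1 trajectory, formant-2 trajectory).
#: Trajectories are (start, end) Hz; classes differ in both the spectral
#: position and the direction of movement of their formants.
CLASS_TEMPLATES: List[dict] = [
    {"f0": (110.0, 130.0), "formants": [(350.0, 350.0), (2400.0, 2400.0)]},
    {"f0": (120.0, 110.0), "formants": [(700.0, 400.0), (1100.0, 1700.0)]},
    {"f0": (100.0, 140.0), "formants": [(600.0, 900.0), (1900.0, 1300.0)]},
    {"f0": (130.0, 115.0), "formants": [(450.0, 750.0), (1500.0, 2200.0)]},
    {"f0": (115.0, 115.0), "formants": [(850.0, 550.0), (2100.0, 1600.0)]},
    {"f0": (105.0, 125.0), "formants": [(500.0, 500.0), (1300.0, 1300.0)]},
    {"f0": (125.0, 105.0), "formants": [(650.0, 350.0), (2300.0, 1800.0)]},
    {"f0": (118.0, 132.0), "formants": [(400.0, 650.0), (1000.0, 1450.0)]},
    {"f0": (112.0, 112.0), "formants": [(750.0, 950.0), (1700.0, 2350.0)]},
    {"f0": (128.0, 112.0), "formants": [(550.0, 850.0), (1200.0, 2050.0)]},
    {"f0": (108.0, 122.0), "formants": [(300.0, 550.0), (2200.0, 1500.0)]},
]


@dataclass
class DatasetSpec:
    """A labeled, speaker-split collection of synthetic utterances."""

    n_classes: int = 4
    train_per_class: int = 25
    test_per_class: int = 25
    n_speakers: int = 10
    train_speaker_frac: float = 0.5
    duration_range: Tuple[float, float] = (0.35, 0.55)
    speaker_jitter_sigma: float = 0.05  # log-normal sigma on f0/formants
    env_rate_range: Tuple[float, float] = (3.0, 6.0)
    snr_db: Optional[float] = 30.0
    amplitude: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_classes > len(CLASS_TEMPLATES):
            raise ValueError(f"at most {len(CLASS_TEMPLATES)} classes available")
        if self.n_speakers < 2:
            raise ValueError("need at least 2 speakers for a disjoint split")


def _utt_seed(global_seed: int, *parts) -> int:
    """Stable per-utterance seed derived from the global seed and identifiers."""
    h = hashlib.sha256(("|".join(map(str, (global_seed,) + parts))).encode())
    return int.from_bytes(h.digest()[:4], "little")


def make_dataset(spec: DatasetSpec, fs: float = 16000.0):
    """Generate the dataset; returns (list of AudioSignal, manifest DataFrame).

    The manifest has one row per utterance: utterance_id, class, speaker,
    split, seed, duration.  Speakers are disjoint across train/test.
    Byte-identical for identical specs.
    """
    rng = np.random.default_rng(spec.seed)
    n_train_spk = max(1, int(round(spec.n_speakers * spec.train_speaker_frac)))
    speakers = np.arange(spec.n_speakers)
    train_speakers = set(speakers[:n_train_spk].tolist())
    # per-speaker multiplicative jitters
    spk_jit = {
        int(s): {
            "f0": float(np.exp(rng.normal(0, spec.speaker_jitter_sigma))),
            "formant": float(np.exp(rng.normal(0, spec.speaker_jitter_sigma))),
        }
        for s in speakers
    }
    signals: List[AudioSignal] = []
    rows = []
    for cls in range(spec.n_classes):
        tpl = CLASS_TEMPLATES[cls]
        for split, count in (("train", spec.train_per_class),
                             ("test", spec.test_per_class)):
            pool = [s for s in speakers
                    if (s in train_speakers) == (split == "train")]
            for i in range(count):
                seed_i = _utt_seed(spec.seed, cls, split, i)
                r = np.random.default_rng(seed_i)
                spk = int(pool[int(r.integers(len(pool)))])
                jf0 = spk_jit[spk]["f0"] * float(
                    np.exp(r.normal(0, spec.speaker_jitter_sigma / 2)))
                jfm = spk_jit[spk]["formant"] * float(
                    np.exp(r.normal(0, spec.speaker_jitter_sigma / 2)))
                dur = float(r.uniform(*spec.duration_range))
                uspec = UtteranceSpec(
                    class_id=cls,
                    duration=dur,
                    f0=(tpl["f0"][0] * jf0, tpl["f0"][1] * jf0),
                    formants=[(a * jfm, b * jfm) for a, b in tpl["formants"]],
                    env_rate=float(r.uniform(*spec.env_rate_range)),
                    snr_db=spec.snr_db,
                    amplitude=spec.amplitude,
                    seed=seed_i,
                )
                signals.append(synth_utterance(uspec, fs))
                rows.append({
                    "utterance_id": f"c{cls}_{split}_{i:03d}",
                    "class": cls, "speaker": spk, "split": split,
                    "seed": seed_i, "duration": dur,
                })
    manifest = pd.DataFrame(rows)
    return signals, manifest
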