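# earfeast

Event-driven auditory feature extraction in Python:

1. **Cochlear filterbank** (`earfeast.cochlea`) — a cascade of second-order
   asymmetric resonators with Greenwood-spaced characteristic frequencies,
   optional fast-acting compression (outer-hair-cell nonlinearity + multi-stage
   AGC loop), inner-hair-cell detection and lateral inhibition across
   neighboring channels.  The compression stage can be switched off for a
   fully linear cascade.
2. **Spike encoding** (`earfeast.spikes`) — leaky integrate-and-fire neurons
   per channel (configurable thresholds, optionally several neurons per
   threshold) turn the inhibited hair-cell output into asynchronous
   `(t, channel, threshold_id, neuron_id)` events.
3. **Event contexts** (`earfeast.context`) — exponential time surfaces over
   the spike stream, summarized per event as fixed-size resampled patches:
   1-D (the k most recent spikes in the event's channel) or 2-D (an odd number
   of adjacent channels, k spikes each).  Contexts are invariant to time
   translation and to uniform time rescaling.
4. **FEAST** (`earfeast.feast`) — competitive learning with per-neuron
   adaptive selection thresholds over context batches (winner threshold up,
   everyone down on a miss), then winner-take-all extraction into per-neuron
   feature maps.
5. **Features + classifier** (`earfeast.features`) — fixed time binning of
   feature maps (or of the raw spike stream as a baseline) into fixed-length
   count vectors, evaluated with a linear-kernel SVM whose regularization is
   chosen by cross-validation on the training split only.
6. **Synthetic data** (`earfeast.synth`) — speech-like utterances (harmonic
   source, class-specific formant trajectories, syllabic amplitude envelope,
   per-speaker jitter) so the entire pipeline is testable without any
   licensed corpus.

The per-sample kernels (cochlear cascade, LIF recurrence, context building,
FEAST training) are JIT-compiled with numba when available and fall back to
pure Python otherwise.

## CLI

```sh
earfeast cochlea --wav in.wav --channels 64 --no-fac --out gram.csv
earfeast encode --cochleagram gram.csv --tau 0.01 --threshold 0.0004 --out events.csv
earfeast feast-train --events events.csv --neurons 32 --scales 1,5,13 --epochs 10 --seed 42 --out banks/
earfeast feast-extract --events events.csv --banks banks/ --out fmaps/
earfeast classify --train train.csv --test test.csv --report report.yaml
earfeast demo --classes 4 --per-class 10 --neurons 16 --seed 0
```

`demo` generates a synthetic dataset and runs
generate → cochlea → encode → FEAST-train → extract → featurize → classify,
printing baseline vs 1-D vs 2-D accuracies.

## Library example

```python
import numpy as np
from earfeast import (design_filterbank, process, LIFConfig, encode,
                      ECParams, ec_batch, FeastParams, train)
from earfeast.feast import extract_from_batch

cfg = design_filterbank(n_channels=64, fs=16000, cf_range=(100, 7000))
gram = process(waveform, cfg)                      # time x channel
stream = encode(gram, LIFConfig(thresholds=(0.0004,)))
batch = ec_batch(stream, ECParams(k=4, n_samples=32), scale=5)
bank = train(batch, FeastParams(m=32, epochs=10, seed=0))
fmap = extract_from_batch(batch, bank)             # feature-space spikes
```
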