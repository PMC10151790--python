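"""Per-sample numeric kernels, JIT-compiled when numba is available.

Everything here is deliberately loop-structured: the cochlear cascade and
the LIF/FEAST recurrences are sequential in time (and, for the cascade,
in channel), so they cannot be expressed as whole-array numpy operations.
The pure-Python fallback is only a safety net; numba is expected.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly by every kernel call
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # noqa: D103 - decorator shim
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


@njit(cache=False)
def car_fac_cascade(
    x,
    a0,
    c0,
    h,
    r_lin,
    g_lin,
    fac_enabled,
    theta,
    zeta_min,
    zeta_max,
    v_scale,
    agc_coeffs,
    agc_weights,
    agc_gain,
    ihc_coeff,
):
    """Run the resonator cascade sample by sample.

    Returns (bm, ihc): both (n_samples, n_channels).  With fac_enabled the
    pole radius of every stage is re-derived each sample from the outer-
    hair-cell nonlinearity and the AGC loop state; otherwise the
    precomputed linear coefficients r_lin/g_lin are used unchanged.
    """
    n_t = x.shape[0]
    n_ch = a0.shape[0]
    n_agc = agc_coeffs.shape[0]

    bm = np.zeros((n_t, n_ch))
    ihc = np.zeros((n_t, n_ch))

    z1 = np.zeros(n_ch)
    z2 = np.zeros(n_ch)
    ihc_state = np.zeros(n_ch)
    agc_state = np.zeros((n_agc, n_ch))

    for t in range(n_t):
        drive = x[t]
        for ch in range(n_ch):
            if fac_enabled:
                # velocity-gated undamping, reduced by accumulated AGC
                v = z2[ch]  # previous z2: proxy for BM velocity state
                nlf = 1.0 / (1.0 + (v_scale * v) * (v_scale * v))
                agc_mix = 0.0
                for s in range(n_agc):
                    agc_mix += agc_weights[s] * agc_state[s, ch]
                undamp = nlf * (1.0 - agc_gain * agc_mix)
                if undamp < 0.0:
                    undamp = 0.0
                elif undamp > 1.0:
                    undamp = 1.0
                zeta = zeta_max - (zeta_max - zeta_min) * undamp
                r = 1.0 - zeta * theta[ch]
                a = r * a0[ch]
                c = r * c0[ch]
                num_dc = 1.0 - 2.0 * a + r * r
                den_dc = num_dc + h[ch] * c
                g = num_dc / den_dc
            else:
                r = r_lin[ch]
                a = r * a0[ch]
                c = r * c0[ch]
                g = g_lin[ch]

            z1_new = a * z1[ch] - c * z2[ch] + drive
            z2_new = c * z1[ch] + a * z2[ch]
            y = g * (drive + h[ch] * z2_new)
            z1[ch] = z1_new
            z2[ch] = z2_new
            bm[t, ch] = y

            # half-wave rectification + first-order smoothing (DIHC)
            hwr = y if y > 0.0 else 0.0
            ihc_state[ch] += ihc_coeff * (hwr - ihc_state[ch])
            ihc[t, ch] = ihc_state[ch]

            if fac_enabled:
                inp = ihc_state[ch]
                for s in range(n_agc):
                    agc_state[s, ch] += agc_coeffs[s] * (inp - agc_state[s, ch])
                    inp = agc_state[s, ch]

            drive = y  # cascade: next channel filters this output

    return bm, ihc


@njit(cache=False)
def lif_count_spikes(drive, c_lif, thresholds, v_init, v_reset):
    """First pass: count spikes so the caller can preallocate exactly."""
    n_t, n_ch = drive.shape
    n_thr = thresholds.shape[0]
    n_per = v_init.shape[1]
    count = 0
    v = np.empty((n_ch, n_thr, n_per))
    for ch in range(n_ch):
        for k in range(n_thr):
            for j in range(n_per):
                v[ch, k, j] = v_init[k, j]
    for t in range(n_t):
        for ch in range(n_ch):
            d = drive[t, ch]
            for k in range(n_thr):
                for j in range(n_per):
                    vm = v[ch, k, j] + c_lif * (d - v[ch, k, j])
                    if vm > thresholds[k]:
                        count += 1
                        vm = v_reset
                    v[ch, k, j] = vm
    return count


@njit(cache=False)
def lif_fill_spikes(drive, c_lif, thresholds, v_init, v_reset, out_t, out_ch, out_thr, out_nrn):
    """Second pass: re-run the recurrence and record spike coordinates."""
    n_t, n_ch = drive.shape
    n_thr = thresholds.shape[0]
    n_per = v_init.shape[1]
    idx = 0
    v = np.empty((n_ch, n_thr, n_per))
    for ch in range(n_ch):
        for k in range(n_thr):
            for j in range(n_per):
                v[ch, k, j] = v_init[k, j]
    for t in range(n_t):
        for ch in range(n_ch):
            d = drive[t, ch]
            for k in range(n_thr):
                for j in range(n_per):
                    vm = v[ch, k, j] + c_lif * (d - v[ch, k, j])
                    if vm > thresholds[k]:
                        out_t[idx] = t
                        out_ch[idx] = ch
                        out_thr[idx] = k
                        out_nrn[idx] = j
                        idx += 1
                        vm = v_reset
                    v[ch, k, j] = vm
    return idx


@njit(cache=False)
def _row_values(sel, w0, dur, n_samples, tau_grid, out):
    """Time-surface profile of one context row on the normalized grid.

    sel holds the selected spike times (sorted); positions are normalized
    to the window [w0, w0 + dur] and the exponential decay runs in grid
    samples so the profile is invariant to uniform time rescaling.
    """
    k = sel.shape[0]
    if dur <= 0.0:
        for p in range(n_samples):
            out[p] = 1.0
        return
    span = n_samples - 1.0
    for p in range(n_samples):
        u = p / span
        # most recent normalized spike position <= u
        last = -1.0
        for q in range(k - 1, -1, -1):
            rho = (sel[q] - w0) / dur
            if rho <= u + 1e-12:
                last = rho
                break
        if last < 0.0:
            out[p] = 0.0
        else:
            out[p] = math.exp(-(u - last) * span / tau_grid)


@njit(cache=False)
def ec_1d_batch(times_flat, offsets, ev_ch, ev_idx, k, n_samples, tau_grid):
    """Build 1-D event contexts for every event; returns (ecs, built mask)."""
    n_ev = ev_ch.shape[0]
    ecs = np.zeros((n_ev, n_samples))
    built = np.zeros(n_ev, dtype=np.uint8)
    for i in range(n_ev):
        j = ev_idx[i]
        if j < k - 1:
            continue
        ch = ev_ch[i]
        start = offsets[ch] + j - (k - 1)
        sel = times_flat[start : offsets[ch] + j + 1]
        w0 = sel[0]
        dur = sel[k - 1] - w0
        _row_values(sel, w0, dur, n_samples, tau_grid, ecs[i])
        built[i] = 1
    return ecs, built


@njit(cache=False)
def _upper_bound(arr, lo, hi, x):
    """Index of first element > x in arr[lo:hi] (absolute index)."""
    while lo < hi:
        mid = (lo + hi) // 2
        if arr[mid] <= x:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=False)
def ec_2d_batch(times_flat, offsets, ev_t, ev_ch, ev_idx, n_channels, scale, k, n_samples, tau_grid):
    """Build 2-D (scale x n_samples) contexts; rows ordered by channel index.

    A context is built only when the anchor's own channel has k spikes of
    history; other rows with insufficient history are zero-filled.  All
    rows share one window [earliest selected spike, anchor].
    """
    n_ev = ev_ch.shape[0]
    half = scale // 2
    ecs = np.zeros((n_ev, scale, n_samples))
    built = np.zeros(n_ev, dtype=np.uint8)
    sel_starts = np.empty(scale, dtype=np.int64)
    sel_ok = np.empty(scale, dtype=np.uint8)
    for i in range(n_ev):
        if ev_idx[i] < k - 1:
            continue
        t_a = ev_t[i]
        ch = ev_ch[i]
        w0 = t_a
        for rrow in range(scale):
            rc = ch - half + rrow
            sel_ok[rrow] = 0
            if rc < 0 or rc >= n_channels:
                continue
            if rc == ch:
                idx = offsets[ch] + ev_idx[i] + 1  # anchor's own position
            else:
                idx = _upper_bound(times_flat, offsets[rc], offsets[rc + 1], t_a)
            if idx - offsets[rc] < k:
                continue
            sel_ok[rrow] = 1
            sel_starts[rrow] = idx - k
            if times_flat[idx - k] < w0:
                w0 = times_flat[idx - k]
        dur = t_a - w0
        for rrow in range(scale):
            if sel_ok[rrow] == 0:
                continue
            sel = times_flat[sel_starts[rrow] : sel_starts[rrow] + k]
            _row_values(sel, w0, dur, n_samples, tau_grid, ecs[i, rrow])
        built[i] = 1
    return ecs, built


@njit(cache=False)
def feast_train_epochs(ecs, ec_norms, weights, vth, order, delta_i, delta_e, eta):
    """Run FEAST learning over a pre-shuffled presentation order.

    order has shape (epochs, n_ecs).  weights/vth are mutated in place.
    Returns (per-epoch mean absolute weight change, final-epoch win counts).
    """
    n_epochs, n_ecs = order.shape
    m, d = weights.shape
    w_norms = np.empty(m)
    for i in range(m):
        s = 0.0
        for c in range(d):
            s += weights[i, c] * weights[i, c]
        w_norms[i] = math.sqrt(s)
    dw_means = np.zeros(n_epochs)
    win_counts = np.zeros(m, dtype=np.int64)
    for ep in range(n_epochs):
        dw_sum = 0.0
        n_wins = 0
        if ep == n_epochs - 1:
            for i in range(m):
                win_counts[i] = 0
        for step in range(n_ecs):
            idx = order[ep, step]
            best = -1
            best_sim = -2.0
            for i in range(m):
                dot = 0.0
                for c in range(d):
                    dot += weights[i, c] * ecs[idx, c]
                sim = dot / (w_norms[i] * ec_norms[idx])
                if sim >= vth[i] and sim > best_sim:
                    best_sim = sim
                    best = i
            if best >= 0:
                vth[best] += delta_i
                if vth[best] > 1.0:
                    vth[best] = 1.0
                s = 0.0
                for c in range(d):
                    w_new = (1.0 - eta) * weights[best, c] + eta * ecs[idx, c]
                    dw_sum += abs(w_new - weights[best, c])
                    weights[best, c] = w_new
                    s += w_new * w_new
                w_norms[best] = math.sqrt(s)
                n_wins += 1
                if ep == n_epochs - 1:
                    win_counts[best] += 1
            else:
                for i in range(m):
                    vth[i] -= delta_e
                    if vth[i] < 0.0:
                        vth[i] = 0.0
        dw_means[ep] = dw_sum / n_ecs
    return dw_means, win_counts
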