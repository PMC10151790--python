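import math

import numpy as np
import pytest

from earfeast.context import (
    ECParams,
    TimeSurfaceParams,
    build_ec_1d,
    build_ec_2d,
    ec_batch,
    row_profile,
    time_surface_value,
)
from earfeast.spikes import EventStream

from conftest import random_stream


def make_stream(times, channels, n_channels=8, fs=16000.0):
    order = np.argsort(times, kind="stable")
    t = np.asarray(times)[order]
    ch = np.asarray(channels)[order]
    return EventStream(t, ch, fs=fs, n_channels=n_channels,
                       duration=int(max(times)) + 1)


class TestTimeSurface:
    def test_at_event_is_one(self):
        assert time_surface_value(10.0, 10.0, 16.0) == 1.0

    def test_one_tau_lag(self):
        assert time_surface_value(26.0, 10.0, 16.0) == pytest.approx(
            math.exp(-1.0), abs=1e-15)

    def test_long_lag_decays_to_zero(self):
        assert time_surface_value(1e9, 0.0, 16.0) < 1e-300 or \
            time_surface_value(1e9, 0.0, 16.0) == 0.0

    def test_ordering_error(self):
        with pytest.raises(ValueError):
            time_surface_value(5.0, 6.0, 16.0)

    def test_default_tau_from_fs(self):
        p = TimeSurfaceParams(fs=16000.0)
        assert p.tau_v == pytest.approx(16.0)


class TestECParams:
    def test_defaults(self):
        p = ECParams()
        assert p.k == 4 and p.n_samples == 32
        assert tuple(p.scales) == (5, 13, 25, 37)
        assert p.tau_grid == pytest.approx(8.0)

    @pytest.mark.parametrize("kwargs", [
        {"k": 1}, {"n_samples": 2, "k": 4}, {"scales": (4,)},
        {"min_history_policy": "bogus"},
    ])
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            ECParams(**kwargs)


class TestEC1D:
    def test_first_events_skipped(self):
        s = make_stream([10, 20, 30, 40, 50], [2] * 5)
        batch = ec_batch(s, ECParams(), scale=1)
        # k=4: only events 4 and 5 have enough history
        assert batch.n_built == 2
        assert batch.n_skipped == 3
        assert build_ec_1d(0, s, ECParams()) is None

    def test_anchor_is_one_and_range(self, stream):
        batch = ec_batch(stream, ECParams(), scale=1)
        assert batch.n_built > 0
        assert np.all(batch.values >= 0.0)
        assert np.all(batch.values <= 1.0)
        assert np.allclose(batch.values[:, -1], 1.0)

    def test_interval_scale_invariance(self):
        # intervals (1,2,4) vs (2,4,8): identical resampled contexts
        s1 = make_stream([0, 1, 3, 7], [0] * 4)
        s2 = make_stream([0, 2, 6, 14], [0] * 4)
        ec1 = build_ec_1d(3, s1, ECParams())
        ec2 = build_ec_1d(3, s2, ECParams())
        assert np.allclose(ec1.values, ec2.values, atol=1e-12)

    def test_even_spacing_invariant_to_interval(self):
        p = ECParams()
        refs = []
        for step in (5, 50, 500):
            s = make_stream([0, step, 2 * step, 3 * step], [0] * 4)
            refs.append(build_ec_1d(3, s, p).values)
        assert np.allclose(refs[0], refs[1], atol=1e-12)
        assert np.allclose(refs[0], refs[2], atol=1e-12)

    def test_time_translation_invariance(self, rng):
        s = random_stream(rng, n_channels=4, rate=0.03, n_samples=1500)
        p = ECParams()
        b1 = ec_batch(s, p, scale=1)
        b2 = ec_batch(s.shifted(777), p, scale=1)
        assert np.array_equal(b1.anchor_index, b2.anchor_index)
        assert np.allclose(b1.values, b2.values, atol=1e-12)

    def test_matches_row_profile_oracle(self, rng):
        s = random_stream(rng, n_channels=4, rate=0.04, n_samples=800)
        p = ECParams()
        batch = ec_batch(s, p, scale=1)
        per_channel = s.channel_times()
        for row, idx in zip(batch.values[:20], batch.anchor_index[:20]):
            ch = int(s.channel[idx])
            ref = row_profile(per_channel[ch], float(s.t[idx]), p.k,
                              p.n_samples, p.tau_grid)
            assert np.allclose(row, ref, atol=1e-12)

    def test_monotone_profile_order_preserved(self):
        # decaying values at spike grid positions keep their order
        s = make_stream([0, 30, 50, 60], [0] * 4)
        p = ECParams(k=4, n_samples=32)
        vals = build_ec_1d(3, s, p).values
        # immediately before each later spike the surface has decayed less
        # (shorter preceding gap) -> larger minimum between spikes
        assert vals[-1] == 1.0
        assert np.all(vals > 0.0)


class TestEC2D:
    def test_boundary_rows_zero(self):
        s = make_stream([10, 20, 30, 40], [0] * 4)
        ec = build_ec_2d(3, s, 5, ECParams())
        assert ec.values.shape == (5, 32)
        assert np.all(ec.values[0] == 0.0)  # channels -2, -1 missing
        assert np.all(ec.values[1] == 0.0)
        assert np.allclose(ec.values[2, -1], 1.0)

    def test_single_channel_only_center_row(self):
        s = make_stream([10, 20, 30, 40, 55], [3] * 5)
        ec = build_ec_2d(4, s, 5, ECParams())
        assert np.all(ec.values[[0, 1, 3, 4]] == 0.0)
        assert ec.values[2].max() == 1.0

    def test_center_row_equals_1d_for_single_channel(self):
        s = make_stream([10, 25, 33, 40, 70], [3] * 5)
        p = ECParams()
        for scale in (5, 13):
            ec2 = build_ec_2d(4, s, scale, p)
            ec1 = build_ec_1d(4, s, p)
            assert np.allclose(ec2.values[scale // 2], ec1.values, atol=1e-12)

    def test_rows_match_shared_window_oracle(self, rng):
        s = random_stream(rng, n_channels=8, rate=0.05, n_samples=600)
        p = ECParams()
        scale = 5
        batch = ec_batch(s, p, scale=scale)
        per_channel = s.channel_times()
        for flat, idx in zip(batch.values[:10], batch.anchor_index[:10]):
            values = flat.reshape(scale, p.n_samples)
            ch = int(s.channel[idx])
            t_a = float(s.t[idx])
            # recompute the shared window: earliest selected spike over rows
            w0 = t_a
            for r in range(scale):
                rc = ch - scale // 2 + r
                if not 0 <= rc < s.n_channels:
                    continue
                past = per_channel[rc][per_channel[rc] <= t_a]
                if past.size >= p.k:
                    w0 = min(w0, np.sort(past)[-p.k])
            for r in range(scale):
                rc = ch - scale // 2 + r
                if not 0 <= rc < s.n_channels:
                    ref = np.zeros(p.n_samples)
                else:
                    ref = row_profile(per_channel[rc], t_a, p.k, p.n_samples,
                                      p.tau_grid, window_start=w0)
                assert np.allclose(values[r], ref, atol=1e-12)

    def test_translation_invariance_2d(self, rng):
        s = random_stream(rng, n_channels=6, rate=0.04, n_samples=800)
        p = ECParams()
        b1 = ec_batch(s, p, scale=5)
        b2 = ec_batch(s.shifted(313), p, scale=5)
        assert np.allclose(b1.values, b2.values, atol=1e-12)

    def test_even_scale_rejected(self, stream):
        with pytest.raises(ValueError):
            ec_batch(stream, ECParams(), scale=4)


class TestBatch:
    def test_exactly_k_events_one_context(self):
        s = make_stream([5, 9, 14, 30], [1] * 4)
        batch = ec_batch(s, ECParams(k=4), scale=1)
        assert batch.n_built == 1
        assert batch.anchor_index[0] == 3

    def test_empty_stream(self):
        s = EventStream([], [], fs=16000, n_channels=4, duration=0)
        batch = ec_batch(s, ECParams(), scale=1)
        assert batch.n_built == 0 and batch.n_skipped == 0

    def test_batch_equals_per_event_loop(self, rng):
        s = random_stream(rng, n_channels=4, rate=0.05, n_samples=400)
        p = ECParams()
        batch = ec_batch(s, p, scale=1)
        built = {int(i): v for i, v in zip(batch.anchor_index, batch.values)}
        for i in range(len(s)):
            ec = build_ec_1d(i, s, p)
            if ec is None:
                assert i not in built
            else:
                assert np.allclose(ec.values, built[i], atol=1e-12)

    def test_counts_add_up(self, stream):
        p = ECParams()
        batch = ec_batch(stream, p, scale=1)
        assert batch.n_built + batch.n_skipped == len(stream)

    def test_csv_export(self, tmp_path, stream):
        batch = ec_batch(stream, ECParams(), scale=1)
        batch.to_csv(tmp_path / "ecs.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "ecs.csv")
        assert len(df) == batch.n_built
        assert df["scale"].iloc[0] == 1
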