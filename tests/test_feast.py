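import numpy as np
import pytest

from earfeast.context import ECParams, ec_batch
from earfeast.feast import (
    FeastParams,
    FeatureMap,
    NeuronBank,
    extract,
    extract_from_batch,
    learn_step,
    similarity,
    train,
)


def naive_cosine(a, b):
    num = sum(x * y for x, y in zip(a, b))
    na = sum(x * x for x in a) ** 0.5
    nb = sum(y * y for y in b) ** 0.5
    return num / (na * nb)


def naive_learn_decision(weights, vth, ec):
    """Literal application of the two threshold rules; returns winner or None."""
    sims = [naive_cosine(w, ec) for w in weights]
    best, best_sim = None, -2.0
    for i, s in enumerate(sims):
        if s >= vth[i] and s > best_sim:
            best, best_sim = i, s
    return best


def random_bank(rng, m=6, dim=16, params=None):
    p = params or FeastParams(m=m, seed=int(rng.integers(1 << 30)))
    w = rng.random((m, dim)) + 0.01
    vth = rng.random(m)
    return NeuronBank(w, vth, 1, p, trained=True)


class TestSimilarity:
    def test_colinear_is_one(self, rng):
        v = rng.random(12) + 0.1
        assert similarity(v, 3.7 * v) == pytest.approx(1.0)

    def test_orthogonal_supports_zero(self):
        a = np.array([1.0, 1.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 2.0, 1.0])
        assert similarity(a, b) == 0.0

    def test_matches_naive_loop(self, rng):
        for _ in range(50):
            a, b = rng.random(20) + 1e-6, rng.random(20) + 1e-6
            assert similarity(a, b) == pytest.approx(naive_cosine(a, b), abs=1e-12)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            similarity(np.zeros(4), np.ones(4))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            similarity(np.ones(4), np.ones(5))


class TestLearnStep:
    def test_no_winner_all_thresholds_drop(self, rng):
        bank = random_bank(rng)
        bank.vth[:] = 1.0
        ec = rng.random(16) + 0.5  # generic: cosine < 1 against all neurons
        before = bank.vth.copy()
        w_before = bank.weights.copy()
        assert learn_step(ec, bank) is None
        assert np.allclose(bank.vth, before - bank.params.delta_e)
        assert np.array_equal(bank.weights, w_before)

    def test_exact_match_is_fixed_point(self, rng):
        bank = random_bank(rng)
        j = 2
        bank.vth[j] = 0.5
        ec = bank.weights[j].copy()
        w_before = bank.weights[j].copy()
        vth_before = bank.vth[j]
        assert learn_step(ec, bank) == j
        assert np.allclose(bank.weights[j], w_before, atol=1e-15)
        assert bank.vth[j] == pytest.approx(
            min(1.0, vth_before + bank.params.delta_i))

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(300):
            bank = random_bank(rng, m=5, dim=8)
            ec = rng.random(8) + 1e-3
            expected = naive_learn_decision(bank.weights.copy(),
                                            bank.vth.copy(), ec)
            got = learn_step(ec, bank)
            assert got == expected

    def test_threshold_clamped_at_one(self, rng):
        bank = random_bank(rng)
        j = 0
        bank.vth[:] = 0.0
        bank.vth[j] = 0.9999
        ec = bank.weights[j].copy()
        learn_step(ec, bank)
        assert bank.vth[j] == 1.0

    def test_threshold_clamped_at_zero(self, rng):
        bank = random_bank(rng)
        bank.vth[:] = 1.0
        ec = rng.random(16) + 0.5
        for _ in range(500):
            learn_step(ec, bank)
        assert np.all(bank.vth >= 0.0)
        assert np.all(bank.vth <= 1.0)


def well_separated_prototypes(m, dim, rng):
    """Nonnegative prototypes with disjoint dominant supports."""
    protos = np.full((m, dim), 0.02)
    block = dim // m
    for i in range(m):
        protos[i, i * block:(i + 1) * block] = 1.0
    return protos


class TestTrain:
    def test_zero_epochs_is_initialization(self, rng):
        ecs = rng.random((50, 12)) + 0.01
        p = FeastParams(m=4, epochs=0, seed=9)
        bank = train(ecs, p)
        ref = NeuronBank.initialize(12, 1, p)
        assert np.array_equal(bank.weights, ref.weights)
        assert np.array_equal(bank.vth, ref.vth)

    def test_identical_ecs_converge_to_direction(self, rng):
        ec = rng.random(16) + 0.1
        ecs = np.tile(ec, (600, 1))
        bank = train(ecs, FeastParams(m=2, epochs=20, seed=3))
        best = max(similarity(ec, bank.weights[i]) for i in range(2))
        assert best > 0.999

    def test_prototype_recovery(self, rng):
        from scipy.optimize import linear_sum_assignment

        m, dim = 8, 32
        protos = well_separated_prototypes(m, dim, rng)
        reps = np.repeat(protos, 150, axis=0)
        jitter = 1.0 + 0.05 * rng.standard_normal(reps.shape)
        ecs = np.clip(reps * jitter, 0.0, None) + 1e-6
        bank = train(ecs, FeastParams(m=m, epochs=10, seed=11))
        cos = np.zeros((m, m))
        for i in range(m):
            for j in range(m):
                cos[i, j] = similarity(protos[i], bank.weights[j])
        row, col = linear_sum_assignment(-cos)
        assert len(set(col)) == m  # perfect one-to-one matching
        assert np.all(cos[row, col] > 0.95)
        wins = bank.win_counts
        assert wins.min() > 0
        assert wins.max() / wins.min() < 3.0

    def test_thresholds_and_hull_invariants(self, rng):
        ecs = rng.random((400, 10)) * 2.0 + 0.05
        p = FeastParams(m=6, epochs=5, seed=21)
        init = NeuronBank.initialize(10, 1, p)
        bank = train(ecs, p)
        assert np.all(bank.vth >= 0.0) and np.all(bank.vth <= 1.0)
        lo = np.minimum(init.weights.min(axis=0), ecs.min(axis=0))
        hi = np.maximum(init.weights.max(axis=0), ecs.max(axis=0))
        assert np.all(bank.weights >= lo - 1e-12)
        assert np.all(bank.weights <= hi + 1e-12)

    def test_dw_non_increasing_after_first_epoch(self, rng):
        ecs = rng.random((500, 12)) + 0.01
        bank = train(ecs, FeastParams(m=6, epochs=8, seed=5))
        dw = np.array(bank.dw_log)
        assert np.all(dw[2:] <= dw[1:-1] * 1.05)

    def test_determinism(self, rng):
        ecs = rng.random((200, 12)) + 0.01
        b1 = train(ecs, FeastParams(m=4, epochs=5, seed=42))
        b2 = train(ecs, FeastParams(m=4, epochs=5, seed=42))
        assert np.array_equal(b1.weights, b2.weights)
        assert np.array_equal(b1.vth, b2.vth)

    def test_kernel_matches_python_learn_step(self, rng):
        """Dual route: the batched training kernel vs the scalar API."""
        ecs = rng.random((60, 8)) + 0.01
        p = FeastParams(m=3, epochs=2, seed=17)
        bank = train(ecs, p)
        ref = NeuronBank.initialize(8, 1, p)
        order_rng = np.random.default_rng(p.seed + 1)
        for ep in range(p.epochs):
            for idx in order_rng.permutation(60):
                learn_step(ecs[idx], ref, p)
        assert np.allclose(bank.weights, ref.weights, atol=1e-12)
        assert np.allclose(bank.vth, ref.vth, atol=1e-12)

    def test_small_batch_warns(self, rng):
        ecs = rng.random((3, 6)) + 0.01
        with pytest.warns(UserWarning):
            train(ecs, FeastParams(m=8, epochs=1, seed=0))

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            train(np.zeros((0, 5)), FeastParams(m=2))

    def test_save_load_round_trip(self, tmp_path, rng):
        ecs = rng.random((100, 12)) + 0.01
        bank = train(ecs, FeastParams(m=4, epochs=3, seed=8))
        bank.save(tmp_path / "b")
        back = NeuronBank.load(tmp_path / "b")
        assert np.allclose(back.weights, bank.weights, atol=1e-16)
        assert np.allclose(back.vth, bank.vth)
        assert back.scale == bank.scale and back.trained


class TestExtract:
    def test_all_match_single_neuron(self, rng, stream):
        p = ECParams()
        batch = ec_batch(stream, p, scale=1)
        bank = random_bank(rng, m=5, dim=32)
        bank.weights[3] = batch.values[0] + 1e-9
        fmap = extract_from_batch(batch, bank)
        assert fmap.winner[0] == 3

    def test_one_feature_spike_per_bank_per_event(self, rng, stream):
        p = ECParams(scales=(5, 13))
        banks = []
        for scale in (1, 5, 13):
            batch = ec_batch(stream, p, scale=scale)
            banks.append(train(batch, FeastParams(m=4, epochs=1, seed=scale)))
        maps = extract(stream, banks, p)
        assert len(maps) == 3
        for fmap, scale in zip(maps, (1, 5, 13)):
            batch = ec_batch(stream, p, scale=scale)
            assert len(fmap) == batch.n_built

    def test_winners_match_brute_force(self, rng, stream):
        batch = ec_batch(stream, ECParams(), scale=1)
        bank = random_bank(rng, m=6, dim=32)
        fmap = extract_from_batch(batch, bank)
        for i in range(min(40, batch.n_built)):
            sims = [naive_cosine(bank.weights[j], batch.values[i])
                    for j in range(bank.m)]
            assert fmap.winner[i] == int(np.argmax(sims))

    def test_untrained_bank_rejected(self, rng, stream):
        batch = ec_batch(stream, ECParams(), scale=1)
        p = FeastParams(m=3)
        bank = NeuronBank.initialize(32, 1, p)
        with pytest.raises(ValueError):
            extract_from_batch(batch, bank)

    def test_feature_map_csv_round_trip(self, tmp_path, rng, stream):
        batch = ec_batch(stream, ECParams(), scale=1)
        bank = random_bank(rng, m=4, dim=32)
        fmap = extract_from_batch(batch, bank)
        fmap.to_csv(tmp_path / "fm.csv")
        back = FeatureMap.from_csv(tmp_path / "fm.csv")
        assert back == fmap
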