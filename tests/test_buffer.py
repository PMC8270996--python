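import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clops.buffer import ReplayBuffer, acquire, bald_mcd, random_acquire
from clops.signal_data import LabeledSegment, TaskDataset

from conftest import random_posterior


def make_task(task_id, n_train, n_classes=2, L=16):
    rng = np.random.default_rng(task_id)
    segs = [
        LabeledSegment(rng.standard_normal(L), i % n_classes, task_id,
                       f"t{task_id}-i{i:03d}", "train")
        for i in range(n_train)
    ]
    # one test segment so the dataset is realistic but storage ignores it
    segs.append(LabeledSegment(rng.standard_normal(L), 0, task_id,
                               f"t{task_id}-test", "test"))
    return TaskDataset(task_id, segs)


def brute_entropy(p):
    return -sum(pi * math.log(pi) for pi in p if pi > 0)


class TestBald:
    def test_identical_slices_give_zero(self):
        G = np.tile([0.2, 0.5, 0.3], (4, 10, 1))
        np.testing.assert_allclose(bald_mcd(G), 0.0, atol=1e-9)

    def test_two_opposite_point_masses_give_ln2(self):
        G = np.array([[[1.0, 0.0], [0.0, 1.0]]])
        assert bald_mcd(G)[0] == pytest.approx(math.log(2), abs=1e-12)

    def test_matches_brute_force_entropies(self, rng):
        G = random_posterior(rng, 5, 20, 4)
        expect = []
        for m in range(5):
            p_bar = G[m].mean(axis=0)
            expect.append(
                brute_entropy(p_bar)
                - np.mean([brute_entropy(G[m, t]) for t in range(20)])
            )
        np.testing.assert_allclose(bald_mcd(G), expect, atol=1e-10)

    def test_non_simplex_rejected(self):
        with pytest.raises(ValueError):
            bald_mcd(np.full((1, 2, 2), 0.9))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_nonnegative_and_bounded_by_mean_entropy(self, seed):
        G = random_posterior(np.random.default_rng(seed), 3, 8, 5)
        scores = bald_mcd(G)
        assert np.all(scores >= -1e-12)
        # duplicating a slice never pushes the score above H(p̄)
        G2 = np.concatenate([G, G[:, :1, :]], axis=1)
        h_mean = -np.sum(
            np.where(G2.mean(1) > 0, G2.mean(1) * np.log(G2.mean(1)), 0), axis=1
        )
        assert np.all(bald_mcd(G2) <= h_mean + 1e-12)


class TestStorage:
    def test_default_fraction_quarter_of_eight_stores_two(self):
        buf = ReplayBuffer(b=0.25)
        task = make_task(0, 8)
        scores = {f"t0-i{i:03d}": float(i) for i in range(8)}
        buf.store_task(task, scores)
        assert len(buf.slots[0]) == 2
        assert buf.slot_ids(0) == ["t0-i006", "t0-i007"]

    def test_ties_break_lexicographically(self):
        buf = ReplayBuffer(b=0.25)
        task = make_task(0, 8)
        buf.store_task(task, {f"t0-i{i:03d}": 1.0 for i in range(8)})
        assert buf.slot_ids(0) == ["t0-i000", "t0-i001"]

    @pytest.mark.parametrize("b,n", [(0.25, 50), (0.1, 50), (0.5, 7), (1.0, 5)])
    def test_matches_sort_oracle(self, b, n, rng):
        buf = ReplayBuffer(b=b)
        task = make_task(1, n)
        scores = {f"t1-i{i:03d}": float(v) for i, v in
                  enumerate(rng.standard_normal(n))}
        buf.store_task(task, scores)
        expect = sorted(scores, key=lambda i: (-scores[i], i))[: math.ceil(b * n)]
        assert buf.slot_ids(1) == sorted(expect)

    def test_missing_score_rejected(self):
        buf = ReplayBuffer(b=0.5)
        with pytest.raises(KeyError):
            buf.store_task(make_task(0, 4), {"t0-i000": 1.0})

    def test_slots_never_evict_other_tasks(self):
        buf = ReplayBuffer(b=0.5)
        for k in (0, 1, 2):
            task = make_task(k, 6)
            buf.store_task(task, {f"t{k}-i{i:03d}": float(i) for i in range(6)})
        assert buf.total_size() == 9
        assert buf.task_ids() == [0, 1, 2]

    def test_loss_area_storage_keeps_smallest_areas(self):
        buf = ReplayBuffer(b=0.25)
        task = make_task(2, 8)
        areas = {f"t2-i{i:03d}": float(i) for i in range(8)}
        buf.store_task_loss_area(task, areas)
        assert buf.slot_ids(2) == ["t2-i000", "t2-i001"]


class TestAcquisition:
    def _buffer_with_slots(self, slot_size=4, n_tasks=2):
        buf = ReplayBuffer(b=1.0)
        for k in range(n_tasks):
            task = make_task(k, slot_size)
            buf.store_task(task, {f"t{k}-i{i:03d}": 0.0 for i in range(slot_size)})
        return buf

    def test_default_fraction_half_of_four_acquires_two_per_task(self):
        buf = self._buffer_with_slots()
        bald = {iid: float(i) for k in buf.task_ids()
                for i, iid in enumerate(buf.slot_ids(k))}
        pool = acquire(buf, bald, a=0.5)
        assert all(len(v) == 2 for v in pool.values())

    def test_full_fraction_returns_entire_buffer(self):
        buf = self._buffer_with_slots()
        bald = {iid: 0.0 for k in buf.task_ids() for iid in buf.slot_ids(k)}
        pool = acquire(buf, bald, a=1.0)
        for k in buf.task_ids():
            assert sorted(pool[k]) == buf.slot_ids(k)

    def test_matches_per_task_sort_oracle(self, rng):
        buf = self._buffer_with_slots(slot_size=9, n_tasks=3)
        bald = {iid: float(rng.standard_normal())
                for k in buf.task_ids() for iid in buf.slot_ids(k)}
        pool = acquire(buf, bald, a=0.4)
        for k in buf.task_ids():
            expect = sorted(buf.slot_ids(k),
                            key=lambda i: (-bald[i], i))[: math.ceil(0.4 * 9)]
            assert pool[k] == expect

    def test_empty_buffer_gives_empty_pool(self):
        assert acquire(ReplayBuffer(b=0.5), {}, a=0.5) == {}


class TestRandomVariants:
    def test_cardinalities_match_guided_versions(self, rng):
        for b, a, n in [(0.25, 0.5, 8), (0.1, 0.3, 17), (0.6, 1.0, 5)]:
            buf = ReplayBuffer(b=b)
            buf.store_task_random(make_task(0, n), np.random.default_rng(0))
            assert len(buf.slots[0]) == math.ceil(b * n)
            pool = random_acquire(buf, a, np.random.default_rng(1))
            assert len(pool[0]) == math.ceil(a * len(buf.slots[0]))

    def test_fixed_seed_reproducible(self):
        sels = [
            ReplayBuffer(b=0.3) for _ in range(2)
        ]
        for buf in sels:
            buf.store_task_random(make_task(0, 10), np.random.default_rng(42))
        assert sels[0].slot_ids(0) == sels[1].slot_ids(0)

    def test_uniform_selection_frequency(self):
        # N=10, b=0.2 → 2 kept per draw; over 1000 seeds each instance should
        # appear ≈ 20% of the time (±3 binomial sd)
        task = make_task(0, 10)
        counts = {f"t0-i{i:03d}": 0 for i in range(10)}
        n_rep = 1000
        for seed in range(n_rep):
            buf = ReplayBuffer(b=0.2)
            buf.store_task_random(task, np.random.default_rng(seed))
            for iid in buf.slot_ids(0):
                counts[iid] += 1
        p = 0.2
        sd = math.sqrt(n_rep * p * (1 - p))
        for iid, c in counts.items():
            assert abs(c - n_rep * p) <= 3 * sd
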