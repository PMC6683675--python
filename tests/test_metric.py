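import itertools

import numpy as np
import pytest

import spikelick as sl
from spikelick.metric import (
    DEFAULT_Q_GRID,
    distance_matrices,
    exchange_responses,
    vp_distance_multi_q,
)
from spikelick.types import ResponseSet


def brute_force_vp(a, b, q):
    """Independent oracle: exhaustive minimum over monotone matchings."""
    best = len(a) + len(b)
    for k in range(1, min(len(a), len(b)) + 1):
        for ia in itertools.combinations(range(len(a)), k):
            for ib in itertools.combinations(range(len(b)), k):
                cost = sum(q * abs(a[x] - b[y]) for x, y in zip(ia, ib))
                cost += (len(a) - k) + (len(b) - k)
                best = min(best, cost)
    return best


def random_train(rng, max_len=5, span=1.0):
    return np.sort(rng.uniform(0, span, rng.integers(0, max_len + 1)))


class TestDistances:
    def test_count_distance_basics(self):
        assert sl.count_distance([], []) == 0
        assert sl.count_distance([1, 2, 3], [1, 2, 3, 4, 5]) == 2

    def test_two_deletions(self):
        for q in (0.0, 1.0, 100.0):
            assert sl.vp_distance([0.1, 0.2], [], q) == 2.0

    def test_shift_beats_delete_insert(self):
        # 10 * 0.01 = 0.1 < 2
        assert sl.vp_distance([0.100], [0.110], 10.0) == pytest.approx(0.1)

    def test_negative_q_rejected(self):
        with pytest.raises(ValueError):
            sl.vp_distance([0.1], [0.2], -1.0)

    def test_q_zero_equals_count_distance(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            a, b = random_train(rng, 8), random_train(rng, 8)
            assert sl.vp_distance(a, b, 0.0) == sl.count_distance(a, b)

    def test_matches_brute_force(self):
        # oracle equivalence on 500 random instances
        rng = np.random.default_rng(1)
        for _ in range(500):
            a, b = random_train(rng), random_train(rng)
            for q in (0.0, 1.0, 10.0, 100.0):
                assert sl.vp_distance(a, b, q) == pytest.approx(
                    brute_force_vp(list(a), list(b), q), abs=1e-9
                )

    def test_metric_axioms(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            a, b, c = (random_train(rng, 6) for _ in range(3))
            q = float(rng.choice([0.5, 1.0, 10.0, 100.0]))
            dab = sl.vp_distance(a, b, q)
            dba = sl.vp_distance(b, a, q)
            assert dab == pytest.approx(dba, abs=1e-9)
            assert sl.vp_distance(a, a, q) == 0.0
            dac = sl.vp_distance(a, c, q)
            dcb = sl.vp_distance(c, b, q)
            assert dab <= dac + dcb + 1e-9

    def test_monotone_in_q_and_bounded(self):
        rng = np.random.default_rng(3)
        qs = np.array([0.0, 1.0, 4.0, 16.0, 64.0, 256.0])
        for _ in range(200):
            a, b = random_train(rng, 6), random_train(rng, 6)
            d = vp_distance_multi_q(a, b, qs)
            assert np.all(np.diff(d) >= -1e-9)
            assert np.all(d <= len(a) + len(b) + 1e-9)

    def test_batch_matches_single_pair(self):
        rng = np.random.default_rng(4)
        resp = [random_train(rng, 40, span=2.0) for _ in range(10)]
        qs = np.asarray(DEFAULT_Q_GRID)
        D = distance_matrices(resp, qs)
        for i in range(10):
            for j in range(i + 1, 10):
                ref = vp_distance_multi_q(resp[i], resp[j], qs)
                assert np.allclose(D[:, i, j], ref)
        assert np.allclose(D, np.transpose(D, (0, 2, 1)))


def count_separable_set(n_per=10, window=2.0, seed=0, counts=(0, 10, 20, 30)):
    rng = np.random.default_rng(seed)
    resp, labs = [], []
    for k, c in enumerate(counts):
        for _ in range(n_per):
            resp.append(np.sort(rng.uniform(0, window, c)))
            labs.append(f"S{k}")
    return ResponseSet(resp, labs, window)


def timing_only_set(n_per=10, seed=0):
    rng = np.random.default_rng(seed)
    resp, labs = [], []
    for lab, off in (("A", 0.0), ("B", 0.05)):
        for _ in range(n_per):
            resp.append(np.sort(
                np.array([0.1, 0.3, 0.5]) + off + rng.normal(0, 0.002, 3)
            ))
            labs.append(lab)
    return ResponseSet(resp, labs, 2.0)


class TestClassifierAndInformation:
    def test_perfectly_separable_diagonal(self):
        rs = count_separable_set()
        conf, ties = sl.classify_confusion(rs, 0.0)
        assert ties == 0
        assert np.allclose(conf, np.diag([10, 10, 10, 10]))
        assert sl.mutual_information(conf) == pytest.approx(2.0)

    def test_all_identical_uniform_rows(self):
        resp = [np.array([0.5, 1.0])] * 8
        rs = ResponseSet(resp, ["A"] * 4 + ["B"] * 4, 2.0)
        conf, ties = sl.classify_confusion(rs, 0.0)
        assert ties == 8
        assert np.allclose(conf, np.full((2, 2), 2.0))
        assert sl.mutual_information(conf) == pytest.approx(0.0)

    def test_timing_only_discrimination(self):
        rs = timing_only_set()
        c_fast, _ = sl.classify_confusion(rs, 40.0)
        c_zero, _ = sl.classify_confusion(rs, 0.0)
        assert sl.mutual_information(c_fast) == pytest.approx(1.0)
        assert sl.mutual_information(c_zero) <= 0.2

    def test_single_response_per_label_rejected(self):
        rs = ResponseSet([np.array([0.1]), np.array([0.2])], ["A", "B"], 1.0)
        with pytest.raises(ValueError):
            sl.classify_confusion(rs, 0.0)

    def test_mutual_information_formula(self):
        assert sl.mutual_information(np.diag([10, 10, 10, 10])) == pytest.approx(2.0)
        assert sl.mutual_information(np.full((4, 4), 2.5)) == pytest.approx(0.0)
        expected = 1 + 0.9 * np.log2(0.9) + 0.1 * np.log2(0.1)
        assert sl.mutual_information(np.array([[9, 1], [1, 9]])) == pytest.approx(
            expected, abs=1e-12
        )

    def test_info_vs_q_count_separable(self):
        info = sl.info_vs_q(count_separable_set())
        assert info.q_at_max == 0.0
        assert info.H_max == info.H_count == pytest.approx(2.0)

    def test_info_vs_q_timing_only(self):
        info = sl.info_vs_q(timing_only_set())
        assert info.H_max > info.H_count

    def test_single_label_no_information(self):
        rng = np.random.default_rng(5)
        rs = ResponseSet(
            [np.sort(rng.uniform(0, 1, 5)) for _ in range(6)], ["A"] * 6, 1.0
        )
        info = sl.info_vs_q(rs)
        assert np.allclose(info.H_of_q, 0.0)

    def test_information_bounded(self):
        rng = np.random.default_rng(6)
        rs = ResponseSet(
            [np.sort(rng.uniform(0, 1, rng.integers(0, 8))) for _ in range(16)],
            [l for l in "ABCD" for _ in range(4)],
            1.0,
        )
        info = sl.info_vs_q(rs)
        assert np.all(info.H_of_q >= -1e-12)
        assert np.all(info.H_of_q <= 2.0 + 1e-12)


class TestControls:
    def test_shuffle_on_separable_set(self):
        rs = count_separable_set()
        mean, sd = sl.shuffle_control(rs, n=40, rng=0)
        info = sl.info_vs_q(rs)
        iq = 0  # q = 0 is where the structure lives
        assert mean[iq] < 1.0
        assert info.H_max > mean[iq] + 2 * sd[iq]

    def test_shuffle_reproduces_small_sample_bias(self):
        # exhaustive oracle: average MI over all distinct label assignments
        rng = np.random.default_rng(7)
        resp = [np.sort(rng.uniform(0, 1, rng.integers(2, 6))) for _ in range(6)]
        labels = ["A", "A", "A", "B", "B", "B"]
        rs = ResponseSet(resp, labels, 1.0)

        D = distance_matrices(resp, [0.0])[0]
        from spikelick.metric import _confusion_from_distances

        his = []
        for perm in set(itertools.permutations(labels)):
            idx = np.array([0 if l == "A" else 1 for l in perm])
            conf, _ = _confusion_from_distances(D, idx, 2)
            his.append(sl.mutual_information(conf))
        exact = float(np.mean(his))
        assert exact > 0  # plug-in MI bias is positive

        mean, _ = sl.shuffle_control(rs, q_grid=[0.0], n=2000, rng=1)
        assert mean[0] == pytest.approx(exact, abs=0.05)

    def test_shuffle_zero_reps_rejected(self):
        with pytest.raises(ValueError):
            sl.shuffle_control(count_separable_set(), n=0, rng=0)

    def test_exchange_conserves_counts_and_psth(self):
        rng = np.random.default_rng(8)
        for trial in range(20):
            resp = [np.sort(rng.uniform(0, 2, rng.integers(0, 30)))
                    for _ in range(12)]
            labs = [l for l in "ABC" for _ in range(4)]
            rs = ResponseSet(resp, labs, 2.0)
            ex = exchange_responses(rs, np.random.default_rng(trial))
            edges = np.arange(0, 2.0 + 0.02, 0.02)
            for lab in "ABC":
                idx = [i for i, l in enumerate(labs) if l == lab]
                before = np.histogram(
                    np.concatenate([rs.responses[i] for i in idx]), edges
                )[0]
                after = np.histogram(
                    np.concatenate([ex.responses[i] for i in idx]), edges
                )[0]
                assert np.array_equal(before, after)
            for i in range(12):
                assert len(ex.responses[i]) == len(rs.responses[i])

    def test_exchange_destroys_timing_information(self):
        rs = timing_only_set()
        info = sl.info_vs_q(rs)
        mean, _ = sl.exchange_control(rs, n=10, rng=2)
        # timing info is destroyed at high q once spikes are redealt
        iq = int(np.argmax(info.H_of_q))
        assert mean[iq] < info.H_max

    def test_exchange_zero_reps_rejected(self):
        with pytest.raises(ValueError):
            sl.exchange_control(count_separable_set(), n=0, rng=0)


class TestFullAnalysis:
    def test_separable_full_msa(self):
        info = sl.run_msa(count_separable_set(), rng=0)
        assert info.H_max == pytest.approx(2.0)
        assert info.significant
        assert info.coding_class == "rate_count"

    def test_timing_set_coding_class(self):
        info = sl.run_msa(timing_only_set(), rng=1)
        assert info.significant
        assert info.coding_class == "spike_timing"

    def test_null_set_not_significant(self):
        rng = np.random.default_rng(9)
        hits = 0
        for seed in range(20):
            resp = [np.sort(rng.uniform(0, 2, rng.poisson(20))) for _ in range(24)]
            labs = [l for l in "ABCD" for _ in range(6)]
            info = sl.run_msa(ResponseSet(resp, labs, 2.0), rng=seed)
            hits += info.coding_class != "not_significant"
        assert hits <= 4  # frozen misclassification bound

    def test_rate_envelope_class(self):
        # labels differ only in their pooled rate envelope; the exchange
        # control preserves that envelope, so H_exchange stays high
        rng = np.random.default_rng(10)
        resp, labs = [], []
        for lab, (lo, hi) in (("A", (0.0, 0.5)), ("B", (1.0, 1.5))):
            for _ in range(10):
                resp.append(np.sort(rng.uniform(lo, hi, 8)))
                labs.append(lab)
        info = sl.run_msa(ResponseSet(resp, labs, 2.0), rng=3)
        assert info.significant
        assert info.coding_class in ("rate_envelope", "spike_timing")
        # the envelope must carry most of the information
        assert info.H_exchange_mean > 0.5

    def test_window_sweep_summary(self):
        sets = [count_separable_set(seed=s) for s in range(3)]
        table = sl.window_sweep(sets, windows=(0.5, 2.0, 0.7), n_shuffle=20,
                                n_exchange=0, rng=0)
        assert len(table) == 3
        canon = table.set_index("window_s")["canonical"]
        assert bool(canon[0.5]) and bool(canon[2.0]) and not bool(canon[0.7])
        row = table[table["window_s"] == 2.0].iloc[0]
        assert row["prop_significant"] == 1.0
        assert row["mean_H_max"] == pytest.approx(2.0)

    def test_q_grid_must_include_zero(self):
        with pytest.raises(ValueError):
            sl.info_vs_q(count_separable_set(), q_grid=[1.0, 2.0])
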