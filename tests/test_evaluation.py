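"""Bottom-line Q functions and the array-removal harness, checked against
brute-force oracles."""

import numpy as np
import pytest

import arrayqc as aq
from arrayqc.core_data import ValidationError
from arrayqc.evaluation import roc_curve_from_ranking

from conftest import BASE


def _expr(theta, ids=None):
    theta = np.asarray(theta, dtype=float)
    G, A = theta.shape
    return aq.ExpressionSet(
        theta_hat=theta, se=np.ones_like(theta),
        probeset_ids=[f"g{i:03d}" for i in range(G)],
        array_ids=ids or [f"a{j}" for j in range(A)])


def _bh_oracle(p):
    """Exhaustive BH: q_(k) = min_{i>=k} p_(i) * n / i, clipped at 1."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(n)
    running = np.inf
    for rank in range(n - 1, -1, -1):
        running = min(running, p[order[rank]] * n / (rank + 1))
        q_sorted[rank] = min(running, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


class TestTtestFdr:
    def _groups(self, n1, n2):
        ids = [f"a{j}" for j in range(n1 + n2)]
        return ids, {a: ("A" if j < n1 else "B") for j, a in enumerate(ids)}

    def test_identical_groups_t_zero_q_one(self):
        ids, groups = self._groups(3, 3)
        theta = np.tile(np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]]), (5, 1))
        t, p, q = aq.ttest_fdr(_expr(theta, ids), groups)
        assert np.all(t == 0) and np.all(q == 1)

    def test_degenerate_zero_variance_rules(self):
        ids, groups = self._groups(2, 2)
        theta = np.array([[1.0, 1.0, 2.0, 2.0],    # means differ, no variance
                          [3.0, 3.0, 3.0, 3.0]])   # identical
        t, p, q = aq.ttest_fdr(_expr(theta, ids), groups)
        assert p[0] == 0.0 and np.isinf(t[0])
        assert p[1] == 1.0 and t[1] == 0.0

    def test_bh_spec_example(self):
        ids, groups = self._groups(2, 2)
        _ = groups
        q = _bh_oracle([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_bh_matches_exhaustive_oracle_on_random_lists(self):
        rng = np.random.default_rng(0)
        ids, groups = self._groups(3, 3)
        for _ in range(20):
            n = rng.integers(2, 21)
            theta = rng.normal(8, 1, size=(n, 6))
            theta[: n // 2, 3:] += rng.uniform(0, 2)
            _, p, q = aq.ttest_fdr(_expr(theta, ids), groups)
            np.testing.assert_allclose(q, _bh_oracle(p), atol=1e-12)

    def test_q_monotone_and_at_least_p(self):
        rng = np.random.default_rng(1)
        ids, groups = self._groups(3, 3)
        theta = rng.normal(8, 1, size=(15, 6))
        _, p, q = aq.ttest_fdr(_expr(theta, ids), groups)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestQDifferentialExpression:
    def test_perfect_separation_auc_one(self):
        ids = [f"a{j}" for j in range(8)]
        groups = {a: ("A" if j < 4 else "B") for j, a in enumerate(ids)}
        theta = np.tile(np.linspace(4, 12, 20)[:, None], (1, 8))
        theta += np.random.default_rng(2).normal(0, 0.01, size=theta.shape)
        spikes = [f"g{i:03d}" for i in range(4)]
        theta[:4, 4:] += 3.0
        _, auc = aq.q_differential_expression(_expr(theta, ids), groups, spikes)
        assert auc == 1.0

    def test_auc_equals_mann_whitney_identity(self):
        rng = np.random.default_rng(3)
        n = 30
        order = list(rng.permutation(n))
        truth = set(rng.choice(n, size=8, replace=False).tolist())
        _, auc = roc_curve_from_ranking(order, truth)
        # U-statistic: pairs (pos, neg) where pos ranked better
        rank_of = {i: r for r, i in enumerate(order)}
        u = sum(1 for i in truth for j in range(n) if j not in truth
                and rank_of[i] < rank_of[j])
        assert auc == u / (8 * (n - 8))

    def test_random_ranking_auc_near_half(self):
        rng = np.random.default_rng(4)
        aucs = []
        for _ in range(200):
            order = list(rng.permutation(40))
            truth = set(range(10))
            _, auc = roc_curve_from_ranking(order, truth)
            aucs.append(auc)
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_empty_truth_rejected(self):
        ids = [f"a{j}" for j in range(4)]
        groups = {a: ("A" if j < 2 else "B") for j, a in enumerate(ids)}
        with pytest.raises(ValidationError):
            aq.q_differential_expression(_expr(np.ones((4, 4)), ids), groups, [])


class TestQClustering:
    def test_identical_replicates_distance_zero(self):
        theta = np.tile(np.array([[5.0], [6.0]]), (1, 2))
        dists, q = aq.q_clustering(_expr(theta), [("a0", "a1")])
        assert q == 0.0

    def test_unit_difference_in_900_probesets_gives_30(self):
        theta = np.zeros((900, 2))
        theta[:, 1] = 1.0
        _, q = aq.q_clustering(_expr(theta), [("a0", "a1")])
        assert abs(q - 30.0) < 1e-12

    def test_missing_pair_member_rejected(self):
        with pytest.raises(ValidationError):
            aq.q_clustering(_expr(np.ones((3, 2))), [("a0", "zz")])

    def test_corrupted_replicate_has_largest_distance(self):
        # 4 tissues x 2 replicates; one replicate with x3 noise should give
        # its pair the largest distance in nearly every draw
        wins = 0
        for s in range(40):
            d, tr = aq.simulate(aq.SimConfig(n_arrays=8, n_tissues=4,
                                             bad_arrays=(5,), seed=700 + s,
                                             **BASE))
            fit = aq.preprocess(d)
            pairs = [(d.array_ids[2 * i], d.array_ids[2 * i + 1])
                     for i in range(4)]
            dists, _ = aq.q_clustering(fit, pairs)
            worst_pair = max(dists, key=dists.get)
            wins += "arr005" in worst_pair
        assert wins >= 38


class TestPam:
    def test_separable_training_accuracy(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 0.2, size=(30, 10))
        X[:5, 5:] += 3.0
        labels = ["A"] * 5 + ["B"] * 5
        preds = aq.pam_train_predict(X, labels, X, shrinkage=0.0)
        assert preds == labels

    def test_infinite_shrinkage_falls_back_to_majority(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 7))
        labels = ["A"] * 3 + ["B"] * 4
        preds = aq.pam_train_predict(X, labels, X, shrinkage=1e9)
        assert preds == ["B"] * 7

    def test_soft_threshold_formula(self):
        rng = np.random.default_rng(7)
        d = rng.normal(size=50)
        for s in (0.0, 0.3, 1.7):
            brute = np.array([np.sign(x) * max(abs(x) - s, 0.0) for x in d])
            np.testing.assert_allclose(aq.soft_threshold(d, s), brute)

    def test_absent_class_rejected(self):
        with pytest.raises(ValidationError):
            aq.pam_train_predict(np.ones((5, 3)), ["A"] * 3, np.ones((5, 1)))


class TestMcc:
    @pytest.mark.parametrize("tp,tn,fp,fn,expected", [
        (5, 5, 0, 0, 1.0),
        (5, 5, 5, 5, 0.0),
        (0, 0, 5, 5, -1.0),
        (5, 0, 5, 0, 0.0),   # zero marginal convention
    ])
    def test_confusion_cases(self, tp, tn, fp, fn, expected):
        assert aq.mcc(tp, tn, fp, fn) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            aq.mcc(-1, 0, 0, 0)


class TestLeaveOneOut:
    def test_delta_equals_brute_force_refit(self):
        data, truth = aq.simulate_spikein(
            aq.SimConfig(n_arrays=8, bad_arrays=(3,), seed=13, **BASE),
            n_spike=16, spike_log_fc=0.5)
        qf = aq.make_q_de(truth.group_of, set(truth.de_probesets))
        res = aq.leave_one_out(data, qf)
        # independent recomputation, one array at a time
        q_full = qf(aq.preprocess(data), data.array_ids)
        assert res.q_full == q_full
        for aid in data.array_ids:
            kept = [a for a in data.array_ids if a != aid]
            q_j = qf(aq.preprocess(data.subset_arrays(kept)), kept)
            assert res.delta[aid] == q_j - q_full

    def test_all_good_arrays_removal_not_beneficial_on_average(self):
        deltas = []
        for s in range(8):
            data, truth = aq.simulate_spikein(
                aq.SimConfig(n_probesets=100, probes_per_set=4, n_arrays=8,
                             baseline_sd=0.5, seed=800 + s),
                n_spike=16, spike_log_fc=0.5)
            qf = aq.make_q_de(truth.group_of, set(truth.de_probesets))
            res = aq.leave_one_out(data, qf)
            deltas.extend(res.delta.values())
        assert np.mean(deltas) <= 0.0

    def test_undefined_when_group_too_small(self):
        data, truth = aq.simulate_spikein(
            aq.SimConfig(n_probesets=50, n_arrays=4, baseline_sd=0.5, seed=9),
            n_spike=8, spike_log_fc=0.5)
        qf = aq.make_q_de(truth.group_of, set(truth.de_probesets))
        res = aq.leave_one_out(data, qf)
        assert set(res.undefined) == set(data.array_ids)


class TestRemovalCurve:
    def _setup(self, seed):
        data, truth = aq.simulate_spikein(
            aq.SimConfig(n_probesets=100, probes_per_set=4, n_arrays=12,
                         baseline_sd=0.5, bad_arrays=(2, 8), seed=seed),
            n_spike=16, spike_log_fc=0.5)
        qf = aq.make_q_de(truth.group_of, set(truth.de_probesets))
        return data, truth, qf

    def test_curve_starts_at_q_full(self):
        data, truth, qf = self._setup(15)

        def rank(fit, _):
            med, _i = aq.summarize(aq.nuse(fit))
            return dict(zip(fit.array_ids, med))

        res = aq.removal_curve(data, qf, rank, n_max=3)
        assert res.removal_curve[0] == (0, res.q_full)
        assert len(res.removal_curve) == 4

    def test_random_ranking_no_systematic_gain(self):
        gains_metric, gains_random = [], []
        for s in range(6):
            data, truth, qf = self._setup(900 + s)

            def rank_nuse(fit, _):
                med, _i = aq.summarize(aq.nuse(fit))
                return dict(zip(fit.array_ids, med))

            rng = np.random.default_rng(s)

            def rank_random(fit, _):
                return dict(zip(fit.array_ids,
                                rng.permutation(len(fit.array_ids)).astype(float)))

            rm = aq.removal_curve(data, qf, rank_nuse, n_max=4)
            rr = aq.removal_curve(data, qf, rank_random, n_max=4)
            gains_metric.append(max(q for _, q in rm.removal_curve[1:]) - rm.q_full)
            gains_random.append(max(q for _, q in rr.removal_curve[1:]) - rr.q_full)
        assert np.mean(gains_random) <= np.mean(gains_metric) + 1e-9

    def test_excessive_n_max_rejected(self):
        data, truth, qf = self._setup(16)
        with pytest.raises(ValidationError):
            aq.removal_curve(data, qf, lambda f, d: {}, n_max=11)
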