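import math

import numpy as np
import pytest
from scipy import stats

from perturbgraph.errors import ValidationError
from perturbgraph.evaluation import (accurately_predicted, aggregate_and_test,
                                     baseline_rank, indirect_rank, ndcg,
                                     pct_accurately_predicted,
                                     perturbagenwise_r2, proximity,
                                     proximity_test, recall_at_k,
                                     samplewise_r2)
from perturbgraph.graphs import ProxyCausalGraph
from .conftest import random_undirected


class TestNdcg:
    def test_perfect_ranking_is_one(self):
        order = np.arange(10)
        assert ndcg(order, {0, 1, 2}, 10) == pytest.approx(1.0)

    def test_single_target_rank_three_of_five(self):
        # DCG = (1 - 3/5)/log2(4) = 0.2; IDCG = (1 - 1/5)/log2(2) = 0.8
        order = np.array([0, 1, 4, 2, 3])
        assert ndcg(order, {4}, 5) == pytest.approx(0.25)

    def test_gain_at_rank_one(self):
        # a single target at rank 1 scores gain (1 - 1/n) and IDCG equals it
        order = np.array([3, 0, 1, 2])
        assert ndcg(order, {3}, 4) == pytest.approx(1.0)

    def test_empty_truth_rejected(self):
        with pytest.raises(ValidationError):
            ndcg(np.arange(4), set(), 4)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(10, 51))
            order = rng.permutation(n)
            truth = set(rng.choice(n, int(rng.integers(1, 9)), replace=False).tolist())
            dcg = 0.0
            for t in truth:
                rank = int(np.nonzero(order == t)[0][0]) + 1
                dcg += (1 - rank / n) / math.log2(rank + 1)
            idcg = sum((1 - r / n) / math.log2(r + 1)
                       for r in range(1, len(truth) + 1))
            assert ndcg(order, truth, n) == pytest.approx(dcg / idcg, abs=1e-12)


class TestRecallAndAccuracy:
    def test_recall_examples(self):
        order = np.arange(20)
        assert recall_at_k(order, {0, 1}, 5) == 1.0
        assert recall_at_k(order, {19}, 20) == 1.0
        assert recall_at_k(order, {3, 15, 16, 17}, 10) == 0.25

    def test_recall_monotone_in_k(self):
        rng = np.random.default_rng(1)
        order = rng.permutation(30)
        truth = {3, 7, 21}
        vals = [recall_at_k(order, truth, k) for k in range(1, 31)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))
        assert vals[-1] == 1.0

    def test_accurately_predicted_definition(self):
        order = np.array([5, 4, 3, 2, 1, 0])
        assert not accurately_predicted(order, {0, 1})  # top-2 = {5, 4}
        assert accurately_predicted(order, {4, 0})
        # definitional identity with recall@|truth| > 0
        rng = np.random.default_rng(2)
        for _ in range(50):
            o = rng.permutation(12)
            truth = set(rng.choice(12, int(rng.integers(1, 5)), replace=False).tolist())
            assert accurately_predicted(o, truth) == \
                (recall_at_k(o, truth, len(truth)) > 0)

    def test_pct_counts(self):
        orders = [np.arange(5)] * 10
        truths = [{0}] * 3 + [{4}] * 7  # 3 hits at top-1
        assert pct_accurately_predicted(orders, truths) == pytest.approx(30.0)


class TestR2:
    def test_samplewise_identity_and_affine(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 20)
        assert samplewise_r2(x, x) == pytest.approx(1.0)
        assert samplewise_r2(2.5 * x - 0.3, x) == pytest.approx(1.0)

    def test_samplewise_matches_hand_covariance(self):
        pred = np.array([0.1, 0.4, 0.35, 0.8, 0.95])
        truth = np.array([0.2, 0.3, 0.5, 0.7, 0.9])
        cov = np.mean((pred - pred.mean()) * (truth - truth.mean()))
        r = cov / (pred.std() * truth.std())
        assert samplewise_r2(pred, truth) == pytest.approx(r * r, abs=1e-12)

    def test_constant_vector_is_missing(self):
        assert math.isnan(samplewise_r2(np.full(5, 0.3), np.arange(5) / 5))

    def test_perturbagenwise_mean_based(self):
        rng = np.random.default_rng(4)
        truth = rng.uniform(0, 1, (6, 4))
        assert perturbagenwise_r2(truth, truth) == pytest.approx(1.0)
        # column permutation leaves per-gene means unchanged
        assert perturbagenwise_r2(truth[:, ::-1], truth) == pytest.approx(1.0)

    def test_perturbagenwise_matches_hand_ols(self):
        pred = np.array([[0.1, 0.3], [0.5, 0.7], [0.2, 0.4], [0.9, 0.8]])
        truth = np.array([[0.2, 0.2], [0.6, 0.6], [0.1, 0.5], [0.7, 0.9]])
        mp, mt = pred.mean(axis=1), truth.mean(axis=1)
        slope, intercept, r, _, _ = stats.linregress(mp, mt)
        assert perturbagenwise_r2(pred, truth) == pytest.approx(r * r, abs=1e-12)


def _path_graph(*names):
    arcs = []
    for a, b in zip(names, names[1:]):
        arcs += [(a, b), (b, a)]
    return ProxyCausalGraph(tuple(names), tuple(arcs), origin="undirected-doubled")


class TestProximity:
    def test_examples(self):
        g = _path_graph("a", "b", "c")
        assert proximity(g, {"a"}, {"a"}) == 0.0
        assert proximity(g, {"a"}, {"c"}) == 2.0
        assert proximity(g, {"a", "b"}, {"c"}) == pytest.approx(1.5)

    def test_symmetry_and_densification(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            g = random_undirected(rng, 8, 0.35)
            nodes = list(g.node_ids)
            P = set(rng.choice(nodes, 2, replace=False))
            R = set(rng.choice(nodes, 2, replace=False))
            try:
                d1 = proximity(g, P, R)
            except ValidationError:
                continue
            assert d1 == pytest.approx(proximity(g, R, P))
            # add an edge: mean pairwise distance can only shrink
            absent = [(a, b) for a in nodes for b in nodes
                      if a < b and (a, b) not in g.arcs]
            if absent and not math.isnan(d1):
                a, b = absent[int(rng.integers(len(absent)))]
                g2 = ProxyCausalGraph(g.node_ids,
                                      g.arcs + ((a, b), (b, a)),
                                      origin="undirected-doubled")
                assert proximity(g2, P, R) <= d1 + 1e-12

    def test_disconnected_pairs_excluded(self, caplog):
        g = ProxyCausalGraph(("a", "b", "c"), (("a", "b"), ("b", "a")),
                             origin="undirected-doubled")
        with caplog.at_level("INFO", logger="perturbgraph.evaluation"):
            d = proximity(g, {"a", "c"}, {"b"})
        assert d == 1.0  # only the a-b pair counts
        assert "excluded" in caplog.text

    def test_closest_variant(self):
        g = _path_graph("a", "b", "c")
        assert proximity(g, {"a", "b"}, {"c"}, variant="closest") == 1.0

    def test_empty_set_rejected(self):
        g = _path_graph("a", "b")
        with pytest.raises(ValidationError):
            proximity(g, set(), {"a"})


def _brute_u(x, y):
    return sum(1.0 if a > b else 0.5 if a == b else 0.0
               for a in x for b in y)


class TestProximityTest:
    def test_rank_biserial_full_enumeration(self):
        x, y = [1.0, 2.0], [3.0, 4.0]
        res = proximity_test(x, y, n_boot=50, seed=0)
        assert res.u_statistic == _brute_u(x, y) == 0.0
        assert res.rank_biserial == pytest.approx(2 * 0.0 / 4 - 1) == -1.0
        assert res.ci_low <= res.rank_biserial <= res.ci_high

    def test_identical_samples_near_zero_effect(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 5, 40).tolist()
        res = proximity_test(x, x, n_boot=100, seed=1)
        assert abs(res.rank_biserial) < 1e-12
        assert res.p_value > 0.4

    def test_direction_method_smaller_gives_negative_r(self):
        res = proximity_test([1, 1, 2], [5, 6, 7], n_boot=50, seed=2)
        assert res.rank_biserial < 0
        assert res.p_value < 0.1

    def test_u_r_relation_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n1, n2 = int(rng.integers(1, 9)), int(rng.integers(1, 9))
            x = rng.integers(0, 4, n1).astype(float).tolist()
            y = rng.integers(0, 4, n2).astype(float).tolist()
            res = proximity_test(x, y, n_boot=10, seed=3)
            assert res.u_statistic == pytest.approx(_brute_u(x, y))
            assert res.rank_biserial == pytest.approx(
                2 * res.u_statistic / (n1 * n2) - 1)


class TestBaselines:
    def test_full_prior_deterministic(self):
        r = baseline_rank("prior_list", [3, 1, 0, 2], 4, seed=9)
        np.testing.assert_array_equal(r.order, [3, 1, 0, 2])

    def test_prior_head_then_shuffled_tail(self):
        r = baseline_rank("prior_list", [5, 2], 8, seed=4)
        np.testing.assert_array_equal(r.order[:2], [5, 2])
        assert sorted(r.order) == list(range(8))

    def test_duplicate_prior_rejected(self):
        with pytest.raises(ValidationError):
            baseline_rank("prior_list", [1, 1], 4, seed=0)

    def test_empty_prior_is_pure_random(self):
        a = baseline_rank("prior_list", [], 6, seed=5)
        b = baseline_rank("random", None, 6, seed=5)
        assert sorted(a.order) == sorted(b.order) == list(range(6))

    def test_random_recall_matches_closed_form(self):
        # singleton truth: E[recall@k] = k/n
        n, k, draws = 12, 3, 4000
        hits = 0
        for i in range(draws):
            r = baseline_rank("random", None, n, seed=i)
            hits += recall_at_k(r, {0}, k)
        got = hits / draws
        se = math.sqrt((k / n) * (1 - k / n) / draws)
        assert abs(got - k / n) < 4 * se


class TestIndirectRank:
    def test_rule_application(self):
        r2 = {"d1": 0.9, "d2": 0.1}
        targets = {"d1": {0, 1}, "d2": {2}}
        r = indirect_rank(r2, targets, n=5, seed=0)
        assert set(r.order[:2].tolist()) == {0, 1}
        assert r.order[2] == 2
        assert set(r.order[3:].tolist()) == {3, 4}

    def test_tie_broken_by_drug_id(self):
        r2 = {"b": 0.5, "a": 0.5}
        targets = {"a": {0}, "b": {1}}
        r = indirect_rank(r2, targets, n=2, seed=1)
        np.testing.assert_array_equal(r.order, [0, 1])  # "a" sorts first

    def test_single_drug_covering_all(self):
        r = indirect_rank({"d": 1.0}, {"d": {0, 1, 2}}, n=3, seed=2)
        assert sorted(r.order) == [0, 1, 2]

    def test_first_occurrence_kept(self):
        r2 = {"d1": 0.9, "d2": 0.5}
        targets = {"d1": {0}, "d2": {0, 1}}
        r = indirect_rank(r2, targets, n=2, seed=3)
        np.testing.assert_array_equal(r.order, [0, 1])


class TestAggregateAndTest:
    def test_single_metric_aggregation_is_mean(self):
        vals = {"m": {"ndcg": [0.2, 0.4, 0.6]}, "o": {"ndcg": [0.1, 0.1, 0.1]}}
        agg, _ = aggregate_and_test(vals, focal="m")
        assert agg["m"] == pytest.approx(0.4)

    def test_dominating_method_small_p(self):
        folds_m = [0.9, 0.85, 0.95, 0.9, 0.88]
        folds_o = [0.5, 0.55, 0.45, 0.5, 0.52]
        agg, p = aggregate_and_test(
            {"m": {"x": folds_m}, "o": {"x": folds_o}}, focal="m")
        diffs = np.array(folds_m) - np.array(folds_o)
        t = diffs.mean() / (diffs.std(ddof=1) / math.sqrt(len(diffs)))
        expected = stats.t.sf(t, df=len(diffs) - 1)
        assert p["o"] == pytest.approx(expected, rel=1e-10)

    def test_identical_methods_p_one(self):
        vals = {"m": {"x": [0.5, 0.6]}, "o": {"x": [0.5, 0.6]}}
        _, p = aggregate_and_test(vals, focal="m")
        assert p["o"] == 1.0

    def test_misaligned_folds_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_and_test({"m": {"x": [1, 2]}, "o": {"x": [1, 2, 3]}},
                               focal="m")
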