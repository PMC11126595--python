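import numpy as np
import pytest

from bilink.errors import InfeasibleSplitError, SamplingError
from bilink.evaluation import (
    auc_exhaustive,
    auc_sampled,
    evaluate,
    make_folds,
    precision_at,
    training_network,
)
from bilink.network import BipartiteNetwork
from bilink.scoring import ScoreMethod, score
from bilink.synthetic import planted
from conftest import random_network

perfect = lambda net, x, y: 1.0 if (x, y) in PERFECT_EDGES else 0.0
constant = lambda net, x, y: 0.7
PERFECT_EDGES: set = set()


class TestFolds:
    def test_exact_partition(self):
        net = random_network(np.random.default_rng(0), 20, 20, 0.25)
        plan = make_folds(net, k=10, seed=3)
        union = frozenset().union(*plan.folds)
        assert union == net.edges
        assert sum(len(f) for f in plan.folds) == net.m  # disjoint

    def test_sizes_within_one(self):
        a = [f"a{i}" for i in range(101)]
        net = BipartiteNetwork(a, ["b0"], [(x, "b0") for x in a])
        plan = make_folds(net, k=10, seed=0)
        sizes = sorted(len(f) for f in plan.folds)
        assert sizes == [10] * 9 + [11]

    def test_deterministic(self):
        net = random_network(np.random.default_rng(1), 15, 15, 0.3)
        assert make_folds(net, 10, seed=5).folds == make_folds(net, 10, seed=5).folds
        assert make_folds(net, 10, seed=5).folds != make_folds(net, 10, seed=6).folds

    def test_infeasible_split(self, toy_net):
        with pytest.raises(InfeasibleSplitError):
            make_folds(toy_net, k=6, seed=0)

    def test_k_below_two_rejected(self, toy_net):
        with pytest.raises(ValueError):
            make_folds(toy_net, k=1, seed=0)


class TestTrainingNetwork:
    def test_nodes_retained_when_isolated(self, toy_net):
        train = training_network(toy_net, [("p3", "d2")])
        assert "p3" in train
        assert train.degree("p3") == 0
        assert train.m == 4

    def test_identity_and_boundary(self, toy_net):
        assert training_network(toy_net, []) == toy_net
        empty = training_network(toy_net, toy_net.edges)
        assert empty.m == 0 and empty.part_a == toy_net.part_a

    def test_unknown_edge_rejected(self, toy_net):
        with pytest.raises(Exception):
            training_network(toy_net, [("p3", "d3")])


class TestAUCSampled:
    @pytest.fixture
    def split(self):
        net = random_network(np.random.default_rng(2), 12, 12, 0.3)
        plan = make_folds(net, k=5, seed=1)
        test = plan.folds[0]
        return training_network(net, test), test

    def test_perfect_scorer_gives_one(self, split):
        train, test = split
        PERFECT_EDGES.clear()
        PERFECT_EDGES.update(test)
        for n in (1, 10, 500):
            for seed in (0, 9):
                assert auc_sampled(train, test, perfect, n=n, seed=seed).auc == 1.0

    def test_constant_scorer_gives_half(self, split):
        train, test = split
        res = auc_sampled(train, test, constant, n=200, seed=4)
        assert res.n_tie == 200 and res.auc == 0.5

    def test_inverted_scorer_gives_zero(self, split):
        train, test = split
        PERFECT_EDGES.clear()
        PERFECT_EDGES.update(test)
        inverted = lambda net, x, y: -perfect(net, x, y)
        assert auc_sampled(train, test, inverted, n=300, seed=0).auc == 0.0

    def test_tally_identity(self, split):
        train, test = split
        res = auc_sampled(train, test, "CN", n=777, seed=3)
        assert res.auc == (res.n_win + 0.5 * res.n_tie) / res.n
        assert res.n_win + res.n_tie <= res.n

    def test_deterministic_in_seed(self, split):
        train, test = split
        r1 = auc_sampled(train, test, "AA", n=400, seed=12)
        r2 = auc_sampled(train, test, "AA", n=400, seed=12)
        assert (r1.n_win, r1.n_tie) == (r2.n_win, r2.n_tie)

    def test_no_nonedge_universe_rejected(self):
        a, b = ["a0", "a1"], ["b0"]
        net = BipartiteNetwork(a, b, [("a0", "b0"), ("a1", "b0")])
        train = training_network(net, [("a1", "b0")])
        with pytest.raises(SamplingError):
            auc_sampled(train, [("a1", "b0")], "CN", n=10, seed=0)

    def test_sampled_converges_to_exhaustive(self):
        """Sampled AUC is an unbiased estimate of the all-pairs AUC; at n=10^5
        it must land within 3 standard errors on a small planted instance."""
        net = planted(3)
        plan = make_folds(net, k=10, seed=3)
        test = plan.folds[0]
        train = training_network(net, test)
        exact = auc_exhaustive(train, test, "CN")
        n = 100_000
        sampled = auc_sampled(train, test, "CN", n=n, seed=8).auc
        se = np.sqrt(0.25 / n)  # variance of a bounded [0,1] comparison <= 1/4
        assert abs(sampled - exact) <= 3 * se

    def test_exhaustive_matches_literal_double_loop(self, toy_net):
        test = [("p3", "d2")]
        train = training_network(toy_net, test)
        non = [p for p in train.non_edges() if p not in set(test)]
        wins = ties = 0
        for te in test:
            s_t = score(train, *te, "CN")
            for ne in non:
                s_n = score(train, *ne, "CN")
                wins += s_t > s_n
                ties += s_t == s_n
        expected = (wins + 0.5 * ties) / (len(test) * len(non))
        assert auc_exhaustive(train, test, "CN") == pytest.approx(expected)


class TestPrecision:
    def test_perfect_ranking_gives_one(self):
        net = random_network(np.random.default_rng(5), 10, 10, 0.3)
        plan = make_folds(net, k=5, seed=2)
        test = plan.folds[0]
        train = training_network(net, test)
        PERFECT_EDGES.clear()
        PERFECT_EDGES.update(test)
        res = precision_at(train, test, perfect)
        assert res.precision == 1.0 and res.l == len(test)

    def test_constant_scorer_hits_first_lexicographic(self, toy_net):
        test = [("p3", "d2")]
        train = training_network(toy_net, test)
        # ties everywhere -> top-l is the first l lexicographic non-edges
        first = sorted(train.non_edges())[:2]
        res = precision_at(train, test, constant, l=2)
        assert res.hits == sum(1 for p in first if p in set(test))

    def test_toy_holdout_cn_top1(self, toy_net):
        """Brute-force ranking of the 4-edge training network puts (p1,d3) on
        top (CN=1) while the held-out edge (p3,d2) scores 0: no hit."""
        test = [("p3", "d2")]
        train = training_network(toy_net, test)
        res = precision_at(train, test, "CN", l=1)
        assert (res.hits, res.precision) == (0, 0.0)

    def test_invalid_l(self, toy_net):
        test = [("p3", "d2")]
        train = training_network(toy_net, test)
        with pytest.raises(ValueError):
            precision_at(train, test, "CN", l=0)
        with pytest.raises(ValueError):
            precision_at(train, test, "CN", l=10**6)

    def test_candidate_order_invariance(self):
        """Equal result whether candidates are enumerated by default or passed
        explicitly in a scrambled order (the tie rule fixes the ranking)."""
        net = random_network(np.random.default_rng(8), 10, 12, 0.25)
        plan = make_folds(net, k=4, seed=1)
        test = plan.folds[0]
        train = training_network(net, test)
        from bilink.scoring import rank_candidates

        default = rank_candidates(train, "AA", top_k=len(test))
        scrambled = list(train.non_edges())
        np.random.default_rng(0).shuffle(scrambled)
        explicit = rank_candidates(train, "AA", top_k=len(test),
                                   candidates=scrambled)
        assert default.predictions == explicit.predictions


class TestEvaluate:
    def test_shape_and_partition(self):
        net = random_network(np.random.default_rng(4), 12, 12, 0.35)
        rep = evaluate(net, ["CN", "PA"], k=5, seed=2)
        assert len(rep.outcomes) == 5 * 2
        seen = [o.fold for o in rep.outcomes if o.method is ScoreMethod.CN]
        assert seen == list(range(5))

    def test_byte_identical_reports_under_fixed_seed(self):
        net = random_network(np.random.default_rng(6), 12, 12, 0.3)
        r1 = evaluate(net, ["CN", "JC"], k=5, seed=11)
        r2 = evaluate(net, ["CN", "JC"], k=5, seed=11)
        assert r1.to_json() == r2.to_json()

    def test_auc_seed_independent_of_sample_count(self):
        """Changing n must not change the folds (separate substreams)."""
        net = random_network(np.random.default_rng(9), 12, 12, 0.3)
        r1 = evaluate(net, ["CN"], k=5, n=50, seed=1)
        r2 = evaluate(net, ["CN"], k=5, n=150, seed=1)
        assert [o.precision for o in r1.outcomes] == [o.precision for o in r2.outcomes]

    def test_planted_structure_cn_beats_pa(self):
        """On the planted-block benchmark, shared-structure scoring must beat
        pure degree product, and clear chance by a wide margin."""
        rep = evaluate(planted(1), ["CN", "PA"], k=10, seed=1)
        s = rep.summary()
        assert s["CN"]["mean_auc"] > s["PA"]["mean_auc"]
        assert s["CN"]["mean_auc"] > 0.65
        assert rep.best_method is ScoreMethod.CN

    def test_summary_recomputable_from_folds(self):
        net = random_network(np.random.default_rng(10), 12, 12, 0.3)
        rep = evaluate(net, ["JC"], k=5, seed=7)
        aucs = [o.auc.auc for o in rep.outcomes]
        assert rep.summary()["JC"]["mean_auc"] == pytest.approx(np.mean(aucs))
        assert rep.summary()["JC"]["sd_auc"] == pytest.approx(np.std(aucs, ddof=1))
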