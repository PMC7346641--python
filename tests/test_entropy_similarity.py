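"""Von Neumann entropy closed forms, similarity metrics, group tests."""

import math

import numpy as np
import pytest

from hgtnet.entropy_similarity import (
    all_pairwise_similarities,
    combined_similarity,
    node_jaccard,
    topology_correlation,
    von_neumann_entropy,
    within_between_test,
)
from hgtnet.errors import (
    InsufficientDataError,
    UndefinedMetricError,
)
from hgtnet.synthetic_cohort import preferential_attachment_graph
from .conftest import make_network


class TestVonNeumannEntropy:
    def test_closed_forms(self):
        # isolated node; K2; path P3; star with 4 leaves
        assert von_neumann_entropy(make_network("k1", [], nodes=["a"])).H_VN == 0.0
        assert von_neumann_entropy(
            make_network("k2", [("a", "b")])
        ).H_VN == pytest.approx(0.25, abs=1e-12)
        assert von_neumann_entropy(
            make_network("p3", [("a", "b"), ("b", "c")])
        ).H_VN == pytest.approx(5 / 9, abs=1e-12)
        assert von_neumann_entropy(
            make_network("s4", [("c", x) for x in "abde"])
        ).H_VN == pytest.approx(0.76, abs=1e-12)

    def test_empty_network_undefined(self):
        with pytest.raises(UndefinedMetricError):
            von_neumann_entropy(make_network("e", []))

    def test_weights_do_not_change_entropy(self):
        # degrees are unweighted: multiplicity of events is ignored
        light = make_network("a", [("a", "b", 1), ("b", "c", 1)])
        heavy = make_network("b", [("a", "b", 9), ("b", "c", 2)])
        assert von_neumann_entropy(light).H_VN == von_neumann_entropy(heavy).H_VN

    def test_upper_bound_on_generated_networks(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = int(rng.integers(5, 300))
            g = preferential_attachment_graph(n, m=2, alpha_target=2.6, rng=rng)
            net = make_network("x", list(g.edges()))
            h = von_neumann_entropy(net).H_VN
            assert 0.0 < h < 1.0 - 1.0 / n


class TestNodeJaccard:
    def test_identity_disjoint_and_half(self):
        a = make_network("a", [("A", "B"), ("B", "C")])
        b = make_network("b", [("B", "C"), ("C", "D")])
        assert node_jaccard(a, a).value == 1.0
        assert node_jaccard(a, b).value == 0.5  # {A,B,C} vs {B,C,D}
        c = make_network("c", [("X", "Y")])
        assert node_jaccard(a, c).value == 0.0

    def test_both_empty_undefined(self):
        with pytest.raises(UndefinedMetricError):
            node_jaccard(make_network("a", []), make_network("b", []))

    def test_symmetry_and_triangle_bound(self):
        rng = np.random.default_rng(1)
        nets = []
        for i in range(4):
            nodes = rng.choice(20, size=10, replace=False)
            nets.append(make_network(f"n{i}", [(f"g{nodes[j]}", f"g{nodes[j+1]}")
                                               for j in range(9)]))
        for a in nets:
            for b in nets:
                assert node_jaccard(a, b).value == node_jaccard(b, a).value
                for c in nets:
                    jac = node_jaccard
                    assert jac(a, c).value >= jac(a, b).value + jac(b, c).value - 1 - 1e-12


class TestTopologyCorrelation:
    def test_self_comparison_is_one(self):
        net = make_network("a", [("a", "b"), ("b", "c"), ("c", "d"), ("a", "c")])
        for prop in ("degree", "pagerank"):
            assert topology_correlation(net, net, prop).value == pytest.approx(1.0)

    def test_rank_reversal_is_minus_one(self):
        # shared nodes a,b,c: degrees 3,2,1 in one net and 1,2,3 in the other
        n1 = make_network("x", [("a", "b"), ("a", "c"), ("a", "z1"), ("b", "z2")])
        n2 = make_network("y", [("c", "b"), ("c", "a"), ("c", "w1"), ("b", "w2")])
        shared_props = topology_correlation(n1, n2, "degree")
        assert shared_props.value == pytest.approx(-1.0)

    def test_too_few_shared_nodes(self):
        n1 = make_network("x", [("a", "b")])
        n2 = make_network("y", [("a", "q")])
        with pytest.raises(InsufficientDataError):
            topology_correlation(n1, n2, "degree")

    def test_zero_variance_ranking_undefined(self):
        ring1 = make_network("x", [("a", "b"), ("b", "c"), ("c", "a")])
        ring2 = make_network("y", [("a", "c"), ("c", "b"), ("b", "a")])
        with pytest.raises(UndefinedMetricError):
            topology_correlation(ring1, ring2, "degree")

    def test_agrees_with_rank_formula_oracle(self):
        # Spearman from first principles: Pearson correlation of midranks
        rng = np.random.default_rng(3)
        core = [f"c{i:02d}" for i in range(30)]
        def rand_net(name, seed):
            r = np.random.default_rng(seed)
            extras = [f"{name}e{i}" for i in range(20)]
            nodes = core + extras
            edges = set()
            while len(edges) < 120:
                u, v = r.choice(len(nodes), size=2, replace=False)
                edges.add((nodes[min(u, v)], nodes[max(u, v)]))
            return make_network(name, sorted(edges))
        n1, n2 = rand_net("a", 1), rand_net("b", 2)
        res = topology_correlation(n1, n2, "degree")
        shared = sorted(n1.nodes & n2.nodes)
        d1 = n1.degrees()
        d2 = n2.degrees()
        x = np.array([d1[s] for s in shared], dtype=float)
        y = np.array([d2[s] for s in shared], dtype=float)
        def midrank(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2
                i = j
            return ranks
        rx, ry = midrank(x), midrank(y)
        oracle = float(np.corrcoef(rx, ry)[0, 1])
        assert res.value == pytest.approx(oracle, abs=1e-9)


class TestCombinedSimilarity:
    def test_identical_networks(self):
        net = make_network("a", [("a", "b"), ("b", "c"), ("a", "d")])
        assert combined_similarity(net, net).value == pytest.approx(1.0)

    def test_disjoint_networks_flagged_zero(self):
        a = make_network("a", [("a", "b")])
        b = make_network("b", [("x", "y")])
        res = combined_similarity(a, b)
        assert res.value == 0.0 and res.correlation_undefined

    def test_product_structure(self):
        # jaccard 0.5 and perfect degree agreement => combined 0.5
        n1 = make_network("x", [("a", "b"), ("a", "c"), ("a", "d")])
        n2 = make_network("y", [("a", "b"), ("a", "c"), ("a", "e")])
        jac = node_jaccard(n1, n2).value
        corr = topology_correlation(n1, n2, "degree").value
        res = combined_similarity(n1, n2)
        assert res.value == pytest.approx(jac * corr)

    def test_symmetry(self):
        n1 = make_network("x", [("a", "b"), ("b", "c"), ("c", "d")])
        n2 = make_network("y", [("b", "c"), ("c", "d"), ("d", "e")])
        assert combined_similarity(n1, n2).value == pytest.approx(
            combined_similarity(n2, n1).value
        )


class TestWithinBetweenTest:
    def _scores(self, values, tag):
        from hgtnet.entropy_similarity import SimilarityScore

        return [SimilarityScore(f"{tag}{i}a", f"{tag}{i}b", "combined", v)
                for i, v in enumerate(values)]

    def test_identical_classes_give_p_one(self):
        vals = [0.1, 0.5, 0.9]
        scores = self._scores(vals, "w") + self._scores(vals, "b")
        pairing = {(s.sample_a, s.sample_b): ("within" if s.sample_a.startswith("w")
                                              else "between") for s in scores}
        res = within_between_test(scores, pairing)
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_classes_match_t_oracle(self):
        rng = np.random.default_rng(0)
        w = 0.9 + rng.normal(0, 1e-3, 10)
        b = 0.1 + rng.normal(0, 1e-3, 10)
        scores = self._scores(w, "w") + self._scores(b, "b")
        pairing = {(s.sample_a, s.sample_b): ("within" if s.sample_a.startswith("w")
                                              else "between") for s in scores}
        res = within_between_test(scores, pairing)
        assert res.p_value < 1e-6
        # direct pooled-t oracle
        sw, sb = w.std(ddof=1), b.std(ddof=1)
        sp = math.sqrt(((9 * sw**2) + (9 * sb**2)) / 18)
        t_oracle = (w.mean() - b.mean()) / (sp * math.sqrt(2 / 10))
        assert res.t_statistic == pytest.approx(t_oracle, rel=1e-9)

    def test_insufficient_class(self):
        scores = self._scores([0.5], "w") + self._scores([0.1, 0.2], "b")
        pairing = {(s.sample_a, s.sample_b): ("within" if s.sample_a.startswith("w")
                                              else "between") for s in scores}
        with pytest.raises(InsufficientDataError):
            within_between_test(scores, pairing)


class TestBatchSimilarities:
    def test_long_table_matches_pairwise_calls(self):
        nets = {
            "a": make_network("a", [("a", "b"), ("b", "c"), ("c", "d"), ("a", "c")]),
            "b": make_network("b", [("b", "c"), ("c", "d"), ("d", "e"), ("b", "d")]),
            "c": make_network("c", [("x", "y")]),
        }
        scores = all_pairwise_similarities(nets, ["jaccard", "degree", "combined"])
        assert len(scores) == 3 * 3  # 3 pairs x 3 metrics
        lookup = {(s.sample_a, s.sample_b, s.metric): s for s in scores}
        assert lookup[("a", "b", "jaccard")].value == pytest.approx(
            node_jaccard(nets["a"], nets["b"]).value
        )
        assert lookup[("a", "b", "combined")].value == pytest.approx(
            combined_similarity(nets["a"], nets["b"]).value
        )
        assert lookup[("a", "c", "combined")].correlation_undefined
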