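"""Community detection, HCC clustering, bias-corrected labeling, composition."""

from fractions import Fraction

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hgtnet.communities import (
    Community,
    CommunityCluster,
    LabelCounts,
    cluster_communities,
    cluster_composition,
    compare_compositions,
    detect_communities,
    label_cluster,
    label_community_clusters,
)
from hgtnet.data_model import TaxonomyTable, TaxonRecord
from hgtnet.errors import InsufficientDataError, ValidationError
from hgtnet.synthetic_cohort import generate_community_motif_set
from .conftest import make_network


def two_cliques_with_bridge():
    g = nx.Graph()
    left = [f"L{i}" for i in range(5)]
    right = [f"R{i}" for i in range(5)]
    for block in (left, right):
        for i in range(5):
            for j in range(i + 1, 5):
                g.add_edge(block[i], block[j], weight=1)
    g.add_edge("L0", "R0", weight=1)
    return make_network("s", [(u, v, d["weight"]) for u, v, d in g.edges(data=True)])


class TestDetectCommunities:
    def test_two_cliques_split_exactly(self):
        comms = detect_communities(two_cliques_with_bridge(), seed=1)
        members = sorted(frozenset(c.members) for c in comms)
        assert len(comms) == 2
        assert {frozenset(f"L{i}" for i in range(5)),
                frozenset(f"R{i}" for i in range(5))} == set(members)

    def test_two_clique_partition_beats_all_two_block_partitions(self):
        # exhaustive modularity oracle over every 2-block partition of 10 nodes
        net = two_cliques_with_bridge()
        comms = detect_communities(net, seed=1)
        found = [set(c.members) for c in comms]
        nodes = sorted(net.nodes)
        best_q, best_part = -1.0, None
        for mask in range(1, 2 ** (len(nodes) - 1)):
            block_a = {nodes[i] for i in range(len(nodes)) if (mask >> i) & 1}
            block_b = set(nodes) - block_a
            if not block_b:
                continue
            q = nx.community.modularity(net.graph, [block_a, block_b])
            if q > best_q:
                best_q, best_part = q, [block_a, block_b]
        assert sorted(map(sorted, found)) == sorted(map(sorted, best_part))

    def test_single_clique_stays_whole(self):
        net = make_network("s", [(f"n{i}", f"n{j}") for i in range(6)
                                 for j in range(i + 1, 6)])
        comms = detect_communities(net, seed=3)
        assert len(comms) == 1 and comms[0].size == 6

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(5)
        edges = set()
        while len(edges) < 120:
            u, v = rng.choice(40, 2, replace=False)
            edges.add((f"n{min(u, v)}", f"n{max(u, v)}"))
        net = make_network("s", sorted(edges))
        a = detect_communities(net, seed=42)
        b = detect_communities(net, seed=42)
        assert [c.members for c in a] == [c.members for c in b]

    def test_partition_covers_all_nodes(self):
        net = two_cliques_with_bridge()
        comms = detect_communities(net, seed=0)
        union = set().union(*(c.members for c in comms))
        assert union == net.nodes
        assert sum(c.size for c in comms) == len(net.nodes)  # disjoint


class TestClusterCommunities:
    def _comm(self, sid, members):
        return Community(sample_id=sid, members=frozenset(members))

    def test_identical_communities_form_one_cluster(self):
        comms = [self._comm(f"s{i}", ["a", "b", "c"]) for i in range(10)]
        clusters, pool = cluster_communities(comms)
        assert len(clusters) == 1 and clusters[0].size == 10 and not pool

    def test_two_disjoint_families(self):
        comms = ([self._comm(f"s{i}", ["a", "b"]) for i in range(5)]
                 + [self._comm(f"t{i}", ["x", "y"]) for i in range(5)])
        clusters, pool = cluster_communities(comms)
        assert len(clusters) == 2 and not pool

    def test_min_size_gate(self):
        comms = ([self._comm(f"s{i}", ["a", "b"]) for i in range(5)]
                 + [self._comm("lone", ["q", "r", "z"])])
        clusters, pool = cluster_communities(comms, min_size=2)
        assert len(clusters) == 1
        assert [c.sample_id for c in pool] == ["lone"]

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        comms, _ = generate_community_motif_set(n_motifs=3, communities_per_motif=5,
                                                seed=7)
        c1, _ = cluster_communities(list(comms))
        shuffled = list(comms)
        rng.shuffle(shuffled)
        c2, _ = cluster_communities(shuffled)
        key = lambda cl: sorted((m.sample_id, tuple(sorted(m.members)))
                                for m in cl.communities)
        assert sorted(map(key, c1)) == sorted(map(key, c2))

    def test_planted_motifs_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        comms, truth = generate_community_motif_set(seed=13)
        clusters, pool = cluster_communities(comms, max_distance=0.6, min_size=2)
        assign = {}
        for cl in clusters:
            for m in cl.communities:
                assign[(m.sample_id, m.members)] = cl.cluster_id
        pred = [assign.get((c.sample_id, c.members), -(i + 1))
                for i, c in enumerate(comms)]
        assert adjusted_rand_score(truth, pred) >= 0.9

    def test_too_few_communities(self):
        with pytest.raises(InsufficientDataError):
            cluster_communities([self._comm("s", ["a"])])


class TestLabelCluster:
    def test_bias_correction_with_study_sample_counts(self):
        # 10/38 > 20/109, so the smaller group wins despite fewer members
        counts = LabelCounts(counts={"Non-IBD": 10, "IBD": 20},
                             num_samples={"Non-IBD": 38, "IBD": 109})
        assert Fraction(10, 38) > Fraction(20, 109)
        assert label_cluster(counts) == "Non-IBD"

    def test_one_sided_counts(self):
        counts = LabelCounts(counts={"Non-IBD": 0, "IBD": 5},
                             num_samples={"Non-IBD": 38, "IBD": 109})
        assert label_cluster(counts) == "IBD"

    def test_exact_tie_is_ambiguous(self):
        counts = LabelCounts(counts={"A": 2, "B": 4},
                             num_samples={"A": 10, "B": 20})
        assert label_cluster(counts) == "ambiguous"

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValidationError):
            label_cluster(LabelCounts(counts={}, num_samples={"A": 1, "B": 1}))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        ca=st.integers(0, 8), cb=st.integers(0, 8),
        na=st.integers(1, 8), nb=st.integers(1, 8),
        scale=st.integers(1, 7),
    )
    def test_scale_invariance_small_grid(self, ca, cb, na, nb, scale):
        if ca == 0 and cb == 0:
            return
        base = label_cluster(LabelCounts({"A": ca, "B": cb}, {"A": na, "B": nb}))
        scaled = label_cluster(LabelCounts({"A": ca * scale, "B": cb * scale},
                                           {"A": na * scale, "B": nb * scale}))
        assert base == scaled

    def test_labeling_clusters_from_sample_groups(self):
        clusters = [CommunityCluster(1, [
            Community("s1", frozenset(["a"])),
            Community("s2", frozenset(["a"])),
            Community("s3", frozenset(["a"])),
        ])]
        groups = {"s1": "CD", "s2": "CD", "s3": "UC", "s4": "UC", "s5": "UC"}
        label_community_clusters(clusters, groups)
        # COUNT: CD=2/num 2=1.0 vs UC=1/num 3=0.33
        assert clusters[0].label == "CD"


def toy_taxonomy():
    recs = {
        "g1": TaxonRecord("s1", "gen1", "Firmicutes"),
        "g2": TaxonRecord("s2", "gen2", "Firmicutes"),
        "g3": TaxonRecord("s3", "gen3", "Firmicutes"),
        "g4": TaxonRecord("s4", "gen4", "Proteobacteria"),
    }
    return TaxonomyTable(recs)


class TestComposition:
    def test_fraction_counting_with_multiplicity(self):
        cluster = CommunityCluster(1, [
            Community("s1", frozenset(["g1", "g2"])),
            Community("s2", frozenset(["g3", "g4"])),
        ])
        prof = cluster_composition(cluster, toy_taxonomy(), "phylum")
        assert prof.fractions == {"Firmicutes": 0.75, "Proteobacteria": 0.25}
        assert sum(prof.fractions.values()) == pytest.approx(1.0)

    def test_single_genome_cluster(self):
        cluster = CommunityCluster(1, [Community("s1", frozenset(["g4"]))])
        prof = cluster_composition(cluster, toy_taxonomy(), "phylum")
        assert prof.fractions == {"Proteobacteria": 1.0}

    def test_unresolvable_genome_names_accession(self):
        from hgtnet.errors import TaxonomyLookupError

        cluster = CommunityCluster(1, [Community("s1", frozenset(["gX"]))])
        with pytest.raises(TaxonomyLookupError, match="gX"):
            cluster_composition(cluster, toy_taxonomy(), "phylum")


class TestCompareCompositions:
    def _profiles(self, fracs, taxon="Proteobacteria"):
        from hgtnet.communities import CompositionProfile

        return [CompositionProfile("phylum", {taxon: f, "Other": 1 - f})
                for f in fracs]

    def test_identical_sides(self):
        p = self._profiles([0.2, 0.4, 0.6])
        res = compare_compositions(p, self._profiles([0.2, 0.4, 0.6]),
                                   "Proteobacteria")
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_strong_separation_with_direction(self):
        rng = np.random.default_rng(1)
        a = self._profiles(0.7 + rng.normal(0, 0.01, 10))
        b = self._profiles(0.1 + rng.normal(0, 0.01, 10))
        res = compare_compositions(a, b, "Proteobacteria")
        assert res.p_value < 1e-6 and res.direction == "a>b"

    def test_absent_taxon_counts_as_zero(self):
        a = self._profiles([0.5, 0.6, 0.7])
        b = self._profiles([0.3, 0.2, 0.25], taxon="Actinobacteria")
        res = compare_compositions(a, b, "Proteobacteria")
        assert res.mean_b == 0.0 and res.mean_a > 0

    def test_insufficient_clusters(self):
        with pytest.raises(InsufficientDataError):
            compare_compositions(self._profiles([0.5]), self._profiles([0.1, 0.2]),
                                 "Proteobacteria")
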