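import itertools

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from effectorkit.cluster import (
    Cluster,
    MCLParams,
    build_graph,
    evalue_weight,
    find_pioneers,
    label_and_find_core,
    mcl_cluster,
)
from effectorkit.io_formats import AnnotationRecord, SimilarityEdge

from _mcl_reference import reference_mcl


def edge(q, s, ev):
    return SimilarityEdge(q, s, ev, 90.0, 100, 250.0, 100)


class TestBuildGraph:
    def test_weight_is_minus_log10_evalue(self):
        g = build_graph([edge("a", "b", 1e-40)]).graph
        assert g["a"]["b"]["weight"] == pytest.approx(40.0)

    def test_edge_above_threshold_dropped(self):
        g = build_graph([edge("a", "b", 1e-30)]).graph
        assert not g.has_edge("a", "b")

    def test_evalue_zero_capped_at_200(self):
        g = build_graph([edge("a", "b", 0.0)]).graph
        assert g["a"]["b"]["weight"] == 200.0

    def test_reciprocal_edges_merged_max_weight(self):
        g = build_graph([edge("a", "b", 1e-40), edge("b", "a", 1e-60)]).graph
        assert g["a"]["b"]["weight"] == pytest.approx(60.0)

    def test_self_hits_dropped_and_universe_kept(self):
        g = build_graph([edge("a", "a", 1e-80)], node_universe=["a", "b", "c"]).graph
        assert set(g.nodes) == {"a", "b", "c"}
        assert g.number_of_edges() == 0

    def test_negative_evalue_rejected(self):
        with pytest.raises(ValueError):
            evalue_weight(-1.0)


def clique_edges(names, ev=1e-50):
    return [edge(a, b, ev) for a, b in itertools.permutations(names, 2)]


class TestMCL:
    def test_two_cliques_two_clusters(self):
        edges = clique_edges("abc") + clique_edges("xyz")
        clusters = mcl_cluster(build_graph(edges))
        assert {c.members for c in clusters} == {frozenset("abc"), frozenset("xyz")}

    def test_edgeless_node_is_singleton(self):
        clusters = mcl_cluster(build_graph([], node_universe=["lonely"]))
        assert [c.members for c in clusters] == [frozenset(["lonely"])]

    def test_barbell_matches_reference_implementation(self):
        """Two 3-cliques joined through one bridge node, inflation 6."""
        edges = clique_edges("abc") + clique_edges("xyz")
        edges += [edge("c", "m", 1e-50), edge("m", "c", 1e-50),
                  edge("m", "x", 1e-50), edge("x", "m", 1e-50)]
        g = build_graph(edges)
        ours = {c.members for c in mcl_cluster(g)}
        ref = reference_mcl(
            list(g.graph.nodes),
            [(u, v, d["weight"]) for u, v, d in g.graph.edges(data=True)],
        )
        assert ours == ref

    def test_partition_property(self):
        edges = clique_edges("abcd") + clique_edges("xy") + [edge("d", "x", 1e-40)]
        g = build_graph(edges, node_universe=list("abcdxyzw"))
        clusters = mcl_cluster(g)
        members = [m for c in clusters for m in c.members]
        assert sorted(members) == sorted("abcdxyzw")

    def test_interpretation_idempotent(self):
        edges = clique_edges("abc") + clique_edges("xyz")
        g = build_graph(edges)
        once = {c.members for c in mcl_cluster(g)}
        twice = {c.members for c in mcl_cluster(g)}
        assert once == twice

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError):
            MCLParams(inflation=1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.data())
    def test_random_small_graphs_match_reference(self, data):
        n = data.draw(st.integers(min_value=2, max_value=8))
        nodes = [f"n{i}" for i in range(n)]
        possible = list(itertools.combinations(nodes, 2))
        chosen = data.draw(st.lists(st.sampled_from(possible), unique=True, max_size=len(possible)))
        weights = data.draw(st.lists(st.integers(min_value=36, max_value=120),
                                     min_size=len(chosen), max_size=len(chosen)))
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for (u, v), w in zip(chosen, weights):
            g.add_edge(u, v, weight=float(w))
        ours = {c.members for c in mcl_cluster(g)}
        ref = reference_mcl(nodes, [(u, v, d["weight"]) for u, v, d in g.edges(data=True)])
        assert ours == ref
        # and always a partition
        assert sorted(m for c in ours for m in c) == sorted(nodes)


def make_cluster(cid, members):
    return Cluster(id=cid, members=frozenset(members))


class TestCoreClusters:
    DATASET_OF = {f"{d}_g": d for d in "ABCDEFGH"}

    def _clusters(self, datasets):
        return [make_cluster(0, [f"{d}_g" for d in datasets])]

    def test_effector_cluster_in_five_datasets_is_core(self):
        labelled, core = label_and_find_core(
            self._clusters("ABCDE"), {"A_g"}, self.DATASET_OF, min_datasets=5
        )
        assert len(core) == 1 and labelled[0].contains_effector

    def test_four_datasets_not_core(self):
        _, core = label_and_find_core(
            self._clusters("ABCD"), {"A_g"}, self.DATASET_OF, min_datasets=5
        )
        assert core == []

    def test_non_effector_cluster_never_core(self):
        _, core = label_and_find_core(
            self._clusters("ABCDEFGH"), set(), self.DATASET_OF, min_datasets=5
        )
        assert core == []

    def test_outgroup_datasets_not_counted(self):
        dataset_of = dict(self.DATASET_OF, out_g="Outgroup")
        clusters = [make_cluster(0, ["A_g", "B_g", "C_g", "D_g", "out_g"])]
        _, core = label_and_find_core(
            clusters, {"A_g"}, dataset_of, min_datasets=5, aphid_datasets=set("ABCDEFGH")
        )
        assert core == []

    def test_unmapped_member_raises(self):
        with pytest.raises(KeyError):
            label_and_find_core([make_cluster(0, ["ghost"])], set(), {})


class TestPioneers:
    GENUS = {"A": "Myzus", "B": "Myzus", "C": "Rhopalosiphum"}

    def _ann(self, sid, ev=None, pfam=False):
        return AnnotationRecord(sid, True, False, False, ev, pfam)

    def test_hitless_single_species_effector_cluster_is_pioneer(self):
        anns = {"A_1": self._ann("A_1"), "A_2": self._ann("A_2")}
        clusters = [make_cluster(0, ["A_1", "A_2"])]
        out = find_pioneers(clusters, anns, {"A_1"}, {"A_1": "A", "A_2": "A"}, self.GENUS)
        assert len(out) == 1

    def test_single_genus_two_species_still_pioneer(self):
        anns = {"A_1": self._ann("A_1"), "B_1": self._ann("B_1")}
        clusters = [make_cluster(0, ["A_1", "B_1"])]
        out = find_pioneers(clusters, anns, {"A_1"}, {"A_1": "A", "B_1": "B"}, self.GENUS)
        assert len(out) == 1

    def test_pfam_domain_disqualifies(self):
        anns = {"A_1": self._ann("A_1"), "A_2": self._ann("A_2", pfam=True)}
        clusters = [make_cluster(0, ["A_1", "A_2"])]
        assert find_pioneers(clusters, anns, {"A_1"}, {"A_1": "A", "A_2": "A"}, self.GENUS) == []

    def test_strong_db_hit_disqualifies(self):
        anns = {"A_1": self._ann("A_1", ev=1e-20)}
        clusters = [make_cluster(0, ["A_1"])]
        assert find_pioneers(clusters, anns, {"A_1"}, {"A_1": "A"}, self.GENUS) == []

    def test_weak_db_hit_does_not_disqualify(self):
        anns = {"A_1": self._ann("A_1", ev=1e-3)}
        clusters = [make_cluster(0, ["A_1"])]
        assert len(find_pioneers(clusters, anns, {"A_1"}, {"A_1": "A"}, self.GENUS)) == 1

    def test_two_genera_disqualify(self):
        anns = {"A_1": self._ann("A_1"), "C_1": self._ann("C_1")}
        clusters = [make_cluster(0, ["A_1", "C_1"])]
        assert find_pioneers(clusters, anns, {"A_1"}, {"A_1": "A", "C_1": "C"}, self.GENUS) == []

    def test_missing_genus_mapping_raises(self):
        anns = {"A_1": self._ann("A_1")}
        clusters = [make_cluster(0, ["A_1"])]
        with pytest.raises(KeyError, match="genus"):
            find_pioneers(clusters, anns, {"A_1"}, {"A_1": "A"}, {})
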