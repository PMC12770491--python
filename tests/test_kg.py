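"""Condition knowledge graph: co-occurrence normalisation, signatures,
inverse-L2 and Jaccard edges, retention cuts and assembled-graph contracts."""

import itertools

import numpy as np
import pytest

from knowrare.experiment import _tensors_by_condition
from knowrare.kg import (R1_DIAGNOSIS, R2_RECORD, R3_DRUG, assemble_graph,
                         build_condition_graph, condition_signatures,
                         cooccurrence_edges, drug_edges, prune_graph, record_edges)


class TestCooccurrence:
    def test_row_normalised_weights(self):
        # v1 co-occurs with v2 in 3 records, with v3 in 1
        records = [{"v1", "v2"}] * 3 + [{"v1", "v3"}]
        w = {(h, t): x for h, t, x in cooccurrence_edges(records)}
        assert w[("v1", "v2")] == 0.75
        assert w[("v1", "v3")] == 0.25
        assert w[("v2", "v1")] == 1.0

    def test_single_partner_weight_one(self):
        w = {(h, t): x for h, t, x in cooccurrence_edges([{"a", "b"}])}
        assert w == {("a", "b"): 1.0, ("b", "a"): 1.0}

    def test_brute_force_oracle(self, rng):
        codes = [f"c{i}" for i in range(8)]
        records = [set(rng.choice(codes, size=rng.integers(2, 5), replace=False))
                   for _ in range(200)]
        got = {(h, t): w for h, t, w in cooccurrence_edges(records)}
        # oracle: nested loop over ordered pairs and records
        for vi in codes:
            for vj in codes:
                if vi == vj:
                    continue
                co = sum(1 for r in records if vi in r and vj in r)
                tot = sum(1 for vk in codes if vk != vi
                          for r in records if vi in r and vk in r)
                if co:
                    assert abs(got[(vi, vj)] - co / tot) < 1e-12
                else:
                    assert (vi, vj) not in got

    def test_outgoing_weights_sum_to_one(self, rng):
        codes = [f"c{i}" for i in range(6)]
        records = [set(rng.choice(codes, size=3, replace=False)) for _ in range(50)]
        edges = cooccurrence_edges(records)
        heads = {h for h, _, _ in edges}
        for head in heads:
            total = sum(w for h, _, w in edges if h == head)
            assert abs(total - 1.0) < 1e-9

    def test_asymmetry_counter_example(self):
        # v1's only partner is v2, but v2 splits its mass with v3
        records = [{"v1", "v2"}, {"v2", "v3"}]
        w = {(h, t): x for h, t, x in cooccurrence_edges(records)}
        assert w[("v1", "v2")] == 1.0
        assert w[("v2", "v1")] == 0.5


class TestSignatures:
    def test_single_patient_zero_std(self, rng):
        X = rng.normal(size=(1, 4, 3))
        s = condition_signatures({"a": X})["a"]
        assert len(s) == 2 * 4 * 3
        np.testing.assert_allclose(s[12:], 0.0)
        np.testing.assert_allclose(s[:12], X[0].ravel())

    def test_identical_patients_zero_std(self, rng):
        one = rng.normal(size=(4, 3))
        s = condition_signatures({"a": np.stack([one, one])})["a"]
        np.testing.assert_allclose(s[:12], one.ravel())
        np.testing.assert_allclose(s[12:], 0.0)

    def test_per_cell_loop_oracle(self, rng):
        X = rng.normal(size=(5, 3, 2))
        s = condition_signatures({"a": X})["a"]
        for t in range(3):
            for v in range(2):
                cell = X[:, t, v]
                assert abs(s[t * 2 + v] - cell.mean()) < 1e-12
                assert abs(s[6 + t * 2 + v] - cell.std()) < 1e-12

    def test_empty_condition_absent(self):
        assert condition_signatures({"a": np.zeros((0, 2, 2))}) == {}


class TestRecordEdges:
    def test_identical_signatures_weight_one(self):
        sigs = {"a": np.zeros(4), "b": np.zeros(4)}
        assert record_edges(sigs) == [("a", "b", 1.0)]

    def test_unit_distance_weight_half(self):
        sigs = {"a": np.zeros(4), "b": np.array([1.0, 0, 0, 0])}
        assert record_edges(sigs)[0][2] == 0.5

    def test_brute_force_retention(self, rng):
        sigs = {f"c{i}": rng.normal(size=6) for i in range(6)}
        got = {(h, t) for h, t, _ in record_edges(sigs, 0.5)}
        pairs = {}
        for a, b in itertools.combinations(sorted(sigs), 2):
            pairs[(a, b)] = 1.0 / (1.0 + np.linalg.norm(sigs[a] - sigs[b]))
        cut = sorted(pairs.values(), reverse=True)[int(np.ceil(0.5 * len(pairs))) - 1]
        expected = {p for p, w in pairs.items() if w >= cut}
        assert got == expected


class TestDrugEdges:
    def test_jaccard_values(self):
        sets = {"a": {1, 2, 3}, "b": {2, 3, 4}}
        assert drug_edges(sets, 1.0) == [("a", "b", 0.5)]

    def test_disjoint_dropped(self):
        assert drug_edges({"a": {1}, "b": {2}}, 1.0) == []

    def test_identical_sets_weight_one(self):
        assert drug_edges({"a": {1, 2}, "b": {1, 2}}, 1.0) == [("a", "b", 1.0)]

    def test_both_empty_skipped(self):
        assert drug_edges({"a": set(), "b": set()}, 1.0) == []


class TestAssembleAndPrune:
    def test_isolated_nodes_allowed(self):
        g = assemble_graph([], [], [], nodes=["a", "b"])
        assert g.nodes == ["a", "b"]
        assert g.directed_edges() == []

    def test_duplicate_edges_rejected(self):
        with pytest.raises(ValueError):
            assemble_graph([("a", "b", 0.5), ("a", "b", 0.7)], [], [])
        with pytest.raises(ValueError):
            assemble_graph([], [], [("a", "b", 0.5), ("b", "a", 0.5)])

    def test_self_loops_rejected(self):
        with pytest.raises(ValueError):
            assemble_graph([("a", "a", 1.0)], [], [])

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            assemble_graph([("a", "b", 1.0)], [], [], nodes=["a"])

    def test_edge_counts_and_symmetry_expansion(self):
        g = assemble_graph([("a", "b", 1.0)], [("a", "c", 0.4)], [("b", "c", 0.2)])
        assert len(g.relation_edges(R1_DIAGNOSIS)) == 1
        directed = g.directed_edges()
        assert len(directed) == 1 + 2 + 2  # symmetric relations both ways
        assert ("c", "a", R2_RECORD, 0.4) in directed

    def test_prune_identity(self):
        g = assemble_graph([("a", "b", 1.0), ("b", "c", 0.5)], [], [])
        assert prune_graph(g, 1.0).edges == g.edges

    def test_prune_keeps_largest(self):
        edges = [(f"n{i}", f"n{i+1}", w) for i, w in
                 enumerate([0.1, 0.9, 0.5, 0.8, 0.3, 0.7, 0.2, 0.6, 0.4, 0.95])]
        g = assemble_graph(edges, [], [])
        pruned = prune_graph(g, 0.5).relation_edges(R1_DIAGNOSIS)
        assert sorted(w for _, _, w in pruned) == [0.6, 0.7, 0.8, 0.9, 0.95]

    def test_prune_ties_all_retained(self):
        edges = [("a", "b", 0.5), ("b", "c", 0.5), ("c", "d", 0.5), ("d", "e", 0.9)]
        g = assemble_graph(edges, [], [])
        pruned = prune_graph(g, 0.5).relation_edges(R1_DIAGNOSIS)
        assert len(pruned) == 4  # cut lands on the tied weight; all kept

    def test_bad_fraction(self):
        g = assemble_graph([("a", "b", 1.0)], [], [])
        with pytest.raises(ValueError):
            prune_graph(g, 0.0)


class TestClusterSignal:
    def test_intra_cluster_edges_outweigh_inter(self, small_cohort, small_preprocessed):
        """With strong planted similarity, each relation weights same-cluster
        pairs above cross-cluster pairs on average."""
        pre = small_preprocessed
        truth = small_cohort.cluster_assignment
        graph = build_condition_graph(
            pre.diagnosis_records, _tensors_by_condition(pre), pre.drug_sets,
            nodes=sorted(np.unique(pre.condition["train"])))
        for rel in (R1_DIAGNOSIS, R2_RECORD, R3_DRUG):
            intra = [w for h, t, w in graph.relation_edges(rel) if truth[h] == truth[t]]
            inter = [w for h, t, w in graph.relation_edges(rel) if truth[h] != truth[t]]
            assert intra, f"{rel}: no intra-cluster edges"
            if inter:
                assert np.mean(intra) > np.mean(inter), rel

    def test_weight_ranges(self, small_preprocessed):
        pre = small_preprocessed
        graph = build_condition_graph(
            pre.diagnosis_records, _tensors_by_condition(pre), pre.drug_sets,
            nodes=sorted(np.unique(pre.condition["train"])))
        for rel, lo_open in ((R1_DIAGNOSIS, False), (R2_RECORD, True), (R3_DRUG, False)):
            for _, _, w in graph.relation_edges(rel):
                assert 0 <= w <= 1
                if lo_open:
                    assert w > 0
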