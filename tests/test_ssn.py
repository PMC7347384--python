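"""Pairwise scoring, E-values, network construction, and exclusivity search."""

import math

import networkx as nx
import numpy as np
import pytest

from butenolide_scout import ssn
from butenolide_scout.ssn import (
    SeqRecord,
    SSNGraph,
    align_pair,
    build_ssn,
    components,
    evalue,
    exclusivity,
    find_exclusive_threshold,
)


class TestAlignPair:
    def test_self_alignment_is_sum_of_diagonal_matrix_entries(self):
        # BLOSUM62 diagonal for H,E,A,G,A,W,G,H,E,E sums to 62
        rec = SeqRecord("a", "HEAGAWGHEE")
        assert align_pair(rec, SeqRecord("b", "HEAGAWGHEE")).raw_score == 62.0

    def test_no_positive_scoring_pair_gives_zero_local_score(self):
        # BLOSUM62 Ala/Thr entry is 0, so the best local alignment scores 0
        ps = align_pair(SeqRecord("a", "AAAA"), SeqRecord("b", "TTTT"))
        assert ps.raw_score == 0.0
        # a zero-bit-equivalent score never produces an edge at real cutoffs
        assert ps.e_value > 1e-10

    def test_symmetry(self):
        a = SeqRecord("a", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")
        b = SeqRecord("b", "MKSAYIAKQRQISFVKSHFSRQREERLGLIE")
        fwd, rev = align_pair(a, b), align_pair(b, a)
        assert fwd.raw_score == rev.raw_score
        assert fwd.bit_score == rev.bit_score
        assert fwd.e_value == rev.e_value

    @pytest.mark.parametrize("bad", ["", "ACDB1", "MK-TA"])
    def test_invalid_sequences_rejected(self, bad):
        with pytest.raises(ValueError):
            SeqRecord("x", bad)


class TestEvalue:
    def test_direct_arithmetic(self):
        assert evalue(20.0, 100, 100) == pytest.approx(1e4 * 2**-20.0, rel=1e-12)
        assert evalue(0.0, 1, 1) == 1.0

    def test_monotone_in_bit_score_and_search_space(self):
        assert evalue(30.0, 100, 100) < evalue(20.0, 100, 100)
        assert evalue(20.0, 200, 100) > evalue(20.0, 100, 100)

    def test_no_underflow_at_huge_bit_scores(self):
        assert evalue(5000.0, 500, 50000) > 0.0

    def test_invalid_lengths(self):
        with pytest.raises(ValueError):
            evalue(10.0, 0, 100)


class TestBuildSsn:
    def test_single_record_graph(self):
        g = build_ssn([SeqRecord("only", "MKT" * 40)], threshold=1e-10)
        assert g.nodes == {"only"} and g.edges == []

    def test_identical_pair_connected_at_strict_cutoff(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQFEVVHSLAKWKRQ"
        recs = [SeqRecord("a", seq[:100] if len(seq) >= 100 else seq * 2),
                SeqRecord("b", seq[:100] if len(seq) >= 100 else seq * 2)]
        g = build_ssn(recs, threshold=1e-10)
        assert ("a", "b") in [(u, v) for u, v, _ in g.edges]

    def test_duplicate_ids_rejected(self):
        recs = [SeqRecord("a", "MKTA" * 10), SeqRecord("a", "MKTV" * 10)]
        with pytest.raises(ValueError, match="duplicate"):
            build_ssn(recs, threshold=1.0)

    def test_edge_set_monotone_in_threshold(self, three_family_records):
        records, _ = three_family_records
        strict = build_ssn(records, threshold=1e-80)
        loose = build_ssn(records, threshold=1e-70)
        strict_edges = {frozenset(e[:2]) for e in strict.edges}
        loose_edges = {frozenset(e[:2]) for e in loose.edges}
        assert strict_edges <= loose_edges

    def test_every_edge_within_threshold(self, three_family_records):
        records, _ = three_family_records
        g = build_ssn(records, threshold=1e-30)
        assert all(e <= 1e-30 for _, _, e in g.edges)


class TestComponents:
    def test_no_edges_gives_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        assert components(SSNGraph(graph=g, threshold=1.0)) == [{"a"}, {"b"}, {"c"}]

    def test_two_cliques(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("x", "y")])
        assert len(components(SSNGraph(graph=g, threshold=1.0))) == 2

    def test_agrees_with_transitive_closure_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = 20
            adj = rng.random((n, n)) < 0.08
            adj = np.triu(adj, 1)
            adj = adj | adj.T | np.eye(n, dtype=bool)
            # oracle: boolean-matrix closure
            reach = adj.copy()
            for _ in range(n):
                reach = reach | (reach @ adj)
            oracle = {frozenset(np.flatnonzero(reach[i]).tolist()) for i in range(n)}
            g = nx.Graph()
            g.add_nodes_from(range(n))
            g.add_edges_from(zip(*np.nonzero(np.triu(adj, 1))))
            got = {frozenset(c) for c in components(SSNGraph(graph=g, threshold=1.0))}
            assert got == oracle


class TestExclusivity:
    def test_single_label_single_component(self):
        r = exclusivity([{"a", "b"}], {"a": "GBL", "b": "GBL"})
        assert r.is_exclusive and r.impure_components == 0

    def test_mixed_component_is_impure(self):
        r = exclusivity([{"a", "b"}], {"a": "GBL", "b": "butenolide"})
        assert not r.is_exclusive and r.impure_components == 1

    def test_label_split_over_pure_components_still_exclusive(self):
        r = exclusivity([{"a"}, {"b"}], {"a": "GBL", "b": "GBL"})
        assert r.is_exclusive

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            exclusivity([{"a"}], {"zzz": "GBL"})


class TestFindExclusiveThreshold:
    def test_identical_sequences_two_labels_inseparable(self):
        # long enough that the pair E-value beats even the strictest grid
        # cutoff, so no threshold can cut the inter-label edge
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSG" * 6
        recs = [SeqRecord("a", seq, label="GBL"), SeqRecord("b", seq, label="butenolide")]
        assert find_exclusive_threshold(recs) is None

    def test_single_label_returns_most_permissive_grid_value(self):
        recs = [SeqRecord("a", "MKTA" * 30, label="GBL"),
                SeqRecord("b", "MKTA" * 30, label="GBL")]
        assert find_exclusive_threshold(recs) == max(ssn.default_threshold_grid())

    def test_separating_threshold_found_and_stricter_values_stay_exclusive(
        self, three_family_records
    ):
        records, _ = three_family_records
        labels = {r.id: r.label for r in records}
        grid = ssn.default_threshold_grid()
        found = find_exclusive_threshold(records, labels, grid)
        assert found is not None
        # oracle: scan the whole grid; exclusivity must hold for every
        # threshold at or below the chosen one
        for t in grid:
            report = exclusivity(components(build_ssn(records, t)), labels)
            if t <= found:
                assert report.is_exclusive, f"threshold {t} not exclusive"

    def test_families_form_one_component_each_at_found_threshold(
        self, three_family_records
    ):
        records, _ = three_family_records
        labels = {r.id: r.label for r in records}
        found = find_exclusive_threshold(records, labels)
        comps = components(build_ssn(records, found))
        labeled = [c for c in comps if any(i in labels for i in c)]
        assert len(labeled) == 3
        for c in labeled:
            assert len({labels[i] for i in c}) == 1


def test_edge_list_roundtrip(tmp_path, three_family_records):
    records, _ = three_family_records
    g = build_ssn(records[:6], threshold=1e-20)
    path = tmp_path / "edges.tsv"
    ssn.write_edge_list(g, path)
    lines = path.read_text().strip().split("\n")
    assert lines[0] == "source\ttarget\te_value\tbit_score"
    assert len(lines) - 1 == len(g.edges)
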