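"""Candidate selection, bipartite network statistics, and the exact 2x2 test."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hcscnet import (
    CandidateInteraction,
    ContingencyTable2x2,
    assemble_tripartite,
    build_network,
    candidate_interactions,
    connected_components,
    fisher_exact_2x2,
    load_summary_fixture,
    expand_summary_to_interactions,
    nod,
    nod_exclusivity_test,
    split_by_mirna_direction,
    summarize_interaction_table,
    unique_target_genes,
)
from hcscnet.targets import AnnotatedInteraction

from _oracles import components_oracle, fisher_oracle, nod_oracle


def _ann(m, g, md, gd):
    return AnnotatedInteraction(m, g, md, gd)


def _random_bipartite(rng):
    n_m = int(rng.integers(1, 8))
    n_g = int(rng.integers(1, 20))
    edges = set()
    for _ in range(int(rng.integers(0, 40))):
        edges.add((f"m{rng.integers(n_m)}", f"g{rng.integers(n_g)}"))
    cands = [CandidateInteraction(m, g, "up", "down") for m, g in sorted(edges)]
    return cands, sorted(edges)


class TestCandidateSelection:
    def test_anti_correlated_retained_same_direction_dropped(self):
        rows = [_ann("m1", "g1", "up", "down"), _ann("m1", "g2", "up", "up")]
        cands = candidate_interactions(rows)
        assert [(c.mirna_id, c.gene_id) for c in cands] == [("m1", "g1")]

    def test_down_mirna_with_only_down_targets_has_zero_candidates(self):
        rows = [_ann("m1", "g1", "down", "down"), _ann("m1", "g2", "down", "down")]
        assert candidate_interactions(rows) == []

    def test_missing_direction_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            candidate_interactions([AnnotatedInteraction("m", "g", "up", None)])

    @settings(max_examples=100)
    @given(seed=st.integers(0, 10**6))
    def test_count_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        rows = [
            _ann(f"m{i%4}", f"g{i}", rng.choice(["up", "down"]), rng.choice(["up", "down"]))
            for i in range(int(rng.integers(1, 50)))
        ]
        brute = sum(1 for r in rows if r.mirna_direction != r.gene_direction)
        assert len(candidate_interactions(rows)) == brute


class TestNetwork:
    def test_empty_candidates_empty_network(self):
        net = build_network([])
        assert net.number_of_nodes() == 0 and net.number_of_edges() == 0

    def test_star_counts_and_node_size_attribute(self):
        cands = [CandidateInteraction("m1", f"g{i}", "up", "down") for i in range(3)]
        net = build_network(cands)
        assert net.number_of_nodes() == 4 and net.number_of_edges() == 3
        assert net.nodes["m1"]["candidate_targets"] == 3

    def test_nod_definition_limits(self):
        # every gene targeted by >=2 miRNAs -> all NOD 0
        shared = [
            CandidateInteraction(m, g, "up", "down")
            for m in ("m1", "m2")
            for g in ("g1", "g2")
        ]
        assert set(nod(build_network(shared)).values()) == {0}
        # one-miRNA star -> NOD = k
        star = [CandidateInteraction("m1", f"g{i}", "up", "down") for i in range(5)]
        assert nod(build_network(star)) == {"m1": 5}

    @settings(max_examples=150)
    @given(seed=st.integers(0, 10**6))
    def test_nod_and_components_match_oracles(self, seed):
        rng = np.random.default_rng(seed)
        cands, edges = _random_bipartite(rng)
        net = build_network(cands)
        assert nod(net) == nod_oracle(edges)
        assert len(connected_components(net)) == components_oracle(edges, list(net.nodes))
        # sum of NODs never exceeds the number of distinct target genes
        genes = {g for _, g in edges}
        assert sum(nod(net).values()) <= len(genes)

    def test_component_ordering_deterministic(self):
        cands = [
            CandidateInteraction("m1", "g1", "up", "down"),
            CandidateInteraction("m2", "g2", "up", "down"),
            CandidateInteraction("m2", "g3", "up", "down"),
        ]
        comps = connected_components(build_network(cands))
        assert comps == [frozenset({"m2", "g2", "g3"}), frozenset({"m1", "g1"})]


class TestFisherExact:
    def test_flat_table_two_sided_is_one(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_enumerated_example(self):
        assert fisher_exact_2x2([[3, 1], [1, 3]]) == pytest.approx(34 / 70, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)

    @settings(max_examples=200)
    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    def test_matches_enumeration_and_scipy(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        for alternative in ("two-sided", "greater"):
            ours = fisher_exact_2x2([[a, b], [c, d]], alternative)
            assert ours == pytest.approx(fisher_oracle(a, b, c, d, alternative), abs=1e-10)
            scipy_p = stats.fisher_exact([[a, b], [c, d]], alternative)[1]
            assert ours == pytest.approx(scipy_p, abs=1e-8)

    def test_exclusivity_reconstruction_runs(self):
        df = load_summary_fixture()
        annotated, _, _ = expand_summary_to_interactions(df)
        up_net, down_net = split_by_mirna_direction(candidate_interactions(annotated))
        table, p = nod_exclusivity_test(up_net, down_net)
        assert 0 <= p <= 1
        assert table.a + table.b == sum(
            1 for _, d in up_net.nodes(data=True) if d.get("kind") == "gene"
        )


class TestTripartiteAndSummary:
    def _cands(self):
        return [
            CandidateInteraction("m1", "g1", "up", "down"),
            CandidateInteraction("m1", "g2", "up", "down"),
            CandidateInteraction("m2", "g2", "up", "down"),
        ]

    def test_no_enrichment_equals_bipartite(self):
        tri = assemble_tripartite(self._cands(), pd.DataFrame())
        assert tri.number_of_edges() == 3

    def test_pathway_adds_node_and_membership_edges(self):
        enr = pd.DataFrame(
            [{"mirna_id": "m1", "pathway_id": "pw1", "pathway_name": "P",
              "overlap_genes": ("g1", "g2")}]
        )
        tri = assemble_tripartite(self._cands(), enr)
        assert tri.number_of_nodes() == 5  # 2 miRNA + 2 gene + 1 pathway
        assert tri.number_of_edges() == 5  # 3 repression + 2 membership
        assert tri.nodes["g1"].get("unique_regulator") is True
        assert tri.nodes["g2"].get("unique_regulator") is None

    def test_dangling_overlap_gene_rejected(self):
        enr = pd.DataFrame(
            [{"mirna_id": "m1", "pathway_id": "pw1", "pathway_name": "P",
              "overlap_genes": ("g-missing",)}]
        )
        with pytest.raises(ValueError, match="g-missing"):
            assemble_tripartite(self._cands(), enr)

    def test_flagged_genes_match_nod_oracle(self):
        cands = self._cands()
        tri = assemble_tripartite(cands, pd.DataFrame())
        flagged = {g for g, d in tri.nodes(data=True) if d.get("unique_regulator")}
        oracle = nod_oracle([(c.mirna_id, c.gene_id) for c in cands])
        assert len(flagged) == sum(oracle.values())
        assert flagged == set(unique_target_genes(build_network(cands)))

    def test_summary_zero_de_mirna_row(self):
        frame = summarize_interaction_table({"m-silent": "up"}, [], [])
        row = frame.iloc[0]
        assert (row.de_targets, row.up_targets, row.down_targets, row.candidates) == (0, 0, 0, 0)
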