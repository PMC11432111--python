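"""Hypergeometric enrichment, ancestor collapsing and marker selection."""

from __future__ import annotations

from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from methylage import enrichment as enr
from methylage import synthetic_data as synth


def exact_tail(N, K, n, k):
    """P(X >= k) by explicit enumeration of the hypergeometric pmf."""
    return sum(
        comb(K, i) * comb(N - K, n - i) / comb(N, n)
        for i in range(k, min(K, n) + 1)
    )


def toy_annotation(term_genes):
    dag = nx.DiGraph()
    dag.add_node("root")
    return enr.GOAnnotation(dag, term_genes, {})


class TestHypergeometric:
    def test_query_equal_to_background_gives_p_one(self):
        background = {f"g{i}" for i in range(10)}
        ann = toy_annotation({"T1": {"g0", "g1", "g2"}})
        out = enr.hypergeometric_enrichment(background, background, ann)
        assert out["pvalue"].item() == pytest.approx(1.0)

    def test_disjoint_query_and_term_gives_p_one(self):
        background = {f"g{i}" for i in range(20)}
        ann = toy_annotation({"T1": {"g0", "g1"}})
        out = enr.hypergeometric_enrichment({"g10", "g11"}, background, ann)
        assert out["pvalue"].item() == pytest.approx(1.0)

    def test_fully_annotated_query_matches_exact_enumeration(self):
        background = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(10)}
        query = {f"g{i}" for i in range(5)}
        ann = toy_annotation({"T1": term})
        out = enr.hypergeometric_enrichment(query, background, ann)
        assert out["pvalue"].item() == pytest.approx(exact_tail(20, 10, 5, 5))

    @pytest.mark.parametrize("seed", [31, 32, 33])
    def test_random_instances_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(10, 31))
        background = {f"g{i}" for i in range(N)}
        terms = {}
        for t in range(4):
            K = int(rng.integers(1, N + 1))
            terms[f"T{t}"] = set(
                rng.choice(sorted(background), size=K, replace=False)
            )
        n = int(rng.integers(1, N))
        query = set(rng.choice(sorted(background), size=n, replace=False))
        out = enr.hypergeometric_enrichment(query, background, toy_annotation(terms))
        for row in out.itertuples():
            K = len(terms[row.term])
            k = len(terms[row.term] & query)
            assert row.pvalue == pytest.approx(exact_tail(N, K, n, k))

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            enr.hypergeometric_enrichment(set(), set(), toy_annotation({}))

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError, match="not contained"):
            enr.hypergeometric_enrichment(
                {"x"}, {"a", "b"}, toy_annotation({"T": {"a"}})
            )


class TestAncestorCollapse:
    @pytest.fixture()
    def dag(self):
        g = nx.DiGraph()
        edges = [
            ("L1", "A1"), ("L1", "A2"), ("L2", "A2"), ("L3", "A3"),
            ("A1", "B1"), ("A2", "B1"), ("A3", "B2"),
            ("B1", "root"), ("B2", "root"),
        ]
        g.add_edges_from(edges)
        return g

    def test_hand_computed_closure_on_toy_dag(self, dag):
        # level 2 below root: A1, A2, A3 (leaves L* are level 3)
        assert enr.ancestors_at_level(dag, "L1", "root", 2) == {"A1", "A2"}
        assert enr.ancestors_at_level(dag, "L2", "root", 2) == {"A2"}
        assert enr.ancestors_at_level(dag, "L3", "root", 2) == {"A3"}

    def test_term_at_ancestor_level_maps_to_itself(self, dag):
        assert enr.ancestors_at_level(dag, "A1", "root", 2) == {"A1"}

    def test_union_semantics_for_shared_ancestor(self, dag):
        enriched = pd.DataFrame(
            {
                "term": ["L1", "L2"],
                "genes": ["gA,gB", "gC"],
            }
        )
        out = enr.collapse_to_ancestors(enriched, dag, 2, root="root")
        a2 = out[out["ancestor"] == "A2"].iloc[0]
        assert a2["n_genes"] == 3
        assert set(a2["genes"].split(",")) == {"gA", "gB", "gC"}

    def test_unknown_term_warned_and_skipped(self, dag):
        enriched = pd.DataFrame({"term": ["NOPE"], "genes": ["gA"]})
        with pytest.warns(RuntimeWarning, match="absent"):
            out = enr.collapse_to_ancestors(enriched, dag, 2, root="root")
        assert out.empty

    def test_mini_ontology_loads_with_single_root(self):
        import tempfile, pathlib

        with tempfile.NamedTemporaryFile("w", suffix=".obo") as fh:
            fh.write(synth.mini_ontology_text())
            fh.flush()
            dag, names = enr.load_obo(fh.name)
        root = enr.find_root(dag)
        assert names[root] == "biological_process"
        level2 = {
            n for n in dag if n != root and enr.term_level(dag, n, root) == 2
        }
        assert len(level2) == 8


class TestFixtureIncidence:
    @pytest.fixture()
    def incidence(self):
        return synth.fixture_incidence()

    def test_union_of_process_genes_is_33(self, incidence):
        assert incidence.membership.shape[1] == 33

    def test_function_counts_match_gene_table(self, incidence):
        _, genes = synth.load_table_fixtures()
        counts = incidence.function_counts
        for row in genes.itertuples():
            assert counts[row.gene] == row.n, row.gene

    def test_gene_absent_from_all_processes_counts_zero(self, incidence):
        membership = incidence.membership.copy()
        membership["ghost"] = False
        table = enr.IncidenceTable(
            membership,
            incidence.gene_direction.reindex(membership.columns),
            incidence.gene_regulatory.reindex(membership.columns, fill_value=False),
        )
        assert table.function_counts["ghost"] == 0

    def test_ordering_by_count_matches_gene_table(self, incidence):
        _, genes = synth.load_table_fixtures()
        ordered = enr.multifunction_genes(incidence, 4)
        # same count-sorted multiset: counts agree pairwise
        counts = incidence.function_counts
        fixture_counts = sorted(genes["n"], reverse=True)
        assert sorted((counts[g] for g in ordered), reverse=True) == fixture_counts


class TestMarkerSelection:
    def test_fixture_multifunction_filter_keeps_14(self):
        incidence = synth.fixture_incidence()
        assert len(enr.multifunction_genes(incidence, 4)) == 14

    def test_fixture_regulatory_filter_keeps_the_10_markers(self):
        incidence = synth.fixture_incidence()
        markers = enr.select_markers(incidence, 4, require_regulatory=True)
        assert {m.gene_symbol for m in markers} == {
            "sirt1", "smad1", "ramp1", "psmd2", "col5a1",
            "calcrl", "bmp1", "thrb", "spred2", "atp1a2",
        }

    def test_min_functions_above_max_count_selects_nothing(self):
        incidence = synth.fixture_incidence()
        assert enr.select_markers(incidence, 12) == []

    def test_stable_sort_descending_count_then_symbol(self):
        incidence = synth.fixture_incidence()
        markers = enr.select_markers(incidence, 4)
        keys = [(-m.n_functions, m.gene_symbol) for m in markers]
        assert keys == sorted(keys)

    def test_incidence_invariant_to_row_and_column_order(self):
        incidence = synth.fixture_incidence()
        shuffled = enr.IncidenceTable(
            incidence.membership.iloc[::-1, ::-1],
            incidence.gene_direction,
            incidence.gene_regulatory,
        )
        assert (
            enr.select_markers(shuffled, 4) == enr.select_markers(incidence, 4)
        )
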