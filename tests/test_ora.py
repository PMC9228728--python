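"""Hypergeometric ORA against an exhaustive enumeration oracle; BH correction."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from kinopipe.io import GeneSetCollection, load_fixture_table
from kinopipe.ora import (
    OraQuery,
    benjamini_hochberg,
    hypergeometric_upper_tail,
    map_peptides_to_accessions,
    run_ora,
)


def enumerated_upper_tail(N, K, n, k):
    """Oracle: count all size-n draws from N items (first K marked) whose
    overlap with the marked set is >= k."""
    hits = total = 0
    marked = set(range(K))
    for draw in combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeometric:
    def test_zero_overlap_is_certain(self):
        assert hypergeometric_upper_tail(20, 5, 7, 0) == 1.0

    def test_worked_enumeration_examples(self):
        # all C(10,5)=252 draws enumerated by hand-checkable oracle
        assert hypergeometric_upper_tail(10, 4, 5, 3) == pytest.approx(66 / 252)
        assert hypergeometric_upper_tail(10, 4, 5, 4) == pytest.approx(6 / 252)
        assert enumerated_upper_tail(10, 4, 5, 3) == pytest.approx(66 / 252)

    @pytest.mark.parametrize("N", [1, 4, 8])
    def test_matches_enumeration_exhaustively(self, N):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(K, n) + 1):
                    assert hypergeometric_upper_tail(N, K, n, k) == pytest.approx(
                        enumerated_upper_tail(N, K, n, k), abs=1e-12
                    ), (N, K, n, k)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_upper_tail(10, 12, 5, 1)
        with pytest.raises(ValueError):
            hypergeometric_upper_tail(10, 4, 5, 5)


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        adjusted = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adjusted, [0.04, 0.04, 0.04, 0.04])

    def test_constant_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.2, 0.2, 0.2]), 0.2)

    def test_single_test_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.037]), [0.037])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_order_equivariant(self, p):
        adj = benjamini_hochberg(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (adj <= 1.0 + 1e-15).all()
        # permutation of inputs permutes outputs identically
        perm = np.random.default_rng(0).permutation(len(p))
        adj_perm = benjamini_hochberg(list(np.asarray(p)[perm]))
        np.testing.assert_allclose(adj_perm, adj[perm], rtol=1e-12)
        # monotone w.r.t. raw ordering
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestMapping:
    def test_multiple_sites_on_one_protein_count_once(self):
        records = [r for r in load_fixture_table("MUSCLE_PCEP")
                   if r.direction == "INCREASED"]
        accessions = map_peptides_to_accessions(records)
        syk = [r for r in records if r.uniprot_accession == "P43405"]
        assert len(syk) == 2  # two phosphosites
        assert len(accessions) < len(records)
        assert "P43405" in accessions

    def test_alum_fixture_has_seven_distinct_accessions(self):
        accessions = map_peptides_to_accessions(load_fixture_table("NODE_ALUM"))
        assert len(accessions) == 7

    def test_empty_records_give_empty_set(self):
        assert map_peptides_to_accessions([]) == frozenset()

    def test_unannotated_peptide_rejected(self):
        annotation = pd.DataFrame(
            {"peptide_id": ["p1"], "uniprot_accession": ["Q1"]}
        )
        assert map_peptides_to_accessions(["p1"], annotation) == frozenset({"Q1"})
        with pytest.raises(ValueError, match="no annotation"):
            map_peptides_to_accessions(["p2"], annotation)


def _collection(**sets):
    return GeneSetCollection(
        {pid: (pid.upper(), "SRC", frozenset(members)) for pid, members in sets.items()}
    )


class TestRunOra:
    def test_planted_fully_contained_set_ranks_first(self):
        universe = frozenset(f"g{i}" for i in range(100))
        query = frozenset(f"g{i}" for i in range(10))
        sets = _collection(
            hit=[f"g{i}" for i in range(10)],
            decoy1=[f"g{i}" for i in range(40, 60)],
            decoy2=[f"g{i}" for i in range(5, 45)],
        )
        res = run_ora(OraQuery(query=query, universe=universe, gene_sets=sets))
        assert res.iloc[0]["pathway_id"] == "hit"
        assert res.iloc[0]["overlap"] == 10
        # enumeration is infeasible at N=100; the closed form for a fully
        # contained query is p = 1 / C(100, 10)
        from math import comb

        assert res.iloc[0]["p_raw"] == pytest.approx(1 / comb(100, 10), rel=1e-9)

    def test_no_overlap_gives_p_one_everywhere(self):
        universe = frozenset(f"g{i}" for i in range(30))
        query = frozenset(["g0", "g1"])
        sets = _collection(far=[f"g{i}" for i in range(10, 20)])
        res = run_ora(OraQuery(query=query, universe=universe, gene_sets=sets))
        assert (res["p_raw"] == 1.0).all()

    def test_query_equal_to_universe_does_not_crash(self):
        universe = frozenset(f"g{i}" for i in range(12))
        sets = _collection(s1=["g0", "g1", "zzz_not_in_universe"], s2=["g5"])
        res = run_ora(OraQuery(query=universe, universe=universe, gene_sets=sets))
        assert len(res) == 2
        assert (res["overlap"] == res["set_size_in_universe"]).all()
        assert (res["p_raw"] == 1.0).all()

    def test_deterministic_output(self):
        universe = frozenset(f"g{i}" for i in range(50))
        query = frozenset(f"g{i}" for i in range(0, 50, 5))
        sets = _collection(a=[f"g{i}" for i in range(20)],
                           b=[f"g{i}" for i in range(10, 40)])
        q = OraQuery(query=query, universe=universe, gene_sets=sets)
        pd.testing.assert_frame_equal(run_ora(q), run_ora(q))

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside universe"):
            OraQuery(query=frozenset({"x"}), universe=frozenset({"y"}))
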