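"""Hypergeometric enrichment, chart filtering, term-map edges, comparison."""

import math
from itertools import combinations

import numpy as np
import pytest

from netprio.enrichment import (
    EnrichmentResult,
    GeneSetCollection,
    annotation_chart,
    compare_charts,
    enrichment_map_edges,
    filter_significant,
    hypergeom_tail,
    overlap_coefficient,
    read_gmt,
    write_gmt,
)
from netprio.errors import InputFormatError, InvalidInputError, UnknownGeneError
from netprio.synthetic import generate_gene_sets


def exact_tail(k, n, K, N):
    """Exhaustive enumeration of P(X >= k), X ~ Hypergeom(N, K, n)."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(max(k, 0), min(n, K) + 1)
    ) / total


class TestGmt:
    def test_basic_line(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S1\tGO\tA\tB\tC\n")
        coll = read_gmt(p)
        assert coll.sets["S1"] == ("GO", frozenset("ABC"))

    def test_duplicate_term_errors(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S1\tGO\tA\nS1\tGO\tB\n")
        with pytest.raises(InputFormatError, match="S1"):
            read_gmt(p)

    def test_short_line_reports_line_number(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S1\tGO\tA\nS2\tGO\n")
        with pytest.raises(InputFormatError, match=":2"):
            read_gmt(p)

    def test_duplicate_members_collapsed(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S1\tGO\tA\tA\tB\n")
        assert read_gmt(p).sets["S1"][1] == frozenset("AB")

    def test_round_trip(self, tmp_path):
        coll = generate_gene_sets([f"G{i}" for i in range(60)], 8, 3, 20, rng_seed=2)
        path = tmp_path / "rt.gmt"
        write_gmt(coll, path)
        assert read_gmt(path).sets == coll.sets


class TestHypergeomTail:
    def test_worked_example(self):
        # N=20, n=5, K=5, k=3: sum_{j>=3} C(5,j)C(15,5-j)/C(20,5) = 1126/15504
        assert hypergeom_tail(3, 5, 5, 20) == pytest.approx(1126 / 15504, rel=1e-12)

    def test_whole_universe_set(self):
        assert hypergeom_tail(7, 7, 7, 7) == pytest.approx(1.0)

    def test_matches_enumeration_for_all_small_universes(self):
        """Implementation equals exhaustive enumeration for all N <= 60."""
        rng = np.random.default_rng(41)
        for N in range(2, 61):
            n = int(rng.integers(1, N + 1))
            K = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            assert hypergeom_tail(k, n, K, N) == pytest.approx(
                exact_tail(k, n, K, N), abs=1e-12)

    def test_monotone_in_k(self):
        ps = [hypergeom_tail(k, 10, 15, 50) for k in range(0, 11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestAnnotationChart:
    @pytest.fixture
    def collection(self):
        return GeneSetCollection(sets={
            "T1": ("GO", frozenset({"A", "B", "C", "D", "E"})),
            "T2": ("KEGG", frozenset({"F", "G", "H"})),
            "T3": ("GO", frozenset({"X", "Y"})),
        })

    def test_counts_and_p_values(self, collection):
        background = set("ABCDEFGHXY") | {f"Z{i}" for i in range(10)}
        chart = annotation_chart({"A", "B", "C", "F", "Z0"}, collection, background)
        row = chart.frame.set_index("term").loc["T1"]
        assert (row["k"], row["n"], row["K"], row["N"]) == (3, 5, 5, 20)
        assert row["p_value"] == pytest.approx(1126 / 15504, rel=1e-9)
        assert row["fold_enrichment"] == pytest.approx((3 / 5) / (5 / 20))
        # zero-overlap terms omitted
        assert "T3" not in chart.terms

    def test_ease_at_least_fisher_rowwise(self, collection):
        background = set("ABCDEFGHXY") | {f"Z{i}" for i in range(10)}
        genes = {"A", "B", "C", "F", "G"}
        fisher = annotation_chart(genes, collection, background, "fisher")
        ease = annotation_chart(genes, collection, background, "ease")
        merged = fisher.frame.merge(ease.frame, on="term", suffixes=("_f", "_e"))
        assert (merged["p_value_e"] >= merged["p_value_f"] - 1e-15).all()

    def test_empty_background_rejected(self, collection):
        with pytest.raises(InvalidInputError):
            annotation_chart({"A"}, collection, set())


class TestFilterSignificant:
    def make_chart(self, pvals):
        import pandas as pd

        frame = pd.DataFrame({
            "term": [f"T{i}" for i in range(len(pvals))],
            "category": "GO", "k": 1, "n": 5, "K": 5, "N": 50,
            "p_value": pvals, "fold_enrichment": 1.0,
        })
        return EnrichmentResult(frame=frame)

    def test_strict_inequality_at_alpha(self):
        chart = self.make_chart([0.05, 0.049999, 0.2])
        kept = filter_significant(chart, 0.05)
        assert kept.terms == {"T1"}

    def test_alpha_above_one_keeps_everything(self):
        chart = self.make_chart([0.3, 0.9, 1.0])
        assert len(filter_significant(chart, 1.1)) == 3

    def test_filtered_count_matches_hand_count(self):
        pvals = [0.001, 0.02, 0.04999, 0.05, 0.051, 0.5]
        kept = filter_significant(self.make_chart(pvals), 0.05)
        assert len(kept) == sum(1 for p in pvals if p < 0.05)

    def test_benjamini_hochberg_option(self):
        pvals = [0.001, 0.01, 0.02, 0.8]
        kept = filter_significant(self.make_chart(pvals), 0.05, correct=True)
        # BH-adjusted: 0.004, 0.02, 0.0267, 0.8 -> first three pass
        assert kept.terms == {"T0", "T1", "T2"}


class TestOverlapCoefficient:
    def test_half_overlap(self):
        assert overlap_coefficient({"a", "b"}, {"b", "c"}) == pytest.approx(0.5)

    def test_subset_is_one(self):
        assert overlap_coefficient({"a"}, {"a", "b", "c"}) == 1.0

    def test_empty_set_undefined(self):
        with pytest.raises(InvalidInputError):
            overlap_coefficient(set(), {"a"})

    def test_matches_set_arithmetic_oracle(self):
        rng = np.random.default_rng(6)
        universe = [f"G{i}" for i in range(40)]
        for _ in range(20):
            a = frozenset(rng.choice(universe, size=int(rng.integers(1, 20)), replace=False))
            b = frozenset(rng.choice(universe, size=int(rng.integers(1, 20)), replace=False))
            assert overlap_coefficient(a, b) == len(a & b) / min(len(a), len(b))


class TestEnrichmentMap:
    def make_chart_and_collection(self, n_terms=10, seed=12):
        universe = [f"G{i}" for i in range(80)]
        coll = generate_gene_sets(universe, n_terms, 5, 30, rng_seed=seed)
        import pandas as pd

        frame = pd.DataFrame({
            "term": sorted(coll.sets), "category": "synthetic",
            "k": 2, "n": 10, "K": 10, "N": 80,
            "p_value": np.linspace(0.001, 0.04, n_terms),
            "fold_enrichment": 1.5,
        })
        return EnrichmentResult(frame=frame), coll

    def test_disjoint_terms_no_edge(self):
        coll = GeneSetCollection(sets={
            "T1": ("GO", frozenset("AB")), "T2": ("GO", frozenset("CD"))})
        chart, _ = self.make_chart_and_collection(2)
        chart = EnrichmentResult(frame=chart.frame.assign(term=["T1", "T2"]))
        edges, _ = enrichment_map_edges(chart, coll, cutoff=0.6)
        assert len(edges) == 0

    def test_identical_sets_coefficient_one(self):
        coll = GeneSetCollection(sets={
            "T1": ("GO", frozenset("ABC")), "T2": ("GO", frozenset("ABC"))})
        chart, _ = self.make_chart_and_collection(2)
        chart = EnrichmentResult(frame=chart.frame.assign(term=["T1", "T2"]))
        edges, nodes = enrichment_map_edges(chart, coll, cutoff=0.6)
        assert len(edges) == 1
        assert edges.loc[0, "overlap_coefficient"] == pytest.approx(1.0)
        assert nodes["neg_log10_p"].tolist() == pytest.approx(
            (-np.log10(chart.frame["p_value"])).tolist())

    def test_matches_all_pairs_brute_force(self):
        chart, coll = self.make_chart_and_collection(10)
        edges, _ = enrichment_map_edges(chart, coll, cutoff=0.6)
        got = {frozenset((a, b)) for a, b in zip(edges["term_a"], edges["term_b"])}
        expected = set()
        for ta, tb in combinations(sorted(chart.terms), 2):
            a, b = coll.sets[ta][1], coll.sets[tb][1]
            if len(a & b) / min(len(a), len(b)) >= 0.6:
                expected.add(frozenset((ta, tb)))
        assert got == expected

    def test_unknown_term_named(self):
        chart, coll = self.make_chart_and_collection(3)
        bad = EnrichmentResult(frame=chart.frame.assign(term=["GHOST", "T2", "T3"]))
        with pytest.raises(UnknownGeneError, match="GHOST"):
            enrichment_map_edges(bad, coll)


class TestCompareCharts:
    def make(self, terms):
        import pandas as pd

        frame = pd.DataFrame({
            "term": list(terms), "category": "GO", "k": 1, "n": 2, "K": 2,
            "N": 10, "p_value": 0.01, "fold_enrichment": 2.0})
        return EnrichmentResult(frame=frame)

    def test_identical_charts(self):
        a = self.make(["T1", "T2"])
        ua, ub, shared = compare_charts(a, self.make(["T1", "T2"]))
        assert ua == set() and ub == set() and shared == {"T1", "T2"}

    def test_disjoint_charts(self):
        ua, ub, shared = compare_charts(self.make(["T1"]), self.make(["T2"]))
        assert shared == set()

    def test_planted_partition(self):
        shared_terms = [f"S{i}" for i in range(5)]
        only_a = [f"A{i}" for i in range(3)]
        only_b = [f"B{i}" for i in range(4)]
        ua, ub, shared = compare_charts(
            self.make(shared_terms + only_a), self.make(shared_terms + only_b))
        assert ua == set(only_a) and ub == set(only_b) and shared == set(shared_terms)
        # partition identity: |unique_a| + |shared| = |chart_a|
        assert len(ua) + len(shared) == 8
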