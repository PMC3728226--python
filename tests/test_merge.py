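import itertools

import numpy as np
import pytest

from synshrink.io import Contig, GeneModel, HitRecord
from synshrink.merge import PredictionSet, merge_annotations, merge_report, qc_filter

CONTIG = Contig("c1", "ACGT" * 2500)


def _gene(gid, start, length, strand="+", source="s", protein=None):
    return GeneModel(gid, "c1", strand, [(start, start + length)],
                     source=source, protein=protein)


def _hit(sig, score=100.0):
    return HitRecord("q", "s", score, sig, (0, 10), (0, 10))


class TestQcFilter:
    def test_protein_length_boundary_is_strict(self):
        g50 = _gene("g50", 0, 150, protein="M" * 50)
        g51 = _gene("g51", 200, 153, protein="M" * 51)
        assert qc_filter([g50, g51]) == [g51]

    def test_internal_stop_removed(self):
        g = _gene("g", 0, 300, protein="M" * 40 + "*" + "K" * 40)
        assert qc_filter([g]) == []

    def test_trailing_stop_is_tolerated(self):
        g = _gene("g", 0, 306, protein="M" * 101 + "*")
        assert qc_filter([g]) == [g]

    def test_frameshift_proxy_cds_not_multiple_of_three(self):
        g = _gene("g", 0, 301, protein="M" * 100)
        assert qc_filter([g]) == []

    def test_seeded_frameshifts_counted_against_truth(self):
        """100 clean genes, 10 with a frameshifting 1-nt exon extension ->
        exactly 90 survive."""
        rng = np.random.default_rng(0)
        genes = []
        for i in range(100):
            start = i * 400
            length = 300 if i >= 10 else 301  # first ten frameshifted
            genes.append(_gene(f"g{i:03d}", start, length, protein="M" * 99))
        big = Contig("c1", "ACGT" * 11000)
        kept = qc_filter(genes, [big])
        assert len(kept) == 90
        assert all(int(g.id[1:]) >= 10 for g in kept)


class TestMergeAnnotations:
    def test_hit_bearing_gene_wins_overlap(self):
        a = _gene("a", 0, 500, source="s1")
        b = _gene("b", 100, 500, source="s2")
        sets = [
            PredictionSet("s1", [a], {"a": _hit(1e-30)}),
            PredictionSet("s2", [b]),
        ]
        assert merge_annotations(sets) == [a]

    def test_longest_wins_without_hits(self):
        a = _gene("a", 0, 500, source="s1")
        b = _gene("b", 100, 900, source="s2")
        merged = merge_annotations([PredictionSet("s1", [a]), PredictionSet("s2", [b])])
        assert merged == [b]

    def test_overlap_chain_resolved_as_one_component(self):
        a = _gene("a", 0, 300)
        b = _gene("b", 200, 300)
        c = _gene("c", 400, 300)  # overlaps b, not a
        merged = merge_annotations([PredictionSet("s", [a, b, c])])
        assert len(merged) == 1

    def test_opposite_strand_overlap_keeps_both(self):
        a = _gene("a", 0, 500, strand="+")
        b = _gene("b", 100, 500, strand="-")
        merged = merge_annotations([PredictionSet("s", [a, b])])
        assert len(merged) == 2

    def test_merged_set_has_no_same_strand_overlaps(self, small_pair):
        genes = list(small_pair.contracted_annotation)
        shifted = [
            GeneModel(f"x_{g.id}", g.contig_id, g.strand,
                      [(a + 7, b + 7) for a, b in g.exons], source="alt")
            for g in genes[::2]
        ]
        merged = merge_annotations([PredictionSet("s1", genes),
                                    PredictionSet("s2", shifted)])
        by_key = {}
        for g in merged:
            by_key.setdefault((g.contig_id, g.strand), []).append(g.span)
        for spans in by_key.values():
            spans.sort()
            for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
                assert a2 >= b1

    def test_idempotent(self):
        a = _gene("a", 0, 500)
        b = _gene("b", 600, 300)
        merged = merge_annotations([PredictionSet("s", [a, b])])
        again = merge_annotations([PredictionSet("merged", merged)])
        assert again == merged

    def test_order_independent(self):
        sets = [
            PredictionSet("s1", [_gene("a", 0, 500, source="s1")], {"a": _hit(1e-10)}),
            PredictionSet("s2", [_gene("b", 100, 700, source="s2")], {"b": _hit(1e-10, 150)}),
            PredictionSet("s3", [_gene("c", 900, 200, source="s3")]),
        ]
        results = {
            tuple(g.id for g in merge_annotations(list(perm)))
            for perm in itertools.permutations(sets)
        }
        assert len(results) == 1

    def test_equal_everything_tie_breaks_lexicographically(self):
        a = _gene("b_gene", 0, 500)
        b = _gene("a_gene", 0, 500)
        merged = merge_annotations([PredictionSet("s", [a, b])])
        assert [g.id for g in merged] == ["a_gene"]

    def test_matches_brute_force_resolution(self):
        """Randomised 3-source scenario vs exhaustive pairwise-overlap
        resolution on a small instance."""
        rng = np.random.default_rng(21)
        sets = []
        all_genes = []
        for s in range(3):
            genes = []
            for i in range(30):
                start = int(rng.integers(0, 9000))
                length = int(rng.integers(50, 400))
                g = _gene(f"s{s}g{i}", start, length,
                          strand="+" if rng.random() < 0.5 else "-",
                          source=f"s{s}")
                genes.append(g)
                all_genes.append(g)
            sets.append(PredictionSet(f"s{s}", genes))
        merged = merge_annotations(sets)

        # oracle: union-find over the pairwise overlap relation
        parent = {g.id: g.id for g in all_genes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for g1, g2 in itertools.combinations(all_genes, 2):
            if (g1.contig_id, g1.strand) == (g2.contig_id, g2.strand):
                a1, b1 = g1.span
                a2, b2 = g2.span
                if a1 < b2 and a2 < b1:
                    parent[find(g1.id)] = find(g2.id)
        comps = {}
        for g in all_genes:
            comps.setdefault(find(g.id), []).append(g)
        expected = sorted(
            min(comp, key=lambda g: (-g.span_length, g.id)).id for comp in comps.values()
        )
        assert sorted(g.id for g in merged) == expected


class TestMergeReport:
    def test_single_source_passthrough(self):
        genes = [_gene("a", 0, 300), _gene("b", 500, 300)]
        sets = [PredictionSet("s1", genes)]
        merged = merge_annotations(sets)
        df = merge_report(sets, merged, {"s1": len(genes)})
        row = df[df.source == "s1"].iloc[0]
        assert row.predicted == 2 and row.post_qc == 2 and row.in_final == 2

    def test_disjoint_sources_contributions_sum(self):
        s1 = [_gene("a", 0, 300, source="s1")]
        s2 = [_gene("b", 1000, 300, source="s2")]
        sets = [PredictionSet("s1", s1), PredictionSet("s2", s2)]
        merged = merge_annotations(sets)
        df = merge_report(sets, merged)
        assert int(df[df.source == "total"].in_final.iloc[0]) == len(merged) == 2
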