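from collections import Counter

import pytest

import oracles
from synshrink.align import _AA_INDEX, ScoringScheme
from synshrink.io import Contig, GeneModel
from synshrink.orthology import (
    BBHResult,
    classify_gene_fates,
    collinear_segments,
    exon_bbh,
    exon_records,
    fate_summary,
)
from synshrink.simulate import AncestorSpec, ContractionSpec, evolve_pair, simulate_ancestor

CODON_OF = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAA",
    "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTT", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
    "Y": "TAT", "V": "GTT",
}


def _single_exon_genome(genes: dict[str, str], contig_id="c1"):
    """genes: id -> protein; returns (contigs, annotation) with 100-nt spacers."""
    seq_parts, annotation, pos = [], [], 0
    for gid, prot in genes.items():
        spacer = "ACGTACGTAC" * 10
        seq_parts.append(spacer)
        pos += len(spacer)
        dna = "".join(CODON_OF[c] for c in prot)
        annotation.append(GeneModel(gid, contig_id, "+", [(pos, pos + len(dna))]))
        seq_parts.append(dna)
        pos += len(dna)
    seq_parts.append("ACGTACGTAC" * 10)
    return [Contig(contig_id, "".join(seq_parts))], annotation


PROT1 = "MKLVQWERTYAHGFDSANKLVQWERTYAHGFDSA"
PROT2 = "MHHWWCCPPQQGGLLKKVVRRDDEEFFYYAANNT"


class TestExonBBH:
    def test_identical_single_exon_genes_pair(self):
        ga, anna = _single_exon_genome({"a1": PROT1})
        gb, annb = _single_exon_genome({"b1": PROT1})
        bbh = exon_bbh(anna, ga, annb, gb, ScoringScheme(min_report_score=30))
        assert len(bbh.pairs) == 1
        assert bbh.gene_pairs == [("a1", "b1")]

    def test_non_reciprocal_best_yields_no_pair(self):
        # a1 is a mutated copy; a2 is exact -> b1's best is a2, so a1 pairs with nothing
        mutated = PROT1[:10] + "WWW" + PROT1[13:]
        ga, anna = _single_exon_genome({"a1": mutated, "a2": PROT1})
        gb, annb = _single_exon_genome({"b1": PROT1})
        bbh = exon_bbh(anna, ga, annb, gb, ScoringScheme(min_report_score=30))
        paired_a = {p.gene_a_id for p in bbh.pairs}
        assert paired_a == {"a2"}
        assert bbh.gene_pairs == [("a2", "b1")]

    def test_matches_brute_force_bbh_oracle(self):
        """Seeded translated search reproduces all-vs-all full-DP BBH on a
        simulated divergent pair without paralog interference."""
        anc = simulate_ancestor(
            AncestorSpec(n_genes=14, n_contigs=2,
                         family_size_distribution={1: 1.0}, seed=31)
        )
        pair = evolve_pair(
            anc,
            ContractionSpec(loss_prob_by_family_size={1: 0.0},
                            transposition_fraction=0.0, substitution_rate=0.025,
                            seed=31),
        )
        scheme = ScoringScheme()
        bbh = exon_bbh(pair.contracted_annotation, pair.contracted_genome,
                       pair.conserved_annotation, pair.conserved_genome, scheme)
        prot_a = {e.id: e.protein for e in
                  exon_records(pair.contracted_annotation, pair.contracted_genome)
                  if e.protein}
        prot_b = {e.id: e.protein for e in
                  exon_records(pair.conserved_annotation, pair.conserved_genome)
                  if e.protein}
        expected = oracles.brute_force_bbh(prot_a, prot_b, scheme.matrix, _AA_INDEX,
                                           min_score=scheme.min_report_score)
        assert {(p.exon_a_id, p.exon_b_id) for p in bbh.pairs} == expected

    def test_pairs_form_a_matching(self, small_bbh):
        counts_a = Counter(p.exon_a_id for p in small_bbh.pairs)
        counts_b = Counter(p.exon_b_id for p in small_bbh.pairs)
        assert all(c == 1 for c in counts_a.values())
        assert all(c == 1 for c in counts_b.values())


def _seg_fixture():
    """Five A genes on one contig, ten B genes on one contig; orthologs
    g1<->h2 and g5<->h9."""
    anna = [GeneModel(f"g{i}", "cA", "+", [(i * 1000, i * 1000 + 300)])
            for i in range(1, 6)]
    annb = [GeneModel(f"h{i}", "cB", "+", [(i * 1000, i * 1000 + 300)])
            for i in range(1, 11)]
    bbh = BBHResult(pairs=[], gene_pairs=[("g1", "h2"), ("g5", "h9")])
    return anna, annb, bbh


class TestCollinearSegments:
    def test_segment_spans_boundary_orthologs(self):
        anna, annb, bbh = _seg_fixture()
        (seg,) = collinear_segments(anna, bbh, annb)
        assert seg.genes_b == [f"h{i}" for i in range(2, 10)]
        assert seg.genes_a == [f"g{i}" for i in range(1, 6)]
        assert seg.boundary_pairs == (("g1", "h2"), ("g5", "h9"))

    def test_boundaries_on_different_b_contigs_yield_nothing(self):
        anna, annb, bbh = _seg_fixture()
        annb = [g if g.id != "h9" else
                GeneModel("h9", "cB2", "+", g.exons) for g in annb]
        assert collinear_segments(anna, bbh, annb) == []

    def test_single_anchor_contig_yields_nothing(self):
        anna, annb, _ = _seg_fixture()
        bbh = BBHResult(pairs=[], gene_pairs=[("g1", "h2")])
        assert collinear_segments(anna, bbh, annb) == []

    def test_simulated_segments_cover_collinear_truth(self, small_pair,
                                                      small_segments):
        in_seg = {g for s in small_segments for g in s.genes_b}
        truth = small_pair.truth.gene_fate
        # every segment's interior collinear gene is recovered inside one
        covered = sum(1 for g, f in truth.items() if f == "collinear" and g in in_seg)
        assert covered / sum(1 for f in truth.values() if f == "collinear") > 0.8


class TestGeneFates:
    def test_rule_application_on_constructed_case(self):
        anna, annb, bbh = _seg_fixture()
        bbh.best_b_to_a = {
            "h2:e0": ("g1:e0", 200.0),
            "h9:e0": ("g5:e0", 200.0),
            "h3:e0": ("g3:e0", 150.0),   # hit inside the segment
        }
        bbh.gene_pairs = bbh.gene_pairs + [("g3", "h3")]
        fates = {f.gene_id: f.fate for f in
                 classify_gene_fates(collinear_segments(anna, bbh, annb),
                                     anna, annb, bbh)}
        assert fates["h2"] == "collinear"
        assert fates["h3"] == "collinear"
        assert fates["h4"] == "lost"  # no significant hit anywhere

    def test_hit_on_other_contig_is_transposed(self):
        anna, annb, bbh = _seg_fixture()
        anna = anna + [GeneModel("g9", "cA2", "+", [(0, 300)])]
        bbh.best_b_to_a = {
            "h2:e0": ("g1:e0", 200.0),
            "h9:e0": ("g5:e0", 200.0),
            "h5:e0": ("g9:e0", 180.0),
        }
        fates = {f.gene_id: f.fate for f in
                 classify_gene_fates(collinear_segments(anna, bbh, annb),
                                     anna, annb, bbh)}
        assert fates["h5"] == "transposed"

    def test_locus_owned_by_better_reciprocal_match_means_lost(self):
        anna, annb, bbh = _seg_fixture()
        from synshrink.orthology import OrthologPair

        bbh.gene_pairs = bbh.gene_pairs + [("g3", "h3")]
        bbh.pairs = [OrthologPair("g3:e0", "h3:e0", "g3", "h3", 300.0, 300.0)]
        bbh.best_b_to_a = {
            "h2:e0": ("g1:e0", 200.0),
            "h9:e0": ("g5:e0", 200.0),
            "h3:e0": ("g3:e0", 300.0),
            "h4:e0": ("g3:e0", 120.0),  # paralog hit onto g3, outscored by h3
        }
        fates = {f.gene_id: f.fate for f in
                 classify_gene_fates(collinear_segments(anna, bbh, annb),
                                     anna, annb, bbh)}
        assert fates["h4"] == "lost"

    def test_fates_partition_in_segment_genes(self, small_fates, small_segments):
        in_seg = {g for s in small_segments for g in s.genes_b}
        classified = {f.gene_id for f in small_fates}
        assert classified <= in_seg
        assert len(classified) == len(small_fates)  # exactly one fate each
        summary = fate_summary(small_fates, small_segments)
        assert summary["collinear"] + summary["transposed"] + summary["lost"] == \
            len(small_fates)
        assert summary["excluded"] == len(in_seg) - len(classified)

    def test_zero_divergence_classification_is_perfect(self):
        anc = simulate_ancestor(AncestorSpec(n_genes=40, n_contigs=4, seed=19))
        pair = evolve_pair(anc, ContractionSpec(substitution_rate=0.0, seed=19))
        bbh = exon_bbh(pair.contracted_annotation, pair.contracted_genome,
                       pair.conserved_annotation, pair.conserved_genome)
        segs = collinear_segments(pair.contracted_annotation, bbh,
                                  pair.conserved_annotation)
        fates = classify_gene_fates(segs, pair.contracted_annotation,
                                    pair.conserved_annotation, bbh)
        truth = pair.truth.gene_fate
        assert fates
        assert all(truth[f.gene_id] == f.fate for f in fates)

    def test_summary_non_collinear_arithmetic(self, small_fates, small_segments):
        summary = fate_summary(small_fates, small_segments)
        assert summary["non_collinear"] == summary["transposed"] + summary["lost"]
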