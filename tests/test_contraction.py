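import numpy as np
import pytest

import oracles
from synshrink.contraction import (
    contraction_fold,
    dinucleotide_entropy,
    flag_repeat_associated,
    orthologous_intergenic_totals,
    orthologous_intron_totals,
    partition_genome,
    scan_long_indels,
)
from synshrink.io import Contig, GeneModel
from synshrink.orthology import BBHResult, CollinearSegment, OrthologPair


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestPartition:
    def test_simple_arithmetic(self):
        contig = Contig("c", "A" * 1000)
        gene = GeneModel("g", "c", "+", [(100, 200), (250, 350), (400, 500)])
        p = partition_genome([contig], [gene])
        assert (p.exonic_total, p.intronic_total, p.intergenic_total) == (300, 100, 600)

    def test_no_genes_all_intergenic(self):
        p = partition_genome([Contig("c", "A" * 500)], [])
        assert p.intergenic_total == p.assembly_total == 500

    def test_union_semantics_against_per_base_oracle(self):
        rng = np.random.default_rng(5)
        contigs = [Contig("c1", _random_dna(rng, 8000)),
                   Contig("c2", _random_dna(rng, 5000))]
        genes = []
        for i in range(30):
            cid = "c1" if rng.random() < 0.6 else "c2"
            limit = 8000 if cid == "c1" else 5000
            start = int(rng.integers(0, limit - 900))
            exons, pos = [], start
            for _ in range(int(rng.integers(1, 4))):
                length = int(rng.integers(30, 200))
                exons.append((pos, pos + length))
                pos += length + int(rng.integers(20, 150))
            if pos >= limit:
                continue
            genes.append(GeneModel(f"g{i}", cid, "+" if rng.random() < 0.5 else "-",
                                   exons))
        p = partition_genome(contigs, genes)
        assert (p.exonic_total, p.intronic_total, p.intergenic_total) == \
            oracles.per_base_partition(contigs, genes)

    def test_partition_always_sums(self, small_pair):
        for genome, annotation in (
            (small_pair.conserved_genome, small_pair.conserved_annotation),
            (small_pair.contracted_genome, small_pair.contracted_annotation),
        ):
            p = partition_genome(genome, annotation)
            assert p.exonic_total + p.intronic_total + p.intergenic_total == \
                p.assembly_total


def _two_exon_pair(intron_a=90, intron_b=270):
    anna = [GeneModel("ga", "cA", "+", [(0, 90), (90 + intron_a, 180 + intron_a)])]
    annb = [GeneModel("gb", "cB", "+", [(0, 90), (90 + intron_b, 180 + intron_b)])]
    pairs = [
        OrthologPair("ga:e0", "gb:e0", "ga", "gb", 100.0, 100.0),
        OrthologPair("ga:e1", "gb:e1", "ga", "gb", 100.0, 100.0),
    ]
    return anna, annb, BBHResult(pairs=pairs, gene_pairs=[("ga", "gb")])


class TestOrthologousTotals:
    def test_flanked_intron_pair_counted(self):
        anna, annb, bbh = _two_exon_pair()
        assert orthologous_intron_totals(bbh, anna, annb) == (90, 270, 3.0)

    def test_inconsistent_exon_order_not_counted(self):
        anna, annb, bbh = _two_exon_pair()
        bbh.pairs[1] = OrthologPair("ga:e1", "gb:e5", "ga", "gb", 100.0, 100.0)
        total_a, total_b, fold = orthologous_intron_totals(bbh, anna, annb)
        assert (total_a, total_b, fold) == (0, 0, None)

    def test_no_qualifying_introns_is_na(self):
        anna, annb, bbh = _two_exon_pair()
        bbh.pairs = []
        assert orthologous_intron_totals(bbh, anna, annb) == (0, 0, None)

    def test_equal_intergenic_totals_fold_one(self):
        anna = [GeneModel("a1", "cA", "+", [(0, 100)]),
                GeneModel("a2", "cA", "+", [(400, 500)])]
        annb = [GeneModel("b1", "cB", "+", [(0, 100)]),
                GeneModel("b2", "cB", "+", [(400, 500)])]
        bbh = BBHResult(pairs=[], gene_pairs=[("a1", "b1"), ("a2", "b2")])
        seg = CollinearSegment("cA", "cB", ["a1", "a2"], ["b1", "b2"],
                               (0, 500), (0, 500))
        assert orthologous_intergenic_totals([seg], bbh, anna, annb) == (300, 300, 1.0)

    def test_fold_rounds_to_one_decimal(self):
        assert contraction_fold(673_000, 2_744_000) == 4.1
        assert contraction_fold(0, 100) is None


class TestScanLongIndels:
    def test_identical_sequences_no_events(self):
        rng = np.random.default_rng(1)
        x = _random_dna(rng, 4000)
        res = scan_long_indels(x, x)
        assert res.alignable and res.events == []

    def test_single_planted_deletion_recovered(self):
        rng = np.random.default_rng(2)
        a = _random_dna(rng, 5000)
        b = a[:2000] + a[2600:]
        (ev,) = scan_long_indels(a, b).events
        assert ev.length == 600
        assert ev.shorter_genome == "B"
        assert abs(ev.position_in_longer - 2000) <= 16

    def test_threshold_is_strict(self):
        rng = np.random.default_rng(3)
        a = _random_dna(rng, 8000)
        b = a[:1500] + a[1900:5000] + a[5700:]  # deletions of 400 and 700
        events = scan_long_indels(a, b, min_indel_length=500).events
        assert [e.length for e in events] == [700]

    def test_self_scan_empty_for_random_sequences(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            x = _random_dna(rng, int(rng.integers(100, 3000)))
            assert scan_long_indels(x, x).events == []

    def test_unalignable_pair_flagged(self):
        res = scan_long_indels("A" * 2000, "C" * 2000)
        assert not res.alignable and res.events == []

    def test_insertion_in_first_sequence_reported_with_side(self):
        rng = np.random.default_rng(6)
        b = _random_dna(rng, 5000)
        a = b[:2500] + b[2500 + 800:]  # now A is the shorter one
        (ev,) = scan_long_indels(a, b).events
        assert ev.shorter_genome == "A" and ev.length == 800


class TestRepeatAssociation:
    def test_planted_at_repeat_flanks_flagged(self):
        rng = np.random.default_rng(7)
        motif = "ATATATATATATATA"  # 15 nt, entropy ~1 bit
        base = _random_dna(rng, 5000)
        longer = base[:1985] + motif + base[2000:2585] + motif + base[2600:]
        shorter = longer[:2000] + longer[2600:]
        (ev,) = scan_long_indels(longer, shorter).events
        assert flag_repeat_associated(ev, longer) is True

    def test_no_repeat_near_breakpoints_not_flagged(self):
        rng = np.random.default_rng(8)
        a = _random_dna(rng, 5000)
        b = a[:2000] + a[2600:]
        (ev,) = scan_long_indels(a, b).events
        assert flag_repeat_associated(ev, a) is False

    def test_high_complexity_repeat_not_flagged(self):
        rng = np.random.default_rng(9)
        motif = "ACGTAGCTTGCA"  # 12 nt, high entropy
        assert dinucleotide_entropy(motif) >= 1.5
        base = _random_dna(rng, 5000)
        longer = base[:1988] + motif + base[2000:2588] + motif + base[2600:]
        shorter = longer[:2000] + longer[2600:]
        (ev,) = scan_long_indels(longer, shorter).events
        assert flag_repeat_associated(ev, longer) is False

    def test_entropy_matches_direct_computation(self):
        for seq in ("ATATATATATATATA", "ACGTAGCTTGCA", "AAAAAAAAAA", "ACACACACAC"):
            assert dinucleotide_entropy(seq) == pytest.approx(
                oracles.shannon_entropy_dinucleotides(seq)
            )

    def test_at_repeat_entropy_is_about_one_bit(self):
        assert dinucleotide_entropy("ATATATATATATATA") == pytest.approx(1.0, abs=0.01)
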