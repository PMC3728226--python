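import math

import numpy as np
import pytest

import oracles
from synshrink.io import Contig, GeneModel, ParameterError
from synshrink.stats import (
    classify_gene_coverage,
    codon_counts,
    completeness_percent,
    effective_number_of_codons,
    gc3,
    gc_content,
    gc_null_sd,
    gc_summary,
    intron_stats,
    percent,
    spearman,
)


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [
        ("GCGC", 1.0), ("ATAT", 0.0), ("ATGCN", 0.5),
    ])
    def test_basic_values(self, seq, expected):
        assert gc_content(seq) == expected

    def test_all_n_is_nan(self):
        assert math.isnan(gc_content("NNNN"))

    def test_bounded_on_random_sequences(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGTN"), size=rng.integers(1, 200)))
            g = gc_content(seq)
            assert math.isnan(g) or 0.0 <= g <= 1.0


class TestGcNullSd:
    def test_single_contig_closed_form(self):
        L, p = 1000, 0.4
        assert gc_null_sd([L], p) == pytest.approx(math.sqrt(0.24 / L))

    def test_degenerate_p_gives_zero(self):
        assert gc_null_sd([100], 1e-12) == pytest.approx(0.0, abs=1e-5)

    def test_closed_form_matches_monte_carlo(self):
        """Analytic null SD vs simulated per-contig GC SD over uniform-base
        genomes."""
        rng = np.random.default_rng(23)
        p = 0.4
        lengths = np.maximum(rng.lognormal(7.0, 0.8, size=200).astype(int), 50)
        analytic = gc_null_sd(list(lengths), p)
        sds = []
        for _ in range(300):
            gcs = rng.binomial(lengths, p) / lengths
            sds.append(np.std(gcs))
        assert abs(analytic - np.mean(sds)) / analytic < 0.05

    def test_simulated_genome_gc_near_target(self, big_ancestor):
        summary = gc_summary(big_ancestor.genome)
        assert sum(c.length for c in big_ancestor.genome) >= 5_000_000
        assert abs(summary.genome_gc - big_ancestor.spec.gc_target) < 0.01


class TestSpearman:
    def test_monotone_limits(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert spearman(x, [10, 20, 30, 40]) == pytest.approx(1.0)
        assert spearman(x, [40, 30, 20, 10]) == pytest.approx(-1.0)

    def test_tied_values_match_midrank_oracle(self):
        x, y = [1.0, 2.0, 3.0], [2.0, 2.0, 1.0]
        assert spearman(x, y) == pytest.approx(oracles.spearman_midrank(x, y))

    def test_random_data_matches_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            x = rng.integers(0, 10, size=30).astype(float)
            y = rng.integers(0, 10, size=30).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            assert spearman(x, y) == pytest.approx(oracles.spearman_midrank(x, y))

    def test_constant_vector_is_nan(self):
        assert math.isnan(spearman([1, 1, 1], [1, 2, 3]))


class TestIntronStats:
    def test_single_intron(self):
        g = GeneModel("g", "c", "+", [(0, 50), (150, 200)])
        mean, median, lengths = intron_stats([g])
        assert mean == median == 100

    def test_lower_middle_median_for_odd_multiset(self):
        genes = [
            GeneModel("g", "c", "+", [(0, 10), (60, 70), (170, 180), (480, 490)]),
        ]
        mean, median, _ = intron_stats(genes)  # introns 50, 100, 300
        assert mean == 150 and median == 100

    def test_no_introns_nan(self):
        g = GeneModel("g", "c", "+", [(0, 50)])
        mean, median, lengths = intron_stats([g])
        assert math.isnan(mean) and lengths.size == 0


UNIFORM_FAMILIES = {
    "F": ["TTT", "TTC"], "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "I": ["ATT", "ATC", "ATA"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "P": ["CCT", "CCC", "CCA", "CCG"], "T": ["ACT", "ACC", "ACA", "ACG"],
    "A": ["GCT", "GCC", "GCA", "GCG"], "Y": ["TAT", "TAC"], "H": ["CAT", "CAC"],
    "Q": ["CAA", "CAG"], "N": ["AAT", "AAC"], "K": ["AAA", "AAG"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "C": ["TGT", "TGC"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
}


class TestEffectiveNumberOfCodons:
    def test_uniform_usage_reaches_maximum(self):
        cds = "".join(codon * 20 for codons in UNIFORM_FAMILIES.values()
                      for codon in codons)
        assert effective_number_of_codons(cds) == 61.0

    def test_single_codon_per_amino_acid_is_minimum(self):
        cds = "".join(codons[0] * 30 for codons in UNIFORM_FAMILIES.values())
        assert effective_number_of_codons(cds) == 20.0

    def test_matches_hand_formula_on_biased_usage(self):
        rng = np.random.default_rng(41)
        codons = []
        for fam in UNIFORM_FAMILIES.values():
            weights = rng.dirichlet(np.ones(len(fam)) * 0.5)
            draws = rng.choice(fam, size=60, p=weights)
            codons.extend(draws)
        rng.shuffle(codons)
        cds = "".join(codons)
        got = effective_number_of_codons(cds)
        expected = oracles.wright_enc_from_counts(codon_counts(cds))
        assert got == pytest.approx(expected)
        assert 20.0 <= got <= 61.0

    def test_too_few_codons_is_none(self):
        assert effective_number_of_codons("ATG") is None


class TestGc3:
    def test_all_gc_third_positions(self):
        assert gc3("TTCTTGGAC") == 1.0

    def test_met_lys_is_zero(self):
        assert gc3("ATGAAA") == 0.0

    def test_random_cds_matches_positional_oracle(self):
        rng = np.random.default_rng(43)
        bases = "ACGT"
        cds = "".join(rng.choice(list(bases), size=900))
        assert gc3(cds) == pytest.approx(oracles.gc3_positional(cds))

    def test_empty_is_none(self):
        assert gc3("") is None


class TestGeneCoverage:
    def test_exact_half_coverage_counts_as_covered(self):
        g = GeneModel("g", "c", "+", [(0, 100)])
        out = classify_gene_coverage([g], {"c": [(0, 50)]})
        assert out["g"] == "covered"

    def test_zero_coverage(self):
        g = GeneModel("g", "c", "+", [(0, 100)])
        assert classify_gene_coverage([g], {"c": []})["g"] == "uncovered"
        assert classify_gene_coverage([g], {})["g"] == "uncovered"

    def test_fragmented_coverage_matches_per_base_count(self):
        g = GeneModel("g", "c", "+", [(100, 300)])
        intervals = [(100, 140), (150, 190), (200, 260), (250, 270)]
        # per-base: union covers 140-100 + 190-150 + 270-200 = 150 of 200
        covered = set()
        for a, b in intervals:
            covered.update(range(a, b))
        frac = len(covered & set(range(100, 300))) / 200
        out = classify_gene_coverage([g], {"c": intervals})
        assert (out["g"] == "covered") == (frac >= 0.5)
        assert out["g"] == "covered"

    def test_monotone_under_interval_growth(self):
        rng = np.random.default_rng(47)
        g = GeneModel("g", "c", "+", [(0, 1000)])
        intervals: list[tuple[int, int]] = []
        prev_covered = False
        for _ in range(20):
            a = int(rng.integers(0, 950))
            intervals.append((a, a + int(rng.integers(10, 120))))
            now = classify_gene_coverage([g], {"c": list(intervals)})["g"] == "covered"
            assert now or not prev_covered  # covered never flips back
            prev_covered = now


class TestCompleteness:
    def test_core_gene_percentages(self):
        rep = completeness_percent(187, 43, 248)
        assert rep.pct_full == 75.4
        assert rep.pct_full_or_partial == 92.7

    def test_empty_and_full(self):
        assert completeness_percent(0, 0, 248).pct_full == 0.0
        assert completeness_percent(248, 0, 248).pct_full_or_partial == 100.0

    def test_zero_total_rejected(self):
        with pytest.raises(ParameterError):
            completeness_percent(0, 0, 0)

    def test_percent_helper_integer_rounding(self):
        assert percent(22, 120) == 18
        assert percent(30, 120) == 25
        assert percent(3850, 28775) == 13
        assert percent(4898, 28775) == 17
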