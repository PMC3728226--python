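"""Composition, codon-usage and completeness statistics.

Includes the uniform-null standard deviation of per-contig GC content
(closed-form binomial), Wright's effective number of codons (ENc), GC3,
intron length summaries, the covered-fraction gene classification used in
assembly validation, and core-gene completeness percentages.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .io import CompletenessReport, Contig, GeneModel, ParameterError

__all__ = [
    "GcSummary",
    "CodonUsageSummary",
    "gc_content",
    "gc_summary",
    "gc_null_sd",
    "spearman",
    "intron_stats",
    "effective_number_of_codons",
    "gc3",
    "classify_gene_coverage",
    "completeness_percent",
    "percent",
]


@dataclass
class GcSummary:
    genome_gc: float
    per_contig_gc: list[float]
    observed_sd: float
    null_sd: float


@dataclass
class CodonUsageSummary:
    codon_counts: dict[str, int]
    enc: float | None
    gc3: float | None


def gc_content(sequence: str) -> float:
    """(G+C)/(A+C+G+T); N bases excluded from both sides; NaN if all-N/empty."""
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        return float("nan")
    return gc / (gc + at)


def gc_null_sd(contig_lengths: list[int], p: float, weighted: bool = False) -> float:
    """SD of per-contig GC expected under independent uniform bases.

    Unweighted (default): sqrt(mean_i p(1-p)/L_i) — the SD of the unweighted
    per-contig GC values, since under the null between-contig mean
    differences are zero. With ``weighted=True`` contigs are weighted by
    length.
    """
    if not contig_lengths or any(L <= 0 for L in contig_lengths):
        raise ParameterError("contig lengths must be positive")
    if not 0.0 < p < 1.0:
        return 0.0
    var = p * (1 - p)
    L = np.asarray(contig_lengths, dtype=float)
    if weighted:
        w = L / L.sum()
        return float(np.sqrt(np.sum(w * var / L)))
    return float(np.sqrt(np.mean(var / L)))


def gc_summary(contigs: list[Contig]) -> GcSummary:
    """Genome GC, per-contig GC, their SD, and the uniform-null SD."""
    per = [gc_content(c.sequence) for c in contigs]
    valid = [g for g in per if not math.isnan(g)]
    whole = gc_content("".join(c.sequence for c in contigs))
    observed = float(np.std(valid)) if valid else float("nan")
    null = gc_null_sd([c.length for c in contigs if c.length > 0], whole)
    return GcSummary(genome_gc=whole, per_contig_gc=per, observed_sd=observed, null_sd=null)


def spearman(x, y) -> float:
    """Spearman rank correlation with midranks for ties (NaN if undefined)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ParameterError("spearman needs two equal-length vectors, n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho = scipy.stats.spearmanr(x, y).statistic
    return float(rho)


def intron_stats(annotation: list[GeneModel], median_mode: str = "lower"):
    """(mean, median, lengths) of all introns; NaNs when there are none.

    ``median_mode='lower'`` takes the lower middle element for even counts;
    ``'interpolate'`` averages the two middles.
    """
    lengths = np.array(
        [b - a for g in annotation for a, b in g.introns], dtype=float
    )
    if lengths.size == 0:
        return float("nan"), float("nan"), lengths
    mean = float(lengths.mean())
    srt = np.sort(lengths)
    if median_mode == "interpolate":
        median = float(np.median(srt))
    else:
        median = float(srt[(len(srt) - 1) // 2])
    return mean, median, lengths


# ---------------------------------------------------------------------------
# codon usage
# ---------------------------------------------------------------------------

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_FAMILY: dict[str, list[str]] = {}
for codon, aa in _CODON_TABLE.items():
    if aa != "*":
        _FAMILY.setdefault(aa, []).append(codon)
# degeneracy classes for Wright's ENc (Met and Trp excluded)
_DEGENERACY_CLASSES = {2: [], 3: [], 4: [], 6: []}
for aa, codons in _FAMILY.items():
    k = len(codons)
    if k in _DEGENERACY_CLASSES:
        _DEGENERACY_CLASSES[k].append(aa)
_CLASS_WEIGHTS = {2: 9, 3: 1, 4: 5, 6: 3}


def codon_counts(cds_set) -> dict[str, int]:
    """Codon counts over one or more in-frame CDS strings (stops dropped)."""
    if isinstance(cds_set, str):
        cds_set = [cds_set]
    counts: Counter[str] = Counter()
    for cds in cds_set:
        usable = len(cds) - len(cds) % 3
        for i in range(0, usable, 3):
            codon = cds[i : i + 3].upper()
            aa = _CODON_TABLE.get(codon)
            if aa is not None and aa != "*":
                counts[codon] += 1
    return dict(counts)


def _aa_homozygosity(counts: dict[str, int], aa: str) -> float | None:
    """Wright's F-hat for one amino acid; None when n < 2."""
    ns = [counts.get(c, 0) for c in _FAMILY[aa]]
    n = sum(ns)
    if n < 2:
        return None
    s = sum((ni / n) ** 2 for ni in ns)
    f = (n * s - 1) / (n - 1)
    return f


def effective_number_of_codons(cds_set) -> float | None:
    """Wright's ENc in [20, 61]; None when no degeneracy class is estimable.

    ENc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, where Fk is the mean codon
    homozygosity of the k-fold degenerate amino acids. A missing F3 is
    imputed as (F2+F4)/2; estimates above 61 (no bias within sampling
    error) are capped at 61 and below 20 raised to 20.
    """
    counts = codon_counts(cds_set)
    fbar: dict[int, float] = {}
    for k, aas in _DEGENERACY_CLASSES.items():
        fs = [f for aa in aas if (f := _aa_homozygosity(counts, aa)) is not None and f > 0]
        if fs:
            fbar[k] = float(np.mean(fs))
    if 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2.0
    if any(k not in fbar for k in (2, 3, 4, 6)):
        return None
    enc = 2.0 + sum(_CLASS_WEIGHTS[k] / fbar[k] for k in (2, 3, 4, 6))
    return float(min(61.0, max(20.0, enc)))


def gc3(cds_set) -> float | None:
    """GC fraction at third positions of synonymously variable codons.

    Codons of the non-degenerate amino acids (Met, Trp) and stop codons are
    excluded: their third position is fixed by the protein sequence and
    carries no usage signal. None when no codon qualifies.
    """
    if isinstance(cds_set, str):
        cds_set = [cds_set]
    gc = total = 0
    for cds in cds_set:
        usable = len(cds) - len(cds) % 3
        for i in range(0, usable, 3):
            codon = cds[i : i + 3].upper()
            if _CODON_TABLE.get(codon, "*") in ("*", "M", "W"):
                continue
            third = codon[2]
            if third in "GC":
                gc += 1
            if third in "ACGT":
                total += 1
    if total == 0:
        return None
    return gc / total


def codon_usage_summary(cds_set) -> CodonUsageSummary:
    return CodonUsageSummary(
        codon_counts=codon_counts(cds_set),
        enc=effective_number_of_codons(cds_set),
        gc3=gc3(cds_set),
    )


# ---------------------------------------------------------------------------
# coverage classification and completeness
# ---------------------------------------------------------------------------

def classify_gene_coverage(
    genes: list[GeneModel],
    covered_intervals: dict[str, list[tuple[int, int]]],
    min_fraction: float = 0.5,
) -> dict[str, str]:
    """gene_id -> 'covered' | 'uncovered' by the fraction of the gene span
    (introns included) overlapped by the merged covered intervals."""
    from .contraction import _merge

    merged = {cid: _merge(iv) for cid, iv in covered_intervals.items()}
    out: dict[str, str] = {}
    for g in genes:
        a, b = g.span
        cov = 0
        for ia, ib in merged.get(g.contig_id, []):
            cov += max(0, min(b, ib) - max(a, ia))
        frac = cov / (b - a)
        out[g.id] = "covered" if frac >= min_fraction else "uncovered"
    return out


def completeness_percent(n_full: int, n_partial: int, n_total: int) -> CompletenessReport:
    """Completeness percentages against a fixed core gene set, 1-decimal."""
    if n_total <= 0:
        raise ParameterError("n_total must be positive")
    if not 0 <= n_full <= n_full + n_partial <= n_total:
        raise ParameterError("inconsistent completeness counts")
    return CompletenessReport(
        n_full=n_full,
        n_partial=n_partial,
        n_total=n_total,
        pct_full=round(100.0 * n_full / n_total, 1),
        pct_full_or_partial=round(100.0 * (n_full + n_partial) / n_total, 1),
    )


def percent(numerator: float, denominator: float, ndigits: int = 0) -> float:
    """100*numerator/denominator rounded to ``ndigits`` (int when 0)."""
    if denominator <= 0:
        raise ParameterError("denominator must be positive")
    value = round(100.0 * numerator / denominator, ndigits)
    return int(value) if ndigits == 0 else value
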