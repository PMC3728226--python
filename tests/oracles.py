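"""Independent brute-force oracles used by the tests.

Everything here is deliberately written the slow, obvious way, without
sharing code with the package implementation.
"""

from __future__ import annotations

from collections import Counter

_CODONS = {
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

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq))


def translate(dna: str) -> str:
    return "".join(
        _CODONS.get(dna[i : i + 3], "X") for i in range(0, len(dna) - len(dna) % 3, 3)
    )


def full_smith_waterman(query: str, subject: str, matrix, aa_index,
                        gap_open: int = -10, gap_extend: int = -1) -> int:
    """Plain cubic-branch affine-gap local alignment score (no banding, no
    seeding); gap of length L costs gap_open + L*gap_extend."""
    m, n = len(query), len(subject)
    NEG = -(10 ** 9)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        qi = aa_index.get(query[i - 1], aa_index["X"])
        for j in range(1, n + 1):
            sj = aa_index.get(subject[j - 1], aa_index["X"])
            E[i][j] = max(E[i][j - 1] + gap_extend, H[i][j - 1] + gap_open + gap_extend)
            F[i][j] = max(F[i - 1][j] + gap_extend, H[i - 1][j] + gap_open + gap_extend)
            H[i][j] = max(0, H[i - 1][j - 1] + int(matrix[qi][sj]), E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def best_sixframe_score(protein: str, dna: str, matrix, aa_index) -> int:
    """Best protein-vs-DNA score over all six frames via the full DP."""
    best = 0
    for strand_seq in (dna, revcomp(dna)):
        for f in range(3):
            prot = translate(strand_seq[f:])
            best = max(best, full_smith_waterman(protein, prot, matrix, aa_index))
    return best


def per_base_partition(contigs, annotation):
    """Label every base exon > intron > intergenic and count."""
    labels = {c.id: ["g"] * c.length for c in contigs}
    for gene in annotation:
        lab = labels[gene.contig_id]
        for a, b in gene.introns:
            for i in range(a, b):
                if lab[i] == "g":
                    lab[i] = "i"
        for a, b in gene.exons:
            for i in range(a, b):
                lab[i] = "e"
    flat = [x for lab in labels.values() for x in lab]
    return flat.count("e"), flat.count("i"), flat.count("g")


def spearman_midrank(x, y) -> float:
    """Pearson correlation of midranks, computed from first principles."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den


def wright_enc_from_counts(counts: dict[str, int]) -> float:
    """ENc from a codon-count table via the homozygosity formula, written
    out longhand."""
    fam: dict[str, list[str]] = {}
    for codon, aa in _CODONS.items():
        if aa != "*":
            fam.setdefault(aa, []).append(codon)
    fbar: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in fam.items():
        k = len(codons)
        if k not in fbar:
            continue
        ns = [counts.get(c, 0) for c in codons]
        n = sum(ns)
        if n < 2:
            continue
        s = sum((ni / n) ** 2 for ni in ns)
        f = (n * s - 1) / (n - 1)
        if f > 0:
            fbar[k].append(f)
    mean = {k: sum(v) / len(v) for k, v in fbar.items() if v}
    if 3 not in mean and 2 in mean and 4 in mean:
        mean[3] = (mean[2] + mean[4]) / 2
    enc = 2 + 9 / mean[2] + 1 / mean[3] + 5 / mean[4] + 3 / mean[6]
    return min(61.0, max(20.0, enc))


def gc3_positional(cds: str) -> float:
    """GC at every third position, counted directly; codons whose third
    position is dictated by the amino acid (Met, Trp, stops) skipped."""
    gc = total = 0
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if _CODONS.get(codon, "*") in ("*", "M", "W"):
            continue
        total += 1
        if codon[2] in "GC":
            gc += 1
    return gc / total


def shannon_entropy_dinucleotides(seq: str) -> float:
    import math

    pairs = [seq[i : i + 2] for i in range(len(seq) - 1)]
    n = len(pairs)
    h = 0.0
    for c in Counter(pairs).values():
        p = c / n
        h -= p * math.log2(p)
    return h


def brute_force_bbh(proteins_a: dict[str, str], proteins_b: dict[str, str],
                    matrix, aa_index, min_score: int = 50):
    """All-vs-all protein-protein BBH with the full DP; ties broken by
    higher score then lexicographic subject id."""
    def best(queries, subjects):
        out = {}
        for qid, q in queries.items():
            scored = []
            for sid, s in subjects.items():
                sc = full_smith_waterman(q, s, matrix, aa_index)
                if sc >= min_score:
                    scored.append((-sc, sid))
            if scored:
                scored.sort()
                out[qid] = (scored[0][1], -scored[0][0])
        return out

    ab = best(proteins_a, proteins_b)
    ba = best(proteins_b, proteins_a)
    pairs = set()
    for a, (b, _) in ab.items():
        if b in ba and ba[b][0] == a:
            pairs.add((a, b))
    return pairs
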