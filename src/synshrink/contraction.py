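"""Contraction statistics: genome partition, orthologous intron/intergenic
totals and folds, and the long-indel scan with repeat association.

The long-indel scan replaces interactive alignment with a deterministic
anchor chain: maximal unique exact k-mers shared by the two sequences are
chained co-linearly (longest increasing subsequence), and a localized
length difference larger than the threshold between consecutive anchors is
emitted as one indel event. No attempt is made to polarize events into
deletions vs insertions; events record only which side is shorter.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .io import Contig, GeneModel, GenomePartition, ValidationError
from .orthology import BBHResult, CollinearSegment

__all__ = [
    "IndelEvent",
    "ScanResult",
    "ContractionReport",
    "partition_genome",
    "orthologous_intron_totals",
    "orthologous_intergenic_totals",
    "scan_long_indels",
    "flag_repeat_associated",
    "dinucleotide_entropy",
    "contraction_fold",
]


@dataclass
class IndelEvent:
    region_pair_id: str
    position_in_longer: int
    length: int
    shorter_genome: str  # "A" | "B"
    repeat_associated: bool = False


@dataclass
class ScanResult:
    events: list[IndelEvent] = field(default_factory=list)
    alignable: bool = True


@dataclass
class ContractionReport:
    partition_a: GenomePartition | None = None
    partition_b: GenomePartition | None = None
    orthologous_intron_totals: tuple[int, int] = (0, 0)
    orthologous_intergenic_totals: tuple[int, int] = (0, 0)
    intron_fold: float | None = None
    intergenic_fold: float | None = None


def contraction_fold(total_a: float, total_b: float) -> float | None:
    """larger/smaller ratio rounded to one decimal; None when undefined."""
    if total_a <= 0 or total_b <= 0:
        return None
    hi, lo = max(total_a, total_b), min(total_a, total_b)
    return round(hi / lo, 1)


# ---------------------------------------------------------------------------
# whole-genome partition
# ---------------------------------------------------------------------------

def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def _total(intervals: list[tuple[int, int]]) -> int:
    return sum(b - a for a, b in intervals)


def _subtract(base: list[tuple[int, int]], minus: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """base \\ minus for two merged interval lists."""
    out: list[tuple[int, int]] = []
    j = 0
    for a, b in base:
        cur = a
        while j < len(minus) and minus[j][1] <= cur:
            j += 1
        k = j
        while k < len(minus) and minus[k][0] < b:
            ma, mb = minus[k]
            if ma > cur:
                out.append((cur, ma))
            cur = max(cur, mb)
            k += 1
        if cur < b:
            out.append((cur, b))
    return out


def partition_genome(contigs: list[Contig], annotation: list[GeneModel]) -> GenomePartition:
    """Exonic / intronic / intergenic totals over an assembly.

    Exonic is the union of exon intervals; intronic is the union of
    per-gene inter-exon gaps minus the exonic union (a base covered by an
    exon of any gene counts as exonic); intergenic is the remainder, so the
    three always sum to the assembly total.
    """
    lengths = {c.id: c.length for c in contigs}
    exons: dict[str, list[tuple[int, int]]] = defaultdict(list)
    introns: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for g in annotation:
        if g.contig_id not in lengths:
            raise ValidationError(f"gene {g.id}: contig {g.contig_id!r} not in assembly")
        exons[g.contig_id].extend(g.exons)
        introns[g.contig_id].extend(g.introns)

    exonic = intronic = 0
    for cid in lengths:
        ex = _merge(exons.get(cid, []))
        inr = _subtract(_merge(introns.get(cid, [])), ex)
        exonic += _total(ex)
        intronic += _total(inr)
    assembly_total = sum(lengths.values())
    return GenomePartition(
        exonic_total=exonic,
        intronic_total=intronic,
        intergenic_total=assembly_total - exonic - intronic,
        assembly_total=assembly_total,
    )


# ---------------------------------------------------------------------------
# orthologous intron / intergenic totals
# ---------------------------------------------------------------------------

def _transcript_introns(gene: GeneModel) -> list[tuple[int, int]]:
    """Genomic intron intervals ordered in transcript direction."""
    introns = gene.introns
    return list(reversed(introns)) if gene.strand == "-" else introns


def orthologous_intron_totals(
    bbh: BBHResult,
    annotation_a: list[GeneModel],
    annotation_b: list[GeneModel],
) -> tuple[int, int, float | None]:
    """Summed lengths of introns whose two flanking exons are BBH-paired
    with the two flanking exons of a single partner-gene intron, in
    consistent transcript order. Returns (total_a, total_b, fold)."""
    genes_a = {g.id: g for g in annotation_a}
    genes_b = {g.id: g for g in annotation_b}

    # exon_a transcript index -> (gene_b, exon_b transcript index)
    partner: dict[tuple[str, int], tuple[str, int]] = {}
    for p in bbh.pairs:
        ka = int(p.exon_a_id.rsplit(":e", 1)[1])
        kb = int(p.exon_b_id.rsplit(":e", 1)[1])
        partner[(p.gene_a_id, ka)] = (p.gene_b_id, kb)

    total_a = total_b = 0
    for ga_id, gene_a in genes_a.items():
        introns_a = _transcript_introns(gene_a)
        for k in range(len(gene_a.exons) - 1):
            left = partner.get((ga_id, k))
            right = partner.get((ga_id, k + 1))
            if left is None or right is None:
                continue
            (gb_id, j), (gb_id2, j2) = left, right
            if gb_id != gb_id2 or j2 != j + 1:
                continue
            gene_b = genes_b[gb_id]
            introns_b = _transcript_introns(gene_b)
            ia, ib = introns_a[k], introns_b[j]
            total_a += ia[1] - ia[0]
            total_b += ib[1] - ib[0]
    return total_a, total_b, contraction_fold(total_a, total_b)


def orthologous_intergenic_totals(
    segments: list[CollinearSegment],
    bbh: BBHResult,
    annotation_a: list[GeneModel],
    annotation_b: list[GeneModel],
) -> tuple[int, int, float | None]:
    """Summed lengths of intergenic regions whose flanking genes are
    gene-level orthologs and adjacent in both genomes."""
    genes_a = {g.id: g for g in annotation_a}
    genes_b = {g.id: g for g in annotation_b}
    gene_map_ba = bbh.gene_map_ba

    order_a: dict[str, list[GeneModel]] = defaultdict(list)
    for g in annotation_a:
        order_a[g.contig_id].append(g)
    for lst in order_a.values():
        lst.sort(key=lambda g: g.span)
    rank_a = {g.id: (cid, i) for cid, lst in order_a.items() for i, g in enumerate(lst)}

    total_a = total_b = 0
    seen: set[tuple[str, str]] = set()
    for seg in segments:
        ordered_b = [g for g in seg.genes_b if g in genes_b]
        for g1, g2 in zip(ordered_b, ordered_b[1:]):
            if (g1, g2) in seen:
                continue
            a1, a2 = gene_map_ba.get(g1), gene_map_ba.get(g2)
            if a1 is None or a2 is None:
                continue
            r1, r2 = rank_a.get(a1), rank_a.get(a2)
            if r1 is None or r2 is None or r1[0] != r2[0] or abs(r1[1] - r2[1]) != 1:
                continue
            seen.add((g1, g2))
            gap_b = max(0, genes_b[g2].span[0] - genes_b[g1].span[1])
            left, right = (a1, a2) if r1[1] < r2[1] else (a2, a1)
            gap_a = max(0, genes_a[right].span[0] - genes_a[left].span[1])
            total_a += gap_a
            total_b += gap_b
    return total_a, total_b, contraction_fold(total_a, total_b)


# ---------------------------------------------------------------------------
# long-indel scan
# ---------------------------------------------------------------------------

def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    counts: Counter[str] = Counter()
    pos: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        counts[kmer] += 1
        pos[kmer] = i
    return {km: p for km, p in pos.items() if counts[km] == 1}


def _lis_chain(points: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain strictly increasing in both coordinates; input sorted
    by the first coordinate."""
    tails: list[int] = []          # smallest second-coordinate per length
    tails_idx: list[int] = []
    prev = [-1] * len(points)
    for i, (_, y) in enumerate(points):
        j = bisect_left(tails, y)
        if j == len(tails):
            tails.append(y)
            tails_idx.append(i)
        else:
            tails[j] = y
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[-1] if tails_idx else -1
    while i >= 0:
        chain.append(points[i])
        i = prev[i]
    return chain[::-1]


def scan_long_indels(
    region_a: str,
    region_b: str,
    min_indel_length: int = 500,
    anchor_k: int = 16,
    region_pair_id: str = "pair",
) -> ScanResult:
    """Localized length differences between two homologous sequences.

    Anchors are k-mers occurring exactly once in each sequence, chained
    co-linearly; the sequence ends act as terminal anchors. Between
    consecutive anchors, a gap-length difference exceeding
    ``min_indel_length`` becomes one event whose length is the difference
    and whose position is the longer side's gap start. Returns an empty,
    non-alignable result when no anchors chain.
    """
    ua = _unique_kmer_positions(region_a, anchor_k)
    ub = _unique_kmer_positions(region_b, anchor_k)
    common = sorted((ua[km], ub[km]) for km in ua.keys() & ub.keys())
    if not common:
        return ScanResult(events=[], alignable=False)
    chain = _lis_chain(common)
    # terminal anchors: virtual k-mers hanging off both ends
    anchors = [(-anchor_k, -anchor_k)] + chain + [(len(region_a), len(region_b))]

    events: list[IndelEvent] = []
    for (pa1, pb1), (pa2, pb2) in zip(anchors, anchors[1:]):
        gap_a = pa2 - (pa1 + anchor_k)
        gap_b = pb2 - (pb1 + anchor_k)
        diff = abs(gap_a - gap_b)
        if diff <= min_indel_length:
            continue
        shorter = "B" if gap_b < gap_a else "A"
        start = (pa1 if shorter == "B" else pb1) + anchor_k
        events.append(
            IndelEvent(
                region_pair_id=region_pair_id,
                position_in_longer=max(0, start),
                length=diff,
                shorter_genome=shorter,
            )
        )
    return ScanResult(events=events, alignable=True)


def dinucleotide_entropy(seq: str) -> float:
    """Shannon entropy (bits) of overlapping dinucleotides."""
    if len(seq) < 2:
        return 0.0
    counts = Counter(seq[i : i + 2] for i in range(len(seq) - 1))
    n = sum(counts.values())
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def flag_repeat_associated(
    event: IndelEvent,
    region_longer: str,
    repeat_min_len: int = 10,
    window: int = 50,
    complexity_threshold: float = 1.5,
) -> bool:
    """True when a low-complexity exact direct repeat flanks both breakpoints.

    Looks for a shared substring of length >= ``repeat_min_len`` between the
    two breakpoint neighbourhoods (+- ``window`` nt) whose dinucleotide
    entropy is below ``complexity_threshold`` bits.
    """
    start = event.position_in_longer
    end = start + event.length
    zone1 = region_longer[max(0, start - window) : min(len(region_longer), start + window)]
    zone2 = region_longer[max(0, end - window) : min(len(region_longer), end + window)]
    k = repeat_min_len
    kmers1 = {zone1[i : i + k] for i in range(len(zone1) - k + 1)}
    shared = [zone2[i : i + k] for i in range(len(zone2) - k + 1) if zone2[i : i + k] in kmers1]
    return any(dinucleotide_entropy(km) < complexity_threshold for km in shared)
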