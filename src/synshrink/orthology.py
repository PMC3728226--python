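"""Exon-level bidirectional best hits, collinear segments, and gene fates.

Orthology between two genomes is established at the exon level: exon
proteins of one genome are searched against the annotated exon sequences of
the other with the translated scorer (or external hit tables), and an exon
pair is orthologous when each exon is the other's best-scoring hit (BBH).
Exon pairs aggregate to gene-level ortholog pairs by majority vote.

Collinear segments follow the classical contig-anchoring construction: an
A-genome contig whose first and last ortholog-bearing genes map to the same
B-genome contig defines a segment, and every B gene between the two anchor
orthologs (inclusive) is then assigned a fate:

* ``collinear``   — its BBH partner lies inside the corresponding A segment;
* ``transposed``  — its best significant hit lies elsewhere in genome A;
* ``lost``        — no significant hit in genome A, or the locus it hits is
  a better reciprocal match of a different B gene.

Genome A is the reduced genome, genome B the larger reference whose genes
are classified.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .align import ScoringScheme, TranslatedSearchIndex, translate_dna
from .io import Contig, GeneModel, HitRecord, ValidationError, gene_cds

__all__ = [
    "ExonRecord",
    "OrthologPair",
    "CollinearSegment",
    "GeneFate",
    "BBHResult",
    "exon_records",
    "exon_bbh",
    "collinear_segments",
    "classify_gene_fates",
    "fate_summary",
]


@dataclass
class ExonRecord:
    """One exon with its transcript-order index and derived protein."""

    id: str
    gene_id: str
    contig_id: str
    transcript_index: int
    interval: tuple[int, int]
    dna: str
    protein: str


@dataclass
class OrthologPair:
    exon_a_id: str
    exon_b_id: str
    gene_a_id: str
    gene_b_id: str
    score_ab: float
    score_ba: float


@dataclass
class CollinearSegment:
    contig_a_id: str
    contig_b_id: str
    genes_a: list[str]
    genes_b: list[str]
    span_a: tuple[int, int]
    span_b: tuple[int, int]
    boundary_pairs: tuple[tuple[str, str], tuple[str, str]] = (("", ""), ("", ""))


@dataclass
class GeneFate:
    gene_id: str
    fate: str  # collinear | transposed | lost
    evidence: str = ""


@dataclass
class BBHResult:
    """Exon pairs plus the per-exon best-hit maps they were derived from."""

    pairs: list[OrthologPair]
    best_a_to_b: dict[str, tuple[str, float]] = field(default_factory=dict)
    best_b_to_a: dict[str, tuple[str, float]] = field(default_factory=dict)
    gene_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def gene_map_ab(self) -> dict[str, str]:
        return {a: b for a, b in self.gene_pairs}

    @property
    def gene_map_ba(self) -> dict[str, str]:
        return {b: a for a, b in self.gene_pairs}


def exon_records(annotation: list[GeneModel], genome: list[Contig]) -> list[ExonRecord]:
    """Split every gene into exon records with in-phase protein pieces.

    Exon ids are ``<gene>:e<k>`` with ``k`` the transcript-order index; the
    exon protein is the slice of the gene's translated CDS covered by the
    exon (codon-floor boundaries).
    """
    contig_seq = {c.id: c.sequence for c in genome}
    out: list[ExonRecord] = []
    for gene in annotation:
        seq = contig_seq.get(gene.contig_id)
        if seq is None:
            raise ValidationError(f"gene {gene.id}: contig {gene.contig_id!r} not in genome")
        cds = gene_cds(gene, seq)
        protein = translate_dna(cds)
        exons = gene.exons if gene.strand == "+" else list(reversed(gene.exons))
        off = 0
        for k, (a, b) in enumerate(exons):
            length = b - a
            piece = protein[off // 3 : (off + length) // 3]
            out.append(
                ExonRecord(
                    id=f"{gene.id}:e{k}",
                    gene_id=gene.id,
                    contig_id=gene.contig_id,
                    transcript_index=k,
                    interval=(a, b),
                    dna=seq[a:b],
                    protein=piece,
                )
            )
            off += length
    return out


def _best_hits_from_index(
    queries: list[ExonRecord], index: TranslatedSearchIndex
) -> dict[str, tuple[str, float]]:
    """exon_id -> (best subject exon id, score); ties broken by longer
    alignment then lexicographic subject id (the search already orders so)."""
    best: dict[str, tuple[str, float]] = {}
    for q in queries:
        if not q.protein:
            continue
        hits = q_hits = index.search(q.protein, query_id=q.id)
        if q_hits:
            hits.sort(key=lambda h: (-h.score,
                                     -(h.query_interval[1] - h.query_interval[0]),
                                     h.subject_id))
            best[q.id] = (hits[0].subject_id, hits[0].score)
    return best


def _best_hits_from_table(
    hits: list[HitRecord], significance_cutoff: float
) -> dict[str, tuple[str, float]]:
    by_query: dict[str, HitRecord] = {}
    for h in hits:
        if h.significance > significance_cutoff:
            continue
        cur = by_query.get(h.query_id)
        if cur is None or (h.significance, -h.score, h.subject_id) < (
            cur.significance, -cur.score, cur.subject_id
        ):
            by_query[h.query_id] = h
    return {q: (h.subject_id, h.score) for q, h in by_query.items()}


def _aggregate_gene_pairs(
    pairs: list[OrthologPair],
    exons_a: dict[str, ExonRecord],
    exons_b: dict[str, ExonRecord],
) -> list[tuple[str, str]]:
    """Gene-level orthologs by majority of paired exons, reciprocally.

    A tie in the majority vote is decided by the pair containing the longest
    exon (then lexicographic partner id, for determinism).
    """

    def majority(votes: dict[str, list[OrthologPair]], exon_len) -> str:
        counts = Counter({k: len(v) for k, v in votes.items()})
        top = max(counts.values())
        tied = [k for k, c in counts.items() if c == top]
        if len(tied) == 1:
            return tied[0]
        tied.sort(key=lambda k: (-max(exon_len(p) for p in votes[k]), k))
        return tied[0]

    by_a: dict[str, dict[str, list[OrthologPair]]] = defaultdict(lambda: defaultdict(list))
    by_b: dict[str, dict[str, list[OrthologPair]]] = defaultdict(lambda: defaultdict(list))
    for p in pairs:
        by_a[p.gene_a_id][p.gene_b_id].append(p)
        by_b[p.gene_b_id][p.gene_a_id].append(p)

    def len_a(p: OrthologPair) -> int:
        e = exons_a[p.exon_a_id].interval
        return e[1] - e[0]

    def len_b(p: OrthologPair) -> int:
        e = exons_b[p.exon_b_id].interval
        return e[1] - e[0]

    choice_a = {a: majority(v, len_a) for a, v in by_a.items()}
    choice_b = {b: majority(v, len_b) for b, v in by_b.items()}
    return sorted(
        (a, b) for a, b in choice_a.items() if choice_b.get(b) == a
    )


def exon_bbh(
    annotation_a: list[GeneModel],
    genome_a: list[Contig],
    annotation_b: list[GeneModel],
    genome_b: list[Contig],
    scheme: ScoringScheme | None = None,
    hits_ab: list[HitRecord] | None = None,
    hits_ba: list[HitRecord] | None = None,
    significance_cutoff: float = 1e-6,
) -> BBHResult:
    """Exon-level bidirectional best hits between two annotated genomes.

    By default each exon protein is searched against the exon sequences of
    the other genome with the internal translated scorer. External hit
    tables (exon id -> exon id, e-value-filtered) may be supplied instead
    for either direction.
    """
    scheme = scheme or ScoringScheme()
    ex_a = exon_records(annotation_a, genome_a)
    ex_b = exon_records(annotation_b, genome_b)
    exmap_a = {e.id: e for e in ex_a}
    exmap_b = {e.id: e for e in ex_b}

    if hits_ab is None:
        index_b = TranslatedSearchIndex([(e.id, e.dna) for e in ex_b], scheme)
        best_ab = _best_hits_from_index(ex_a, index_b)
    else:
        best_ab = _best_hits_from_table(hits_ab, significance_cutoff)
    if hits_ba is None:
        index_a = TranslatedSearchIndex([(e.id, e.dna) for e in ex_a], scheme)
        best_ba = _best_hits_from_index(ex_b, index_a)
    else:
        best_ba = _best_hits_from_table(hits_ba, significance_cutoff)

    pairs: list[OrthologPair] = []
    for ea, (eb, score_ab) in best_ab.items():
        back = best_ba.get(eb)
        if back is not None and back[0] == ea:
            if ea not in exmap_a or eb not in exmap_b:
                raise ValidationError(f"hit references unknown exon {ea!r} or {eb!r}")
            pairs.append(
                OrthologPair(
                    exon_a_id=ea,
                    exon_b_id=eb,
                    gene_a_id=exmap_a[ea].gene_id,
                    gene_b_id=exmap_b[eb].gene_id,
                    score_ab=score_ab,
                    score_ba=back[1],
                )
            )
    pairs.sort(key=lambda p: (p.gene_a_id, p.exon_a_id))
    gene_pairs = _aggregate_gene_pairs(pairs, exmap_a, exmap_b)
    return BBHResult(pairs=pairs, best_a_to_b=best_ab, best_b_to_a=best_ba,
                     gene_pairs=gene_pairs)


# ---------------------------------------------------------------------------
# collinear segments
# ---------------------------------------------------------------------------

def collinear_segments(
    annotation_a: list[GeneModel],
    bbh: BBHResult,
    annotation_b: list[GeneModel],
) -> list[CollinearSegment]:
    """Segments anchored by the first and last ortholog-bearing genes of each
    A contig whose partners lie on one B contig.

    Contigs with fewer than two ortholog-bearing genes yield no segment.
    """
    gene_map_ab = bbh.gene_map_ab
    genes_b = {g.id: g for g in annotation_b}

    by_contig_a: dict[str, list[GeneModel]] = defaultdict(list)
    for g in annotation_a:
        by_contig_a[g.contig_id].append(g)
    by_contig_b: dict[str, list[GeneModel]] = defaultdict(list)
    for g in annotation_b:
        by_contig_b[g.contig_id].append(g)
    for lst in by_contig_a.values():
        lst.sort(key=lambda g: g.span)
    for lst in by_contig_b.values():
        lst.sort(key=lambda g: g.span)

    segments: list[CollinearSegment] = []
    for contig_a in sorted(by_contig_a):
        ordered = by_contig_a[contig_a]
        anchored = [g for g in ordered if g.id in gene_map_ab]
        if len(anchored) < 2:
            continue
        first, last = anchored[0], anchored[-1]
        pb_first = genes_b[gene_map_ab[first.id]]
        pb_last = genes_b[gene_map_ab[last.id]]
        if pb_first.contig_id != pb_last.contig_id:
            continue
        contig_b = pb_first.contig_id
        b_lo = min(pb_first.span[0], pb_last.span[0])
        b_hi = max(pb_first.span[1], pb_last.span[1])
        seg_b = [g.id for g in by_contig_b[contig_b]
                 if g.span[0] >= b_lo and g.span[1] <= b_hi]
        i0, i1 = ordered.index(first), ordered.index(last)
        seg_a = [g.id for g in ordered[i0 : i1 + 1]]
        segments.append(
            CollinearSegment(
                contig_a_id=contig_a,
                contig_b_id=contig_b,
                genes_a=seg_a,
                genes_b=seg_b,
                span_a=(first.span[0], last.span[1]),
                span_b=(b_lo, b_hi),
                boundary_pairs=((first.id, pb_first.id), (last.id, pb_last.id)),
            )
        )
    return segments


# ---------------------------------------------------------------------------
# gene fates
# ---------------------------------------------------------------------------

def _overlaps(iv: tuple[int, int], span: tuple[int, int]) -> bool:
    return iv[0] < span[1] and iv[1] > span[0]


def classify_gene_fates(
    segments: list[CollinearSegment],
    annotation_a: list[GeneModel],
    annotation_b: list[GeneModel],
    bbh: BBHResult,
) -> list[GeneFate]:
    """Fate of every reference (B) gene lying inside a collinear segment.

    The locus-ownership test precedes the location test: a hit onto an A
    locus that is the better reciprocal match of a different B gene means
    the queried gene is lost, even if that locus is outside the segment.
    """
    genes_a = {g.id: g.span for g in annotation_a}
    contig_a = {g.id: g.contig_id for g in annotation_a}
    gene_map_ba = bbh.gene_map_ba  # B gene -> A gene (reciprocal, majority)
    gene_map_ab = bbh.gene_map_ab

    # per-B-gene best significant hit in genome A (max over its exons)
    best_hit_b: dict[str, tuple[str, float]] = {}
    for exon_b, (exon_a, score) in bbh.best_b_to_a.items():
        gb = exon_b.rsplit(":e", 1)[0]
        ga = exon_a.rsplit(":e", 1)[0]
        cur = best_hit_b.get(gb)
        if cur is None or score > cur[1]:
            best_hit_b[gb] = (ga, score)

    fates: dict[str, GeneFate] = {}
    for seg in segments:
        for gb in seg.genes_b:
            if gb in fates:
                continue
            partner = gene_map_ba.get(gb)
            if partner is not None and contig_a[partner] == seg.contig_a_id and _overlaps(
                genes_a[partner], seg.span_a
            ):
                fates[gb] = GeneFate(gb, "collinear", f"bbh_partner={partner}")
                continue
            hit = best_hit_b.get(gb)
            if hit is None:
                fates[gb] = GeneFate(gb, "lost", "no_significant_hit")
                continue
            locus, score = hit
            owner = gene_map_ab.get(locus)
            if owner is not None and owner != gb:
                owner_score = max(
                    (p.score_ba for p in bbh.pairs if p.gene_a_id == locus),
                    default=0.0,
                )
                if owner_score > score:
                    fates[gb] = GeneFate(
                        gb, "lost", f"locus={locus} better match of {owner}"
                    )
                    continue
            inside = contig_a[locus] == seg.contig_a_id and _overlaps(
                genes_a[locus], seg.span_a
            )
            if not inside:
                fates[gb] = GeneFate(
                    gb, "transposed", f"best_hit={locus}@{contig_a[locus]}"
                )
            else:
                fates[gb] = GeneFate(gb, "collinear", f"best_hit_in_place={locus}")
    return [fates[g] for g in sorted(fates)]


def fate_summary(fates: list[GeneFate], segments: list[CollinearSegment]) -> dict:
    """Counts partitioning the in-segment reference gene set."""
    genes_b = {g for s in segments for g in s.genes_b}
    genes_a = {g for s in segments for g in s.genes_a}
    counts = Counter(f.fate for f in fates)
    collinear = counts.get("collinear", 0)
    summary = {
        "n_segments": len(segments),
        "genes_in_segments_b": len(genes_b),
        "genes_in_segments_a": len(genes_a),
        "collinear": collinear,
        "transposed": counts.get("transposed", 0),
        "lost": counts.get("lost", 0),
        "non_collinear": len(fates) - collinear,
        "excluded": len(genes_b) - len(fates),
    }
    return summary
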