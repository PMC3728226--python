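"""Domain types and on-disk formats.

All internal coordinates are 0-based half-open intervals ``[start, end)``.
GFF3 and tabular hit files use the 1-based inclusive conventions of their
formats and are converted at the read/write boundary, so no other module
ever performs an off-by-one adjustment.

Introns are the gaps between consecutive exons of one gene; gene models are
treated as plain exon chains (no UTR substructure).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "FormatError",
    "ValidationError",
    "ParameterError",
    "Contig",
    "GeneModel",
    "HitRecord",
    "FamilyTable",
    "GenomePartition",
    "CompletenessReport",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_hit_table",
    "write_hit_table",
    "read_coverage_table",
    "write_coverage_table",
    "read_family_table",
    "write_family_table",
    "gene_cds",
    "gene_protein",
    "revcomp",
]


class FormatError(ValueError):
    """A file violates its format; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed records violate a semantic invariant (e.g. out-of-bounds exon)."""


class ParameterError(ValueError):
    """A parameter or spec object is inconsistent or out of range."""


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize_dna(seq: str) -> str:
    """Uppercase and collapse every non-ACGTN symbol to N."""
    return _NON_ACGTN.sub("N", seq.upper())


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Contig:
    """A sequence record with mean read coverage: the unit of filtering."""

    id: str
    sequence: str
    mean_coverage: float | None = None

    def __post_init__(self) -> None:
        self.sequence = _normalize_dna(self.sequence)
        if self.mean_coverage is not None and self.mean_coverage < 0:
            raise ValidationError(f"contig {self.id}: negative coverage")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A stranded, exon-structured gene on a contig.

    ``exons`` are non-overlapping half-open intervals sorted by start,
    regardless of strand; for minus-strand genes the transcript reads the
    exon chain right-to-left on the reverse complement.
    """

    id: str
    contig_id: str
    strand: str
    exons: list[tuple[int, int]]
    source: str = ""
    protein: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.id}: strand must be + or -")
        if not self.exons:
            raise ValidationError(f"gene {self.id}: needs at least one exon")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        prev_end = None
        for a, b in self.exons:
            if b <= a:
                raise ValidationError(f"gene {self.id}: empty exon [{a},{b})")
            if prev_end is not None and a < prev_end:
                raise ValidationError(f"gene {self.id}: overlapping exons")
            prev_end = b

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def span_length(self) -> int:
        a, b = self.span
        return b - a

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, in contig coordinates."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]

    @property
    def exon_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def intron_length(self) -> int:
        return sum(b - a for a, b in self.introns)


@dataclass
class HitRecord:
    """One row of a tabular similarity search result.

    ``score`` is an alignment score in arbitrary units (higher is better);
    ``significance`` is e-value-like (lower is stronger). Intervals are
    half-open in the query/subject coordinate systems; ``subject_reversed``
    marks hits whose subject coordinates arrived in reverse orientation.
    """

    query_id: str
    subject_id: str
    score: float
    significance: float
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    subject_taxon: str | None = None
    subject_reversed: bool = False

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.score):
            raise ValidationError(f"hit {self.query_id}->{self.subject_id}: non-finite score")
        if self.significance < 0:
            raise ValidationError(f"hit {self.query_id}->{self.subject_id}: negative significance")


@dataclass
class FamilyTable:
    """gene_id -> family_id for one genome."""

    assignments: dict[str, str] = field(default_factory=dict)

    @property
    def family_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for fam in self.assignments.values():
            sizes[fam] = sizes.get(fam, 0) + 1
        return sizes

    def size_of_gene(self, gene_id: str) -> int:
        fam = self.assignments[gene_id]
        return self.family_sizes[fam]


@dataclass
class GenomePartition:
    """Exon / intron / intergenic split of an assembly, in nucleotides."""

    exonic_total: int
    intronic_total: int
    intergenic_total: int
    assembly_total: int

    def __post_init__(self) -> None:
        parts = self.exonic_total + self.intronic_total + self.intergenic_total
        if parts != self.assembly_total:
            raise ValidationError(
                f"partition does not sum: {self.exonic_total}+{self.intronic_total}"
                f"+{self.intergenic_total} != {self.assembly_total}"
            )


@dataclass
class CompletenessReport:
    """Completeness of a gene space against a fixed core gene set."""

    n_full: int
    n_partial: int
    n_total: int
    pct_full: float
    pct_full_or_partial: float


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a multi-record FASTA file into ``[(id, sequence), ...]``.

    Sequences are uppercased with non-ACGTN symbols replaced by N. Raises
    :class:`FormatError` naming the line on malformed input.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    current_id: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if current_id is not None:
                    records.append((current_id, _normalize_dna("".join(chunks))))
                current_id = line[1:].split()[0] if line[1:].strip() else ""
                if not current_id:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                chunks = []
            else:
                if current_id is None:
                    raise FormatError(f"{path}:{lineno}: sequence data before any header")
                chunks.append(line.strip())
    if current_id is not None:
        records.append((current_id, _normalize_dna("".join(chunks))))
    if not records:
        raise FormatError(f"{path}:1: empty FASTA file")
    seen: set[str] = set()
    for rid, _ in records:
        if rid in seen:
            raise FormatError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_attrs(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_gff3(path: str | Path, contigs: Sequence[Contig] | Mapping[str, Contig] | None = None) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA/exon-or-CDS features).

    Input coordinates (1-based inclusive) become 0-based half-open. Exons are
    grouped under their gene via Parent links (exon -> mRNA -> gene or
    exon -> gene) and sorted ascending. If ``contigs`` is given, every exon is
    checked against contig bounds.
    """
    path = Path(path)
    bounds: dict[str, int] | None = None
    if contigs is not None:
        if isinstance(contigs, Mapping):
            bounds = {c.id: c.length for c in contigs.values()}
        else:
            bounds = {c.id: c.length for c in contigs}

    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    pending_exons: list[tuple[int, str, str, int, int, str]] = []
    order: list[str] = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
            seqid, source, ftype, start_s, end_s, _score, strand, _frame, attr_s = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start1 < 1 or end1 < start1:
                raise FormatError(f"{path}:{lineno}: bad coordinate range {start1}-{end1}")
            attrs = _parse_attrs(attr_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise FormatError(f"{path}:{lineno}: gene feature without ID")
                genes[gid] = {
                    "contig": seqid,
                    "strand": strand,
                    "source": source,
                    "exons": [],
                    "protein": attrs.get("protein"),
                }
                order.append(gid)
            elif ftype == "mRNA":
                mid, parent = attrs.get("ID"), attrs.get("Parent")
                if mid is None or parent is None:
                    raise FormatError(f"{path}:{lineno}: mRNA needs ID and Parent")
                mrna_parent[mid] = parent
            elif ftype in ("exon", "CDS"):
                parent = attrs.get("Parent")
                if parent is None:
                    raise FormatError(f"{path}:{lineno}: {ftype} without Parent")
                pending_exons.append((lineno, seqid, parent, start1 - 1, end1, strand))

    for lineno, seqid, parent, start0, end0, strand in pending_exons:
        gid = mrna_parent.get(parent, parent)
        if gid not in genes:
            raise FormatError(f"{path}:{lineno}: exon Parent {parent!r} resolves to no gene")
        info = genes[gid]
        if bounds is not None:
            clen = bounds.get(seqid)
            if clen is None:
                raise ValidationError(f"gene {gid}: contig {seqid!r} not in assembly")
            if end0 > clen:
                raise ValidationError(
                    f"gene {gid}: exon [{start0},{end0}) outside contig {seqid} (length {clen})"
                )
        info["exons"].append((start0, end0))

    out: list[GeneModel] = []
    for gid in order:
        info = genes[gid]
        if not info["exons"]:
            raise ValidationError(f"gene {gid}: no exon/CDS features")
        out.append(
            GeneModel(
                id=gid,
                contig_id=info["contig"],
                strand=info["strand"],
                exons=info["exons"],
                source=info["source"],
                protein=info["protein"],
            )
        )
    return out


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> Path:
    """Write gene models as gene/mRNA/exon GFF3 (1-based inclusive on disk)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            a, b = g.span
            src = g.source or "synshrink"
            fh.write(
                f"{g.contig_id}\t{src}\tgene\t{a + 1}\t{b}\t.\t{g.strand}\t.\tID={g.id}\n"
            )
            fh.write(
                f"{g.contig_id}\t{src}\tmRNA\t{a + 1}\t{b}\t.\t{g.strand}\t.\t"
                f"ID={g.id}.t1;Parent={g.id}\n"
            )
            for i, (ea, eb) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.contig_id}\t{src}\texon\t{ea + 1}\t{eb}\t.\t{g.strand}\t.\t"
                    f"ID={g.id}.e{i};Parent={g.id}.t1\n"
                )
    return path


# ---------------------------------------------------------------------------
# tabular hits / coverage / families
# ---------------------------------------------------------------------------

def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Read an outfmt-6-like TSV (12 columns, optional 13th taxon column).

    Columns: query, subject, identity, length, mismatches, gaps, qstart,
    qend, sstart, send, evalue, bitscore [, taxon]. 1-based inclusive hit
    coordinates become 0-based half-open; reversed subject intervals are
    normalised with ``subject_reversed=True``.
    """
    path = Path(path)
    records: list[HitRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) not in (12, 13):
                raise FormatError(f"{path}:{lineno}: expected 12 or 13 columns, got {len(cols)}")
            try:
                qstart, qend = int(cols[6]), int(cols[7])
                sstart, send = int(cols[8]), int(cols[9])
                evalue = float(cols[10])
                bitscore = float(cols[11])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinate/score field") from None
            reversed_ = sstart > send
            if reversed_:
                sstart, send = send, sstart
            records.append(
                HitRecord(
                    query_id=cols[0],
                    subject_id=cols[1],
                    score=bitscore,
                    significance=evalue,
                    query_interval=(qstart - 1, qend),
                    subject_interval=(sstart - 1, send),
                    subject_taxon=cols[12] if len(cols) == 13 else None,
                    subject_reversed=reversed_,
                )
            )
    return records


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for h in hits:
            qa, qb = h.query_interval
            sa, sb = h.subject_interval
            s1, s2 = (sb, sa + 1) if h.subject_reversed else (sa + 1, sb)
            row = [
                h.query_id, h.subject_id, "100.0", str(qb - qa), "0", "0",
                str(qa + 1), str(qb), str(s1), str(s2),
                f"{h.significance:.3g}", f"{h.score:.1f}",
            ]
            if h.subject_taxon is not None:
                row.append(h.subject_taxon)
            fh.write("\t".join(row) + "\n")
    return path


def read_coverage_table(path: str | Path) -> dict[str, float]:
    """TSV of (contig_id, mean_coverage) -> dict."""
    path = Path(path)
    cov: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            try:
                cov[cols[0]] = float(cols[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric coverage") from None
    return cov


def write_coverage_table(coverages: Mapping[str, float], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for cid, cov in coverages.items():
            fh.write(f"{cid}\t{cov:.2f}\n")
    return path


def read_family_table(path: str | Path) -> dict[str, FamilyTable]:
    """TSV of (genome, gene_id, family_id) -> per-genome FamilyTable."""
    path = Path(path)
    tables: dict[str, FamilyTable] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns (genome, gene, family)")
            genome, gene, family = cols
            tables.setdefault(genome, FamilyTable()).assignments[gene] = family
    return tables


def write_family_table(tables: Mapping[str, FamilyTable], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for genome, table in tables.items():
            for gene, family in table.assignments.items():
                fh.write(f"{genome}\t{gene}\t{family}\n")
    return path


# ---------------------------------------------------------------------------
# sequence helpers shared by several modules
# ---------------------------------------------------------------------------

def gene_cds(gene: GeneModel, contig_seq: str) -> str:
    """Spliced coding sequence of a gene, strand-corrected."""
    parts = [contig_seq[a:b] for a, b in gene.exons]
    cds = "".join(parts)
    return revcomp(cds) if gene.strand == "-" else cds


def gene_protein(gene: GeneModel, contig_seq: str) -> str:
    """Translate the spliced CDS (trailing partial codon dropped)."""
    from .align import translate_dna

    return translate_dna(gene_cds(gene, contig_seq))
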