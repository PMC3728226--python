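"""Merge gene predictions from several sources into one non-redundant
annotation.

Overlapping predictions (same contig, same strand, gene spans sharing at
least one base) are grouped into connected components; each component is
resolved to the member with the strongest similarity hit, or, when no
member has a significant hit, to the longest gene span. Ties fall back to
the lexicographically smallest gene id so the merge is deterministic and
order-independent.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .io import Contig, GeneModel, HitRecord, ValidationError, gene_protein

logger = logging.getLogger(__name__)

__all__ = ["PredictionSet", "qc_filter", "merge_annotations", "merge_report"]


@dataclass
class PredictionSet:
    source: str
    genes: list[GeneModel]
    best_hit: dict[str, HitRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [g.id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"prediction set {self.source}: duplicate gene ids")


def qc_filter(
    genes: list[GeneModel],
    contigs: list[Contig] | None = None,
    min_protein_aa: int = 50,
) -> list[GeneModel]:
    """Keep genes with protein length strictly above ``min_protein_aa``,
    no internal stop codon, and CDS length divisible by 3 (frameshift
    proxy). Genes whose protein cannot be obtained are excluded with a
    warning."""
    contig_seq = {c.id: c.sequence for c in contigs} if contigs else {}
    kept = []
    for g in genes:
        cds_len = g.exon_length
        protein = g.protein
        if protein is None:
            seq = contig_seq.get(g.contig_id)
            if seq is None:
                logger.warning("gene %s: no protein and no contig sequence; excluded", g.id)
                continue
            protein = gene_protein(g, seq)
        protein = protein.rstrip("*")
        if cds_len % 3 != 0:
            continue
        if "*" in protein:
            continue
        if len(protein) <= min_protein_aa:
            continue
        kept.append(g)
    return kept


def _components(genes: list[GeneModel]) -> list[list[GeneModel]]:
    """Connected components of the same-strand overlap relation, found with
    a sweep over span-sorted genes per (contig, strand)."""
    groups: dict[tuple[str, str], list[GeneModel]] = defaultdict(list)
    for g in genes:
        groups[(g.contig_id, g.strand)].append(g)
    components: list[list[GeneModel]] = []
    for key in sorted(groups):
        block = sorted(groups[key], key=lambda g: (g.span, g.id))
        current: list[GeneModel] = []
        reach = -1
        for g in block:
            a, b = g.span
            if current and a >= reach:
                components.append(current)
                current = []
                reach = -1
            current.append(g)
            reach = max(reach, b)
        if current:
            components.append(current)
    return components


def merge_annotations(
    sets: list[PredictionSet],
    contigs: list[Contig] | None = None,
    significance_cutoff: float = 1e-6,
) -> list[GeneModel]:
    """Resolve overlapping predictions across sources to one gene each.

    Within each overlap component the survivor is the member with the best
    significant hit (minimum significance, ties by maximum score); when no
    member has one, the longest gene span; remaining ties go to the
    lexicographically smallest gene id.
    """
    if contigs is not None:
        known = {c.id for c in contigs}
        for ps in sets:
            for g in ps.genes:
                if g.contig_id not in known:
                    raise ValidationError(
                        f"set {ps.source}: gene {g.id} references unknown contig {g.contig_id!r}"
                    )
    hit_of: dict[int, HitRecord] = {}
    all_genes: list[GeneModel] = []
    for ps in sets:
        for g in ps.genes:
            all_genes.append(g)
            h = ps.best_hit.get(g.id)
            if h is not None and h.significance <= significance_cutoff:
                hit_of[id(g)] = h

    survivors: list[GeneModel] = []
    for comp in _components(all_genes):
        with_hits = [g for g in comp if id(g) in hit_of]
        if with_hits:
            winner = min(
                with_hits,
                key=lambda g: (hit_of[id(g)].significance, -hit_of[id(g)].score, g.id),
            )
        else:
            winner = min(comp, key=lambda g: (-g.span_length, g.id))
        survivors.append(winner)
    survivors.sort(key=lambda g: (g.contig_id, g.span, g.id))
    # drop exact duplicates (same id, same locus) that arise when the same
    # set is merged with itself
    seen: set[tuple] = set()
    out = []
    for g in survivors:
        key = (g.id, g.contig_id, g.strand, tuple(g.exons))
        if key not in seen:
            seen.add(key)
            out.append(g)
    return out


def merge_report(
    sets: list[PredictionSet],
    merged: list[GeneModel],
    post_qc: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-source contribution table: predicted / post-QC / in final set."""
    merged_keys = {(g.source, g.id) for g in merged}
    rows = []
    for ps in sets:
        contributed = sum(1 for g in ps.genes if (g.source, g.id) in merged_keys)
        rows.append(
            {
                "source": ps.source,
                "predicted": len(ps.genes),
                "post_qc": (post_qc or {}).get(ps.source, len(ps.genes)),
                "in_final": contributed,
            }
        )
    df = pd.DataFrame(rows)
    total = df.drop(columns="source").sum()
    total["source"] = "total"
    return pd.concat([df, total.to_frame().T], ignore_index=True)[
        ["source", "predicted", "post_qc", "in_final"]
    ]
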