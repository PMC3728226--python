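"""Two-step assembly decontamination: read-coverage threshold, then taxonomy
of each contig's best similarity hit.

Contigs below the coverage threshold are removed first (contamination from
associated organisms enters at lower read depth than the sequenced target).
Surviving contigs are kept when their best remaining hit's lineage contains
the target clade, or when they have no hit at all under the significance
cutoff.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .io import Contig, HitRecord, ValidationError

__all__ = [
    "FilterDecision",
    "filter_by_coverage",
    "taxonomy_filter",
    "decontaminate",
    "filter_report",
]

DEFAULT_MIN_COVERAGE = 75.0
DEFAULT_TARGET_CLADE = "Magnoliophyta"
DEFAULT_SIGNIFICANCE_CUTOFF = 1e-6


@dataclass
class FilterDecision:
    contig_id: str
    kept: bool
    reason: str  # low_coverage | nonplant_best_hit | passed_coverage_and_taxonomy | passed_no_hit

    def __post_init__(self) -> None:
        keep_reasons = {"passed_coverage_and_taxonomy", "passed_no_hit"}
        drop_reasons = {"low_coverage", "nonplant_best_hit"}
        if self.reason not in keep_reasons | drop_reasons:
            raise ValidationError(f"unknown filter reason {self.reason!r}")
        if self.kept != (self.reason in keep_reasons):
            raise ValidationError(f"contig {self.contig_id}: kept flag contradicts reason")


def filter_by_coverage(
    contigs: list[Contig], min_coverage: float = DEFAULT_MIN_COVERAGE
) -> tuple[list[Contig], list[Contig]]:
    """Partition contigs into (kept, removed) by mean read coverage.

    A contig is kept iff its coverage is >= the threshold (the boundary
    value itself passes). Missing coverage is an error.
    """
    kept, removed = [], []
    for c in contigs:
        if c.mean_coverage is None:
            raise ValidationError(f"contig {c.id}: no coverage value")
        (kept if c.mean_coverage >= min_coverage else removed).append(c)
    return kept, removed


def _best_hit(hits: list[HitRecord]) -> HitRecord:
    """Minimum significance; ties by maximum score, then subject id."""
    return min(hits, key=lambda h: (h.significance, -h.score, h.subject_id))


def _lineage_contains(lineage: str | None, clade: str) -> bool:
    if not lineage:
        return False
    return clade in [part.strip() for part in lineage.split(";")]


def taxonomy_filter(
    contigs: list[Contig],
    hits: list[HitRecord],
    target_clade: str = DEFAULT_TARGET_CLADE,
    significance_cutoff: float = DEFAULT_SIGNIFICANCE_CUTOFF,
) -> list[FilterDecision]:
    """Keep contigs whose single best hit lies inside the target clade, or
    that have no hit under the cutoff. Only the top hit counts."""
    ids = {c.id for c in contigs}
    by_contig: dict[str, list[HitRecord]] = defaultdict(list)
    for h in hits:
        if h.query_id not in ids:
            raise ValidationError(f"hit references unknown contig {h.query_id!r}")
        if h.significance <= significance_cutoff:
            by_contig[h.query_id].append(h)

    decisions = []
    for c in contigs:
        contig_hits = by_contig.get(c.id)
        if not contig_hits:
            decisions.append(FilterDecision(c.id, True, "passed_no_hit"))
            continue
        best = _best_hit(contig_hits)
        if _lineage_contains(best.subject_taxon, target_clade):
            decisions.append(FilterDecision(c.id, True, "passed_coverage_and_taxonomy"))
        else:
            decisions.append(FilterDecision(c.id, False, "nonplant_best_hit"))
    return decisions


def decontaminate(
    contigs: list[Contig],
    hits: list[HitRecord],
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    target_clade: str = DEFAULT_TARGET_CLADE,
    significance_cutoff: float = DEFAULT_SIGNIFICANCE_CUTOFF,
) -> list[FilterDecision]:
    """Both filter steps in order; one decision per input contig.

    An optional minimum-length floor on the final kept set is a separate
    output-side choice (see the ``filter`` CLI subcommand), not part of the
    decision path.
    """
    passed_cov, failed_cov = filter_by_coverage(contigs, min_coverage)
    decisions = [FilterDecision(c.id, False, "low_coverage") for c in failed_cov]
    decisions.extend(taxonomy_filter(passed_cov, [h for h in hits
                                                  if h.query_id in {c.id for c in passed_cov}],
                                     target_clade, significance_cutoff))
    order = {c.id: i for i, c in enumerate(contigs)}
    decisions.sort(key=lambda d: order[d.contig_id])
    return decisions


def filter_report(
    decisions: list[FilterDecision],
    contigs: list[Contig],
    genome_size: int | None = None,
    ndigits: int = 0,
) -> dict:
    """Summary of a filtering run: contigs kept, total length kept, and the
    kept fraction of the (independently estimated) genome size."""
    from .stats import percent

    lengths = {c.id: c.length for c in contigs}
    kept = [d for d in decisions if d.kept]
    total_kept = sum(lengths[d.contig_id] for d in kept)
    report = {
        "n_input": len(decisions),
        "n_kept": len(kept),
        "total_kept_length": total_kept,
        "reasons": {r: sum(1 for d in decisions if d.reason == r)
                    for r in sorted({d.reason for d in decisions})},
    }
    if genome_size:
        report["pct_of_genome"] = percent(total_kept, genome_size, ndigits)
    return report
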