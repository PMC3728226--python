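"""End-to-end orchestration of the contraction analysis on a synthetic
genome pair, with a single validated config, structured logging, and a
reproducible run directory.

Stage order: simulate -> filter -> merge -> orthomap -> contract -> stats
-> famloss -> report. Each stage writes its outputs under its own
subdirectory; a manifest records the config hash and seeds so a rerun with
the same config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .align import ScoringScheme
from .contraction import (
    contraction_fold,
    flag_repeat_associated,
    orthologous_intergenic_totals,
    orthologous_intron_totals,
    partition_genome,
    scan_long_indels,
)
from .families import family_size_spectrum, loss_by_family_size, monotone_trend_test
from .filtering import decontaminate, filter_report
from .io import (
    ParameterError,
    gene_cds,
    read_fasta,
    read_gff3,
    write_coverage_table,
    write_family_table,
    write_fasta,
    write_gff3,
    write_hit_table,
)
from .merge import PredictionSet, merge_annotations, merge_report, qc_filter
from .orthology import classify_gene_fates, collinear_segments, exon_bbh, fate_summary
from .simulate import (
    AncestorSpec,
    ContractionSpec,
    evolve_pair,
    simulate_ancestor,
    simulate_contaminated_assembly,
    write_truth_tables,
)
from .stats import effective_number_of_codons, gc3, gc_summary, intron_stats

logger = logging.getLogger("synshrink.pipeline")

ALL_STAGES = ["simulate", "filter", "merge", "orthomap", "contract", "stats", "famloss", "report"]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    seed: int = 1
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    # simulator
    n_genes: int = 120
    n_contigs: int = 6
    substitution_rate: float = 0.02
    transposition_fraction: float = 0.10
    loss_prob_by_family_size: dict[int, float] = field(
        default_factory=lambda: {1: 0.05, 2: 0.20, 3: 0.35, 4: 0.45, 5: 0.50}
    )
    intron_fold: float = 2.5
    intergenic_fold: float = 4.0
    n_contaminant_contigs: int = 30
    # thresholds
    min_coverage: float = 75.0
    clade: str = "Magnoliophyta"
    evalue: float = 1e-6
    min_protein_aa: int = 50
    min_indel_length: int = 500
    coverage_fraction: float = 0.5
    min_report_score: int = 50
    n_indel_pairs: int = 20

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ParameterError(f"unknown stages: {unknown}")
        if not 0 < self.coverage_fraction <= 1:
            raise ParameterError("coverage_fraction must be in (0, 1]")
        if self.min_indel_length < 0 or self.min_coverage < 0:
            raise ParameterError("thresholds must be non-negative")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        if "loss_prob_by_family_size" in data:
            data = dict(data)
            data["loss_prob_by_family_size"] = {
                int(k): float(v) for k, v in data["loss_prob_by_family_size"].items()
            }
        return cls(**data)

    def digest(self) -> str:
        canon = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=str) + "\n")


def _stage_log(name: str, **counts) -> None:
    logger.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in counts.items()))


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run the configured stages in dependency order under ``outdir``.

    A failing stage aborts the run: partial outputs are retained and a
    FAILED marker naming the stage is written.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) and h.stream is sys.stderr
               for h in logger.handlers):
        logger.addHandler(logging.StreamHandler(sys.stderr))

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages_run": [],
    }
    state: dict = {}
    try:
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            _STAGE_FUNCS[stage](config, out, state)
            manifest["stages_run"].append(stage)
            _write_json(manifest, out / "manifest.json")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        logger.removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    logger.removeHandler(handler)
    handler.close()
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, out: Path, state: dict) -> None:
    d = out / "simulate"
    d.mkdir(exist_ok=True)
    anc_spec = AncestorSpec(n_genes=cfg.n_genes, n_contigs=cfg.n_contigs, seed=cfg.seed)
    contraction = ContractionSpec(
        loss_prob_by_family_size=cfg.loss_prob_by_family_size,
        transposition_fraction=cfg.transposition_fraction,
        intron_deletion_target_fold=cfg.intron_fold,
        intergenic_deletion_target_fold=cfg.intergenic_fold,
        substitution_rate=cfg.substitution_rate,
        seed=cfg.seed,
    )
    ancestor = simulate_ancestor(anc_spec)
    pair = evolve_pair(ancestor, contraction)
    contigs, hits, labels = simulate_contaminated_assembly(
        pair.contracted_genome, n_contaminant_contigs=cfg.n_contaminant_contigs, seed=cfg.seed
    )
    pair.truth.contamination_label = labels

    write_fasta([(c.id, c.sequence) for c in pair.conserved_genome], d / "conserved.fasta")
    write_gff3(pair.conserved_annotation, d / "conserved.gff3")
    write_fasta([(c.id, c.sequence) for c in pair.contracted_genome], d / "contracted.fasta")
    write_gff3(pair.contracted_annotation, d / "contracted.gff3")
    write_fasta([(c.id, c.sequence) for c in contigs], d / "assembly.fasta")
    write_coverage_table({c.id: c.mean_coverage for c in contigs}, d / "coverage.tsv")
    write_hit_table(hits, d / "assembly_hits.tsv")
    write_family_table({"conserved": ancestor.families}, d / "families.tsv")
    write_truth_tables(pair.truth, d)

    state.update(pair=pair, ancestor=ancestor, assembly=contigs, assembly_hits=hits)
    _stage_log("simulate", genes=cfg.n_genes,
               conserved_nt=sum(c.length for c in pair.conserved_genome),
               contracted_nt=sum(c.length for c in pair.contracted_genome))


def _stage_filter(cfg: PipelineConfig, out: Path, state: dict) -> None:
    d = out / "filter"
    d.mkdir(exist_ok=True)
    contigs, hits = state["assembly"], state["assembly_hits"]
    decisions = decontaminate(contigs, hits, cfg.min_coverage, cfg.clade, cfg.evalue)
    seqs = {c.id: c.sequence for c in contigs}
    write_fasta([(dc.contig_id, seqs[dc.contig_id]) for dc in decisions if dc.kept],
                d / "kept.fasta")
    with open(d / "decisions.tsv", "w") as fh:
        for dc in decisions:
            fh.write(f"{dc.contig_id}\t{int(dc.kept)}\t{dc.reason}\n")
    genome_size = sum(c.length for c in contigs)
    summary = filter_report(decisions, contigs, genome_size=genome_size)
    _write_json(summary, d / "summary.json")
    state["filter_decisions"] = decisions
    _stage_log("filter", n_in=len(contigs), n_kept=summary["n_kept"])


def _stage_merge(cfg: PipelineConfig, out: Path, state: dict) -> None:
    d = out / "merge"
    d.mkdir(exist_ok=True)
    pair = state["pair"]
    genome = pair.contracted_genome
    base = pair.contracted_annotation
    # two overlapping prediction tracks derived from the assembly annotation:
    # the full track and an alternative naming of every other gene
    track_a = [dataclasses.replace(g, source="simA") for g in base]
    track_b = [dataclasses.replace(g, id=f"alt_{g.id}", source="simB")
               for i, g in enumerate(base) if i % 2 == 0]
    sets = [PredictionSet("simA", track_a), PredictionSet("simB", track_b)]
    qc = {ps.source: len(qc_filter(ps.genes, genome, cfg.min_protein_aa)) for ps in sets}
    merged = merge_annotations(sets, genome)
    write_gff3(merged, d / "merged.gff3")
    merge_report(sets, merged, qc).to_csv(d / "report.tsv", sep="\t", index=False)
    _stage_log("merge", sources=len(sets), merged=len(merged))


def _stage_orthomap(cfg: PipelineConfig, out: Path, state: dict) -> None:
    d = out / "orthomap"
    d.mkdir(exist_ok=True)
    pair = state["pair"]
    scheme = ScoringScheme(min_report_score=cfg.min_report_score)
    bbh = exon_bbh(pair.contracted_annotation, pair.contracted_genome,
                   pair.conserved_annotation, pair.conserved_genome, scheme)
    segments = collinear_segments(pair.contracted_annotation, bbh, pair.conserved_annotation)
    fates = classify_gene_fates(segments, pair.contracted_annotation,
                                pair.conserved_annotation, bbh)
    summary = fate_summary(fates, segments)
    with open(d / "pairs.tsv", "w") as fh:
        for p in bbh.pairs:
            fh.write(f"{p.exon_a_id}\t{p.exon_b_id}\t{p.score_ab:.1f}\t{p.score_ba:.1f}\n")
    with open(d / "segments.tsv", "w") as fh:
        for s in segments:
            fh.write(f"{s.contig_a_id}\t{s.contig_b_id}\t{len(s.genes_a)}\t{len(s.genes_b)}\n")
    with open(d / "fates.tsv", "w") as fh:
        for f in fates:
            fh.write(f"{f.gene_id}\t{f.fate}\t{f.evidence}\n")
    _write_json(summary, d / "summary.json")
    state.update(bbh=bbh, segments=segments, fates=fates, fate_counts=summary)
    _stage_log("orthomap", pairs=len(bbh.pairs), segments=len(segments), fates=len(fates))


def _stage_contract(cfg: PipelineConfig, out: Path, state: dict) -> None:
    d = out / "contract"
    d.mkdir(exist_ok=True)
    pair, bbh, segments = state["pair"], state["bbh"], state["segments"]
    part_a = partition_genome(pair.contracted_genome, pair.contracted_annotation)
    part_b = partition_genome(pair.conserved_genome, pair.conserved_annotation)
    in_a, in_b, in_fold = orthologous_intron_totals(
        bbh, pair.contracted_annotation, pair.conserved_annotation)
    ig_a, ig_b, ig_fold = orthologous_intergenic_totals(
        segments, bbh, pair.contracted_annotation, pair.conserved_annotation)

    events = []
    region_pairs = pair.matched_intergenic_pairs()[: cfg.n_indel_pairs]
    for rid, cons_seq, contr_seq in region_pairs:
        res = scan_long_indels(cons_seq, contr_seq, cfg.min_indel_length,
                               region_pair_id=rid)
        for ev in res.events:
            ev.repeat_associated = flag_repeat_associated(ev, cons_seq)
            events.append(ev)
    with open(d / "indel_events.tsv", "w") as fh:
        for ev in events:
            fh.write(f"{ev.region_pair_id}\t{ev.position_in_longer}\t{ev.length}\t"
                     f"{ev.shorter_genome}\t{int(ev.repeat_associated)}\n")
    report = {
        "partition_contracted": dataclasses.asdict(part_a),
        "partition_conserved": dataclasses.asdict(part_b),
        "orthologous_intron_totals": [in_a, in_b],
        "intron_fold": in_fold,
        "orthologous_intergenic_totals": [ig_a, ig_b],
        "intergenic_fold": ig_fold,
        "whole_genome_intergenic_fold": contraction_fold(
            part_a.intergenic_total, part_b.intergenic_total),
        "n_region_pairs_scanned": len(region_pairs),
        "n_long_indels": len(events),
        "n_repeat_associated": sum(1 for e in events if e.repeat_associated),
    }
    _write_json(report, d / "report.json")
    state["contract_report"] = report
    _stage_log("contract", intron_fold=in_fold, intergenic_fold=ig_fold, indels=len(events))


def _stage_stats(cfg: PipelineConfig, out: Path, state: dict) -> None:
    d = out / "stats"
    d.mkdir(exist_ok=True)
    pair = state["pair"]
    result = {}
    for name, genome, annotation in (
        ("contracted", pair.contracted_genome, pair.contracted_annotation),
        ("conserved", pair.conserved_genome, pair.conserved_annotation),
    ):
        gsum = gc_summary(genome)
        mean_i, median_i, _ = intron_stats(annotation)
        seqs = {c.id: c.sequence for c in genome}
        cds_set = [gene_cds(g, seqs[g.contig_id]) for g in annotation]
        result[name] = {
            "genome_gc": round(gsum.genome_gc, 4),
            "per_contig_gc_sd": round(gsum.observed_sd, 4),
            "null_gc_sd": round(gsum.null_sd, 4),
            "mean_intron_length": round(mean_i, 1),
            "median_intron_length": median_i,
            "enc": round(enc, 2) if (enc := effective_number_of_codons(cds_set)) else None,
            "gc3": round(g3, 4) if (g3 := gc3(cds_set)) is not None else None,
        }
    _write_json(result, d / "stats.json")
    state["stats"] = result
    _stage_log("stats", genomes=2)


def _stage_famloss(cfg: PipelineConfig, out: Path, state: dict) -> None:
    d = out / "famloss"
    d.mkdir(exist_ok=True)
    ancestor, fates = state["ancestor"], state["fates"]
    loss = loss_by_family_size(fates, ancestor.families)
    z, p = monotone_trend_test(loss, seed=cfg.seed)
    with open(d / "loss_by_size.tsv", "w") as fh:
        fh.write("family_size\tn_genes\tn_lost\tloss_fraction\tci_lo\tci_hi\tlow_support\n")
        for s in loss.sizes:
            lo, hi = loss.ci95[s]
            fh.write(f"{s}\t{loss.n_genes[s]}\t{loss.n_lost[s]}\t"
                     f"{loss.loss_fraction[s]:.3f}\t{lo:.3f}\t{hi:.3f}\t"
                     f"{int(s in loss.low_support)}\n")
    spectrum = family_size_spectrum({"conserved": ancestor.families})
    _write_json({"trend_z": z, "trend_p": p, "spectrum": spectrum,
                 "note": "trend test is additive tooling beyond the per-size fractions"},
                d / "summary.json")
    state["famloss"] = {"trend_z": z, "trend_p": p}
    _stage_log("famloss", buckets=len(loss.sizes), trend_p=round(p, 4))


def _stage_report(cfg: PipelineConfig, out: Path, state: dict) -> None:
    render_report(out)
    _stage_log("report", path=str(out / "report.md"))


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "merge": _stage_merge,
    "orthomap": _stage_orthomap,
    "contract": _stage_contract,
    "stats": _stage_stats,
    "famloss": _stage_famloss,
    "report": _stage_report,
}


def render_report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run (report.md).

    Requires the orthomap and contract outputs; famloss and stats sections
    are included only when present. Raises naming the missing stage."""
    run = Path(run_dir)
    lines = ["# Genome-contraction analysis report", ""]
    for required in ("orthomap/summary.json", "contract/report.json"):
        if not (run / required).exists():
            raise FileNotFoundError(
                f"incomplete run: missing stage output {required.split('/')[0]!r}"
            )
    fate = json.loads((run / "orthomap/summary.json").read_text())
    lines += ["## Gene fates in collinear segments", ""]
    for key in ("n_segments", "genes_in_segments_a", "genes_in_segments_b",
                "collinear", "transposed", "lost", "non_collinear"):
        lines.append(f"- {key}: {fate[key]}")
    contract = json.loads((run / "contract/report.json").read_text())
    lines += ["", "## Contraction", ""]
    for side in ("contracted", "conserved"):
        p = contract[f"partition_{side}"]
        lines.append(
            f"- {side}: exonic {p['exonic_total']} nt, intronic {p['intronic_total']} nt, "
            f"intergenic {p['intergenic_total']} nt (assembly {p['assembly_total']} nt)"
        )
    lines.append(f"- orthologous intron fold: {contract['intron_fold']}")
    lines.append(f"- orthologous intergenic fold: {contract['intergenic_fold']}")
    lines.append(f"- long indels: {contract['n_long_indels']} "
                 f"({contract['n_repeat_associated']} repeat-associated)")
    stats_path = run / "stats/stats.json"
    if stats_path.exists():
        st = json.loads(stats_path.read_text())
        lines += ["", "## Composition", ""]
        for name, s in st.items():
            lines.append(f"- {name}: GC {s['genome_gc']}, ENc {s['enc']}, "
                         f"mean intron {s['mean_intron_length']} nt")
    fam_path = run / "famloss/summary.json"
    if fam_path.exists():
        fam = json.loads(fam_path.read_text())
        lines += ["", "## Loss by family size", "",
                  f"- trend z = {fam['trend_z']:.2f}, one-sided p = {fam['trend_p']:.4f}"]
    text = "\n".join(lines) + "\n"
    (run / "report.md").write_text(text)
    return text
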