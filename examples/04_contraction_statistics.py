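"""Contraction statistics: genome partition, orthologous folds, long indels.

Folds are larger/smaller ratios of summed homologous feature lengths;
long indels are localized length differences between orthologous
intergenic regions, flagged when flanked by a direct low-complexity
repeat (a signature of recombination-mediated deletion).
"""

from synshrink import (
    AncestorSpec,
    ContractionSpec,
    evolve_pair,
    exon_bbh,
    collinear_segments,
    flag_repeat_associated,
    orthologous_intergenic_totals,
    orthologous_intron_totals,
    partition_genome,
    scan_long_indels,
    simulate_ancestor,
)

ancestor = simulate_ancestor(AncestorSpec(n_genes=80, n_contigs=5, seed=2))
pair = evolve_pair(ancestor, ContractionSpec(seed=2))
bbh = exon_bbh(pair.contracted_annotation, pair.contracted_genome,
               pair.conserved_annotation, pair.conserved_genome)
segments = collinear_segments(pair.contracted_annotation, bbh, pair.conserved_annotation)

for name, genome, ann in (("contracted", pair.contracted_genome, pair.contracted_annotation),
                          ("conserved ", pair.conserved_genome, pair.conserved_annotation)):
    p = partition_genome(genome, ann)
    print(f"{name}: exonic {p.exonic_total:>6}  intronic {p.intronic_total:>6}  "
          f"intergenic {p.intergenic_total:>6}  (total {p.assembly_total})")

in_a, in_b, in_fold = orthologous_intron_totals(
    bbh, pair.contracted_annotation, pair.conserved_annotation)
ig_a, ig_b, ig_fold = orthologous_intergenic_totals(
    segments, bbh, pair.contracted_annotation, pair.conserved_annotation)
print(f"orthologous introns:    {in_a} vs {in_b} nt -> fold {in_fold}")
print(f"orthologous intergenic: {ig_a} vs {ig_b} nt -> fold {ig_fold}")

n_events = n_repeat = 0
for rid, longer, shorter in pair.matched_intergenic_pairs()[:20]:
    for ev in scan_long_indels(longer, shorter, 500, region_pair_id=rid).events:
        n_events += 1
        n_repeat += flag_repeat_associated(ev, longer)
print(f"long indels (>500 nt) in 20 region pairs: {n_events}, "
      f"{n_repeat} repeat-associated")
# The folds recover the simulator's targets (2.5x introns, 4x intergenic);
# exon totals stay nearly equal because deletions never touch exons.
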