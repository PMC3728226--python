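# Methods

## The inference problem

Given two annotated genomes descended from a common ancestor — a *reduced*
genome A and a *reference* genome B — the pipeline decides, for each B gene
lying in a region whose gene order is conserved, whether it is still present
in place in A (`collinear`), present elsewhere (`transposed`), or absent
(`lost`), and measures how much shorter A's introns and intergenic regions
are than their B counterparts. All coordinates are 0-based half-open; GFF3
and tabular hit files convert at the I/O boundary and nowhere else. Gene
models are exon chains: introns are the gaps between consecutive exons, and
UTRs are not modelled — none of the statistics computed here needs finer
transcript structure.

## Homology scoring

No external aligner is required. The internal scorer is a translated-search
design: the DNA subject is translated in six frames; exact amino-acid
k-mer seeds (k = 4) locate candidate diagonals; diagonals within 32
residues of each other cluster, and clusters with at least 3 seeds are
scored by Smith–Waterman with affine gaps (BLOSUM62, gap open −10, extend
−1, a gap of length L costing −10 − L) on a window spanning the cluster
±32 residues. The minimum-seed rule discards isolated chance 4-mer
matches; at the divergences this scorer targets (≲ 20% amino-acid), a true
homolog seeds a diagonal many times, so sensitivity is unaffected — the
tests verify window-restricted scores equal the full unbanded DP on
mutated queries. The within-row affine-gap recurrence is resolved exactly
with a prefix-max scan (a horizontal gap run always opens from a cell that
did not itself end in one), which lets each DP row be vectorised.

Scores are raw; no e-value calibration is attempted. When the internal
scorer is used, "significant" means score ≥ 50; externally supplied hit
tables use an e-value cutoff of 10⁻⁶ instead. These two regimes are kept
explicit in the APIs that accept either.

## Orthology, segments, fates

Exon proteins are the in-phase slices of the gene's translated CDS. BBH
pairing is exon-level: ties on score break by longer alignment, then
lexicographic id, so results are order-independent. Gene-level orthologs
are the reciprocal majority vote of paired exons (ties: the pair with the
longest exon, then lexicographic id).

A collinear segment needs two distinct anchor genes — the first and last
ortholog-bearing genes of an A contig — whose partners lie on one B contig;
single-anchor contigs yield no segment. "Inside the segment" for fate
calls means overlapping the A-coordinate interval spanned by the two
anchor genes.

Fate precedence, per B gene in a segment: (1) gene-level BBH partner
inside the segment → collinear; (2) no significant hit → lost; (3) the
best-hit locus is the BBH partner of a *different* B gene with a higher
score → lost (the locus is owned by the other gene; this test deliberately
precedes the location test, otherwise every paralog-absorbed loss would
masquerade as a transposition); (4) best hit outside the segment →
transposed; (5) otherwise collinear. Genes in no segment are reported
separately, not classified.

## Contraction statistics

The genome partition counts a base as exonic if any exon covers it,
intronic if an intron but no exon covers it, intergenic otherwise — so the
three totals sum to the assembly length by construction. An intron is
*orthologous* when its two flanking exons are BBH-paired with two
transcript-adjacent exons of one partner gene, in consistent order; an
intergenic region qualifies when its flanking genes are orthologous and
adjacent in both genomes. Folds are larger/smaller, reported rounded to
one decimal with raw totals alongside.

The long-indel scan chains k-mers (k = 16) unique in both sequences by
longest increasing subsequence, with the sequence ends as terminal
anchors; a gap-length difference > 500 nt between consecutive anchors is
one event, positioned at the longer side's gap start. Events are *not*
polarized into deletion-in-A vs insertion-in-B — without an outgroup the
direction is unknowable, so events record only which side is shorter. The
repeat-association flag looks for a shared ≥ 10-mer between the two
breakpoint neighbourhoods (± 50 nt) whose dinucleotide Shannon entropy is
below 1.5 bits; entropy stands in for a DUST-like low-complexity
definition and is configurable.

## Composition statistics

The null SD of per-contig GC under independent uniform bases is analytic:
for unweighted per-contig values, sd = √(meanᵢ p(1−p)/Lᵢ) (between-contig
mean differences vanish under the null); a Monte-Carlo cross-check lives in
the tests, and a length-weighted variant is available. ENc follows
Wright's estimator — per-amino-acid homozygosity F̂ = (nΣp̂² − 1)/(n − 1),
class means for degeneracy classes {2, 3, 4, 6}, F̄₃ imputed as
(F̄₂ + F̄₄)/2 when Ile is unobserved, estimates clamped to [20, 61]. GC3 is
computed over synonymously variable codons only: Met, Trp and stop codons
are excluded because their third base is fixed by the protein and carries
no usage signal (this makes the degenerate two-codon example ATG AAA score
0, as a usage statistic should). Intron medians default to the
lower-middle element for even counts, with interpolation available.

## The simulator

`simulate_ancestor` builds gene families by duplicating a founder CDS with
~5% per-copy divergence (so family structure is recoverable by similarity)
and scatters members across contigs. Exon counts are 1 + Poisson(3.5)
(mean 4.5); exon lengths are lognormal around 214 nt rounded to codon
multiples; intron lengths lognormal with mean 134 nt and log-sigma 0.9
(median ≈ 89 nt); intergenic lengths lognormal with mean 1 kb; genome GC
0.40. CDSs are stop-free with fixed start/stop codons so every gene
translates cleanly.

`evolve_pair` derives two lineages. The conserved lineage receives only
substitutions (codon-safe inside exons: a substitution creating an
internal stop is reverted). The contracted lineage additionally undergoes:

* **gene loss** with probability looked up by family size (non-decreasing
  by contract), removing the whole locus;
* **transposition** of a configurable fraction of survivors to an
  intergenic position on a different contig;
* **deletions** confined to introns and intergenic regions (exons are
  immune, and intron *count* per surviving gene never changes). Deletions
  are planned per region proportionally to hit the configured class-wide
  folds (defaults 2.5× introns, 4.0× intergenic), with a post-deletion
  floor of 20 nt per intron, and any class-wide shortfall from spacing
  constraints redistributed to regions with spare capacity — so realized
  folds track targets to within a few percent;
* **repeat-mediated deletions**: a configurable fraction of deletions gets
  an identical low-complexity motif (e.g. (AT)ₙ, 15 nt) overwritten at
  both breakpoints in both lineages before the cut, leaving the canonical
  two-copies-flanking signature in the longer genome. The copies are
  planted identical after lineage substitutions, modelling recent,
  homogenised repeats.

One master seed drives per-stage derived streams; identical specs
reproduce byte-identical FASTA/GFF3. A conservation identity is asserted
in the tests: with substitution rate 0, contracted total = conserved total
− Σ deletion lengths − Σ lost locus lengths, exactly.

`simulate_contaminated_assembly` mixes random contaminant contigs into a
target assembly with coverages drawn from two normal modes (target high,
contaminant low) and taxon-labelled best hits, a configurable fraction of
target contigs receiving no hit.

What the simulator does **not** emulate: transposable elements and
segmental duplication, codon-aware substitution models, sequencing error,
assembly fragmentation or misjoins, UTRs, alternative isoforms, and
pseudogene decay (lost loci vanish instantly rather than eroding). Passing
recovery tests therefore demonstrate the *inference logic* is correct
under the stated generative model, not that real-data alignment noise,
repeat content, or annotation error are handled — on real genomes the
scorer's sensitivity and the anchor scan's alignability flag are the
binding constraints.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| min_coverage | 75× | coverage filter threshold; the boundary value is kept |
| target clade | Magnoliophyta | lineage component the best hit must contain |
| e-value cutoff | 10⁻⁶ | significance for external hit tables |
| min protein | > 50 aa | QC floor for merged gene models (strict) |
| seed k / band / min seeds | 4 aa / 32 / 3 | translated-search seeding |
| min_report_score | 50 | internal-scorer significance |
| min_indel_length | 500 nt | long-indel threshold (strict) |
| anchor_k | 16 nt | unique-k-mer anchors for the indel scan |
| repeat_min_len / window / entropy | 10 nt / 50 nt / 1.5 bits | repeat association |
| coverage_fraction | 0.5 | gene counted covered at ≥ 50% of its span |
| intron floor | 20 nt | minimum post-deletion intron length |

## Numerical and degenerate-input choices

Undefined ratios (no qualifying introns/regions, all-N sequences, constant
rank vectors, too few codons) are returned as `None`/NaN, never silently
zero. Coverage exactly at the threshold passes; protein length exactly 50
aa fails; an indel difference of exactly 500 nt is not an event. All
tie-breaks (BBH, merge survivor, cluster choice) end in lexicographic ids
so every operation is deterministic and permutation-invariant. The
Cochran–Armitage trend test uses a seeded permutation null for totals
≤ 1000 and the normal approximation above; it is additive tooling beyond
the per-size fractions and is labelled as such in pipeline output.

## Problem sizes

Unit tests run on 40–80-gene pairs; oracle-equivalence checks use 14–16
genes (where all-vs-all full DP is feasible) and 9-kb contigs for
per-base partition labelling. The recovery study runs at 1,000 genes,
seed 5, loss probabilities {1: 0.05, 2: 0.2, ≥3: 0.5}, 10% transposition,
folds 2.5/4.0, substitution rate 0.02/lineage; the acceptance script uses
500 genes so a full from-scratch run stays under a minute on one CPU.

## Known limitations

* The scorer's seeds are exact amino-acid 4-mers: sensitivity degrades
  beyond ~25% protein divergence; external hit tables are the intended
  fallback there.
* Segments assume no inversions or rearrangements between anchors;
  inversion-aware chaining is out of scope.
* Only the reference genome's genes are fate-classified; A-side genes
  without B partners (e.g. A-specific duplicates) are not categorised.
* The indel scan merges deletions that fall between the same anchor pair
  into one event; at high deletion density events under-count.
* Binomial CIs treat genes as independent, ignoring family structure
  (members of one family share a founder and a loss probability).
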