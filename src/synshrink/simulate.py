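"""Synthetic genome-pair and contaminated-assembly generator with ground truth.

The generator emulates the evolutionary scenario the pipeline is built to
infer: a common ancestor gives rise to a *conserved* lineage (substitutions
only) and a *contracted* lineage in which

* genes are lost with a probability that increases with gene-family size
  (redundant copies are more dispensable),
* a fraction of surviving genes transpose to new locations,
* introns and intergenic regions shrink through deletions until configured
  contraction folds are reached (exons are immune; intron *count* per
  surviving gene never changes),
* a fraction of deletions is recombination-mediated: an identical
  low-complexity direct repeat flanks both breakpoints, so the longer
  lineage retains two copies and the shorter one.

Every event is recorded in :class:`TruthTables` so recovery can be measured.
All randomness flows from explicit seeds via per-stage derived streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io import (
    Contig,
    FamilyTable,
    GeneModel,
    HitRecord,
    ParameterError,
    revcomp,
)

__all__ = [
    "LengthDist",
    "AncestorSpec",
    "ContractionSpec",
    "DeletionEvent",
    "TruthTables",
    "AncestorGenome",
    "EvolvedPair",
    "simulate_ancestor",
    "evolve_pair",
    "simulate_contaminated_assembly",
    "simulate_region_pair",
    "write_truth_tables",
]

_STOPS = ("TAA", "TAG", "TGA")
_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class LengthDist:
    """A named length distribution. ``lognormal`` is parameterised by its
    arithmetic mean and log-scale sigma; ``constant`` always returns the mean."""

    name: str = "lognormal"
    mean: float = 100.0
    sigma: float = 0.8
    min_value: int = 1

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ParameterError("distribution mean must be positive")
        if self.name not in ("lognormal", "constant"):
            raise ParameterError(f"unknown distribution {self.name!r}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.name == "constant":
            vals = np.full(size, self.mean)
        else:
            mu = math.log(self.mean) - self.sigma ** 2 / 2.0
            vals = rng.lognormal(mu, self.sigma, size)
        return np.maximum(np.rint(vals).astype(int), self.min_value)


@dataclass
class AncestorSpec:
    """Parameters of the simulated ancestral genome.

    Defaults follow compact plant-genome characteristics: ~4.5 exons per
    gene, mean intron length 134 nt (median ~89 via the lognormal sigma),
    genome GC 0.40.
    """

    n_genes: int = 500
    family_size_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.70, 2: 0.15, 3: 0.08, 4: 0.04, 5: 0.03}
    )
    exons_per_gene_mean: float = 4.5
    exon_length: LengthDist = field(default_factory=lambda: LengthDist("lognormal", 214.0, 0.5, 30))
    intron_length: LengthDist = field(default_factory=lambda: LengthDist("lognormal", 134.0, 0.9, 25))
    intergenic_length: LengthDist = field(default_factory=lambda: LengthDist("lognormal", 1000.0, 0.8, 50))
    gc_target: float = 0.40
    n_contigs: int = 10
    paralog_divergence: float = 0.05
    max_total_length: int = 200_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_contigs < 1:
            raise ParameterError("n_genes and n_contigs must be >= 1")
        total_p = sum(self.family_size_distribution.values())
        if abs(total_p - 1.0) > 1e-9:
            raise ParameterError("family size probabilities must sum to 1")
        if any(s < 1 for s in self.family_size_distribution):
            raise ParameterError("family sizes must be >= 1")
        if not 0.0 < self.gc_target < 1.0:
            raise ParameterError("gc_target must be in (0, 1)")
        expected = self.n_genes * (
            self.exons_per_gene_mean * self.exon_length.mean
            + (self.exons_per_gene_mean - 1) * self.intron_length.mean
            + self.intergenic_length.mean
        )
        if expected > self.max_total_length:
            raise ParameterError(
                f"spec implies ~{expected:.0f} nt, above cap {self.max_total_length}"
            )


@dataclass
class ContractionSpec:
    """Parameters of the contracting lineage."""

    loss_prob_by_family_size: dict[int, float] = field(
        default_factory=lambda: {1: 0.05, 2: 0.20, 3: 0.35, 4: 0.45, 5: 0.50}
    )
    transposition_fraction: float = 0.10
    intron_deletion_target_fold: float = 2.5
    intergenic_deletion_target_fold: float = 4.0
    deletion_length_distribution: LengthDist = field(
        default_factory=lambda: LengthDist("lognormal", 400.0, 1.0, 30)
    )
    repeat_mediated_fraction: float = 0.20
    substitution_rate: float = 0.02
    min_intron_length: int = 20
    min_intergenic_length: int = 10
    repeat_length: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = sorted(self.loss_prob_by_family_size)
        probs = [self.loss_prob_by_family_size[s] for s in sizes]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ParameterError("loss probabilities must be in [0,1]")
        if any(b < a for a, b in zip(probs, probs[1:])):
            raise ParameterError("loss probability must be non-decreasing in family size")
        for frac in (self.transposition_fraction, self.repeat_mediated_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ParameterError("fractions must be in [0,1]")
        if self.intron_deletion_target_fold < 1.0 or self.intergenic_deletion_target_fold < 1.0:
            raise ParameterError("target folds must be >= 1")
        if self.substitution_rate < 0:
            raise ParameterError("substitution_rate must be >= 0")

    def loss_prob(self, family_size: int) -> float:
        sizes = sorted(self.loss_prob_by_family_size)
        applicable = [s for s in sizes if s <= family_size]
        return self.loss_prob_by_family_size[applicable[-1]] if applicable else 0.0


@dataclass
class DeletionEvent:
    region_id: str
    position: int
    length: int
    repeat_mediated: bool


@dataclass
class TruthTables:
    """Ground truth of one evolved pair / contaminated assembly."""

    gene_fate: dict[str, str] = field(default_factory=dict)
    deletions: list[DeletionEvent] = field(default_factory=list)
    contamination_label: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# internal genome representation: per-contig part lists
# ---------------------------------------------------------------------------

@dataclass
class _Intergenic:
    uid: str
    seq: str


@dataclass
class _SimGene:
    uid: str
    family: str
    strand: str
    exons: list[str]     # transcript order
    introns: list[str]   # transcript order, len = len(exons) - 1

    @property
    def genomic_seq(self) -> str:
        parts = [self.exons[0]]
        for intron, exon in zip(self.introns, self.exons[1:]):
            parts.append(intron)
            parts.append(exon)
        s = "".join(parts)
        return revcomp(s) if self.strand == "-" else s

    def exon_offsets(self) -> list[tuple[int, int]]:
        """Exon intervals relative to the gene's genomic start, sorted."""
        ivals = []
        pos = 0
        for i, ex in enumerate(self.exons):
            ivals.append((pos, pos + len(ex)))
            pos += len(ex)
            if i < len(self.introns):
                pos += len(self.introns[i])
        if self.strand == "-":
            total = pos
            ivals = sorted((total - b, total - a) for a, b in ivals)
        return ivals


_Part = _Intergenic | _SimGene


@dataclass
class AncestorGenome:
    """Simulated ancestral genome: emitted records plus internal structure."""

    spec: AncestorSpec
    parts: list[list[_Part]]           # per contig
    genome: list[Contig] = field(default_factory=list)
    annotation: list[GeneModel] = field(default_factory=list)
    families: FamilyTable = field(default_factory=FamilyTable)


@dataclass
class EvolvedPair:
    """A (conserved, contracted) genome pair with full ground truth.

    ``conserved`` plays the role of the larger reference genome (genome B in
    the orthology modules), ``contracted`` the reduced genome (genome A).
    """

    conserved_genome: list[Contig]
    conserved_annotation: list[GeneModel]
    contracted_genome: list[Contig]
    contracted_annotation: list[GeneModel]
    truth: TruthTables
    conserved_parts: list[list[_Part]] = field(default_factory=list, repr=False)
    contracted_parts: list[list[_Part]] = field(default_factory=list, repr=False)

    def matched_intergenic_pairs(self) -> list[tuple[str, str, str]]:
        """(region_id, conserved_seq, contracted_seq) for intergenic regions
        that survived contraction as a single unsplit unit in both lineages."""
        cons = {p.uid: p.seq for row in self.conserved_parts for p in row
                if isinstance(p, _Intergenic)}
        out = []
        for row in self.contracted_parts:
            for p in row:
                if isinstance(p, _Intergenic) and p.uid in cons:
                    out.append((p.uid, cons[p.uid], p.seq))
        return out


# ---------------------------------------------------------------------------
# sequence sampling / mutation helpers
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _random_cds(rng: np.random.Generator, n_nt: int, gc: float) -> str:
    """Random in-frame CDS: ATG + stop-free codons + one stop codon."""
    if n_nt % 3 or n_nt < 9:
        raise ParameterError("CDS length must be a multiple of 3 and >= 9")
    n_codons = n_nt // 3 - 2
    body = _random_dna(rng, 3 * n_codons, gc)
    codons = [body[i : i + 3] for i in range(0, len(body), 3)]
    for i, c in enumerate(codons):
        while codons[i] in _STOPS:
            codons[i] = _random_dna(rng, 3, gc)
    stop = _STOPS[rng.integers(len(_STOPS))]
    return "ATG" + "".join(codons) + stop


def _mutate_noncoding(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0 or not seq:
        return seq
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq
    positions = rng.choice(len(seq), size=n, replace=False)
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    for pos in positions:
        cur = arr[pos].decode()
        choices = [b for b in "ACGT" if b != cur]
        arr[pos] = choices[rng.integers(3)].encode()
    return arr.tobytes().decode()


def _mutate_cds(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitutions that keep the CDS translatable: the start codon, the
    terminal stop, and stop-free reading are preserved (a substitution that
    would create an internal stop is reverted)."""
    if rate <= 0 or len(seq) < 9:
        return seq
    mutated = list(_mutate_noncoding(seq[3:-3], rate, rng))
    for i in range(0, len(mutated) - 2, 3):
        if "".join(mutated[i : i + 3]) in _STOPS:
            mutated[i : i + 3] = seq[3 + i : 6 + i]
    return seq[:3] + "".join(mutated) + seq[-3:]


# ---------------------------------------------------------------------------
# ancestor
# ---------------------------------------------------------------------------

def _emit(parts: list[list[_Part]], contig_prefix: str = "ctg",
          source: str = "sim") -> tuple[list[Contig], list[GeneModel]]:
    """Materialise a part structure into Contig + GeneModel records."""
    contigs: list[Contig] = []
    genes: list[GeneModel] = []
    for ci, row in enumerate(parts):
        cid = f"{contig_prefix}{ci + 1:03d}"
        chunks: list[str] = []
        pos = 0
        for part in row:
            if isinstance(part, _Intergenic):
                chunks.append(part.seq)
                pos += len(part.seq)
            else:
                from .align import translate_dna

                gseq = part.genomic_seq
                exons = [(pos + a, pos + b) for a, b in part.exon_offsets()]
                genes.append(
                    GeneModel(
                        id=part.uid,
                        contig_id=cid,
                        strand=part.strand,
                        exons=exons,
                        source=source,
                        protein=translate_dna("".join(part.exons)).rstrip("*"),
                    )
                )
                chunks.append(gseq)
                pos += len(gseq)
        contigs.append(Contig(id=cid, sequence="".join(chunks)))
    return contigs, genes


def simulate_ancestor(spec: AncestorSpec) -> AncestorGenome:
    """Generate the ancestral genome: families of diverged paralogs placed on
    contigs, separated by intergenic sequence. Deterministic given the seed."""
    rng = np.random.default_rng([spec.seed, 1])

    sizes = sorted(spec.family_size_distribution)
    probs = [spec.family_size_distribution[s] for s in sizes]

    genes: list[_SimGene] = []
    fam_idx = 0
    families = FamilyTable()
    while len(genes) < spec.n_genes:
        fam_idx += 1
        fam_id = f"fam{fam_idx:04d}"
        size = int(rng.choice(sizes, p=probs))
        size = min(size, spec.n_genes - len(genes))

        n_exons = 1 + int(rng.poisson(max(spec.exons_per_gene_mean - 1.0, 0.0)))
        exon_lengths = spec.exon_length.sample(rng, n_exons)
        exon_lengths = np.maximum((exon_lengths // 3) * 3, 30)
        total = int(exon_lengths.sum())
        cds = _random_cds(rng, total, spec.gc_target)
        founder_exons: list[str] = []
        off = 0
        for L in exon_lengths:
            founder_exons.append(cds[off : off + int(L)])
            off += int(L)
        founder_introns = [
            _random_dna(rng, int(L), spec.gc_target)
            for L in spec.intron_length.sample(rng, n_exons - 1)
        ]

        for copy in range(size):
            uid = f"g{len(genes) + 1:05d}"
            if copy == 0:
                exons, introns = founder_exons, founder_introns
            else:
                mutated_cds = _mutate_cds(cds, spec.paralog_divergence, rng)
                exons = []
                off = 0
                for L in exon_lengths:
                    exons.append(mutated_cds[off : off + int(L)])
                    off += int(L)
                introns = [
                    _mutate_noncoding(s, spec.paralog_divergence, rng)
                    for s in founder_introns
                ]
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(_SimGene(uid, fam_id, strand, list(exons), list(introns)))
            families.assignments[uid] = fam_id

    rng.shuffle(genes)  # scatter family members across contigs

    parts: list[list[_Part]] = [[] for _ in range(spec.n_contigs)]
    ig_counter = 0
    for ci in range(spec.n_contigs):
        L = int(spec.intergenic_length.sample(rng, 1)[0])
        ig_counter += 1
        parts[ci].append(_Intergenic(f"ig{ig_counter:05d}", _random_dna(rng, L, spec.gc_target)))
    for gi, gene in enumerate(genes):
        ci = gi % spec.n_contigs
        parts[ci].append(gene)
        L = int(spec.intergenic_length.sample(rng, 1)[0])
        ig_counter += 1
        parts[ci].append(_Intergenic(f"ig{ig_counter:05d}", _random_dna(rng, L, spec.gc_target)))

    genome, annotation = _emit(parts)
    return AncestorGenome(spec=spec, parts=parts, genome=genome,
                          annotation=annotation, families=families)


# ---------------------------------------------------------------------------
# deletion planning
# ---------------------------------------------------------------------------

_LOW_COMPLEXITY_MOTIFS = ("AT", "TA", "CA", "AC", "GA", "TG")


@dataclass
class _Del:
    pos: int
    length: int
    motif: str | None  # repeat motif when recombination-mediated


def _plan_deletions(region_len: int, target_remove: int, rng: np.random.Generator,
                    dist: LengthDist, floor: int, repeat_frac: float,
                    repeat_len: int, margin: int = 30) -> list[_Del]:
    """Non-overlapping deletions in one region, summing to ~target_remove
    while never shrinking the region below ``floor``."""
    removable = max(0, region_len - floor)
    target = min(target_remove, removable)
    if target <= 0:
        return []
    free: list[tuple[int, int]] = [(margin, region_len - margin)]
    plan: list[_Del] = []
    removed = 0
    for _ in range(200):
        if removed >= target:
            break
        want = min(int(dist.sample(rng, 1)[0]), target - removed)
        fits = [(a, b) for a, b in free if b - a >= want + 2 * margin]
        if not fits:
            caps = [b - a - 2 * margin for a, b in free]
            if not caps or max(caps) < dist.min_value:
                break
            want = max(caps)
            fits = [(a, b) for a, b in free if b - a >= want + 2 * margin]
        a, b = fits[rng.integers(len(fits))]
        pos = int(rng.integers(a, b - want + 1))
        motif = None
        if rng.random() < repeat_frac and want >= repeat_len and pos >= repeat_len:
            base = _LOW_COMPLEXITY_MOTIFS[rng.integers(len(_LOW_COMPLEXITY_MOTIFS))]
            motif = (base * repeat_len)[:repeat_len]
        plan.append(_Del(pos, want, motif))
        removed += want
        free.remove((a, b))
        if pos - margin > a:
            free.append((a, pos - margin))
        if b > pos + want + margin:
            free.append((pos + want + margin, b))
    plan.sort(key=lambda d: d.pos)
    return plan


def _plan_region_set(
    regions: dict,
    fold: float,
    rng: np.random.Generator,
    dist: LengthDist,
    floor: int,
    repeat_frac: float,
    repeat_len: int,
    margin: int,
) -> dict:
    """Deletion plans for a whole class of regions (all introns, or all
    intergenic regions), hitting the class-wide contraction fold.

    Each region first receives a proportional target so per-region folds
    track the class fold; any class-wide shortfall from spacing constraints
    is then redistributed to regions with spare capacity."""
    f = 1.0 - 1.0 / fold
    removable_total = sum(max(0, L - floor) for L in regions.values())
    if f * sum(regions.values()) > removable_total:
        raise ParameterError(
            f"target fold {fold} unreachable under the minimum-length floor {floor}"
        )
    plans = {rid: _plan_deletions(L, int(round(f * L)), rng, dist, floor,
                                  repeat_frac, repeat_len, margin)
             for rid, L in regions.items()}
    removed = {rid: sum(d.length for d in plan) for rid, plan in plans.items()}
    total_target = int(round(f * sum(regions.values())))
    deficit = total_target - sum(removed.values())
    for _ in range(3):
        if deficit <= max(1, int(0.005 * total_target)):
            break
        order = sorted(regions, key=lambda r: -(regions[r] - floor - removed[r]))
        for rid in order:
            if deficit <= 0:
                break
            cap = regions[rid] - floor - removed[rid]
            if cap < dist.min_value:
                continue
            new_plan = _plan_deletions(
                regions[rid], removed[rid] + min(cap, deficit), rng, dist,
                floor, repeat_frac, repeat_len, margin)
            delta = sum(d.length for d in new_plan) - removed[rid]
            if delta > 0:
                deficit -= delta
                plans[rid] = new_plan
                removed[rid] += delta
    return plans


def _plant_repeats(seq: str, plan: list[_Del]) -> str:
    """Overwrite both breakpoint flanks of repeat-mediated deletions with the
    deletion's motif (length-preserving)."""
    arr = list(seq)
    for d in plan:
        if d.motif is None:
            continue
        r = len(d.motif)
        arr[d.pos - r : d.pos] = d.motif
        arr[d.pos + d.length - r : d.pos + d.length] = d.motif
    return "".join(arr)


def _apply_deletions(seq: str, plan: list[_Del]) -> str:
    out = []
    prev = 0
    for d in plan:
        out.append(seq[prev : d.pos])
        prev = d.pos + d.length
    out.append(seq[prev:])
    return "".join(out)


# ---------------------------------------------------------------------------
# lineage evolution
# ---------------------------------------------------------------------------

def _substitute_parts(parts: list[list[_Part]], rate: float,
                      rng: np.random.Generator) -> list[list[_Part]]:
    out: list[list[_Part]] = []
    for row in parts:
        new_row: list[_Part] = []
        for p in row:
            if isinstance(p, _Intergenic):
                new_row.append(_Intergenic(p.uid, _mutate_noncoding(p.seq, rate, rng)))
            else:
                cds = "".join(p.exons)
                mut = _mutate_cds(cds, rate, rng)
                exons, off = [], 0
                for ex in p.exons:
                    exons.append(mut[off : off + len(ex)])
                    off += len(ex)
                introns = [_mutate_noncoding(s, rate, rng) for s in p.introns]
                new_row.append(_SimGene(p.uid, p.family, p.strand, exons, introns))
        out.append(new_row)
    return out


def evolve_pair(ancestor: AncestorGenome, contraction: ContractionSpec) -> EvolvedPair:
    """Evolve the ancestor into a conserved and a contracted lineage.

    The conserved lineage receives substitutions only. The contracted lineage
    additionally undergoes family-size-dependent gene loss (the locus is
    removed), transposition of surviving genes to other contigs, and intron /
    intergenic deletions planned per region to hit the configured folds,
    with a fraction placed between planted direct low-complexity repeats.
    """
    rng = np.random.default_rng([contraction.seed, 2])
    truth = TruthTables()
    fam_sizes = ancestor.families.family_sizes

    # --- fate decisions -----------------------------------------------------
    all_genes = [p for row in ancestor.parts for p in row if isinstance(p, _SimGene)]
    for g in all_genes:
        p_loss = contraction.loss_prob(fam_sizes[g.family])
        if rng.random() < p_loss:
            truth.gene_fate[g.uid] = "lost"
        elif rng.random() < contraction.transposition_fraction:
            truth.gene_fate[g.uid] = "transposed"
        else:
            truth.gene_fate[g.uid] = "collinear"

    # --- deletion plans on ancestor coordinates -----------------------------
    dist = contraction.deletion_length_distribution
    intron_regions: dict[tuple[str, int], int] = {}
    ig_regions: dict[str, int] = {}
    for row in ancestor.parts:
        for p in row:
            if isinstance(p, _SimGene):
                if truth.gene_fate[p.uid] == "lost":
                    continue
                for k, intron in enumerate(p.introns):
                    intron_regions[(p.uid, k)] = len(intron)
            else:
                ig_regions[p.uid] = len(p.seq)

    intron_plans = _plan_region_set(
        intron_regions, contraction.intron_deletion_target_fold, rng, dist,
        contraction.min_intron_length, contraction.repeat_mediated_fraction,
        contraction.repeat_length, margin=5)
    ig_plans = _plan_region_set(
        ig_regions, contraction.intergenic_deletion_target_fold, rng, dist,
        contraction.min_intergenic_length, contraction.repeat_mediated_fraction,
        contraction.repeat_length, margin=20)
    intron_plans = {k: v for k, v in intron_plans.items() if v}
    ig_plans = {k: v for k, v in ig_plans.items() if v}
    for (uid, k), plan in intron_plans.items():
        for d in plan:
            truth.deletions.append(DeletionEvent(
                f"intron:{uid}:{k}", d.pos, d.length, d.motif is not None))
    for uid, plan in ig_plans.items():
        for d in plan:
            truth.deletions.append(DeletionEvent(
                f"intergenic:{uid}", d.pos, d.length, d.motif is not None))

    # --- conserved lineage: substitutions, then repeat planting -------------
    sub_rng_b = np.random.default_rng([contraction.seed, 3])
    conserved = _substitute_parts(ancestor.parts, contraction.substitution_rate, sub_rng_b)
    for row in conserved:
        for i, p in enumerate(row):
            if isinstance(p, _Intergenic) and p.uid in ig_plans:
                row[i] = _Intergenic(p.uid, _plant_repeats(p.seq, ig_plans[p.uid]))
            elif isinstance(p, _SimGene):
                introns = [
                    _plant_repeats(s, intron_plans[(p.uid, k)])
                    if (p.uid, k) in intron_plans else s
                    for k, s in enumerate(p.introns)
                ]
                row[i] = replace(p, introns=introns)

    # --- contracted lineage --------------------------------------------------
    sub_rng_a = np.random.default_rng([contraction.seed, 4])
    contracted = _substitute_parts(ancestor.parts, contraction.substitution_rate, sub_rng_a)

    transposed_genes: list[tuple[_SimGene, int]] = []
    for ci, row in enumerate(contracted):
        kept: list[_Part] = []
        for p in row:
            if isinstance(p, _SimGene):
                fate = truth.gene_fate[p.uid]
                if fate == "lost":
                    continue
                if fate == "transposed":
                    transposed_genes.append((p, ci))
                    continue
            kept.append(p)
        contracted[ci] = kept

    # deletions (after repeat planting at homologous coordinates)
    for row in contracted:
        for i, p in enumerate(row):
            if isinstance(p, _Intergenic) and p.uid in ig_plans:
                plan = ig_plans[p.uid]
                row[i] = _Intergenic(p.uid, _apply_deletions(_plant_repeats(p.seq, plan), plan))
            elif isinstance(p, _SimGene):
                introns = []
                for k, s in enumerate(p.introns):
                    plan = intron_plans.get((p.uid, k))
                    introns.append(_apply_deletions(_plant_repeats(s, plan), plan) if plan else s)
                row[i] = replace(p, introns=introns)

    # transposition: reinsert each mover by splitting an intergenic region on
    # a different contig (split halves get fresh uids)
    split_counter = 0
    for g, origin_ci in transposed_genes:
        introns = []
        for k, s in enumerate(g.introns):
            plan = intron_plans.get((g.uid, k))
            introns.append(_apply_deletions(_plant_repeats(s, plan), plan) if plan else s)
        g = replace(g, introns=introns)
        other = [ci for ci in range(len(contracted)) if ci != origin_ci]
        if not other:
            other = [origin_ci]
        candidates = [
            (ci, pi) for ci in other for pi, p in enumerate(contracted[ci])
            if isinstance(p, _Intergenic) and len(p.seq) >= 40
        ]
        if not candidates:
            contracted[int(rng.integers(len(contracted)))].append(g)
            continue
        ci, pi = candidates[rng.integers(len(candidates))]
        host = contracted[ci][pi]
        assert isinstance(host, _Intergenic)
        cut = int(rng.integers(20, len(host.seq) - 19))
        split_counter += 1
        left = _Intergenic(f"{host.uid}.s{split_counter}a", host.seq[:cut])
        right = _Intergenic(f"{host.uid}.s{split_counter}b", host.seq[cut:])
        contracted[ci][pi : pi + 1] = [left, g, right]

    conserved_genome, conserved_annotation = _emit(conserved)
    contracted_genome, contracted_annotation = _emit(contracted)
    return EvolvedPair(
        conserved_genome=conserved_genome,
        conserved_annotation=conserved_annotation,
        contracted_genome=contracted_genome,
        contracted_annotation=contracted_annotation,
        truth=truth,
        conserved_parts=conserved,
        contracted_parts=contracted,
    )


# ---------------------------------------------------------------------------
# contaminated assembly
# ---------------------------------------------------------------------------

_PLANT_LINEAGE = "Eukaryota;Viridiplantae;Streptophyta;Magnoliophyta;Lamiales"
_CONTAMINANT_LINEAGES = (
    "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacterales",
    "Bacteria;Cyanobacteriota;Cyanophyceae;Nostocales",
    "Eukaryota;Fungi;Ascomycota;Saccharomycetes",
    "Eukaryota;Sar;Ciliophora;Oligohymenophorea",
)


def simulate_contaminated_assembly(
    target_genome: list[Contig],
    n_contaminant_contigs: int = 50,
    target_coverage_mean: float = 150.0,
    contaminant_coverage_mean: float = 20.0,
    coverage_cv: float = 0.10,
    no_hit_fraction: float = 0.20,
    contaminant_length: LengthDist | None = None,
    gc: float = 0.45,
    seed: int = 0,
) -> tuple[list[Contig], list[HitRecord], dict[str, str]]:
    """Mix contaminant contigs into a target assembly.

    Coverages are drawn from two normal modes (target high, contaminant
    low, as when contaminating organisms are at lower abundance than the
    sequenced one). Contaminant contigs receive best hits outside
    Magnoliophyta; a configurable fraction of target contigs receives no
    hit at all. Returns (contigs, hit table, truth labels).
    """
    if target_coverage_mean <= contaminant_coverage_mean:
        raise ParameterError("target coverage mode must exceed the contaminant mode")
    rng = np.random.default_rng([seed, 5])
    dist = contaminant_length or LengthDist("lognormal", 2000.0, 0.7, 300)

    contigs: list[Contig] = []
    hits: list[HitRecord] = []
    labels: dict[str, str] = {}

    for c in target_genome:
        cov = max(1.0, rng.normal(target_coverage_mean, coverage_cv * target_coverage_mean))
        contigs.append(Contig(c.id, c.sequence, mean_coverage=cov))
        labels[c.id] = "target"
        if rng.random() >= no_hit_fraction:
            hits.append(HitRecord(
                query_id=c.id, subject_id=f"plantdb_{rng.integers(10 ** 6):06d}",
                score=float(rng.integers(150, 400)),
                significance=float(10.0 ** -rng.uniform(20, 80)),
                query_interval=(0, min(500, c.length)),
                subject_interval=(0, min(500, c.length)),
                subject_taxon=_PLANT_LINEAGE,
            ))

    for i in range(n_contaminant_contigs):
        cid = f"contam{i + 1:04d}"
        L = int(dist.sample(rng, 1)[0])
        cov = max(1.0, rng.normal(contaminant_coverage_mean, coverage_cv * contaminant_coverage_mean))
        contigs.append(Contig(cid, _random_dna(rng, L, gc), mean_coverage=cov))
        labels[cid] = "contaminant"
        lineage = _CONTAMINANT_LINEAGES[int(rng.integers(len(_CONTAMINANT_LINEAGES)))]
        hits.append(HitRecord(
            query_id=cid, subject_id=f"envdb_{rng.integers(10 ** 6):06d}",
            score=float(rng.integers(150, 400)),
            significance=float(10.0 ** -rng.uniform(20, 80)),
            query_interval=(0, min(500, L)),
            subject_interval=(0, min(500, L)),
            subject_taxon=lineage,
        ))
    return contigs, hits, labels


# ---------------------------------------------------------------------------
# standalone region pairs (for indel-scan studies)
# ---------------------------------------------------------------------------

def simulate_region_pair(
    length: int = 8000,
    n_deletions: int = 2,
    deletion_length: tuple[int, int] = (600, 1500),
    repeat_mediated: float = 0.3,
    substitution_rate: float = 0.02,
    gc: float = 0.40,
    repeat_length: int = 15,
    seed: int = 0,
) -> tuple[str, str, list[DeletionEvent]]:
    """One orthologous region pair with planted deletions.

    Returns (longer_seq, shorter_seq, truth) where truth positions refer to
    the longer sequence.
    """
    rng = np.random.default_rng([seed, 6])
    base = _random_dna(rng, length, gc)
    lo, hi = deletion_length
    slot = length // max(n_deletions, 1)
    plan: list[_Del] = []
    for i in range(n_deletions):
        want = int(rng.integers(lo, hi + 1))
        a = i * slot + 200
        b = (i + 1) * slot - 200 - want
        if b <= a:
            continue
        pos = int(rng.integers(a, b))
        motif = None
        if rng.random() < repeat_mediated:
            m = _LOW_COMPLEXITY_MOTIFS[rng.integers(len(_LOW_COMPLEXITY_MOTIFS))]
            motif = (m * repeat_length)[:repeat_length]
        plan.append(_Del(pos, want, motif))
    plan.sort(key=lambda d: d.pos)
    longer = _mutate_noncoding(base, substitution_rate, rng)
    shorter = _mutate_noncoding(base, substitution_rate, rng)
    longer = _plant_repeats(longer, plan)
    shorter = _apply_deletions(_plant_repeats(shorter, plan), plan)
    truth = [DeletionEvent("region", d.pos, d.length, d.motif is not None) for d in plan]
    return longer, shorter, truth


# ---------------------------------------------------------------------------
# truth table serialisation
# ---------------------------------------------------------------------------

def write_truth_tables(truth: TruthTables, directory) -> None:
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "truth_fates.tsv", "w") as fh:
        for gene, fate in truth.gene_fate.items():
            fh.write(f"{gene}\t{fate}\n")
    with open(d / "truth_deletions.tsv", "w") as fh:
        for ev in truth.deletions:
            fh.write(f"{ev.region_id}\t{ev.position}\t{ev.length}\t{int(ev.repeat_mediated)}\n")
    with open(d / "truth_contamination.tsv", "w") as fh:
        for cid, label in truth.contamination_label.items():
            fh.write(f"{cid}\t{label}\n")
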