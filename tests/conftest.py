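import pytest

from synshrink.align import ScoringScheme
from synshrink.orthology import classify_gene_fates, collinear_segments, exon_bbh
from synshrink.simulate import (
    AncestorSpec,
    ContractionSpec,
    evolve_pair,
    simulate_ancestor,
)


@pytest.fixture(scope="session")
def big_ancestor():
    """~5.8 Mb genome for law-of-large-numbers composition checks."""
    return simulate_ancestor(AncestorSpec(n_genes=2200, n_contigs=10, seed=9))


@pytest.fixture(scope="session")
def small_ancestor():
    return simulate_ancestor(AncestorSpec(n_genes=60, n_contigs=4, seed=7))


@pytest.fixture(scope="session")
def small_pair(small_ancestor):
    return evolve_pair(small_ancestor, ContractionSpec(seed=7))


@pytest.fixture(scope="session")
def small_bbh(small_pair):
    return exon_bbh(
        small_pair.contracted_annotation,
        small_pair.contracted_genome,
        small_pair.conserved_annotation,
        small_pair.conserved_genome,
        ScoringScheme(),
    )


@pytest.fixture(scope="session")
def small_segments(small_pair, small_bbh):
    return collinear_segments(
        small_pair.contracted_annotation, small_bbh, small_pair.conserved_annotation
    )


@pytest.fixture(scope="session")
def small_fates(small_pair, small_bbh, small_segments):
    return classify_gene_fates(
        small_segments,
        small_pair.contracted_annotation,
        small_pair.conserved_annotation,
        small_bbh,
    )


# ---------------------------------------------------------------------------
# the recovery-study conditions: a 1000-gene pair with family-size-dependent
# loss, 10% transposition, intron fold 2.5, intergenic fold 4.0, 2%
# substitutions per lineage
# ---------------------------------------------------------------------------

RECOVERY_LOSS_PROBS = {1: 0.05, 2: 0.20, 3: 0.50}


@pytest.fixture(scope="session")
def recovery_ancestor():
    return simulate_ancestor(AncestorSpec(n_genes=1000, n_contigs=12, seed=5))


@pytest.fixture(scope="session")
def recovery_pair(recovery_ancestor):
    spec = ContractionSpec(
        loss_prob_by_family_size=RECOVERY_LOSS_PROBS,
        transposition_fraction=0.10,
        intron_deletion_target_fold=2.5,
        intergenic_deletion_target_fold=4.0,
        substitution_rate=0.02,
        seed=5,
    )
    return evolve_pair(recovery_ancestor, spec)


@pytest.fixture(scope="session")
def recovery_bbh(recovery_pair):
    return exon_bbh(
        recovery_pair.contracted_annotation,
        recovery_pair.contracted_genome,
        recovery_pair.conserved_annotation,
        recovery_pair.conserved_genome,
        ScoringScheme(),
    )


@pytest.fixture(scope="session")
def recovery_segments(recovery_pair, recovery_bbh):
    return collinear_segments(
        recovery_pair.contracted_annotation, recovery_bbh,
        recovery_pair.conserved_annotation,
    )


@pytest.fixture(scope="session")
def recovery_fates(recovery_pair, recovery_bbh, recovery_segments):
    return classify_gene_fates(
        recovery_segments,
        recovery_pair.contracted_annotation,
        recovery_pair.conserved_annotation,
        recovery_bbh,
    )
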