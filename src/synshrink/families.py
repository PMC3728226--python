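"""Gene-family size versus gene loss.

Genes of the reference (larger) genome are bucketed by the size of their
family in that genome; the fraction classified as lost per bucket
quantifies how redundancy predisposes to loss. A Cochran-Armitage-style
one-sided trend test makes the qualitative claim (loss increases with
family size) testable; for small totals the null distribution is obtained
by permutation.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .io import FamilyTable, ParameterError, ValidationError
from .orthology import GeneFate

__all__ = [
    "LossByFamilySize",
    "loss_by_family_size",
    "family_size_spectrum",
    "monotone_trend_test",
]


@dataclass
class LossByFamilySize:
    sizes: list[int]
    n_genes: dict[int, int]
    n_lost: dict[int, int]
    loss_fraction: dict[int, float]
    ci95: dict[int, tuple[float, float]] = field(default_factory=dict)
    low_support: set[int] = field(default_factory=set)


def _binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson interval."""
    alpha = 1 - level
    lo = scipy.stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = scipy.stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def loss_by_family_size(
    fates: list[GeneFate],
    families: FamilyTable,
    min_support: int = 10,
) -> LossByFamilySize:
    """Bucket fate-classified reference genes by family size; fraction lost
    per bucket with Clopper-Pearson 95% CIs. Genes missing from the family
    table are an error (all ids listed)."""
    missing = [f.gene_id for f in fates if f.gene_id not in families.assignments]
    if missing:
        raise ValidationError(
            f"{len(missing)} fate-classified genes missing from family table: "
            + ", ".join(sorted(missing)[:10])
        )
    sizes_of = families.family_sizes
    n_genes: dict[int, int] = defaultdict(int)
    n_lost: dict[int, int] = defaultdict(int)
    for f in fates:
        s = sizes_of[families.assignments[f.gene_id]]
        n_genes[s] += 1
        if f.fate == "lost":
            n_lost[s] += 1
    sizes = sorted(n_genes)
    frac = {s: n_lost[s] / n_genes[s] for s in sizes}
    ci = {s: _binomial_ci(n_lost[s], n_genes[s]) for s in sizes}
    low = {s for s in sizes if n_genes[s] < min_support}
    return LossByFamilySize(
        sizes=sizes,
        n_genes=dict(n_genes),
        n_lost=dict(n_lost),
        loss_fraction=frac,
        ci95=ci,
        low_support=low,
    )


def family_size_spectrum(tables: dict[str, FamilyTable]) -> dict[str, dict[int, int]]:
    """Per genome: number of genes belonging to families of each size."""
    if not tables:
        raise ParameterError("at least one family table required")
    out: dict[str, dict[int, int]] = {}
    for genome, table in tables.items():
        sizes_of = table.family_sizes
        hist: dict[int, int] = defaultdict(int)
        for fam_size in (sizes_of[f] for f in table.assignments.values()):
            hist[fam_size] += 1
        out[genome] = dict(sorted(hist.items()))
    return out


def monotone_trend_test(
    loss: LossByFamilySize,
    n_permutations: int = 2000,
    exact_max_n: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """One-sided Cochran-Armitage trend test of loss fraction increasing
    with family size.

    Returns (z statistic, p value); the p value comes from a seeded
    permutation null when the total gene count is at most ``exact_max_n``,
    otherwise from the normal approximation. (NaN, NaN) when fewer than
    two buckets have support.
    """
    sizes = [s for s in loss.sizes if loss.n_genes[s] > 0]
    if len(sizes) < 2:
        return float("nan"), float("nan")
    n = np.array([loss.n_genes[s] for s in sizes], dtype=float)
    k = np.array([loss.n_lost[s] for s in sizes], dtype=float)
    w = np.array(sizes, dtype=float)
    N, K = n.sum(), k.sum()
    if K == 0 or K == N:
        return 0.0, 1.0
    pbar = K / N
    t_obs = float((w * k).sum())
    mean = pbar * float((w * n).sum())
    var = pbar * (1 - pbar) * (float((n * w ** 2).sum()) - float((n * w).sum()) ** 2 / N)
    z = (t_obs - mean) / np.sqrt(var) if var > 0 else 0.0

    if N <= exact_max_n:
        rng = np.random.default_rng([seed, 7])
        labels = np.repeat(w, n.astype(int))
        indicator = np.zeros(int(N))
        indicator[: int(K)] = 1.0
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(indicator)
            if float((labels * perm).sum()) >= t_obs - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    else:
        p = float(scipy.stats.norm.sf(z))
    return float(z), float(p)
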