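"""Cross-dataset DEG comparison statistics.

Two differential-expression tables are compared by (i) intersecting their
significant gene sets and testing the overlap with a one-sided (upper-tail)
hypergeometric test against a caller-supplied background universe, (ii)
measuring sign concordance of the shared log2 fold changes, and (iii) rank
correlation (Spearman) of the shared fold changes.  Multiple comparisons are
corrected with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats import DEGRecord, DEGTable

__all__ = [
    "OverlapResult",
    "ConcordanceResult",
    "CorrelationResult",
    "VennPartition",
    "filter_significant",
    "hypergeom_overlap_test",
    "bh_adjust",
    "venn_partition",
    "direction_concordance",
    "correlate_shared_lfc",
    "top_n_upregulated",
]


@dataclass
class OverlapResult:
    """Observed vs expected overlap of two gene sets within a background of N genes.

    k = observed overlap, K = size of set A, n = size of set B, N = background.
    """

    k: int
    K: int
    n: int
    N: int
    expected: float
    p_value: float
    padj: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError(f"k={self.k} outside [0, min(K={self.K}, n={self.n})]")
        if max(self.K, self.n) > self.N or self.N <= 0:
            raise ValueError(f"K={self.K}, n={self.n} must not exceed N={self.N} > 0")


@dataclass
class ConcordanceResult:
    """Fraction of shared DEGs regulated in the same direction."""

    n_shared: int
    n_concordant: int
    fraction: float


@dataclass
class CorrelationResult:
    """Spearman correlation of shared log2 fold changes."""

    rho: float
    p_value: float
    n_shared: int
    shared_genes: list[str] = field(default_factory=list)


@dataclass
class VennPartition:
    """Disjoint region counts of a 2- or 3-set Venn decomposition.

    Region labels are concatenations of set names joined by '&'
    (e.g. 'A', 'A&B', 'A&B&C'); each gene is counted in exactly one region.
    """

    region_counts: dict[str, int]

    def total(self) -> int:
        return sum(self.region_counts.values())


def filter_significant(
    table: DEGTable, alpha: float = 0.05, direction: str = "any"
) -> DEGTable:
    """Keep records with padj < alpha (strict); optionally restrict by sign.

    Missing padj is treated as non-significant and never passes.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0,1), got {alpha}")
    if direction not in ("any", "up", "down"):
        raise ValueError(f"direction must be any/up/down, got {direction!r}")
    kept = []
    for r in table.records:
        if r.padj is None or not (r.padj < alpha):
            continue
        if direction == "up" and not r.log2fc > 0:
            continue
        if direction == "down" and not r.log2fc < 0:
            continue
        kept.append(r)
    return DEGTable(dataset_id=table.dataset_id, species=table.species, records=kept)


def hypergeom_overlap_test(k: int, K: int, n: int, N: int) -> OverlapResult:
    """Upper-tail hypergeometric test: P(X >= k), X ~ Hypergeom(N, K, n).

    The tail includes the observed overlap k (the standard enrichment
    convention), so k = 0 always gives p = 1.
    """
    if not (0 <= k <= min(K, n)) or max(K, n) > N or N <= 0:
        raise ValueError(
            f"invalid hypergeometric configuration k={k}, K={K}, n={n}, N={N}"
        )
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(1.0, max(p, np.nextafter(0, 1)))
    return OverlapResult(k=k, K=K, n=n, N=N, expected=n * K / N, p_value=p)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0,1]")
    _, padj, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in padj]


def venn_partition(
    sets: Sequence[set[str]], names: Sequence[str] | None = None
) -> VennPartition:
    """Disjoint Venn region counts for 2 or 3 gene sets."""
    if len(sets) not in (2, 3):
        raise ValueError(f"venn_partition supports 2 or 3 sets, got {len(sets)}")
    if names is None:
        names = ["A", "B", "C"][: len(sets)]
    if len(names) != len(sets):
        raise ValueError("names must match sets in length")
    sets = [set(s) for s in sets]
    universe = set().union(*sets)
    counts: dict[str, int] = {}
    idx = list(range(len(sets)))
    for r in range(1, len(sets) + 1):
        for combo in combinations(idx, r):
            region = set.intersection(*(sets[i] for i in combo))
            for i in idx:
                if i not in combo:
                    region = region - sets[i]
            counts["&".join(names[i] for i in combo)] = len(region)
    assert sum(counts.values()) == len(universe)
    return VennPartition(region_counts=counts)


def direction_concordance(a: DEGTable, b: DEGTable) -> ConcordanceResult:
    """Fraction of shared genes with the same log2fc sign in both tables.

    Genes with a fold change of exactly 0 in either table are excluded from
    both numerator and denominator.  Both tables should already be
    significance-filtered.
    """
    da, db = a.as_dict(), b.as_dict()
    shared = [g for g in da if g in db]
    n_shared = 0
    n_conc = 0
    for g in shared:
        fa, fb = da[g].log2fc, db[g].log2fc
        if fa == 0 or fb == 0:
            continue
        n_shared += 1
        if (fa > 0) == (fb > 0):
            n_conc += 1
    frac = n_conc / n_shared if n_shared else float("nan")
    return ConcordanceResult(n_shared=n_shared, n_concordant=n_conc, fraction=frac)


def correlate_shared_lfc(a: DEGTable, b: DEGTable) -> CorrelationResult:
    """Spearman rank correlation of log2 fold changes over shared genes."""
    da, db = a.as_dict(), b.as_dict()
    shared = sorted(g for g in da if g in db)
    if len(shared) < 2:
        raise ValueError(
            f"need >= 2 shared genes for a correlation, found {len(shared)}"
        )
    x = np.array([da[g].log2fc for g in shared])
    y = np.array([db[g].log2fc for g in shared])
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(
        rho=float(rho), p_value=float(p), n_shared=len(shared), shared_genes=shared
    )


def top_n_upregulated(a: DEGTable, shared: Sequence[str], n: int = 10) -> list[str]:
    """The n shared genes with the largest log2fc in table a.

    Ties broken by smaller padj (missing sorts last), then symbol.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    da = a.as_dict()
    candidates = [da[g] for g in shared if g in da]

    def key(r: DEGRecord):
        padj = float("inf") if r.padj is None else r.padj
        return (-r.log2fc, padj, r.gene_symbol)

    return [r.gene_symbol for r in sorted(candidates, key=key)[:n]]
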