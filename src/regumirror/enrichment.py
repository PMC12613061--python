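"""Over-representation analysis over GMT catalogs and Fisher's exact test.

ORA asks whether a query gene list hits a predefined gene set more often than
expected by chance given a background universe, via the same upper-tail
hypergeometric test used for pairwise DEG overlaps.  Redundant terms (gene
sets sharing most of their members) are collapsed by single-linkage
clustering on Jaccard similarity of member sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy import stats

from .formats import GeneSetCollection
from .overlap import OverlapResult, bh_adjust, hypergeom_overlap_test

__all__ = [
    "EnrichmentResult",
    "ora",
    "simplify_terms",
    "marker_cluster_enrichment",
    "fisher_2x2",
]


@dataclass
class EnrichmentResult:
    """One term's over-representation statistics.

    k = query genes in the set, K = set members in the background,
    n = query size, N = background size.
    """

    term_id: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    padj: float
    member_hits: list[str] = field(default_factory=list)


def ora(
    query: set[str],
    background: set[str],
    catalog: GeneSetCollection,
    min_size: int = 10,
    max_size: int = 500,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of `query` in each catalog term.

    Terms are restricted to the background before the size filter
    (min_size <= K <= max_size); BH correction runs across retained terms
    only.  Results are sorted by padj, then term_id.
    """
    query = set(query)
    background = set(background)
    if not query <= background:
        missing = sorted(query - background)[:5]
        raise ValueError(f"query is not a subset of background (e.g. {missing})")
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    rows: list[tuple[str, int, int, list[str]]] = []
    for term in catalog.term_ids():
        members_bg = catalog.members(term) & background
        K = len(members_bg)
        if not (min_size <= K <= max_size):
            continue
        hits = sorted(query & members_bg)
        rows.append((term, len(hits), K, hits))
    if not rows:
        return []
    N, n = len(background), len(query)
    pvals = [hypergeom_overlap_test(k, K, n, N).p_value for _, k, K, _ in rows]
    padj = bh_adjust(pvals)
    results = [
        EnrichmentResult(term, k, K, n, N, p, q, hits)
        for (term, k, K, hits), p, q in zip(rows, pvals, padj)
    ]
    results.sort(key=lambda r: (r.padj, r.term_id))
    return results


def _jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def simplify_terms(
    results: Sequence[EnrichmentResult],
    catalog: GeneSetCollection,
    cutoff: float = 0.7,
) -> list[EnrichmentResult]:
    """Collapse redundant terms by single-linkage Jaccard clustering.

    Terms whose member sets have Jaccard similarity >= cutoff are linked;
    each connected cluster keeps one representative: the smallest padj,
    ties broken by smaller term_id.  Output preserves the input order of the
    survivors.
    """
    if not (0.0 < cutoff <= 1.0):
        raise ValueError(f"cutoff must lie in (0,1], got {cutoff}")
    terms = [r.term_id for r in results]
    members = {t: catalog.members(t) for t in terms}
    # union-find over pairwise similarity links
    parent = {t: t for t in terms}

    def find(t: str) -> str:
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for i, a in enumerate(terms):
        for b in terms[i + 1 :]:
            if _jaccard(members[a], members[b]) >= cutoff:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    clusters: dict[str, list[EnrichmentResult]] = {}
    for r in results:
        clusters.setdefault(find(r.term_id), []).append(r)
    keep = {
        min(group, key=lambda r: (r.padj, r.term_id)).term_id
        for group in clusters.values()
    }
    return [r for r in results if r.term_id in keep]


def marker_cluster_enrichment(
    up_genes: set[str],
    markers: Mapping[str, set[str]],
    background: set[str],
) -> dict[str, OverlapResult]:
    """Per-cluster hypergeometric enrichment of upregulated genes in markers.

    Mirrors testing a DEG list against single-cell cluster marker sets with
    all expressed genes as the background; BH correction across clusters.
    """
    background = set(background)
    if not background:
        raise ValueError("background must be non-empty")
    up = set(up_genes) & background
    names = list(markers)
    results: dict[str, OverlapResult] = {}
    pvals = []
    for name in names:
        mk = set(markers[name]) & background
        res = hypergeom_overlap_test(
            k=len(up & mk), K=len(up), n=len(mk), N=len(background)
        )
        results[name] = res
        pvals.append(res.p_value)
    for name, q in zip(names, bh_adjust(pvals)):
        results[name].padj = q
    return results


def fisher_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table [[a, b], [c, d]].

    Returns (sample odds ratio ad/bc, two-sided conditional p).  The odds
    ratio is inf when bc = 0 and ad > 0, and NaN when both products vanish.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("table counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("table total must be positive")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        oddsr = math.inf if a * d > 0 else math.nan
    else:
        oddsr = (a * d) / (b * c)
    return oddsr, float(p)
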