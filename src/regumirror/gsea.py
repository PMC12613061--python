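"""Ranked gene set enrichment analysis (GSEA).

Genes are ranked by a metric (here log2 fold change, descending).  For a
gene set S the enrichment score ES is the signed extremum of a weighted
Kolmogorov-Smirnov running sum: walking down the ranking, hitting a member
of S increments the sum by |metric|^weight normalized over in-set members,
and a miss decrements it by 1/(N - |S|).  Significance comes from a gene
permutation null (random sets of the same size drawn from the ranked list),
with an add-one pseudocount p-value and the canonical NES normalization by
the mean |null ES| of the same sign.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .formats import GeneSetCollection
from .overlap import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["RankedList", "GseaResult", "gsea_es", "gsea_significance"]


@dataclass
class RankedList:
    """Gene symbols ordered by a descending ranking metric (log2 fold change)."""

    genes: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.genes) != self.metric.size:
            raise ValueError("genes and metric must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list symbols must be unique")
        if not np.isfinite(self.metric).all():
            raise ValueError("ranking metric must be finite")
        if (np.diff(self.metric) > 0).any():
            order = np.argsort(-self.metric, kind="stable")
            self.genes = [self.genes[i] for i in order]
            self.metric = self.metric[order]

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_table(cls, table) -> "RankedList":
        """Build from a DEGTable, ranking all genes by log2fc descending."""
        recs = sorted(table.records, key=lambda r: (-r.log2fc, r.gene_symbol))
        return cls([r.gene_symbol for r in recs], np.array([r.log2fc for r in recs]))


@dataclass
class GseaResult:
    set_id: str
    es: float
    nes: float
    p_value: float
    padj: float
    leading_edge: list[str] = field(default_factory=list)
    n_perm: int = 0
    seed: int = 0
    n_same_sign: int = 0


def _running_sum(
    metric: np.ndarray, hit_mask: np.ndarray, weight: float
) -> np.ndarray:
    """Cumulative KS running sum over the ranking for one membership mask."""
    n = metric.size
    n_hits = int(hit_mask.sum())
    w = np.abs(metric) ** weight
    hit_w = np.where(hit_mask, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        # all in-set metrics are exactly zero under positive weight: fall
        # back to equal increments so the statistic stays defined
        hit_w = hit_mask.astype(float)
        denom = float(n_hits)
    steps = hit_w / denom - (~hit_mask) / (n - n_hits)
    return np.cumsum(steps)


def _es_from_running(running: np.ndarray) -> tuple[float, int]:
    """Signed extremum of largest magnitude and its index (positive wins ties)."""
    imax = int(np.argmax(running))
    imin = int(np.argmin(running))
    if abs(running[imax]) >= abs(running[imin]):
        return float(running[imax]), imax
    return float(running[imin]), imin


def gsea_es(
    ranked: RankedList, gene_set: set[str], weight: float = 1.0
) -> tuple[float, list[str]]:
    """Enrichment score and leading edge of a gene set in a ranked list."""
    hit_mask = np.array([g in gene_set for g in ranked.genes])
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError("gene set has no members in the ranked list")
    if n_hits == len(ranked):
        raise ValueError("gene set covers the whole ranked list; ES undefined")
    running = _running_sum(ranked.metric, hit_mask, weight)
    es, idx = _es_from_running(running)
    if es >= 0:
        leading = [g for i, g in enumerate(ranked.genes) if hit_mask[i] and i <= idx]
    else:
        leading = [g for i, g in enumerate(ranked.genes) if hit_mask[i] and i > idx]
    return es, leading


def _null_es(
    metric: np.ndarray, set_size: int, n_perm: int, weight: float, rng: np.random.Generator
) -> np.ndarray:
    """Null ES distribution from uniform random membership relabelings."""
    n = metric.size
    w = np.abs(metric) ** weight
    miss = 1.0 / (n - set_size)
    out = np.empty(n_perm)
    # vectorized over permutations in blocks to bound memory
    block = max(1, min(n_perm, 4_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        m = min(block, n_perm - done)
        # m x n hit masks with exactly set_size hits each
        keys = rng.random((m, n))
        idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        hits = np.zeros((m, n), dtype=bool)
        np.put_along_axis(hits, idx, True, axis=1)
        hw = np.where(hits, w, 0.0)
        denom = hw.sum(axis=1, keepdims=True)
        denom[denom == 0] = set_size  # degenerate all-zero metric guard
        steps = hw / denom - (~hits) * miss
        running = np.cumsum(steps, axis=1)
        hi = running.max(axis=1)
        lo = running.min(axis=1)
        out[done : done + m] = np.where(np.abs(hi) >= np.abs(lo), hi, lo)
        done += m
    return out


def gsea_significance(
    ranked: RankedList,
    sets: GeneSetCollection,
    n_perm: int = 10_000,
    weight: float = 1.0,
    seed: int | None = None,
) -> list[GseaResult]:
    """Permutation GSEA over a catalog: ES, NES, add-one permutation p, BH padj.

    The null relabels set membership uniformly at random over the ranked
    list (gene permutation), `n_perm` times per distinct set size;
    p = (1 + #{same-sign |null| >= |ES|}) / (1 + #same-sign nulls) and
    NES = ES / mean(|null ES| of the same sign).
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    if seed is None:
        raise ValueError("a seed is required for the permutation null")
    rng = np.random.default_rng(seed)
    present_sizes: dict[str, int] = {}
    observed: dict[str, tuple[float, list[str]]] = {}
    genes_in_list = set(ranked.genes)
    for term in sets.term_ids():
        members = sets.members(term) & genes_in_list
        if not members or len(members) == len(ranked):
            logger.warning("skipping set %s: empty or full coverage in ranked list", term)
            continue
        present_sizes[term] = len(members)
        observed[term] = gsea_es(ranked, set(members), weight=weight)
    # one shared null per distinct set size (draws ordered by set size for
    # seed-stable output regardless of catalog order)
    nulls: dict[int, np.ndarray] = {}
    for size in sorted(set(present_sizes.values())):
        nulls[size] = _null_es(ranked.metric, size, n_perm, weight, rng)
    results: list[GseaResult] = []
    pvals: list[float] = []
    for term in observed:
        es, leading = observed[term]
        null = nulls[present_sizes[term]]
        same_sign = null >= 0 if es >= 0 else null < 0
        n_same = int(same_sign.sum())
        if n_same == 0:
            warnings.warn(
                f"no same-sign permutations for set {term}; p floored at 1/(1+n_perm)"
            )
            p = 1.0 / (1.0 + n_perm)
            nes = float("nan")
        else:
            exceed = int((np.abs(null[same_sign]) >= abs(es)).sum())
            p = (1.0 + exceed) / (1.0 + n_same)
            nes = es / float(np.abs(null[same_sign]).mean())
        results.append(
            GseaResult(
                set_id=term,
                es=es,
                nes=nes,
                p_value=p,
                padj=float("nan"),
                leading_edge=leading,
                n_perm=n_perm,
                seed=seed,
                n_same_sign=n_same,
            )
        )
        pvals.append(p)
    for r, q in zip(results, bh_adjust(pvals)):
        r.padj = q
    results.sort(key=lambda r: (r.p_value, r.set_id))
    return results
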