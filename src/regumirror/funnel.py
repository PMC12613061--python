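"""YAP/TAZ-TEAD direct-target prediction funnel.

Candidate direct targets are genes whose promoters (±2 kb of a TSS) carry
ChIP-seq peaks for both YAP1 and at least one TEAD factor in *both* human
and mouse (via an ortholog map), whose promoter-bound peaks contain at least
one TEAD-binding motif in either species, and which are consistently
downregulated (padj < 0.05, log2FC < 0) at both knockout time points.

Peak strength uses the ENCODE narrowPeak score (-log10(q) x 10), binned into
the five-tier color scale blue (<200), cyan (200-499), green (500-749),
yellow (750-999), red (>=1000).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from intervaltree import IntervalTree

from .formats import (
    DEGTable,
    GenomicInterval,
    NarrowPeakRecord,
    OrthologMap,
    PFM,
    SequenceStore,
    TSSRecord,
)
from .motifs import UNIFORM_BACKGROUND, pwm_threshold, scan_motifs

logger = logging.getLogger(__name__)

__all__ = [
    "FACTORS",
    "TEAD_FACTORS",
    "TIERS",
    "FactorPeak",
    "PromoterWindow",
    "PromoterOccupancy",
    "TargetPanelRecord",
    "SpeciesInputs",
    "FunnelOptions",
    "FunnelResult",
    "remove_blacklisted",
    "effective_score",
    "classify_tier",
    "tier_rank",
    "build_promoter_windows",
    "assign_promoter_peaks",
    "species_occupancy_filter",
    "cross_species_consensus",
    "build_target_panel",
    "run_funnel",
]

FACTORS = ("YAP1", "TEAD1", "TEAD2", "TEAD3", "TEAD4")
TEAD_FACTORS = FACTORS[1:]
TIERS = ("blue", "cyan", "green", "yellow", "red")


def classify_tier(score: int) -> str:
    """Map a narrowPeak score to the five-tier color scale."""
    if score < 0:
        raise ValueError(f"score must be >= 0, got {score}")
    if score < 200:
        return "blue"
    if score < 500:
        return "cyan"
    if score < 750:
        return "green"
    if score < 1000:
        return "yellow"
    return "red"


def tier_rank(tier: str) -> int:
    return TIERS.index(tier)


def effective_score(peak: NarrowPeakRecord) -> int:
    """narrowPeak score, repaired from -log10(q) x 10 when the column is zeroed."""
    if peak.score > 0:
        return peak.score
    if peak.neglog10_q is not None:
        repaired = round(peak.neglog10_q * 10)
        logger.info("peak %s: repaired zero score to %d from q-value", peak.name, repaired)
        return repaired
    logger.warning("peak %s: zero score and no q-value; effective score 0", peak.name)
    return 0


@dataclass(frozen=True)
class FactorPeak:
    """The best (highest effective score) promoter peak of one factor at one gene."""

    peak: NarrowPeakRecord
    effective_score: int
    tier: str


@dataclass(frozen=True)
class PromoterWindow:
    """Symmetric window [tss - flank, tss + flank) around one TSS (clipped at 0)."""

    gene_symbol: str
    interval: GenomicInterval


@dataclass
class PromoterOccupancy:
    """Per-gene, per-factor best promoter peak for one species."""

    species: str
    gene_symbol: str
    factors: dict[str, FactorPeak] = field(default_factory=dict)

    def best_score(self) -> int:
        return max((fp.effective_score for fp in self.factors.values()), default=0)

    def best_tier(self) -> str:
        return classify_tier(self.best_score())


@dataclass
class TargetPanelRecord:
    """One predicted direct target surviving every funnel gate."""

    gene_symbol: str  # human-cased
    mouse_symbol: str
    human_score: int
    human_tier: str
    mouse_score: int
    mouse_tier: str
    tead_motif_present: bool
    log2fc_2wk: float
    log2fc_8wk: float


def remove_blacklisted(
    peaks: Sequence[NarrowPeakRecord], blacklist: Sequence[GenomicInterval]
) -> list[NarrowPeakRecord]:
    """Drop peaks with >= 1 bp overlap with any blacklist interval."""
    trees: dict[str, IntervalTree] = {}
    for iv in blacklist:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    kept = []
    removed = 0
    for p in peaks:
        tree = trees.get(p.interval.chrom)
        if tree is not None and tree.overlap(p.interval.start, p.interval.end):
            removed += 1
            continue
        kept.append(p)
    if removed:
        logger.info("blacklist removed %d of %d peaks", removed, len(peaks))
    return kept


def build_promoter_windows(
    tss: Sequence[TSSRecord], flank: int = 2000
) -> list[PromoterWindow]:
    """One window per TSS record: [max(0, tss - flank), tss + flank)."""
    if flank <= 0:
        raise ValueError(f"flank must be > 0, got {flank}")
    return [
        PromoterWindow(
            gene_symbol=t.gene_symbol,
            interval=GenomicInterval(t.chrom, max(0, t.tss - flank), t.tss + flank),
        )
        for t in tss
    ]


def assign_promoter_peaks(
    peaks_by_factor: Mapping[str, Sequence[NarrowPeakRecord]],
    windows: Sequence[PromoterWindow],
    species: str,
) -> list[PromoterOccupancy]:
    """Per gene, per factor, keep the highest-effective-score promoter peak.

    A peak is promoter-bound for a gene iff it overlaps any of that gene's
    windows by >= 1 bp; equal scores break ties by smaller start, then
    chromosome name.
    """
    trees: dict[str, IntervalTree] = {}
    for w in windows:
        trees.setdefault(w.interval.chrom, IntervalTree()).addi(
            w.interval.start, w.interval.end, w.gene_symbol
        )
    best: dict[str, dict[str, tuple]] = {}
    for factor, peaks in peaks_by_factor.items():
        for peak in peaks:
            tree = trees.get(peak.interval.chrom)
            if tree is None:
                continue
            genes = {hit.data for hit in tree.overlap(peak.interval.start, peak.interval.end)}
            if not genes:
                continue
            eff = effective_score(peak)
            key = (-eff, peak.interval.start, peak.interval.chrom)
            for gene in genes:
                slot = best.setdefault(gene, {})
                if factor not in slot or key < slot[factor][0]:
                    slot[factor] = (key, peak, eff)
    out = []
    for gene in sorted(best):
        occ = PromoterOccupancy(species=species, gene_symbol=gene)
        for factor in FACTORS:
            if factor in best[gene]:
                _, peak, eff = best[gene][factor]
                occ.factors[factor] = FactorPeak(peak, eff, classify_tier(eff))
        out.append(occ)
    return out


def species_occupancy_filter(
    occ: Sequence[PromoterOccupancy],
    require_yap1: bool = True,
    require_tead: bool = True,
) -> set[str]:
    """Genes with a YAP1 best peak AND at least one TEAD1-4 best peak."""
    out = set()
    for o in occ:
        if require_yap1 and "YAP1" not in o.factors:
            continue
        if require_tead and not any(t in o.factors for t in TEAD_FACTORS):
            continue
        if o.factors:
            out.add(o.gene_symbol)
    return out


def cross_species_consensus(
    human_pass: set[str], mouse_pass: set[str], orthologs: OrthologMap
) -> list[tuple[str, str]]:
    """Ortholog pairs occupied in both species; one row per qualifying human gene.

    A human gene with several mouse orthologs qualifies if any pairing
    passes; the first qualifying mouse symbol in sorted order represents it.
    """
    qualifying: dict[str, list[str]] = {}
    for h, m in orthologs.pairs:
        if h in human_pass and m in mouse_pass:
            qualifying.setdefault(h, []).append(m)
    out = []
    for h in sorted(qualifying):
        mice = sorted(qualifying[h])
        if len(mice) > 1:
            logger.info("human gene %s qualifies via %d mouse orthologs", h, len(mice))
        out.append((h, mice[0]))
    return out


def build_target_panel(
    consensus: Sequence[tuple[str, str]],
    motif_present: Mapping[str, bool],
    deg_2wk: DEGTable,
    deg_8wk: DEGTable,
    human_occ: Mapping[str, PromoterOccupancy],
    mouse_occ: Mapping[str, PromoterOccupancy],
    alpha: float = 0.05,
    require_motif: bool = True,
    require_down_2wk: bool = True,
    require_down_8wk: bool = True,
) -> list[TargetPanelRecord]:
    """Intersect the consensus with the motif gate and consistent downregulation."""
    d2, d8 = deg_2wk.as_dict(), deg_8wk.as_dict()
    panel = []
    for h, m in sorted(consensus):
        has_motif = bool(motif_present.get(h, False))
        if require_motif and not has_motif:
            continue
        r2, r8 = d2.get(m), d8.get(m)
        if require_down_2wk and not (
            r2 is not None and r2.padj is not None and r2.padj < alpha and r2.log2fc < 0
        ):
            continue
        if require_down_8wk and not (
            r8 is not None and r8.padj is not None and r8.padj < alpha and r8.log2fc < 0
        ):
            continue
        ho, mo = human_occ[h], mouse_occ[m]
        panel.append(
            TargetPanelRecord(
                gene_symbol=h,
                mouse_symbol=m,
                human_score=ho.best_score(),
                human_tier=ho.best_tier(),
                mouse_score=mo.best_score(),
                mouse_tier=mo.best_tier(),
                tead_motif_present=has_motif,
                log2fc_2wk=r2.log2fc if r2 else float("nan"),
                log2fc_8wk=r8.log2fc if r8 else float("nan"),
            )
        )
    return panel


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass
class SpeciesInputs:
    """Per-species raw funnel inputs."""

    peaks_by_factor: dict[str, list[NarrowPeakRecord]]
    blacklist: list[GenomicInterval]
    tss: list[TSSRecord]
    genome: SequenceStore


@dataclass
class FunnelOptions:
    flank: int = 2000
    alpha: float = 0.05
    p_cutoff: float = 5e-5
    pseudocount: float = 1.0
    apply_blacklist: bool = True
    require_yap1: bool = True
    require_tead: bool = True
    require_motif: bool = True
    require_down_2wk: bool = True
    require_down_8wk: bool = True
    scan_full_window: bool = False


@dataclass
class FunnelResult:
    panel: list[TargetPanelRecord]
    stage_counts: dict[str, int]
    consensus: list[tuple[str, str]]
    motif_genes: set[str]
    human_occupancy: dict[str, PromoterOccupancy]
    mouse_occupancy: dict[str, PromoterOccupancy]

    def panel_genes(self) -> list[str]:
        return [r.gene_symbol for r in self.panel]


def _species_occupancy(
    inputs: SpeciesInputs, species: str, options: FunnelOptions
) -> dict[str, PromoterOccupancy]:
    peaks_by_factor = {}
    for factor, peaks in inputs.peaks_by_factor.items():
        peaks_by_factor[factor] = (
            remove_blacklisted(peaks, inputs.blacklist)
            if options.apply_blacklist
            else list(peaks)
        )
    windows = build_promoter_windows(inputs.tss, flank=options.flank)
    occ = assign_promoter_peaks(peaks_by_factor, windows, species)
    return {o.gene_symbol: o for o in occ}


def _gene_scan_intervals(
    occ: PromoterOccupancy,
    inputs: SpeciesInputs,
    options: FunnelOptions,
) -> list[NarrowPeakRecord]:
    if not options.scan_full_window:
        return [fp.peak for fp in occ.factors.values()]
    # alternative gate: scan the whole promoter window instead of the peaks
    out = []
    for t in inputs.tss:
        if t.gene_symbol != occ.gene_symbol:
            continue
        end = min(t.tss + options.flank, inputs.genome.chrom_length(t.chrom))
        iv = GenomicInterval(t.chrom, max(0, t.tss - options.flank), end)
        out.append(NarrowPeakRecord(interval=iv, name=f"window:{t.gene_symbol}"))
    return out


def run_funnel(
    human: SpeciesInputs,
    mouse: SpeciesInputs,
    pfms: Sequence[PFM],
    orthologs: OrthologMap,
    deg_2wk: DEGTable,
    deg_8wk: DEGTable,
    options: FunnelOptions | None = None,
) -> FunnelResult:
    """Run every funnel stage; each stage's gene set is a subset of the last."""
    options = options or FunnelOptions()
    human_occ = _species_occupancy(human, "human", options)
    mouse_occ = _species_occupancy(mouse, "mouse", options)
    human_pass = species_occupancy_filter(
        human_occ.values(), options.require_yap1, options.require_tead
    )
    mouse_pass = species_occupancy_filter(
        mouse_occ.values(), options.require_yap1, options.require_tead
    )
    consensus = cross_species_consensus(human_pass, mouse_pass, orthologs)

    thresholds = {
        p.motif_id: pwm_threshold(
            p, UNIFORM_BACKGROUND, options.p_cutoff, options.pseudocount
        )
        for p in pfms
    }
    motif_genes: set[str] = set()
    for h, m in consensus:
        found = False
        for occ, inputs in ((human_occ[h], human), (mouse_occ[m], mouse)):
            peaks = _gene_scan_intervals(occ, inputs, options)
            if scan_motifs(
                inputs.genome, peaks, pfms, thresholds,
                pseudocount=options.pseudocount,
            ):
                found = True
                break
        if found:
            motif_genes.add(h)
    motif_present = {h: h in motif_genes for h, _ in consensus}

    panel = build_target_panel(
        consensus,
        motif_present,
        deg_2wk,
        deg_8wk,
        human_occ,
        mouse_occ,
        alpha=options.alpha,
        require_motif=options.require_motif,
        require_down_2wk=options.require_down_2wk,
        require_down_8wk=options.require_down_8wk,
    )
    stage_counts = {
        "promoter_occupancy_human": len(human_pass),
        "promoter_occupancy_mouse": len(mouse_pass),
        "cross_species_consensus": len(consensus),
        "tead_motif": len(motif_genes) if options.require_motif else len(consensus),
        "downregulated_panel": len(panel),
    }
    logger.info("funnel stage counts: %s", stage_counts)
    return FunnelResult(
        panel=panel,
        stage_counts=stage_counts,
        consensus=consensus,
        motif_genes=motif_genes,
        human_occupancy=human_occ,
        mouse_occupancy=mouse_occ,
    )
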