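"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators cover the pipeline's input surface:

* `gen_deg_pair` — two differential-expression tables over a shared gene
  universe with an exact number of shared significant genes, a tunable sign
  concordance among them, and positively rank-correlated fold changes.
* `gen_gene_sets` — a GMT-ready catalog with planted enriched sets that
  preferentially sample a designated query.
* `gen_regulatory_fixture` — a complete two-species regulatory fixture
  (pseudo-genomes, TSS annotation, per-factor ChIP peaks, blacklist,
  TEAD-like PFM, ortholog map, two knockout DEG tables) with planted direct
  targets plus decoy genes each violating exactly one funnel gate.

All generators are pure functions of their parameters and seed: equal seeds
give byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .formats import (
    DEGRecord,
    DEGTable,
    GeneSetCollection,
    GenomicInterval,
    NarrowPeakRecord,
    OrthologMap,
    PFM,
    SequenceStore,
    TSSRecord,
    read_bed_intervals,
    read_deg_table,
    read_jaspar_pfm,
    read_narrowpeak,
    read_ortholog_map,
    read_tss,
    write_bed_intervals,
    write_deg_table,
    write_jaspar_pfm,
    write_narrowpeak,
    write_ortholog_map,
    write_tss_bed6,
)
from .funnel import SpeciesInputs, TEAD_FACTORS

__all__ = [
    "DegPairSpec",
    "FixtureTruth",
    "DECOY_STAGES",
    "gen_deg_pair",
    "gen_gene_sets",
    "gen_regulatory_fixture",
    "load_fixture",
]

DECOY_STAGES = (
    "blacklist",
    "no_yap1",
    "no_tead",
    "no_ortholog",
    "no_motif",
    "not_down_2wk",
    "not_down_8wk",
)

# width-9 TEAD-like motif around the GGAATG MCAT core; sharply peaked
# columns make the match threshold at p=5e-5 admit only the exact consensus
TEAD_CONSENSUS = "AGGAATGTC"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def synthetic_tead_pfm(peak_count: int = 20) -> PFM:
    """A synthetic TEAD-like PFM (consensus AGGAATGTC, MCAT core GGAATG)."""
    counts = np.ones((4, len(TEAD_CONSENSUS)))
    for j, base in enumerate(TEAD_CONSENSUS):
        counts["ACGT".index(base), j] = peak_count
    return PFM(motif_id="SYN0001", name="TEAD_SYNTH", counts=counts)


# ---------------------------------------------------------------------------
# paired DEG tables
# ---------------------------------------------------------------------------


@dataclass
class DegPairSpec:
    """Parameters for a pair of DEG tables with controlled overlap structure."""

    n_genes: int = 10_000
    n_deg_a: int = 1_000
    n_deg_b: int = 1_000
    overlap_target: float = 0.5
    concordance_target: float = 0.9
    lfc_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_target <= 1.0):
            raise ValueError("overlap_target must lie in [0,1]")
        if not (0.0 <= self.concordance_target <= 1.0):
            raise ValueError("concordance_target must lie in [0,1]")
        if self.lfc_sd <= 0:
            raise ValueError("lfc_sd must be positive")
        n_shared = round(self.overlap_target * self.n_deg_b)
        if max(self.n_deg_a, self.n_deg_b) > self.n_genes:
            raise ValueError("DEG counts cannot exceed the gene universe")
        if n_shared > min(self.n_deg_a, self.n_deg_b):
            raise ValueError("infeasible overlap: more shared than smaller DEG set")
        if self.n_deg_a + self.n_deg_b - n_shared > self.n_genes:
            raise ValueError("infeasible overlap: sets cannot fit in the universe")

    @property
    def n_shared(self) -> int:
        return round(self.overlap_target * self.n_deg_b)


def gen_deg_pair(spec: DegPairSpec) -> tuple[DEGTable, DEGTable, dict]:
    """Two DEG tables with exactly `spec.n_shared` shared significant genes.

    Among shared genes, signs agree with probability `concordance_target`;
    magnitudes of concordant genes are correlated so that Spearman rho of
    the shared fold changes increases with the concordance target.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    perm = rng.permutation(spec.n_genes)
    a_sig_idx = perm[: spec.n_deg_a]
    shared_idx = a_sig_idx[: spec.n_shared]
    b_only_idx = perm[spec.n_deg_a : spec.n_deg_a + spec.n_deg_b - spec.n_shared]
    b_sig_idx = np.concatenate([shared_idx, b_only_idx]).astype(int)

    def magnitudes(n: int) -> np.ndarray:
        return np.abs(rng.normal(0, spec.lfc_sd, n)) + 0.25

    sign_a = rng.choice([-1.0, 1.0], spec.n_genes)
    mag_a = magnitudes(spec.n_genes)
    lfc_a = sign_a * mag_a

    lfc_b = rng.choice([-1.0, 1.0], spec.n_genes) * magnitudes(spec.n_genes)
    concordant = rng.random(spec.n_shared) < spec.concordance_target
    shared_sign_b = np.where(concordant, sign_a[shared_idx], -sign_a[shared_idx])
    shared_mag_b = 0.25 + np.abs(
        0.7 * (mag_a[shared_idx] - 0.25) + 0.3 * np.abs(rng.normal(0, spec.lfc_sd, spec.n_shared))
    )
    lfc_b[shared_idx] = shared_sign_b * shared_mag_b

    padj_a = rng.uniform(0.05, 1.0, spec.n_genes)
    padj_a[a_sig_idx] = rng.uniform(1e-8, 0.049, spec.n_deg_a)
    padj_b = rng.uniform(0.05, 1.0, spec.n_genes)
    padj_b[b_sig_idx] = rng.uniform(1e-8, 0.049, b_sig_idx.size)

    def table(dataset_id: str, lfc: np.ndarray, padj: np.ndarray) -> DEGTable:
        recs = [
            DEGRecord(genes[i], float(lfc[i]), float(padj[i]))
            for i in range(spec.n_genes)
        ]
        return DEGTable(dataset_id=dataset_id, species="mouse", records=recs)

    truth = {
        "shared_significant": sorted(genes[i] for i in shared_idx),
        "a_significant": sorted(genes[i] for i in a_sig_idx),
        "b_significant": sorted(genes[i] for i in b_sig_idx),
        "n_shared": spec.n_shared,
        "n_concordant_drawn": int(concordant.sum()),
        "seed": spec.seed,
    }
    return table("sim_a", lfc_a, padj_a), table("sim_b", lfc_b, padj_b), truth


# ---------------------------------------------------------------------------
# gene-set catalogs with planted enrichment
# ---------------------------------------------------------------------------


def gen_gene_sets(
    background: Sequence[str],
    n_sets: int,
    planted: Mapping[str, float] | None = None,
    query: Sequence[str] | None = None,
    set_size: tuple[int, int] = (20, 60),
    seed: int = 0,
) -> tuple[GeneSetCollection, dict]:
    """A catalog of `n_sets` null sets plus planted sets enriched in `query`.

    `planted` maps a set name to its enrichment odds: members are sampled
    without replacement with weight `odds` for query genes and 1 otherwise,
    so odds 1 is a null set and large odds concentrate the set in the query.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    bg = sorted(set(background))
    planted = dict(planted or {})
    query_set = set(query or [])
    if planted and not query_set:
        raise ValueError("planted sets require a designated query")
    is_query = np.array([g in query_set for g in bg], dtype=float)
    sets: dict[str, tuple[str, frozenset[str]]] = {}

    def draw(odds: float) -> frozenset[str]:
        size = int(rng.integers(set_size[0], set_size[1] + 1))
        w = np.where(is_query > 0, odds, 1.0)
        members = rng.choice(len(bg), size=size, replace=False, p=w / w.sum())
        return frozenset(bg[i] for i in members)

    for name, odds in planted.items():
        sets[name] = (f"planted odds={odds}", draw(float(odds)))
    n_null = n_sets - len(planted)
    for i in range(max(0, n_null)):
        sets[f"NULL{i:03d}"] = ("null set", draw(1.0))
    truth = {"planted": sorted(planted), "query": sorted(query_set), "seed": seed}
    return GeneSetCollection(sets=sets), truth


# ---------------------------------------------------------------------------
# the regulatory fixture
# ---------------------------------------------------------------------------


@dataclass
class FixtureTruth:
    """Ground truth of a generated regulatory fixture."""

    planted_targets: list[str]
    decoys: dict[str, str]  # harmonized symbol -> violated funnel stage
    params: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureTruth":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


_SPACING = 5000
_MARGIN = 3000
_PEAK_HALF = 100
_TIER_SCORES = (80, 300, 620, 850, 1200)


def gen_regulatory_fixture(
    n_genes: int = 48,
    n_targets: int = 19,
    decoys_per_stage: int = 3,
    seed: int = 0,
    out_dir: str | Path = ".",
) -> FixtureTruth:
    """Write a complete two-species funnel fixture with planted ground truth.

    Every planted target carries YAP1 + >=1 TEAD promoter peaks in both
    pseudo-species with the TEAD consensus motif planted inside, an ortholog
    pair, and significant downregulation at both knockout time points.  Each
    decoy satisfies every gate except the one named by its stage; `no_motif`
    decoys carry a one-mismatch near-consensus and their promoter windows
    are scrubbed of chance consensus occurrences.
    """
    need = n_targets + len(DECOY_STAGES) * decoys_per_stage
    if n_genes < need:
        raise ValueError(f"n_genes must be >= {need} for this sizing, got {n_genes}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    roles: list[str] = ["target"] * n_targets
    for stage in DECOY_STAGES:
        roles += [stage] * decoys_per_stage
    roles += ["background"] * (n_genes - len(roles))

    human_syms = [f"GENE{i:04d}" for i in range(n_genes)]
    mouse_syms = [f"Gene{i:04d}" for i in range(n_genes)]

    # per-gene regulatory plan, shared across species for determinism
    n_teads = 1 + rng.integers(0, len(TEAD_FACTORS), size=n_genes)
    tead_choices = [
        sorted(rng.choice(TEAD_FACTORS, size=int(k), replace=False))
        for k in n_teads
    ]

    per_species: dict[str, dict] = {}
    for species, chrom, syms in (
        ("human", "chrH", human_syms),
        ("mouse", "chrM", mouse_syms),
    ):
        genome = rng.integers(0, 4, size=_MARGIN * 2 + n_genes * _SPACING)
        tss_list: list[TSSRecord] = []
        peaks: dict[str, list[NarrowPeakRecord]] = {f: [] for f in ("YAP1", *TEAD_FACTORS)}
        blacklist: list[GenomicInterval] = []
        for i, role in enumerate(roles):
            tss = _MARGIN + i * _SPACING
            strand = "+" if i % 2 == 0 else "-"
            tss_list.append(TSSRecord(syms[i].upper(), chrom, strand, tss))
            if role == "background":
                continue
            factors = []
            if role != "no_yap1":
                factors.append("YAP1")
            if role != "no_tead":
                factors.extend(tead_choices[i])
            gene_peaks = []
            for k, factor in enumerate(factors):
                center = tss - 400 + 250 * k
                iv = GenomicInterval(chrom, center - _PEAK_HALF, center + _PEAK_HALF)
                eff = int(rng.choice(_TIER_SCORES))
                zero_score = rng.random() < 0.25
                peak = NarrowPeakRecord(
                    interval=iv,
                    name=f"{species}_{factor}_{syms[i]}",
                    score=0 if zero_score else eff,
                    signal_value=round(float(rng.uniform(1, 50)), 3),
                    neglog10_p=round(eff / 8.0, 3),
                    neglog10_q=round(eff / 10.0, 3),
                    summit_offset=_PEAK_HALF,
                )
                peaks[factor].append(peak)
                gene_peaks.append(peak)
            if role == "blacklist":
                lo = min(p.interval.start for p in gene_peaks)
                hi = max(p.interval.end for p in gene_peaks)
                blacklist.append(GenomicInterval(chrom, lo, hi))
            # plant the motif in the first peak of every gene that must pass
            # the motif gate; no_motif decoys get a one-mismatch near-miss
            plant_at = gene_peaks[0].interval.start + 40
            motif = TEAD_CONSENSUS
            if role == "no_motif":
                near = list(TEAD_CONSENSUS)
                near[4] = "C" if near[4] != "C" else "G"  # break the MCAT core
                motif = "".join(near)
            codes = [int("ACGT".index(b)) for b in motif]
            genome[plant_at : plant_at + len(codes)] = codes
        # scrub chance consensus occurrences from no_motif promoter windows
        base_arr = np.frombuffer(b"ACGT", dtype=np.uint8)
        seq_bytes = base_arr[genome].tobytes()
        seq = seq_bytes.decode()
        seq_list = None
        for i, role in enumerate(roles):
            if role != "no_motif":
                continue
            tss = _MARGIN + i * _SPACING
            lo, hi = tss - 2100, tss + 2100
            needles = (TEAD_CONSENSUS, _revcomp(TEAD_CONSENSUS))
            while True:
                window = seq[lo:hi]
                found = [(window.find(n), n) for n in needles]
                found = [(p, n) for p, n in found if p != -1]
                if not found:
                    break
                pos, needle = min(found)
                if seq_list is None:
                    seq_list = list(seq)
                mid = lo + pos + len(needle) // 2
                cur = seq_list[mid]
                seq_list[mid] = {"A": "C", "C": "A", "G": "T", "T": "G"}[cur]
                seq = "".join(seq_list)
        per_species[species] = {
            "chrom": chrom,
            "seq": seq,
            "tss": tss_list,
            "peaks": peaks,
            "blacklist": blacklist,
        }

    # ortholog map: 1:1 except no_ortholog decoys
    pairs = [
        (human_syms[i], mouse_syms[i].upper())
        for i, role in enumerate(roles)
        if role != "no_ortholog"
    ]

    # knockout DEG tables over the mouse symbols
    def deg_table(dataset_id: str, flipped_stage: str) -> DEGTable:
        recs = []
        for i, role in enumerate(roles):
            if role == "background":
                lfc = float(rng.normal(0, 1))
                padj = float(rng.uniform(0, 1))
            elif role == flipped_stage:
                lfc = float(np.abs(rng.normal(0, 1)) + 0.5)  # significantly UP
                padj = float(rng.uniform(1e-6, 0.049))
            else:
                lfc = -float(np.abs(rng.normal(0, 1)) + 0.5)
                padj = float(rng.uniform(1e-6, 0.049))
            recs.append(DEGRecord(mouse_syms[i].upper(), round(lfc, 4), round(padj, 8)))
        return DEGTable(dataset_id=dataset_id, species="mouse", records=recs)

    deg_2wk = deg_table("yt_2wk", "not_down_2wk")
    deg_8wk = deg_table("yt_8wk", "not_down_8wk")

    # ---- write everything -------------------------------------------------
    for species in ("human", "mouse"):
        d = per_species[species]
        SequenceStore({d["chrom"]: d["seq"]}).to_fasta(out_dir / f"{species}.fa")
        write_tss_bed6(d["tss"], out_dir / f"{species}_tss.bed")
        for factor, plist in d["peaks"].items():
            write_narrowpeak(plist, out_dir / f"{species}_{factor}.narrowPeak")
        write_bed_intervals(d["blacklist"], out_dir / f"{species}_blacklist.bed")
    write_jaspar_pfm([synthetic_tead_pfm()], out_dir / "tead_pfm.jaspar")
    write_ortholog_map(OrthologMap(pairs=pairs), out_dir / "orthologs.tsv")
    write_deg_table(deg_2wk, out_dir / "deg_2wk.tsv")
    write_deg_table(deg_8wk, out_dir / "deg_8wk.tsv")

    truth = FixtureTruth(
        planted_targets=[human_syms[i] for i, r in enumerate(roles) if r == "target"],
        decoys={
            human_syms[i]: role
            for i, role in enumerate(roles)
            if role not in ("target", "background")
        },
        params={
            "n_genes": n_genes,
            "n_targets": n_targets,
            "decoys_per_stage": decoys_per_stage,
            "spacing": _SPACING,
            "flank": 2000,
        },
        seed=seed,
    )
    truth.to_json(out_dir / "truth.json")
    return truth


def load_fixture(fixture_dir: str | Path):
    """Read a generated fixture back through the standard readers.

    Returns (human_inputs, mouse_inputs, pfms, orthologs, deg_2wk, deg_8wk,
    truth).
    """
    d = Path(fixture_dir)
    species_inputs = {}
    for species in ("human", "mouse"):
        peaks_by_factor = {
            factor: read_narrowpeak(d / f"{species}_{factor}.narrowPeak")
            for factor in ("YAP1", *TEAD_FACTORS)
        }
        blacklist_path = d / f"{species}_blacklist.bed"
        blacklist = (
            read_bed_intervals(blacklist_path)
            if blacklist_path.stat().st_size > 0
            else []
        )
        species_inputs[species] = SpeciesInputs(
            peaks_by_factor=peaks_by_factor,
            blacklist=blacklist,
            tss=read_tss(d / f"{species}_tss.bed", format="bed6"),
            genome=SequenceStore.from_fasta(d / f"{species}.fa"),
        )
    pfms = read_jaspar_pfm(d / "tead_pfm.jaspar")
    orthologs = read_ortholog_map(d / "orthologs.tsv")
    deg_2wk = read_deg_table(d / "deg_2wk.tsv", dataset_id="yt_2wk")
    deg_8wk = read_deg_table(d / "deg_8wk.tsv", dataset_id="yt_8wk")
    truth = FixtureTruth.from_json(d / "truth.json")
    return (
        species_inputs["human"],
        species_inputs["mouse"],
        pfms,
        orthologs,
        deg_2wk,
        deg_8wk,
        truth,
    )
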