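"""Readers and writers for the external formats the pipeline consumes.

All genomic coordinates are normalized to 0-based half-open intervals on
ingestion (the BED/narrowPeak convention); GTF's 1-based closed coordinates
are converted at the boundary and never circulate internally.  Gene symbols
are harmonized (trimmed, uppercased) by every reader so that human and mouse
symbols occupy one shared namespace.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "SchemaError",
    "InvalidSymbolError",
    "DEGRecord",
    "DEGTable",
    "GenomicInterval",
    "NarrowPeakRecord",
    "TSSRecord",
    "PFM",
    "GeneSetCollection",
    "OrthologMap",
    "SequenceStore",
    "harmonize_symbol",
    "read_deg_table",
    "write_deg_table",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_bed_intervals",
    "write_bed_intervals",
    "read_tss",
    "write_tss_bed6",
    "read_jaspar_pfm",
    "write_jaspar_pfm",
    "read_gmt",
    "write_gmt",
    "read_ortholog_map",
    "write_ortholog_map",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class SchemaError(FormatError):
    """A tabular file is missing a required column."""


class InvalidSymbolError(ValueError):
    """A gene symbol is empty or blank."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential-expression call: log2 fold change and BH-adjusted p."""

    gene_symbol: str
    log2fc: float
    padj: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.log2fc):
            raise ValueError(f"log2fc must be finite, got {self.log2fc}")
        if self.padj is not None and not (0.0 <= self.padj <= 1.0):
            raise ValueError(f"padj must lie in [0,1], got {self.padj}")


@dataclass
class DEGTable:
    """A differential-expression table for one dataset/contrast.

    Symbols are unique after harmonization; the table is the unit of every
    cross-dataset comparison.
    """

    dataset_id: str
    species: str  # "human" | "mouse"
    records: list[DEGRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.dataset_id:
            raise ValueError("dataset_id must be non-empty")
        seen = set()
        for r in self.records:
            if r.gene_symbol in seen:
                raise ValueError(f"duplicate gene symbol {r.gene_symbol!r}")
            seen.add(r.gene_symbol)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def symbols(self) -> set[str]:
        return {r.gene_symbol for r in self.records}

    def get(self, symbol: str) -> DEGRecord | None:
        for r in self.records:
            if r.gene_symbol == symbol:
                return r
        return None

    def as_dict(self) -> dict[str, DEGRecord]:
        return {r.gene_symbol: r for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [r.gene_symbol for r in self.records],
                "log2fc": [r.log2fc for r in self.records],
                "padj": [np.nan if r.padj is None else r.padj for r in self.records],
            }
        )


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of + - ., got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class NarrowPeakRecord:
    """ENCODE narrowPeak (BED6+4) peak call.

    ``-1`` sentinels for missing -log10 p/q and summit offset are preserved
    as ``None`` internally and round-tripped back to ``-1`` on write.
    """

    interval: GenomicInterval
    name: str = "."
    score: int = 0
    signal_value: float = 0.0
    neglog10_p: float | None = None
    neglog10_q: float | None = None
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"score must be >= 0, got {self.score}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak of length "
                f"{len(self.interval)}"
            )


@dataclass(frozen=True, order=True)
class TSSRecord:
    """A single transcription start site (0-based position, strand-aware 5' end)."""

    gene_symbol: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"TSS strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss}")


@dataclass
class PFM:
    """Position frequency matrix, rows A,C,G,T (counts, not probabilities)."""

    motif_id: str
    name: str
    counts: np.ndarray  # shape (4, w)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x w matrix (rows A,C,G,T)")
        if self.width < 4:
            raise ValueError(f"motif width must be >= 4, got {self.width}")
        if (self.counts < 0).any():
            raise FormatError("PFM counts must be non-negative")
        if (self.counts.sum(axis=0) <= 0).any():
            raise FormatError("every PFM column needs at least one positive count")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.counts.argmax(axis=0))


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style): term_id -> (description, member symbols)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {term!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, term: str) -> bool:
        return term in self.sets

    def members(self, term: str) -> frozenset[str]:
        return self.sets[term][1]

    def description(self, term: str) -> str:
        return self.sets[term][0]

    def term_ids(self) -> list[str]:
        return list(self.sets)


@dataclass
class OrthologMap:
    """1:1-or-many correspondence between human and mouse gene symbols."""

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate ortholog pairs")

    def __len__(self) -> int:
        return len(self.pairs)

    def mouse_for_human(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for h, m in self.pairs:
            out.setdefault(h, []).append(m)
        return out


class SequenceStore:
    """In-memory genome: chromosome name -> uppercase nucleotide string."""

    def __init__(self, chroms: Mapping[str, str]):
        self._chroms = {name: seq.upper() for name, seq in chroms.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SequenceStore":
        chroms = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
        }
        if not chroms:
            raise FormatError(f"no sequences found in {path}")
        return cls(chroms)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in sorted(self._chroms.items())
        ]
        SeqIO.write(records, str(path), "fasta")

    def chrom_names(self) -> list[str]:
        return list(self._chroms)

    def chrom_length(self, chrom: str) -> int:
        return len(self._chroms[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._chroms:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self._chroms[chrom]
        if start < 0 or end > len(seq) or end <= start:
            raise IndexError(
                f"requested {chrom}:{start}-{end} outside sequence of length {len(seq)}"
            )
        return seq[start:end]

    def fetch_interval(self, interval: GenomicInterval) -> str:
        return self.fetch(interval.chrom, interval.start, interval.end)


# ---------------------------------------------------------------------------
# symbol harmonization
# ---------------------------------------------------------------------------


def harmonize_symbol(symbol: str) -> str:
    """Trim and uppercase a gene symbol so human and mouse spellings collide.

    Mouse symbols use title case (``Spp1``) while human symbols are uppercase
    (``SPP1``); mapping both to uppercase makes cross-species intersection a
    plain set operation.
    """
    out = symbol.strip().upper()
    if not out:
        raise InvalidSymbolError(f"empty or blank gene symbol: {symbol!r}")
    return out


# ---------------------------------------------------------------------------
# DEG tables
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {"", "na", "nan", "n/a", "null", "none", "."}


def read_deg_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    dataset_id: str | None = None,
    species: str = "mouse",
) -> DEGTable:
    """Read a TSV/CSV differential-expression table.

    ``column_map`` names the gene / log2fc / padj columns (defaults
    ``{"gene": "gene", "log2fc": "log2fc", "padj": "padj"}``).  Symbols are
    harmonized; case-insensitive duplicates are collapsed keeping the record
    with the smallest padj (missing padj sorts last).
    """
    path = Path(path)
    cmap = {"gene": "gene", "log2fc": "log2fc", "padj": "padj"}
    if column_map:
        cmap.update(column_map)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    for role, col in cmap.items():
        if col not in df.columns:
            raise SchemaError(
                f"{path}: missing mapped column {col!r} (for {role!r}); "
                f"available: {list(df.columns)}"
            )
    if dataset_id is None:
        dataset_id = path.stem
    best: dict[str, DEGRecord] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        raw = getattr(row, "_asdict", None)
        vals = row._asdict() if raw else dict(zip(df.columns, row))
        sym = harmonize_symbol(str(vals[cmap["gene"]]))
        try:
            lfc = float(vals[cmap["log2fc"]])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}:{i}: unparseable log2fc {vals[cmap['log2fc']]!r}") from exc
        padj_raw = vals[cmap["padj"]]
        padj: float | None
        if padj_raw is None or str(padj_raw).strip().lower() in _MISSING_TOKENS:
            padj = None
        else:
            try:
                padj = float(padj_raw)
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}:{i}: unparseable padj {padj_raw!r}") from exc
            if math.isnan(padj):
                padj = None
        rec = DEGRecord(sym, lfc, padj)
        prev = best.get(sym)
        if prev is None or _padj_key(rec) < _padj_key(prev):
            best[sym] = rec
    if not best:
        logger.warning("%s: empty DEG table", path)
    logger.info("%s: read %d rows, %d unique genes", path, len(df), len(best))
    return DEGTable(dataset_id=dataset_id, species=species, records=list(best.values()))


def _padj_key(rec: DEGRecord) -> float:
    return math.inf if rec.padj is None else rec.padj


def write_deg_table(table: DEGTable, path: str | Path) -> None:
    """Write a DEG table as a 3-column TSV (gene, log2fc, padj; missing -> NA)."""
    with open(path, "w") as fh:
        fh.write("gene\tlog2fc\tpadj\n")
        for r in table.records:
            padj = "NA" if r.padj is None else repr(r.padj)
            fh.write(f"{r.gene_symbol}\t{r.log2fc!r}\t{padj}\n")


# ---------------------------------------------------------------------------
# narrowPeak / BED
# ---------------------------------------------------------------------------


def _opt_float(tok: str) -> float | None:
    val = float(tok)
    return None if val == -1 else val


def read_narrowpeak(path: str | Path) -> list[NarrowPeakRecord]:
    """Read an ENCODE narrowPeak (BED6+4) file; -1 sentinels become None."""
    out: list[NarrowPeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 10:
                raise FormatError(
                    f"{path}:{lineno}: narrowPeak needs 10 columns, got {len(cols)}"
                )
            chrom, start, end, name, score, strand = cols[:6]
            start_i, end_i = int(start), int(end)
            if start_i >= end_i:
                raise FormatError(f"{path}:{lineno}: start {start_i} >= end {end_i}")
            summit = int(cols[9])
            out.append(
                NarrowPeakRecord(
                    interval=GenomicInterval(chrom, start_i, end_i, strand),
                    name=name,
                    score=int(score),
                    signal_value=float(cols[6]),
                    neglog10_p=_opt_float(cols[7]),
                    neglog10_q=_opt_float(cols[8]),
                    summit_offset=None if summit == -1 else summit,
                )
            )
    return out


def write_narrowpeak(peaks: Iterable[NarrowPeakRecord], path: str | Path) -> None:
    def fmt(v: float | None) -> str:
        return "-1" if v is None else repr(v)

    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            summit = -1 if p.summit_offset is None else p.summit_offset
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{p.score}\t{iv.strand}"
                f"\t{p.signal_value!r}\t{fmt(p.neglog10_p)}\t{fmt(p.neglog10_q)}\t{summit}\n"
            )


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 lines as plain intervals (used for blacklists)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            strand = cols[5] if len(cols) >= 6 else "."
            start, end = int(cols[1]), int(cols[2])
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            out.append(GenomicInterval(cols[0], start, end, strand))
    return out


def write_bed_intervals(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# TSS annotation
# ---------------------------------------------------------------------------


def read_tss(path: str | Path, format: str = "bed6") -> list[TSSRecord]:
    """Read TSS positions from a BED6 file or GTF gene features.

    The TSS is the strand-aware 5' end as a single 0-based position:
    ``start`` for + strand, ``end - 1`` (0-based) for - strand.
    """
    if format == "bed6":
        return _read_tss_bed6(path)
    if format == "gtf":
        return _read_tss_gtf(path)
    raise ValueError(f"unknown TSS format {format!r}; expected 'gtf' or 'bed6'")


def _read_tss_bed6(path: str | Path) -> list[TSSRecord]:
    out: list[TSSRecord] = []
    seen: set[TSSRecord] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 needs 6 columns")
            chrom, start, end, name, _score, strand = cols[:6]
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: TSS feature without strand")
            start_i, end_i = int(start), int(end)
            tss = start_i if strand == "+" else end_i - 1
            rec = TSSRecord(harmonize_symbol(name), chrom, strand, tss)
            if rec not in seen:
                seen.add(rec)
                out.append(rec)
    return out


def _read_tss_gtf(path: str | Path) -> list[TSSRecord]:
    out: list[TSSRecord] = []
    seen: set[TSSRecord] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise FormatError(f"{path}:{lineno}: GTF needs 9 columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = cols[:9]
            if feature != "gene":
                continue
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: gene feature without strand")
            name = _gtf_attr(attrs, "gene_name") or _gtf_attr(attrs, "gene_id")
            if name is None:
                raise FormatError(f"{path}:{lineno}: gene feature lacks gene_name/gene_id")
            # GTF is 1-based closed; 0-based 5' end is start-1 (+) or end-1 (-)
            tss = int(start) - 1 if strand == "+" else int(end) - 1
            rec = TSSRecord(harmonize_symbol(name), chrom, strand, tss)
            if rec not in seen:
                seen.add(rec)
                out.append(rec)
    return out


def _gtf_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part[len(key):].strip().strip('"')
    return None


def write_tss_bed6(tss: Iterable[TSSRecord], path: str | Path) -> None:
    """Write TSSs as single-base BED6 features ([tss, tss+1)).

    The strand-aware 5' end of a single-base feature is the base itself, so
    the round trip through `read_tss` recovers the same position on either
    strand.
    """
    with open(path, "w") as fh:
        for rec in tss:
            fh.write(
                f"{rec.chrom}\t{rec.tss}\t{rec.tss + 1}\t{rec.gene_symbol}\t0\t{rec.strand}\n"
            )


# ---------------------------------------------------------------------------
# JASPAR PFMs
# ---------------------------------------------------------------------------


def read_jaspar_pfm(path: str | Path) -> list[PFM]:
    """Read JASPAR-format PFMs (header '>ID NAME', rows 'A [ n1 n2 ... ]')."""
    with open(path) as fh:
        try:
            parsed = motifs.parse(fh, "jaspar")
        except Exception as exc:
            raise FormatError(f"{path}: not valid JASPAR PFM text: {exc}") from exc
    out: list[PFM] = []
    for m in parsed:
        counts = np.array([m.counts[base] for base in "ACGT"], dtype=float)
        motif_id = m.matrix_id or m.name
        name = m.name or motif_id
        if name == motif_id and (m.name is None or m.name == m.matrix_id):
            logger.warning("%s: motif %s has no name, defaulting to its ID", path, motif_id)
        out.append(PFM(motif_id=motif_id, name=name, counts=counts))
    if not out:
        raise FormatError(f"{path}: no motifs found")
    return out


def write_jaspar_pfm(pfms: Iterable[PFM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pfms:
            fh.write(f">{p.motif_id} {p.name}\n")
            for i, base in enumerate("ACGT"):
                row = " ".join(f"{v:.0f}" if v == int(v) else repr(v) for v in p.counts[i])
                fh.write(f"{base} [ {row} ]\n")


# ---------------------------------------------------------------------------
# GMT gene-set catalogs
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT catalog: term, description, tab-separated member symbols."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise FormatError(f"{path}:{lineno}: GMT needs term and description")
            term, desc = cols[0], cols[1]
            if term in sets:
                raise FormatError(f"{path}:{lineno}: duplicate term_id {term!r}")
            members = frozenset(
                harmonize_symbol(tok) for tok in cols[2:] if tok.strip()
            )
            if not members:
                logger.warning("%s:%d: dropping empty gene set %r", path, lineno, term)
                continue
            sets[term] = (desc, members)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, (desc, members) in collection.sets.items():
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# ortholog maps
# ---------------------------------------------------------------------------


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a human/mouse symbol correspondence TSV (columns human_symbol, mouse_symbol)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("human_symbol", "mouse_symbol"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for h, m in zip(df["human_symbol"], df["mouse_symbol"]):
        pair = (harmonize_symbol(h), harmonize_symbol(m))
        if pair not in seen:
            seen.add(pair)
            pairs.append(pair)
    by_human: dict[str, int] = {}
    for h, _ in pairs:
        by_human[h] = by_human.get(h, 0) + 1
    multi = sum(1 for n in by_human.values() if n > 1)
    if multi:
        logger.info("%s: %d human symbols with multiple mouse orthologs", path, multi)
    return OrthologMap(pairs=pairs)


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("human_symbol\tmouse_symbol\n")
        for h, m in omap.pairs:
            fh.write(f"{h}\t{m}\n")
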