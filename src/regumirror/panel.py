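"""Cross-dataset fold-change matrices and direction-stratified gene selection.

Given a gene panel (e.g. the predicted direct targets) and several
differential-expression tables, assemble the log2FC matrix gene x dataset
with per-cell significance flags, and select the strongest up/down regulated
genes from an overlap against a reference table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .formats import DEGTable, harmonize_symbol

__all__ = [
    "FoldChangeMatrix",
    "build_lfc_matrix",
    "select_top_bottom",
    "export_matrix",
    "import_matrix",
]


@dataclass
class FoldChangeMatrix:
    """log2FC per (panel gene, dataset) with a parallel significance mask.

    A cell is missing (NaN) iff the gene is absent from that dataset;
    `significant` flags padj < alpha cells (False where missing).
    """

    lfc: pd.DataFrame
    significant: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.lfc.index.equals(self.significant.index) or not self.lfc.columns.equals(
            self.significant.columns
        ):
            raise ValueError("lfc and significance frames must share labels")
        if self.lfc.index.has_duplicates or self.lfc.columns.has_duplicates:
            raise ValueError("row/column labels must be unique")


def build_lfc_matrix(
    panel: Sequence[str], datasets: Sequence[DEGTable], alpha: float = 0.05
) -> FoldChangeMatrix:
    """Matrix in panel order x dataset order; absent genes give missing cells."""
    if not panel:
        raise ValueError("panel must be non-empty")
    genes = [harmonize_symbol(g) for g in panel]
    if len(set(genes)) != len(genes):
        raise ValueError("panel symbols must be unique after harmonization")
    ids = [d.dataset_id for d in datasets]
    if len(set(ids)) != len(ids):
        raise ValueError("dataset ids must be unique")
    lfc = pd.DataFrame(np.nan, index=genes, columns=ids)
    sig = pd.DataFrame(False, index=genes, columns=ids)
    for d in datasets:
        dd = d.as_dict()
        hit = 0
        for g in genes:
            rec = dd.get(g)
            if rec is None:
                continue
            hit += 1
            lfc.loc[g, d.dataset_id] = rec.log2fc
            sig.loc[g, d.dataset_id] = rec.padj is not None and rec.padj < alpha
        if hit == 0:
            logging.getLogger(__name__).warning(
                "dataset %s contains no panel genes", d.dataset_id
            )
    return FoldChangeMatrix(lfc=lfc, significant=sig)


def select_top_bottom(
    overlap: Sequence[str], reference: DEGTable, n: int = 25
) -> tuple[list[str], list[str]]:
    """The n most up- and n most down-regulated overlap genes in `reference`.

    Genes with log2fc exactly 0 fall in neither list; ties break by smaller
    padj then symbol.  Each list is ordered by |log2fc| descending.
    """
    dd = reference.as_dict()
    recs = [dd[g] for g in overlap if g in dd]

    def key(r):
        padj = float("inf") if r.padj is None else r.padj
        return (-abs(r.log2fc), padj, r.gene_symbol)

    up = sorted((r for r in recs if r.log2fc > 0), key=key)[:n]
    down = sorted((r for r in recs if r.log2fc < 0), key=key)[:n]
    return [r.gene_symbol for r in up], [r.gene_symbol for r in down]


def export_matrix(matrix: FoldChangeMatrix, path: str | Path) -> None:
    """Write the matrix as TSV: gene column, one column per dataset, NA for missing.

    Significance flags travel in parallel columns suffixed `.sig` so the
    round trip preserves the full object.
    """
    out = pd.DataFrame(index=matrix.lfc.index)
    for col in matrix.lfc.columns:
        out[col] = [
            "NA" if pd.isna(v) else repr(float(v)) for v in matrix.lfc[col]
        ]
        out[f"{col}.sig"] = [
            "1" if bool(s) else "0" for s in matrix.significant[col]
        ]
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def import_matrix(path: str | Path) -> FoldChangeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene", dtype=str)
    value_cols = [c for c in df.columns if not c.endswith(".sig")]
    lfc = pd.DataFrame(index=df.index)
    sig = pd.DataFrame(index=df.index)
    for col in value_cols:
        lfc[col] = [np.nan if v == "NA" else float(v) for v in df[col]]
        sig[col] = [v == "1" for v in df[f"{col}.sig"]]
    lfc.index = lfc.index.astype(str)
    sig.index = sig.index.astype(str)
    return FoldChangeMatrix(lfc=lfc, significant=sig)
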