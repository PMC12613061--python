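"""Config-driven orchestration of the full analysis.

A YAML run configuration registers datasets (differential-expression
tables), gene-set catalogs, and the funnel's regulatory inputs, and names
the stages to execute (any of ``compare``, ``enrich``, ``gsea``, ``funnel``,
``panel``).  Stages run in dependency order; each writes TSV/JSON outputs
under its own subdirectory of the run directory plus a line in the run log
with parameter echo and input hashes.  Outputs are deterministic: rerunning
with the same config and seeds reproduces every file byte for byte
(timestamps live only in the log).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import enrichment as enr
from . import overlap as ov
from .formats import (
    DEGTable,
    SequenceStore,
    read_bed_intervals,
    read_deg_table,
    read_gmt,
    read_jaspar_pfm,
    read_narrowpeak,
    read_ortholog_map,
    read_tss,
)
from .funnel import FunnelOptions, SpeciesInputs, run_funnel
from .gsea import RankedList, gsea_significance
from .panel import build_lfc_matrix, export_matrix

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run", "summarize"]

STAGES = ("compare", "enrich", "gsea", "funnel", "panel")


class ConfigError(ValueError):
    """The run configuration is invalid."""


@dataclass
class RunConfig:
    """Validated run configuration; see `RunConfig.from_yaml`."""

    output_dir: Path
    datasets: dict[str, dict[str, Any]]
    stages: list[str]
    alpha: float = 0.05
    seed: int | None = None
    background: int | None = None
    compare: dict = field(default_factory=dict)
    enrich: dict = field(default_factory=dict)
    gsea: dict = field(default_factory=dict)
    funnel: dict = field(default_factory=dict)
    panel: dict = field(default_factory=dict)
    base_dir: Path = Path(".")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        for key in ("output_dir", "datasets", "stages"):
            if key not in raw:
                raise ConfigError(f"{path}: missing required key {key!r}")
        cfg = cls(
            output_dir=Path(raw["output_dir"]),
            datasets=dict(raw["datasets"]),
            stages=list(raw["stages"]),
            alpha=float(raw.get("alpha", 0.05)),
            seed=raw.get("seed"),
            background=raw.get("background"),
            compare=raw.get("compare", {}) or {},
            enrich=raw.get("enrich", {}) or {},
            gsea=raw.get("gsea", {}) or {},
            funnel=raw.get("funnel", {}) or {},
            panel=raw.get("panel", {}) or {},
            base_dir=path.parent,
        )
        cfg.validate()
        return cfg

    def resolve(self, p: str | Path) -> Path:
        p = Path(p)
        return p if p.is_absolute() else self.base_dir / p

    def validate(self) -> None:
        for stage in self.stages:
            if stage not in STAGES:
                raise ConfigError(f"unknown stage {stage!r}; valid: {STAGES}")
        for ds_id, spec in self.datasets.items():
            if "path" not in spec:
                raise ConfigError(f"dataset {ds_id!r}: missing 'path'")
            if not self.resolve(spec["path"]).exists():
                raise ConfigError(f"dataset {ds_id!r}: no such file {spec['path']}")
        if ("gsea" in self.stages or self.funnel) and self.seed is None:
            if "gsea" in self.stages:
                raise ConfigError("stochastic stage 'gsea' requires an explicit seed")
        if self.funnel:
            for key in ("pfm", "orthologs"):
                if key in self.funnel and not self.resolve(self.funnel[key]).exists():
                    raise ConfigError(f"funnel.{key}: no such file {self.funnel[key]}")

    def load_dataset(self, ds_id: str) -> DEGTable:
        spec = self.datasets[ds_id]
        return read_deg_table(
            self.resolve(spec["path"]),
            column_map=spec.get("columns"),
            dataset_id=ds_id,
            species=spec.get("species", "mouse"),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj: Any, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run(config: RunConfig) -> Path:
    """Execute all configured stages; returns the run directory.

    A failed stage aborts downstream stages but already-written outputs are
    preserved.
    """
    run_dir = config.output_dir
    run_dir.mkdir(parents=True, exist_ok=True)
    log_path = run_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="a")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("regumirror")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        meta = {
            "alpha": config.alpha,
            "seed": config.seed,
            "stages": config.stages,
            "inputs": {
                ds: _sha256(config.resolve(spec["path"]))
                for ds, spec in config.datasets.items()
            },
        }
        _write_json(meta, run_dir / "run_meta.json")
        for stage in STAGES:
            if stage not in config.stages:
                continue
            logger.info("stage %s: start", stage)
            _STAGE_FUNCS[stage](config, run_dir)
            logger.info("stage %s: done", stage)
    finally:
        root.removeHandler(handler)
        handler.close()
    return run_dir


def _stage_compare(config: RunConfig, run_dir: Path) -> None:
    pairs = config.compare.get("pairs")
    if not pairs:
        raise ConfigError("compare stage needs compare.pairs")
    for a_id, b_id in pairs:
        a, b = config.load_dataset(a_id), config.load_dataset(b_id)
        N = config.background or len(a.symbols() | b.symbols())
        a_sig = ov.filter_significant(a, config.alpha)
        b_sig = ov.filter_significant(b, config.alpha)
        shared = sorted(a_sig.symbols() & b_sig.symbols())
        res = ov.hypergeom_overlap_test(
            k=len(shared), K=len(a_sig), n=len(b_sig), N=N
        )
        conc = ov.direction_concordance(a_sig, b_sig)
        out = run_dir / "compare" / f"{a_id}__{b_id}"
        out.mkdir(parents=True, exist_ok=True)
        _write_json(
            {
                "k": res.k,
                "K": res.K,
                "n": res.n,
                "N": res.N,
                "expected": res.expected,
                "p_value": res.p_value,
                "overlap_pct_of_b": 100.0 * res.k / res.n if res.n else None,
            },
            out / "overlap.json",
        )
        _write_json(
            {
                "n_shared": conc.n_shared,
                "n_concordant": conc.n_concordant,
                "fraction": conc.fraction,
            },
            out / "concordance.json",
        )
        with open(out / "shared_lfc.tsv", "w") as fh:
            fh.write("gene\tlog2fc_a\tlog2fc_b\n")
            da, db = a_sig.as_dict(), b_sig.as_dict()
            for g in shared:
                fh.write(f"{g}\t{da[g].log2fc!r}\t{db[g].log2fc!r}\n")
        if len(shared) >= 3:
            corr = ov.correlate_shared_lfc(a_sig, b_sig)
            _write_json(
                {"rho": corr.rho, "p_value": corr.p_value, "n_shared": corr.n_shared},
                out / "correlation.json",
            )


def _stage_enrich(config: RunConfig, run_dir: Path) -> None:
    spec = config.enrich
    for key in ("query_dataset", "gmt"):
        if key not in spec:
            raise ConfigError(f"enrich stage needs enrich.{key}")
    table = config.load_dataset(spec["query_dataset"])
    direction = spec.get("direction", "up")
    sig = ov.filter_significant(table, config.alpha, direction=direction)
    background = table.symbols()
    catalog = read_gmt(config.resolve(spec["gmt"]))
    results = enr.ora(
        sig.symbols(),
        background,
        catalog,
        min_size=int(spec.get("min_size", 10)),
        max_size=int(spec.get("max_size", 500)),
    )
    if spec.get("simplify", True):
        sig_results = [r for r in results if r.padj < config.alpha]
        kept = enr.simplify_terms(sig_results, catalog, cutoff=float(spec.get("cutoff", 0.7)))
        kept_ids = {r.term_id for r in kept}
        results = [r for r in results if r.padj >= config.alpha or r.term_id in kept_ids]
    out = run_dir / "enrich"
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "enrichment.tsv", "w") as fh:
        fh.write("term\tk\tK\tn\tN\tp_value\tpadj\n")
        for r in results:
            fh.write(f"{r.term_id}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t{r.p_value!r}\t{r.padj!r}\n")


def _stage_gsea(config: RunConfig, run_dir: Path) -> None:
    spec = config.gsea
    for key in ("ranked_dataset", "gmt"):
        if key not in spec:
            raise ConfigError(f"gsea stage needs gsea.{key}")
    table = config.load_dataset(spec["ranked_dataset"])
    ranked = RankedList.from_table(table)
    catalog = read_gmt(config.resolve(spec["gmt"]))
    results = gsea_significance(
        ranked,
        catalog,
        n_perm=int(spec.get("n_perm", 10_000)),
        weight=float(spec.get("weight", 1.0)),
        seed=int(config.seed),
    )
    out = run_dir / "gsea"
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "gsea.tsv", "w") as fh:
        fh.write("set_id\tes\tnes\tp_value\tpadj\tleading_edge_size\n")
        for r in results:
            fh.write(
                f"{r.set_id}\t{r.es!r}\t{r.nes!r}\t{r.p_value!r}\t{r.padj!r}\t{len(r.leading_edge)}\n"
            )


def _load_species_inputs(config: RunConfig, spec: dict) -> SpeciesInputs:
    peaks = {
        factor: [
            p
            for path in paths
            for p in read_narrowpeak(config.resolve(path))
        ]
        for factor, paths in spec["peaks"].items()
    }
    return SpeciesInputs(
        peaks_by_factor=peaks,
        blacklist=read_bed_intervals(config.resolve(spec["blacklist"]))
        if spec.get("blacklist")
        else [],
        tss=read_tss(config.resolve(spec["tss"]), format=spec.get("tss_format", "bed6")),
        genome=SequenceStore.from_fasta(config.resolve(spec["genome"])),
    )


def _stage_funnel(config: RunConfig, run_dir: Path) -> None:
    spec = config.funnel
    for key in ("human", "mouse", "pfm", "orthologs", "deg_2wk", "deg_8wk"):
        if key not in spec:
            raise ConfigError(f"funnel stage needs funnel.{key}")
    human = _load_species_inputs(config, spec["human"])
    mouse = _load_species_inputs(config, spec["mouse"])
    pfms = read_jaspar_pfm(config.resolve(spec["pfm"]))
    orthologs = read_ortholog_map(config.resolve(spec["orthologs"]))
    deg_2wk = config.load_dataset(spec["deg_2wk"])
    deg_8wk = config.load_dataset(spec["deg_8wk"])
    options = FunnelOptions(
        alpha=config.alpha,
        flank=int(spec.get("flank", 2000)),
        p_cutoff=float(spec.get("p_cutoff", 5e-5)),
    )
    result = run_funnel(human, mouse, pfms, orthologs, deg_2wk, deg_8wk, options)
    out = run_dir / "funnel"
    out.mkdir(parents=True, exist_ok=True)
    _write_json(result.stage_counts, out / "stage_counts.json")
    with open(out / "panel.tsv", "w") as fh:
        fh.write(
            "gene\thuman_score\thuman_tier\tmouse_score\tmouse_tier"
            "\ttead_motif\tlog2fc_2wk\tlog2fc_8wk\n"
        )
        for r in result.panel:
            fh.write(
                f"{r.gene_symbol}\t{r.human_score}\t{r.human_tier}"
                f"\t{r.mouse_score}\t{r.mouse_tier}\t{r.tead_motif_present}"
                f"\t{r.log2fc_2wk!r}\t{r.log2fc_8wk!r}\n"
            )


def _stage_panel(config: RunConfig, run_dir: Path) -> None:
    spec = config.panel
    genes = spec.get("genes")
    if genes == "from_funnel" or genes is None:
        panel_path = run_dir / "funnel" / "panel.tsv"
        if not panel_path.exists():
            raise ConfigError("panel stage: no gene list and no funnel output found")
        with open(panel_path) as fh:
            next(fh)
            genes = [line.split("\t", 1)[0] for line in fh if line.strip()]
    elif isinstance(genes, str):
        with open(config.resolve(genes)) as fh:
            genes = [line.strip() for line in fh if line.strip()]
    ds_ids = spec.get("datasets") or list(config.datasets)
    matrix = build_lfc_matrix(
        genes, [config.load_dataset(i) for i in ds_ids], alpha=config.alpha
    )
    out = run_dir / "panel"
    out.mkdir(parents=True, exist_ok=True)
    export_matrix(matrix, out / "matrix.tsv")


_STAGE_FUNCS = {
    "compare": _stage_compare,
    "enrich": _stage_enrich,
    "gsea": _stage_gsea,
    "funnel": _stage_funnel,
    "panel": _stage_panel,
}


def summarize(run_dir: str | Path) -> dict:
    """Aggregate a run directory into one JSON-ready summary document."""
    run_dir = Path(run_dir)
    meta_path = run_dir / "run_meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"{run_dir}: not a run directory (no run_meta.json)")
    with open(meta_path) as fh:
        meta = json.load(fh)
    summary: dict[str, Any] = {"meta": meta, "missing_stages": []}
    compare_dir = run_dir / "compare"
    if compare_dir.is_dir():
        blocks = {}
        for pair_dir in sorted(compare_dir.iterdir()):
            block = {}
            for name in ("overlap", "concordance", "correlation"):
                p = pair_dir / f"{name}.json"
                if p.exists():
                    with open(p) as fh:
                        block[name] = json.load(fh)
            blocks[pair_dir.name] = block
        summary["compare"] = blocks
    else:
        summary["missing_stages"].append("compare")
    for stage, fname in (
        ("enrich", "enrichment.tsv"),
        ("gsea", "gsea.tsv"),
    ):
        p = run_dir / stage / fname
        if p.exists():
            with open(p) as fh:
                header = fh.readline().rstrip("\n").split("\t")
                rows = [dict(zip(header, line.rstrip("\n").split("\t"))) for line in fh]
            summary[stage] = {"n_rows": len(rows), "top": rows[:10]}
        else:
            summary["missing_stages"].append(stage)
    sc = run_dir / "funnel" / "stage_counts.json"
    if sc.exists():
        with open(sc) as fh:
            summary["funnel"] = {"stage_counts": json.load(fh)}
        panel_path = run_dir / "funnel" / "panel.tsv"
        if panel_path.exists():
            with open(panel_path) as fh:
                next(fh)
                summary["funnel"]["panel_genes"] = [
                    line.split("\t", 1)[0] for line in fh if line.strip()
                ]
    else:
        summary["missing_stages"].append("funnel")
    if not (run_dir / "panel" / "matrix.tsv").exists():
        summary["missing_stages"].append("panel")
    _write_json(summary, run_dir / "summary.json")
    return summary
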