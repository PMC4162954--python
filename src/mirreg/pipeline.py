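"""End-to-end run orchestration: filtering -> catalog -> Monte Carlo ->
promoter proximity -> network assembly, with a machine-readable manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .catalog import consensus_filter, conservation_match
from .expression import (
    DERecord,
    FeatureKind,
    Thresholds,
    classify_cross_cell_line,
    filter_gene_de,
    filter_mirna_de,
)
from .io import (
    read_bed,
    read_catalog,
    read_de_table,
    read_tss_table,
    read_validated_table,
    write_concordance_report,
    write_de_table,
    write_edges,
    write_graph_export,
    write_master_results,
)
from .master import identify_master_regulators
from .network import (
    annotate_validated,
    assemble_network,
    classify_feedback_loops,
    summarise_interactions,
)
from .proximity import compile_tss, find_proximal_tfbs, intersect_with_de

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Paths, thresholds and run settings for one end-to-end execution."""

    mirna_de_path: str
    gene_de_path: str
    gene_table_path: str
    mirna_table_path: str
    site_table_path: str
    tss_table_path: str
    peaks_path: str
    outdir: str
    validated_path: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    statistic: str = "target_count"
    seed: int = 0
    mirna_fold_scale: str = "signed-linear"
    gene_fold_scale: str = "signed-linear"
    tf_id: str = "SOX2"

    def input_paths(self) -> dict[str, str]:
        out = {
            "mirna_de": self.mirna_de_path,
            "gene_de": self.gene_de_path,
            "gene_table": self.gene_table_path,
            "mirna_table": self.mirna_table_path,
            "site_table": self.site_table_path,
            "tss_table": self.tss_table_path,
            "peaks": self.peaks_path,
        }
        if self.validated_path is not None:
            out["validated"] = self.validated_path
        return out


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the output bundle; returns the manifest dict.

    All inputs are checked before any output is written, so a missing file
    aborts without partial results. Re-running with identical inputs and
    seed produces byte-identical result tables.
    """
    missing = [p for p in config.input_paths().values() if not Path(p).exists()]
    if missing:
        raise PipelineError(f"startup: missing input files {missing}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = config.thresholds

    try:
        mirna_de = read_de_table(config.mirna_de_path, config.mirna_fold_scale)
        gene_de = read_de_table(config.gene_de_path, config.gene_fold_scale)
        catalog = read_catalog(config.gene_table_path, config.mirna_table_path,
                               config.site_table_path)
        tss = read_tss_table(config.tss_table_path)
        peaks = read_bed(config.peaks_path)
        validated = (read_validated_table(config.validated_path)
                     if config.validated_path else [])
    except Exception as exc:
        raise PipelineError(f"input: {exc}") from exc

    try:
        sig_mirnas = filter_mirna_de(mirna_de, thresholds)
        sig_genes = filter_gene_de(gene_de, thresholds)
        write_de_table(sig_mirnas, outdir / "filtered_mirna_de.tsv", "log2")
        write_de_table(sig_genes, outdir / "filtered_gene_de.tsv", "log2")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"expression_filtering: {exc}") from exc

    cell_lines = sorted({r.cell_line for r in sig_mirnas})
    try:
        if len(cell_lines) == 2:
            a, b = cell_lines
            report = classify_cross_cell_line(
                [r for r in sig_mirnas if r.cell_line == a],
                [r for r in sig_mirnas if r.cell_line == b],
            )
            write_concordance_report(report, outdir / "concordance.tsv")
        else:
            write_concordance_report(
                classify_cross_cell_line(sig_mirnas, []), outdir / "concordance.tsv"
            )
    except Exception as exc:
        raise PipelineError(f"concordance: {exc}") from exc

    try:
        mr_results = identify_master_regulators(
            sig_mirnas, sig_genes, catalog, thresholds, config.seed,
            statistic=config.statistic,
        )
        write_master_results(mr_results, outdir / "master_regulators.tsv")
    except Exception as exc:
        raise PipelineError(f"master_regulator: {exc}") from exc

    mature_map: dict[str, list[str]] = {}
    for m in catalog.mirnas:
        mature_map.setdefault(m.precursor_id, []).append(m.mature_id)

    try:
        mirna_tss = [t for t in tss if t.source == "mirna_tss"]
        host_tss = [t for t in tss if t.source == "host_gene_tss"]
        compiled = compile_tss(mirna_tss, host_tss)
        hits = find_proximal_tfbs(compiled, peaks, thresholds)
        proximity_table = intersect_with_de(hits, sig_mirnas, mature_map)
        proximity_table.to_csv(outdir / "proximity.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(f"promoter_proximity: {exc}") from exc

    try:
        matched = conservation_match(list(catalog.sites), list(catalog.mirnas))
        consensus = consensus_filter(matched, thresholds)
        edges = assemble_network(mr_results, consensus, hits, sig_mirnas,
                                 sig_genes, mature_map, tf_id=config.tf_id)
        edges = annotate_validated(edges, validated)
        write_edges(edges, outdir / "edges.tsv")
        write_graph_export(edges, outdir / "nodes.tsv", outdir / "graph_edges.tsv")
        summary = summarise_interactions(edges)
        tf_repressors = [m for m, g, e in validated if g == config.tf_id]
        loops = classify_feedback_loops(sig_mirnas, tf_repressors)
        with open(outdir / "interaction_summary.json", "w") as fh:
            json.dump({
                "n_interactions": summary.n_interactions,
                "n_unique_genes": summary.n_unique_genes,
                "n_high_conf_interactions": summary.n_high_conf_interactions,
                "n_high_conf_genes": summary.n_high_conf_genes,
                "n_genes_multi_high": summary.n_genes_multi_high,
                "feedback_loops": [{"mirna": m, "loop": l} for m, l in loops],
            }, fh, indent=2)
            fh.write("\n")
    except Exception as exc:
        raise PipelineError(f"network_summary: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "statistic": config.statistic,
        "tf_id": config.tf_id,
        "thresholds": dataclasses.asdict(thresholds),
        "fold_scales": {"mirna": config.mirna_fold_scale,
                        "gene": config.gene_fold_scale},
        "inputs": {name: {"path": str(path), "sha256": _sha256(path)}
                   for name, path in config.input_paths().items()},
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()
                          and p.name != "manifest.json"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
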