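"""Readers and writers for the pipeline's tab-separated file dialects.

All tables carry a header row and are matched by column name
(order-insensitive); unknown columns are ignored on read. Fold changes may
arrive as signed linear values (``fold_scale="signed-linear"``, the qRT-PCR
array convention) or as log2 (``fold_scale="log2"``); the internal
representation is always log2. BED input is 0-based half-open and validated
per line; 1-based TSS tables are converted at the reader via the
``#coords=`` header flag.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalog import (
    Catalog,
    ConservationClass,
    GeneRecord,
    MiRNARecord,
    SiteConservation,
    SiteType,
    TargetSite,
)
from .expression import (
    ConcordanceReport,
    DERecord,
    FeatureKind,
    log2_to_signed_fold,
    signed_fold_to_log2,
)
from .master import MasterRegulatorResult
from .network import NetworkEdge
from .proximity import TFBSPeak, TSSRecord

__all__ = [
    "SchemaError",
    "read_de_table", "write_de_table",
    "read_gene_table", "write_gene_table",
    "read_mirna_table", "write_mirna_table",
    "read_site_table", "write_site_table",
    "read_catalog",
    "read_tss_table", "write_tss_table",
    "read_bed", "write_bed",
    "read_validated_table", "write_validated_table",
    "write_concordance_report",
    "write_master_results",
    "write_edges", "read_edges",
    "write_graph_export",
]

FOLD_SCALES = ("signed-linear", "log2")


class SchemaError(ValueError):
    """A table is missing required columns or violates its schema."""


def _read_tsv(path: str | Path, required: Sequence[str], *,
              comment: str | None = None) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str, comment=comment,
                        keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return frame


def _opt_float(value: str) -> float | None:
    return None if value == "" else float(value)


# ---------------------------------------------------------------- DE tables

def read_de_table(path: str | Path, fold_scale: str = "signed-linear") -> list[DERecord]:
    if fold_scale not in FOLD_SCALES:
        raise ValueError(f"fold_scale must be one of {FOLD_SCALES}")
    frame = _read_tsv(path, ["feature_id", "feature_kind", "cell_line",
                             "fold_change", "p_value"])
    has_fdr = "fdr" in frame.columns
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        fold = float(row.fold_change)
        log2fc = (signed_fold_to_log2(fold, label=str(i))
                  if fold_scale == "signed-linear" else fold)
        fdr = _opt_float(row.fdr) if has_fdr else None
        records.append(DERecord(
            feature_id=row.feature_id,
            feature_kind=FeatureKind(row.feature_kind),
            cell_line=row.cell_line,
            log2fc=log2fc,
            p_value=float(row.p_value),
            fdr=fdr,
        ))
    return records


def write_de_table(records: Sequence[DERecord], path: str | Path,
                   fold_scale: str = "signed-linear") -> None:
    if fold_scale not in FOLD_SCALES:
        raise ValueError(f"fold_scale must be one of {FOLD_SCALES}")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["feature_id", "feature_kind", "cell_line",
                         "fold_change", "p_value", "fdr"])
        for rec in records:
            fold = (log2_to_signed_fold(rec.log2fc)
                    if fold_scale == "signed-linear" else rec.log2fc)
            writer.writerow([
                rec.feature_id, rec.feature_kind.value, rec.cell_line,
                repr(fold), repr(rec.p_value),
                "" if rec.fdr is None else repr(rec.fdr),
            ])


# ------------------------------------------------------------- catalog files

def read_gene_table(path: str | Path) -> list[GeneRecord]:
    frame = _read_tsv(path, ["gene_id", "utr_length"])
    return [GeneRecord(r.gene_id, int(r.utr_length))
            for r in frame.itertuples(index=False)]


def write_gene_table(genes: Sequence[GeneRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id", "utr_length"])
        for g in genes:
            writer.writerow([g.gene_id, g.utr_length])


def read_mirna_table(path: str | Path) -> list[MiRNARecord]:
    frame = _read_tsv(path, ["mature_id", "precursor_id", "conservation_class"])
    return [
        MiRNARecord(r.mature_id, r.precursor_id, ConservationClass(r.conservation_class))
        for r in frame.itertuples(index=False)
    ]


def write_mirna_table(mirnas: Sequence[MiRNARecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["mature_id", "precursor_id", "conservation_class"])
        for m in mirnas:
            writer.writerow([m.mature_id, m.precursor_id, m.conservation_class.value])


def read_site_table(path: str | Path) -> list[TargetSite]:
    frame = _read_tsv(path, ["mature_id", "gene_id", "utr_offset", "site_type",
                             "site_conservation", "in_targetscan"])
    has_microt = "microt_score" in frame.columns
    has_mirsvr = "mirsvr_score" in frame.columns
    sites = []
    for r in frame.itertuples(index=False):
        sites.append(TargetSite(
            mature_id=r.mature_id,
            gene_id=r.gene_id,
            utr_offset=int(r.utr_offset),
            site_type=SiteType(r.site_type),
            site_conservation=SiteConservation(r.site_conservation),
            in_targetscan=r.in_targetscan in ("1", "true", "True"),
            microt_score=_opt_float(r.microt_score) if has_microt else None,
            mirsvr_score=_opt_float(r.mirsvr_score) if has_mirsvr else None,
        ))
    return sites


def write_site_table(sites: Sequence[TargetSite], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["mature_id", "gene_id", "utr_offset", "site_type",
                         "site_conservation", "in_targetscan",
                         "microt_score", "mirsvr_score"])
        for s in sites:
            writer.writerow([
                s.mature_id, s.gene_id, s.utr_offset, s.site_type.value,
                s.site_conservation.value, int(s.in_targetscan),
                "" if s.microt_score is None else repr(s.microt_score),
                "" if s.mirsvr_score is None else repr(s.mirsvr_score),
            ])


def read_catalog(gene_path: str | Path, mirna_path: str | Path,
                 site_path: str | Path) -> Catalog:
    return Catalog(
        genes=tuple(read_gene_table(gene_path)),
        mirnas=tuple(read_mirna_table(mirna_path)),
        sites=tuple(read_site_table(site_path)),
    )


# --------------------------------------------------------------- TSS and BED

def read_tss_table(path: str | Path) -> list[TSSRecord]:
    """TSS table with a ``#coords=0`` / ``#coords=1`` coordinate-base header flag.

    1-based positions are converted to the 0-based internal convention.
    Malformed strand or source values raise with the offending row number.
    """
    base = 0
    with open(path) as fh:
        first = fh.readline().strip()
    skip = 0
    if first.startswith("#coords="):
        base = int(first.split("=", 1)[1])
        if base not in (0, 1):
            raise SchemaError(f"{path}: coordinate base must be 0 or 1")
        skip = 1
    frame = pd.read_csv(path, sep="\t", dtype=str, skiprows=skip,
                        keep_default_na=False)
    missing = [c for c in ("precursor_id", "chrom", "position", "strand", "source")
               if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=2 + skip):
        try:
            records.append(TSSRecord(row.precursor_id, row.chrom,
                                     int(row.position) - base, row.strand, row.source))
        except ValueError as exc:
            raise SchemaError(f"{path}, line {i}: {exc}") from exc
    return records


def write_tss_table(records: Sequence[TSSRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("#coords=0\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["precursor_id", "chrom", "position", "strand", "source"])
        for r in records:
            writer.writerow([r.precursor_id, r.chrom, r.position, r.strand, r.source])


def read_bed(path: str | Path, default_dataset: str = "peaks") -> list[TFBSPeak]:
    """BED3+ peaks, 0-based half-open; start >= end fails with its line number."""
    peaks = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(f"{path}, line {i}: BED needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start < 0 or start >= end:
                raise SchemaError(
                    f"{path}, line {i}: invalid interval [{start}, {end})"
                )
            dataset = fields[3] if len(fields) > 3 and fields[3] else default_dataset
            peaks.append(TFBSPeak(chrom, start, end, dataset))
    return peaks


def write_bed(peaks: Sequence[TFBSPeak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.dataset}\n")


# ------------------------------------------------------- validated + reports

def read_validated_table(path: str | Path) -> list[tuple[str, str, str]]:
    frame = _read_tsv(path, ["mirna_id", "gene_id", "evidence"])
    return [(r.mirna_id, r.gene_id, r.evidence) for r in frame.itertuples(index=False)]


def write_validated_table(rows: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["mirna_id", "gene_id", "evidence"])
        for mirna, gene, evidence in rows:
            writer.writerow([mirna, gene, evidence])


def write_concordance_report(report: ConcordanceReport, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["feature_id", "category"])
        writer.writerows(report.rows())


def write_master_results(results: Sequence[MasterRegulatorResult],
                         path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["cell_line", "mature_id", "direction", "statistic_kind",
                         "observed_raw", "observed_normalised", "group_mean_utr",
                         "background_mean_utr", "empirical_p", "adjusted_p",
                         "is_master"])
        for r in results:
            writer.writerow([
                r.cell_line, r.mature_id, r.direction, r.statistic_kind,
                repr(r.observed_raw), repr(r.observed_normalised),
                repr(r.group_mean_utr), repr(r.background_mean_utr),
                repr(r.empirical_p), repr(r.adjusted_p), int(r.is_master),
            ])


def write_edges(edges: Sequence[NetworkEdge], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["source", "target", "edge_type", "sign",
                         "confidence", "validated"])
        for e in edges:
            writer.writerow([e.source_id, e.target_id, e.edge_type, e.sign,
                             e.confidence, int(e.validated)])


def read_edges(path: str | Path) -> list[NetworkEdge]:
    frame = _read_tsv(path, ["source", "target", "edge_type", "sign",
                             "confidence", "validated"])
    return [
        NetworkEdge(r.source, r.target, r.edge_type, r.sign, r.confidence,
                    r.validated in ("1", "true", "True"))
        for r in frame.itertuples(index=False)
    ]


def write_graph_export(edges: Sequence[NetworkEdge], node_path: str | Path,
                       edge_path: str | Path) -> None:
    """Plain node-list + edge-list export for visualisation tools."""
    kind: dict[str, str] = {}
    for e in edges:
        src_kind = "tf" if e.edge_type.startswith("tf_") else "mirna"
        tgt_kind = "mirna" if e.edge_type == "tf_mirna" else "gene"
        kind.setdefault(e.source_id, src_kind)
        kind.setdefault(e.target_id, tgt_kind)
    with open(node_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["node_id", "node_kind"])
        for node in sorted(kind):
            writer.writerow([node, kind[node]])
    write_edges(edges, edge_path)
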