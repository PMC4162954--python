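"""Synthetic input generator with planted ground truth.

Emulates the statistical structure the analysis assumes, so every pipeline
stage is testable without external databases:

* a gene universe with log-normal 3'UTR lengths;
* a TargetScan-style site table whose per-gene site counts grow linearly
  with UTR length (Poisson rate per kb), with two-component (true site vs
  decoy) score distributions for the microT-CDS and mirSVR co-predictors;
* differential-expression tables in which a chosen set of *planted master*
  miRNAs has its consensus targets over-represented in the inversely
  deregulated gene group by a configurable enrichment factor;
* a synthetic chromosome on which *planted proximal* precursors get exactly
  one TF peak inside the promoter window and all others get peaks far away.

All generators are deterministic under a fixed seed; each stage draws from
its own child stream so adding a stage never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .catalog import (
    Catalog,
    ConservationClass,
    GeneRecord,
    MiRNARecord,
    SiteConservation,
    SiteType,
    TargetSite,
    consensus_filter,
    conservation_match,
)
from .expression import DERecord, FeatureKind, Thresholds, benjamini_hochberg
from .proximity import TFBSPeak, TSSRecord

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticBundle",
    "generate_universe",
    "generate_target_db",
    "generate_de_tables",
    "generate_genomic_features",
    "generate_bundle",
]

_SITE_TYPES = (SiteType.EIGHT_MER, SiteType.SEVEN_MER_M8,
               SiteType.SEVEN_MER_A1, SiteType.SIX_MER)
_SITE_TYPE_PROBS = (0.15, 0.35, 0.35, 0.15)
_CONS_CLASSES = (ConservationClass.BROADLY_CONSERVED,
                 ConservationClass.MAMMAL_CONSERVED,
                 ConservationClass.PRIMATE_SPECIFIC)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    Defaults give a desk-scale regime: 2000 genes with median ~1.1 kb UTRs,
    30 miRNAs each hitting ~6% of genes, 10% of genes deregulated in each
    direction, and a 5-fold enrichment for planted masters.
    """

    n_genes: int = 2000
    n_mirnas: int = 30
    utr_log_mean: float = 7.0   # natural-log scale, nt
    utr_log_sd: float = 0.6
    site_rate_per_kb: float = 0.05  # expected sites per kb of UTR per miRNA
    planted_masters: tuple[str, ...] = ()
    enrichment_factor: float = 1.0
    frac_genes_up: float = 0.10
    frac_genes_down: float = 0.10
    planted_proximal: tuple[str, ...] = ()
    window_nt: int = 5000
    seed: int = 0
    cell_line: str = "simA"
    tf_id: str = "SOX2"
    # two-component co-predictor score model (true site vs decoy)
    true_site_fraction: float = 0.85
    conserved_site_fraction: float = 0.75
    microt_true: tuple[float, float] = (0.60, 0.15)
    microt_decoy: tuple[float, float] = (0.15, 0.10)
    mirsvr_true: tuple[float, float] = (0.35, 0.20)   # magnitude; stored negative
    mirsvr_decoy: tuple[float, float] = (0.02, 0.04)

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.n_mirnas < 0:
            raise ValueError("n_genes and n_mirnas must be non-negative")
        if not (0 <= self.frac_genes_up <= 1 and 0 <= self.frac_genes_down <= 1
                and self.frac_genes_up + self.frac_genes_down <= 1):
            raise ValueError("gene fractions must lie in [0,1] and sum to <= 1")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if self.site_rate_per_kb < 0 or self.window_nt <= 0:
            raise ValueError("invalid site rate or window")

    def mature_ids(self) -> list[str]:
        return [f"miR-n{i + 1:03d}" for i in range(self.n_mirnas)]

    def precursor_ids(self) -> list[str]:
        return [f"hsa-mir-n{i + 1:03d}" for i in range(self.n_mirnas)]


@dataclass(frozen=True)
class SyntheticTruth:
    true_masters: frozenset[str]
    true_proximal: frozenset[str]
    true_targets: frozenset[tuple[str, str]]


@dataclass(frozen=True)
class SyntheticBundle:
    config: SyntheticConfig
    catalog: Catalog
    mirna_de: tuple[DERecord, ...]
    gene_de: tuple[DERecord, ...]
    tss: tuple[TSSRecord, ...]
    peaks: tuple[TFBSPeak, ...]
    truth: SyntheticTruth


def _stage_rng(config: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed,
                                                        spawn_key=(stage,)))


def generate_universe(config: SyntheticConfig) -> tuple[list[GeneRecord], list[MiRNARecord]]:
    """Genes with log-normal UTR lengths (floor 50 nt) and round-robin miRNA classes."""
    rng = _stage_rng(config, 0)
    lengths = np.maximum(
        50, np.rint(rng.lognormal(config.utr_log_mean, config.utr_log_sd,
                                  size=config.n_genes)).astype(int)
    )
    genes = [GeneRecord(f"G{i + 1:05d}", int(lengths[i])) for i in range(config.n_genes)]
    matures = config.mature_ids()
    precursors = config.precursor_ids()
    mirnas = [
        MiRNARecord(matures[i], precursors[i], _CONS_CLASSES[i % 3])
        for i in range(config.n_mirnas)
    ]
    return genes, mirnas


def generate_target_db(
    config: SyntheticConfig,
    genes: Sequence[GeneRecord],
    mirnas: Sequence[MiRNARecord],
) -> list[TargetSite]:
    """Site table: counts ~ Poisson(rate x UTR-kb) per (miRNA, gene) pair.

    Offsets are uniform in the UTR; site types follow fixed canonical
    frequencies; co-predictor scores come from the two-component true/decoy
    model so most true sites pass the default consensus thresholds.
    """
    rng = _stage_rng(config, 1)
    if not genes or not mirnas or config.site_rate_per_kb == 0:
        return []
    lengths = np.array([g.utr_length for g in genes], dtype=float)
    lam = config.site_rate_per_kb * lengths / 1000.0
    counts = rng.poisson(np.broadcast_to(lam, (len(mirnas), len(genes))))
    mi_idx, g_idx = np.nonzero(counts)
    n_pairs_sites = counts[mi_idx, g_idx]
    total = int(n_pairs_sites.sum())
    if total == 0:
        return []

    mi_rep = np.repeat(mi_idx, n_pairs_sites)
    g_rep = np.repeat(g_idx, n_pairs_sites)
    offsets = (rng.random(total) * lengths[g_rep]).astype(int)
    types = rng.choice(len(_SITE_TYPES), size=total, p=_SITE_TYPE_PROBS)
    conserved = rng.random(total) < config.conserved_site_fraction
    is_true = rng.random(total) < config.true_site_fraction

    def mix(true_params, decoy_params):
        mu = np.where(is_true, true_params[0], decoy_params[0])
        sd = np.where(is_true, true_params[1], decoy_params[1])
        return rng.normal(mu, sd)

    microt = np.clip(mix(config.microt_true, config.microt_decoy), 0.0, 1.0)
    mirsvr = -np.abs(mix(config.mirsvr_true, config.mirsvr_decoy))

    sites = [
        TargetSite(
            mature_id=mirnas[mi_rep[k]].mature_id,
            gene_id=genes[g_rep[k]].gene_id,
            utr_offset=int(offsets[k]),
            site_type=_SITE_TYPES[types[k]],
            site_conservation=(SiteConservation.CONSERVED if conserved[k]
                               else SiteConservation.NONCONSERVED),
            in_targetscan=True,
            microt_score=float(round(microt[k], 4)),
            mirsvr_score=float(round(mirsvr[k], 4)),
        )
        for k in range(total)
    ]
    return sites


def generate_de_tables(
    config: SyntheticConfig,
    genes: Sequence[GeneRecord],
    mirnas: Sequence[MiRNARecord],
    sites: Sequence[TargetSite],
    thresholds: Thresholds | None = None,
) -> tuple[list[DERecord], list[DERecord], SyntheticTruth]:
    """DE tables with planted master-regulator enrichment.

    Deregulated genes get |log2fc| ~ |N(1.5, 0.5)| and p ~ U(0, 0.005);
    the rest are null (log2fc ~ N(0, 0.2), p ~ U(0, 1)); FDR is
    Benjamini-Hochberg over the full gene p-vector. Planted masters are
    significantly down-regulated and have their consensus-target membership
    in the up-group raised to ``enrichment_factor`` times the base rate.
    """
    thresholds = thresholds or Thresholds()
    rng = _stage_rng(config, 2)
    n_genes = len(genes)
    gene_ids = [g.gene_id for g in genes]
    n_up = round(config.frac_genes_up * n_genes)
    n_down = round(config.frac_genes_down * n_genes)
    perm = rng.permutation(n_genes)
    up = set(perm[:n_up].tolist())
    down = set(perm[n_up:n_up + n_down].tolist())
    index_of = {g: i for i, g in enumerate(gene_ids)}

    planted = [m for m in config.planted_masters]
    unknown = set(planted) - {m.mature_id for m in mirnas}
    if unknown:
        raise ValueError(f"planted masters not in miRNA table: {sorted(unknown)}")

    true_targets: set[tuple[str, str]] = set()
    if planted and config.enrichment_factor > 1:
        matched = conservation_match(list(sites), list(mirnas))
        consensus = consensus_filter(matched, thresholds)
        targets_by_mirna: dict[str, set[int]] = {}
        for t in consensus:
            targets_by_mirna.setdefault(t.mature_id, set()).add(index_of[t.gene_id])
        all_planted_targets: set[int] = set()
        for m in planted:
            all_planted_targets |= targets_by_mirna.get(m, set())
        forced: set[int] = set()
        for m in planted:
            targets = targets_by_mirna.get(m, set())
            true_targets |= {(m, gene_ids[i]) for i in targets}
            want = round(config.enrichment_factor * config.frac_genes_up * len(targets))
            if want > n_up:
                raise ValueError(
                    f"{m}: required enriched target count {want} exceeds group size {n_up}"
                )
            current = targets & up
            need = want - len(current)
            forced |= current
            if need <= 0:
                continue
            candidates = sorted(targets - up - down - forced)
            if need > len(candidates):
                raise ValueError(f"{m}: not enough free targets to plant enrichment")
            chosen = rng.choice(candidates, size=need, replace=False)
            evictable = sorted(up - forced - all_planted_targets) or sorted(up - forced)
            if need > len(evictable):
                raise ValueError(f"{m}: cannot keep group size while planting enrichment")
            evicted = rng.choice(evictable, size=need, replace=False)
            up -= set(int(i) for i in evicted)
            up |= set(int(i) for i in chosen)
            forced |= set(int(i) for i in chosen)

    log2fc = rng.normal(0.0, 0.2, size=n_genes)
    p_vals = rng.random(n_genes)
    magnitudes = np.abs(rng.normal(1.5, 0.5, size=n_genes))
    for i in sorted(up):
        log2fc[i] = magnitudes[i]
        p_vals[i] = rng.random() * 0.005
    for i in sorted(down):
        log2fc[i] = -magnitudes[i]
        p_vals[i] = rng.random() * 0.005
    fdr = benjamini_hochberg(p_vals.tolist())
    gene_de = [
        DERecord(gene_ids[i], FeatureKind.GENE, config.cell_line,
                 float(log2fc[i]), float(p_vals[i]), float(fdr[i]))
        for i in range(n_genes)
    ]

    planted_set = set(planted)
    mirna_de = []
    for m in mirnas:
        mag = abs(float(rng.normal(1.5, 0.5)))
        if m.mature_id in planted_set:
            fc = -mag
        else:
            fc = mag if rng.random() < 0.5 else -mag
        mirna_de.append(DERecord(m.mature_id, FeatureKind.MIRNA, config.cell_line,
                                 fc, float(rng.random() * 0.005)))

    truth = SyntheticTruth(
        true_masters=frozenset(planted if config.enrichment_factor > 1 else ()),
        true_proximal=frozenset(config.planted_proximal),
        true_targets=frozenset(true_targets),
    )
    return mirna_de, gene_de, truth


def generate_genomic_features(
    config: SyntheticConfig, mirnas: Sequence[MiRNARecord]
) -> tuple[list[TSSRecord], list[TFBSPeak], frozenset[str]]:
    """One TSS per precursor on a synthetic chromosome plus planted peaks.

    Planted-proximal precursors receive one peak whose midpoint sits at a
    uniform signed offset within the window; all other precursors get a peak
    at 2.5x the window, safely outside. Strands alternate.
    """
    rng = _stage_rng(config, 3)
    planted = set(config.planted_proximal)
    unknown = planted - set(config.precursor_ids())
    if unknown:
        raise ValueError(f"planted proximal precursors unknown: {sorted(unknown)}")
    w = config.window_nt
    chrom = "chrS1"
    tss_list, peaks = [], []
    for i, m in enumerate(mirnas):
        pos = 100_000 * (i + 1)
        strand = "+" if i % 2 == 0 else "-"
        tss_list.append(TSSRecord(m.precursor_id, chrom, pos, strand, "mirna_tss"))
        if m.precursor_id in planted:
            offset = int(rng.integers(-w, w + 1))
            mid = pos + offset if strand == "+" else pos - offset
        else:
            mid = pos + int(2.5 * w)
        peaks.append(TFBSPeak(chrom, mid - 100, mid + 100, dataset="sim_chip"))
    return tss_list, peaks, frozenset(planted)


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, str]:
    """Write the bundle in the exact file dialects the pipeline readers consume.

    DE tables are written on the log2 scale (exact round-trip); the truth
    file records every planted master, proximal precursor and target pair.
    Also emits a small validated-interaction table covering a planted
    master's targets plus one TF-repressing miRNA row.
    """
    from pathlib import Path

    from . import io as mio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gene_table": outdir / "genes.tsv",
        "mirna_table": outdir / "mirnas.tsv",
        "site_table": outdir / "sites.tsv",
        "mirna_de": outdir / "mirna_de.tsv",
        "gene_de": outdir / "gene_de.tsv",
        "tss_table": outdir / "tss.tsv",
        "peaks": outdir / "peaks.bed",
        "validated": outdir / "validated.tsv",
        "truth": outdir / "truth.tsv",
    }
    mio.write_gene_table(bundle.catalog.genes, paths["gene_table"])
    mio.write_mirna_table(bundle.catalog.mirnas, paths["mirna_table"])
    mio.write_site_table(bundle.catalog.sites, paths["site_table"])
    mio.write_de_table(bundle.mirna_de, paths["mirna_de"], "log2")
    mio.write_de_table(bundle.gene_de, paths["gene_de"], "log2")
    mio.write_tss_table(bundle.tss, paths["tss_table"])
    mio.write_bed(bundle.peaks, paths["peaks"])

    validated: list[tuple[str, str, str]] = []
    for m in sorted(bundle.truth.true_masters):
        for _, g in sorted(t for t in bundle.truth.true_targets if t[0] == m)[:2]:
            validated.append((m, g, "reporter assay"))
    non_planted = [m.mature_id for m in bundle.catalog.mirnas
                   if m.mature_id not in bundle.truth.true_masters]
    if non_planted:
        validated.append((non_planted[0], bundle.config.tf_id, "qpcr"))
    mio.write_validated_table(validated, paths["validated"])

    with open(paths["truth"], "w") as fh:
        fh.write("kind\tid\tgene_id\n")
        for m in sorted(bundle.truth.true_masters):
            fh.write(f"master\t{m}\t\n")
        for p in sorted(bundle.truth.true_proximal):
            fh.write(f"proximal\t{p}\t\n")
        for m, g in sorted(bundle.truth.true_targets):
            fh.write(f"target\t{m}\t{g}\n")
    return {k: str(v) for k, v in paths.items()}


def generate_bundle(config: SyntheticConfig,
                    thresholds: Thresholds | None = None) -> SyntheticBundle:
    """Generate the complete, mutually consistent input bundle."""
    genes, mirnas = generate_universe(config)
    sites = generate_target_db(config, genes, mirnas)
    mirna_de, gene_de, truth = generate_de_tables(config, genes, mirnas, sites, thresholds)
    tss, peaks, proximal = generate_genomic_features(config, mirnas)
    truth = replace(truth, true_proximal=proximal)
    return SyntheticBundle(
        config=config,
        catalog=Catalog(tuple(genes), tuple(mirnas), tuple(sites)),
        mirna_de=tuple(mirna_de),
        gene_de=tuple(gene_de),
        tss=tuple(tss),
        peaks=tuple(peaks),
        truth=truth,
    )
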