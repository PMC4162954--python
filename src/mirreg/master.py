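"""Monte Carlo master-regulator enrichment test.

Identifies deregulated miRNAs that target significantly more of the
*inversely* deregulated genes than expected by chance: down-regulated miRNAs
are tested against the up-regulated gene group and vice versa. For each
miRNA, random gene sets of the same size as the deregulated group are drawn
from the universe of genes carrying at least one TargetScan site; the number
of sampled genes the miRNA targets (or a weighted 3'UTR site score) forms a
null distribution against which an empirical p-value with an add-one
pseudo-count is computed. The observed statistic is corrected for 3'UTR
length bias by the ratio of background to group mean UTR length, since site
counts grow with UTR length.

Per-miRNA random streams are derived from the master seed by stable hashing
of (cell line, mature id), so results are invariant to iteration order.
"""

from __future__ import annotations

import hashlib
import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .catalog import Catalog, GeneRecord, TargetSite, consensus_filter, conservation_match
from .expression import (
    DERecord,
    FeatureKind,
    Thresholds,
    benjamini_hochberg,
    harmonise_mirna_id,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SITE_TYPE_WEIGHTS",
    "COOPERATIVE_GAP_NT",
    "COOPERATIVE_BONUS",
    "NullDistribution",
    "MasterRegulatorResult",
    "weighted_utr_score",
    "sample_background",
    "null_distribution",
    "utr_length_normalise",
    "empirical_pvalue",
    "targetscan_universe",
    "identify_master_regulators",
]

# Seed-match efficacy weights follow the canonical ordering
# 8mer > 7mer-m8 > 7mer-A1 > 6mer; two sites whose start offsets lie 13-46 nt
# apart act cooperatively and earn a pairwise bonus.
SITE_TYPE_WEIGHTS: dict[str, float] = {
    "8mer": 1.0,
    "7mer_m8": 0.75,
    "7mer_A1": 0.5,
    "6mer": 0.25,
}
COOPERATIVE_GAP_NT: tuple[int, int] = (13, 46)
COOPERATIVE_BONUS: float = 0.2


@dataclass(frozen=True)
class NullDistribution:
    """Monte Carlo null for one miRNA's statistic over random gene sets."""

    mature_id: str
    statistic_kind: str  # "target_count" | "weighted_score"
    values: np.ndarray
    background_mean_utr: float

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise ValueError("null distribution must be non-empty")


@dataclass(frozen=True, slots=True)
class MasterRegulatorResult:
    """One miRNA's enrichment result against its inverse gene group."""

    cell_line: str
    mature_id: str
    direction: str  # "mirna_down_genes_up" | "mirna_up_genes_down"
    statistic_kind: str
    observed_raw: float
    observed_normalised: float
    group_mean_utr: float
    background_mean_utr: float
    empirical_p: float
    adjusted_p: float
    is_master: bool


def weighted_utr_score(sites_in_one_utr: Sequence[TargetSite]) -> float:
    """Weighted score of one miRNA's sites within one 3'UTR.

    Sum of per-site type weights plus a cooperative-spacing bonus for each
    consecutive pair (by offset) whose start-offset gap lies in the
    cooperativity window. All sites must share (mature_id, gene_id).
    """
    if not sites_in_one_utr:
        return 0.0
    keys = {(s.mature_id, s.gene_id) for s in sites_in_one_utr}
    if len(keys) > 1:
        raise ValueError(f"sites from multiple miRNA-gene pairs: {sorted(keys)}")
    offsets = sorted(s.utr_offset for s in sites_in_one_utr)
    score = sum(SITE_TYPE_WEIGHTS[s.site_type.value] for s in sites_in_one_utr)
    lo, hi = COOPERATIVE_GAP_NT
    for prev, nxt in zip(offsets, offsets[1:]):
        if lo <= nxt - prev <= hi:
            score += COOPERATIVE_BONUS
    return score


def sample_background(
    universe: Sequence[GeneRecord], n: int, rng_seed: int | np.random.Generator
) -> set[str]:
    """Uniform sample of ``n`` gene ids without replacement from the universe."""
    if n > len(universe):
        raise ValueError(f"cannot sample {n} genes from a universe of {len(universe)}")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    idx = rng.choice(len(universe), size=n, replace=False)
    return {universe[i].gene_id for i in idx}


def _subset_matrix(rng: np.random.Generator, b: int, n_universe: int, n: int) -> np.ndarray:
    """(b, n) index matrix of b uniform size-n subsets of range(n_universe)."""
    r = rng.random((b, n_universe))
    return np.argpartition(r, n - 1, axis=1)[:, :n]


def null_distribution(
    mature_id: str,
    target_values: Mapping[str, float],
    universe: Sequence[GeneRecord],
    n: int,
    iterations: int,
    rng_seed: int | np.random.Generator,
    statistic_kind: str = "target_count",
) -> NullDistribution:
    """Monte Carlo null of a miRNA's statistic over random size-``n`` gene sets.

    ``target_values`` maps targeted gene ids to their per-gene contribution
    (1.0 for ``target_count``; the weighted UTR score for ``weighted_score``);
    unlisted genes contribute 0. ``background_mean_utr`` is the mean 3'UTR
    length over all sampled genes pooled across iterations.
    """
    if n > len(universe):
        raise ValueError(f"cannot sample {n} genes from a universe of {len(universe)}")
    if n == 0:
        raise ValueError("background sample size must be positive")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    contrib = np.array([target_values.get(g.gene_id, 0.0) for g in universe])
    utr = np.array([float(g.utr_length) for g in universe])

    n_universe = len(universe)
    values = np.empty(iterations)
    utr_total = 0.0
    # chunk so the (rows x universe) random matrix stays ~32 MB
    chunk = max(1, (4 << 20) // max(1, n_universe))
    for start in range(0, iterations, chunk):
        b = min(chunk, iterations - start)
        idx = _subset_matrix(rng, b, n_universe, n)
        values[start:start + b] = contrib[idx].sum(axis=1)
        utr_total += float(utr[idx].sum())
    return NullDistribution(
        mature_id=mature_id,
        statistic_kind=statistic_kind,
        values=values,
        background_mean_utr=utr_total / (iterations * n),
    )


def utr_length_normalise(
    observed_raw: float, group_mean_utr: float, background_mean_utr: float
) -> float:
    """Correct the observed statistic for 3'UTR-length bias.

    Multiplies by background_mean_utr / group_mean_utr: a group of unusually
    long UTRs (which accumulates sites by length alone) is scaled down.
    """
    if group_mean_utr <= 0 or background_mean_utr <= 0:
        raise ValueError("mean UTR lengths must be positive")
    return observed_raw * (background_mean_utr / group_mean_utr)


def empirical_pvalue(observed_normalised: float, null: NullDistribution) -> float:
    """Exceedance p-value with add-one pseudo-count; never 0, floor 1/(B+1)."""
    b = len(null.values)
    exceed = int(np.count_nonzero(null.values >= observed_normalised))
    return (1 + exceed) / (b + 1)


def targetscan_universe(catalog: Catalog) -> list[GeneRecord]:
    """Background universe: genes with at least one TargetScan site, catalog order."""
    with_site = {s.gene_id for s in catalog.sites if s.in_targetscan}
    return [g for g in catalog.genes if g.gene_id in with_site]


def _child_rng(master_seed: int, cell_line: str, mature_key: str) -> np.random.Generator:
    digest = hashlib.sha256(f"{cell_line}\t{mature_key}".encode()).digest()
    spawn = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence(entropy=master_seed,
                                                        spawn_key=(spawn,)))


def identify_master_regulators(
    sig_mirnas: Sequence[DERecord],
    sig_genes: Sequence[DERecord],
    catalog: Catalog,
    thresholds: Thresholds,
    rng_seed: int,
    statistic: str = "target_count",
    normalise: str = "observed",
) -> list[MasterRegulatorResult]:
    """Test every significant miRNA for enrichment among inverse gene groups.

    For each cell line, down-regulated miRNAs are tested against the
    up-regulated gene group and up-regulated miRNAs against the
    down-regulated group, each against a Monte Carlo null of the same group
    size. Benjamini-Hochberg adjustment is applied within (cell line,
    direction); ``is_master`` marks adjusted p <= ``mr_alpha``.

    The UTR-length correction is applied to the observed statistic only
    (``normalise="observed"``, default); ``normalise="none"`` switches it off
    and leaves both sides raw.
    """
    if statistic not in ("target_count", "weighted_score"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if normalise not in ("observed", "none"):
        raise ValueError(f"unknown normalise mode {normalise!r}")

    matched_sites = conservation_match(list(catalog.sites), list(catalog.mirnas))
    consensus = consensus_filter(matched_sites, thresholds)
    universe = targetscan_universe(catalog)
    gene_lengths = catalog.gene_lengths()

    # per-miRNA consensus targets and (for the weighted statistic) per-gene scores
    targets_by_mirna: dict[str, set[str]] = defaultdict(set)
    for t in consensus:
        targets_by_mirna[harmonise_mirna_id(t.mature_id)].add(t.gene_id)
    sites_by_pair: dict[tuple[str, str], list[TargetSite]] = defaultdict(list)
    if statistic == "weighted_score":
        for s in matched_sites:
            sites_by_pair[(harmonise_mirna_id(s.mature_id), s.gene_id)].append(s)

    def per_gene_values(mkey: str) -> dict[str, float]:
        genes = targets_by_mirna.get(mkey, set())
        if statistic == "target_count":
            return {g: 1.0 for g in genes}
        return {g: weighted_utr_score(sites_by_pair[(mkey, g)]) for g in genes}

    mirnas_by_line: dict[str, list[DERecord]] = defaultdict(list)
    for rec in sig_mirnas:
        if rec.feature_kind is not FeatureKind.MIRNA:
            raise ValueError(f"{rec.feature_id}: expected miRNA record")
        mirnas_by_line[rec.cell_line].append(rec)
    genes_by_line: dict[str, list[DERecord]] = defaultdict(list)
    for rec in sig_genes:
        if rec.feature_kind is not FeatureKind.GENE:
            raise ValueError(f"{rec.feature_id}: expected gene record")
        genes_by_line[rec.cell_line].append(rec)

    results: list[MasterRegulatorResult] = []
    for cell_line in sorted(mirnas_by_line):
        groups: dict[str, list[str]] = {"up": [], "down": []}
        for rec in genes_by_line.get(cell_line, []):
            if rec.feature_id not in gene_lengths:
                logger.warning("%s: gene %s absent from catalog gene table; dropped",
                               cell_line, rec.feature_id)
                continue
            if rec.log2fc > 0:
                groups["up"].append(rec.feature_id)
            elif rec.log2fc < 0:
                groups["down"].append(rec.feature_id)

        for rec in sorted(mirnas_by_line[cell_line], key=lambda r: r.feature_id):
            if rec.log2fc < 0:
                direction, group = "mirna_down_genes_up", groups["up"]
            else:
                direction, group = "mirna_up_genes_down", groups["down"]
            if not group:
                logger.warning("%s/%s: empty inverse gene group; skipped",
                               cell_line, rec.feature_id)
                continue
            mkey = harmonise_mirna_id(rec.feature_id)
            values = per_gene_values(mkey)
            observed_raw = float(sum(values.get(g, 0.0) for g in group))
            group_mean_utr = float(np.mean([gene_lengths[g] for g in group]))
            rng = _child_rng(rng_seed, cell_line, mkey)
            null = null_distribution(
                rec.feature_id, values, universe, len(group),
                thresholds.mc_iterations, rng, statistic_kind=statistic,
            )
            if normalise == "observed":
                observed_norm = utr_length_normalise(
                    observed_raw, group_mean_utr, null.background_mean_utr
                )
            else:
                observed_norm = observed_raw
            p = empirical_pvalue(observed_norm, null)
            results.append(MasterRegulatorResult(
                cell_line=cell_line,
                mature_id=rec.feature_id,
                direction=direction,
                statistic_kind=statistic,
                observed_raw=observed_raw,
                observed_normalised=observed_norm,
                group_mean_utr=group_mean_utr,
                background_mean_utr=null.background_mean_utr,
                empirical_p=p,
                adjusted_p=p,  # replaced below
                is_master=False,
            ))

    # BH within (cell line, direction)
    final: list[MasterRegulatorResult] = []
    by_block: dict[tuple[str, str], list[MasterRegulatorResult]] = defaultdict(list)
    for r in results:
        by_block[(r.cell_line, r.direction)].append(r)
    for block in by_block.values():
        adjusted = benjamini_hochberg([r.empirical_p for r in block])
        for r, adj in zip(block, adjusted):
            final.append(MasterRegulatorResult(
                cell_line=r.cell_line, mature_id=r.mature_id, direction=r.direction,
                statistic_kind=r.statistic_kind, observed_raw=r.observed_raw,
                observed_normalised=r.observed_normalised,
                group_mean_utr=r.group_mean_utr,
                background_mean_utr=r.background_mean_utr,
                empirical_p=r.empirical_p, adjusted_p=float(adj),
                is_master=bool(adj <= thresholds.mr_alpha),
            ))
    final.sort(key=lambda r: (r.cell_line, r.direction, r.mature_id))
    return final
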