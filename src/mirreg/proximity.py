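"""TFBS-to-miRNA-promoter proximity mapping.

Compiles miRNA and host-gene transcription start sites (TSSs), intersects
ChIP-derived transcription-factor binding peaks with +/-window regions
around each TSS, and joins the hits with per-cell-line significant miRNAs.

Distances are signed in the direction of transcription: negative means the
peak lies upstream of the TSS. The peak anchor is its midpoint by default
(configurable to nearest-edge); coordinates are 0-based half-open
throughout.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .expression import DERecord, FeatureKind, Thresholds, harmonise_mirna_id, log2_to_signed_fold

logger = logging.getLogger(__name__)

__all__ = [
    "TSSRecord",
    "TFBSPeak",
    "ProximityHit",
    "compile_tss",
    "signed_distance",
    "find_proximal_tfbs",
    "intersect_with_de",
]

_STRANDS = ("+", "-")
_SOURCES = ("mirna_tss", "host_gene_tss")


@dataclass(frozen=True, slots=True)
class TSSRecord:
    """A transcription start site for a miRNA precursor or its host gene."""

    precursor_id: str
    chrom: str
    position: int  # 0-based
    strand: str
    source: str  # mirna_tss | host_gene_tss

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"{self.precursor_id}: negative TSS position")
        if self.strand not in _STRANDS:
            raise ValueError(f"{self.precursor_id}: invalid strand {self.strand!r}")
        if self.source not in _SOURCES:
            raise ValueError(f"{self.precursor_id}: invalid source {self.source!r}")


@dataclass(frozen=True, slots=True)
class TFBSPeak:
    """A transcription-factor binding interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    dataset: str = "peaks"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"peak {self.chrom}:{self.start}-{self.end}: start must be < end"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True, slots=True)
class ProximityHit:
    """One peak within the window of one precursor's TSS (miRNA or host gene)."""

    precursor_id: str
    peak: TFBSPeak
    tss: TSSRecord
    distance_to_tss: int  # signed, negative = upstream in transcription direction


def compile_tss(
    mirna_tss: Sequence[TSSRecord], host_tss: Sequence[TSSRecord]
) -> list[TSSRecord]:
    """Union of both TSS sources, deduplicated on (precursor, chrom, position, strand).

    The first occurrence's source tag is kept, so a TSS present in both
    sources retains the miRNA-TSS tag when that list comes first.
    """
    seen: set[tuple[str, str, int, str]] = set()
    out: list[TSSRecord] = []
    for rec in list(mirna_tss) + list(host_tss):
        key = (rec.precursor_id, rec.chrom, rec.position, rec.strand)
        if key not in seen:
            seen.add(key)
            out.append(rec)
    return out


def signed_distance(peak: TFBSPeak, tss: TSSRecord, anchor: str = "midpoint") -> int:
    """Signed distance from a TSS to a peak, in transcription direction.

    ``midpoint`` anchors the peak at floor((start+end)/2); ``nearest_edge``
    measures to the closest peak edge and returns 0 when the TSS lies inside
    the peak. On the minus strand the sign is mirrored.
    """
    if peak.chrom != tss.chrom:
        raise ValueError(
            f"peak on {peak.chrom} and TSS {tss.precursor_id} on {tss.chrom}"
        )
    if anchor == "midpoint":
        d = peak.midpoint - tss.position
    elif anchor == "nearest_edge":
        if peak.start <= tss.position < peak.end:
            d = 0
        elif tss.position < peak.start:
            d = peak.start - tss.position
        else:
            d = (peak.end - 1) - tss.position
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    return d if tss.strand == "+" else -d


def find_proximal_tfbs(
    tss_list: Sequence[TSSRecord],
    peaks: Sequence[TFBSPeak],
    thresholds: Thresholds,
    anchor: str = "midpoint",
) -> list[ProximityHit]:
    """All peaks within +/-``proximity_window_nt`` of any TSS, boundary inclusive.

    A precursor reachable through several of its TSSs (miRNA or host gene)
    is reported once per distinct peak, keeping the smallest-|distance| TSS.
    Output order is deterministic and independent of input permutations.
    """
    window = thresholds.proximity_window_nt
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for i, peak in enumerate(peaks):
        if anchor == "midpoint":
            trees[peak.chrom].addi(peak.midpoint, peak.midpoint + 1, i)
        else:
            trees[peak.chrom].addi(peak.start, peak.end, i)

    best: dict[tuple[str, int], ProximityHit] = {}
    for tss in tss_list:
        tree = trees.get(tss.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(tss.position - window, tss.position + window + 1):
            peak = peaks[iv.data]
            d = signed_distance(peak, tss, anchor=anchor)
            if abs(d) > window:
                continue
            key = (tss.precursor_id, iv.data)
            hit = ProximityHit(tss.precursor_id, peak, tss, d)
            prev = best.get(key)
            if prev is None or _hit_rank(hit) < _hit_rank(prev):
                best[key] = hit
    hits = list(best.values())
    hits.sort(key=lambda h: (h.precursor_id, h.peak.chrom, h.peak.start, h.distance_to_tss))
    return hits


def _hit_rank(hit: ProximityHit) -> tuple:
    # smallest |distance| wins; deterministic tie-break on source then position
    return (abs(hit.distance_to_tss), hit.tss.source != "mirna_tss", hit.tss.position)


def intersect_with_de(
    hits: Sequence[ProximityHit],
    sig_mirnas: Sequence[DERecord],
    mature_map: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Join proximity hits with significant mature miRNAs, per cell line.

    ``mature_map`` maps precursor ids to their mature ids. The result has one
    row per (cell_line, mature miRNA) that is significant and whose precursor
    has at least one hit, reporting the smallest-|distance| peak; sorted by
    cell line then fold change descending. Mature ids without a precursor
    mapping are logged and excluded.
    """
    precursors_of: dict[str, list[str]] = defaultdict(list)
    display_name: dict[str, str] = {}
    for precursor, matures in mature_map.items():
        for mature in matures:
            key = harmonise_mirna_id(mature)
            precursors_of[key].append(precursor)
            display_name.setdefault(key, mature)

    hits_by_precursor: dict[str, list[ProximityHit]] = defaultdict(list)
    for hit in hits:
        hits_by_precursor[hit.precursor_id].append(hit)

    rows = []
    for rec in sig_mirnas:
        if rec.feature_kind is not FeatureKind.MIRNA:
            raise ValueError(f"{rec.feature_id}: expected miRNA record")
        key = harmonise_mirna_id(rec.feature_id)
        precursors = precursors_of.get(key)
        if not precursors:
            logger.warning("%s: no precursor mapping; excluded", rec.feature_id)
            continue
        candidates = [h for p in precursors for h in hits_by_precursor.get(p, [])]
        if not candidates:
            continue
        nearest = min(candidates, key=_hit_rank)
        rows.append({
            "cell_line": rec.cell_line,
            "precursor_id": nearest.precursor_id,
            "mature_id": display_name[key],
            "fold_change": log2_to_signed_fold(rec.log2fc),
            "distance_to_tss": nearest.distance_to_tss,
        })
    frame = pd.DataFrame(
        rows,
        columns=["cell_line", "precursor_id", "mature_id", "fold_change", "distance_to_tss"],
    )
    return frame.sort_values(
        ["cell_line", "fold_change"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)
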