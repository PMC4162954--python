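"""miRNA target-prediction catalog: conservation matching and consensus filtering.

The catalog models a TargetScan-style universe of predicted 3'UTR binding
sites, annotated with the two co-predictor scores used for consensus
filtering (microT-CDS, and miRanda's mirSVR). A miRNA-gene pair survives the
consensus filter iff it has a TargetScan site and at least one co-predictor
agrees; pairs supported by all three tools form the high-confidence tier.

Conservation matching restricts broadly conserved miRNAs to conserved sites,
while mammal- and primate-specific miRNAs (e.g. the C19MC cluster) keep all
their sites — poorly conserved miRNAs may legitimately bind poorly conserved
sites.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .expression import Thresholds, harmonise_mirna_id

__all__ = [
    "ConservationClass",
    "SiteType",
    "SiteConservation",
    "GeneRecord",
    "MiRNARecord",
    "TargetSite",
    "ConsensusTarget",
    "Catalog",
    "UnknownMiRNAError",
    "conservation_match",
    "mirsvr_passes",
    "consensus_filter",
    "targets_of",
]


class ConservationClass(str, Enum):
    BROADLY_CONSERVED = "broadly_conserved"
    MAMMAL_CONSERVED = "mammal_conserved"
    PRIMATE_SPECIFIC = "primate_specific"


class SiteType(str, Enum):
    EIGHT_MER = "8mer"
    SEVEN_MER_M8 = "7mer_m8"
    SEVEN_MER_A1 = "7mer_A1"
    SIX_MER = "6mer"


class SiteConservation(str, Enum):
    CONSERVED = "conserved"
    NONCONSERVED = "nonconserved"


class UnknownMiRNAError(KeyError):
    """A site references a mature miRNA absent from the miRNA table."""


@dataclass(frozen=True, slots=True)
class GeneRecord:
    """A gene with its 3'UTR length in nucleotides (>= 1)."""

    gene_id: str
    utr_length: int

    def __post_init__(self) -> None:
        if self.utr_length < 1:
            raise ValueError(f"{self.gene_id}: utr_length must be >= 1")


@dataclass(frozen=True, slots=True)
class MiRNARecord:
    mature_id: str
    precursor_id: str
    conservation_class: ConservationClass


@dataclass(frozen=True, slots=True)
class TargetSite:
    """One predicted binding site of a miRNA in a gene's 3'UTR.

    ``utr_offset`` is 0-based from the UTR start; co-predictor scores are
    ``None`` when the tool makes no prediction for this site.
    """

    mature_id: str
    gene_id: str
    utr_offset: int
    site_type: SiteType
    site_conservation: SiteConservation
    in_targetscan: bool
    microt_score: float | None = None
    mirsvr_score: float | None = None

    def __post_init__(self) -> None:
        if self.utr_offset < 0:
            raise ValueError(f"{self.mature_id}/{self.gene_id}: negative utr_offset")


@dataclass(frozen=True, slots=True)
class ConsensusTarget:
    """A miRNA-gene pair surviving the three-tool consensus filter.

    ``high`` confidence: predicted by TargetScan plus both co-predictors;
    ``standard``: TargetScan plus exactly one of microT-CDS / miRanda.
    """

    mature_id: str
    gene_id: str
    confidence: str  # "high" | "standard"


@dataclass(frozen=True)
class Catalog:
    """A complete target-prediction catalog bundle."""

    genes: tuple[GeneRecord, ...]
    mirnas: tuple[MiRNARecord, ...]
    sites: tuple[TargetSite, ...]

    def __post_init__(self) -> None:
        seen = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r} in catalog")
            seen.add(g.gene_id)

    def gene_lengths(self) -> dict[str, int]:
        return {g.gene_id: g.utr_length for g in self.genes}


def conservation_match(
    sites: Sequence[TargetSite],
    mirnas: Sequence[MiRNARecord],
    *,
    restrict_specific_to_nonconserved: bool = False,
) -> list[TargetSite]:
    """Keep only sites whose conservation matches their miRNA's conservation class.

    Broadly conserved miRNAs keep conserved sites only. Mammal-conserved and
    primate-specific miRNAs keep all sites by default (the permissive reading
    of "equal conservation"); set ``restrict_specific_to_nonconserved`` to
    instead limit them to nonconserved sites. Idempotent; never adds sites.
    """
    classes = {harmonise_mirna_id(m.mature_id): m.conservation_class for m in mirnas}
    out = []
    for site in sites:
        key = harmonise_mirna_id(site.mature_id)
        if key not in classes:
            raise UnknownMiRNAError(
                f"site references unknown mature miRNA {site.mature_id!r}"
            )
        cls = classes[key]
        if cls is ConservationClass.BROADLY_CONSERVED:
            if site.site_conservation is SiteConservation.CONSERVED:
                out.append(site)
        elif restrict_specific_to_nonconserved:
            if site.site_conservation is SiteConservation.NONCONSERVED:
                out.append(site)
        else:
            out.append(site)
    return out


def mirsvr_passes(score: float | None, thresholds: Thresholds) -> bool:
    """Whether a mirSVR score meets the co-predictor criterion.

    Published mirSVR scores are negative for good targets, but thresholds are
    conventionally printed as positive magnitudes; the default ``magnitude``
    mode accepts either sign convention (|score| >= cut-off).
    """
    if score is None:
        return False
    m = thresholds.mirsvr_min_magnitude
    mode = thresholds.mirsvr_sign
    if mode == "magnitude":
        return abs(score) >= m
    if mode == "le_negative":
        return score <= -m
    return score >= m  # ge_positive


def consensus_filter(
    sites: Sequence[TargetSite], thresholds: Thresholds
) -> list[ConsensusTarget]:
    """Collapse sites to miRNA-gene pairs surviving the three-tool consensus.

    A pair is retained iff some site is in TargetScan AND (some site has
    microT-CDS >= ``microt_min`` OR some site meets the mirSVR criterion).
    Confidence is ``high`` when both co-predictor criteria hold. Absent
    scores never predict. Output is sorted by (mature_id, gene_id).
    """
    groups: dict[tuple[str, str], list[TargetSite]] = defaultdict(list)
    for site in sites:
        groups[(site.mature_id, site.gene_id)].append(site)

    out = []
    for (mature_id, gene_id), group in groups.items():
        has_ts = any(s.in_targetscan for s in group)
        has_microt = any(
            s.microt_score is not None and s.microt_score >= thresholds.microt_min
            for s in group
        )
        has_mirsvr = any(mirsvr_passes(s.mirsvr_score, thresholds) for s in group)
        if has_ts and (has_microt or has_mirsvr):
            confidence = "high" if (has_microt and has_mirsvr) else "standard"
            out.append(ConsensusTarget(mature_id, gene_id, confidence))
    out.sort(key=lambda t: (t.mature_id, t.gene_id))
    return out


def targets_of(
    mature_id: str,
    consensus: Iterable[ConsensusTarget],
    gene_universe: frozenset[str] | set[str],
) -> set[str]:
    """Consensus target genes of one miRNA, restricted to a gene universe."""
    key = harmonise_mirna_id(mature_id)
    return {
        t.gene_id
        for t in consensus
        if harmonise_mirna_id(t.mature_id) == key and t.gene_id in gene_universe
    }
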