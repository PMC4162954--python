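"""Assembly and summarisation of the TF -> miRNA -> gene regulatory network.

Edges come in three flavours: ``tf_mirna`` (the knocked-down transcription
factor binds near a deregulated miRNA's promoter), ``mirna_gene`` (a
master-regulator miRNA has a consensus target that is inversely
deregulated), and ``tf_gene``. miRNA->gene edges always repress; the sign of
a TF->miRNA edge is inferred from the knockdown response (a miRNA that drops
when the TF is silenced was being activated by it).

Summary counting supports merged miRNA groups that share one published
target list (e.g. the four C19MC miR-518 members), so interaction totals
match group-level counting.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .catalog import ConsensusTarget
from .expression import DERecord, FeatureKind, harmonise_mirna_id
from .master import MasterRegulatorResult
from .proximity import ProximityHit

__all__ = [
    "NetworkEdge",
    "InteractionSummary",
    "assemble_network",
    "summarise_interactions",
    "annotate_validated",
    "classify_feedback_loops",
    "STRONG_EVIDENCE",
]

# evidence classes counted as strong experimental validation
STRONG_EVIDENCE = frozenset({"reporter assay", "western blot", "qpcr"})


@dataclass(frozen=True, slots=True)
class NetworkEdge:
    source_id: str
    target_id: str
    edge_type: str  # tf_mirna | mirna_gene | tf_gene
    sign: str  # activating | repressing | unknown
    confidence: str = "standard"  # high | standard
    validated: bool = False

    def __post_init__(self) -> None:
        if self.edge_type not in ("tf_mirna", "mirna_gene", "tf_gene"):
            raise ValueError(f"unknown edge_type {self.edge_type!r}")
        if self.sign not in ("activating", "repressing", "unknown"):
            raise ValueError(f"unknown sign {self.sign!r}")
        if self.edge_type == "mirna_gene" and self.sign != "repressing":
            raise ValueError("mirna_gene edges always repress")
        if self.source_id == self.target_id:
            raise ValueError(f"self-edge on {self.source_id!r}")


@dataclass(frozen=True, slots=True)
class InteractionSummary:
    n_interactions: int
    n_unique_genes: int
    n_high_conf_interactions: int
    n_high_conf_genes: int
    n_genes_multi_high: int  # genes with >= 2 high-confidence interactions


def assemble_network(
    mr_results: Sequence[MasterRegulatorResult],
    consensus_targets: Sequence[ConsensusTarget],
    proximity_hits: Sequence[ProximityHit],
    sig_mirnas: Sequence[DERecord],
    sig_genes: Sequence[DERecord],
    mature_map: Mapping[str, Sequence[str]],
    tf_id: str = "SOX2",
) -> list[NetworkEdge]:
    """Build the deduplicated edge list from the upstream module outputs.

    TF->miRNA edges: every significant miRNA whose precursor carries a
    proximal TF peak; activating if the miRNA fell after TF knockdown,
    repressing if it rose, ``unknown`` when cell lines disagree.
    miRNA->gene edges: every consensus target of a flagged master regulator
    whose gene is inversely deregulated in the same cell line.
    """
    precursors_of: dict[str, set[str]] = defaultdict(set)
    display: dict[str, str] = {}
    for precursor, matures in mature_map.items():
        for mature in matures:
            key = harmonise_mirna_id(mature)
            precursors_of[key].add(precursor)
            display.setdefault(key, mature)

    hit_precursors = {h.precursor_id for h in proximity_hits}

    # TF -> miRNA: collect response signs per mature miRNA across cell lines
    response_signs: dict[str, set[str]] = defaultdict(set)
    for rec in sig_mirnas:
        key = harmonise_mirna_id(rec.feature_id)
        display.setdefault(key, rec.feature_id)
        if precursors_of.get(key, set()) & hit_precursors:
            response_signs[key].add("activating" if rec.log2fc < 0 else "repressing")

    edges: dict[tuple[str, str, str], NetworkEdge] = {}
    for key, signs in response_signs.items():
        sign = signs.pop() if len(signs) == 1 else "unknown"
        mature = display[key]
        if mature == tf_id:
            continue
        edges[(tf_id, mature, "tf_mirna")] = NetworkEdge(
            source_id=tf_id, target_id=mature, edge_type="tf_mirna", sign=sign
        )

    # miRNA -> gene: master regulators against inversely deregulated targets
    masters: dict[tuple[str, str], MasterRegulatorResult] = {
        (r.cell_line, harmonise_mirna_id(r.mature_id)): r
        for r in mr_results if r.is_master
    }
    mirna_sign: dict[tuple[str, str], int] = {}
    for rec in sig_mirnas:
        mirna_sign[(rec.cell_line, harmonise_mirna_id(rec.feature_id))] = (
            1 if rec.log2fc > 0 else -1
        )
    gene_sign: dict[tuple[str, str], int] = {}
    for rec in sig_genes:
        if rec.feature_kind is not FeatureKind.GENE:
            raise ValueError(f"{rec.feature_id}: expected gene record")
        gene_sign[(rec.cell_line, rec.feature_id)] = 1 if rec.log2fc > 0 else -1

    targets_by_mirna: dict[str, list[ConsensusTarget]] = defaultdict(list)
    for t in consensus_targets:
        targets_by_mirna[harmonise_mirna_id(t.mature_id)].append(t)

    for (cell_line, mkey), result in masters.items():
        msign = mirna_sign.get((cell_line, mkey))
        if msign is None:
            continue
        for target in targets_by_mirna.get(mkey, []):
            gsign = gene_sign.get((cell_line, target.gene_id))
            if gsign is None or gsign == msign:
                continue  # only inversely deregulated targets
            mature = display.get(mkey, result.mature_id)
            if mature == target.gene_id:
                continue
            key = (mature, target.gene_id, "mirna_gene")
            prev = edges.get(key)
            confidence = target.confidence
            if prev is not None and prev.confidence == "high":
                confidence = "high"
            edges[key] = NetworkEdge(
                source_id=mature, target_id=target.gene_id,
                edge_type="mirna_gene", sign="repressing", confidence=confidence,
            )
    out = list(edges.values())
    out.sort(key=lambda e: (e.edge_type, e.source_id, e.target_id))
    return out


def summarise_interactions(
    edges: Iterable[NetworkEdge],
    grouping: Mapping[str, str] | None = None,
) -> InteractionSummary:
    """Count distinct (miRNA group, gene) interactions over mirna_gene edges.

    ``grouping`` maps mature ids to a shared group label for miRNAs published
    with one merged target list; unmapped miRNAs form their own group. Genes
    are deduplicated by symbol; high-confidence counts are restricted to
    ``confidence == "high"``.
    """
    grouping = grouping or {}
    norm_grouping = {harmonise_mirna_id(k): v for k, v in grouping.items()}

    pairs: set[tuple[str, str]] = set()
    high_pairs: set[tuple[str, str]] = set()
    for edge in edges:
        if edge.edge_type != "mirna_gene":
            continue
        key = harmonise_mirna_id(edge.source_id)
        group = norm_grouping.get(key, key)
        pairs.add((group, edge.target_id))
        if edge.confidence == "high":
            high_pairs.add((group, edge.target_id))

    genes = {g for _, g in pairs}
    high_genes = {g for _, g in high_pairs}
    high_count_per_gene: dict[str, int] = defaultdict(int)
    for _, g in high_pairs:
        high_count_per_gene[g] += 1
    return InteractionSummary(
        n_interactions=len(pairs),
        n_unique_genes=len(genes),
        n_high_conf_interactions=len(high_pairs),
        n_high_conf_genes=len(high_genes),
        n_genes_multi_high=sum(1 for c in high_count_per_gene.values() if c >= 2),
    )


def annotate_validated(
    edges: Sequence[NetworkEdge],
    validated_table: Iterable[tuple[str, str, str]],
    strong_evidence: frozenset[str] = STRONG_EVIDENCE,
) -> list[NetworkEdge]:
    """Set the validated flag on edges matched by a strong-evidence interaction.

    ``validated_table`` rows are (mirna, gene, evidence); only evidence
    classes in ``strong_evidence`` (case-insensitive) count. The edge list
    length and order are unchanged.
    """
    strong = {e.lower() for e in strong_evidence}
    validated_pairs = {
        (harmonise_mirna_id(mirna), gene)
        for mirna, gene, evidence in validated_table
        if evidence.strip().lower() in strong
    }
    out = []
    for edge in edges:
        flag = (harmonise_mirna_id(edge.source_id), edge.target_id) in validated_pairs
        out.append(replace(edge, validated=flag) if flag != edge.validated else edge)
    return out


def classify_feedback_loops(
    sig_mirnas: Sequence[DERecord],
    validated_tf_repressors: Iterable[str],
) -> list[tuple[str, str]]:
    """Classify autoregulatory loops between the TF and miRNAs that repress it.

    A TF-repressing miRNA that falls after TF knockdown implies the TF
    activates its own repressor (negative loop); one that rises implies the
    TF represses its repressor (positive loop). miRNAs absent from the
    significant set are excluded.
    """
    repressors = {harmonise_mirna_id(m) for m in validated_tf_repressors}
    out = []
    for rec in sig_mirnas:
        key = harmonise_mirna_id(rec.feature_id)
        if key not in repressors:
            continue
        loop = "negative" if rec.log2fc < 0 else "positive"
        out.append((rec.feature_id, loop))
    return out
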