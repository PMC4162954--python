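"""Differential-expression filtering and cross-cell-line concordance.

Ingests per-cell-line differential-expression (DE) tables for miRNAs and
genes, applies the inclusion thresholds used throughout the pipeline
(miRNA: p <= 0.05; gene: >= 2-fold, p <= 0.01, FDR <= 0.05, all boundaries
inclusive), and classifies which features respond the same way in two cell
lines after knocking down the transcription factor.

Fold changes are handled in two dialects: *signed linear* (the convention of
qRT-PCR array software, where -3.63 means 3.63-fold down) and log2. The
internal representation is always log2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FeatureKind",
    "DERecord",
    "Thresholds",
    "ConcordanceReport",
    "FoldChangeDialectError",
    "KindMismatchError",
    "MissingFDRError",
    "DuplicateFeatureError",
    "signed_fold_to_log2",
    "log2_to_signed_fold",
    "relative_quantification",
    "benjamini_hochberg",
    "harmonise_mirna_id",
    "filter_mirna_de",
    "filter_gene_de",
    "classify_cross_cell_line",
]


class FeatureKind(str, Enum):
    MIRNA = "mirna"
    GENE = "gene"


class FoldChangeDialectError(ValueError):
    """Signed-linear fold change outside its legal domain (|x| >= 1)."""


class KindMismatchError(ValueError):
    """A record of the wrong feature kind was passed to a filter."""


class MissingFDRError(ValueError):
    """A gene record lacks the FDR value required by the gene filter."""


class DuplicateFeatureError(ValueError):
    """The same (harmonised) feature id occurs twice in one significant list."""


@dataclass(frozen=True, slots=True)
class DERecord:
    """One feature's differential-expression result in one cell line.

    ``log2fc`` is the log2 fold change of knockdown versus control; ``fdr``
    may be ``None`` for miRNA records (the miRNA filter uses raw p only).
    """

    feature_id: str
    feature_kind: FeatureKind
    cell_line: str
    log2fc: float
    p_value: float
    fdr: float | None = None

    def __post_init__(self) -> None:
        if not self.feature_id:
            raise ValueError("feature_id must be non-empty")
        if not math.isfinite(self.log2fc):
            raise ValueError(f"{self.feature_id}: log2fc must be finite")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"{self.feature_id}: p_value {self.p_value!r} outside [0, 1]")
        if self.fdr is not None and not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"{self.feature_id}: fdr {self.fdr!r} outside [0, 1]")


@dataclass(frozen=True, slots=True)
class Thresholds:
    """All tunable cut-offs of the pipeline, boundaries inclusive.

    Defaults are the published analysis settings: miRNA p <= 0.05; gene
    >= 2-fold with p <= 0.01 and FDR <= 0.05; +/-5 kb promoter windows;
    microT-CDS >= 0.4 and mirSVR magnitude >= 0.1 for the consensus filter;
    10,000 Monte Carlo iterations; master-regulator alpha 0.05.
    """

    mirna_p_max: float = 0.05
    gene_p_max: float = 0.01
    gene_fdr_max: float = 0.05
    gene_min_fold: float = 2.0  # linear scale
    proximity_window_nt: int = 5000
    microt_min: float = 0.4
    mirsvr_min_magnitude: float = 0.1
    mirsvr_sign: str = "magnitude"  # magnitude | le_negative | ge_positive
    mc_iterations: int = 10000
    mr_alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("mirna_p_max", "gene_p_max", "gene_fdr_max", "mr_alpha"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be a probability in (0, 1], got {v!r}")
        for name in ("gene_min_fold", "proximity_window_nt", "microt_min",
                     "mirsvr_min_magnitude", "mc_iterations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mirsvr_sign not in ("magnitude", "le_negative", "ge_positive"):
            raise ValueError(f"unknown mirsvr_sign mode {self.mirsvr_sign!r}")


def signed_fold_to_log2(signed_fold: float, *, label: str | None = None) -> float:
    """Convert a signed linear fold change to log2.

    Positive x maps to log2(x); negative x (meaning |x|-fold down) maps to
    -log2(|x|). Values with |x| < 1 (including zero) are illegal in this
    dialect and raise :class:`FoldChangeDialectError`.
    """
    where = f" (row {label})" if label is not None else ""
    if not math.isfinite(signed_fold):
        raise FoldChangeDialectError(f"non-finite signed fold change{where}")
    if abs(signed_fold) < 1.0:
        raise FoldChangeDialectError(
            f"signed-linear fold change must satisfy |x| >= 1, got {signed_fold!r}{where}"
        )
    if signed_fold > 0:
        return math.log2(signed_fold)
    return -math.log2(-signed_fold)


def log2_to_signed_fold(log2fc: float) -> float:
    """Inverse of :func:`signed_fold_to_log2` (round-trips exactly up to FP error)."""
    if not math.isfinite(log2fc):
        raise FoldChangeDialectError("non-finite log2 fold change")
    if log2fc >= 0:
        return 2.0 ** log2fc
    return -(2.0 ** (-log2fc))


def relative_quantification(delta_delta_ct: float) -> float:
    """Relative expression versus control by the 2^-ddCt method.

    Returns the fraction of control expression remaining; strictly positive
    and monotone decreasing in the ddCt input.
    """
    if not math.isfinite(delta_delta_ct):
        raise ValueError("delta_delta_ct must be finite")
    return 2.0 ** (-delta_delta_ct)


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        return []
    if np.any((ps < 0) | (ps > 1)) or not np.all(np.isfinite(ps)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(ps, method="fdr_bh")[1].tolist()


def harmonise_mirna_id(name: str) -> str:
    """Canonical matching key for a mature miRNA name.

    Case-insensitive, strips a leading ``hsa-`` prefix, preserves the star
    strand (trailing ``*``) and ``-3p``/``-5p`` suffixes verbatim. No fuzzy
    matching: ``hsa-miR-148a`` and ``mir-148a`` harmonise equal, nothing else
    is collapsed.
    """
    key = name.strip().lower()
    if key.startswith("hsa-"):
        key = key[4:]
    return key


def filter_mirna_de(records: Sequence[DERecord], thresholds: Thresholds) -> list[DERecord]:
    """Retain miRNA records with p <= ``mirna_p_max`` (inclusive), order preserved."""
    for rec in records:
        if rec.feature_kind is not FeatureKind.MIRNA:
            raise KindMismatchError(
                f"{rec.feature_id}: expected miRNA record, got {rec.feature_kind.value}"
            )
    return [rec for rec in records if rec.p_value <= thresholds.mirna_p_max]


def filter_gene_de(records: Sequence[DERecord], thresholds: Thresholds) -> list[DERecord]:
    """Retain genes >= ``gene_min_fold``-fold deregulated with p and FDR below cut-off.

    All three boundaries are inclusive. Raises :class:`MissingFDRError` if any
    record lacks an FDR value.
    """
    min_log2 = math.log2(thresholds.gene_min_fold)
    kept = []
    for rec in records:
        if rec.feature_kind is not FeatureKind.GENE:
            raise KindMismatchError(
                f"{rec.feature_id}: expected gene record, got {rec.feature_kind.value}"
            )
        if rec.fdr is None:
            raise MissingFDRError(f"{rec.feature_id}: gene record without FDR value")
        if (abs(rec.log2fc) >= min_log2
                and rec.p_value <= thresholds.gene_p_max
                and rec.fdr <= thresholds.gene_fdr_max):
            kept.append(rec)
    return kept


@dataclass(frozen=True)
class ConcordanceReport:
    """Partition of two significant sets by cross-cell-line behaviour.

    The four sets are pairwise disjoint and their union is the union of both
    input id sets (ids harmonised via :func:`harmonise_mirna_id` for miRNAs).
    """

    exclusive_a: frozenset[str]
    exclusive_b: frozenset[str]
    mutual_same_direction: frozenset[str]
    opposite_direction: frozenset[str]

    def __post_init__(self) -> None:
        sets = [self.exclusive_a, self.exclusive_b,
                self.mutual_same_direction, self.opposite_direction]
        total = sum(len(s) for s in sets)
        if len(frozenset().union(*sets)) != total:
            raise ValueError("concordance categories must be pairwise disjoint")

    @property
    def shared(self) -> frozenset[str]:
        return self.mutual_same_direction | self.opposite_direction

    def rows(self) -> list[tuple[str, str]]:
        """Long-format (feature_id, category) rows, sorted for stable output."""
        out: list[tuple[str, str]] = []
        for category, ids in (
            ("exclusive_a", self.exclusive_a),
            ("exclusive_b", self.exclusive_b),
            ("mutual_same_direction", self.mutual_same_direction),
            ("opposite_direction", self.opposite_direction),
        ):
            out.extend((fid, category) for fid in sorted(ids))
        return out


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def classify_cross_cell_line(
    sig_a: Sequence[DERecord], sig_b: Sequence[DERecord]
) -> ConcordanceReport:
    """Classify two significant lists into exclusive / concordant / opposite sets.

    Direction uses the sign of log2fc only; magnitude is ignored. miRNA ids
    are harmonised before matching. Duplicate ids within one list raise
    :class:`DuplicateFeatureError`.
    """

    def index(records: Sequence[DERecord], which: str) -> dict[str, DERecord]:
        out: dict[str, DERecord] = {}
        for rec in records:
            key = (harmonise_mirna_id(rec.feature_id)
                   if rec.feature_kind is FeatureKind.MIRNA else rec.feature_id)
            if key in out:
                raise DuplicateFeatureError(
                    f"duplicate feature {rec.feature_id!r} in list {which}"
                )
            out[key] = rec
        return out

    a, b = index(sig_a, "a"), index(sig_b, "b")
    shared = a.keys() & b.keys()
    same = frozenset(k for k in shared if _sign(a[k].log2fc) == _sign(b[k].log2fc))
    return ConcordanceReport(
        exclusive_a=frozenset(a.keys() - shared),
        exclusive_b=frozenset(b.keys() - shared),
        mutual_same_direction=same,
        opposite_direction=frozenset(shared) - same,
    )
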