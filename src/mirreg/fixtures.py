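"""Curated example datasets from the SOX2-knockdown embryonal-carcinoma study.

Small, text-only bundles used by tests and the ``mirreg fixtures``
subcommand:

* the consensus miRNA-target interaction table for the 2102Ep and NTera-2
  cell lines, with confidence tiers (``high`` = all three prediction tools,
  ``standard`` = TargetScan plus one co-predictor) and validated-target
  flags, including the four C19MC miR-518 members that share one target
  list;
* a promoter-proximity bundle (TSS table, TF ChIP peaks on a synthetic
  coordinate frame realising the published peak-to-TSS distances, the
  significant-miRNA table and the precursor-to-mature map);
* a validated-interaction table (strong-evidence rows plus the three
  miRNAs known to repress SOX2, used for feedback-loop classification);
* a two-cell-line concordance example.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .expression import DERecord, FeatureKind, signed_fold_to_log2
from .io import read_bed, read_de_table, read_tss_table, read_validated_table
from .proximity import TFBSPeak, TSSRecord

__all__ = [
    "load_consensus_interactions",
    "mir518_grouping",
    "load_proximity_bundle",
    "load_validated_interactions",
    "concordance_example",
    "write_fixture_bundle",
]

MIR518_GROUP = "miR-518a-3p/b/c/f"


def _data(name: str):
    return resources.files("mirreg.data").joinpath(name)


def load_consensus_interactions() -> pd.DataFrame:
    """The published per-cell-line miRNA-target interaction table."""
    with resources.as_file(_data("ecc_consensus_targets.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def mir518_grouping() -> dict[str, str]:
    """Merged-row grouping: the four C19MC miR-518 members share one target list."""
    return {m: MIR518_GROUP
            for m in ("miR-518a-3p", "miR-518b", "miR-518c", "miR-518f")}


def load_proximity_bundle() -> tuple[
    list[TSSRecord], list[TFBSPeak], list[DERecord], dict[str, list[str]]
]:
    """TSS records, ChIP peaks, significant miRNAs and the precursor->mature map.

    Coordinates live on a synthetic chromosome chosen so that each peak's
    midpoint realises the published signed distance to its precursor's TSS;
    the distances, fold changes and identifiers are the published values.
    """
    with resources.as_file(_data("ecc_tfbs_tss.tsv")) as path:
        tss = read_tss_table(path)
    with resources.as_file(_data("ecc_tfbs_peaks.bed")) as path:
        peaks = read_bed(path)
    with resources.as_file(_data("ecc_proximal_mirna_de.tsv")) as path:
        de = read_de_table(path, fold_scale="signed-linear")
    with resources.as_file(_data("ecc_mature_map.tsv")) as path:
        frame = pd.read_csv(path, sep="\t")
    mature_map: dict[str, list[str]] = {}
    for row in frame.itertuples(index=False):
        mature_map.setdefault(row.precursor_id, []).append(row.mature_id)
    return tss, peaks, de, mature_map


def load_validated_interactions() -> list[tuple[str, str, str]]:
    with resources.as_file(_data("ecc_validated_targets.tsv")) as path:
        return read_validated_table(path)


# The 18 miRNAs significant in both cell lines, with their response
# directions: 14 deregulated the same way in 2102Ep and NTera-2 (of which
# miR-135b*, miR-138, miR-375 and miR-522 exceeded 2-fold in both) and four
# oppositely (miR-181a-2* strongly up in 2102Ep, down in NTera-2).
# Fold magnitudes not published for both lines are representative values
# consistent with the published direction and >2-fold annotations.
_SHARED_SAME = [
    ("mir-1180", -1.40, -1.30),
    ("miR-125b", -1.60, -1.50),
    ("miR-135b*", -3.04, -2.33),
    ("miR-138", -2.40, -2.20),
    ("miR-19a", -1.50, -1.35),
    ("miR-221", -1.70, -1.40),
    ("miR-31", -1.80, -1.30),
    ("miR-31*", -1.50, -1.20),
    ("miR-372", -1.30, -1.40),
    ("miR-375", -2.90, -2.50),
    ("miR-378", -1.40, -1.60),
    ("miR-455-3p", -1.30, -1.20),
    ("miR-517c", -2.10, -1.90),
    ("miR-522", -2.50, -2.20),
]
_SHARED_OPPOSITE = [
    ("miR-1197", 1.50, -1.40),
    ("miR-181a-2*", 3.05, -4.47),
    ("miR-184", -1.60, 1.30),
    ("miR-218", 1.40, -1.50),
]


def concordance_example() -> tuple[list[DERecord], list[DERecord]]:
    """Significant miRNA lists for both cell lines (99 and 62 miRNAs).

    The 18 shared miRNAs carry the published identities and directions; the
    per-cell-line exclusive entries (81 and 44) are synthetic placeholder
    ids, present only so each list has the published size — concordance
    classification depends on the shared set alone.
    """

    def rec(name: str, line: str, fold: float) -> DERecord:
        return DERecord(name, FeatureKind.MIRNA, line,
                        signed_fold_to_log2(fold), 0.01)

    list_a = [rec(n, "2102Ep", fa) for n, fa, _ in _SHARED_SAME + _SHARED_OPPOSITE]
    list_b = [rec(n, "NTera-2", fb) for n, _, fb in _SHARED_SAME + _SHARED_OPPOSITE]
    list_a += [rec(f"miR-syn2102-{i:02d}", "2102Ep", -1.5) for i in range(99 - 18)]
    list_b += [rec(f"miR-synNT-{i:02d}", "NTera-2", -1.5) for i in range(62 - 18)]
    return list_a, list_b


def write_fixture_bundle(outdir: str | Path) -> list[Path]:
    """Copy every packaged example file into ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("ecc_consensus_targets.tsv", "ecc_tfbs_tss.tsv",
                 "ecc_tfbs_peaks.bed", "ecc_proximal_mirna_de.tsv",
                 "ecc_mature_map.tsv", "ecc_validated_targets.tsv"):
        target = outdir / name
        target.write_text(_data(name).read_text())
        written.append(target)
    return written
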