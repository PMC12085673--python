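"""Strand-aware genomic neighborhood analysis of miRNA loci.

For every significantly age-correlated miRNA, count other significant
miRNAs within a +/-10 kb window around its locus, split by strand
equality — a check of whether age correlation clusters along the genome
(which would point at transcription-level rather than miRNA-level
regulation). Coordinates are 1-based inclusive (GFF3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import gffutils
import numpy as np
import pandas as pd

__all__ = [
    "MiRNALocus", "load_annotation", "neighborhood_counts",
    "reference_average", "cumulative_coordinates",
]


@dataclass(frozen=True)
class MiRNALocus:
    feature_id: str
    chromosome: str
    start: int          # 1-based inclusive
    end: int
    strand: str         # '+' or '-'

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.feature_id}: start {self.start} > end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"{self.feature_id}: undefined strand")


def load_annotation(source: str, expressed=None,
                    featuretype=("miRNA", "miRNA_primary_transcript")
                    ) -> list[MiRNALocus]:
    """Parse a GFF3 file (path or text) into miRNA loci.

    One locus per feature id (first record wins; multi-locus ids are
    noted in a warning). If ``expressed`` is given, features present in
    the expression data but absent from the annotation are reported in a
    coverage warning.
    """
    from_string = "\n" in source
    db = gffutils.create_db(source, dbfn=":memory:", from_string=from_string,
                            force=True, keep_order=True,
                            merge_strategy="create_unique")
    loci: dict[str, MiRNALocus] = {}
    multi = []
    for ft in featuretype:
        for rec in db.features_of_type(ft):
            name = (rec.attributes.get("Name") or
                    rec.attributes.get("ID") or [rec.id])[0]
            if name in loci:
                multi.append(name)
                continue
            loci[name] = MiRNALocus(name, rec.seqid, rec.start, rec.end,
                                    rec.strand)
    if multi:
        warnings.warn(f"{len(set(multi))} feature(s) with multiple loci; "
                      "first record used")
    if expressed is not None:
        missing = sorted(set(expressed) - set(loci))
        if missing:
            warnings.warn(f"{len(missing)} expressed feature(s) missing "
                          f"from annotation, e.g. {missing[:3]}")
    return list(loci.values())


def _neighbor_tuples(loci: list[MiRNALocus], anchors: list[MiRNALocus],
                     neighbors: list[MiRNALocus],
                     window: int) -> pd.DataFrame:
    rows = []
    for a in anchors:
        lo, hi = a.start - window, a.end + window
        same = opp = 0
        for b in neighbors:
            if b is a or b.feature_id == a.feature_id:
                continue
            if b.chromosome != a.chromosome:
                continue
            if b.end >= lo and b.start <= hi:     # closed-interval overlap
                if b.strand == a.strand:
                    same += 1
                else:
                    opp += 1
        rows.append({"feature": a.feature_id, "n_same_strand": same,
                     "n_opposite_strand": opp})
    return pd.DataFrame(rows, columns=["feature", "n_same_strand",
                                       "n_opposite_strand"])


def neighborhood_counts(loci: list[MiRNALocus], significant: set[str],
                        window: int = 10_000
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per significant anchor, counts of other significant miRNAs whose
    locus overlaps the +/-``window`` range, split by strand; plus the
    global (same, opposite) tuple-occurrence table."""
    unknown = significant - {l.feature_id for l in loci}
    if unknown:
        raise ValueError(f"significant features missing from annotation: "
                         f"{sorted(unknown)[:5]}")
    sig = [l for l in loci if l.feature_id in significant]
    per_anchor = _neighbor_tuples(loci, sig, sig, window)
    tuples = (per_anchor.groupby(["n_same_strand", "n_opposite_strand"])
              .size().rename("occurrences").reset_index())
    return per_anchor, tuples


def reference_average(loci: list[MiRNALocus], window: int = 10_000
                      ) -> tuple[float, float]:
    """Mean (same-strand, opposite-strand) neighbor counts over all
    annotated loci (anchors excluded from their own counts)."""
    if not loci:
        raise ValueError("no loci")
    t = _neighbor_tuples(loci, loci, loci, window)
    return (float(t["n_same_strand"].mean()),
            float(t["n_opposite_strand"].mean()))


def cumulative_coordinates(loci: list[MiRNALocus],
                           chromosome_lengths: dict[str, int]) -> pd.Series:
    """Absolute genome offset per feature: sum of preceding chromosome
    lengths (declared dict order) plus the locus start."""
    offsets = {}
    running = 0
    for chrom, length in chromosome_lengths.items():
        offsets[chrom] = running
        running += length
    out = {}
    for l in loci:
        if l.chromosome not in offsets:
            raise ValueError(f"undeclared chromosome: {l.chromosome!r}")
        if l.end > chromosome_lengths[l.chromosome]:
            raise ValueError(f"{l.feature_id} beyond declared length of "
                             f"{l.chromosome!r}")
        out[l.feature_id] = offsets[l.chromosome] + l.start
    return pd.Series(out, name="cumulative_coordinate")
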