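"""Positional classification of lncRNAs relative to the nearest coding gene.

Every lncRNA receives exactly one of four classes — overlapping,
promoter_associated, terminal_associated, distal — with a concurrent /
opposite orientation where a partner gene exists. The decision tree, in
precedence order:

1. *overlapping*: the lncRNA genomic span shares >= 1 bp with a coding gene
   span (partner = largest overlap, ties by gene id).
2. *promoter_associated*: the lncRNA TSS lies within (inner, outer] bp
   upstream of a coding TSS, measured along the coding gene's strand axis
   (partner = smallest |distance|). A promoter_associated + opposite call is
   a promoter-associated antisense RNA (paancRNA).
3. *terminal_associated*: the lncRNA TSS lies within (inner, outer] bp
   downstream of a coding TES.
4. *distal*: no coding gene span within ``distal_min_gap_bp`` of the lncRNA
   span (or no gene on the chromosome).
5. Proximity fallback for the residual geometry (gene nearby but outside both
   windows): assign promoter or terminal by which side of the nearest gene's
   axis the lncRNA TSS falls on, so classification is total and deterministic.

Signed distances are negative upstream of the anchor (partner TSS or TES).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_model import TranscriptModel
from .utils import round_half_up

log = logging.getLogger(__name__)

CLASSES = ("distal", "overlapping", "terminal_associated", "promoter_associated")


@dataclass(frozen=True)
class ClassWindows:
    """Window geometry for the positional classes (bp)."""

    distal_min_gap_bp: int = 5000
    promoter_window_bp: tuple[int, int] = (0, 5000)   # (inner, outer] upstream of TSS
    terminal_window_bp: tuple[int, int] = (0, 5000)   # (inner, outer] downstream of TES

    def __post_init__(self) -> None:
        for inner, outer in (self.promoter_window_bp, self.terminal_window_bp):
            if not (0 <= inner < outer):
                raise ValueError("window requires 0 <= inner < outer")
        if self.distal_min_gap_bp <= 0:
            raise ValueError("distal_min_gap_bp must be positive")


@dataclass(frozen=True)
class LncClassAssignment:
    lnc_id: str
    klass: str                       # one of CLASSES
    orientation: str                 # {"concurrent", "opposite", "not_applicable"}
    partner_gene_id: str | None
    signed_distance_bp: int | None   # None only for distal
    anchor: str                      # {"partner_TSS", "partner_TES", "none"}

    @property
    def is_paancrna(self) -> bool:
        return self.klass == "promoter_associated" and self.orientation == "opposite"


class GeneIndex:
    """Per-chromosome vectorised index over coding gene spans supporting
    overlap and nearest-gene queries."""

    def __init__(self, coding: Iterable[TranscriptModel]) -> None:
        genes = sorted(coding, key=lambda t: t.transcript_id)
        if not genes:
            raise ValueError("coding gene set is empty")
        self._chrom: dict[str, dict[str, np.ndarray]] = {}
        by_chrom: dict[str, list[TranscriptModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in by_chrom.items():
            self._chrom[chrom] = {
                "ids": np.array([g.transcript_id for g in gs]),
                "start": np.array([g.start for g in gs], dtype=np.int64),
                "end": np.array([g.end for g in gs], dtype=np.int64),
                "tss": np.array([g.tss for g in gs], dtype=np.int64),
                "tes": np.array([g.tes for g in gs], dtype=np.int64),
                "plus": np.array([g.strand == "+" for g in gs]),
            }

    def chroms(self) -> list[str]:
        return sorted(self._chrom)

    def arrays(self, chrom: str) -> dict[str, np.ndarray] | None:
        return self._chrom.get(chrom)

    def nearest(self, chrom: str, start: int, end: int) -> tuple[str, int] | None:
        """Nearest gene to a query span by span gap (0 when overlapping);
        ties by smaller gene id. None when the chromosome is absent."""
        arr = self._chrom.get(chrom)
        if arr is None:
            return None
        gap = np.maximum(0, np.maximum(arr["start"] - end, start - arr["end"]))
        i = _argmin_with_id_tiebreak(gap, arr["ids"])
        return str(arr["ids"][i]), int(gap[i])


def _argmin_with_id_tiebreak(values: np.ndarray, ids: np.ndarray) -> int:
    best = values.min()
    cand = np.flatnonzero(values == best)
    return int(cand[np.argmin(ids[cand])])


def build_gene_index(coding: Iterable[TranscriptModel]) -> GeneIndex:
    return GeneIndex(coding)


def classify_lncrna(
    lnc: TranscriptModel,
    index: GeneIndex,
    windows: ClassWindows = ClassWindows(),
) -> LncClassAssignment:
    """Assign one lncRNA its positional class (see module docstring)."""
    arr = index.arrays(lnc.chrom)
    if arr is None:
        log.warning("%s: chromosome %s absent from gene index; distal",
                    lnc.transcript_id, lnc.chrom)
        return LncClassAssignment(lnc.transcript_id, "distal", "not_applicable",
                                  None, None, "none")

    ids, start, end = arr["ids"], arr["start"], arr["end"]
    plus = arr["plus"]
    l_start, l_end, l_tss = lnc.start, lnc.end, lnc.tss

    def orientation(i: int) -> str:
        return "concurrent" if plus[i] == (lnc.strand == "+") else "opposite"

    # 1. overlap of genomic spans
    ov = np.minimum(end, l_end) - np.maximum(start, l_start)
    if (ov > 0).any():
        masked = np.where(ov > 0, ov, -1)
        i = int(np.flatnonzero(masked == masked.max())[
            np.argmin(ids[masked == masked.max()])])
        return LncClassAssignment(lnc.transcript_id, "overlapping", orientation(i),
                                  str(ids[i]), 0, "none")

    # signed position of the lncRNA TSS on each gene's strand axis
    d_prom = np.where(plus, l_tss - arr["tss"], arr["tss"] - l_tss)
    d_term = np.where(plus, l_tss - arr["tes"], arr["tes"] - l_tss)

    # 2. promoter window: (inner, outer] upstream -> d in [-outer, -inner)
    p_in, p_out = windows.promoter_window_bp
    pq = (d_prom >= -p_out) & (d_prom < -p_in)
    if pq.any():
        absd = np.where(pq, np.abs(d_prom), np.iinfo(np.int64).max)
        i = _argmin_with_id_tiebreak(absd, ids)
        return LncClassAssignment(lnc.transcript_id, "promoter_associated",
                                  orientation(i), str(ids[i]),
                                  int(d_prom[i]), "partner_TSS")

    # 3. terminal window: (inner, outer] downstream -> d in (inner, outer]
    t_in, t_out = windows.terminal_window_bp
    tq = (d_term > t_in) & (d_term <= t_out)
    if tq.any():
        absd = np.where(tq, np.abs(d_term), np.iinfo(np.int64).max)
        i = _argmin_with_id_tiebreak(absd, ids)
        return LncClassAssignment(lnc.transcript_id, "terminal_associated",
                                  orientation(i), str(ids[i]),
                                  int(d_term[i]), "partner_TES")

    # 4. distal: no gene span within the gap threshold of the lncRNA span
    gap = np.maximum(0, np.maximum(start - l_end, l_start - end))
    i = _argmin_with_id_tiebreak(gap, ids)
    if gap[i] > windows.distal_min_gap_bp:
        return LncClassAssignment(lnc.transcript_id, "distal", "not_applicable",
                                  None, None, "none")

    # 5. proximity fallback relative to the nearest gene
    if d_prom[i] < 0:
        return LncClassAssignment(lnc.transcript_id, "promoter_associated",
                                  orientation(i), str(ids[i]),
                                  int(d_prom[i]), "partner_TSS")
    return LncClassAssignment(lnc.transcript_id, "terminal_associated",
                              orientation(i), str(ids[i]),
                              int(d_term[i]), "partner_TES")


def classify_many(
    lncs: Iterable[TranscriptModel],
    index: GeneIndex,
    windows: ClassWindows = ClassWindows(),
) -> list[LncClassAssignment]:
    return [classify_lncrna(l, index, windows) for l in lncs]


def class_table(
    assignments: Sequence[LncClassAssignment],
    directions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-class x orientation counts, optionally joined with DE directions
    to give the percent up-regulated per cell (1-decimal half-up; NaN for
    empty cells)."""
    rows = []
    for klass in CLASSES:
        orientations = (["not_applicable"] if klass == "distal"
                        else ["concurrent", "opposite"])
        for orient in orientations:
            members = [a for a in assignments
                       if a.klass == klass and a.orientation == orient]
            n = len(members)
            if directions is not None and n:
                n_up = sum(directions.get(a.lnc_id) == "up" for a in members)
                pct_up = round_half_up(100.0 * n_up / n, 1)
            else:
                pct_up = float("nan")
            rows.append({"class": klass, "orientation": orient,
                         "n": n, "pct_up": pct_up})
    return pd.DataFrame(rows).set_index(["class", "orientation"])


def assignments_frame(assignments: Sequence[LncClassAssignment]) -> pd.DataFrame:
    """TSV-ready table (lnc_id, class, orientation, partner, distance, anchor)."""
    return pd.DataFrame(
        [
            {
                "lnc_id": a.lnc_id,
                "class": a.klass,
                "orientation": a.orientation,
                "partner_gene_id": a.partner_gene_id if a.partner_gene_id else "NA",
                "signed_distance_bp": a.signed_distance_bp
                if a.signed_distance_bp is not None else "NA",
                "anchor": a.anchor,
            }
            for a in assignments
        ]
    )
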