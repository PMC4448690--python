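"""PolII coverage statistics: traveling ratio and strand-aware metaprofiles.

The traveling ratio (pausing/stalling index) of a gene is the mean per-bp
PolII density over a fixed promoter window, default TSS-30 .. TSS+300
(strand-oriented), divided by the mean density over the remaining gene body
(TSS+301 .. TES). High values indicate promoter-proximal pausing.

Metaprofiles average coverage (as reads per million, RPM) in fixed-width
bins across a set of anchors, with minus-strand anchors mirrored so that
positive offsets always point downstream of the anchor.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_model import TranscriptModel

log = logging.getLogger(__name__)


@dataclass
class CoverageTrack:
    """Dense per-bp read density per chromosome plus the track depth."""

    values: dict[str, np.ndarray]
    total_mapped_reads: float

    def __post_init__(self) -> None:
        for chrom, arr in self.values.items():
            if (arr < 0).any():
                raise ValueError(f"{chrom}: negative coverage")
        if self.total_mapped_reads <= 0:
            raise ValueError("total_mapped_reads must be positive")

    @classmethod
    def from_bedgraph(
        cls,
        path: str | Path,
        chrom_lengths: Mapping[str, int],
        total_mapped_reads: float | None = None,
    ) -> "CoverageTrack":
        df = pd.read_csv(
            path, sep="\t", comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64,
                   "value": np.float64},
        )
        values = {c: np.zeros(n, dtype=np.float64) for c, n in chrom_lengths.items()}
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in values:
                raise ValueError(f"bedGraph chromosome {chrom!r} not in chrom_lengths")
            arr = values[chrom]
            if (sub["end"] > arr.size).any():
                raise ValueError(f"{chrom}: bedGraph interval beyond chromosome end")
            for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
                arr[s:e] = v
        if total_mapped_reads is None:
            total_mapped_reads = float(sum(a.sum() for a in values.values())) or 1.0
        return cls(values=values, total_mapped_reads=total_mapped_reads)

    def to_bedgraph(self, path: str | Path) -> None:
        """Run-length-encoded bedGraph; zero runs are omitted."""
        with open(path, "w") as fh:
            for chrom in sorted(self.values):
                arr = self.values[chrom]
                if arr.size == 0:
                    continue
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [arr.size]))
                for s, e in zip(starts, ends):
                    v = arr[s]
                    if v != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


@dataclass(frozen=True)
class TravelingRatioRecord:
    gene_id: str
    promoter_density: float
    body_density: float
    tr: float  # NaN when the body density is zero


@dataclass
class MetaProfile:
    bin_edges: np.ndarray       # offsets relative to anchor, len n_bins + 1
    mean_rpm: np.ndarray
    mean_coverage: np.ndarray   # same profile before RPM normalisation
    n_anchors: int
    n_clipped: int = 0

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center": self.bin_centers,
                             "mean_rpm": self.mean_rpm})


def compute_traveling_ratio(
    gene: TranscriptModel,
    track: CoverageTrack,
    promoter_window: tuple[int, int] = (-30, 300),
    min_gene_length: int | None = None,
) -> TravelingRatioRecord | None:
    """Traveling ratio for one gene; None when the gene is too short,
    NaN ratio when the body has zero coverage."""
    w0, w1 = promoter_window
    span_len = gene.span.length
    if span_len <= w1 + 1 or (min_gene_length is not None and span_len < min_gene_length):
        log.info("%s: too short for traveling ratio (%d bp)", gene.transcript_id, span_len)
        return None
    arr = track.values.get(gene.chrom)
    if arr is None:
        raise KeyError(f"chromosome {gene.chrom} absent from coverage track")

    if gene.strand == "+":
        tss = gene.tss
        prom = arr[max(0, tss + w0): tss + w1 + 1]
        body = arr[tss + w1 + 1: gene.end]
    else:
        # mirror: offset o of TSS maps to genomic position tss - 1 - o
        tss = gene.tss
        prom = arr[max(0, tss - 1 - w1): min(arr.size, tss - w0)]
        body = arr[gene.start: max(0, tss - 1 - w1)]

    prom_density = float(prom.mean()) if prom.size else float("nan")
    body_density = float(body.mean()) if body.size else float("nan")
    tr = prom_density / body_density if body_density > 0 else float("nan")
    if not body_density > 0:
        log.info("%s: zero body coverage, TR undefined", gene.transcript_id)
    return TravelingRatioRecord(gene.transcript_id, prom_density, body_density, tr)


def traveling_ratios(
    genes: Iterable[TranscriptModel],
    track: CoverageTrack,
    promoter_window: tuple[int, int] = (-30, 300),
    min_gene_length: int | None = None,
) -> pd.DataFrame:
    records = []
    for g in genes:
        rec = compute_traveling_ratio(g, track, promoter_window, min_gene_length)
        if rec is not None:
            records.append(rec)
    return pd.DataFrame(
        [(r.gene_id, r.promoter_density, r.body_density, r.tr) for r in records],
        columns=["gene_id", "promoter_density", "body_density", "tr"],
    ).set_index("gene_id")


def compute_metaprofile(
    anchors: Sequence[tuple[str, int, str]],
    track: CoverageTrack,
    window_bp: int = 3000,
    bin_width: int = 50,
) -> MetaProfile:
    """Average coverage profile around (chrom, position, strand) anchors.

    Windows are symmetric, [-window_bp, +window_bp); minus-strand windows
    are reversed before averaging. Windows extending beyond chromosome
    bounds are clipped (NaN-padded) and counted.
    """
    if not anchors:
        raise ValueError("anchor set is empty")
    if (2 * window_bp) % bin_width:
        raise ValueError("bin_width must divide the window size")
    n_bins = 2 * window_bp // bin_width
    rows = np.full((len(anchors), 2 * window_bp), np.nan)
    n_clipped = 0
    for k, (chrom, pos, strand) in enumerate(anchors):
        arr = track.values.get(chrom)
        if arr is None:
            raise KeyError(f"chromosome {chrom} absent from coverage track")
        lo, hi = pos - window_bp, pos + window_bp
        clo, chi = max(0, lo), min(arr.size, hi)
        if clo > lo or chi < hi:
            n_clipped += 1
        rows[k, clo - lo: chi - lo] = arr[clo:chi]
        if strand == "-":
            rows[k] = rows[k, ::-1]
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        binned = np.nanmean(rows.reshape(len(anchors), n_bins, bin_width), axis=2)
        mean_cov = np.nanmean(binned, axis=0)
    edges = np.arange(-window_bp, window_bp + 1, bin_width)
    return MetaProfile(
        bin_edges=edges,
        mean_rpm=mean_cov * 1e6 / track.total_mapped_reads,
        mean_coverage=mean_cov,
        n_anchors=len(anchors),
        n_clipped=n_clipped,
    )


def stalling_index_shift(tr_a: pd.DataFrame, tr_b: pd.DataFrame) -> dict:
    """Paired summary of traveling ratios from two conditions sharing gene ids
    (e.g. untreated vs 30 min of stress): medians, per-gene deltas/ratios and
    a two-sided rank-sum p-value."""
    shared = tr_a.index.intersection(tr_b.index)
    a = tr_a.loc[shared, "tr"].astype(float)
    b = tr_b.loc[shared, "tr"].astype(float)
    ok = a.notna() & b.notna()
    a, b = a[ok], b[ok]
    if len(a) == 0:
        raise ValueError("no shared genes with defined traveling ratios")
    delta = b - a
    ratio = b / a
    p = float(stats.mannwhitneyu(b, a, alternative="two-sided").pvalue)
    return {
        "n": int(len(a)),
        "median_tr_a": float(a.median()),
        "median_tr_b": float(b.median()),
        "median_delta": float(delta.median()),
        "median_ratio": float(ratio.median()),
        "rank_sum_p": p,
    }
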