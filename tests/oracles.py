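"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorised/indexed code paths:
plain loops, explicit tie-breaks, literal rule transcriptions.
"""
from __future__ import annotations

import numpy as np

from stresslnc.annotation_model import TranscriptModel
from stresslnc.lnc_classifier import ClassWindows


def oracle_classify(lnc: TranscriptModel, genes: list[TranscriptModel],
                    windows: ClassWindows = ClassWindows()):
    """Exhaustive loop-based positional classifier.

    Returns (class, orientation, partner_id, signed_distance) following the
    published decision tree: overlap > promoter window > terminal window >
    distal, with a proximity fallback, nearest-partner selection and
    smaller-gene-id tie-breaks.
    """
    same_chrom = [g for g in genes if g.chrom == lnc.chrom]
    if not same_chrom:
        return ("distal", "not_applicable", None, None)

    def orient(g):
        return "concurrent" if g.strand == lnc.strand else "opposite"

    # 1. overlap (largest overlap, ties by id)
    best = None
    for g in sorted(same_chrom, key=lambda g: g.transcript_id):
        ov = min(g.end, lnc.end) - max(g.start, lnc.start)
        if ov > 0 and (best is None or ov > best[0]):
            best = (ov, g)
    if best is not None:
        g = best[1]
        return ("overlapping", orient(g), g.transcript_id, 0)

    def d_prom(g):
        return lnc.tss - g.tss if g.strand == "+" else g.tss - lnc.tss

    def d_term(g):
        return lnc.tss - g.tes if g.strand == "+" else g.tes - lnc.tss

    # 2. promoter window (smallest |distance|, ties by id)
    p_in, p_out = windows.promoter_window_bp
    best = None
    for g in sorted(same_chrom, key=lambda g: g.transcript_id):
        d = d_prom(g)
        if -p_out <= d < -p_in and (best is None or abs(d) < abs(best[0])):
            best = (d, g)
    if best is not None:
        return ("promoter_associated", orient(best[1]),
                best[1].transcript_id, best[0])

    # 3. terminal window
    t_in, t_out = windows.terminal_window_bp
    best = None
    for g in sorted(same_chrom, key=lambda g: g.transcript_id):
        d = d_term(g)
        if t_in < d <= t_out and (best is None or abs(d) < abs(best[0])):
            best = (d, g)
    if best is not None:
        return ("terminal_associated", orient(best[1]),
                best[1].transcript_id, best[0])

    # 4/5. distal gap test, else proximity fallback
    nearest = None
    for g in sorted(same_chrom, key=lambda g: g.transcript_id):
        gap = max(0, max(g.start - lnc.end, lnc.start - g.end))
        if nearest is None or gap < nearest[0]:
            nearest = (gap, g)
    gap, g = nearest
    if gap > windows.distal_min_gap_bp:
        return ("distal", "not_applicable", None, None)
    if d_prom(g) < 0:
        return ("promoter_associated", orient(g), g.transcript_id, d_prom(g))
    return ("terminal_associated", orient(g), g.transcript_id, d_term(g))


def d_rule_oracle(rn: float, rl: float, rh: float, d_cut: float = 1.0):
    """Literal transcription of the translational-shift rule for one probe."""
    d1 = abs(rn - rl)
    d2 = abs(rl - rh)
    d3 = abs(rn - rh)
    regulated = d1 >= d_cut or d2 >= d_cut or d3 >= d_cut
    trend = None
    if regulated:
        if rh >= rl and rh >= rn:
            trend = "High_pool"
        elif rl >= rn:
            trend = "Low_pool"
        else:
            trend = "None_pool"
    return d1, d2, d3, regulated, trend


def random_layout(rng: np.random.Generator, n_genes: int = 3, n_lncs: int = 6,
                  chrom_len: int = 100_000):
    """A random gene/lncRNA arrangement for oracle-equivalence checks."""
    from stresslnc.annotation_model import GenomicInterval

    genes, lncs = [], []
    for i in range(n_genes):
        length = int(rng.integers(2000, 10_000))
        start = int(rng.integers(0, chrom_len - length))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(TranscriptModel(
            f"g{i:03d}", (GenomicInterval("chr1", start, start + length, strand),),
            biotype="coding"))
    for i in range(n_lncs):
        length = int(rng.integers(300, 2000))
        start = int(rng.integers(0, chrom_len - length))
        strand = "+" if rng.random() < 0.5 else "-"
        lncs.append(TranscriptModel(
            f"l{i:03d}", (GenomicInterval("chr1", start, start + length, strand),),
            biotype="noncoding"))
    return genes, lncs
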