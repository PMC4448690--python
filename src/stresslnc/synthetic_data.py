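"""Synthetic study generator with planted ground truth.

Emulates the study design end to end on one synthetic chromosome: coding
genes plus lncRNAs of each positional class (promoter-associated lncRNA
TSSs drawn from the 0.5-1.5 kb upstream peak region), negative-binomial
count matrices in which most coding genes go down while a per-class
fraction of lncRNAs goes up, promoter-proximal PolII pileups whose 30-min
pausing gain raises the traveling ratio, and 3-pool polysome intensity
matrices in which lncRNAs shift into and mRNAs out of polysome pools.

Every generator is a pure function of (config, seed); emitted files
re-parse through the package's own readers, and planted classes are
verified against the classifier at generation time.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation_model import GenomicInterval, TranscriptModel, write_annotation
from .lnc_classifier import ClassWindows, GeneIndex, classify_lncrna

CHROM = "chrS"

DEFAULT_LNC_PER_CLASS = {
    "distal": 25,
    "overlapping": 25,
    "terminal_associated": 25,
    "promoter_associated": 25,
}

# per-class up-regulated fractions mirroring the observed class table
DEFAULT_FRACTION_UP = {
    "distal": 0.651,
    "overlapping": 0.659,
    "terminal_associated": 0.707,
    "promoter_associated": 0.759,
}

# planted transcriptional-class proportions (polysome arrays) per biotype
DEFAULT_ARRAY_CLASS_PROPORTIONS = {
    "coding": {"high": 0.1, "low": 0.5, "no_change": 0.4},
    "noncoding": {"high": 0.5, "low": 0.1, "no_change": 0.4},
}
# planted trend proportions among translationally regulated probes
DEFAULT_ARRAY_TREND_PROPORTIONS = {
    "coding": {"None_pool": 0.8, "Low_pool": 0.15, "High_pool": 0.05},
    "noncoding": {"High_pool": 0.8, "Low_pool": 0.15, "None_pool": 0.05},
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    seed: int
    # --- annotation geometry ---
    n_coding_genes: int = 100
    lnc_per_class: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LNC_PER_CLASS))
    opposite_fraction: float = 0.5        # of lncRNAs with a partner gene
    chrom_length: int | None = None       # None: sized to fit the layout
    gene_spacing_bp: int = 30000          # minimum inter-gene gap
    ieg_length_range: tuple[int, int] = (1000, 3000)    # up-regulated coding genes
    ieg_exon_range: tuple[int, int] = (1, 3)
    gene_length_range: tuple[int, int] = (6000, 15000)  # down-regulated coding genes
    gene_exon_range: tuple[int, int] = (4, 12)
    lnc_length_range: tuple[int, int] = (300, 2000)
    promoter_offset_range: tuple[int, int] = (500, 1500)  # lnc TSS upstream of TSS
    terminal_offset_range: tuple[int, int] = (500, 1500)
    multi_exon_lnc_fraction: float = 0.1
    # --- counts ---
    fraction_up: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTION_UP))
    coding_down_fraction: float = 0.7
    intron_up_fraction: float = 0.3
    up_fold: float = 3.0
    down_fold: float = 1 / 3
    intron_up_fold: float = 2.0
    nb_dispersion: float = 0.1
    depth: int = 10_000_000       # total mapped reads per library
    base_count_log_mean: float = math.log(200.0)
    base_count_log_sd: float = 0.5
    # --- PolII coverage ---
    pausing_gain: float = 3.0
    body_level: float = 5.0
    peak_amplitude: float = 12.0   # paused-PolII peak just downstream of the TSS
    peak_offset: int = 100
    peak_sigma: float = 150.0
    lobe_amplitude: float = 0.6    # divergent lobes ~1 kb either side of the TSS
    lobe_offset: int = 1000
    lobe_sigma: float = 300.0
    pausing_zone_bp: tuple[int, int] = (-1200, 300)  # gain applies here (TSS axis)
    # --- polysome arrays ---
    n_array_coding: int = 300
    n_array_noncoding: int = 300
    array_replicates: int = 3
    noise_sd: float = 0.1
    d_spread: float = 2.0          # planted max pairwise fraction-contrast spread
    rt_effect: float = math.log2(3.0)
    rt_no_change: float = 0.4      # |log2| Total effect planted inside the 1.5x band
    regulated_fraction: float = 0.6
    array_class_proportions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_ARRAY_CLASS_PROPORTIONS.items()})
    array_trend_proportions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_ARRAY_TREND_PROPORTIONS.items()})

    def __post_init__(self) -> None:
        for name, frac in {**dict(self.fraction_up),
                           "coding_down": self.coding_down_fraction,
                           "intron_up": self.intron_up_fraction,
                           "opposite": self.opposite_fraction}.items():
            if not 0 <= frac <= 1:
                raise ValueError(f"fraction {name}={frac} outside [0, 1]")
        if any(n < 0 for n in self.lnc_per_class.values()):
            raise ValueError("lncRNA counts must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SyntheticAnnotation:
    coding: list[TranscriptModel]
    lncs: list[TranscriptModel]
    truth: pd.DataFrame          # per-lnc class/orientation/partner; per-gene direction
    coding_truth: pd.DataFrame   # gene_id -> planted DE direction
    chrom_length: int

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {CHROM: self.chrom_length}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_annotation(self.coding, outdir / "coding.gtf")
        write_annotation(self.lncs, outdir / "lnc.bed12", fmt="bed12")
        self.truth.to_csv(outdir / "lnc_truth.tsv", sep="\t")
        self.coding_truth.to_csv(outdir / "coding_truth.tsv", sep="\t")


def _split_exons(rng: np.random.Generator, chrom: str, start: int, end: int,
                 strand: str, n_exons: int) -> tuple[GenomicInterval, ...]:
    """Partition [start, end) into n_exons exons separated by introns,
    keeping first/last segments exonic so the span is preserved."""
    length = end - start
    if n_exons == 1:
        return (GenomicInterval(chrom, start, end, strand),)
    n_seg = 2 * n_exons - 1
    min_seg = max(2, length // (4 * n_seg))
    cuts = np.sort(rng.choice(length - n_seg * min_seg, size=n_seg - 1,
                              replace=False)) if length - n_seg * min_seg >= n_seg else None
    if cuts is None:
        return (GenomicInterval(chrom, start, end, strand),)
    seg_lens = np.diff(np.concatenate(([0], cuts, [length - n_seg * min_seg]))) + min_seg
    exons = []
    pos = start
    for i, seg in enumerate(seg_lens):
        if i % 2 == 0:
            exons.append(GenomicInterval(chrom, pos, pos + int(seg), strand))
        pos += int(seg)
    return tuple(exons)


def _make_lnc_exons(rng: np.random.Generator, cfg: SimulationConfig, start: int,
                    end: int, strand: str) -> tuple[GenomicInterval, ...]:
    if end - start >= 400 and rng.random() < cfg.multi_exon_lnc_fraction:
        return _split_exons(rng, CHROM, start, end, strand, 2)
    return (GenomicInterval(CHROM, start, end, strand),)


def generate_annotation(cfg: SimulationConfig, verify: bool = True) -> SyntheticAnnotation:
    """Place coding genes and lncRNAs of every positional class on one
    synthetic chromosome; returns models plus the planted truth table."""
    rng = np.random.default_rng(cfg.seed)
    per_class = dict(DEFAULT_LNC_PER_CLASS) | dict(cfg.lnc_per_class)
    n_partnered = sum(n for k, n in per_class.items() if k != "distal")
    n_genes = max(cfg.n_coding_genes, n_partnered)

    # planted coding DE direction decides the gene structure (short, exon-poor
    # immediate-early-like genes go up; long multi-exon genes go down)
    n_down = round(cfg.coding_down_fraction * n_genes)
    directions = np.array(["down"] * n_down + ["up"] * (n_genes - n_down))
    rng.shuffle(directions)

    coding: list[TranscriptModel] = []
    cursor = 50_000
    for i, direction in enumerate(directions):
        if direction == "up":
            length = int(rng.integers(*cfg.ieg_length_range, endpoint=True))
            n_ex = int(rng.integers(*cfg.ieg_exon_range, endpoint=True))
        else:
            length = int(rng.integers(*cfg.gene_length_range, endpoint=True))
            n_ex = int(rng.integers(*cfg.gene_exon_range, endpoint=True))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene{i:05d}"
        exons = _split_exons(rng, CHROM, cursor, cursor + length, strand, n_ex)
        coding.append(TranscriptModel(gid, exons, biotype="coding", source="RefSeq"))
        cursor += length + cfg.gene_spacing_bp + int(rng.integers(0, 5000))

    # assign partner genes without reuse so planted windows cannot collide
    gene_order = rng.permutation(n_genes)
    gi = 0
    lncs: list[TranscriptModel] = []
    truth_rows = []

    def add_lnc(lid: str, start: int, end: int, strand: str, klass: str,
                orientation: str, partner: str | None) -> None:
        exons = _make_lnc_exons(rng, cfg, start, end, strand)
        lncs.append(TranscriptModel(lid, exons, biotype="noncoding", source="de-novo"))
        truth_rows.append({"lnc_id": lid, "class": klass,
                           "orientation": orientation,
                           "partner_gene_id": partner or "NA"})

    lnc_counter = 0
    for klass in ("overlapping", "promoter_associated", "terminal_associated"):
        for _ in range(per_class.get(klass, 0)):
            g = coding[gene_order[gi]]
            gi += 1
            opposite = rng.random() < cfg.opposite_fraction
            strand = g.strand if not opposite else ("-" if g.strand == "+" else "+")
            orientation = "opposite" if opposite else "concurrent"
            lid = f"lnc{lnc_counter:05d}"
            lnc_counter += 1
            lo, hi = cfg.lnc_length_range
            if klass == "overlapping":
                max_len = min(hi, g.span.length - 100)
                length = int(rng.integers(max(201, min(lo, max_len - 1)), max_len,
                                          endpoint=True))
                start = g.start + int(rng.integers(0, g.span.length - length))
                add_lnc(lid, start, start + length, strand, klass, orientation, g.transcript_id)
                continue

            off_lo, off_hi = (cfg.promoter_offset_range
                              if klass == "promoter_associated"
                              else cfg.terminal_offset_range)
            offset = int(rng.integers(off_lo, off_hi, endpoint=True))
            anchor = g.tss if klass == "promoter_associated" else g.tes
            axis = 1 if g.strand == "+" else -1
            # genomic position of the lncRNA TSS
            if klass == "promoter_associated":
                tss = anchor - axis * offset
            else:
                tss = anchor + axis * offset
            # does the lncRNA extend toward or away from the gene body?
            toward = (strand == g.strand) == (klass == "promoter_associated")
            if toward:
                max_len = min(hi, offset - 50)
                length = int(rng.integers(201, max(202, max_len), endpoint=True))
            else:
                length = int(rng.integers(max(lo, 201), hi, endpoint=True))
            if strand == "+":
                start, end = tss, tss + length
            else:
                start, end = tss - length, tss
            add_lnc(lid, start, end, strand, klass, orientation, g.transcript_id)

    # distal lncRNAs in a dedicated zone clear of every gene window
    distal_cursor = cursor + 20_000
    for _ in range(per_class.get("distal", 0)):
        lid = f"lnc{lnc_counter:05d}"
        lnc_counter += 1
        length = int(rng.integers(max(cfg.lnc_length_range[0], 201),
                                  cfg.lnc_length_range[1], endpoint=True))
        strand = "+" if rng.random() < 0.5 else "-"
        add_lnc(lid, distal_cursor, distal_cursor + length, strand,
                "distal", "not_applicable", None)
        distal_cursor += length + 1000

    needed = distal_cursor + 20_000
    chrom_length = cfg.chrom_length or needed
    if chrom_length < needed:
        raise ValueError(
            f"chromosome length {chrom_length} too small for layout ({needed} bp)"
        )

    truth = pd.DataFrame(truth_rows).set_index("lnc_id") if truth_rows else \
        pd.DataFrame(columns=["class", "orientation", "partner_gene_id"])
    coding_truth = pd.DataFrame(
        {"gene_id": [g.transcript_id for g in coding], "direction": directions}
    ).set_index("gene_id")

    ann = SyntheticAnnotation(coding=coding, lncs=lncs, truth=truth,
                              coding_truth=coding_truth, chrom_length=chrom_length)
    if verify and lncs:
        index = GeneIndex(coding)
        for lnc in lncs:
            got = classify_lncrna(lnc, index, ClassWindows())
            want = truth.loc[lnc.transcript_id]
            if got.klass != want["class"] or got.orientation != want["orientation"]:
                raise AssertionError(
                    f"planted class collision for {lnc.transcript_id}: "
                    f"planted {want['class']}/{want['orientation']}, "
                    f"classified {got.klass}/{got.orientation}"
                )
    return ann


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

CONDITIONS = ("control", "t30", "t2h")
COMPARTMENTS = ("nucleus", "cytosol")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean ``mean`` and variance mean + dispersion*mean^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


@dataclass
class SyntheticCounts:
    counts: pd.DataFrame        # features x samples
    lengths: pd.Series          # feature spliced/intronic length (nt)
    library_sizes: pd.Series
    truth: pd.DataFrame         # feature_id -> kind, planted direction / fold

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(outdir / "counts.tsv", sep="\t")
        self.lengths.rename("length_nt").to_csv(outdir / "feature_lengths.tsv", sep="\t")
        self.library_sizes.rename("library_size").to_csv(outdir / "library_sizes.tsv", sep="\t")
        self.truth.to_csv(outdir / "counts_truth.tsv", sep="\t")


def simulate_counts(cfg: SimulationConfig, ann: SyntheticAnnotation) -> SyntheticCounts:
    """Negative-binomial counts for exonic/intronic coding features and
    lncRNAs across conditions x compartments, with planted fold changes:
    per-class lncRNA up-fractions (planted as exact counts), the coding
    down-fraction, and intronic up-shifts in a gene subset."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))

    features: list[str] = []
    lengths: list[int] = []
    kinds: list[str] = []
    base: list[float] = []
    fold_t: list[float] = []  # planted treated/control fold (both time points)

    def add(fid: str, length: int, kind: str, fold: float) -> None:
        features.append(fid)
        lengths.append(length)
        kinds.append(kind)
        base.append(float(np.exp(rng.normal(cfg.base_count_log_mean,
                                            cfg.base_count_log_sd))))
        fold_t.append(fold)

    # coding genes: exonic + intronic features
    n_intron_eligible = [g for g in ann.coding if g.intronic_length > 0]
    n_intron_up = round(cfg.intron_up_fraction * len(n_intron_eligible))
    intron_up = set(g.transcript_id for g in n_intron_eligible[:n_intron_up])
    for g in ann.coding:
        direction = ann.coding_truth.loc[g.transcript_id, "direction"]
        fold = cfg.up_fold if direction == "up" else cfg.down_fold
        add(f"{g.transcript_id}:exon", g.spliced_length, "coding_exon", fold)
        if g.intronic_length > 0:
            ifold = cfg.intron_up_fold if g.transcript_id in intron_up else fold
            add(f"{g.transcript_id}:intron", g.intronic_length, "coding_intron", ifold)

    # lncRNAs: per-class planted up counts (exact, not Bernoulli draws)
    lnc_truth_dir = {}
    fraction_up = dict(DEFAULT_FRACTION_UP) | dict(cfg.fraction_up)
    for klass, frac in fraction_up.items():
        members = [l for l in ann.lncs
                   if ann.truth.loc[l.transcript_id, "class"] == klass]
        n_up = round(frac * len(members))
        flags = np.array([True] * n_up + [False] * (len(members) - n_up))
        rng.shuffle(flags)
        for lnc, up in zip(members, flags):
            lnc_truth_dir[lnc.transcript_id] = "up" if up else "down"
            add(lnc.transcript_id, lnc.spliced_length, "lncRNA",
                cfg.up_fold if up else cfg.down_fold)

    base_arr = np.array(base)
    fold_arr = np.array(fold_t)
    cols = {}
    for comp in COMPARTMENTS:
        for cond in CONDITIONS:
            mean = base_arr if cond == "control" else base_arr * fold_arr
            cols[f"{cond}_{comp}"] = _nb_draw(rng, mean, cfg.nb_dispersion)
    counts = pd.DataFrame(cols, index=pd.Index(features, name="feature_id"))
    # the simulated features are a subset of a full sequencing library;
    # library size is the configured depth, not the subset's column sum
    if (counts.sum(axis=0) > cfg.depth).any():
        raise ValueError("configured depth smaller than simulated feature counts")
    library_sizes = pd.Series(cfg.depth, index=counts.columns, dtype=int)

    truth = pd.DataFrame({
        "feature_id": features,
        "kind": kinds,
        "planted_fold": fold_arr,
        "direction": ["up" if f > 1 else ("down" if f < 1 else "unchanged")
                      for f in fold_arr],
    }).set_index("feature_id")
    truth.loc[list(lnc_truth_dir), "direction"] = [
        lnc_truth_dir[k] for k in truth.index if k in lnc_truth_dir]
    return SyntheticCounts(counts=counts,
                           lengths=pd.Series(lengths, index=counts.index),
                           library_sizes=library_sizes, truth=truth)


# ---------------------------------------------------------------------------
# PolII coverage
# ---------------------------------------------------------------------------

def _add_gaussian(arr: np.ndarray, center: int, sigma: float, amplitude: float) -> None:
    half = int(4 * sigma)
    lo, hi = max(0, center - half), min(arr.size, center + half)
    if lo >= hi:
        return
    x = np.arange(lo, hi)
    arr[lo:hi] += amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def simulate_coverage(cfg: SimulationConfig, ann: SyntheticAnnotation) -> dict:
    """PolII coverage tracks per condition (Poisson-sampled per bp).

    Every coding gene gets uniform gene-body coverage plus a promoter-
    proximal pileup: a paused-PolII peak just downstream of the TSS and two
    divergent lobes ~1 kb either side. In the 30-min track only, coverage in
    the promoter-proximal pausing zone (``pausing_zone_bp`` on the gene
    axis, upstream lobe + paused peak + promoter window) is scaled by
    ``pausing_gain``, so the traveling ratio rises by the gain while the
    gene body is untouched; the 2-h track reverts to the control intensity.
    Returns {condition: CoverageTrack}.
    """
    from .pol2_profiles import CoverageTrack

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    n = ann.chrom_length
    base = np.zeros(n)
    zone = np.zeros(n, dtype=bool)
    z0, z1 = cfg.pausing_zone_bp
    for g in ann.coding:
        base[g.start:g.end] += cfg.body_level
        axis = 1 if g.strand == "+" else -1
        _add_gaussian(base, g.tss + axis * cfg.peak_offset,
                      cfg.peak_sigma, cfg.peak_amplitude)
        _add_gaussian(base, g.tss + cfg.lobe_offset, cfg.lobe_sigma,
                      cfg.lobe_amplitude)
        _add_gaussian(base, g.tss - cfg.lobe_offset, cfg.lobe_sigma,
                      cfg.lobe_amplitude)
        if axis == 1:
            lo, hi = g.tss + z0, g.tss + z1 + 1
        else:
            lo, hi = g.tss - 1 - z1, g.tss - z0
        zone[max(0, lo):min(n, hi)] = True

    tracks = {}
    for cond in CONDITIONS:
        gain = cfg.pausing_gain if cond == "t30" else 1.0
        lam = np.where(zone, gain * base, base)
        sampled = rng.poisson(lam).astype(np.float64)
        tracks[cond] = CoverageTrack(values={CHROM: sampled},
                                     total_mapped_reads=float(sampled.sum()) or 1.0)
    return tracks


# ---------------------------------------------------------------------------
# Polysome arrays
# ---------------------------------------------------------------------------

_TREND_EFFECTS = {
    # stress-minus-control log2 shift per fraction pool (None, Low, High),
    # scaled so that the maximum pairwise spread equals d_spread
    "None_pool": np.array([0.5, 0.0, -0.5]),
    "Low_pool": np.array([-0.5, 0.5, -0.5]),
    "High_pool": np.array([-0.5, 0.0, 0.5]),
}


@dataclass
class SyntheticArrays:
    values: pd.DataFrame    # linear intensities, probes x samples
    samples: pd.DataFrame   # sample sheet: state, pool, replicate
    truth: pd.DataFrame     # per probe: biotype, class, regulated, trend

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.values.to_csv(outdir / "array_matrix.tsv", sep="\t")
        self.samples.to_csv(outdir / "array_samples.tsv", sep="\t")
        self.truth.to_csv(outdir / "array_truth.tsv", sep="\t")


def _draw_labels(rng: np.random.Generator, n: int, proportions: Mapping[str, float]) -> np.ndarray:
    """Deterministic label counts (largest remainder), then shuffled."""
    items = sorted(proportions.items())
    counts = [int(math.floor(p * n)) for _, p in items]
    remainders = [p * n - c for (_, p), c in zip(items, counts)]
    while sum(counts) < n:
        i = int(np.argmax(remainders))
        counts[i] += 1
        remainders[i] = -1
    labels = np.concatenate([[k] * c for (k, _), c in zip(items, counts)]) \
        if n else np.array([], dtype=object)
    rng.shuffle(labels)
    return labels


def simulate_polysome_arrays(cfg: SimulationConfig) -> SyntheticArrays:
    """3-pool polysome intensity matrices with planted (transcriptional
    class, trend) labels: two probes per transcript, triplicate arrays per
    state x pool, Gaussian log2 noise of sd ``noise_sd``."""
    from .polysome_shift import POOLS, STATES

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    transcripts = ([("coding", f"mrna{i:05d}") for i in range(cfg.n_array_coding)]
                   + [("noncoding", f"lnc{i:05d}") for i in range(cfg.n_array_noncoding)])

    rows = []
    for biotype in ("coding", "noncoding"):
        n_bio = sum(1 for b, _ in transcripts if b == biotype)
        classes = _draw_labels(rng, n_bio, cfg.array_class_proportions[biotype])
        n_reg = round(cfg.regulated_fraction * n_bio)
        reg = np.array([True] * n_reg + [False] * (n_bio - n_reg))
        rng.shuffle(reg)
        trends = _draw_labels(rng, n_reg, cfg.array_trend_proportions[biotype])
        it = iter(trends)
        members = [t for b, t in transcripts if b == biotype]
        for tid, cls, r in zip(members, classes, reg):
            rows.append({"transcript_id": tid, "biotype": biotype,
                         "transcriptional_class": cls, "regulated": bool(r),
                         "trend": next(it) if r else "NA"})
    t_truth = pd.DataFrame(rows).set_index("transcript_id")

    sample_rows = []
    for state in STATES:
        for pool in POOLS:
            for rep in range(1, cfg.array_replicates + 1):
                sample_rows.append({"sample": f"{state}_{pool}_r{rep}",
                                    "state": state, "pool": pool, "replicate": rep})
    sheet = pd.DataFrame(sample_rows).set_index("sample")

    probe_rows = []
    log2_means = {}
    for tid, row in t_truth.iterrows():
        rt = {"high": cfg.rt_effect, "low": -cfg.rt_effect,
              "no_change": cfg.rt_no_change * (1 if rng.random() < 0.5 else -1)}[
            row["transcriptional_class"]]
        shifts = np.zeros(3)
        if row["regulated"]:
            shifts = cfg.d_spread * _TREND_EFFECTS[row["trend"]]
        effect = {"Total": rt, "None": rt + shifts[0],
                  "Low": rt + shifts[1], "High": rt + shifts[2]}
        for p in (1, 2):
            pid = f"{tid}_p{p}"
            baseline = rng.normal(8.0, 1.5) + rng.normal(0.0, 0.2)
            log2_means[pid] = (baseline, effect)
            probe_rows.append({"probe_id": pid, "transcript_id": tid,
                               **row.to_dict()})
    p_truth = pd.DataFrame(probe_rows).set_index("probe_id")

    probes = list(log2_means)
    data = np.empty((len(probes), len(sheet)))
    for j, (sample, srow) in enumerate(sheet.iterrows()):
        for i, pid in enumerate(probes):
            baseline, effect = log2_means[pid]
            mu = baseline + (effect[srow["pool"]] if srow["state"] == "stress" else 0.0)
            data[i, j] = mu
    data = data + rng.normal(0.0, cfg.noise_sd, size=data.shape)
    values = pd.DataFrame(np.power(2.0, data), index=pd.Index(probes, name="probe_id"),
                          columns=sheet.index)
    return SyntheticArrays(values=values, samples=sheet, truth=p_truth)
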