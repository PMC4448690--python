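"""Transcript annotation parsing, gene-locus construction and representative selection.

Coordinates are internally 0-based half-open throughout. GTF I/O converts
from/to the 1-based inclusive dialect, BED12 I/O is natively 0-based
half-open, so both round-trip bit-exactly.

A *gene locus* groups transcripts on the same strand whose exons overlap
(transitively, >= 1 bp by default); the locus representative is the member
transcript with the highest RPKM in any experimental condition.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import gffutils
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

LNCRNA_MIN_NT = 200  # transcripts must exceed this spliced length to be lncRNA


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based, inclusive
    end: int    # exclusive
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: an exon chain on one strand with derived TSS/TES."""

    transcript_id: str
    exons: tuple[GenomicInterval, ...]
    biotype: str = "noncoding"       # {"coding", "noncoding"}
    source: str = "de-novo"          # RefSeq / GENCODE / ENCODE / de-novo
    locus_id: str | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"{self.transcript_id}: exons on mixed chromosomes/strands"
            )
        starts = [e.start for e in self.exons]
        if starts != sorted(starts):
            raise AnnotationError(f"{self.transcript_id}: exons not sorted")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise AnnotationError(f"{self.transcript_id}: overlapping exons")
        if self.biotype not in ("coding", "noncoding"):
            raise AnnotationError(f"{self.transcript_id}: biotype {self.biotype!r}")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def tss(self) -> int:
        """5' end, strand-aware (plus: first exon start; minus: last exon end)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """3' end, strand-aware."""
        return self.end if self.strand == "+" else self.start

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def is_lncrna(self) -> bool:
        """Noncoding and spliced length > 200 nt. Shorter transcripts are kept
        in the model but are not lncRNA candidates."""
        return self.biotype == "noncoding" and self.spliced_length > LNCRNA_MIN_NT

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return tuple(out)

    @property
    def intronic_length(self) -> int:
        return sum(i.length for i in self.introns)


@dataclass
class GeneLocus:
    """Transcripts sharing (transitively) >= 1 bp of same-strand exonic overlap."""

    locus_id: str
    transcripts: tuple[TranscriptModel, ...]
    representative: str | None = None

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(t.start for t in self.transcripts),
            max(t.end for t in self.transcripts),
            self.strand,
        )


BiotypeRule = Callable[[Mapping[str, str]], str]

_CODING_TOKENS = {"protein_coding", "coding", "mRNA"}


def default_biotype_rule(attrs: Mapping[str, str]) -> str:
    for key in ("transcript_biotype", "gene_biotype", "biotype"):
        v = attrs.get(key)
        if v is not None:
            return "coding" if v in _CODING_TOKENS else "noncoding"
    return "noncoding"


def _source_label(raw: str) -> str:
    return raw if raw in ("RefSeq", "GENCODE", "ENCODE") else "de-novo"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_annotation(
    path: str | Path,
    fmt: str | None = None,
    biotype_rule: BiotypeRule = default_biotype_rule,
) -> list[TranscriptModel]:
    """Read a GTF or BED12 annotation into TranscriptModels.

    ``fmt`` is "gtf" or "bed12"; inferred from the file extension when None.
    Transcripts with exons on mixed strands/chromosomes are rejected and
    logged rather than aborting the whole file.
    """
    path = Path(path)
    if fmt is None:
        fmt = "bed12" if path.suffix.lower() in (".bed", ".bed12") else "gtf"
    if fmt == "gtf":
        return _read_gtf(path, biotype_rule)
    if fmt == "bed12":
        return _read_bed12(path, biotype_rule)
    raise ValueError(f"unknown annotation format {fmt!r}")


def _read_gtf(path: Path, biotype_rule: BiotypeRule) -> list[TranscriptModel]:
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            keep_order=True,
        )
    except Exception as exc:  # gffutils reports the offending line
        raise AnnotationError(f"{path}: failed to parse GTF: {exc}") from exc

    by_tx: dict[str, list] = {}
    meta: dict[str, tuple[str, Mapping[str, str]]] = {}
    for feat in db.features_of_type("exon"):
        tid_vals = feat.attributes.get("transcript_id")
        if not tid_vals:
            raise AnnotationError(f"{path}: exon without transcript_id near {feat.start}")
        tid = tid_vals[0]
        by_tx.setdefault(tid, []).append(feat)
        attrs = {k: v[0] for k, v in feat.attributes.items() if v}
        meta[tid] = (feat.source, attrs)

    out: list[TranscriptModel] = []
    for tid in sorted(by_tx):
        feats = sorted(by_tx[tid], key=lambda f: f.start)
        source, attrs = meta[tid]
        try:
            exons = tuple(
                # GTF is 1-based inclusive
                GenomicInterval(f.seqid, f.start - 1, f.end, f.strand)
                for f in feats
            )
            out.append(
                TranscriptModel(
                    transcript_id=tid,
                    exons=exons,
                    biotype=biotype_rule(attrs),
                    source=_source_label(attrs.get("source_tag", source)),
                )
            )
        except AnnotationError as exc:
            log.warning("rejected transcript %s: %s", tid, exc)
    return out


def _read_bed12(path: Path, biotype_rule: BiotypeRule) -> list[TranscriptModel]:
    out: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise AnnotationError(f"{path}:{lineno}: expected 12 BED fields")
            try:
                chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                strand = fields[5]
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise AnnotationError(f"{path}:{lineno}: blockCount mismatch")
            try:
                exons = tuple(
                    GenomicInterval(chrom, start + bs, start + bs + sz, strand)
                    for bs, sz in zip(starts, sizes)
                )
                if exons[-1].end != end:
                    raise AnnotationError("blocks do not span thickEnd")
                out.append(
                    TranscriptModel(
                        transcript_id=name,
                        exons=exons,
                        biotype=biotype_rule({}),
                    )
                )
            except AnnotationError as exc:
                log.warning("rejected transcript %s (%s:%d): %s", fields[3], path, lineno, exc)
    return out


def write_annotation(
    transcripts: Iterable[TranscriptModel],
    path: str | Path,
    fmt: str | None = None,
) -> None:
    """Write transcripts back to GTF (exon records) or BED12."""
    path = Path(path)
    if fmt is None:
        fmt = "bed12" if path.suffix.lower() in (".bed", ".bed12") else "gtf"
    transcripts = list(transcripts)
    with open(path, "w") as fh:
        if fmt == "gtf":
            for t in transcripts:
                gene = t.locus_id or t.transcript_id
                bt = "protein_coding" if t.biotype == "coding" else "noncoding"
                for e in t.exons:
                    attrs = (
                        f'gene_id "{gene}"; transcript_id "{t.transcript_id}"; '
                        f'transcript_biotype "{bt}"; source_tag "{t.source}";'
                    )
                    fh.write(
                        f"{e.chrom}\t{t.source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{e.strand}\t.\t{attrs}\n"
                    )
        elif fmt == "bed12":
            for t in transcripts:
                sizes = ",".join(str(e.length) for e in t.exons)
                starts = ",".join(str(e.start - t.start) for e in t.exons)
                fh.write(
                    f"{t.chrom}\t{t.start}\t{t.end}\t{t.transcript_id}\t0\t{t.strand}\t"
                    f"{t.start}\t{t.end}\t0\t{t.n_exons}\t{sizes}\t{starts}\n"
                )
        else:
            raise ValueError(f"unknown annotation format {fmt!r}")


# ---------------------------------------------------------------------------
# Locus merging and representative selection
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def merge_loci(
    transcripts: Sequence[TranscriptModel],
    min_overlap_bp: int = 1,
) -> list[GeneLocus]:
    """Partition transcripts into gene loci by transitive same-strand exonic
    overlap (>= ``min_overlap_bp``). Transcripts with no partner form
    singleton loci. The partition is independent of input order."""
    txs = sorted(transcripts, key=lambda t: t.transcript_id)
    uf = _UnionFind(len(txs))
    trees: dict[tuple[str, str], IntervalTree] = {}
    for i, t in enumerate(txs):
        tree = trees.setdefault((t.chrom, t.strand), IntervalTree())
        for e in t.exons:
            for hit in tree.overlap(e.start, e.end):
                if min(hit.end, e.end) - max(hit.begin, e.start) >= min_overlap_bp:
                    uf.union(i, hit.data)
            tree.addi(e.start, e.end, i)

    groups: dict[int, list[TranscriptModel]] = {}
    for i, t in enumerate(txs):
        groups.setdefault(uf.find(i), []).append(t)

    loci = []
    for members in groups.values():
        members = sorted(members, key=lambda t: t.transcript_id)
        locus_id = f"locus_{members[0].transcript_id}"
        members = tuple(replace(t, locus_id=locus_id) for t in members)
        loci.append(GeneLocus(locus_id=locus_id, transcripts=members))
    return sorted(loci, key=lambda l: l.locus_id)


def select_representative(
    locus: GeneLocus,
    rpkm_by_condition: Mapping[str, Mapping[str, float]],
) -> str:
    """Representative = member with the highest RPKM in any experimental
    condition; ties broken by longer spliced length, then transcript_id."""
    if not locus.transcripts:
        raise ValueError(f"{locus.locus_id}: empty locus")
    best = None
    for t in locus.transcripts:
        try:
            vals = rpkm_by_condition[t.transcript_id]
        except KeyError as exc:
            raise KeyError(
                f"{locus.locus_id}: no RPKM values for {t.transcript_id}"
            ) from exc
        if not vals:
            raise ValueError(f"{t.transcript_id}: empty RPKM map")
        key = (max(vals.values()), t.spliced_length)
        # max RPKM desc, length desc, id asc
        if best is None or key > best[0] or (key == best[0] and t.transcript_id < best[1]):
            best = (key, t.transcript_id)
    return best[1]
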