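"""Sequence-level features: longest-ORF search, coding bias index (CBI),
PWM scanning of promoter sequences and motif co-occurrence statistics.

The CBI of an ORF compares the observed usage of "optimal" codons to the
expectation under uniform synonymous usage:

    CBI = (N_opt - N_rand) / (N_tot - N_rand)

where N_opt is the observed optimal-codon count, N_tot the number of codons
at degenerate amino-acid positions and N_rand the optimal count expected by
chance. CBI is 1 when only optimal codons are used and 0 at random usage;
lncRNA ORFs typically score near zero, which is why the statistic serves as
a coding-potential proxy.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .utils import round_half_up

log = logging.getLogger(__name__)

STOP_CODONS = set(standard_dna_table.stop_codons)

# synonymous families of the standard genetic code, keyed by amino acid
SYNONYMOUS: dict[str, frozenset[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    SYNONYMOUS.setdefault(_aa, set()).add(_codon)  # type: ignore[arg-type]
SYNONYMOUS = {aa: frozenset(cs) for aa, cs in SYNONYMOUS.items()}

# Bundled default optimal-codon set for human (most-used codon per amino acid
# in highly expressed genes); configurable in every CBI call.
HUMAN_OPTIMAL_CODONS: dict[str, frozenset[str]] = {
    "A": frozenset({"GCC"}), "R": frozenset({"CGC", "AGG"}),
    "N": frozenset({"AAC"}), "D": frozenset({"GAC"}),
    "C": frozenset({"TGC"}), "Q": frozenset({"CAG"}),
    "E": frozenset({"GAG"}), "G": frozenset({"GGC"}),
    "H": frozenset({"CAC"}), "I": frozenset({"ATC"}),
    "L": frozenset({"CTG"}), "K": frozenset({"AAG"}),
    "F": frozenset({"TTC"}), "P": frozenset({"CCC"}),
    "S": frozenset({"AGC"}), "T": frozenset({"ACC"}),
    "Y": frozenset({"TAC"}), "V": frozenset({"GTG"}),
}


@dataclass(frozen=True)
class OrfRecord:
    """Longest sense-strand open reading frame of one transcript.

    ``start_nt``/``end_nt`` are 0-based transcript coordinates; ``end_nt``
    is exclusive and includes the stop codon. ``length_codons`` excludes
    the stop codon.
    """

    transcript_id: str
    frame: int
    start_nt: int
    end_nt: int
    length_codons: int
    cbi: float | None = None


def find_longest_orf(
    seq: str,
    transcript_id: str = "",
    min_codons: int = 1,
    require_stop: bool = True,
) -> OrfRecord | None:
    """Longest ATG..stop span across the three sense-strand frames.

    Ties are broken by the 5'-most start. Returns None when no qualifying
    ORF exists. Codons containing N never match ATG or a stop.
    """
    s = seq.upper().replace("U", "T")
    if not s:
        raise ValueError("empty sequence")
    if set(s) - set("ACGTN"):
        raise ValueError(f"unexpected characters in sequence: {sorted(set(s) - set('ACGTN'))}")
    best: OrfRecord | None = None
    for frame in range(3):
        start: int | None = None
        for i in range(frame, len(s) - 2, 3):
            codon = s[i:i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                n_codons = (i - start) // 3
                cand = OrfRecord(transcript_id, frame, start, i + 3, n_codons)
                if n_codons >= min_codons and (
                    best is None
                    or n_codons > best.length_codons
                    or (n_codons == best.length_codons and start < best.start_nt)
                ):
                    best = cand
                start = None
        if start is not None and not require_stop:
            n_codons = (len(s) - start) // 3
            if n_codons >= min_codons and (
                best is None or n_codons > best.length_codons
                or (n_codons == best.length_codons and start < best.start_nt)
            ):
                best = OrfRecord(transcript_id, frame, start,
                                 start + 3 * n_codons, n_codons)
    return best


def orf_codons(seq: str, orf: OrfRecord) -> list[str]:
    """Codons of an ORF excluding the stop codon."""
    s = seq.upper().replace("U", "T")
    return [s[i:i + 3] for i in range(orf.start_nt, orf.start_nt + 3 * orf.length_codons, 3)]


def compute_cbi(
    codons: Sequence[str],
    optimal_codons: Mapping[str, frozenset[str]] = HUMAN_OPTIMAL_CODONS,
) -> float:
    """Coding bias index over an ORF's codons (stop codon excluded).

    Only codons of amino acids with >= 2 synonymous codons and at least one
    declared optimal codon contribute. Returns NaN when no degenerate codon
    is present (the index is undefined).
    """
    if not codons:
        raise ValueError("empty codon list")
    n_opt = 0.0
    n_tot = 0.0
    n_rand = 0.0
    aa_of = standard_dna_table.forward_table
    for codon in codons:
        codon = codon.upper().replace("U", "T")
        aa = aa_of.get(codon)
        if aa is None:
            continue  # stop or ambiguous
        family = SYNONYMOUS[aa]
        optimal = optimal_codons.get(aa, frozenset()) & family
        if len(family) < 2 or not optimal:
            continue
        n_tot += 1
        n_rand += len(optimal) / len(family)
        if codon in optimal:
            n_opt += 1
    if n_tot == 0 or n_tot == n_rand:
        return float("nan")
    return (n_opt - n_rand) / (n_tot - n_rand)


def score_transcript_orfs(
    sequences: Mapping[str, str],
    optimal_codons: Mapping[str, frozenset[str]] = HUMAN_OPTIMAL_CODONS,
    min_codons: int = 10,
) -> pd.DataFrame:
    """Longest ORF + CBI per transcript (the coding-potential screen applied
    to lncRNA candidates). Transcripts without a qualifying ORF get NA rows."""
    rows = []
    for tid, seq in sequences.items():
        orf = find_longest_orf(seq, tid, min_codons=min_codons)
        if orf is None:
            rows.append({"transcript_id": tid, "frame": pd.NA, "start_nt": pd.NA,
                         "end_nt": pd.NA, "length_codons": 0, "cbi": np.nan})
        else:
            cbi = compute_cbi(orf_codons(seq, orf), optimal_codons)
            rows.append({"transcript_id": tid, "frame": orf.frame,
                         "start_nt": orf.start_nt, "end_nt": orf.end_nt,
                         "length_codons": orf.length_codons, "cbi": cbi})
    return pd.DataFrame(rows).set_index("transcript_id")


# ---------------------------------------------------------------------------
# PWM scanning and co-occurrence statistics
# ---------------------------------------------------------------------------

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_meme_motifs(path: str | Path) -> dict[str, np.ndarray]:
    """Parse MEME minimal-format motifs into (length x 4) probability
    matrices keyed by motif name (columns A, C, G, T)."""
    with open(path) as fh:
        parsed = motifs.parse(fh, "minimal")
    out = {}
    for m in parsed:
        pwm = np.array([[m.pwm[b][i] for b in "ACGT"] for i in range(m.length)])
        out[m.name] = pwm
    return out


def _log_odds(pwm: np.ndarray, background: float = 0.25,
              pseudo: float = 1e-6) -> np.ndarray:
    p = np.asarray(pwm, dtype=float)
    if p.ndim != 2 or p.shape[1] != 4:
        raise ValueError("PWM must have shape (length, 4)")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-3):
        raise ValueError("PWM rows must sum to 1")
    return np.log2((p + pseudo) / (background + pseudo))


def _window_scores(seq: str, lod: np.ndarray) -> np.ndarray:
    L = lod.shape[0]
    n = len(seq) - L + 1
    if n <= 0:
        return np.full(0, -np.inf)
    enc = np.full(len(seq), -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        enc[np.frombuffer(seq.encode(), dtype=np.uint8)
            == ord(base)] = idx
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for off in range(L):
        col = enc[off:off + n]
        ok = col >= 0
        valid &= ok
        scores[ok] += lod[off, col[ok]]
    scores[~valid] = -np.inf
    return scores


def scan_pwm(
    sequences: Mapping[str, str],
    pwm: np.ndarray,
    threshold: float,
) -> pd.Series:
    """Count non-overlapping PWM hits (log-odds score >= threshold, both
    strands, uniform background) per sequence."""
    lod = _log_odds(pwm)
    L = lod.shape[0]
    counts = {}
    for sid, seq in sequences.items():
        s = seq.upper().replace("U", "T")
        if set(s) - set("ACGTN"):
            raise ValueError(f"{sid}: sequence/PWM alphabet mismatch")
        fwd = _window_scores(s, lod)
        rev = _window_scores(str(Seq(s).reverse_complement()), lod)[::-1]
        # candidate hits on either strand, greedily resolved left to right
        hits = sorted(
            set(np.flatnonzero(fwd >= threshold)) | set(np.flatnonzero(rev >= threshold))
        )
        n = 0
        next_free = 0
        for pos in hits:
            if pos >= next_free:
                n += 1
                next_free = pos + L
        counts[sid] = n
    return pd.Series(counts, name="hits", dtype=int)


def build_hit_table(
    sequences: Mapping[str, str],
    pwms: Mapping[str, np.ndarray],
    thresholds: Mapping[str, float] | float,
) -> pd.DataFrame:
    """Hit-count table (promoters x motifs)."""
    cols = {}
    for name, pwm in pwms.items():
        thr = thresholds if isinstance(thresholds, (int, float)) else thresholds[name]
        cols[name] = scan_pwm(sequences, pwm, thr)
    return pd.DataFrame(cols)


def cooccurrence_summary(
    hits: pd.DataFrame,
    universe_size: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-motif occurrence statistics over a promoter universe.

    Returns (per-motif table, overall dict). The table carries raw values
    plus report-style roundings: mean hits per hit-carrying promoter to one
    decimal, percent of the universe to two decimals. The overall dict gives
    the count and percent of promoters containing every motif simultaneously
    (percent reported to one decimal, the convention of the printed summary).
    """
    if (hits.to_numpy() < 0).any():
        raise ValueError("hit counts must be non-negative")
    n_universe = universe_size if universe_size is not None else len(hits)
    if n_universe < len(hits.index[(hits > 0).any(axis=1)]):
        raise ValueError("universe smaller than the number of hit promoters")
    rows = []
    for motif in hits.columns:
        col = hits[motif]
        total = int(col.sum())
        n_with = int((col > 0).sum())
        mean = total / n_with if n_with else float("nan")
        frac = 100.0 * n_with / n_universe
        rows.append({
            "motif": motif,
            "total_hits": total,
            "n_promoters_with_hit": n_with,
            "mean_hits_per_hit_promoter": mean,
            "mean_rounded": round_half_up(mean, 1) if n_with else float("nan"),
            "pct_of_universe": frac,
            "pct_rounded": round_half_up(frac, 2),
        })
    n_all = int((hits > 0).all(axis=1).sum())
    pct_all = 100.0 * n_all / n_universe
    overall = {
        "universe": n_universe,
        "n_all_motifs": n_all,
        "pct_all_motifs": pct_all,
        "pct_all_motifs_rounded": round_half_up(pct_all, 1),
    }
    return pd.DataFrame(rows).set_index("motif"), overall
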