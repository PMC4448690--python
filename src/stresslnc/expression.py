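"""RPKM quantification and the detection / differential-expression filters.

The differential rule is deliberately simple, matching the study design it
implements: a feature is *up* in a treated-vs-control comparison when
RPKM(treated)/RPKM(control) > 1.5 with the detection filter (treated reads
> 10 and treated RPKM > 1); *down* mirrors the rule on the control side.
A feature counts as up overall when any treated comparison calls it up.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_model import TranscriptModel
from .utils import round_half_up

log = logging.getLogger(__name__)

LOG2_FC_CUT = math.log2(1.5)


def compute_rpkm(count: float, length_nt: int, library_size: int) -> float:
    """Reads per kilobase of feature per million mapped reads:
    ``count * 1e9 / (length_nt * library_size)``."""
    if length_nt <= 0:
        raise ValueError(f"length_nt must be > 0, got {length_nt}")
    if library_size <= 0:
        raise ValueError(f"library_size must be > 0, got {library_size}")
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    return count * 1e9 / (length_nt * library_size)


def rpkm_matrix(
    counts: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: pd.Series,
) -> pd.DataFrame:
    """Vectorised RPKM for a (features x samples) count matrix."""
    lengths = lengths.reindex(counts.index)
    library_sizes = library_sizes.reindex(counts.columns)
    if (lengths <= 0).any():
        raise ValueError("all feature lengths must be > 0")
    if (library_sizes <= 0).any():
        raise ValueError("all library sizes must be > 0")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be >= 0")
    if (counts.sum(axis=0) > library_sizes).any():
        raise ValueError("library_size smaller than column count sum")
    return counts * 1e9 / np.outer(lengths.to_numpy(), library_sizes.to_numpy())


@dataclass(frozen=True)
class ExpressionRecord:
    """Counts + RPKM for one feature in one sample."""

    feature_id: str
    length_nt: int
    count: float
    rpkm: float


@dataclass(frozen=True)
class DifferentialCall:
    feature_id: str
    fold_change: float        # treated / control, linear scale
    treated_reads: float
    treated_rpkm: float
    detected: bool
    direction: str            # {"up", "down", "unchanged"}


def _ratio(num: float, den: float, pseudocount: float) -> float:
    if num == 0 or den == 0:
        num += pseudocount
        den += pseudocount
    return num / den


def call_differential(
    treated: ExpressionRecord,
    control: ExpressionRecord,
    fc_cut: float = 1.5,
    min_reads: float = 10,
    min_rpkm: float = 1.0,
    pseudocount: float = 0.1,
) -> DifferentialCall:
    """Single treated-vs-control call.

    up:   fc > fc_cut AND treated reads > min_reads AND treated RPKM > min_rpkm
    down: control/treated > fc_cut AND the mirrored filter on the control side
    A pseudocount (RPKM units) is added to both sides of a ratio whenever
    either side is zero.
    """
    if treated.feature_id != control.feature_id:
        raise ValueError(
            f"feature mismatch: {treated.feature_id} vs {control.feature_id}"
        )
    fc = _ratio(treated.rpkm, control.rpkm, pseudocount)
    detected = treated.count > min_reads and treated.rpkm > min_rpkm
    control_detected = control.count > min_reads and control.rpkm > min_rpkm
    if fc > fc_cut and detected:
        direction = "up"
    elif _ratio(control.rpkm, treated.rpkm, pseudocount) > fc_cut and control_detected:
        direction = "down"
    else:
        direction = "unchanged"
    return DifferentialCall(
        feature_id=treated.feature_id,
        fold_change=fc,
        treated_reads=treated.count,
        treated_rpkm=treated.rpkm,
        detected=detected,
        direction=direction,
    )


def combine_calls(calls: Sequence[DifferentialCall]) -> DifferentialCall:
    """Collapse per-comparison calls for one feature into an overall call:
    detected if detected in any treated comparison; up if up anywhere,
    else down if down anywhere, else unchanged."""
    if not calls:
        raise ValueError("no calls to combine")
    fid = calls[0].feature_id
    if any(c.feature_id != fid for c in calls):
        raise ValueError("combine_calls requires a single feature")
    detected = any(c.detected for c in calls)
    if any(c.direction == "up" for c in calls):
        direction = "up"
    elif any(c.direction == "down" for c in calls):
        direction = "down"
    else:
        direction = "unchanged"
    best = max(calls, key=lambda c: c.treated_rpkm)
    return DifferentialCall(fid, best.fold_change, best.treated_reads,
                            best.treated_rpkm, detected, direction)


def summarize_de(calls: Iterable[DifferentialCall]) -> dict:
    """Detected / up / down counts with report-style percentages.

    ``pct_up`` = 100 * n_up / n_detected, half-up to one decimal; percentages
    are NaN (undefined), not zero, when nothing is detected.
    """
    calls = list(calls)
    n_detected = sum(c.detected for c in calls)
    n_up = sum(c.detected and c.direction == "up" for c in calls)
    n_down = sum(c.detected and c.direction == "down" for c in calls)
    if n_detected:
        pct_up = round_half_up(100.0 * n_up / n_detected, 1)
        pct_down = round_half_up(100.0 * n_down / n_detected, 1)
    else:
        pct_up = pct_down = float("nan")
    return {
        "n_total": len(calls),
        "n_detected": n_detected,
        "n_up": n_up,
        "n_down": n_down,
        "pct_up": pct_up,
        "pct_down": pct_down,
    }


def de_calls_from_matrix(
    counts: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: pd.Series,
    comparisons: Sequence[tuple[str, str]],
    fc_cut: float = 1.5,
    min_reads: float = 10,
    min_rpkm: float = 1.0,
    pseudocount: float = 0.1,
) -> list[DifferentialCall]:
    """Run the detection/differential filter over a count matrix for a list
    of (treated_column, control_column) comparisons and combine per feature
    (up in any comparison counts as up overall)."""
    rpkm = rpkm_matrix(counts, lengths, library_sizes)
    out = []
    for fid in counts.index:
        ln = int(lengths[fid])
        per = []
        for t_col, c_col in comparisons:
            t = ExpressionRecord(fid, ln, float(counts.at[fid, t_col]),
                                 float(rpkm.at[fid, t_col]))
            c = ExpressionRecord(fid, ln, float(counts.at[fid, c_col]),
                                 float(rpkm.at[fid, c_col]))
            per.append(call_differential(t, c, fc_cut, min_reads, min_rpkm,
                                         pseudocount))
        out.append(combine_calls(per))
    return out


# ---------------------------------------------------------------------------
# Intron/exon quadrant analysis
# ---------------------------------------------------------------------------

def intron_exon_quadrants(
    table: pd.DataFrame,
    fc_cut: float = 1.5,
    pseudocount: float = 0.1,
) -> tuple[pd.DataFrame, pd.Series]:
    """Quadrant assignment per gene from exonic vs intronic RPKM fold changes.

    ``table`` is indexed by gene id with columns ``exon_rpkm_treated``,
    ``exon_rpkm_control``, ``intron_rpkm_treated``, ``intron_rpkm_control``
    and ``intron_length``. Genes without introns (intron_length == 0) are
    excluded and logged.

    Quadrants follow the sign pair (log2 exonic fc, log2 intronic fc) with
    x = exonic, y = intronic: I (+,+), II (-,+), III (-,-), IV (+,-); a zero
    log fold change counts as "+". ``altered`` flags |log2 fc| >= log2(fc_cut)
    on either axis.
    """
    required = {"exon_rpkm_treated", "exon_rpkm_control",
                "intron_rpkm_treated", "intron_rpkm_control", "intron_length"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    eligible = table[table["intron_length"] > 0].copy()
    n_excluded = len(table) - len(eligible)
    if n_excluded:
        log.info("intron_exon_quadrants: excluded %d intron-less genes", n_excluded)

    def fc(num: pd.Series, den: pd.Series) -> pd.Series:
        zero = (num == 0) | (den == 0)
        return (num + pseudocount * zero) / (den + pseudocount * zero)

    exonic_fc = fc(eligible["exon_rpkm_treated"], eligible["exon_rpkm_control"])
    intronic_fc = fc(eligible["intron_rpkm_treated"], eligible["intron_rpkm_control"])
    lx, ly = np.log2(exonic_fc), np.log2(intronic_fc)
    quadrant = np.where(
        lx >= 0, np.where(ly >= 0, "I", "IV"), np.where(ly >= 0, "II", "III")
    )
    cut = math.log2(fc_cut)
    out = pd.DataFrame(
        {
            "exonic_fc": exonic_fc,
            "intronic_fc": intronic_fc,
            "quadrant": quadrant,
            "altered": (np.abs(lx) >= cut) | (np.abs(ly) >= cut),
        },
        index=eligible.index,
    )
    counts = (
        out.loc[out["altered"], "quadrant"]
        .value_counts()
        .reindex(["I", "II", "III", "IV"], fill_value=0)
    )
    return out, counts


# ---------------------------------------------------------------------------
# Gene-structure comparison of up vs down genes
# ---------------------------------------------------------------------------

def gene_structure_compare(
    up_ids: Iterable[str],
    down_ids: Iterable[str],
    models: Mapping[str, TranscriptModel] | Iterable[TranscriptModel],
) -> dict:
    """Compare genomic length and exon number between up- and down-regulated
    genes (two-sided Mann-Whitney-Wilcoxon); medians reported per group."""
    if not isinstance(models, Mapping):
        models = {t.transcript_id: t for t in models}
    up = [models[i] for i in up_ids]
    down = [models[i] for i in down_ids]
    if not up or not down:
        raise ValueError("both groups must be non-empty")
    up_len = np.array([t.span.length for t in up], dtype=float)
    down_len = np.array([t.span.length for t in down], dtype=float)
    up_nex = np.array([t.n_exons for t in up], dtype=float)
    down_nex = np.array([t.n_exons for t in down], dtype=float)
    p_len = stats.mannwhitneyu(up_len, down_len, alternative="two-sided").pvalue
    p_nex = stats.mannwhitneyu(up_nex, down_nex, alternative="two-sided").pvalue
    return {
        "n_up": len(up),
        "n_down": len(down),
        "median_length_up": float(np.median(up_len)),
        "median_length_down": float(np.median(down_len)),
        "median_exons_up": float(np.median(up_nex)),
        "median_exons_down": float(np.median(down_nex)),
        "p_length": float(p_len),
        "p_exons": float(p_nex),
    }
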