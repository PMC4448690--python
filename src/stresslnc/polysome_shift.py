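"""Polysome-fraction microarray analysis: normalisation, stress-vs-control
contrasts per fraction pool, transcriptional classification and the
translational-shift (D) rule.

Samples are labelled by state (stress / control), pool (Total, None, Low,
High — whole-cell RNA plus the untranslated, low-polysome and heavy-polysome
pools of the sucrose gradient) and replicate. After log2 transformation and
quantile normalisation, per-probe contrasts are the log2 mean differences

    RT = stress Total - control Total,  RN/RL/RH likewise per pool.

Probes significant in the Total contrast (p < 0.1) are classed
transcriptionally high / low / no_change at a 1.5-fold cut. A probe is
translationally regulated when any pairwise spread among the fraction
contrasts reaches one log2 unit:

    D1 = |RN - RL|, D2 = |RL - RH|, D3 = |RN - RH|;  regulated iff max >= 1,

and its trend is the pool whose contrast is highest (ties resolved
High > Low > None).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)

POOLS = ("Total", "None", "Low", "High")
STATES = ("stress", "control")
CONTRAST_OF_POOL = {"Total": "RT", "None": "RN", "Low": "RL", "High": "RH"}
TREND_PRIORITY = ("High_pool", "Low_pool", "None_pool")  # tie-break order
_TREND_OF_CONTRAST = {"RN": "None_pool", "RL": "Low_pool", "RH": "High_pool"}


@dataclass
class PolysomeExperiment:
    """Intensity matrix (probes x samples) with its sample sheet.

    ``samples`` is indexed by sample id with columns state, pool, replicate;
    ``log2`` records whether values are already log2-transformed.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    log2: bool = False

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples sheet missing entries for {sorted(missing)}")
        bad_state = set(self.samples["state"]) - set(STATES)
        bad_pool = set(self.samples["pool"]) - set(POOLS)
        if bad_state or bad_pool:
            raise ValueError(f"unknown state/pool labels: {bad_state | bad_pool}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("intensities must be finite")

    def columns_for(self, state: str, pool: str) -> list[str]:
        sel = self.samples[(self.samples["state"] == state)
                           & (self.samples["pool"] == pool)]
        return [c for c in self.values.columns if c in sel.index]


def read_experiment(matrix_tsv: str | Path, sheet_tsv: str | Path,
                    log2: bool = False) -> PolysomeExperiment:
    values = pd.read_csv(matrix_tsv, sep="\t", index_col=0)
    # keep_default_na: the pool label "None" is data, not a missing value
    samples = pd.read_csv(sheet_tsv, sep="\t", index_col=0, keep_default_na=False)
    return PolysomeExperiment(values=values, samples=samples, log2=log2)


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Force every column to share the identical sorted value multiset
    (the mean of the per-rank values across columns). Idempotent."""
    x = df.to_numpy(dtype=float)
    order = np.argsort(x, axis=0, kind="stable")
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[order[:, j], j] = ref
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def normexp_background_correct(x: np.ndarray, offset: float = 50.0) -> np.ndarray:
    """Background-correct one channel of linear intensities under the
    normal + exponential convolution model.

    Observed X = B + S with B ~ N(mu, sigma^2) background and S ~ Exp(alpha)
    signal; (mu, sigma, alpha) are fit by maximum likelihood and each value is
    replaced by E[S | X = x] (always positive), plus ``offset`` to damp the
    variance of low intensities.
    """
    x = np.asarray(x, dtype=float)
    mu0 = np.quantile(x, 0.05)
    low = x[x <= np.quantile(x, 0.25)]
    sigma0 = max(low.std(), 1e-3)
    alpha0 = max(x.mean() - mu0, 1e-3)

    def nll(params: np.ndarray) -> float:
        mu, lsig, lalp = params
        sigma, alpha = np.exp(lsig), np.exp(lalp)
        z = x - mu - sigma**2 / alpha
        logphi = stats.norm.logcdf(z / sigma)
        ll = (-np.log(alpha) + (mu - x) / alpha + sigma**2 / (2 * alpha**2) + logphi)
        return -np.sum(ll)

    from scipy.optimize import minimize

    res = minimize(nll, x0=[mu0, np.log(sigma0), np.log(alpha0)],
                   method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-6, "maxiter": 2000})
    mu, sigma, alpha = res.x[0], float(np.exp(res.x[1])), float(np.exp(res.x[2]))
    a = x - mu - sigma**2 / alpha
    with np.errstate(over="ignore"):
        ratio = np.exp(stats.norm.logpdf(a / sigma) - stats.norm.logcdf(a / sigma))
    signal = a + sigma * ratio
    return np.maximum(signal, 1e-6) + offset


def normalize_arrays(
    exp: PolysomeExperiment,
    background: str = "none",
    offset: float = 50.0,
    floor: float = 1e-3,
) -> PolysomeExperiment:
    """Background-correct (optional), log2-transform and quantile-normalise.

    ``background``: "none", "subtract" (subtract the column 5th percentile and
    floor), or "normexp" (model-based, see :func:`normexp_background_correct`).
    """
    vals = exp.values.copy()
    if not exp.log2:
        if background == "normexp":
            for c in vals.columns:
                vals[c] = normexp_background_correct(vals[c].to_numpy(), offset)
        elif background == "subtract":
            for c in vals.columns:
                corrected = vals[c] - np.quantile(vals[c], 0.05) + offset
                n_floored = int((corrected <= 0).sum())
                if n_floored:
                    log.info("%s: floored %d non-positive intensities", c, n_floored)
                vals[c] = np.maximum(corrected, floor)
        elif background != "none":
            raise ValueError(f"unknown background mode {background!r}")
        if (vals.to_numpy() <= 0).any():
            log.info("flooring non-positive intensities before log2")
            vals = vals.clip(lower=floor)
        vals = np.log2(vals)
    return PolysomeExperiment(values=quantile_normalize(vals),
                              samples=exp.samples, log2=True)


# ---------------------------------------------------------------------------
# Replicate QC
# ---------------------------------------------------------------------------

def qc_replicates(
    exp: PolysomeExperiment,
    distance_threshold: float = 0.15,
) -> tuple[PolysomeExperiment, list[str]]:
    """Remove replicates that fail to cluster with their (state, pool)
    siblings under average-linkage hierarchical clustering at 1 - Pearson
    correlation distance. Groups with fewer than three replicates are
    skipped with a warning; removal never reduces a group below two."""
    vals = exp.values
    corr = np.corrcoef(vals.to_numpy().T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=distance_threshold, criterion="distance")
    cluster_of = dict(zip(vals.columns, labels))

    removed: list[str] = []
    for (state, pool), group in exp.samples.groupby(["state", "pool"]):
        cols = [c for c in vals.columns if c in group.index]
        if len(cols) < 3:
            log.warning("QC skipped for %s/%s: only %d replicates", state, pool, len(cols))
            continue
        flagged = [c for c in cols
                   if not any(cluster_of[c] == cluster_of[o] for o in cols if o != c)]
        if len(cols) - len(flagged) < 2:
            raise ValueError(
                f"replicate QC would leave <2 replicates for {state}/{pool}"
            )
        removed.extend(flagged)

    if not removed:
        return exp, []
    keep = [c for c in vals.columns if c not in removed]
    cleaned = PolysomeExperiment(values=vals[keep],
                                 samples=exp.samples.loc[keep],
                                 log2=exp.log2)
    return cleaned, removed


# ---------------------------------------------------------------------------
# Contrasts, classification, D rule
# ---------------------------------------------------------------------------

def compute_contrasts(exp: PolysomeExperiment, equal_var: bool = False) -> pd.DataFrame:
    """Per-probe stress-minus-control log2 mean differences per pool
    (columns RT, RN, RL, RH) plus ``p_total``, the two-sample t-test p-value
    of the Total contrast (Welch by default)."""
    if not exp.log2:
        raise ValueError("contrasts require a log2-transformed experiment")
    out = pd.DataFrame(index=exp.values.index)
    for pool in POOLS:
        s_cols = exp.columns_for("stress", pool)
        c_cols = exp.columns_for("control", pool)
        name = CONTRAST_OF_POOL[pool]
        if not s_cols or not c_cols:
            log.warning("pool %s missing in one state; contrast %s is NA", pool, name)
            out[name] = np.nan
            continue
        out[name] = (exp.values[s_cols].mean(axis=1)
                     - exp.values[c_cols].mean(axis=1))
        if pool == "Total":
            if len(s_cols) > 1 and len(c_cols) > 1:
                t = stats.ttest_ind(exp.values[s_cols], exp.values[c_cols],
                                    axis=1, equal_var=equal_var)
                out["p_total"] = t.pvalue
            else:
                out["p_total"] = np.nan
    if "p_total" not in out:
        out["p_total"] = np.nan
    return out


def classify_transcription(
    contrasts: pd.DataFrame,
    p_cut: float = 0.1,
    fc_cut: float = 1.5,
) -> pd.Series:
    """Transcriptional class per probe from the Total contrast.

    Probes failing the significance gate (p_total >= p_cut) are "excluded";
    among significant probes: "high" when the fold change is >= fc_cut,
    "low" when <= 1/fc_cut, else "no_change". The fold-change cut is applied
    as |RT| >= log2(fc_cut) (RT is a log2 ratio, so this is identical to the
    signed-linear convention with cuts at +/-fc_cut).
    """
    thr = np.log2(fc_cut)
    rt = contrasts["RT"]
    sig = contrasts["p_total"] < p_cut
    cls = np.where(rt >= thr, "high", np.where(rt <= -thr, "low", "no_change"))
    return pd.Series(np.where(sig, cls, "excluded"),
                     index=contrasts.index, name="transcriptional_class")


def _signed_linear(r: pd.Series) -> pd.Series:
    """log2 ratio -> signed linear fold change (Partek convention)."""
    return np.sign(r) * np.power(2.0, np.abs(r))


def detect_translational_shift(
    contrasts: pd.DataFrame,
    d_cut: float = 1.0,
    scale: str = "log2",
) -> pd.DataFrame:
    """Apply the D rule to the fraction contrasts.

    ``scale``: "log2" applies the cut to log2-ratio differences (default);
    "linear" first converts RN/RL/RH to signed linear fold changes.
    Probes with any undefined fraction contrast get an NA call.
    Returns columns d1, d2, d3, regulated, trend (NA when not regulated).
    """
    if scale == "log2":
        rn, rl, rh = contrasts["RN"], contrasts["RL"], contrasts["RH"]
    elif scale == "linear":
        rn, rl, rh = (_signed_linear(contrasts[c]) for c in ("RN", "RL", "RH"))
    else:
        raise ValueError(f"unknown scale {scale!r}")
    d1 = (rn - rl).abs()
    d2 = (rl - rh).abs()
    d3 = (rn - rh).abs()
    valid = rn.notna() & rl.notna() & rh.notna()
    n_na = int((~valid).sum())
    if n_na:
        log.warning("detect_translational_shift: %d probes with NA contrasts", n_na)
    regulated = ((pd.concat([d1, d2, d3], axis=1).max(axis=1) >= d_cut) & valid
                 ).astype("boolean")
    regulated[~valid] = pd.NA

    # trend = pool with the highest stress/control ratio; ties High > Low > None
    stacked = pd.concat({"RH": rh, "RL": rl, "RN": rn}, axis=1)  # priority order
    best = stacked.idxmax(axis=1)  # idxmax takes the first (highest-priority) max
    trend = best.map(_TREND_OF_CONTRAST).where(regulated.fillna(False))
    out = pd.DataFrame({"d1": d1, "d2": d2, "d3": d3,
                        "regulated": regulated, "trend": trend})
    out.loc[~valid, ["d1", "d2", "d3"]] = np.nan
    return out


def calls_table(
    contrasts: pd.DataFrame,
    biotype: pd.Series,
    p_cut: float = 0.1,
    fc_cut: float = 1.5,
    d_cut: float = 1.0,
    scale: str = "log2",
) -> pd.DataFrame:
    """Full per-probe regulation calls: transcriptional class, D statistics,
    translational-shift flag and trend pool, joined with probe biotype."""
    cls = classify_transcription(contrasts, p_cut=p_cut, fc_cut=fc_cut)
    shifts = detect_translational_shift(contrasts, d_cut=d_cut, scale=scale)
    out = shifts.copy()
    out.insert(0, "transcriptional_class", cls)
    out["biotype"] = biotype.reindex(out.index)
    return out


def trend_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Count trend pools per transcriptional class x biotype over regulated,
    significant probes (3 classes x biotypes x 3 trend pools)."""
    sig = calls[(calls["transcriptional_class"] != "excluded")
                & calls["regulated"].fillna(False).astype(bool)]
    classes = ["high", "low", "no_change"]
    biotypes = sorted(calls["biotype"].dropna().unique())
    idx = pd.MultiIndex.from_product(
        [classes, biotypes, list(TREND_PRIORITY)],
        names=["transcriptional_class", "biotype", "trend"],
    )
    counts = (sig.groupby(["transcriptional_class", "biotype", "trend"],
                          observed=True).size()
              .reindex(idx, fill_value=0).rename("n"))
    return counts.reset_index()


def collapse_probes(values: pd.DataFrame, probe_to_transcript: Mapping[str, str]) -> pd.DataFrame:
    """Collapse probe-level values to transcripts by the per-transcript median."""
    mapping = pd.Series(probe_to_transcript)
    return values.groupby(mapping.reindex(values.index)).median()


def fraction_enrichment(quantities: Sequence[float]) -> np.ndarray:
    """Percent of a transcript per pool: 100 * q_i / sum(q); requires
    non-negative quantities, not all zero."""
    q = np.asarray(quantities, dtype=float)
    if (q < 0).any():
        raise ValueError("pool quantities must be non-negative")
    total = q.sum()
    if total == 0:
        raise ValueError("all-zero pool quantities: enrichment undefined")
    return 100.0 * q / total
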