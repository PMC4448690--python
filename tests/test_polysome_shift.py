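import itertools

import numpy as np
import pandas as pd
import pytest

from oracles import d_rule_oracle
from stresslnc.polysome_shift import (
    PolysomeExperiment,
    classify_transcription,
    compute_contrasts,
    detect_translational_shift,
    fraction_enrichment,
    normalize_arrays,
    normexp_background_correct,
    qc_replicates,
    quantile_normalize,
    trend_summary,
)


def _sheet(groups):
    """groups: dict (state, pool) -> n replicates."""
    rows = []
    for (state, pool), n in groups.items():
        for r in range(1, n + 1):
            rows.append({"sample": f"{state}_{pool}_r{r}", "state": state,
                         "pool": pool, "replicate": r})
    return pd.DataFrame(rows).set_index("sample")


def _experiment(values_by_sample, log2=True):
    sheet_rows = []
    for name in values_by_sample:
        state, pool, rep = name.rsplit("_", 2)
        sheet_rows.append({"sample": name, "state": state, "pool": pool,
                           "replicate": int(rep[1:])})
    sheet = pd.DataFrame(sheet_rows).set_index("sample")
    values = pd.DataFrame(values_by_sample)
    return PolysomeExperiment(values=values, samples=sheet, log2=log2)


class TestQuantileNormalization:
    def test_rank_aligned_columns_forced_to_mean(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(df)
        assert np.allclose(out["a"], [1.5, 3.0, 4.5])
        assert np.allclose(out["b"], [1.5, 3.0, 4.5])

    def test_identical_columns_unchanged(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        out = quantile_normalize(df)
        assert np.allclose(out.to_numpy(), df.to_numpy())

    def test_idempotent_and_sorted_columns_identical(self, rng):
        df = pd.DataFrame(rng.random((200, 5)), columns=list("abcde"))
        once = quantile_normalize(df)
        twice = quantile_normalize(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy())
        ref = np.sort(once["a"].to_numpy())
        for c in "bcde":
            assert np.allclose(np.sort(once[c].to_numpy()), ref)

    def test_preserves_within_column_ranks(self, rng):
        df = pd.DataFrame(rng.random((100, 3)), columns=list("xyz"))
        out = quantile_normalize(df)
        for c in df:
            assert (df[c].rank().to_numpy() == out[c].rank().to_numpy()).all()


class TestNormexp:
    def test_recovers_mean_signal_on_model_data(self):
        rng = np.random.default_rng(7)
        signal = rng.exponential(60.0, size=5000)
        x = rng.normal(30.0, 3.0, size=5000) + signal
        corrected = normexp_background_correct(x, offset=0.0)
        assert (corrected > 0).all()
        assert np.mean(corrected) == pytest.approx(signal.mean(), rel=0.15)

    def test_monotone_in_intensity(self):
        rng = np.random.default_rng(8)
        x = rng.normal(100.0, 10.0, 2000) + rng.exponential(200.0, 2000)
        corrected = normexp_background_correct(x)
        order = np.argsort(x)
        assert (np.diff(corrected[order]) >= -1e-9).all()


class TestNormalizeArrays:
    def test_log2_and_quantile_end_to_end(self, rng):
        raw = pd.DataFrame(rng.lognormal(8, 1, size=(100, 6)),
                           columns=[f"{s}_{p}_r1" for s, p in
                                    itertools.product(["stress", "control"],
                                                      ["Total", "None", "Low"])])
        exp = _experiment({c: raw[c].to_numpy() for c in raw}, log2=False)
        norm = normalize_arrays(exp)
        assert norm.log2
        cols = norm.values.to_numpy()
        ref = np.sort(cols[:, 0])
        for j in range(1, cols.shape[1]):
            assert np.allclose(np.sort(cols[:, j]), ref)

    def test_nonpositive_values_floored(self):
        exp = _experiment({"stress_Total_r1": np.array([0.0, 4.0]),
                           "control_Total_r1": np.array([2.0, 8.0])}, log2=False)
        norm = normalize_arrays(exp, background="none")
        assert np.isfinite(norm.values.to_numpy()).all()


class TestReplicateQC:
    def _build(self, rng, with_outlier):
        base = rng.random(60) * 4 + 6
        cols = {}
        for r in range(1, 4):
            cols[f"stress_Total_r{r}"] = base + rng.normal(0, 0.02, 60)
            cols[f"control_Total_r{r}"] = base[::-1] + rng.normal(0, 0.02, 60)
        if with_outlier:
            cols["stress_Total_r4"] = rng.permutation(base)
        return _experiment(cols)

    def test_permuted_outlier_removed(self, rng):
        exp = self._build(rng, with_outlier=True)
        cleaned, removed = qc_replicates(exp)
        assert removed == ["stress_Total_r4"]
        assert "stress_Total_r4" not in cleaned.values.columns

    def test_concordant_replicates_kept(self, rng):
        exp = self._build(rng, with_outlier=False)
        _, removed = qc_replicates(exp)
        assert removed == []

    def test_two_replicate_group_skipped(self, rng):
        base = rng.random(40) + 5
        cols = {f"stress_Total_r{r}": base + rng.normal(0, 0.01, 40) for r in (1, 2)}
        cols.update({f"control_Total_r{r}": base[::-1] + rng.normal(0, 0.01, 40)
                     for r in (1, 2, 3)})
        _, removed = qc_replicates(_experiment(cols))
        assert removed == []


class TestContrasts:
    def test_constant_shift_recovered_exactly(self, rng):
        base = rng.random(50) + 4
        cols = {}
        for pool in ("Total", "None", "Low", "High"):
            for r in (1, 2, 3):
                cols[f"control_{pool}_r{r}"] = base
                cols[f"stress_{pool}_r{r}"] = base + 1.0
        con = compute_contrasts(_experiment(cols))
        for c in ("RT", "RN", "RL", "RH"):
            assert np.allclose(con[c], 1.0)
        assert (con["p_total"] < 0.05).all()  # exact shift, zero variance... noise-free

    def test_planted_shifts_unbiased_within_3_se(self):
        rng = np.random.default_rng(21)
        n, sd, reps = 400, 0.1, 3
        shift = rng.normal(0, 1, n)
        cols = {}
        for pool in ("Total", "None", "Low", "High"):
            for r in range(1, reps + 1):
                cols[f"control_{pool}_r{r}"] = 8 + rng.normal(0, sd, n)
                cols[f"stress_{pool}_r{r}"] = 8 + shift + rng.normal(0, sd, n)
        con = compute_contrasts(_experiment(cols))
        se = sd * np.sqrt(2 / reps)
        for c in ("RT", "RN", "RL", "RH"):
            resid = con[c].to_numpy() - shift
            assert abs(resid.mean()) < 3 * se / np.sqrt(n)

    def test_missing_pool_gives_na(self, rng):
        base = rng.random(20) + 4
        cols = {f"{s}_Total_r{r}": base for s in ("stress", "control")
                for r in (1, 2)}
        cols["stress_High_r1"] = base  # High absent in control
        con = compute_contrasts(_experiment(cols))
        assert con["RH"].isna().all()


class TestClassifyTranscription:
    def _contrasts(self, rt, p):
        return pd.DataFrame({"RT": rt, "RN": 0.0, "RL": 0.0, "RH": 0.0,
                             "p_total": p}, index=[f"p{i}" for i in range(len(rt))])

    def test_rule_applications(self):
        con = self._contrasts([np.log2(2.0), -np.log2(1.2), np.log2(3.0)],
                              [0.01, 0.01, 0.5])
        cls = classify_transcription(con)
        assert list(cls) == ["high", "no_change", "excluded"]

    def test_low_class_at_negative_cut(self):
        con = self._contrasts([-np.log2(1.5)], [0.001])
        assert classify_transcription(con).iloc[0] == "low"

    def test_partition_of_significant_probes(self, rng):
        con = self._contrasts(rng.normal(0, 1.5, 200), rng.random(200))
        cls = classify_transcription(con)
        sig = cls[cls != "excluded"]
        assert set(sig.unique()) <= {"high", "low", "no_change"}
        assert (con["p_total"] < 0.1).sum() == len(sig)


class TestDRule:
    @staticmethod
    def _contrasts(triples):
        return pd.DataFrame(
            [{"RT": 0.0, "RN": rn, "RL": rl, "RH": rh, "p_total": 0.01}
             for rn, rl, rh in triples],
            index=[f"p{i}" for i in range(len(triples))],
        )

    def test_worked_example(self):
        out = detect_translational_shift(self._contrasts([(0.2, 0.5, 1.6)]))
        row = out.iloc[0]
        assert row["d1"] == pytest.approx(0.3)
        assert row["d2"] == pytest.approx(1.1)
        assert row["d3"] == pytest.approx(1.4)
        assert bool(row["regulated"]) and row["trend"] == "High_pool"

    def test_zero_case_not_regulated(self):
        out = detect_translational_shift(self._contrasts([(0.0, 0.0, 0.0)]))
        assert not bool(out.iloc[0]["regulated"])
        assert pd.isna(out.iloc[0]["trend"])

    def test_boundary_is_inclusive(self):
        out = detect_translational_shift(self._contrasts([(0.0, 0.0, 1.0)]))
        assert bool(out.iloc[0]["regulated"])  # D >= 1, non-strict

    def test_tie_priority_high_low_none(self):
        out = detect_translational_shift(
            self._contrasts([(1.0, 1.0, 0.0), (1.0, 0.0, 1.0), (1.5, 1.5, 1.5 - 1.0)]))
        assert out.iloc[0]["trend"] == "Low_pool"   # RN == RL tie -> Low over None
        assert out.iloc[1]["trend"] == "High_pool"  # RN == RH tie -> High
        assert out.iloc[2]["trend"] == "Low_pool"

    def test_grid_matches_exhaustive_oracle(self):
        grid = np.linspace(-2, 2, 11)
        triples = list(itertools.product(grid, grid, grid))
        out = detect_translational_shift(self._contrasts(triples))
        for (rn, rl, rh), (_, row) in zip(triples, out.iterrows()):
            d1, d2, d3, reg, trend = d_rule_oracle(rn, rl, rh)
            assert row["d1"] == pytest.approx(d1)
            assert bool(row["regulated"]) == reg
            assert (row["trend"] if reg else None) == trend

    def test_na_contrast_gives_na_call(self):
        con = self._contrasts([(0.0, 0.0, 2.0)])
        con.loc["p0", "RL"] = np.nan
        out = detect_translational_shift(con)
        assert pd.isna(out.iloc[0]["regulated"])


class TestTrendSummary:
    def _calls(self, rows):
        return pd.DataFrame(rows)

    def test_single_regulated_probe_single_cell(self):
        calls = self._calls([
            {"transcriptional_class": "high", "regulated": True,
             "trend": "High_pool", "biotype": "noncoding"},
            {"transcriptional_class": "excluded", "regulated": True,
             "trend": "High_pool", "biotype": "noncoding"},
            {"transcriptional_class": "low", "regulated": False,
             "trend": pd.NA, "biotype": "coding"},
        ])
        out = trend_summary(calls)
        assert out["n"].sum() == 1
        hit = out[out["n"] == 1].iloc[0]
        assert (hit["transcriptional_class"], hit["trend"]) == ("high", "High_pool")

    def test_no_regulated_probes_all_zero(self):
        calls = self._calls([{"transcriptional_class": "high", "regulated": False,
                              "trend": pd.NA, "biotype": "coding"}])
        assert trend_summary(calls)["n"].sum() == 0


class TestFractionEnrichment:
    def test_worked_examples(self):
        assert np.allclose(fraction_enrichment([3, 1]), [75.0, 25.0])
        assert np.allclose(fraction_enrichment([1, 1]), [50.0, 50.0])

    def test_sums_to_100(self, rng):
        for _ in range(50):
            q = rng.random(int(rng.integers(2, 6))) + 1e-9
            assert fraction_enrichment(q).sum() == pytest.approx(100.0)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            fraction_enrichment([0.0, 0.0])
        with pytest.raises(ValueError):
            fraction_enrichment([-1.0, 2.0])
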