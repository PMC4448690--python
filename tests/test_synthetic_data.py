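import numpy as np
import pandas as pd
import pytest

from stresslnc.annotation_model import read_annotation, write_annotation
from stresslnc.lnc_classifier import build_gene_index, classify_many
from stresslnc.pol2_profiles import CoverageTrack
from stresslnc.polysome_shift import read_experiment
from stresslnc.synthetic_data import (
    SimulationConfig,
    generate_annotation,
    simulate_counts,
    simulate_coverage,
    simulate_polysome_arrays,
)

SMALL = dict(n_coding_genes=20,
             lnc_per_class={"distal": 5, "overlapping": 5,
                            "terminal_associated": 5, "promoter_associated": 5})


class TestAnnotationGenerator:
    def test_planted_classes_recovered_exactly(self):
        ann = generate_annotation(SimulationConfig(seed=1, **SMALL))
        index = build_gene_index(ann.coding)
        for a in classify_many(ann.lncs, index):
            truth = ann.truth.loc[a.lnc_id]
            assert a.klass == truth["class"]
            assert a.orientation == truth["orientation"]

    def test_seed_determinism(self):
        a = generate_annotation(SimulationConfig(seed=7, **SMALL))
        b = generate_annotation(SimulationConfig(seed=7, **SMALL))
        assert [(t.transcript_id, t.start, t.end, t.strand) for t in a.lncs] == \
            [(t.transcript_id, t.start, t.end, t.strand) for t in b.lncs]

    def test_different_seeds_same_class_counts(self):
        a = generate_annotation(SimulationConfig(seed=1, **SMALL))
        b = generate_annotation(SimulationConfig(seed=2, **SMALL))
        assert not ([(t.start, t.end) for t in a.lncs]
                    == [(t.start, t.end) for t in b.lncs])
        assert a.truth["class"].value_counts().to_dict() == \
            b.truth["class"].value_counts().to_dict()

    def test_zero_lncs_valid(self):
        ann = generate_annotation(SimulationConfig(
            seed=1, n_coding_genes=5,
            lnc_per_class={k: 0 for k in SMALL["lnc_per_class"]}))
        assert ann.lncs == [] and len(ann.coding) == 5

    def test_infeasible_chromosome_length_errors(self):
        with pytest.raises(ValueError):
            generate_annotation(SimulationConfig(seed=1, chrom_length=10_000, **SMALL))

    def test_emitted_files_reparse(self, tmp_path):
        ann = generate_annotation(SimulationConfig(seed=3, **SMALL))
        ann.write(tmp_path)
        coding = read_annotation(tmp_path / "coding.gtf")
        lncs = read_annotation(tmp_path / "lnc.bed12")
        assert len(coding) == len(ann.coding) and len(lncs) == len(ann.lncs)
        assert all(t.biotype == "coding" for t in coding)
        got = {t.transcript_id: [(e.start, e.end) for e in t.exons] for t in lncs}
        want = {t.transcript_id: [(e.start, e.end) for e in t.exons] for t in ann.lncs}
        assert got == want


class TestCounts:
    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=5, **SMALL)
        ann = generate_annotation(cfg)
        c1 = simulate_counts(cfg, ann)
        c2 = simulate_counts(cfg, ann)
        assert c1.counts.equals(c2.counts)

    def test_planted_up_counts_are_exact(self):
        cfg = SimulationConfig(seed=5, **SMALL)
        ann = generate_annotation(cfg)
        sc = simulate_counts(cfg, ann)
        lnc = sc.truth[sc.truth["kind"] == "lncRNA"].join(ann.truth["class"])
        for klass, frac in cfg.fraction_up.items():
            members = lnc[lnc["class"] == klass]
            assert (members["direction"] == "up").sum() == round(frac * len(members))

    def test_poisson_limit_recovers_planted_fold(self):
        """At zero dispersion and high depth the empirical fold change
        approaches the planted fold."""
        cfg = SimulationConfig(seed=6, n_coding_genes=10,
                               lnc_per_class={"distal": 300, "overlapping": 0,
                                              "terminal_associated": 0,
                                              "promoter_associated": 0},
                               nb_dispersion=0.0,
                               base_count_log_mean=np.log(2000.0),
                               base_count_log_sd=0.1)
        ann = generate_annotation(cfg)
        sc = simulate_counts(cfg, ann)
        up = sc.truth[(sc.truth["kind"] == "lncRNA")
                      & (sc.truth["direction"] == "up")].index
        ratio = (sc.counts.loc[up, "t30_nucleus"]
                 / sc.counts.loc[up, "control_nucleus"])
        assert ratio.mean() == pytest.approx(cfg.up_fold, rel=0.01)

    def test_library_size_covers_column_sums(self):
        cfg = SimulationConfig(seed=5, **SMALL)
        sc = simulate_counts(cfg, generate_annotation(cfg))
        assert (sc.counts.sum(axis=0) <= sc.library_sizes).all()


class TestCoverage:
    def test_tracks_reparse_through_bedgraph(self, tmp_path):
        cfg = SimulationConfig(seed=2, n_coding_genes=5,
                               lnc_per_class={k: 0 for k in SMALL["lnc_per_class"]})
        ann = generate_annotation(cfg)
        tracks = simulate_coverage(cfg, ann)
        p = tmp_path / "c.bedGraph"
        tracks["control"].to_bedgraph(p)
        back = CoverageTrack.from_bedgraph(
            p, ann.chrom_lengths,
            total_mapped_reads=tracks["control"].total_mapped_reads)
        assert np.array_equal(back.values["chrS"], tracks["control"].values["chrS"])

    def test_pausing_gain_raises_thirty_minute_tr(self):
        from stresslnc.pol2_profiles import stalling_index_shift, traveling_ratios

        cfg = SimulationConfig(seed=2, n_coding_genes=40,
                               lnc_per_class={k: 0 for k in SMALL["lnc_per_class"]})
        ann = generate_annotation(cfg)
        tracks = simulate_coverage(cfg, ann)
        t0 = traveling_ratios(ann.coding, tracks["control"], min_gene_length=2000)
        t30 = traveling_ratios(ann.coding, tracks["t30"], min_gene_length=2000)
        res = stalling_index_shift(t0, t30)
        assert res["median_ratio"] == pytest.approx(cfg.pausing_gain, rel=0.15)
        # 2-h track reverts to control statistics
        t2h = traveling_ratios(ann.coding, tracks["t2h"], min_gene_length=2000)
        rev = stalling_index_shift(t0, t2h)
        assert rev["median_ratio"] == pytest.approx(1.0, rel=0.1)

    def test_null_gain_indistinguishable(self):
        from stresslnc.pol2_profiles import stalling_index_shift, traveling_ratios

        cfg = SimulationConfig(seed=4, n_coding_genes=40, pausing_gain=1.0,
                               lnc_per_class={k: 0 for k in SMALL["lnc_per_class"]})
        ann = generate_annotation(cfg)
        tracks = simulate_coverage(cfg, ann)
        t0 = traveling_ratios(ann.coding, tracks["control"], min_gene_length=2000)
        t30 = traveling_ratios(ann.coding, tracks["t30"], min_gene_length=2000)
        assert stalling_index_shift(t0, t30)["rank_sum_p"] > 0.05

    def test_metaprofile_shows_promoter_proximal_pileup(self):
        from stresslnc.pol2_profiles import compute_metaprofile

        cfg = SimulationConfig(seed=2, n_coding_genes=40,
                               lnc_per_class={k: 0 for k in SMALL["lnc_per_class"]})
        ann = generate_annotation(cfg)
        tracks = simulate_coverage(cfg, ann)
        anchors = [(g.chrom, g.tss, g.strand) for g in ann.coding]
        prof = compute_metaprofile(anchors, tracks["control"],
                                   window_bp=3000, bin_width=50)
        centers = prof.bin_centers
        near = prof.mean_rpm[np.abs(centers) < 500].mean()
        far_up = prof.mean_rpm[centers < -2000].mean()
        assert near > 2 * far_up
        # the upstream divergent lobe is visible above the upstream baseline
        lobe = prof.mean_rpm[(centers > -1300) & (centers < -700)].mean()
        assert lobe > 1.5 * far_up


class TestPolysomeArrays:
    def test_seed_determinism_and_reparse(self, tmp_path):
        cfg = SimulationConfig(seed=9, n_array_coding=20, n_array_noncoding=20)
        a = simulate_polysome_arrays(cfg)
        b = simulate_polysome_arrays(cfg)
        assert a.values.equals(b.values)
        a.write(tmp_path)
        exp = read_experiment(tmp_path / "array_matrix.tsv",
                              tmp_path / "array_samples.tsv")
        assert exp.values.shape == a.values.shape

    def test_planted_labels_recovered(self):
        from stresslnc.polysome_shift import PolysomeExperiment, calls_table, \
            compute_contrasts

        cfg = SimulationConfig(seed=9, n_array_coding=150, n_array_noncoding=150)
        arr = simulate_polysome_arrays(cfg)
        exp = PolysomeExperiment(values=np.log2(arr.values), samples=arr.samples,
                                 log2=True)
        calls = calls_table(compute_contrasts(exp), arr.truth["biotype"])
        ok = ((calls["transcriptional_class"] == arr.truth["transcriptional_class"])
              & (calls["regulated"].fillna(False).astype(bool) == arr.truth["regulated"])
              & (calls["trend"].fillna("NA") == arr.truth["trend"]))
        assert ok.mean() >= 0.95

    def test_trend_story_matches_design(self):
        """lncRNA probes shift into the heavy pool, mRNAs into the free pool."""
        from stresslnc.polysome_shift import PolysomeExperiment, calls_table, \
            compute_contrasts, trend_summary

        cfg = SimulationConfig(seed=10, n_array_coding=150, n_array_noncoding=150)
        arr = simulate_polysome_arrays(cfg)
        exp = PolysomeExperiment(values=np.log2(arr.values), samples=arr.samples,
                                 log2=True)
        calls = calls_table(compute_contrasts(exp), arr.truth["biotype"])
        cube = trend_summary(calls)
        by_bio = cube.groupby(["biotype", "trend"])["n"].sum()
        assert by_bio["noncoding"].idxmax() == "High_pool"
        assert by_bio["coding"].idxmax() == "None_pool"

    def test_null_effects_rarely_called_regulated(self):
        from stresslnc.polysome_shift import PolysomeExperiment, \
            compute_contrasts, detect_translational_shift

        cfg = SimulationConfig(seed=11, n_array_coding=100, n_array_noncoding=100,
                               regulated_fraction=0.0, rt_effect=0.0,
                               rt_no_change=0.0)
        arr = simulate_polysome_arrays(cfg)
        exp = PolysomeExperiment(values=np.log2(arr.values), samples=arr.samples,
                                 log2=True)
        out = detect_translational_shift(compute_contrasts(exp))
        assert out["regulated"].fillna(False).astype(bool).mean() < 0.01
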