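"""Tests for the seeded synthetic-data generator."""

import numpy as np
import pandas as pd
import pytest

from spermage import SyntheticConfig
from spermage.synthetic import (
    ConfigurationError,
    generate_disease_table,
    generate_fixture,
    generate_global_table,
    generate_manifest,
    generate_paired_betas,
    generate_read_table,
    sample_donors,
    write_fixture,
)


def _noiseless_config(**over):
    base = dict(
        seed=5,
        n_candidate_windows=40,
        n_probes=400,
        planted_hypo=4,
        planted_hyper=0,
        drift_per_year=(0.005, 0.005),
        interval_range=(10.0, 10.0),
        noise_sd=0.0,
        donor_sd=0.0,
        baseline_range=(0.3, 0.5),
    )
    base.update(over)
    return SyntheticConfig(**base)


class TestManifest:
    def test_planted_windows_cover_enough_probes(self):
        cfg = SyntheticConfig(
            seed=1, n_candidate_windows=10, n_probes=100, planted_hypo=2,
            planted_hyper=0, probes_per_planted_window=3,
        )
        probes, clusters, truth, tracks, genes = generate_manifest(cfg)
        assert len(truth) == 2
        for t in truth.itertuples():
            inside = probes[
                (probes.chrom == t.chrom)
                & (probes.pos - 1 >= t.start)
                & (probes.pos - 1 < t.end)
            ]
            assert len(inside) >= 3

    def test_same_seed_gives_identical_manifest(self):
        cfg = SyntheticConfig(
            seed=9, n_candidate_windows=30, n_probes=300, planted_hypo=3,
            planted_hyper=1,
        )
        a = generate_manifest(cfg)
        b = generate_manifest(cfg)
        for left, right in zip(a[:3], b[:3]):
            pd.testing.assert_frame_equal(left, right)

    def test_reference_scale_plants_147_disjoint_truth_regions(self):
        cfg = SyntheticConfig(seed=2, n_candidate_windows=400, n_probes=4000)
        _, _, truth, _, _ = generate_manifest(cfg)
        assert len(truth) == 147
        assert (truth.direction == "hypo").sum() == 139
        assert (truth.direction == "hyper").sum() == 8
        for _, grp in truth.groupby("chrom"):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            order = np.argsort(starts)
            assert np.all(starts[order][1:] >= ends[order][:-1])  # disjoint

    def test_probes_sorted_by_position(self, small_fixture):
        probes = small_fixture.probes
        for _, grp in probes.groupby("chrom"):
            assert grp["pos"].is_monotonic_increasing

    def test_impossible_placement_raises(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(seed=0, n_candidate_windows=10, planted_hypo=20)
        with pytest.raises(ConfigurationError):
            SyntheticConfig(seed=0, n_candidate_windows=10, n_probes=10)

    def test_most_hypo_truth_windows_near_nucleosome_track(self, small_fixture):
        from spermage.annotate import build_trees, _min_distance

        trees = build_trees(small_fixture.tracks["nucleosome"])
        hypo = small_fixture.truth[small_fixture.truth.direction == "hypo"]
        near = sum(
            _min_distance(trees, t.chrom, t.start, t.end) <= 1000
            for t in hypo.itertuples()
        )
        assert near / len(hypo) > 0.6  # configured fraction is 0.88


class TestPairedBetas:
    def test_noiseless_planted_difference_is_exact(self):
        cfg = _noiseless_config()
        probes, clusters, truth, _, _ = generate_manifest(cfg)
        betas, samples = generate_paired_betas(cfg, probes, clusters)
        planted_clusters = clusters.loc[clusters.direction == "hypo", "cluster_id"]
        pid = probes.loc[probes.cluster_id.isin(planted_clusters), "probe_id"].iloc[0]
        outside = probes.loc[probes.cluster_id == -1, "probe_id"].iloc[0]
        for d in samples.donor_id.unique():
            young, aged = f"{d}_young", f"{d}_aged"
            assert betas.at[pid, aged] - betas.at[pid, young] == pytest.approx(-0.05)
            assert betas.at[outside, aged] - betas.at[outside, young] == pytest.approx(0.0)

    def test_values_lie_in_unit_interval(self, small_fixture):
        v = small_fixture.betas.to_numpy()
        assert v.min() >= 0.0 and v.max() <= 1.0

    def test_per_window_drift_matches_configuration_on_average(self):
        recovered = []
        for seed in range(4):
            cfg = SyntheticConfig(
                seed=seed, n_candidate_windows=60, n_probes=600,
                planted_hypo=10, planted_hyper=0,
                drift_per_year=(0.004, 0.004),
            )
            probes, clusters, truth, _, _ = generate_manifest(cfg)
            betas, samples = generate_paired_betas(cfg, probes, clusters)
            ages = samples.set_index("sample_id").age
            planted = clusters.loc[clusters.direction == "hypo", "cluster_id"]
            sel = probes.cluster_id.isin(planted).to_numpy()
            b = betas.to_numpy()[sel]
            for d in samples.donor_id.unique():
                cols = list(betas.columns)
                young_i = cols.index(f"{d}_young")
                aged_i = cols.index(f"{d}_aged")
                interval = ages[f"{d}_aged"] - ages[f"{d}_young"]
                recovered.append(np.mean(b[:, aged_i] - b[:, young_i]) / interval)
        assert np.mean(recovered) == pytest.approx(-0.004, abs=5e-4)

    def test_same_seed_bitwise_identical_files(self, small_config, small_fixture, tmp_path):
        import filecmp

        again = generate_fixture(small_config)
        p1 = write_fixture(small_fixture, tmp_path / "a")
        p2 = write_fixture(again, tmp_path / "b")
        for name in p1:
            assert filecmp.cmp(p1[name], p2[name], shallow=False), name


class TestReadTable:
    def test_bimodal_mixture_produces_bimodal_counts(self):
        cfg = SyntheticConfig(seed=3, n_amplicons=1, reads_per_sample=200,
                              minority_read_frac=0.0)
        patterns = [([(0.5, 0.1), (0.5, 0.9)], [(1.0, 0.1)])]
        reads, samples = generate_read_table(cfg, patterns=patterns)
        young_ids = set(samples.loc[samples.age < 45, "sample_id"])
        meth = reads[reads.sample_id.isin(young_ids)]["call_string"].map(
            lambda s: s.count("M")
        )
        low = (meth <= 2).mean()
        high = (meth >= 6).mean()
        assert low > 0.3 and high > 0.3 and ((meth > 2) & (meth < 6)).mean() < 0.25

    def test_zero_mean_component_gives_all_unmethylated(self):
        cfg = SyntheticConfig(seed=4, n_amplicons=1, reads_per_sample=50,
                              minority_read_frac=0.0)
        patterns = [([(1.0, 0.0)], [(1.0, 0.0)])]
        reads, _ = generate_read_table(cfg, patterns=patterns)
        assert not reads["call_string"].str.contains("M").any()

    def test_seeded_determinism(self):
        cfg = SyntheticConfig(seed=6, n_amplicons=2, reads_per_sample=30)
        a, _ = generate_read_table(cfg)
        b, _ = generate_read_table(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_minority_lengths_injected(self, small_fixture):
        lengths = small_fixture.reads["call_string"].str.len()
        frac_long = (lengths == lengths.min() + 1).mean()
        assert 0.0 < frac_long < 0.10


class TestDiseaseAndGlobalTables:
    def test_gene_without_associations_absent_from_universe(self):
        from spermage.enrich import load_associations

        cfg = SyntheticConfig(seed=7, n_genes=50, n_diseases=3, association_rate=0.2)
        table = load_associations(generate_disease_table(cfg))
        universe = table.universe
        all_genes = {f"GENE{i:05d}" for i in range(50)}
        assert universe < all_genes  # some genes drew no association at all

    def test_global_table_recovers_planted_trend(self):
        from spermage.preprocess import global_trend

        cfg = SyntheticConfig(seed=8, global_drift_per_year=0.002)
        trend = global_trend(generate_global_table(cfg))
        assert trend.n_samples == 34
        assert trend.slope == pytest.approx(0.002, abs=0.001)
        assert trend.regression_p < 0.05


class TestDonorCohort:
    def test_paired_design_with_configured_intervals(self):
        cfg = SyntheticConfig(seed=10)
        samples = sample_donors(cfg)
        assert len(samples) == 34
        for _, grp in samples.groupby("donor_id"):
            assert set(grp.group) == {"young", "aged"}
            young = grp.loc[grp.group == "young", "age"].item()
            aged = grp.loc[grp.group == "aged", "age"].item()
            assert 23 <= young <= 56
            assert 8.9 <= aged - young <= 19.1
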