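"""Synthetic-assay generator: planted truths, read simulation, bin sorting."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from mprasplice import simgen
from mprasplice.simgen import SimConfig


def make_inputs(n, seed=0, duplicates=0):
    rng = np.random.default_rng(seed)
    feats = pd.DataFrame(
        {"f1": rng.normal(size=n), "f2": rng.normal(size=n)},
        index=[f"v{i}" for i in range(n)],
    )
    seqs = [f"SEQ{i}" for i in range(n - duplicates)] + ["SEQDUP"] * duplicates
    manifest = pd.DataFrame({"variant_id": feats.index, "variable_region": seqs})
    return manifest, feats


class TestPlantTruth:
    def test_zero_effects_zero_noise_gives_intercept(self):
        manifest, feats = make_inputs(50)
        cfg = SimConfig(n_variants=50, rna_noise_sd=0.0, intercept=1.5, seed=1)
        truth = simgen.plant_truth(manifest, feats, cfg)
        np.testing.assert_allclose(truth["true_rna_logratio"], 1.5)

    def test_identical_sequences_share_sigma(self):
        manifest, feats = make_inputs(40, duplicates=10)
        cfg = SimConfig(n_variants=40, noise_encoded=True, seed=2)
        truth = simgen.plant_truth(manifest, feats, cfg)
        dup = truth[manifest["variable_region"].to_numpy() == "SEQDUP"]
        assert dup["true_sigma"].nunique() == 1

    def test_effect_sign_matches_coefficient(self):
        manifest, feats = make_inputs(2000, seed=3)
        cfg = SimConfig(
            n_variants=2000, effect_sizes={"f1": 1.0, "f2": -0.5}, seed=3
        )
        truth = simgen.plant_truth(manifest, feats, cfg)
        r1 = st.pearsonr(feats["f1"], truth["true_rna_logratio"])[0]
        r2 = st.pearsonr(feats["f2"], truth["true_rna_logratio"])[0]
        assert r1 > 0.3 and r2 < -0.15

    def test_missing_feature_raises(self):
        manifest, feats = make_inputs(10)
        cfg = SimConfig(n_variants=10, effect_sizes={"nope": 1.0})
        with pytest.raises(KeyError):
            simgen.plant_truth(manifest, feats, cfg)

    def test_protein_link_saturates(self):
        manifest, feats = make_inputs(100)
        cfg = SimConfig(n_variants=100, intercept=50.0, rna_noise_sd=0.0)
        truth = simgen.plant_truth(manifest, feats, cfg)
        np.testing.assert_allclose(
            truth["true_protein_value"], cfg.protein_a + cfg.protein_b, atol=1e-9
        )


class TestRnaReads:
    def test_symmetric_at_zero_ratio(self):
        manifest, feats = make_inputs(300)
        cfg = SimConfig(n_variants=300, rna_noise_sd=0.0, intercept=0.0, seed=4)
        truth = simgen.plant_truth(manifest, feats, cfg)
        iso = simgen.simulate_rna_reads(truth, cfg)
        frac = iso["count_iso_up"].sum() / (iso["count_iso_up"] + iso["count_iso_down"]).sum()
        assert frac == pytest.approx(0.5, abs=0.01)

    def test_extreme_ratio_one_isoform(self):
        manifest, feats = make_inputs(20)
        cfg = SimConfig(n_variants=20, rna_noise_sd=0.0, intercept=40.0, seed=5)
        truth = simgen.plant_truth(manifest, feats, cfg)
        iso = simgen.simulate_rna_reads(truth, cfg)
        assert (iso["count_iso_down"] == 0).all()

    def test_logratio_recovered_at_depth(self):
        # depth 10,000: estimated log2 ratio within +-0.1 of truth for |r|<=4
        manifest, feats = make_inputs(1000, seed=6)
        cfg = SimConfig(n_variants=1000, rna_noise_sd=2.0, seed=6)
        truth = simgen.plant_truth(manifest, feats, cfg)
        truth["true_rna_logratio"] = truth["true_rna_logratio"].clip(-4, 4)
        iso = simgen.simulate_rna_reads(truth, cfg)
        est = np.log2((iso["count_iso_up"] + 1) / (iso["count_iso_down"] + 1))
        err = np.abs(est - truth["true_rna_logratio"])
        assert np.quantile(err, 0.95) < 0.1


@pytest.fixture(scope="module")
def sim():
    manifest, feats = make_inputs(300, seed=7)
    cfg = SimConfig(
        n_variants=300,
        cells_per_variant=800,
        reads_per_variant_bins=800,
        effect_sizes={"f1": 1.0},
        seed=7,
    )
    truth = simgen.plant_truth(manifest, feats, cfg)
    profiles, medians, boundaries = simgen.simulate_sorted_bins(truth, cfg)
    return cfg, truth, profiles, medians, boundaries


class TestSortedBins:
    def test_occupancy_within_bounds(self, sim):
        cfg, truth, profiles, medians, boundaries = sim
        rng = np.random.default_rng(cfg.seed + 2)
        mu = truth["true_protein_value"].to_numpy()
        sigma = truth["true_sigma"].to_numpy()
        values = rng.normal(mu[:, None], sigma[:, None], size=(len(mu), cfg.cells_per_variant))
        idx = np.searchsorted(boundaries, values.ravel())
        occ = np.bincount(idx, minlength=cfg.n_bins) / values.size
        assert occ.max() <= 0.10 and occ.min() >= 0.01

    def test_bin_medians_increasing(self, sim):
        _, _, _, medians, _ = sim
        m = medians["median_log2_ratio"].to_numpy()
        assert np.all(np.diff(m) > 0)

    def test_reads_sum_to_multinomial_totals(self, sim):
        cfg, truth, profiles, _, _ = sim
        bin_cols = [c for c in profiles.columns if c.startswith("bin_")]
        total = profiles[bin_cols].to_numpy().sum()
        expected = cfg.reads_per_variant_bins * cfg.n_variants
        assert abs(total - expected) <= cfg.n_bins  # rounding of per-bin depths

    def test_zero_sigma_concentrates_reads(self):
        manifest, feats = make_inputs(60, seed=8)
        cfg = SimConfig(
            n_variants=60,
            cells_per_variant=500,
            reads_per_variant_bins=500,
            sigma_bounds=(1e-6, 1.0),
            sigma_log_mean=-20.0,
            sigma_log_sd=0.0,
            effect_sizes={"f1": 1.0},
            seed=8,
        )
        truth = simgen.plant_truth(manifest, feats, cfg)
        profiles, _, _ = simgen.simulate_sorted_bins(truth, cfg)
        counts = profiles[[c for c in profiles.columns if c.startswith("bin_")]].to_numpy()
        for row in counts:
            occupied = np.nonzero(row)[0]
            assert len(occupied) <= 2
            if len(occupied) == 2:
                assert occupied[1] - occupied[0] == 1  # adjacent bins

    def test_weighted_mean_recovers_protein_value(self, sim):
        cfg, truth, profiles, medians, _ = sim
        counts = profiles[[c for c in profiles.columns if c.startswith("bin_")]].to_numpy(float)
        m = medians["median_log2_ratio"].to_numpy()
        # depth-correct by bin totals then renormalize per variant
        bt = counts.sum(axis=0)
        w = counts / np.where(bt > 0, bt, 1) * (bt / bt.sum())
        w = w / w.sum(axis=1, keepdims=True)
        est = w @ m
        err = np.abs(est - truth["true_protein_value"].to_numpy())
        assert np.median(err) < 0.15

    def test_infeasible_occupancy_bounds_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_bins=4, bin_occupancy_bounds=(0.01, 0.10))


class TestReproducibility:
    def test_bit_identical_for_same_seed(self):
        manifest, feats = make_inputs(80, seed=9)
        cfg = SimConfig(n_variants=80, cells_per_variant=200, reads_per_variant_bins=300, seed=9)
        out1 = simgen.simulate_assay(manifest, feats, cfg)
        out2 = simgen.simulate_assay(manifest, feats, cfg)
        for a, b in zip(out1[:4], out2[:4]):
            pd.testing.assert_frame_equal(a, b)

    def test_counts_nonnegative_integers(self):
        manifest, feats = make_inputs(50, seed=10)
        cfg = SimConfig(n_variants=50, cells_per_variant=200, reads_per_variant_bins=300, seed=10)
        _, iso, profiles, _, _ = simgen.simulate_assay(manifest, feats, cfg)
        assert (iso[["count_iso_up", "count_iso_down", "rna_reads", "dna_reads"]] >= 0).all().all()
        bins = profiles[[c for c in profiles.columns if c.startswith("bin_")]]
        assert (bins >= 0).all().all() and bins.to_numpy().dtype.kind == "i"
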