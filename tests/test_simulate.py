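import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import creland
from creland.errors import ConfigError
from creland.simulate import (SimConfig, simulate_dataset, simulate_expression,
                              simulate_peaks, simulate_signal_tracks,
                              simulate_state_maps, true_accessible_intervals,
                              write_fixture_bundle)


def tiny_config(**kw):
    defaults = dict(n_cell_types=3, chrom_lengths={"chr1": 200_000}, n_genes=20,
                    seed=0)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestConfigValidation:
    def test_cyclic_lineage_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(n_cell_types=3, lineage_tree=[None, 2, 1])

    def test_two_roots_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(n_cell_types=3, lineage_tree=[None, None, 0])

    def test_quiescent_target_bounds(self):
        with pytest.raises(ConfigError):
            tiny_config(quiescent_target=1.5)

    def test_quiescent_state_cannot_be_accessible(self):
        with pytest.raises(ConfigError):
            tiny_config(accessible_states={0, 9})

    def test_beta_reference_entry_must_be_zero(self):
        beta = np.ones(27)
        with pytest.raises(ConfigError):
            tiny_config(beta_ccre_truth=beta)


class TestStateMaps:
    def test_single_state_degenerate_genome(self):
        cfg = tiny_config(n_states=1, accessible_states=frozenset(),
                          emission_means=np.zeros((1, 8)),
                          beta_promoter_truth=np.zeros(1),
                          beta_ccre_truth=np.zeros(1))
        truth = simulate_state_maps(cfg)
        for seg in truth.state_maps.values():
            frac = creland.state_coverage_fractions(seg)
            assert frac[0] == 1.0

    def test_full_inheritance_copies_parent_exactly(self):
        cfg = tiny_config(n_cell_types=2, lineage_tree=[None, 0], inherit_prob=1.0)
        truth = simulate_state_maps(cfg)
        parent, child = truth.state_maps["ct00"], truth.state_maps["ct01"]
        assert child == parent or all(
            np.array_equal(truth.bin_states["ct00"][c], truth.bin_states["ct01"][c])
            for c in truth.bin_states["ct00"])

    def test_maps_tile_genome_without_overlap(self):
        truth = simulate_state_maps(tiny_config())
        for seg in truth.state_maps.values():
            assert seg.total_bases == 200_000
            for starts, ends, _ in seg.data.values():
                assert starts[0] == 0
                assert (starts[1:] == ends[:-1]).all()

    def test_quiescent_fraction_converges_to_target(self):
        # Monte-Carlo check against the generator's own stationary distribution
        for seed in range(10):
            cfg = SimConfig(n_cell_types=3, chrom_lengths={"chr1": 10_000_000},
                            seed=seed)
            truth = simulate_state_maps(cfg)
            for seg in truth.state_maps.values():
                frac = creland.state_coverage_fractions(seg)[0]
                assert abs(frac - cfg.quiescent_target) <= 0.03


class TestPeaks:
    def test_noiseless_replicates_equal_truth(self):
        cfg = tiny_config(peak_dropout=0.0, peak_jitter=0)
        truth = simulate_state_maps(cfg)
        true_accessible_intervals(truth)
        peaks = simulate_peaks(truth)
        for ct in truth.cell_types:
            for rep in peaks[ct]:
                pd.testing.assert_frame_equal(rep, truth.true_accessibility[ct])

    def test_no_accessible_states_means_no_peaks(self):
        cfg = tiny_config(accessible_states=frozenset())
        truth = simulate_state_maps(cfg)
        true_accessible_intervals(truth)
        peaks = simulate_peaks(truth)
        assert all(len(rep) == 0 for reps in peaks.values() for rep in reps)

    def test_dropout_retention_matches_binomial_rate(self):
        # binomial oracle on the generator's own dropout draws
        rates = []
        for seed in range(5):
            cfg = SimConfig(n_cell_types=2, chrom_lengths={"chr1": 48_000_000},
                            peak_dropout=0.2, peak_jitter=0, n_replicates=1,
                            seed=seed)
            truth = simulate_state_maps(cfg)
            true_accessible_intervals(truth)
            peaks = simulate_peaks(truth)
            for ct in truth.cell_types:
                n_true = len(truth.true_accessibility[ct])
                assert n_true > 1000
                rates.append(len(peaks[ct][0]) / n_true)
        assert all(abs(r - 0.8) <= 0.04 for r in rates)

    def test_peaks_stay_inside_segmented_genome(self):
        truth = simulate_dataset(tiny_config(seed=3))
        for reps in truth.peaks.values():
            for rep in reps:
                assert (rep["start"] >= 0).all()
                assert (rep["end"] <= 200_000).all()
                assert (rep["start"] < rep["end"]).all()


class TestExpression:
    def test_null_model_gives_constant_expression(self):
        cfg = tiny_config(beta_promoter_truth=np.zeros(27),
                          beta_ccre_truth=np.zeros(27),
                          expression_intercept=5.0, expression_noise_sd=0.0)
        truth = simulate_dataset(cfg)
        np.testing.assert_allclose(truth.expression_log2.to_numpy(), 5.0)

    def test_noiseless_matrix_reproduces_linear_model(self):
        cfg = tiny_config(expression_noise_sd=0.0, n_genes=50)
        truth = simulate_dataset(cfg)
        # independent re-evaluation of the stated formula from truth inputs
        pooled = np.zeros_like(truth.prom_proportions)
        links = truth.true_links
        np.add.at(pooled, links["gene_idx"].to_numpy(),
                  truth.ccre_proportions[links["ccre_idx"].to_numpy()])
        n_links = truth.genes["n_links"].to_numpy()
        nz = n_links > 0
        pooled[nz] /= n_links[nz, None, None]
        want = (cfg.expression_intercept
                + truth.prom_proportions @ cfg.beta_promoter_truth
                + pooled @ cfg.beta_ccre_truth)
        np.testing.assert_allclose(truth.expression_log2.to_numpy(), want, atol=1e-12)
        np.testing.assert_allclose(truth.noiseless_log2.to_numpy(), want, atol=1e-12)

    def test_tpm_round_trips_log_scale(self):
        truth = simulate_dataset(tiny_config(seed=5))
        back = np.log2(truth.tpm.to_numpy() + 1.0)
        clipped = np.clip(truth.expression_log2.to_numpy(), 0.0, None)
        np.testing.assert_allclose(back, clipped, atol=1e-9)

    def test_links_lie_within_distance_bound(self):
        truth = simulate_dataset(tiny_config(seed=6, max_link_distance=50_000))
        mids = ((truth.true_ccres["start"] + truth.true_ccres["end"]) // 2).to_numpy()
        tss = truth.genes["tss"].to_numpy()
        links = truth.true_links
        d = np.abs(mids[links["ccre_idx"]] - tss[links["gene_idx"]])
        assert (d <= 50_000).all()


class TestSignals:
    def test_noiseless_signal_equals_emission_mean(self):
        cfg = tiny_config(signal_noise_sd=0.0)
        truth = simulate_state_maps(cfg)
        tracks = simulate_signal_tracks(truth, features=["atac"])
        for ct in truth.cell_types:
            _, _, values = tracks[ct]["atac"]["chr1"]
            want = cfg.emission_means[truth.bin_states[ct]["chr1"], 0]
            np.testing.assert_array_equal(values, want)

    def test_identical_maps_correlate_perfectly_without_noise(self):
        cfg = tiny_config(n_cell_types=2, lineage_tree=[None, 0], inherit_prob=1.0,
                          signal_noise_sd=0.0)
        truth = simulate_state_maps(cfg)
        tracks = simulate_signal_tracks(truth, features=["h3k4me3"])
        a = tracks["ct00"]["h3k4me3"]["chr1"][2]
        b = tracks["ct01"]["h3k4me3"]["chr1"][2]
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(1.0)

    def test_two_state_separation_matches_gaussian_overlap(self):
        # closed-form normal-tail oracle for nearest-mean classification
        emission = np.array([[0.0], [5.0]])
        cfg = SimConfig(n_cell_types=1, lineage_tree=[None], n_states=2,
                        chrom_lengths={"chr1": 4_000_000}, quiescent_target=0.5,
                        accessible_states={1}, feature_names=("atac",),
                        emission_means=emission, signal_noise_sd=1.0,
                        beta_promoter_truth=np.array([0.0, 1.0]),
                        beta_ccre_truth=np.array([0.0, 1.0]), seed=2)
        truth = simulate_state_maps(cfg)
        tracks = simulate_signal_tracks(truth, features=["atac"])
        values = tracks["ct00"]["atac"]["chr1"][2]
        states = truth.bin_states["ct00"]["chr1"]
        predicted = (values > 2.5).astype(int)
        err = (predicted != states).mean()
        # truncation at 0 only reduces state-0 errors, so compare within 2%
        expected = norm.sf(2.5)
        assert abs(err - expected) <= 0.02


class TestFixtureBundle:
    def test_same_seed_reproduces_identical_manifest(self, tmp_path):
        cfg = tiny_config(seed=9)
        m1 = write_fixture_bundle(simulate_dataset(cfg), tmp_path / "a", signals=True)
        m2 = write_fixture_bundle(simulate_dataset(tiny_config(seed=9)), tmp_path / "b",
                                  signals=True)
        a = m1.read_text().splitlines()
        b = m2.read_text().splitlines()
        assert [line.split()[0] for line in a] == [line.split()[0] for line in b]

    def test_every_bed_record_is_valid(self, tmp_path, small_truth):
        out = tmp_path / "bundle"
        write_fixture_bundle(small_truth, out, signals=False)
        lengths = small_truth.config.chrom_lengths
        for bed in out.rglob("*.bed"):
            df = pd.read_csv(bed, sep="\t", header=None)
            if len(df) == 0:
                continue
            assert (df[1] >= 0).all()
            assert (df[1] < df[2]).all()
            assert all(e <= lengths[c] for c, e in zip(df[0], df[2]))

    def test_empty_genome_yields_valid_empty_files(self, tmp_path):
        cfg = SimConfig(n_cell_types=2, chrom_lengths={"chr1": 100}, bin_size=200,
                        n_genes=0, seed=0)
        truth = simulate_dataset(cfg)
        manifest = write_fixture_bundle(truth, tmp_path / "empty", signals=False)
        assert manifest.exists()
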