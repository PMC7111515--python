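import numpy as np
import pandas as pd
import pytest

import creland
from creland import erp as E
from creland.simulate import SimConfig, simulate_dataset


def make_dataset(n_genes=4, n_ccres=6, T=4, S=5, seed=0, proportions=None,
                 expr=None, pairs=None):
    """A hand-buildable dataset with direct control over proportions/pairs."""
    rng = np.random.default_rng(seed)
    genes = pd.DataFrame({"gene": [f"g{i}" for i in range(n_genes)],
                          "chrom": "chr1",
                          "tss": np.arange(n_genes) * 10_000 + 5_000,
                          "strand": "+"})
    ccres = pd.DataFrame({"chrom": "chr1",
                          "start": np.arange(n_ccres) * 5_000,
                          "end": np.arange(n_ccres) * 5_000 + 400})
    if proportions is None:
        raw = rng.random((n_ccres, T, S))
        proportions = raw / raw.sum(axis=2, keepdims=True)
    majority = proportions.argmax(axis=2)
    prom = rng.random((n_genes, T, S))
    prom = prom / prom.sum(axis=2, keepdims=True)
    if pairs is None:
        pairs = pd.DataFrame({"gene_idx": np.repeat(np.arange(n_genes), 2),
                              "ccre_idx": rng.integers(0, n_ccres, 2 * n_genes)})
        pairs["distance"] = 1000
        pairs["screen_r"] = np.nan
        pairs["selected"] = True
    if expr is None:
        expr = rng.random((n_genes, T)) * 4
    return E.ErpDataset(genes=genes, expr_log2=expr, cell_types=[f"ct{t}" for t in range(T)],
                        ccres=ccres, proportions=proportions, majority=majority,
                        prom_proportions=prom, pairs=pairs, n_states=S)


class TestCategorizeGenes:
    def test_rule_extremes(self):
        tpm = pd.DataFrame({"a": [0.0, 100.0], "b": [0.0, 100.0], "c": [0.0, 100.0]},
                           index=["silent", "house"])
        cats = E.categorize_genes(tpm)
        assert cats["silent"] == "consistently_low"
        assert cats["house"] == "consistently_high"

    def test_matches_direct_rule_application(self):
        rng = np.random.default_rng(1)
        tpm = pd.DataFrame(rng.random((50, 5)) * 30, columns=list("abcde"))
        cats = E.categorize_genes(tpm, low_threshold=1.0, variability_threshold=1.0)
        expressed = tpm > 1.0
        spread = (np.log2(tpm + 1).max(axis=1) - np.log2(tpm + 1).min(axis=1))
        for g in tpm.index:
            n = expressed.loc[g].sum()
            if n == 0:
                want = "consistently_low"
            elif n == 5:
                want = "consistently_high" if spread[g] < 1.0 else "differentially_high"
            else:
                want = "differentially_low"
            assert cats[g] == want


class TestAssignCandidates:
    def test_distance_bound_is_inclusive_and_chromosome_restricted(self):
        genes = pd.DataFrame({"gene": ["g"], "chrom": ["chr1"], "tss": [1_000_100],
                              "strand": ["+"]})
        ccres = pd.DataFrame({
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [0, 2_000_200, 1_000_000],
            "end": [200, 2_000_400, 1_000_200],
        })  # midpoints: 100 (exactly 1 Mb away), 2,000,300 (too far), other chrom
        pairs = E.assign_candidates(genes, ccres, max_distance=1_000_000)
        assert set(pairs["ccre_idx"]) == {0}

    def test_promoter_overlapping_ccres_excluded_from_distal_set(self):
        genes = pd.DataFrame({"gene": ["g"], "chrom": ["chr1"], "tss": [10_000],
                              "strand": ["+"]})
        ccres = pd.DataFrame({"chrom": ["chr1", "chr1"],
                              "start": [9_500, 20_000], "end": [10_200, 20_400]})
        pairs = E.assign_candidates(genes, ccres, promoter_window=1000)
        assert set(pairs["ccre_idx"]) == {1}

    def test_matches_all_pairs_distance_scan(self):
        rng = np.random.default_rng(2)
        genes = pd.DataFrame({"gene": [f"g{i}" for i in range(10)], "chrom": "chr1",
                              "tss": rng.integers(0, 500_000, 10), "strand": "+"})
        ccres = pd.DataFrame({"chrom": "chr1",
                              "start": np.sort(rng.integers(0, 500_000, 30))})
        ccres["end"] = ccres["start"] + 200
        pairs = E.assign_candidates(genes, ccres, max_distance=50_000,
                                    promoter_window=0)
        got = set(zip(pairs["gene_idx"], pairs["ccre_idx"]))
        mids = (ccres["start"] + ccres["end"]) // 2
        want = {(gi, ci) for gi in range(10) for ci in range(30)
                if abs(mids[ci] - genes.loc[gi, "tss"]) <= 50_000}
        assert got == want


class TestDesignAndScores:
    def test_pooled_vector_is_unweighted_mean(self):
        S = 5
        props = np.zeros((2, 3, S))
        props[0, :, 2] = 1.0  # cCRE 0 fully in state 2
        props[1, :, 4] = 1.0  # cCRE 1 fully in state 4
        pairs = pd.DataFrame({"gene_idx": [0, 0], "ccre_idx": [0, 1],
                              "distance": 0, "screen_r": np.nan, "selected": True})
        ds = make_dataset(n_genes=1, n_ccres=2, T=3, S=S, proportions=props, pairs=pairs)
        pooled, n_sel = E._pooled_proportions(ds, np.array([True, True]))
        assert n_sel[0] == 2
        want = (np.eye(S)[2] + np.eye(S)[4]) / 2
        np.testing.assert_allclose(pooled[0, 0], want)

    def test_erp_score_of_pure_state_element(self):
        ds = make_dataset()
        model = E.ErpModel(mode="ccre", beta_promoter=np.zeros(5),
                           beta_ccre=np.array([0.0, 1.0, 2.0, 3.0, 4.0]),
                           intercept=0.0, reference_state=0, n_states=5)
        pure = np.eye(5)[3][None, None, :]
        assert model.erp_scores(pure)[0, 0] == pytest.approx(3.0)
        ref = np.eye(5)[0][None, None, :]
        assert model.erp_scores(ref)[0, 0] == pytest.approx(0.0)

    def test_erp_score_matches_dot_product_oracle(self):
        rng = np.random.default_rng(3)
        ds = make_dataset(seed=3)
        beta = rng.normal(size=5)
        beta[0] = 0.0
        model = E.ErpModel(mode="ccre", beta_promoter=np.zeros(5), beta_ccre=beta,
                           intercept=0.0, reference_state=0, n_states=5)
        got = model.erp_scores(ds.proportions)
        want = np.einsum("nts,s->nt", ds.proportions, beta)
        np.testing.assert_allclose(got, want, atol=1e-12)


class TestFit:
    def test_constant_response_fits_intercept_only(self):
        ds = make_dataset(expr=np.full((4, 4), 3.25))
        model = E.fit_erp(ds, mode="both")
        assert model.intercept == pytest.approx(3.25, abs=1e-8)
        np.testing.assert_allclose(model.beta_promoter, 0.0, atol=1e-7)
        np.testing.assert_allclose(model.beta_ccre, 0.0, atol=1e-7)

    def test_rank_deficient_design_warns_but_predicts(self, caplog):
        ds = make_dataset(seed=4)
        # duplicate pair rows alias the pooled block against itself
        ds.pairs = pd.concat([ds.pairs, ds.pairs], ignore_index=True)
        dup = E.fit_erp(ds, mode="ccre")
        pred = E.predict_expression(ds, dup)
        assert np.isfinite(pred).all()

    def test_noiseless_truth_recovered(self):
        cfg = SimConfig(seed=1, n_cell_types=6, n_genes=200,
                        chrom_lengths={"chr1": 1_500_000, "chr2": 1_500_000},
                        expression_noise_sd=0.0)
        truth = simulate_dataset(cfg)
        ds = E.dataset_from_truth(truth)
        model = E.fit_erp(ds, mode="both")
        assert np.abs(model.beta_promoter - cfg.beta_promoter_truth).max() < 1e-6
        assert np.abs(model.beta_ccre - cfg.beta_ccre_truth).max() < 1e-6


class TestPredictionIdentity:
    def test_mean_of_erp_equals_pooled_design_route(self):
        for seed in range(10):
            ds = make_dataset(seed=seed, n_genes=6, n_ccres=10)
            model = E.fit_erp(ds, mode="ccre")
            a = E.predict_expression(ds, model)
            b = E.predict_mean_erp(ds, model)
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_zero_coefficients_predict_intercept(self):
        ds = make_dataset(seed=11)
        model = E.ErpModel(mode="ccre", beta_promoter=np.zeros(5),
                           beta_ccre=np.zeros(5), intercept=1.5,
                           reference_state=0, n_states=5)
        np.testing.assert_allclose(E.predict_mean_erp(ds, model), 1.5)

    def test_fitted_values_invariant_to_reference_state(self):
        for seed in range(5):
            ds = make_dataset(seed=seed, n_genes=6, n_ccres=10)
            m0 = E.fit_erp(ds, mode="both", reference_state=0)
            m3 = E.fit_erp(ds, mode="both", reference_state=3)
            p0 = E.predict_expression(ds, m0)
            p3 = E.predict_expression(ds, m3)
            np.testing.assert_allclose(p0, p3, atol=1e-9)


class TestScreen:
    def test_proxy_equal_to_expression_is_selected(self):
        pairs_in = pd.DataFrame({"gene_idx": np.arange(4), "ccre_idx": np.arange(4),
                                 "distance": 0, "screen_r": np.nan, "selected": True})
        ds = make_dataset(seed=5, T=5, pairs=pairs_in)
        proxy = np.zeros_like(ds.proportions[:, :, 0])
        for _, row in ds.pairs.iterrows():
            proxy[row["ccre_idx"]] = ds.expr_log2[row["gene_idx"]]
        pairs = E.correlation_filter(ds, proxy, min_abs_r=0.99)
        assert pairs["selected"].all()
        np.testing.assert_allclose(pairs["screen_r"], 1.0, atol=1e-9)

    def test_constant_proxy_deselected_with_undefined_r(self):
        ds = make_dataset(seed=6, T=5)
        proxy = np.ones_like(ds.proportions[:, :, 0])
        pairs = E.correlation_filter(ds, proxy, min_abs_r=0.0)
        assert not pairs["selected"].any()
        assert pairs["screen_r"].isna().all()

    def test_matches_correlation_formula_oracle(self):
        ds = make_dataset(seed=7, T=6)
        rng = np.random.default_rng(7)
        proxy = rng.random((len(ds.ccres), 6))
        pairs = E.correlation_filter(ds, proxy, min_abs_r=0.0)
        for _, row in pairs.iterrows():
            want = np.corrcoef(proxy[row["ccre_idx"]],
                               ds.expr_log2[row["gene_idx"]])[0, 1]
            assert row["screen_r"] == pytest.approx(want, abs=1e-12)

    def test_too_few_cell_types_rejected(self):
        ds = make_dataset(T=2)
        with pytest.raises(ValueError):
            E.correlation_filter(ds, np.zeros((6, 2)))


class TestSubselect:
    def test_reference_state_everywhere_pair_never_kept(self):
        cfg = SimConfig(seed=2, n_cell_types=6, n_genes=30,
                        chrom_lengths={"chr1": 1_000_000})
        truth = simulate_dataset(cfg)
        ds = E.dataset_from_truth(truth)
        # append a synthetic all-reference cCRE paired to gene 0
        n = len(ds.ccres)
        ds.ccres = pd.concat([ds.ccres, pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [200]})], ignore_index=True)
        ref_prop = np.zeros((1, ds.n_cell_types, ds.n_states))
        ref_prop[0, :, 0] = 1.0
        ds.proportions = np.concatenate([ds.proportions, ref_prop])
        ds.majority = np.concatenate([ds.majority,
                                      np.zeros((1, ds.n_cell_types), dtype=np.int64)])
        extra = pd.DataFrame({"gene_idx": [0], "ccre_idx": [n], "distance": [0],
                              "screen_r": [np.nan], "selected": [True]})
        ds.pairs = pd.concat([ds.pairs, extra], ignore_index=True)
        sub = E.subselect(ds)
        assert not sub.pairs["selected"].iloc[-1]

    def test_noiseless_truth_pairs_all_retained(self):
        cfg = SimConfig(seed=3, n_cell_types=8, n_genes=60,
                        chrom_lengths={"chr1": 1_500_000}, expression_noise_sd=0.0)
        truth = simulate_dataset(cfg)
        ds = E.dataset_from_truth(truth)
        sub = E.subselect(ds)
        kept = sub.pairs["selected"].to_numpy()
        assert kept.mean() > 0.95
        assert np.abs(sub.model.beta_ccre - cfg.beta_ccre_truth).max() < 1e-6

    def test_deterministic_for_fixed_inputs(self):
        cfg = SimConfig(seed=4, n_cell_types=6, n_genes=40,
                        chrom_lengths={"chr1": 1_000_000})
        truth = simulate_dataset(cfg)
        ds = E.dataset_from_truth(truth)
        ds.pairs = E.add_distractor_pairs(ds, n_per_gene=10, seed=1).drop(columns="is_true")
        a = E.subselect(ds).pairs["selected"]
        b = E.subselect(ds).pairs["selected"]
        pd.testing.assert_series_equal(a, b)


class TestLooEvaluate:
    def test_perfect_predictions_score_one(self):
        cfg = SimConfig(seed=5, n_cell_types=6, n_genes=150,
                        chrom_lengths={"chr1": 1_500_000}, expression_noise_sd=0.0)
        truth = simulate_dataset(cfg)
        ds = E.dataset_from_truth(truth)
        ev = E.loo_evaluate(ds, mode="both", selection="given")
        assert (ev["adjusted_r2"] > 0.999).all()

    def test_mean_prediction_gives_zero_r_squared(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        assert E._r_squared(obs, np.full(4, obs.mean())) == pytest.approx(0.0)
        assert E.adjusted_r_squared(0.0, 4, 2) <= 0.0

    def test_adjusted_r2_undefined_when_underdetermined(self):
        assert np.isnan(E.adjusted_r_squared(0.9, n=3, p=5))

    def test_fold_internal_selection_pipeline_runs(self):
        cfg = SimConfig(seed=9, n_cell_types=6, n_genes=40,
                        chrom_lengths={"chr1": 800_000})
        truth = simulate_dataset(cfg)
        ds = E.dataset_from_truth(truth)
        ds.pairs = E.add_distractor_pairs(ds, n_per_gene=5, seed=2).drop(columns="is_true")
        ev = E.loo_evaluate(ds, mode="ccre", selection="pipeline", min_abs_r=0.2,
                            subselect_kwargs={"max_iter": 2, "n_starts": 2})
        assert len(ev) == 6
        assert ev["adjusted_r2"].notna().all()

    def test_category_wise_rows_cover_categories(self):
        cfg = SimConfig(seed=6, n_cell_types=6, n_genes=150,
                        chrom_lengths={"chr1": 1_500_000})
        truth = simulate_dataset(cfg)
        ds = E.dataset_from_truth(truth)
        ev = E.loo_evaluate(ds, mode="ccre", by_category=True, selection="given")
        assert set(ev["category"]) <= set(E.CATEGORIES)
        assert (ev.groupby("left_out").size() <= 4).all()


class TestExportPairs:
    def make_scored(self):
        ds = make_dataset(seed=8, n_genes=3, n_ccres=6, T=4)
        model = E.fit_erp(ds, mode="ccre")
        return ds, model

    def test_zero_threshold_exports_all_selected(self):
        ds, model = self.make_scored()
        table = E.export_pairs(ds, model, erp_threshold=0.0)
        assert len(table) == int(ds.pairs["selected"].sum())

    def test_tad_restriction_drops_cross_tad_pairs(self):
        ds, model = self.make_scored()
        # single TAD covering only the first gene's neighbourhood
        tads = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [7_000]})
        table = E.export_pairs(ds, model, erp_threshold=0.0, tads=tads)
        mids = (table["ccre_start"] + table["ccre_end"]) // 2
        tss = ds.genes.set_index("gene")["tss"]
        for _, row in table.iterrows():
            lo = min(mids[row.name], tss[row["gene"]])
            hi = max(mids[row.name], tss[row["gene"]])
            assert row["same_tad"] == (lo >= 0 and hi < 7_000)
        only = E.export_pairs(ds, model, erp_threshold=0.0, tads=tads,
                              same_tad_only=True)
        assert only["same_tad"].all()

    def test_threshold_matches_direct_scan(self):
        ds, model = self.make_scored()
        erp = model.erp_scores(ds.proportions)
        table = E.export_pairs(ds, model, erp_threshold=0.4)
        sel = ds.pairs[ds.pairs["selected"]].reset_index(drop=True)
        want = (np.abs(erp[sel["ccre_idx"].to_numpy()]) >= 0.4).any(axis=1)
        assert len(table) == int(want.sum())
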