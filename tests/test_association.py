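"""Residualization, PC covariates, interaction model, BH and lambda."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ebdeconv import (
    BulkMatrix,
    ProportionMatrix,
    celltype_association,
    compute_lambda,
    draw_proportions,
    make_bulk,
    make_phenotype,
    pca_covariates,
    permutation_null,
    residualize,
    run_twas,
)
from ebdeconv.association import CellTypeAssociation
from ebdeconv.simulate import BetaSpec


def _props(w, samples=None, celltypes=None) -> ProportionMatrix:
    w = np.asarray(w, dtype=float)
    samples = samples or [f"s{i}" for i in range(w.shape[0])]
    celltypes = celltypes or [f"ct{i}" for i in range(w.shape[1])]
    return ProportionMatrix(pd.DataFrame(w, index=samples, columns=celltypes))


class TestResidualize:
    def test_intercept_only_centers_rows(self):
        y = np.array([[1.0, 2.0, 3.0, 6.0]])
        out = residualize(y, None)
        np.testing.assert_allclose(out, y - 3.0, atol=1e-12)

    def test_perfect_covariate_leaves_zero(self):
        cov = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = 2.5 * cov.T + 1.0
        out = residualize(y, cov)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_hand_projection_four_samples(self):
        # y = (1, 2, 4, 3), covariate x = (0, 1, 2, 3): slope 0.8, intercept 1.3
        y = np.array([[1.0, 2.0, 4.0, 3.0]])
        x = np.array([[0.0], [1.0], [2.0], [3.0]])
        out = residualize(y, x)
        np.testing.assert_allclose(out[0], y[0] - (1.3 + 0.8 * x[:, 0]))

    def test_output_orthogonal_to_covariates(self):
        rng = np.random.default_rng(13)
        y = rng.normal(size=(20, 30))
        cov = rng.normal(size=(30, 3))
        out = residualize(y, cov)
        assert np.max(np.abs(out @ cov)) < 1e-8
        assert np.max(np.abs(out.sum(axis=1))) < 1e-8

    def test_collinear_covariates_named(self):
        cov = pd.DataFrame({"age": [1.0, 2, 3, 4], "age2x": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError, match="age2x"):
            residualize(np.ones((2, 4)), cov)


class TestPCACovariates:
    def test_rank_one_matrix_single_component(self):
        rng = np.random.default_rng(14)
        y = np.outer(rng.normal(size=30), rng.normal(size=20))
        scores = pca_covariates(y, 1)
        # PC1 of a rank-1 standardized matrix carries all the variance
        z = (y - y.mean(1, keepdims=True)) / y.std(1, ddof=1, keepdims=True)
        total = np.linalg.svd(z.T, compute_uv=False) ** 2
        assert total[0] / total.sum() > 0.999999
        assert scores.shape == (20, 1)

    def test_planted_factors_recovered(self):
        rng = np.random.default_rng(15)
        n, g = 100, 500
        f1, f2 = rng.normal(size=n), rng.normal(size=n)
        load1, load2 = rng.normal(size=g), rng.normal(size=g)
        y = np.outer(load1, f1) + np.outer(load2, f2) + 0.05 * rng.normal(size=(g, n))
        scores = pca_covariates(y, 2)
        span = np.linalg.lstsq(scores, np.column_stack([f1, f2]), rcond=None)[0]
        fitted = scores @ span
        for j, f in enumerate([f1, f2]):
            assert abs(np.corrcoef(fitted[:, j], f)[0, 1]) > 0.99

    def test_bit_identical_reruns(self):
        rng = np.random.default_rng(16)
        y = rng.normal(size=(40, 25))
        a = pca_covariates(y, 3)
        b = pca_covariates(y.copy(), 3)
        np.testing.assert_array_equal(a, b)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError, match="n_components"):
            pca_covariates(np.ones((10, 5)), 5)


class TestCelltypeAssociation:
    def test_constant_phenotype_rejected(self):
        rng = np.random.default_rng(17)
        props = _props(rng.dirichlet(np.ones(2), size=10))
        with pytest.raises(ValueError, match="no variance"):
            celltype_association(rng.normal(size=10), props, np.ones(10))

    def test_matches_statsmodels_ols_single_celltype(self):
        """K=1 interaction model checked against an independent OLS fit."""
        w = np.array([0.2, 0.5, 0.9, 0.4, 0.7, 0.3])
        d = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        y = np.array([1.0, 3.0, 2.5, 4.0, 1.5, 3.5])
        out = celltype_association(y, _props(w[:, None]), d)

        dc = d - d.mean()
        design = np.column_stack([w, w * dc])
        ref = sm.OLS(y, design).fit()
        assert out.loc["ct0", "estimate"] == pytest.approx(ref.params[1])
        assert out.loc["ct0", "se"] == pytest.approx(ref.bse[1])
        assert out.loc["ct0", "t"] == pytest.approx(ref.tvalues[1])
        assert out.loc["ct0", "p"] == pytest.approx(ref.pvalues[1])

    def test_planted_effect_detected_specifically(self):
        """delta = 5 on one cell type: that type significant, others not."""
        spec = BetaSpec(list("ABCDE"), [0.35, 0.25, 0.2, 0.12, 0.08],
                        [0.07, 0.05, 0.04, 0.03, 0.02], [0.0] * 5, [1.0] * 5)
        rng = np.random.default_rng(18)
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            props = draw_proportions(spec, 200, seed=1000 + rep)
            y_base = rng.normal(0, 0.1, size=200)
            d = np.zeros(200)
            d[rng.permutation(200)[:100]] = 1.0
            y = y_base + 5.0 * d * props.values[:, 0]
            out = celltype_association(y, props, d)
            ok = out.loc["A", "p"] < 1e-4 and (out.drop(index="A")["p"] > 0.01).all()
            hits += ok
        assert hits / n_rep >= 0.95

    def test_all_zero_celltype_reported_na(self):
        rng = np.random.default_rng(19)
        w = rng.dirichlet(np.ones(2), size=20)
        w = np.column_stack([w, np.zeros(20)])
        d = np.tile([0.0, 1.0], 10)
        out = celltype_association(rng.normal(size=20), _props(w), d)
        assert out.loc["ct2"].isna().all()
        assert out.loc[["ct0", "ct1"]].notna().all().all()


class TestComputeLambda:
    def test_unit_lambda_at_chisq_median(self):
        m0 = stats.chi2.ppf(0.5, df=1)
        t = np.full(100, np.sqrt(m0))
        assert compute_lambda(t) == pytest.approx(1.0)

    def test_quadratic_scaling(self):
        rng = np.random.default_rng(20)
        t = rng.normal(size=1000)
        assert compute_lambda(3.0 * t) == pytest.approx(9.0 * compute_lambda(t))

    def test_standard_normal_null_is_calibrated(self):
        rng = np.random.default_rng(21)
        t = rng.normal(size=1_000_000)
        assert compute_lambda(t) == pytest.approx(1.0, abs=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            compute_lambda(np.array([np.nan]))


@pytest.fixture(scope="module")
def twas_data():
    """Null mixture dataset: 400 transcripts, 120 samples, 5 cell types."""
    from ebdeconv.benchmark import standardized_panel

    spec = BetaSpec(list("ABCDE"), [0.35, 0.25, 0.2, 0.12, 0.08],
                    [0.07, 0.05, 0.04, 0.03, 0.02], [0.0] * 5, [1.0] * 5)
    panel = standardized_panel(400, spec.celltype_names, seed=22)
    props = draw_proportions(spec, 120, seed=23)
    bulk = make_bulk(panel, props, noise_sd_fraction=0.05, seed=24)
    pheno, bulk = make_phenotype(props, bulk, seed=25, n_covariates=2)
    return bulk, props, pheno


class TestRunTwas:
    def test_global_null_yields_no_hits(self, twas_data):
        bulk, props, pheno = twas_data
        table = run_twas(bulk, props, pheno, n_pcs=4)
        assert (table["q"] <= 0.1).sum() == 0

    def test_q_at_least_p(self, twas_data):
        bulk, props, pheno = twas_data
        table = run_twas(bulk, props, pheno, n_pcs=4)
        assert (table["q"] >= table["p"] - 1e-15).all()

    def test_bh_worked_example(self):
        q = multipletests([0.001, 0.01, 0.02, 0.9], method="fdr_bh")[1]
        np.testing.assert_allclose(q, [0.004, 0.02, 0.02 * 4 / 3, 0.9])

    def test_planted_interaction_found(self, twas_data):
        bulk, props, pheno = twas_data
        d = pheno["phenotype"].to_numpy()
        boosted = bulk.data.copy()
        boosted.loc["gene_7"] += 5.0 * d * props.values[:, 0]
        table = run_twas(BulkMatrix(boosted), props, pheno, n_pcs=4)
        top = table.sort_values("p").iloc[0]
        assert top["transcript"] == "gene_7"
        assert top["celltype"] == "A"
        assert top["q"] < 0.1

    def test_transcript_and_sample_order_invariant(self, twas_data):
        bulk, props, pheno = twas_data
        base = run_twas(bulk, props, pheno, n_pcs=4)
        rng = np.random.default_rng(27)
        g_perm = rng.permutation(bulk.shape[0])
        s_perm = rng.permutation(bulk.shape[1])
        shuffled_bulk = BulkMatrix(bulk.data.iloc[g_perm, s_perm])
        shuffled = run_twas(shuffled_bulk, props, pheno, n_pcs=4)
        key = ["transcript", "celltype"]
        merged = base.merge(shuffled, on=key, suffixes=("_a", "_b"))
        assert len(merged) == len(base)
        np.testing.assert_allclose(merged["t_a"], merged["t_b"], atol=1e-8)

    def test_model_results_interface(self, twas_data):
        bulk, props, pheno = twas_data
        res = CellTypeAssociation(bulk, props, pheno, n_pcs=4).fit()
        summary = res.summary()
        assert set(summary.index) == set(props.celltype_names)
        assert res.n_significant(0.1) == (res.table["q"] <= 0.1).sum()
        assert ((summary["lambda"] > 0.5) & (summary["lambda"] < 2.0)).all()


class TestPermutationNull:
    def test_deterministic_with_seed(self, twas_data):
        bulk, props, pheno = twas_data
        a = permutation_null(bulk, props, pheno, n_perm=2, seed=3, n_pcs=4)
        b = permutation_null(bulk, props, pheno, n_perm=2, seed=3, n_pcs=4)
        pd.testing.assert_frame_equal(a, b)

    def test_lambda_centered_near_one(self, twas_data):
        bulk, props, pheno = twas_data
        lam = permutation_null(bulk, props, pheno, n_perm=30, seed=4, n_pcs=4)
        assert 0.95 < np.median(lam.to_numpy()) < 1.05

    def test_null_pvalues_uniform(self):
        """KS distance of null p-values from uniform < 0.05 per cell type."""
        from ebdeconv.benchmark import standardized_panel

        spec = BetaSpec(list("ABCDE"), [0.35, 0.25, 0.2, 0.12, 0.08],
                        [0.07, 0.05, 0.04, 0.03, 0.02], [0.0] * 5, [1.0] * 5)
        panel = standardized_panel(2000, spec.celltype_names, seed=28)
        props = draw_proportions(spec, 150, seed=29)
        bulk = make_bulk(panel, props, noise_sd_fraction=0.05, seed=30)
        pheno, bulk = make_phenotype(props, bulk, seed=31, n_covariates=2)
        rng = np.random.default_rng(32)
        pheno["phenotype"] = pheno["phenotype"].to_numpy()[rng.permutation(150)]
        table = run_twas(bulk, props, pheno, n_pcs=4)
        for ct, sub in table.groupby("celltype"):
            ks = stats.kstest(sub["p"], "uniform").statistic
            assert ks < 0.05
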