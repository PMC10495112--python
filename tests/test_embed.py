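import numpy as np
import pytest
import scipy.sparse as sp

from skinsci import embed, qc
from skinsci import synthetic as syn
from skinsci.embed import EmbedConfig, LeidenClusterer, MNNAligner


class TestSizeFactors:
    def test_closed_form(self):
        np.testing.assert_allclose(embed.size_factors([100, 400]), [0.5, 2.0])

    def test_equal_totals_give_unit_factors(self):
        np.testing.assert_allclose(embed.size_factors([7, 7, 7]), 1.0)

    def test_geometric_mean_is_one(self):
        totals = np.random.default_rng(3).integers(100, 5000, 500)
        sf = embed.size_factors(totals)
        assert abs(np.mean(np.log(sf))) < 1e-9

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            embed.size_factors([10, 0])


class TestNormalize:
    def test_formula_and_sparsity(self):
        counts = sp.csr_matrix(np.array([[0, 2], [4, 0]]))
        x = embed.normalize(counts, np.array([2.0, 2.0]))
        assert x[0, 0] == 0 and x.nnz == 2
        assert x[0, 1] == pytest.approx(np.log(2))  # count == sf
        assert x[1, 0] == pytest.approx(np.log(3))

    def test_scale_invariance(self):
        a = embed.normalize(sp.csr_matrix(np.array([[3.0]])), np.array([1.5]))
        b = embed.normalize(sp.csr_matrix(np.array([[6.0]])), np.array([3.0]))
        assert a[0, 0] == pytest.approx(b[0, 0])


class TestPCA:
    def test_rank_one_data(self):
        rng = np.random.default_rng(0)
        data = np.outer(rng.normal(size=30), rng.normal(size=100))  # genes x cells
        scores = embed.pca(data, n_pcs=5)
        var = scores.var(axis=0)
        assert var[0] / var.sum() > 0.999

    def test_variances_nonincreasing_and_svd_oracle(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(100, 200))  # genes x cells
        scores = embed.pca(data, n_pcs=20, seed=0)
        var = scores.var(axis=0)
        assert (np.diff(var) <= 1e-10).all()
        X = data.T - data.T.mean(axis=0)
        _, s, _ = np.linalg.svd(X, full_matrices=False)
        oracle = (s[:20] ** 2) / X.shape[0]
        np.testing.assert_allclose(np.sort(var)[::-1], oracle, rtol=1e-6)

    def test_n_pcs_too_large(self):
        with pytest.raises(ValueError, match="n_pcs"):
            embed.pca(np.zeros((5, 10)), n_pcs=11)


class TestAmbientProfiles:
    def test_single_gene_indicator(self):
        from conftest import toy_count_matrix

        counts = np.zeros((4, 1), dtype=int)
        counts[2, 0] = 7
        prof = embed.ambient_profiles({"s1": toy_count_matrix(counts)})
        assert prof.loc["s1"].idxmax() == "g002"
        assert prof.loc["s1"].max() > 0.999

    def test_duplicate_barcodes_same_profile(self):
        from conftest import toy_count_matrix

        one = np.array([[3], [1], [0]])
        two = np.hstack([one, one])
        p1 = embed.ambient_profiles({"s1": toy_count_matrix(one)})
        p2 = embed.ambient_profiles({"s1": toy_count_matrix(two)})
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy())

    def test_recovers_generative_profile(self):
        # small gene panel so 500 background barcodes (~7 UMIs each) pin
        # the profile down to a few percent total variation
        small_programs = syn.make_programs(4, 50, 5, 8.0, seed=11)
        cfg = syn.SimConfig(
            programs=small_programs,
            samples=[syn.SampleSpec("s1", "wt", 50, 0.2, 500)],
            seed=8,
        )
        cm, truth = syn.simulate_dataset(cfg)
        groups = qc.split_background(cm)
        prof = embed.ambient_profiles(groups)
        tv = 0.5 * np.abs(
            prof.loc["s1"].to_numpy() - truth.ambient_profiles.loc["s1"].to_numpy()
        ).sum()
        assert tv < 0.05

    def test_all_zero_background_rejected(self):
        from conftest import toy_count_matrix

        with pytest.raises(ValueError, match="background"):
            embed.ambient_profiles({"s1": toy_count_matrix(np.zeros((3, 2), int))})


class TestBackgroundLoadings:
    def _profiles(self, n_genes=5):
        import pandas as pd

        p = np.full((2, n_genes), 1.0 / n_genes)
        return pd.DataFrame(p, index=["s1", "s2"],
                            columns=[f"g{i}" for i in range(n_genes)])

    def test_zero_expression_gives_zero_raw_loading(self):
        x = sp.csr_matrix(np.array([[0.0, 1.0], [0.0, 2.0]]))  # cell 0 all-zero
        raw = embed.background_loadings(
            x, self._profiles(2), mode="profile_dot", standardize=False
        )
        assert raw[0, 0] == 0.0 and raw[0, 1] == 0.0

    def test_duplicate_profiles_identical_columns(self):
        rng = np.random.default_rng(0)
        x = sp.csr_matrix(rng.poisson(1.0, size=(5, 40)).astype(float))
        L = embed.background_loadings(x, self._profiles(), mode="profile_dot")
        np.testing.assert_allclose(L[:, 0], L[:, 1])

    def test_loading_monotone_in_contamination(self, small_programs):
        means = []
        for rho in (0.0, 0.15, 0.3):
            cfg = syn.SimConfig(
                programs=small_programs,
                samples=[
                    syn.SampleSpec("s1", "wt", 400, rho, 200,
                                   ambient_concentration=1e6)
                ],
                seed=4,
            )
            cm, _ = syn.simulate_dataset(cfg)
            kept, _ = qc.filter_barcodes(cm)
            prof = embed.ambient_profiles(qc.split_background(cm))
            norm = embed.normalize(kept, embed.size_factors(kept.total_umis))
            raw = embed.background_loadings(
                norm, prof, sample_ids=kept.cells["sample_id"], standardize=False
            )
            means.append(raw.mean())
        assert means[0] < means[1] < means[2]


class TestRegressOutBackground:
    def test_null_regression_centers_only(self):
        rng = np.random.default_rng(2)
        P = rng.normal(size=(50, 4)) + 3.0
        out = embed.regress_out_background(P, np.zeros((50, 0)))
        np.testing.assert_allclose(out, P - P.mean(axis=0), atol=1e-12)

    def test_zero_variance_loadings_dropped(self):
        rng = np.random.default_rng(2)
        P = rng.normal(size=(30, 3))
        with pytest.warns(UserWarning, match="zero-variance"):
            out = embed.regress_out_background(P, np.ones((30, 2)))
        np.testing.assert_allclose(out, P - P.mean(axis=0), atol=1e-12)

    def test_perfect_fit_gives_zero_residuals(self):
        rng = np.random.default_rng(3)
        L = rng.normal(size=(100, 3))
        B = rng.normal(size=(3, 10))
        resid = embed.regress_out_background(L @ B, L)
        assert np.abs(resid).max() < 1e-8

    def test_residuals_orthogonal_to_loadings(self):
        rng = np.random.default_rng(4)
        P = rng.normal(size=(200, 10))
        L = rng.normal(size=(200, 3))
        R = embed.regress_out_background(P, L)
        cors = np.abs(R.T @ L) / np.outer(
            np.linalg.norm(R, axis=0), np.linalg.norm(L, axis=0)
        )
        assert cors.max() < 1e-8
        assert np.abs(R.sum(axis=0)).max() < 1e-8  # orthogonal to intercept

    def test_mismatched_cells_rejected(self):
        with pytest.raises(ValueError, match="cells"):
            embed.regress_out_background(np.zeros((10, 2)), np.zeros((9, 1)))


def well_mixed_types(n, seed, n_types=4, spread=25.0, within_sd=0.1, d=6):
    """Tight, well-separated type clusters shared by both batches.

    MNN assumes the batch shift is small relative to between-type
    separation, so mutual pairs match cells of the same type.
    """
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, spread / 2, size=(n_types, d))
    labels = rng.integers(0, n_types, n)
    return centers[labels] + rng.normal(0, within_sd, size=(n, d))


class TestMNNAlign:
    def test_single_batch_identity(self):
        X = np.random.default_rng(0).normal(size=(50, 5))
        out = embed.mnn_align(X, ["a"] * 50)
        np.testing.assert_array_equal(out, X)

    def test_identical_batches_near_zero_shift(self):
        X = well_mixed_types(300, seed=1)
        stacked = np.vstack([X, X])
        batches = ["a"] * 300 + ["b"] * 300
        out = embed.mnn_align(stacked, batches, mnn_k=5)
        # corrections are within-cluster mean reversion only: tiny vs spread
        assert np.abs(out[300:] - X).max() < 0.5

    def test_constant_shift_recovered(self):
        X = well_mixed_types(1000, seed=2)
        v = np.array([4.0, -3.0, 2.0, -2.0, 1.5, -1.0])
        stacked = np.vstack([X, X + v])
        out = embed.mnn_align(stacked, ["a"] * 1000 + ["b"] * 1000, mnn_k=10)
        correction = (out[1000:] - (X + v)).mean(axis=0)
        assert (np.abs(correction + v) <= 0.1 * np.linalg.norm(v)).all()

    def test_batch_labels_required(self):
        with pytest.raises(ValueError, match="batch"):
            MNNAligner().fit_transform(np.zeros((10, 2)))


class TestClustering:
    def test_two_blobs_exact_recovery(self):
        rng = np.random.default_rng(5)
        X = np.vstack(
            [rng.normal(0, 1, size=(300, 5)), rng.normal(30, 1, size=(300, 5))]
        )
        labels = LeidenClusterer(resolution=2e-4, random_state=0).fit_predict(X)
        truth = np.repeat([0, 1], 300)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, labels) == 1.0

    def test_tiny_resolution_single_cluster_on_connected_blob(self):
        X = np.random.default_rng(6).normal(size=(200, 4))
        labels = LeidenClusterer(resolution=1e-12, random_state=0).fit_predict(X)
        assert labels.max() == 0

    def test_deterministic(self):
        X = np.random.default_rng(7).normal(size=(300, 5))
        l1 = LeidenClusterer(resolution=1e-3, random_state=3).fit_predict(X)
        l2 = LeidenClusterer(resolution=1e-3, random_state=3).fit_predict(X)
        np.testing.assert_array_equal(l1, l2)


class TestUmap:
    def test_deterministic_and_separates_types(self):
        rng = np.random.default_rng(8)
        X = np.vstack([
            rng.normal(0, 0.5, size=(80, 5)),
            rng.normal(8, 0.5, size=(80, 5)),
            rng.normal(-8, 0.5, size=(80, 5)),
        ])
        cfg = EmbedConfig(n_neighbors=10, seed=42)
        e1 = embed.umap_embed(X, cfg)
        e2 = embed.umap_embed(X, cfg)
        np.testing.assert_array_equal(e1, e2)
        labels = np.repeat([0, 1, 2], 80)
        cents = np.stack([e1[labels == k].mean(axis=0) for k in range(3)])
        radii = [np.linalg.norm(e1[labels == k] - cents[k], axis=1).mean()
                 for k in range(3)]
        from scipy.spatial.distance import pdist

        assert pdist(cents).min() > max(radii)

    def test_too_many_neighbors_rejected(self):
        with pytest.raises(ValueError, match="n_neighbors"):
            embed.umap_embed(np.zeros((10, 3)), EmbedConfig(n_neighbors=20))


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        EmbedConfig(n_pcs=1)
    with pytest.raises(ValueError):
        EmbedConfig(cluster_resolution=0)
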