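import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from skinsci import embed, programs, qc
from skinsci import synthetic as syn
from skinsci.programs import FractionEstimate, GeneSignature

from conftest import toy_count_matrix


def brute_force_specificity(mean_table: np.ndarray, cluster: int) -> np.ndarray:
    """Independent direct-summation JSD-complement specificity."""
    out = np.zeros(mean_table.shape[0])
    for g in range(mean_table.shape[0]):
        row = mean_table[g]
        if row.sum() == 0:
            continue
        p = row / row.sum()
        e = np.zeros_like(p)
        e[cluster] = 1.0
        m = 0.5 * (p + e)
        kl_p = sum(pi * np.log(pi / mi) for pi, mi in zip(p, m) if pi > 0)
        kl_e = sum(ei * np.log(ei / mi) for ei, mi in zip(e, m) if ei > 0)
        out[g] = 1.0 - (0.5 * kl_p + 0.5 * kl_e) / np.log(2.0)
    return out


class TestSpecificity:
    def test_exclusive_gene_scores_one(self):
        # gene 0 expressed only in cluster 0 (scores exactly 1 there and
        # exactly 0 for disjoint clusters); gene 1 mostly in cluster 0
        x = np.array([[1.0, 1.0, 0.0, 0.0], [1.0, 1.0, 0.2, 0.2]])
        labels = np.array([0, 0, 1, 1])
        spec = programs.specificity_scores(x, labels)
        assert spec.loc[0, 0] == pytest.approx(1.0)
        assert spec.loc[0, 1] == pytest.approx(0.0)
        assert 0 < spec.loc[1, 1] < spec.loc[1, 0] < 1

    def test_all_zero_gene_scores_zero(self):
        x = np.array([[0.0, 0.0], [1.0, 2.0]])
        spec = programs.specificity_scores(x, np.array([0, 1]))
        assert (spec.loc[0] == 0).all()

    def test_uniform_gene_matches_brute_force(self):
        x = np.ones((1, 8))
        labels = np.repeat([0, 1, 2, 3], 2)
        spec = programs.specificity_scores(x, labels)
        oracle = brute_force_specificity(np.ones((1, 4)) / 4, 0)[0]
        assert spec.loc[0].nunique() == 1
        assert spec.loc[0, 0] == pytest.approx(oracle, abs=1e-12)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(0)
        means = rng.gamma(1.0, size=(50, 5))
        # build per-cell data whose cluster means equal `means` exactly
        x = np.repeat(means, 2, axis=1)
        labels = np.repeat(np.arange(5), 2)
        spec = programs.specificity_scores(x, labels)
        for c in range(5):
            np.testing.assert_allclose(
                spec[c].to_numpy(), brute_force_specificity(means, c), atol=1e-12
            )

    def test_argmax_specificity_matches_argmax_mean(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(1.0, size=(30, 12))
        labels = np.repeat(np.arange(4), 3)
        spec = programs.specificity_scores(x, labels)
        means = np.stack([x[:, labels == c].mean(axis=1) for c in range(4)], axis=1)
        np.testing.assert_array_equal(
            spec.to_numpy().argmax(axis=1), means.argmax(axis=1)
        )

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            programs.specificity_scores(np.ones((3, 4)), np.zeros(4))


class TestSelectSignature:
    def _table(self):
        spec = pd.DataFrame({0: [0.09, 0.10, 0.11], 1: [0.5, 0.5, 0.5]})
        return spec, ["gA", "gB", "gC"]

    def test_strict_threshold(self):
        spec, genes = self._table()
        sig = programs.select_signature(spec, genes, 0, genes, min_specificity=0.1)
        assert sig.gene_ids == ["gC"]

    def test_zero_threshold_keeps_all(self):
        spec, genes = self._table()
        sig = programs.select_signature(spec, genes, 0, genes, min_specificity=0.0)
        assert sig.gene_ids == genes

    def test_empty_result_reports_near_misses(self):
        spec, genes = self._table()
        with pytest.raises(ValueError, match="gC"):
            programs.select_signature(spec, genes, 0, genes, min_specificity=0.2)

    def test_generator_markers_pass_default_threshold(self, small_programs):
        cfg = syn.SimConfig(
            programs=small_programs,
            samples=[syn.SampleSpec("s1", "wt", 1200, 0.0, 0)],
            seed=6,
        )
        cm, truth = syn.simulate_dataset(cfg)
        kept, _ = qc.filter_barcodes(cm)
        tb = truth.barcodes.set_index("barcode").loc[kept.cells["barcode"]]
        labels = pd.Categorical(tb["true_type"]).codes
        norm = embed.normalize(kept, embed.size_factors(kept.total_umis))
        spec = programs.specificity_scores(norm, labels)
        gene_ids = kept.genes["gene_id"].tolist()
        target = sorted(set(tb["true_type"])).index("type00")
        candidates = [gene_ids[g] for g in small_programs.markers[0]]
        sig = programs.select_signature(
            spec, candidates, target, gene_ids, min_specificity=0.1
        )
        assert set(sig.gene_ids) == set(candidates)


class TestSignatureScore:
    def test_single_gene_equals_zscore(self):
        x = np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        sig = GeneSignature("s", ["g000"])
        score = programs.signature_score(x, ["g000", "g001"], sig)
        z = (x[0] - x[0].mean()) / x[0].std()
        np.testing.assert_allclose(score, z)

    def test_constant_gene_contributes_zero(self):
        x = np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        both = programs.signature_score(
            x, ["g000", "g001"], GeneSignature("s", ["g000", "g001"])
        )
        single = programs.signature_score(
            x, ["g000", "g001"], GeneSignature("s", ["g000"])
        )
        np.testing.assert_allclose(both, single / 2)

    def test_absent_genes_dropped_without_effect(self):
        x = np.array([[1.0, 2.0, 3.0]])
        with pytest.warns(UserWarning, match="absent"):
            padded = programs.signature_score(
                x, ["g000"], GeneSignature("s", ["g000", "missing"])
            )
        base = programs.signature_score(x, ["g000"], GeneSignature("s", ["g000"]))
        np.testing.assert_allclose(padded, base)

    def test_all_genes_missing_rejected(self):
        with pytest.raises(ValueError, match="none"):
            programs.signature_score(
                np.ones((1, 2)), ["g000"], GeneSignature("s", ["nope"])
            )

    def test_separates_boosted_program(self, small_programs):
        cfg = syn.SimConfig(
            programs=small_programs,
            samples=[syn.SampleSpec("s1", "wt", 1000, 0.0, 0)],
            seed=12,
        )
        cm, truth = syn.simulate_dataset(cfg)
        kept, _ = qc.filter_barcodes(cm)
        tb = truth.barcodes.set_index("barcode").loc[kept.cells["barcode"]]
        norm = embed.normalize(kept, embed.size_factors(kept.total_umis))
        gene_ids = kept.genes["gene_id"].tolist()
        sig = GeneSignature(
            "type00", [gene_ids[g] for g in small_programs.markers[0]]
        )
        score = programs.signature_score(norm, gene_ids, sig)
        is_target = (tb["true_type"] == "type00").to_numpy()
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(is_target, score) >= 0.9


class TestScoreRatio:
    def test_equal_scores_give_unit_ratio(self):
        s = np.array([-1.0, 0.0, 2.0])
        ratio, _ = programs.score_ratio(s, s.copy())
        np.testing.assert_allclose(ratio, 1.0)

    def test_larger_numerator_exceeds_one(self):
        ratio, shift = programs.score_ratio(np.array([5.0]), np.array([1.0]))
        assert ratio[0] > 1 and shift == 0.0

    def test_shift_makes_denominator_safe(self):
        ratio, shift = programs.score_ratio(np.array([-3.0]), np.array([-2.0]))
        assert shift == pytest.approx(3.1)
        assert np.isfinite(ratio).all()

    def test_tracks_trajectory_direction(self, small_programs):
        cfg = syn.SimConfig(
            programs=small_programs,
            samples=[syn.SampleSpec("s1", "wt", 0, 0.0, 0)],
            trajectory=syn.TrajectorySpec("type00", "type01", n_cells=800),
            seed=19,
        )
        cm, truth = syn.simulate_trajectory(cfg)
        norm = embed.normalize(cm, embed.size_factors(cm.total_umis))
        gene_ids = cm.genes["gene_id"].tolist()
        mes = programs.signature_score(
            norm, gene_ids,
            GeneSignature("start", [gene_ids[g] for g in small_programs.markers[0]]),
        )
        epi = programs.signature_score(
            norm, gene_ids,
            GeneSignature("end", [gene_ids[g] for g in small_programs.markers[1]]),
        )
        ratio, _ = programs.score_ratio(mes, epi)
        from scipy.stats import spearmanr

        rho = spearmanr(ratio, truth.barcodes["latent_time"]).statistic
        assert rho <= -0.8


class TestExpressingFraction:
    def test_absent_signature_zero_fraction(self):
        cm = toy_count_matrix(np.array([[0, 0, 0], [1, 2, 3]]))
        est = programs.expressing_fraction(
            cm, GeneSignature("s", ["g000"]), ["a", "a", "a"]
        )[0]
        assert est.fraction == 0 and est.ci_low == 0 and est.ci_high == 0

    def test_all_expressing(self):
        cm = toy_count_matrix(np.array([[1, 2, 3]]))
        est = programs.expressing_fraction(
            cm, GeneSignature("s", ["g000"]), ["a"] * 3
        )[0]
        assert est.fraction == 1 and est.ci_low == 1 and est.ci_high == 1

    def test_binomial_point_estimate(self):
        rng = np.random.default_rng(0)
        expressed = rng.random(500) < 0.3
        counts = np.zeros((2, 500), dtype=int)
        counts[0, expressed] = 1
        counts[1] = 5  # keep total UMIs positive everywhere
        cm = toy_count_matrix(counts)
        est = programs.expressing_fraction(
            cm, GeneSignature("s", ["g000"]), ["a"] * 500, n_boot=100, seed=1
        )[0]
        assert abs(est.fraction - 0.3) < 0.05
        assert est.ci_low <= est.fraction <= est.ci_high

    def test_single_bootstrap_degenerate_ci(self):
        counts = np.array([[1, 0, 1, 0, 1, 0] * 5])
        cm = toy_count_matrix(counts)
        est = programs.expressing_fraction(
            cm, GeneSignature("s", ["g000"]), ["a"] * 30, n_boot=1, seed=2
        )[0]
        assert est.ci_low <= est.fraction <= est.ci_high
        # with one resample the interval collapses around it (plus clamping)
        assert (est.ci_high - est.ci_low) <= abs(est.fraction - 0.5) + 0.5

    def test_ci_must_bracket_estimate(self):
        with pytest.raises(ValueError):
            FractionEstimate("g", 0.5, 0.6, 0.7, 10)

    def test_small_group_warns(self):
        cm = toy_count_matrix(np.ones((1, 5), dtype=int))
        with pytest.warns(UserWarning, match="unstable"):
            programs.expressing_fraction(
                cm, GeneSignature("s", ["g000"]), ["a"] * 5
            )
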