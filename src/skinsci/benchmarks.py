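"""Self-contained benchmark experiments on synthetic data.

Each function generates its data with the package's own simulator,
runs the relevant stage(s), and returns the measured quantities.  They
back both the acceptance checks of the test suite and the
reproducibility script; problem sizes are chosen to finish in seconds
to a couple of minutes on one CPU.
"""

from __future__ import annotations

import hashlib
import os

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score, silhouette_score

from . import comparative, embed, pipeline, programs, qc, trajectory
from . import synthetic as syn

__all__ = [
    "residual_orthogonality",
    "ambient_correction_benefit",
    "abundance_recovery",
    "de_null_calibration",
    "de_power",
    "bh_exactness",
    "filter_semantics",
    "specificity_exactness",
    "bootstrap_coverage",
    "pseudotime_recovery",
    "mnn_shift_recovery",
    "pipeline_determinism",
]


def _contaminated_sim(seed: int, n_cells: int = 1000, n_samples: int = 4):
    """The reference contaminated multi-sample experiment.

    Eight cell types over four pooled libraries, mean contamination 0.3
    across the experiment with sample-specific levels (libraries differ
    in how dirty they are), sample-distinct ambient profiles via
    abundance jitter.
    """
    ps = syn.make_programs(
        n_types=8, n_genes=1000, n_markers_per_type=40, marker_boost=8.0, seed=11
    )
    mult = np.random.default_rng(5).lognormal(0, 0.4, size=(n_samples, 8))
    rhos = [0.5, 0.35, 0.25, 0.1][:n_samples]
    samples = [
        syn.SampleSpec(
            f"s{i}", f"g{i}", n_cells, rhos[i], 300, ambient_concentration=10.0
        )
        for i in range(n_samples)
    ]
    cfg = syn.SimConfig(
        programs=ps, samples=samples, abundance_multipliers=mult, seed=seed
    )
    cm, truth = syn.simulate_dataset(cfg)
    kept, _ = qc.filter_barcodes(cm)
    background = qc.split_background(cm)
    true_type = (
        truth.barcodes.set_index("barcode")["true_type"]
        .loc[kept.cells["barcode"]]
        .to_numpy()
    )
    return kept, background, true_type


def residual_orthogonality(seed: int) -> dict:
    """Max |correlation| between corrected-PCA columns and loadings."""
    kept, background, _ = _contaminated_sim(seed, n_cells=400, n_samples=2)
    state = embed.embed_pipeline(kept, background, embed.EmbedConfig(n_pcs=30))
    R, L = state.pca_corrected, state.loadings
    cors = np.abs(R.T @ L) / np.outer(
        np.linalg.norm(R, axis=0), np.linalg.norm(L, axis=0)
    )
    return {"max_abs_correlation": float(cors.max()), "n": kept.n_cells}


def ambient_correction_benefit(seed: int) -> dict:
    """Silhouette gain from background correction and clustering accuracy."""
    kept, background, true_type = _contaminated_sim(seed)
    state = embed.embed_pipeline(
        kept, background, embed.EmbedConfig(cluster_resolution=2e-4, seed=0)
    )
    sil_raw = float(silhouette_score(state.pca, true_type))
    sil_cor = float(silhouette_score(state.pca_corrected, true_type))
    ari = float(adjusted_rand_score(true_type, state.clusters))
    return {
        "silhouette_raw": sil_raw,
        "silhouette_corrected": sil_cor,
        "silhouette_gain": sil_cor - sil_raw,
        "clustering_ari": ari,
        "n": kept.n_cells,
    }


def abundance_recovery(seed: int, n_cells: int = 2000) -> dict:
    """Recovery of log2 abundance ratios for multipliers {0.25..4}.

    Five tested types carry the multipliers; a sixth buffer type absorbs
    the complement so each query sample's expected composition keeps the
    tested ratios at exactly {-2, -1, 0, 1, 2} versus the reference.
    """
    ps = syn.make_programs(6, 300, 8, 6.0, seed=11)
    tested = np.array([0.25, 0.5, 1.0, 2.0, 4.0])
    base = np.array([0.4] + [0.12] * 5)
    mult = np.ones((4, 6))
    for q in range(1, 4):
        rolled = np.roll(tested, q - 1)
        mult[q, 1:] = rolled
        mult[q, 0] = (1.0 - 0.12 * rolled.sum()) / 0.4
    samples = [
        syn.SampleSpec(f"s{i}", f"g{i}", n_cells, 0.0, 0) for i in range(4)
    ]
    cfg = syn.SimConfig(
        programs=ps,
        samples=samples,
        abundance_multipliers=mult,
        base_abundance=base,
        seed=seed,
    )
    _, truth = syn.simulate_dataset(cfg)
    counts = pd.crosstab(
        truth.barcodes["true_type"], truth.barcodes["sample_id"]
    )
    table = comparative.abundance_log2(counts, "s0", pseudocount=0)
    errs = []
    for q in range(1, 4):
        expected = np.log2(np.roll(tested, q - 1))
        observed = table.log2_ratio.loc[
            [f"type{k:02d}" for k in range(1, 6)], f"s{q}"
        ].to_numpy()
        errs.extend(np.abs(observed - expected))
    errs = np.asarray(errs)
    return {
        "fraction_within_tolerance": float((errs <= 0.35).mean()),
        "max_abs_error": float(errs.max()),
        "n": int(n_cells * 4),
    }


def _de_sim(seed: int, n_genes, n_per_side, de_genes=(), fold=4.0, libsize_meanlog=7.1):
    ps = syn.make_programs(1, n_genes, 0, 2.0, seed=13)
    cfg = syn.SimConfig(
        programs=ps,
        samples=[
            syn.SampleSpec("a", "condA", n_per_side, 0.0, 0),
            syn.SampleSpec("b", "condB", n_per_side, 0.0, 0),
        ],
        de_spec=[syn.DESpec(int(g), "type00", "condB", fold) for g in de_genes],
        library_size_lognormal=(libsize_meanlog, 0.5),
        seed=seed,
    )
    cm, _ = syn.simulate_dataset(cfg)
    labels = cm.cells["genotype"].to_numpy()
    sf = embed.size_factors(cm.total_umis)
    return cm, labels, sf


def de_null_calibration(seed: int) -> dict:
    """Fraction of Wald p < 0.05 under a no-effect simulation."""
    cm, labels, sf = _de_sim(seed, n_genes=200, n_per_side=300)
    table = comparative.fit_gene_glm(cm, labels, sf, reference_level="condA")
    return {
        "null_p05_fraction": float((table["wald_p"] < 0.05).mean()),
        "n": int(len(table)),
    }


def de_power(seed: int) -> dict:
    """Power for 4-fold effects at 500 cells/side, ~0.5 mean UMI/gene."""
    rng = np.random.default_rng(seed)
    de_genes = rng.choice(500, size=30, replace=False)
    cm, labels, sf = _de_sim(
        seed + 1, n_genes=500, n_per_side=500,
        de_genes=de_genes, fold=4.0, libsize_meanlog=np.log(250.0),
    )
    table = comparative.fit_gene_glm(cm, labels, sf, reference_level="condA")
    table = table.set_index("gene_id")
    sig_ids = {
        f"g{g:05d}" for g in de_genes
    } & set(table.index[table["q_bh"] < 0.05])
    n_deg = comparative.count_degs(table.reset_index(), 0.05, 2.0)
    return {
        "power_q05": float(len(sig_ids) / len(de_genes)),
        "deg_count_q05_fc2": int(n_deg),
        "n": int(cm.n_cells),
    }


def bh_exactness(seed: int, n_vectors: int = 1000) -> dict:
    """Max |difference| between bh_adjust and a brute-force step-up."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        p = rng.random(rng.integers(1, 60))
        m = len(p)
        order = np.argsort(p, kind="stable")
        q = np.empty(m)
        running = np.inf
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, m * p[i] / rank)
            q[i] = min(running, 1.0)
        worst = max(worst, float(np.abs(comparative.bh_adjust(p) - q).max()))
    return {"max_abs_difference": worst, "n": n_vectors}


def filter_semantics(seed: int = 0) -> dict:
    """Threshold boundary check against a brute-force predicate oracle."""
    from .io import CountMatrix
    import scipy.sparse as sp

    totals = np.array([500, 600, 601, 6000, 6001, 14, 15])
    n = len(totals)
    counts = sp.csr_matrix(
        (totals.astype(np.int64), (np.zeros(n, int), np.arange(n))), shape=(1, n)
    )
    cm = CountMatrix(
        counts=counts,
        genes=pd.DataFrame({"gene_id": ["g0"], "gene_name": ["g0"]}),
        cells=pd.DataFrame(
            {
                "barcode": [f"b{i}" for i in range(n)],
                "sample_id": ["s1"] * n,
                "genotype": ["g"] * n,
                "rt_index": ["r"] * n,
            }
        ),
    )
    kept, _ = qc.filter_barcodes(cm)
    background = qc.split_background(cm)["s1"]
    kept_ok = sorted(kept.cells["total_umis"]) == [601, 6000]
    brute_kept = {int(t) for t in totals if 600 < t <= 6000}
    brute_bg = {int(t) for t in totals if t < 15}
    bg_ok = set(background.cells["total_umis"]) == brute_bg
    return {
        "kept_matches_oracle": float(
            kept_ok and set(kept.cells["total_umis"]) == brute_kept
        ),
        "background_matches_oracle": float(bg_ok),
        "n": n,
    }


def specificity_exactness(seed: int) -> dict:
    """JSD-complement specificity vs direct-summation oracle."""
    rng = np.random.default_rng(seed)
    means = rng.gamma(1.0, size=(50, 5))
    x = np.repeat(means, 2, axis=1)  # cluster means equal `means` exactly
    labels = np.repeat(np.arange(5), 2)
    spec = programs.specificity_scores(x, labels)
    worst = 0.0
    for c in range(5):
        for g in range(50):
            p = means[g] / means[g].sum()
            e = np.zeros(5)
            e[c] = 1.0
            m = 0.5 * (p + e)
            kl_p = sum(pi * np.log(pi / mi) for pi, mi in zip(p, m) if pi > 0)
            kl_e = np.log(1.0 / m[c])
            oracle = 1.0 - (0.5 * kl_p + 0.5 * kl_e) / np.log(2.0)
            worst = max(worst, abs(float(spec.loc[g, c]) - oracle))
    exclusive = np.zeros((1, 6))
    exclusive[0, :3] = 1.0  # expressed in cluster 0 only
    spec1 = programs.specificity_scores(exclusive, np.repeat([0, 1], 3))
    return {
        "max_abs_difference": worst,
        "exclusive_gene_score": float(spec1.loc[0, 0]),
        "n": 250,
    }


def bootstrap_coverage(seed: int, n_repeats: int = 200, p_true: float = 0.3) -> dict:
    """Coverage of 95% percentile bootstrap CIs for an expressing fraction."""
    import scipy.sparse as sp

    from .io import CountMatrix

    rng = np.random.default_rng(seed)
    covered = 0
    n = 500
    sig = programs.GeneSignature("s", ["g0"])
    genes = pd.DataFrame({"gene_id": ["g0", "g1"], "gene_name": ["g0", "g1"]})
    for rep in range(n_repeats):
        expressed = rng.random(n) < p_true
        counts = np.vstack([expressed.astype(np.int64), np.full(n, 5)])
        cm = CountMatrix(
            counts=sp.csr_matrix(counts),
            genes=genes,
            cells=pd.DataFrame(
                {
                    "barcode": [f"b{i}" for i in range(n)],
                    "sample_id": ["s1"] * n,
                    "genotype": ["g"] * n,
                    "rt_index": ["r"] * n,
                }
            ),
        )
        est = programs.expressing_fraction(
            cm, sig, ["grp"] * n, n_boot=100, seed=int(rng.integers(2**31))
        )[0]
        if est.ci_low <= p_true <= est.ci_high:
            covered += 1
    return {"coverage": covered / n_repeats, "n": n_repeats}


def pseudotime_recovery(seed: int) -> dict:
    """Rank agreement of tree pseudotime with the true latent time."""
    ps = syn.make_programs(4, 200, 25, 10.0, seed=11)
    cfg = syn.SimConfig(
        programs=ps,
        samples=[syn.SampleSpec("s1", "wt", 0, 0.0, 0)],
        trajectory=syn.TrajectorySpec("type00", "type01", n_cells=1000),
        seed=seed,
    )
    cm, truth = syn.simulate_trajectory(cfg)
    norm = embed.normalize(cm, embed.size_factors(cm.total_umis))
    coords = embed.pca(norm, 10, seed=0)
    t = truth.barcodes["latent_time"].to_numpy()
    roots = np.argsort(t)[:25]
    est = trajectory.PrincipalGraphPseudotime(n_nodes=25, random_state=0).fit(coords)
    pt = est.order_cells(roots)
    rho, _ = trajectory.ordering_diagnostics(pt, t)
    # node-level oracle: recompute tree distances by pure relaxation
    g = est.graph_
    inf = float("inf")
    dist = np.full((g.n_nodes, g.n_nodes), inf)
    np.fill_diagonal(dist, 0.0)
    adj: dict[int, list] = {i: [] for i in range(g.n_nodes)}
    for (a, b), w in zip(g.edges.tolist(), g.edge_lengths):
        adj[a].append((b, w))
        adj[b].append((a, w))
    for src in range(g.n_nodes):
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v, w in adj[u]:
                    if dist[src, u] + w < dist[src, v] - 1e-12:
                        dist[src, v] = dist[src, u] + w
                        nxt.append(v)
            frontier = nxt
    node_pt = dist[:, np.unique(g.cell_assignment[roots])].min(axis=1)
    oracle = node_pt[g.cell_assignment]
    return {
        "spearman_vs_latent_time": float(rho),
        "max_root_pseudotime": float(pt[roots].max()),
        "max_oracle_difference": float(np.abs(pt - oracle).max()),
        "n": 1000,
    }


def mnn_shift_recovery(seed: int) -> dict:
    """Recovery of a constructed constant batch shift.

    Both batches share tight, well-separated type clusters (the regime
    MNN assumes: batch shift smaller than between-type separation);
    batch 2 is batch 1 plus a constant vector.  Reported error is the
    worst component of (mean correction + v) relative to ``|v|``.
    """
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, 12.5, size=(4, 6))
    labels = rng.integers(0, 4, 1000)
    X = centers[labels] + rng.normal(0, 0.1, size=(1000, 6))
    v = np.array([4.0, -3.0, 2.0, -2.0, 1.5, -1.0])
    out = embed.mnn_align(
        np.vstack([X, X + v]), ["a"] * 1000 + ["b"] * 1000, mnn_k=10
    )
    correction = (out[1000:] - (X + v)).mean(axis=0)
    rel_err = np.abs(correction + v) / np.linalg.norm(v)
    return {"max_componentwise_relative_error": float(rel_err.max()), "n": 1000}


def _run_and_hash(config: dict, out_dir) -> str:
    pipeline.run_pipeline(config, out_dir)
    digest = hashlib.sha256()
    for name in sorted(os.listdir(out_dir)):
        if name.endswith((".tsv", ".mtx")) or name == "counts":
            path = os.path.join(out_dir, name)
            if os.path.isdir(path):
                for sub in sorted(os.listdir(path)):
                    with open(os.path.join(path, sub), "rb") as fh:
                        digest.update(fh.read())
            else:
                with open(path, "rb") as fh:
                    digest.update(fh.read())
    return digest.hexdigest()


def pipeline_determinism(seed: int, tmp_root, n_cells: int = 800) -> dict:
    """Two runs with one master seed must emit byte-identical tables."""
    config = pipeline.default_config(seed=seed)
    config["simulation"]["cells_per_sample"] = n_cells
    config["simulation"]["empty_per_sample"] = 250
    h1 = _run_and_hash(config, os.path.join(tmp_root, "run1"))
    h2 = _run_and_hash(config, os.path.join(tmp_root, "run2"))
    return {"outputs_identical": float(h1 == h2), "n": int(n_cells * 4)}
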