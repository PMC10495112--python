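"""Embedding: normalization, PCA, ambient correction, alignment, clustering.

The chain mirrors a pooled multi-genotype single-nucleus workflow:

1. per-cell size factors (total UMIs over their geometric mean) and
   log normalization ``x = ln(1 + count / sf)``;
2. PCA on all genes (gene-centered, unscaled), top 50 PCs by default;
3. ambient-background correction: each sample's ambient profile is
   estimated from its sub-15-UMI barcodes, each cell gets one
   "background loading" per sample (dot product of its normalized
   expression with the ambient proportion profile, standardized), and
   the PCA matrix is residualized on those loadings by OLS — the
   residuals are the background-corrected PCA matrix;
4. mutual-nearest-neighbor (MNN) alignment across samples on the
   corrected PCA matrix;
5. UMAP for visualization only (no downstream statistic reads the 2-D
   coordinates) and Leiden community detection on a k-NN graph of the
   aligned PCA matrix, with CPM-style resolutions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import CountMatrix

__all__ = [
    "EmbedConfig",
    "EmbeddingState",
    "size_factors",
    "normalize",
    "pca",
    "ambient_profiles",
    "background_loadings",
    "regress_out_background",
    "mnn_align",
    "umap_embed",
    "cluster",
    "BackgroundRegressor",
    "MNNAligner",
    "LeidenClusterer",
    "embed_pipeline",
]


@dataclass
class EmbedConfig:
    """Tunable knobs of the embedding chain.

    Defaults follow the study conventions: 50 PCs, UMAP ``min_dist``
    0.15 with 20 neighbors, and small CPM-style Leiden resolutions
    (2e-4 for a single-genotype subset, 1e-4 for the pooled set).
    """

    n_pcs: int = 50
    n_neighbors: int = 20
    min_dist: float = 0.15
    cluster_resolution: float = 2e-4
    knn_for_clustering: int = 20
    mnn_k: int = 20
    mnn_sigma: float = 20.0
    loading_mode: str = "own_profile"  # or "profile_dot": one column per sample
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pcs < 2:
            raise ValueError("n_pcs must be >= 2")
        if self.cluster_resolution <= 0:
            raise ValueError("cluster_resolution must be positive")


@dataclass
class EmbeddingState:
    size_factors: np.ndarray
    normalized: sp.csr_matrix
    pca: np.ndarray
    ambient_profiles: pd.DataFrame | None = None
    loadings: np.ndarray | None = None
    pca_corrected: np.ndarray | None = None
    pca_aligned: np.ndarray | None = None
    umap2d: np.ndarray | None = None
    clusters: np.ndarray | None = None
    barcodes: np.ndarray | None = field(default=None, repr=False)


def size_factors(totals) -> np.ndarray:
    """Per-cell size factors: total UMIs / geometric mean of totals.

    The geometric mean of the returned factors is exactly 1 (up to
    float rounding).  Zero-total cells are a hard error — they should
    have been removed by QC.
    """
    totals = np.asarray(totals, dtype=float)
    if (totals <= 0).any():
        raise ValueError("all totals must be positive; filter zero-UMI barcodes first")
    return totals / np.exp(np.mean(np.log(totals)))


def normalize(cm_or_counts, sf: np.ndarray) -> sp.csr_matrix:
    """Log size-factor normalization ``x_gi = ln(1 + count_gi / sf_i)``.

    Sparse zeros stay zeros; doubling a count together with its size
    factor leaves the normalized value unchanged.
    """
    counts = cm_or_counts.counts if isinstance(cm_or_counts, CountMatrix) else cm_or_counts
    sf = np.asarray(sf, dtype=float)
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    x = sp.csr_matrix(counts, dtype=float).multiply(1.0 / sf[None, :]).tocsr()
    x.data = np.log1p(x.data)
    return x


def pca(normalized, n_pcs: int, seed: int = 0) -> np.ndarray:
    """Cell x n_pcs PCA scores on all genes, gene-centered, unscaled."""
    X = normalized.T if sp.issparse(normalized) else np.asarray(normalized).T
    if sp.issparse(X):
        X = np.asarray(X.todense())
    if n_pcs > min(X.shape):
        raise ValueError(f"n_pcs={n_pcs} exceeds data rank bound {min(X.shape)}")
    # full SVD: exact and deterministic (seed kept for API compatibility)
    model = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    return model.fit_transform(X)


def ambient_profiles(
    background_groups: dict[str, CountMatrix], eps: float = 1e-9
) -> pd.DataFrame:
    """Per-sample ambient RNA proportion profiles from background barcodes.

    Each sample's sub-threshold barcodes are pooled into proportions,
    smoothed by a tiny uniform ``eps`` and renormalized to sum 1
    (smoothing proportions rather than raw counts keeps the profile
    invariant to duplicating barcodes).  A sample without any background
    barcode falls back to the pooled profile over all samples, with a
    warning.
    """
    pooled_all = None
    raw: dict[str, np.ndarray] = {}
    for sid, grp in background_groups.items():
        counts = np.asarray(grp.counts.sum(axis=1)).ravel().astype(float)
        raw[sid] = counts
        pooled_all = counts if pooled_all is None else pooled_all + counts
    if pooled_all is None or pooled_all.sum() == 0:
        raise ValueError("no background counts available in any sample")
    rows = {}
    for sid, counts in raw.items():
        if counts.sum() == 0:
            warnings.warn(
                f"sample {sid!r} has no background counts; using pooled profile",
                stacklevel=2,
            )
            counts = pooled_all
        p = counts / counts.sum() + eps
        rows[sid] = p / p.sum()
    any_grp = next(iter(background_groups.values()))
    return pd.DataFrame.from_dict(rows, orient="index", columns=any_grp.genes["gene_id"])


def background_loadings(
    normalized,
    profiles: pd.DataFrame,
    sample_ids=None,
    mode: str = "own_profile",
    standardize: bool = True,
) -> np.ndarray:
    """Per-cell background loadings against ambient proportion profiles.

    ``mode="own_profile"`` (default): one column; each cell's loading is
    the dot product of its normalized expression with its *own* sample's
    ambient profile — the sample-specific contamination covariate that
    the regression removes.  Requires ``sample_ids``.

    ``mode="profile_dot"``: one column per sample profile,
    ``loading[i, s] = sum_g x_gi * profile_sg``, regardless of which
    sample cell i belongs to.  With several near-identical profiles the
    columns are strongly collinear and their joint span can eat real
    low-rank structure, which is why this is not the default; it is kept
    because the one-profile-per-sample reading of the correction is a
    genuine alternative.

    Columns are standardized to mean 0 / sd 1 unless ``standardize`` is
    False; zero-variance columns are dropped with a warning.
    """
    P = profiles.to_numpy()  # samples x genes
    raw = (P @ normalized).T if sp.issparse(normalized) else (P @ np.asarray(normalized)).T
    raw = np.asarray(raw, dtype=float)
    if mode == "own_profile":
        if sample_ids is None:
            raise ValueError("mode='own_profile' requires sample_ids")
        col = {s: j for j, s in enumerate(profiles.index)}
        idx = np.array([col[s] for s in np.asarray(sample_ids)])
        raw = raw[np.arange(len(idx)), idx][:, None]
    elif mode != "profile_dot":
        raise ValueError(f"unknown loading mode {mode!r}")
    if not standardize:
        return raw
    sd = raw.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant background loading column(s)",
            stacklevel=2,
        )
    raw = raw[:, keep]
    return (raw - raw.mean(axis=0)) / raw.std(axis=0)


class BackgroundRegressor(BaseEstimator, TransformerMixin):
    """OLS residualization of a PCA matrix on background loadings.

    ``fit(X, loadings=L)`` fits ``X ~ 1 + L`` per PC by least squares;
    ``transform`` returns the residual matrix, which is orthogonal to
    the intercept and to every loading column at machine precision.
    Zero-variance loading columns are dropped; with no usable loadings
    the output is the column-centered input.
    """

    def fit(self, X, y=None, *, loadings=None):
        X = np.asarray(X, dtype=float)
        if loadings is None:
            loadings = np.empty((X.shape[0], 0))
        L = np.asarray(loadings, dtype=float)
        if L.ndim == 1:
            L = L[:, None]
        if L.shape[0] != X.shape[0]:
            raise ValueError(
                f"{X.shape[0]} cells in PCA matrix but {L.shape[0]} in loadings"
            )
        keep = L.std(axis=0) > 0 if L.size else np.zeros(0, dtype=bool)
        if L.size and not keep.all():
            warnings.warn("dropping zero-variance loading columns", stacklevel=2)
        self.loadings_ = L[:, keep] if L.size else L
        self.design_ = np.column_stack([np.ones(X.shape[0]), self.loadings_])
        self.coef_, *_ = np.linalg.lstsq(self.design_, X, rcond=None)
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X - self.design_ @ self.coef_

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X, **fit_params).transform(X)


def regress_out_background(pca_mat, loadings) -> np.ndarray:
    """Residuals of ``pca_mat ~ 1 + loadings`` (background-corrected PCA)."""
    return BackgroundRegressor().fit_transform(pca_mat, loadings=loadings)


class MNNAligner(BaseEstimator, TransformerMixin):
    """Sequential mutual-nearest-neighbor batch alignment in PCA space.

    Batches are merged in order of first appearance; the first batch is
    the unchanged reference.  For each incoming batch, mutual
    k-nearest-neighbor pairs against the accumulated reference define
    pair-wise correction vectors, and every incoming cell is shifted by
    a Gaussian-kernel weighted average of those vectors (bandwidth
    ``sigma`` on the distance to each pair's incoming member).  The
    merge order matters and is therefore part of the contract.
    """

    def __init__(self, k: int = 20, sigma: float = 20.0):
        self.k = k
        self.sigma = sigma

    def fit_transform(self, X, y=None, *, batch=None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if batch is None:
            raise ValueError("batch labels are required")
        batch = np.asarray(batch)
        if batch.shape[0] != X.shape[0]:
            raise ValueError("batch labels must match the number of cells")
        order = pd.unique(batch)
        out = X.copy()
        if len(order) == 1:
            return out
        ref_idx = np.flatnonzero(batch == order[0])
        if len(ref_idx) < 2:
            raise ValueError(f"batch {order[0]!r} has fewer than 2 cells")
        ref_pool = list(ref_idx)
        for b in order[1:]:
            inc_idx = np.flatnonzero(batch == b)
            if len(inc_idx) < 2:
                raise ValueError(f"batch {b!r} has fewer than 2 cells")
            ref = out[ref_pool]
            inc = out[inc_idx]
            k = min(self.k, len(ref), len(inc))
            nn_ri = NearestNeighbors(n_neighbors=k).fit(inc)
            _, ref_to_inc = nn_ri.kneighbors(ref)
            nn_ir = NearestNeighbors(n_neighbors=k).fit(ref)
            _, inc_to_ref = nn_ir.kneighbors(inc)
            inc_nbrs = [set(row) for row in ref_to_inc]
            pairs = [
                (r, j)
                for j in range(len(inc))
                for r in inc_to_ref[j]
                if j in inc_nbrs[r]
            ]
            if not pairs:
                raise ValueError(
                    f"no mutual nearest neighbors between batch {b!r} and the "
                    f"reference; try a larger k (current k={self.k})"
                )
            pr = np.array([p[0] for p in pairs])
            pj = np.array([p[1] for p in pairs])
            vecs = ref[pr] - inc[pj]  # correction vectors toward the reference
            anchors = inc[pj]
            d2 = (
                (inc**2).sum(axis=1)[:, None]
                - 2.0 * inc @ anchors.T
                + (anchors**2).sum(axis=1)[None, :]
            )
            w = np.exp(-np.maximum(d2, 0.0) / (2.0 * self.sigma**2))
            wsum = w.sum(axis=1, keepdims=True)
            # cells far from every anchor fall back to the unweighted mean shift
            uniform = np.full_like(w, 1.0 / w.shape[1])
            w = np.where(wsum > 1e-300, w / np.where(wsum == 0, 1.0, wsum), uniform)
            out[inc_idx] = inc + w @ vecs
            ref_pool.extend(inc_idx)
        return out

    def fit(self, X, y=None, **kw):  # pragma: no cover - alignment is one-shot
        self.aligned_ = self.fit_transform(X, **kw)
        return self


def mnn_align(pca_corrected, batch_labels, mnn_k: int = 20, mnn_sigma: float = 20.0):
    """Functional wrapper over :class:`MNNAligner`."""
    return MNNAligner(k=mnn_k, sigma=mnn_sigma).fit_transform(
        pca_corrected, batch=batch_labels
    )


def umap_embed(pca_aligned, config: EmbedConfig | None = None) -> np.ndarray:
    """2-D UMAP of the aligned PCA matrix — for visualization only."""
    import umap  # deferred: numba compilation is slow at import time

    cfg = config or EmbedConfig()
    X = np.asarray(pca_aligned, dtype=float)
    if cfg.n_neighbors > X.shape[0] - 1:
        raise ValueError(
            f"n_neighbors={cfg.n_neighbors} needs at least {cfg.n_neighbors + 1} cells"
        )
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=cfg.n_neighbors,
        min_dist=cfg.min_dist,
        random_state=cfg.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns about forced determinism
        return np.asarray(reducer.fit_transform(X))


class LeidenClusterer(BaseEstimator, ClusterMixin):
    """Leiden community detection on a k-NN graph of the aligned PCA.

    Uses the constant-Potts-model (CPM) partition, whose small
    resolution values (order 1e-4) control how many cross-edges justify
    merging two groups.
    """

    def __init__(self, resolution: float = 2e-4, knn: int = 20, random_state: int = 0):
        self.resolution = resolution
        self.knn = knn
        self.random_state = random_state

    def fit_predict(self, X, y=None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        k = min(self.knn, X.shape[0] - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
        _, idx = nn.kneighbors(X)
        src = np.repeat(np.arange(X.shape[0]), k)
        dst = idx[:, 1:].ravel()
        edges = {(min(a, b), max(a, b)) for a, b in zip(src, dst)}
        g = igraph.Graph(n=X.shape[0], edges=sorted(edges))
        part = leidenalg.find_partition(
            g,
            leidenalg.CPMVertexPartition,
            resolution_parameter=self.resolution,
            seed=self.random_state,
            n_iterations=2,
        )
        self.labels_ = np.asarray(part.membership)
        return self.labels_

    def fit(self, X, y=None):
        self.fit_predict(X)
        return self


def cluster(pca_aligned, config: EmbedConfig | None = None) -> np.ndarray:
    """Functional wrapper over :class:`LeidenClusterer`."""
    cfg = config or EmbedConfig()
    return LeidenClusterer(
        resolution=cfg.cluster_resolution,
        knn=cfg.knn_for_clustering,
        random_state=cfg.seed,
    ).fit_predict(pca_aligned)


def embed_pipeline(
    cm: CountMatrix,
    background_groups: dict[str, CountMatrix] | None,
    config: EmbedConfig | None = None,
    with_umap: bool = False,
) -> EmbeddingState:
    """Run the full chain: normalize, PCA, correct, align, cluster.

    ``background_groups`` may be None (no ambient correction: the
    corrected matrix is the centered PCA matrix).  Batches for MNN
    alignment are the ``sample_id`` column, merged in order of first
    appearance.
    """
    cfg = config or EmbedConfig()
    sf = size_factors(cm.total_umis)
    norm = normalize(cm, sf)
    P = pca(norm, min(cfg.n_pcs, min(cm.n_genes, cm.n_cells) - 1), seed=cfg.seed)
    state = EmbeddingState(
        size_factors=sf,
        normalized=norm,
        pca=P,
        barcodes=cm.cells["barcode"].to_numpy(),
    )
    if background_groups:
        state.ambient_profiles = ambient_profiles(background_groups)
        state.loadings = background_loadings(
            norm,
            state.ambient_profiles,
            sample_ids=cm.cells["sample_id"].to_numpy(),
            mode=cfg.loading_mode,
        )
        state.pca_corrected = regress_out_background(P, state.loadings)
    else:
        state.pca_corrected = regress_out_background(P, np.empty((cm.n_cells, 0)))
    batches = cm.cells["sample_id"].to_numpy()
    if len(pd.unique(batches)) > 1:
        state.pca_aligned = mnn_align(
            state.pca_corrected, batches, mnn_k=cfg.mnn_k, mnn_sigma=cfg.mnn_sigma
        )
    else:
        state.pca_aligned = state.pca_corrected.copy()
    if with_umap:
        state.umap2d = umap_embed(state.pca_aligned, cfg)
    state.clusters = cluster(state.pca_aligned, cfg)
    return state
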