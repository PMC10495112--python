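"""Barcode-level quality control.

Real cells are kept when their UMI total lies in ``(min_umi, max_umi]``
(strictly more than 600, at most 6000 by default — barcodes above the
upper bound are discarded as likely multiplets).  Barcodes below 15 UMIs
are harvested per sample as the ambient-RNA background.  The knee curve
is a diagnostic only; the cut itself is configuration-driven.

Doublet detection is a deliberately simple nearest-neighbor heuristic:
simulated doublets are synthesized by averaging random cell pairs in PCA
space, and each cell is scored by the fraction of simulated doublets
among its nearest neighbors in the pooled set; the top fraction of cells
at a prior rate (default 11%) is flagged.  This trades the full
variance-normalized re-projection of dedicated doublet callers for a
deterministic, testable stand-in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_is_fitted

from .io import CountMatrix

__all__ = [
    "QCThresholds",
    "filter_barcodes",
    "split_background",
    "knee_curve",
    "DoubletDetector",
    "doublet_scores",
]


@dataclass
class QCThresholds:
    min_umi: int = 600
    max_umi: int = 6000
    background_max_umi: int = 15
    doublet_rate_prior: float = 0.11
    knn_k: int = 30

    def __post_init__(self) -> None:
        if not self.background_max_umi < self.min_umi < self.max_umi:
            raise ValueError(
                "thresholds must satisfy background_max_umi < min_umi < max_umi"
            )
        if not 0.0 <= self.doublet_rate_prior < 1.0:
            raise ValueError("doublet_rate_prior must lie in [0, 1)")


def filter_barcodes(
    cm: CountMatrix, thresholds: QCThresholds | None = None
) -> tuple[CountMatrix, CountMatrix]:
    """Partition barcodes above ``min_umi`` into kept and discarded-high.

    Kept: ``min_umi < total <= max_umi``.  Discarded-high: ``total >
    max_umi``.  Barcodes at or below ``min_umi`` fall in neither output.
    """
    t = thresholds or QCThresholds()
    totals = cm.total_umis
    kept = cm.subset_cells((totals > t.min_umi) & (totals <= t.max_umi))
    high = cm.subset_cells(totals > t.max_umi)
    return kept, high


def split_background(
    cm: CountMatrix, thresholds: QCThresholds | None = None
) -> dict[str, CountMatrix]:
    """Harvest per-sample background barcodes (``total < background_max_umi``)."""
    t = thresholds or QCThresholds()
    totals = cm.total_umis
    out: dict[str, CountMatrix] = {}
    for sample_id, grp in cm.cells.groupby("sample_id", sort=True):
        mask = np.zeros(cm.n_cells, dtype=bool)
        mask[grp.index] = True
        mask &= totals < t.background_max_umi
        if not mask.any():
            warnings.warn(
                f"sample {sample_id!r} has no background barcodes", stacklevel=2
            )
        out[str(sample_id)] = cm.subset_cells(mask)
    return out


def knee_curve(totals) -> pd.DataFrame:
    """Rank-vs-UMI table for the knee diagnostic, sorted descending.

    Ties are broken by barcode position/lexicographic order so output is
    deterministic.  No threshold is chosen automatically.
    """
    s = pd.Series(np.asarray(totals))
    if s.empty:
        raise ValueError("need at least one barcode")
    s = s.sort_values(ascending=False, kind="stable")
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(s) + 1),
            "barcode_index": s.index.to_numpy(),
            "total_umis": s.to_numpy(),
        }
    )


class DoubletDetector(BaseEstimator):
    """Simulated-doublet k-NN scorer in PCA space.

    Parameters
    ----------
    doublet_rate_prior : float
        Fraction of cells to flag (ranked by score, ties broken by cell
        index).  The flagged count is exactly ``round(prior * n_cells)``.
    knn_k : int
        Neighborhood size used for scoring.
    n_simulated : int or None
        Number of synthetic doublets (averages of random cell pairs);
        defaults to the number of cells.
    random_state : int
        Seed for pair sampling.

    Attributes
    ----------
    scores_ : ndarray of shape (n_cells,)
        Fraction of simulated doublets among each cell's neighbors,
        rescaled to account for the simulated:observed pool ratio only
        implicitly (raw fraction in [0, 1]).
    flags_ : boolean ndarray of shape (n_cells,)
    """

    def __init__(
        self,
        doublet_rate_prior: float = 0.11,
        knn_k: int = 30,
        n_simulated: int | None = None,
        random_state: int = 0,
    ):
        self.doublet_rate_prior = doublet_rate_prior
        self.knn_k = knn_k
        self.n_simulated = n_simulated
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if n <= self.knn_k:
            raise ValueError(f"need more than knn_k={self.knn_k} cells, got {n}")
        rng = np.random.default_rng(self.random_state)
        n_sim = self.n_simulated if self.n_simulated is not None else n
        pairs = rng.integers(0, n, size=(n_sim, 2))
        sim = 0.5 * (X[pairs[:, 0]] + X[pairs[:, 1]])
        pool = np.vstack([X, sim])
        is_sim = np.zeros(len(pool), dtype=bool)
        is_sim[n:] = True
        nn = NearestNeighbors(n_neighbors=self.knn_k + 1).fit(pool)
        _, idx = nn.kneighbors(X)
        idx = idx[:, 1:]  # drop self (a cell is always its own nearest point)
        self.scores_ = is_sim[idx].mean(axis=1)
        n_flag = int(round(self.doublet_rate_prior * n))
        flags = np.zeros(n, dtype=bool)
        if n_flag > 0:
            # stable sort => ties resolved by cell index
            order = np.argsort(-self.scores_, kind="stable")
            flags[order[:n_flag]] = True
        self.flags_ = flags
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).flags_


def doublet_scores(
    pca_coords, thresholds: QCThresholds | None = None, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Functional wrapper over :class:`DoubletDetector`."""
    t = thresholds or QCThresholds()
    det = DoubletDetector(
        doublet_rate_prior=t.doublet_rate_prior, knn_k=t.knn_k, random_state=seed
    ).fit(pca_coords)
    check_is_fitted(det)
    return det.scores_, det.flags_
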