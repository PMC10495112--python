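"""Cell-type abundance comparison and per-cell-type differential expression.

Abundance: per-sample cell totals are turned into size factors (total /
geometric mean of totals), per-type counts are pseudocounted and
size-factor normalized, and differences are reported as
``log2(normalized query count / normalized reference count)`` against a
named reference sample.  The default pseudocount of 1 keeps genotypes
that have lost a cell type entirely (zero cells) at finite, strongly
negative ratios.

Differential expression fits, per gene and within one cell type, UMI
counts against a two-level condition with a Poisson log-link GLM whose
offset is the log cell size factor.  For this saturated two-group
design the maximum-likelihood solution is closed-form (group rate =
group count sum / group size-factor sum), which this module uses
directly; a quasi-likelihood correction then inflates the Wald standard
error by the Pearson dispersion (floored at 1).  Genes expressed in
fewer than 10 cells are excluded before testing, and Benjamini-Hochberg
q-values are computed over the tested genes only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .io import CountMatrix

__all__ = [
    "AbundanceTable",
    "abundance_log2",
    "fit_gene_glm",
    "bh_adjust",
    "count_degs",
    "BETA_CAP",
]

BETA_CAP = 20.0  # |log fold change| bound reported under complete separation


@dataclass
class AbundanceTable:
    counts: pd.DataFrame  # cell-type x sample integers
    sample_size_factors: pd.Series
    normalized: pd.DataFrame
    log2_ratio: pd.DataFrame
    reference_sample: str
    pseudocount: float


def abundance_log2(
    type_sample_counts: pd.DataFrame,
    reference_sample: str,
    pseudocount: float = 1.0,
) -> AbundanceTable:
    """Log2 cell-type abundance ratios of every sample vs a reference.

    ``sf_s = total_s / geomean(totals)``; ``norm = (count + pseudocount)
    / sf``; ``log2_ratio = log2(norm / norm_ref)``.  The pseudocount is
    applied to query and reference symmetrically.
    """
    counts = type_sample_counts.astype(float)
    if reference_sample not in counts.columns:
        raise KeyError(f"reference sample {reference_sample!r} not in table")
    if (counts.values < 0).any():
        raise ValueError("cell counts must be nonnegative")
    if counts[reference_sample].sum() == 0:
        raise ValueError(f"reference sample {reference_sample!r} has no cells")
    totals = counts.sum(axis=0)
    sf = totals / np.exp(np.mean(np.log(totals)))
    norm = (counts + pseudocount) / sf
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_ratio = np.log2(norm.div(norm[reference_sample], axis=0))
    return AbundanceTable(
        counts=type_sample_counts.copy(),
        sample_size_factors=sf,
        normalized=norm,
        log2_ratio=log2_ratio,
        reference_sample=reference_sample,
        pseudocount=pseudocount,
    )


def fit_gene_glm(
    cm_subset: CountMatrix,
    condition_labels,
    cell_size_factors,
    min_cells_expressing: int = 10,
    reference_level=None,
) -> pd.DataFrame:
    """Per-gene quasi-Poisson GLM for a two-level condition contrast.

    The model is ``count ~ Poisson(sf * exp(b0 + b1 * [cond == B]))``;
    ``b1`` is the natural-log fold change of condition B over the
    reference A (first label in order of appearance unless
    ``reference_level`` names it).  Standard errors come from the
    Fisher information, inflated by ``max(1, Pearson chi^2 / df)``.
    Genes detected in fewer than ``min_cells_expressing`` cells are
    omitted from the output (and therefore from the BH correction).
    Complete separation (a gene detected in one condition only) is
    reported with ``|beta|`` capped at 20 and ``separation=True``.
    """
    labels = np.asarray(condition_labels)
    levels = list(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 condition levels, got {levels}")
    if reference_level is not None:
        if reference_level not in levels:
            raise ValueError(f"{reference_level!r} is not a condition level")
        levels = [reference_level] + [l for l in levels if l != reference_level]
    mask_b = labels == levels[1]
    sf = np.asarray(cell_size_factors, dtype=float)
    if (sf <= 0).any():
        raise ValueError("cell size factors must be positive")
    counts = sp.csr_matrix(cm_subset.counts)
    n_expr = np.diff(counts.tocsr().indptr)
    keep = np.flatnonzero(n_expr >= min_cells_expressing)

    S_a = sf[~mask_b].sum()
    S_b = sf[mask_b].sum()
    n = len(labels)
    rows = []
    for g in keep:
        y = np.asarray(counts[g].todense()).ravel().astype(float)
        Y_a = y[~mask_b].sum()
        Y_b = y[mask_b].sum()
        separation = (Y_a == 0) or (Y_b == 0)
        # Haldane-style half-count continuity for SE under separation
        Ya_se, Yb_se = max(Y_a, 0.5), max(Y_b, 0.5)
        if separation:
            beta = np.sign(Y_b - Y_a) * BETA_CAP
        else:
            beta = np.log((Y_b / S_b) / (Y_a / S_a))
        mu = np.where(mask_b, sf * (Yb_se / S_b), sf * (Ya_se / S_a))
        pearson = float(((y - mu) ** 2 / mu).sum())
        df = max(n - 2, 1)
        phi = max(1.0, pearson / df)
        se = np.sqrt((1.0 / Ya_se + 1.0 / Yb_se) * phi)
        z = beta / se
        p = 2.0 * scipy.stats.norm.sf(abs(z))
        rows.append(
            {
                "gene_id": cm_subset.genes["gene_id"].iloc[g],
                "n_cells_expressing": int(n_expr[g]),
                "beta": float(beta),
                "fold_change": float(np.exp(beta)),
                "se": float(se),
                "wald_p": float(p),
                "separation": bool(separation),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "n_cells_expressing", "beta", "fold_change",
            "se", "wald_p", "separation",
        ],
    )
    table["q_bh"] = bh_adjust(table["wald_p"].to_numpy()) if len(table) else []
    return table


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, clipped at 1.

    ``q_i = min over {j : p_j >= p_i} of (m * p_j / rank_j)``, computed
    literally in that arithmetic so the result is bit-identical to the
    step-up definition (library implementations can differ by one ulp
    through a different operation order).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    stepped = m * p[order] / ranks
    q_sorted = np.minimum(np.minimum.accumulate(stepped[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def count_degs(
    de_table: pd.DataFrame, q_threshold: float = 0.05, min_fold_change: float = 1.0
) -> int:
    """Number of genes with ``q < q_threshold`` and fold-change magnitude
    strictly above ``min_fold_change`` (1 disables the effect filter)."""
    if len(de_table) == 0:
        return 0
    sig = de_table["q_bh"].to_numpy() < q_threshold
    if min_fold_change > 1.0:
        fc = de_table["fold_change"].to_numpy()
        sig &= np.maximum(fc, 1.0 / fc) > min_fold_change
    return int(sig.sum())
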