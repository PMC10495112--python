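"""Synthetic sci-RNA-seq-style count generator with known ground truth.

The generator emulates the structure of a combinatorial-indexing
single-nucleus experiment in which several genotypes are pooled in one
run and distinguished by their reverse-transcription index: per-sample
ambient RNA contamination, doublet barcodes, sub-15-UMI empty barcodes,
very unequal cell-type abundances that differ across genotypes,
genotype-restricted expression changes in chosen genes, and an optional
continuous differentiation trajectory within one lineage.

Counts for a real cell are multinomial given a lognormal library size:
``counts ~ Multinomial(L, (1-rho) * p + rho * a)`` where ``p`` is the
cell's expression program and ``a`` the sample ambient profile (the
abundance-weighted mean of that sample's programs, mirroring supernatant
RNA pooling).  Overdispersion enters through lognormal library sizes and
program heterogeneity rather than per-gene negative binomials, which
keeps the ambient mixture exact and closed-form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix

__all__ = [
    "ProgramSet",
    "SampleSpec",
    "DESpec",
    "TrajectorySpec",
    "SimConfig",
    "TruthTable",
    "make_programs",
    "simulate_dataset",
    "simulate_trajectory",
]


@dataclass
class ProgramSet:
    """Per-type relative expression programs.

    ``rates`` is a cell-type x gene matrix whose rows sum to one; the
    marker genes of type k have a strictly higher rate in row k than in
    any other row.
    """

    type_names: list[str]
    rates: np.ndarray
    markers: list[np.ndarray]

    @property
    def n_types(self) -> int:
        return self.rates.shape[0]

    @property
    def n_genes(self) -> int:
        return self.rates.shape[1]

    def validate(self) -> None:
        sums = self.rates.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("program rows must each sum to 1")
        for k, marks in enumerate(self.markers):
            for g in marks:
                others = np.delete(self.rates[:, g], k)
                if others.size and not (self.rates[k, g] > others).all():
                    raise ValueError(
                        f"marker gene {g} of type {self.type_names[k]} is not "
                        "strictly enriched over every other type"
                    )


@dataclass
class SampleSpec:
    """One pooled library (one genotype, one RT index).

    ``ambient_fraction`` is the mean per-cell contamination fraction;
    individual cells draw their own fraction from a Beta distribution
    with this mean and concentration ``ambient_concentration``, because
    contamination load varies from nucleus to nucleus in real
    preparations (set the concentration very high for an effectively
    fixed fraction).
    """

    sample_id: str
    genotype: str
    n_cells: int
    ambient_fraction: float = 0.0
    n_empty_barcodes: int = 0
    ambient_concentration: float = 6.0


@dataclass
class DESpec:
    """One genotype-restricted rate shift: gene x cell type x genotype."""

    gene: int
    cell_type: str
    genotype: str
    fold_change: float


@dataclass
class TrajectorySpec:
    """A linear differentiation path between two type programs.

    Cells receive a latent time ``t ~ Uniform(0, 1)`` and the program
    ``(1 - t) * p_start + t * p_end``; they are added to ``sample_id``
    on top of that sample's discrete-type cells.
    """

    start_type: str
    end_type: str
    n_cells: int
    sample_id: str | None = None  # default: first sample


@dataclass
class SimConfig:
    programs: ProgramSet
    samples: list[SampleSpec]
    abundance_multipliers: np.ndarray | None = None  # sample x type, > 0
    base_abundance: np.ndarray | None = None  # per type, default uniform
    de_spec: list[DESpec] = field(default_factory=list)
    doublet_rate: float = 0.0
    library_size_lognormal: tuple[float, float] = (7.1, 0.5)
    min_library_size: int = 50
    trajectory: TrajectorySpec | None = None
    seed: int = 0

    def validate(self) -> None:
        self.programs.validate()
        if not 0.0 <= self.doublet_rate < 0.5:
            raise ValueError("doublet_rate must lie in [0, 0.5)")
        for s in self.samples:
            if not 0.0 <= s.ambient_fraction < 1.0:
                raise ValueError(f"{s.sample_id}: ambient_fraction must be in [0, 1)")
        mult = self._multipliers()
        if (mult <= 0).any():
            raise ValueError("abundance multipliers must be positive")
        names = set(self.programs.type_names)
        for de in self.de_spec:
            if de.cell_type not in names:
                raise ValueError(f"de_spec references unknown cell type {de.cell_type!r}")
            if not 0 <= de.gene < self.programs.n_genes:
                raise ValueError(f"de_spec references unknown gene index {de.gene}")
            if de.fold_change <= 0:
                raise ValueError("de_spec fold changes must be positive")
        if self.trajectory is not None:
            for t in (self.trajectory.start_type, self.trajectory.end_type):
                if t not in names:
                    raise ValueError(f"trajectory references unknown cell type {t!r}")

    def _multipliers(self) -> np.ndarray:
        if self.abundance_multipliers is None:
            return np.ones((len(self.samples), self.programs.n_types))
        return np.asarray(self.abundance_multipliers, dtype=float)

    def _base(self) -> np.ndarray:
        if self.base_abundance is None:
            return np.ones(self.programs.n_types)
        return np.asarray(self.base_abundance, dtype=float)


@dataclass
class TruthTable:
    """Ground truth for one simulated dataset.

    ``barcodes`` has one row per emitted barcode (true_type, sample_id,
    genotype, is_doublet, is_empty, latent_time).  ``ambient_profiles``
    holds the exact per-sample mixing distributions used when sampling.
    ``log2_abundance_ratios`` gives, per (cell type, sample), the log2
    ratio of the expected within-sample type proportion versus the
    reference (first) sample.  ``de_genes`` lists the injected
    expression shifts.
    """

    barcodes: pd.DataFrame
    ambient_profiles: pd.DataFrame  # sample x gene
    log2_abundance_ratios: pd.DataFrame  # type x sample
    de_genes: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.barcodes.to_csv(path, sep="\t", index=False)


def make_programs(
    n_types: int,
    n_genes: int,
    n_markers_per_type: int,
    marker_boost: float,
    seed: int,
    type_sd: float = 0.15,
) -> ProgramSet:
    """Draw cell-type programs with disjoint, strictly enriched marker sets.

    Gene-level base rates are shared lognormals, so most of the
    transcriptome is common to all types (as it is for related cell
    types in one tissue); types deviate through a small per-type
    lognormal jitter (``type_sd``) plus their marker modules, whose
    rates are raised to ``marker_boost`` times the highest rate of that
    gene in any other type before rows are renormalized.  Deterministic
    given ``seed``.
    """
    if marker_boost <= 1:
        raise ValueError("marker_boost must exceed 1")
    if n_markers_per_type * n_types > n_genes:
        raise ValueError(
            f"{n_types} types x {n_markers_per_type} markers exceed {n_genes} genes"
        )
    rng = np.random.default_rng(seed)
    gene_scale = rng.lognormal(0.0, 1.0, size=n_genes)
    rates = gene_scale * rng.lognormal(0.0, type_sd, size=(n_types, n_genes))
    order = rng.permutation(n_genes)
    markers = [
        np.sort(order[k * n_markers_per_type : (k + 1) * n_markers_per_type])
        for k in range(n_types)
    ]
    if n_types == 1:
        markers = [np.arange(n_genes)]
    # Enforce strict marker enrichment after row renormalization; boosting
    # one row inflates its sum, so repeat until a fixed point.
    for _ in range(200):
        rates = rates / rates.sum(axis=1, keepdims=True)
        if n_types == 1:
            break
        changed = False
        for k, marks in enumerate(markers):
            others = np.delete(rates[:, marks], k, axis=0)
            target = marker_boost * others.max(axis=0)
            low = rates[k, marks] < target
            if low.any():
                rates[k, marks[low]] = target[low]
                changed = True
        if not changed:
            break
    else:  # pragma: no cover - fixed point reached within a few rounds
        raise RuntimeError("marker enforcement did not converge")
    ps = ProgramSet(
        type_names=[f"type{k:02d}" for k in range(n_types)],
        rates=rates,
        markers=markers,
    )
    ps.validate()
    return ps


def _shifted_program(rates: np.ndarray, shifts: list[DESpec]) -> np.ndarray:
    p = rates.copy()
    for de in shifts:
        p[de.gene] *= de.fold_change
    return p / p.sum()


def simulate_dataset(config: SimConfig) -> tuple[CountMatrix, TruthTable]:
    """Simulate one pooled multi-sample experiment.

    Returns the count matrix over all emitted barcodes (real cells,
    doublets, and empty barcodes, per sample) and the matching truth
    table.  Byte-identical for identical configs and seeds.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ps = config.programs
    type_index = {t: k for k, t in enumerate(ps.type_names)}
    mult = config._multipliers()
    base = config._base()
    meanlog, sdlog = config.library_size_lognormal

    # Per-(sample, genotype, type) programs after genotype-restricted shifts.
    sample_programs: list[np.ndarray] = []
    for si, s in enumerate(config.samples):
        progs = np.empty_like(ps.rates)
        for k, tname in enumerate(ps.type_names):
            shifts = [
                de
                for de in config.de_spec
                if de.cell_type == tname and de.genotype == s.genotype
            ]
            progs[k] = _shifted_program(ps.rates[k], shifts) if shifts else ps.rates[k]
        sample_programs.append(progs)

    # Sample ambient profile: abundance-weighted mean of its programs.
    weights = base[None, :] * mult  # sample x type
    weights = weights / weights.sum(axis=1, keepdims=True)
    ambient = np.stack(
        [weights[si] @ sample_programs[si] for si in range(len(config.samples))]
    )

    def draw_library_sizes(n: int) -> np.ndarray:
        L = np.round(rng.lognormal(meanlog, sdlog, size=n)).astype(np.int64)
        return np.maximum(L, config.min_library_size)

    cols: list[np.ndarray] = []
    col_gene_idx: list[np.ndarray] = []
    records: list[dict] = []

    def emit(vec_counts: np.ndarray, **rec) -> None:
        nz = np.flatnonzero(vec_counts)
        col_gene_idx.append(nz)
        cols.append(vec_counts[nz])
        records.append(rec)

    for si, s in enumerate(config.samples):
        a_s = ambient[si]
        progs = sample_programs[si]
        n_doub = int(round(config.doublet_rate * s.n_cells))
        n_single = s.n_cells - n_doub

        def draw_rho() -> float:
            if s.ambient_fraction == 0.0:
                return 0.0
            c = s.ambient_concentration
            return float(
                rng.beta(s.ambient_fraction * c, (1.0 - s.ambient_fraction) * c)
            )

        def draw_cell(type_k: int, rho: float) -> np.ndarray:
            L = draw_library_sizes(1)[0]
            mix = (1.0 - rho) * progs[type_k] + rho * a_s
            return rng.multinomial(L, mix)

        type_counts = rng.multinomial(n_single, weights[si])
        c = 0
        for k in range(ps.n_types):
            for _ in range(type_counts[k]):
                rho = draw_rho()
                emit(
                    draw_cell(k, rho),
                    barcode=f"{s.sample_id}_c{c:05d}",
                    true_type=ps.type_names[k],
                    sample_id=s.sample_id,
                    genotype=s.genotype,
                    is_doublet=False,
                    is_empty=False,
                    latent_time=np.nan,
                    ambient_fraction=rho,
                )
                c += 1
        for _ in range(n_doub):
            ka, kb = rng.choice(ps.n_types, size=2, p=weights[si])
            rho_a, rho_b = draw_rho(), draw_rho()
            emit(
                draw_cell(ka, rho_a) + draw_cell(kb, rho_b),
                barcode=f"{s.sample_id}_c{c:05d}",
                true_type=f"{ps.type_names[ka]}+{ps.type_names[kb]}",
                sample_id=s.sample_id,
                genotype=s.genotype,
                is_doublet=True,
                is_empty=False,
                latent_time=np.nan,
                ambient_fraction=0.5 * (rho_a + rho_b),
            )
            c += 1
        traj = config.trajectory
        traj_here = traj is not None and (
            traj.sample_id == s.sample_id
            or (traj.sample_id is None and si == 0)
        )
        if traj_here:
            p_start = progs[type_index[traj.start_type]]
            p_end = progs[type_index[traj.end_type]]
            tvals = rng.uniform(0.0, 1.0, size=traj.n_cells)
            Ls = draw_library_sizes(traj.n_cells)
            for t, L in zip(tvals, Ls):
                rho = draw_rho()
                p_t = (1.0 - t) * p_start + t * p_end
                mix = (1.0 - rho) * p_t + rho * a_s
                emit(
                    rng.multinomial(L, mix),
                    barcode=f"{s.sample_id}_c{c:05d}",
                    true_type=f"traj:{traj.start_type}->{traj.end_type}",
                    sample_id=s.sample_id,
                    genotype=s.genotype,
                    is_doublet=False,
                    is_empty=False,
                    latent_time=float(t),
                    ambient_fraction=rho,
                )
                c += 1
        for e in range(s.n_empty_barcodes):
            L = int(rng.integers(1, 15))  # empties stay below the 15-UMI rule
            emit(
                rng.multinomial(L, a_s),
                barcode=f"{s.sample_id}_e{e:05d}",
                true_type="empty",
                sample_id=s.sample_id,
                genotype=s.genotype,
                is_doublet=False,
                is_empty=True,
                latent_time=np.nan,
                ambient_fraction=1.0,
            )

    n_cols = len(cols)
    indptr = np.zeros(n_cols + 1, dtype=np.int64)
    indptr[1:] = np.cumsum([len(v) for v in cols])
    csc = sp.csc_matrix(
        (
            np.concatenate(cols) if cols else np.empty(0, dtype=np.int64),
            np.concatenate(col_gene_idx) if cols else np.empty(0, dtype=np.int64),
            indptr,
        ),
        shape=(ps.n_genes, n_cols),
    )
    barcodes = pd.DataFrame.from_records(records)
    rt_by_sample = {s.sample_id: f"RT{si:02d}" for si, s in enumerate(config.samples)}
    cells = pd.DataFrame(
        {
            "barcode": barcodes["barcode"],
            "sample_id": barcodes["sample_id"],
            "genotype": barcodes["genotype"],
            "rt_index": barcodes["sample_id"].map(rt_by_sample),
        }
    )
    gene_ids = [f"g{j:05d}" for j in range(ps.n_genes)]
    genes = pd.DataFrame({"gene_id": gene_ids, "gene_name": gene_ids})
    cm = CountMatrix(counts=csc.tocsr(), genes=genes, cells=cells)

    props = weights  # expected within-sample type proportions
    ratios = np.log2(props / props[0][None, :]).T  # type x sample
    truth = TruthTable(
        barcodes=barcodes,
        ambient_profiles=pd.DataFrame(
            ambient,
            index=[s.sample_id for s in config.samples],
            columns=gene_ids,
        ),
        log2_abundance_ratios=pd.DataFrame(
            ratios,
            index=ps.type_names,
            columns=[s.sample_id for s in config.samples],
        ),
        de_genes=pd.DataFrame(
            [
                {
                    "gene_id": gene_ids[de.gene],
                    "gene_index": de.gene,
                    "cell_type": de.cell_type,
                    "genotype": de.genotype,
                    "fold_change": de.fold_change,
                }
                for de in config.de_spec
            ],
            columns=["gene_id", "gene_index", "cell_type", "genotype", "fold_change"],
        ),
    )
    return cm, truth


def simulate_trajectory(config: SimConfig) -> tuple[CountMatrix, TruthTable]:
    """Simulate a dataset whose config includes a differentiation trajectory."""
    if config.trajectory is None:
        raise ValueError("config.trajectory must be set for simulate_trajectory")
    return simulate_dataset(config)
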