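import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from skinsci import synthetic as syn
from skinsci.io import CountMatrix


@pytest.fixture(scope="session")
def small_programs() -> syn.ProgramSet:
    return syn.make_programs(
        n_types=4, n_genes=200, n_markers_per_type=10, marker_boost=8.0, seed=11
    )


@pytest.fixture(scope="session")
def two_sample_sim(small_programs):
    """Two-genotype simulation with contamination, doublets and empties."""
    cfg = syn.SimConfig(
        programs=small_programs,
        samples=[
            syn.SampleSpec("wt", "wildtype", 400, 0.2, 150),
            syn.SampleSpec("mut", "mutant", 400, 0.1, 150),
        ],
        doublet_rate=0.11,
        seed=3,
    )
    return syn.simulate_dataset(cfg)


def toy_count_matrix(counts: np.ndarray, sample_ids=None) -> CountMatrix:
    """Dense array -> CountMatrix with minimal annotations."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    if sample_ids is None:
        sample_ids = ["s1"] * n_cells
    genes = pd.DataFrame(
        {"gene_id": [f"g{i:03d}" for i in range(n_genes)],
         "gene_name": [f"gene{i}" for i in range(n_genes)]}
    )
    cells = pd.DataFrame(
        {"barcode": [f"bc{i:04d}" for i in range(n_cells)],
         "sample_id": sample_ids,
         "genotype": sample_ids,
         "rt_index": ["RT00"] * n_cells}
    )
    return CountMatrix(counts=sp.csr_matrix(counts), genes=genes, cells=cells)
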