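import numpy as np
import pytest

import immunosift as ims
from immunosift.io import NormalizedMatrix


@pytest.fixture(scope="session")
def small_config() -> ims.SyntheticConfig:
    return ims.SyntheticConfig(
        cells_per_clone_per_timepoint=60,
        n_genes=400,
        timepoints=(0, 6),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    ds, truth = ims.generate_scc_experiment(small_config)
    return ds, truth


@pytest.fixture(scope="session")
def small_normalized(small_experiment):
    ds, truth = small_experiment
    kept, _ = ims.filter_cells(ds)
    norm = ims.lognormalize(kept)
    return norm, kept.cell_meta, truth


def make_norm(values: np.ndarray, genes=None, cells=None) -> NormalizedMatrix:
    """Hand-built normalized matrix for unit fixtures."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[1])]
    cells = cells or [f"c{i}" for i in range(values.shape[0])]
    return NormalizedMatrix(values=values, gene_names=list(genes), cell_ids=list(cells))
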