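import numpy as np
import pandas as pd
import pytest

from ctspec import CellTypeProfile, GeneStats, RawExpressionMatrix


def make_profile(E, dataset_id="d1", genes=None, cell_types=None):
    E = np.asarray(E, dtype=float)
    genes = genes or [f"g{i:04d}" for i in range(E.shape[0])]
    cell_types = cell_types or [f"ct{j}" for j in range(E.shape[1])]
    return CellTypeProfile(dataset_id=dataset_id,
                           E=pd.DataFrame(E, index=genes, columns=cell_types))


def random_profile(rng, n_genes=300, n_cell_types=4, dataset_id="d1", genes=None):
    E = np.abs(rng.normal(2.0, 1.0, size=(n_genes, n_cell_types)))
    return make_profile(E, dataset_id=dataset_id, genes=genes)


def null_stats(rng, genes, trait_id="null"):
    return GeneStats(z=pd.Series(rng.normal(0, 1, len(genes)), index=list(genes)),
                     trait_id=trait_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_raw():
    """3 genes x 4 cells, two cell types, counts."""
    values = pd.DataFrame(
        [[2.0, 0.0, 1.0, 3.0],
         [3.0, 10.0, 1.0, 3.0],
         [5.0, 0.0, 2.0, 2.0]],
        index=["gA", "gB", "gC"],
        columns=["c1", "c2", "c3", "c4"])
    labels = pd.Series({"c1": "T1", "c2": "T1", "c3": "T2", "c4": "T2"})
    return RawExpressionMatrix(values=values, unit="count", labels=labels)


@pytest.fixture
def simple_profile():
    return make_profile([[0.0, 1.0, 2.0],
                         [1.0, 1.0, 2.0],
                         [2.0, 2.0, 2.0],
                         [0.0, 3.0, 0.0],
                         [4.0, 0.0, 1.0]])
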