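import numpy as np
import pytest

from lrcomm import (
    CCCConfig,
    ExpressionDataset,
    benchmark_spec,
    load_toy_knowledgebase,
    simulate_expression,
)
from lrcomm.knowledgebase import Knowledgebase, LRPair, PathwayComponent


@pytest.fixture(scope="session")
def toy_kb():
    return load_toy_knowledgebase()


@pytest.fixture(scope="session")
def small_ds(toy_kb):
    """~180-cell, 6-type dataset with planted events (session-shared)."""
    spec = benchmark_spec(toy_kb, seed=7, n_cells_per_type=30)
    return simulate_expression(spec)


@pytest.fixture
def mini_kb():
    """One JAK-STAT pair plus one Notch pair, with reporter annotations."""
    return Knowledgebase(
        pairs=[
            LRPair("upd3", "dome", "JAK-STAT", "high"),
            LRPair("Dl", "N", "Notch", "moderate"),
        ],
        components=[
            PathwayComponent("JAK-STAT", "upd3", "ligand"),
            PathwayComponent("JAK-STAT", "dome", "receptor"),
            PathwayComponent("JAK-STAT", "Socs36E", "reporter"),
            PathwayComponent("Notch", "Dl", "ligand"),
            PathwayComponent("Notch", "N", "receptor"),
        ],
    )


def make_dataset(matrix, cell_types, gene_ids, sample=None):
    matrix = np.asarray(matrix, dtype=float)
    return ExpressionDataset(
        matrix=matrix,
        cell_ids=[f"c{i}" for i in range(matrix.shape[0])],
        gene_ids=list(gene_ids),
        cell_type=np.asarray(cell_types, dtype=object),
        sample=None if sample is None else np.asarray(sample, dtype=object),
    )


@pytest.fixture
def planted_two_type_ds():
    """Ligand expressed only in type A, receptor only in type B."""
    rng = np.random.default_rng(0)
    n = 40
    mat = np.zeros((2 * n, 2))
    mat[:n, 0] = 2.0 + rng.random(n)      # ligand in A
    mat[n:, 1] = 2.0 + rng.random(n)      # receptor in B
    return make_dataset(mat, ["A"] * n + ["B"] * n, ["lig", "rec"])


@pytest.fixture
def one_pair_kb():
    return Knowledgebase(pairs=[LRPair("lig", "rec", "toy", "high")])


def default_cfg(**kw):
    kw.setdefault("n_permutations", 200)
    kw.setdefault("seed", 0)
    return CCCConfig(**kw)
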