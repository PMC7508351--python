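"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pytest

from symisle import expression as ex
from symisle import pipeline as pl
from symisle.homology import SimilarityHit, select_best_hits
from symisle.simulate import (
    SimulationConfig,
    simulate_genome_pair,
    simulate_similarity,
)


def hits_from_frame(frame):
    """Convert the simulator's similarity DataFrame into SimilarityHit objects."""
    return [SimilarityHit(*row) for row in frame.itertuples(index=False)]


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=7,
        n_islands_per_category={"NRU": 25, "NRD": 10, "NRN": 10, "NDD": 5},
        n_ril_contigs=12,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_genome_pair(small_config)


@pytest.fixture(scope="session")
def small_best_hits(small_config, small_genome):
    *_rest, truth = small_genome
    frame = simulate_similarity(truth, small_config)
    return select_best_hits(hits_from_frame(frame))


@pytest.fixture(scope="session")
def small_members(small_genome):
    genes_a, *_ = small_genome
    return pl.island_members_from_gene_table(genes_a)


@pytest.fixture(scope="session")
def small_calls(small_members, small_best_hits, small_genome):
    _, genes_b, *_ = small_genome
    return pl.call_all_islands(small_members, small_best_hits, genes_b)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def toy_matrix(rows, columns=None, genes=None):
    """Small count DataFrame helper."""
    import pandas as pd

    arr = np.asarray(rows, dtype=float)
    columns = columns or [f"s{j + 1}" for j in range(arr.shape[1])]
    genes = genes or [f"g{i + 1}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=genes, columns=columns)


@pytest.fixture
def expression_matrix_factory():
    import pandas as pd

    def make(counts, conditions, species="A"):
        frame = toy_matrix(counts)
        meta = pd.DataFrame(
            {
                "sample_id": list(frame.columns),
                "species": species,
                "condition": conditions,
                "replicate": range(1, len(frame.columns) + 1),
            }
        )
        return ex.ExpressionMatrix(counts=frame, samples=meta)

    return make
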