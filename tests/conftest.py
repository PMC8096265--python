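import numpy as np
import pandas as pd
import pytest

from checs import (
    CountMatrix,
    ScreenSimParams,
    build_manifest,
    simulate_screen,
)


@pytest.fixture(scope="session")
def small_manifest():
    return build_manifest(n_genes=20, guides_per_gene=(4, 6), n_controls=2, seed=11)


@pytest.fixture(scope="session")
def small_screen(small_manifest):
    params = ScreenSimParams(
        n_genes=20, n_controls=2, n_replicates=5, n_cells=40_000,
        reads_per_sample=100_000, hit_gene_fraction=0.1,
        n_guides_total=None, seed=11,
    )
    counts, truth = simulate_screen(small_manifest, params)
    return counts, truth


def toy_counts(columns: dict[str, list[int]], guides: list[str]) -> CountMatrix:
    """Hand-built count matrix for arithmetic oracles."""
    return CountMatrix(
        pd.DataFrame(columns, index=pd.Index(guides, name="guide_id"))
    )


@pytest.fixture
def rng():
    return np.random.default_rng(7)
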