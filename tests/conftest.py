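import numpy as np
import pytest

from tffinder import (
    ExpressionMatrix,
    simulate_regulatory_dataset,
    standardize,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """4 samples x 3 genes, nothing constant."""
    return ExpressionMatrix(
        sample_ids=("s1", "s2", "s3", "s4"),
        gene_ids=("g1", "g2", "g3"),
        values=np.array(
            [
                [1.0, 2.0, 0.5],
                [2.0, 1.0, 1.5],
                [3.0, 3.0, 0.0],
                [4.0, 2.5, 2.0],
            ]
        ),
    )


@pytest.fixture
def planted_dataset():
    """One module, 3 TFs -> 8 targets, a few decoys; low noise."""
    return simulate_regulatory_dataset(
        n_samples=40,
        n_modules=1,
        tfs_per_module=3,
        targets_per_module=8,
        n_decoy_tfs=20,
        n_decoy_targets=0,
        noise_sd=0.05,
        seed=7,
    )


@pytest.fixture
def standardized_blocks(planted_dataset):
    ds = planted_dataset
    std = standardize(ds.expression)
    return std.select(ds.all_tf_ids), std.select(ds.positive_target_ids), ds
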