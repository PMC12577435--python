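import numpy as np
import pytest

from crossvae import (
    CrossSystemVAE,
    ExpressionDataset,
    ProcessingState,
    TrainConfig,
    generate,
    preprocess,
    preset,
)


@pytest.fixture()
def tiny_raw_ds() -> ExpressionDataset:
    """Hand-built 6-cell, 4-gene raw-count dataset spanning two systems."""
    counts = np.array(
        [
            [5, 0, 2, 1],
            [3, 1, 0, 2],
            [0, 4, 1, 3],
            [2, 2, 2, 0],
            [1, 0, 3, 4],
            [0, 3, 1, 1],
        ],
        dtype=float,
    )
    return ExpressionDataset(
        matrix=counts,
        gene_ids=[f"g{i}" for i in range(4)],
        cell_ids=[f"c{i}" for i in range(6)],
        system=np.array(["a", "a", "a", "b", "b", "b"]),
        sample=np.array(["a1", "a1", "a2", "b1", "b1", "b2"]),
        cell_type=np.array(["t0", "t1", "t0", "t1", "t0", "t1"]),
        state=ProcessingState.RAW_COUNTS,
    )


@pytest.fixture(scope="session")
def small_ds() -> "ExpressionDataset":
    """Preprocessed balanced synthetic dataset, shared across model tests."""
    ds, _ = generate(preset("balanced_two_system", n_cells_total=600, n_genes=120, seed=7))
    return preprocess(ds, min_cells=3)


@pytest.fixture(scope="session")
def toy_fit(small_ds):
    """A briefly trained baseline cVAE on the small dataset."""
    model = CrossSystemVAE(small_ds, n_hidden=32, n_latent=8)
    return model, model.fit(TrainConfig(n_epochs=25, seed=0))
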