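import numpy as np
import pandas as pd
import pytest

from cernet import CeRNANetworkModel, ExpressionMatrix, SynthConfig


@pytest.fixture
def small_config() -> SynthConfig:
    """A fast-to-generate study used by most module tests."""
    return SynthConfig(n_circ=12, n_mir=8, n_mrna=20, n_planted_triplets=5,
                       target_length=60, n_extra_de=2,
                       n_flagged_distractors=6, n_unflagged_distractors=4,
                       n_gene_sets=4, seed=7)


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """Four features, 3 vs 3, hand-set values."""
    values = pd.DataFrame(
        [[6.0, 6.1, 5.9, 8.0, 8.1, 7.9],
         [7.0, 7.2, 6.8, 7.1, 6.9, 7.0],
         [9.0, 9.1, 8.9, 6.0, 6.2, 5.8],
         [5.0, 5.1, 4.9, 5.0, 5.2, 4.8]],
        index=["f1", "f2", "f3", "f4"],
        columns=["c1", "c2", "c3", "t1", "t2", "t3"])
    groups = pd.Series(["control"] * 3 + ["case"] * 3, index=values.columns)
    return ExpressionMatrix(values, groups)


def fit_synthetic(seed: int, **overrides):
    """Fit the full pipeline on the default synthetic study at a seed."""
    config = SynthConfig(seed=seed, **overrides)
    model, truth = CeRNANetworkModel.from_synthetic(config)
    return truth, model.fit()


@pytest.fixture(scope="session")
def ten_seed_runs():
    """Ten fitted pipelines on the default study conditions (seeds 0-9).

    Shared across recovery, direction-invariant and validation tests to
    keep the suite within budget.
    """
    return [fit_synthetic(seed) for seed in range(10)]


def rng_for(test_seed: int) -> np.random.Generator:
    return np.random.default_rng(test_seed)
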