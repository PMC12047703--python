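import numpy as np
import pytest

import chromgae as cg


@pytest.fixture(scope="session")
def small_truth():
    """Small 2-chromosome synthetic dataset used across unit tests."""
    cfg = cg.SynthConfig(n_segments=120, n_chroms=2, seed=7)
    _, truth = cg.generate(cfg)
    return truth


@pytest.fixture(scope="session")
def small_dataset():
    """Featurized small dataset (features + true score maps)."""
    cfg = cg.SynthConfig(n_segments=160, n_chroms=2, seed=11)
    dataset, truth = cg.build_training_dataset(cfg)
    return dataset, truth


@pytest.fixture(scope="session")
def default_trained():
    """One converged model under the default generator conditions.

    Trained once per session on three chromosomes with the fourth held
    out; shared by the end-to-end evaluation and explainability tests.
    """
    dataset, truth = cg.build_training_dataset(cg.SynthConfig(seed=1))
    fold = cg.FoldSpec(
        train_chroms=("chr1", "chr2", "chr3"), test_chrom="chr4"
    )
    params, history = cg.train(
        dataset, fold, cg.TrainConfig(epochs=200, seed=1)
    )
    return params, history, dataset, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
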