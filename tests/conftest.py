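import numpy as np
import pandas as pd
import pytest

from methylearn import (
    EncoderTopology,
    MethylationArray,
    TrainConfig,
    generate_cluster_dataset,
    train_test_val_split,
    train_vae,
)


@pytest.fixture
def tiny_array():
    """Hand-sized 4 samples x 3 CpGs array with a class column."""
    beta = pd.DataFrame(
        [[0.1, 0.9, 0.5], [0.2, 0.8, 0.4], [0.9, 0.1, 0.6], [0.8, 0.2, 0.5]],
        index=["s1", "s2", "s3", "s4"],
        columns=["cg1", "cg2", "cg3"],
    )
    pheno = pd.DataFrame({"group": ["a", "a", "b", "b"]},
                         index=["s1", "s2", "s3", "s4"])
    return MethylationArray(beta, pheno)


@pytest.fixture(scope="session")
def cluster_split():
    """Moderately sized 3-class dataset split 70/20/10 (shared across tests)."""
    arr, truth = generate_cluster_dataset(
        n_samples=150, n_cpgs=120, n_classes=3, n_informative=30,
        effect=4.0, noise_sd=0.5, seed=11,
    )
    return train_test_val_split(arr, seed=5), truth


@pytest.fixture(scope="session")
def small_vae(cluster_split):
    """A briefly trained VAE reused by encode/decode/finetune tests."""
    split, _ = cluster_split
    topo = EncoderTopology(hidden_widths=[48], latent_dim=8)
    config = TrainConfig(learning_rate=5e-3, beta_kl=0.2, max_epochs=80,
                         patience=80, batch_size=32, seed=2)
    return train_vae(split.train, split.val, topo, config)


def rng_matrix(seed, n, p, lo=0.05, hi=0.95):
    rng = np.random.default_rng(seed)
    return rng.uniform(lo, hi, size=(n, p))
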