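"""Shared fixtures: small synthetic datasets and a quickly trained model."""

from __future__ import annotations

import numpy as np
import pytest

from tewick.encoder import ModelConfig
from tewick.synth import four_family_preset, generate_benchmark, registry_for
from tewick.trainer import TEClassifier, TrainConfig


def tiny_model_config(num_classes: int, seed: int = 1) -> ModelConfig:
    """2 layers x 2 heads, dim 32: the desk-scale architecture."""
    return ModelConfig(num_classes=num_classes, kmer_size=5,
                       embedding_dim=32, num_hidden_layers=2,
                       num_attention_heads=2, intermediate_size=64,
                       max_embeddings=256, local_attention_window=256,
                       global_att_tokens=(0,), dropout=0.1, seed=seed)


@pytest.fixture(scope="session")
def four_family_small():
    """Four families at 40 copies each: fast, still well separated."""
    specs = four_family_preset(n_copies=40)
    records, splits = generate_benchmark(specs, seed=7)
    return records, splits, registry_for(specs)


N_FIXTURE_EPOCHS = 24


@pytest.fixture(scope="session")
def trained_tiny(four_family_small, tmp_path_factory):
    """A short training run with checkpoints, shared across tests."""
    _, splits, registry = four_family_small
    ckpt_dir = tmp_path_factory.mktemp("ckpts")
    model = TEClassifier(
        splits, registry,
        model_config=tiny_model_config(num_classes=4),
        train_config=TrainConfig(num_epochs=N_FIXTURE_EPOCHS, batch_size=8,
                                 learning_rate=1e-3, seed=3,
                                 checkpoint_dir=str(ckpt_dir)))
    results = model.fit()
    return model, results, ckpt_dir


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
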