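"""Shared fixtures: small model configurations and a cached planted-signal
dataset so the heavier integration tests reuse one featurization pass."""

from __future__ import annotations

import numpy as np
import pytest

from structcpi.fixtures import FixtureSpec, make_cpi_dataset
from structcpi.model import CPIModel, ModelConfig
from structcpi.training import GraphCache, TrainConfig


SMALL_MODEL = dict(d_model=16, n_layers=2, heads=2, bcn_latent=48,
                   bcn_stride=3, ffn_hidden=32, decoder_hidden=32)


@pytest.fixture(scope="session")
def small_bcn_config() -> ModelConfig:
    return ModelConfig(arch="bcn", task="regression", **SMALL_MODEL)


@pytest.fixture(scope="session")
def small_transformer_config() -> ModelConfig:
    return ModelConfig(arch="transformer", task="regression", **SMALL_MODEL)


@pytest.fixture(scope="session")
def planted_dataset():
    """120-sample planted-signal dataset with featurized graph cache."""
    spec = FixtureSpec(n_samples=120, n_proteins=8, n_residues=24, seed=7)
    samples, structures, info = make_cpi_dataset(spec)
    cache = GraphCache.build(samples, structures)
    return samples, cache, info


@pytest.fixture()
def tiny_pair(small_bcn_config):
    """One protein graph / ligand graph pair plus a fresh small model."""
    from structcpi.featurize import build_ligand_graph, build_protein_graph
    from structcpi.fixtures import make_helix_protein

    pg = build_protein_graph(make_helix_protein(12, seed=3))
    lg = build_ligand_graph("CC(=O)Oc1ccccc1C(=O)O")
    model = CPIModel.new(small_bcn_config, seed=5)
    return pg, lg, model


def fast_train_config(**overrides) -> TrainConfig:
    base = dict(batch_size=32, learning_rate=2e-3, max_epochs=10,
                patience=3, seed=0)
    base.update(overrides)
    return TrainConfig(**base)
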