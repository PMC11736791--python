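"""Fine-tuning strategy contracts: trainability masks, frozen-parameter
integrity, low-rank adapter semantics, and transfer benefit on a planted
target task."""

from __future__ import annotations

import numpy as np
import pytest

from structcpi.fixtures import FixtureSpec, make_cpi_dataset
from structcpi.model import CPIModel, ModelConfig
from structcpi.training import GraphCache, bootstrap_evaluate, evaluate, train_model
from structcpi.transfer import (FineTuneSpec, apply_block, apply_free,
                                apply_lora, apply_strategy)

from conftest import SMALL_MODEL, fast_train_config


@pytest.fixture(scope="module")
def base_model():
    return CPIModel.new(ModelConfig(task="classification", **SMALL_MODEL), seed=0)


def test_free_strategy_marks_every_parameter_trainable(base_model):
    adapted = apply_free(base_model)
    assert adapted.trainable == set(adapted.params)


def test_trainable_and_frozen_sets_partition_manifest(base_model):
    for spec in (FineTuneSpec("free"), FineTuneSpec("block"),
                 FineTuneSpec("lora", lora_rank=2)):
        adapted = apply_strategy(base_model, spec)
        frozen = set(adapted.params) - adapted.trainable
        assert frozen | adapted.trainable == set(adapted.params)
        assert not (frozen & adapted.trainable)


def test_block_mode_freezes_all_but_head_and_final_interaction_layer(
        base_model, planted_dataset):
    samples, cache, info = planted_dataset
    class_samples = [
        type(s)(s.protein_ref, s.smiles, float(lbl))
        for s, lbl in zip(samples[:30], info["class_labels"][:30])
    ]
    adapted = apply_block(base_model)
    before = {k: v.data.copy() for k, v in adapted.params.items()}
    # forward pass before any step equals the base model output
    pair = cache.pair(class_samples[0])
    assert adapted.predict(*pair) == base_model.predict(*pair)
    train_model(adapted, class_samples[:20], cache,
                fast_train_config(max_epochs=3, patience=2),
                val_samples=class_samples[20:])
    for name in set(adapted.params) - adapted.trainable:
        assert np.array_equal(adapted.params[name].data, before[name]), name
    changed = [n for n in adapted.trainable
               if not np.array_equal(adapted.params[n].data, before[n])]
    assert changed  # the unfrozen layers actually moved


def test_block_trainable_parameter_count_below_20_percent_of_default():
    model = CPIModel.new(ModelConfig(task="classification"), seed=1)  # defaults
    adapted = apply_block(model)
    frac = adapted.n_parameters(adapted.trainable) / adapted.n_parameters()
    assert frac < 0.20


def test_lora_zero_init_reproduces_base_outputs_exactly(base_model, planted_dataset):
    samples, cache, _ = planted_dataset
    adapted = apply_lora(base_model, FineTuneSpec("lora", lora_rank=2))
    for s in samples[:5]:
        assert adapted.predict(*cache.pair(s)) == base_model.predict(*cache.pair(s))


def test_lora_scale_zero_reproduces_base_regardless_of_factors(base_model,
                                                               planted_dataset):
    samples, cache, _ = planted_dataset
    adapted = apply_lora(base_model, FineTuneSpec("lora", lora_rank=2,
                                                  lora_scale=0.0))
    rng = np.random.default_rng(0)
    for name in adapted.params:
        if name.startswith("lora."):
            adapted.params[name].data = rng.standard_normal(
                adapted.params[name].shape)
    for s in samples[:5]:
        assert adapted.predict(*cache.pair(s)) == pytest.approx(
            base_model.predict(*cache.pair(s)), abs=1e-12)


def test_lora_delta_rank_bounded_by_r_after_training(base_model, planted_dataset):
    samples, cache, info = planted_dataset
    class_samples = [
        type(s)(s.protein_ref, s.smiles, float(lbl))
        for s, lbl in zip(samples[:30], info["class_labels"][:30])
    ]
    r = 2
    adapted = apply_lora(base_model, FineTuneSpec("lora", lora_rank=r))
    train_model(adapted, class_samples[:20], cache,
                fast_train_config(max_epochs=3, patience=2),
                val_samples=class_samples[20:])
    assert len(adapted.lora) == 2   # ligand path + protein path for the BCN
    for a_name, b_name, _, _ in adapted.lora.values():
        delta = adapted.params[b_name].data @ adapted.params[a_name].data
        singulars = np.linalg.svd(delta, compute_uv=False)
        assert np.sum(singulars > 1e-10 * max(1.0, singulars[0])) <= r
    # base weights stayed frozen
    for name in set(adapted.params) - adapted.trainable:
        assert np.array_equal(adapted.params[name].data,
                              base_model.params[name].data), name


def test_transformer_lora_attaches_to_output_layer(planted_dataset):
    model = CPIModel.new(ModelConfig(arch="transformer", task="classification",
                                     **SMALL_MODEL), seed=2)
    adapted = apply_lora(model, FineTuneSpec("lora", lora_rank=2))
    assert set(adapted.lora) == {"tx.out.W"}
    samples, cache, _ = planted_dataset
    for s in samples[:3]:
        assert adapted.predict(*cache.pair(s)) == model.predict(*cache.pair(s))


def test_lora_rank_must_be_below_smallest_adapted_dimension(base_model):
    with pytest.raises(ValueError, match="rank"):
        apply_lora(base_model, FineTuneSpec("lora", lora_rank=SMALL_MODEL["d_model"]))


def test_zero_learning_rate_free_tuning_preserves_outputs(base_model,
                                                          planted_dataset):
    samples, cache, info = planted_dataset
    class_samples = [
        type(s)(s.protein_ref, s.smiles, float(lbl))
        for s, lbl in zip(samples[:20], info["class_labels"][:20])
    ]
    adapted = apply_free(base_model)
    before = adapted.predict(*cache.pair(class_samples[0]))
    train_model(adapted, class_samples[:15], cache,
                fast_train_config(max_epochs=2, patience=1, learning_rate=0.0),
                val_samples=class_samples[15:])
    assert adapted.predict(*cache.pair(class_samples[0])) == before


def test_all_strategies_improve_target_auc_over_unadapted_base():
    """Source task with a planted signal; target task with the signal
    shifted (different proteins and class balance). Every strategy's
    bootstrap-averaged validation AUC beats the frozen base model."""
    source_spec = FixtureSpec(n_samples=100, n_proteins=8, n_residues=20, seed=21)
    target_spec = FixtureSpec(n_samples=60, n_proteins=6, n_residues=20, seed=22,
                              planted_fraction=0.4)
    src_samples, src_structs, src_info = make_cpi_dataset(source_spec)
    tgt_samples, tgt_structs, tgt_info = make_cpi_dataset(target_spec)
    src = [type(s)(s.protein_ref, s.smiles, float(lbl))
           for s, lbl in zip(src_samples, src_info["class_labels"])]
    tgt = [type(s)(s.protein_ref, s.smiles, float(lbl))
           for s, lbl in zip(tgt_samples, tgt_info["class_labels"])]
    src_cache = GraphCache.build(src, src_structs)
    tgt_cache = GraphCache.build(tgt, tgt_structs)

    model_config = ModelConfig(task="classification", **SMALL_MODEL)
    base = CPIModel.new(model_config, seed=23)
    # brief source training: enough to be above chance, short of convergence
    train_model(base, src[:80], src_cache,
                fast_train_config(max_epochs=4, patience=3, seed=23),
                val_samples=src[80:])

    base_auc = evaluate(base, tgt, tgt_cache).auc
    for strategy in ("free", "block", "lora"):
        adapted = apply_strategy(base, FineTuneSpec(strategy, lora_rank=2))
        report, _ = bootstrap_evaluate(
            tgt, tgt_cache, model_config,
            fast_train_config(max_epochs=6, patience=5, seed=24),
            iterations=10, base_model=adapted)
        assert report.auc > base_auc, (strategy, report.auc, base_auc)
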