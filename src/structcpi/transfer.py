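"""Fine-tuning strategies for adapting a source checkpoint to a small
function-specific target dataset.

Three strategies:

* **free** — every parameter of the model is trainable.
* **block** — only the decoder head and the final layer of the active
  interaction module are trainable; everything else stays frozen
  (bit-identical before and after fine-tuning).
* **lora** — base weights frozen; trainable low-rank adapter pairs
  (B: out x r, A: r x in, effective delta (alpha/r) B A, B zero-initialised
  so the adapted model initially reproduces the base exactly). In the
  transformer module the adapter attaches to the final output layer after
  the attention mechanism; in the BCN module two adapters attach to the
  ligand-input and protein-input paths feeding the joint representation.
  The decoder head also trains by default (it is the task head for the
  target problem; set ``train_head=False`` to adapt only the low-rank
  pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import CPIModel
from .nn import param

__all__ = ["FineTuneSpec", "apply_free", "apply_block", "apply_lora",
           "apply_strategy"]

_DECODER = ("dec.fc1.W", "dec.fc1.b", "dec.fc2.W", "dec.fc2.b")


@dataclass
class FineTuneSpec:
    strategy: str = "lora"            # "free" | "block" | "lora"
    lora_rank: int = 4
    lora_scale: float = 1.0
    train_head: bool = True
    target_components: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.strategy not in ("free", "block", "lora"):
            raise ValueError(f"unknown fine-tuning strategy {self.strategy!r}")
        if self.strategy == "lora" and self.lora_rank < 1:
            raise ValueError("lora_rank must be >= 1")


def apply_free(model: CPIModel) -> CPIModel:
    """Every parameter trainable."""
    adapted = model.clone()
    adapted.trainable = set(adapted.params)
    return adapted


def _final_interaction_layer(model: CPIModel) -> list[str]:
    if model.config.arch == "bcn":
        # the learnable attention vectors are the BCN's last layer
        return [n for n in model.params if n.startswith("bcn.") and n.endswith(".q")]
    return ["tx.out.W", "tx.out.b"]


def apply_block(model: CPIModel) -> CPIModel:
    """Trainable = classifier/decoder head + final interaction layer."""
    adapted = model.clone()
    names = list(_DECODER) + _final_interaction_layer(adapted)
    missing = [n for n in names if n not in adapted.params]
    if missing:
        raise ValueError(f"named components absent from checkpoint: {missing}")
    adapted.trainable = set(names)
    return adapted


def apply_lora(model: CPIModel, spec: FineTuneSpec) -> CPIModel:
    """Attach zero-initialised low-rank adapter pairs; freeze base weights."""
    adapted = model.clone()
    rng = np.random.default_rng(0)
    trainable: set[str] = set(_DECODER) if spec.train_head else set()
    if adapted.config.arch == "transformer":
        targets = {"tx.out.W": ("lora.tx.out", *adapted.params["tx.out.W"].shape)}
    else:
        d = adapted.config.d_model
        targets = {"lora.bcn.lig": ("lora.bcn.lig", d, d),
                   "lora.bcn.prot": ("lora.bcn.prot", d, d)}
    for target, (stem, d_in, d_out) in targets.items():
        r = spec.lora_rank
        if r >= min(d_in, d_out):
            raise ValueError(f"lora rank {r} must be below the smallest "
                             f"dimension {min(d_in, d_out)} of {target}")
        a_name, b_name = f"{stem}.A", f"{stem}.B"
        # A random, B zero: the delta starts at zero, so the adapted model
        # initially reproduces the base outputs exactly.
        adapted.params[a_name] = param(
            rng.standard_normal((r, d_in)) / np.sqrt(d_in), a_name)
        adapted.params[b_name] = param(np.zeros((d_out, r)), b_name)
        adapted.lora[target] = (a_name, b_name, spec.lora_scale, r)
        trainable.update({a_name, b_name})
    adapted.trainable = trainable
    return adapted


def apply_strategy(model: CPIModel, spec: FineTuneSpec) -> CPIModel:
    if spec.strategy == "free":
        return apply_free(model)
    if spec.strategy == "block":
        return apply_block(model)
    return apply_lora(model, spec)
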