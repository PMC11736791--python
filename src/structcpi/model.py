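"""The full compound-protein interaction model.

``CPIModel`` wires a protein contact-map encoder and a ligand GCN-GRU
encoder into one of two interaction modules (bilinear co-attention or
transformer) followed by a fully connected decoder. Parameters live in a
flat named dict; a trainability mask and optional low-rank (LoRa) adapter
pairs support the fine-tuning strategies in :mod:`structcpi.transfer`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .autograd import Tensor
from .encoders import (encode_ligand, encode_protein, init_ligand_encoder,
                       init_protein_encoder)
from .featurize import (N_ATOM_FEATURES, N_RESIDUE_FEATURES, LigandGraph,
                        ProteinGraph)
from .interaction import (AttentionMap, bcn_forward, init_bcn,
                          init_transformer, transformer_forward)
from .nn import glorot, linear, load_params, param, save_params

__all__ = ["ModelConfig", "CPIModel"]


@dataclass
class ModelConfig:
    arch: str = "bcn"                 # "bcn" | "transformer"
    task: str = "regression"          # "regression" | "classification"
    d_model: int = 128
    n_layers: int = 3
    heads: int = 2
    bcn_latent: int = 768
    bcn_stride: int = 3
    ffn_hidden: int = 512
    decoder_hidden: int = 512

    def __post_init__(self):
        if self.arch not in ("bcn", "transformer"):
            raise ValueError(f"unknown architecture {self.arch!r}")
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.bcn_latent % self.bcn_stride != 0:
            raise ValueError(f"latent size {self.bcn_latent} not divisible "
                             f"by pooling stride {self.bcn_stride}")
        if self.d_model % self.heads != 0:
            raise ValueError(f"model width {self.d_model} not divisible by "
                             f"heads {self.heads}")


class CPIModel:
    """Encoder -> interaction -> decoder, with named-parameter plumbing."""

    def __init__(self, config: ModelConfig, params: dict[str, Tensor]):
        self.config = config
        self.params = params
        self.trainable: set[str] = set(params)
        # adapted weight name -> (A name, B name, alpha, r); see transfer.py
        self.lora: dict[str, tuple[str, str, float, int]] = {}

    # ------------------------------------------------------------- creation
    @classmethod
    def new(cls, config: ModelConfig, seed: int) -> "CPIModel":
        rng = np.random.default_rng(seed)
        widths = (config.d_model,) * config.n_layers
        params: dict[str, Tensor] = {}
        params.update(init_protein_encoder(rng, N_RESIDUE_FEATURES, widths))
        params.update(init_ligand_encoder(rng, N_ATOM_FEATURES, widths))
        if config.arch == "bcn":
            params.update(init_bcn(rng, config.d_model, config.heads,
                                   config.bcn_latent, config.bcn_stride))
            joint_dim = config.bcn_latent // config.bcn_stride
        else:
            params.update(init_transformer(rng, config.d_model, config.heads,
                                           config.ffn_hidden))
            joint_dim = config.d_model
        params["dec.fc1.W"] = param(glorot(rng, joint_dim, config.decoder_hidden),
                                    "dec.fc1.W")
        params["dec.fc1.b"] = param(np.zeros(config.decoder_hidden), "dec.fc1.b")
        params["dec.fc2.W"] = param(glorot(rng, config.decoder_hidden, 1), "dec.fc2.W")
        params["dec.fc2.b"] = param(np.zeros(1), "dec.fc2.b")
        return cls(config, params)

    # ------------------------------------------------------------- adapters
    def _effective(self, name: str) -> Tensor:
        """Base weight plus the (alpha/r)-scaled low-rank delta, if adapted."""
        w = self.params[name]
        if name in self.lora:
            a_name, b_name, alpha, r = self.lora[name]
            delta = (self.params[b_name] @ self.params[a_name]).T * (alpha / r)
            w = w + delta
        return w

    def _adapted_input(self, feats: Tensor, path: str) -> Tensor:
        """Low-rank adapter on an interaction input path (BCN LoRa)."""
        key = f"lora.bcn.{path}"
        if f"{key}.A" not in self.params:
            return feats
        a_name, b_name, alpha, r = self.lora[key]
        delta = (self.params[b_name] @ self.params[a_name]) * (alpha / r)
        return feats + feats @ delta.T

    # -------------------------------------------------------------- forward
    def forward(self, protein_graph: ProteinGraph, ligand_graph: LigandGraph
                ) -> tuple[Tensor, AttentionMap]:
        """Raw prediction (pre-sigmoid for classification) and attention."""
        residue_emb, _ = encode_protein(protein_graph, self.params)
        atom_emb = encode_ligand(ligand_graph, self.params)
        if self.config.arch == "bcn":
            atom_emb = self._adapted_input(atom_emb, "lig")
            residue_emb = self._adapted_input(residue_emb, "prot")
            joint, attention = bcn_forward(atom_emb, residue_emb, self.params,
                                           heads=self.config.heads,
                                           stride=self.config.bcn_stride)
        else:
            joint, attention = self._transformer(residue_emb, atom_emb)
        attention.atom_ids = ligand_graph.atom_ids
        attention.residue_ids = protein_graph.residue_ids
        hidden = linear(joint, self.params["dec.fc1.W"], self.params["dec.fc1.b"]).relu()
        out = linear(hidden, self.params["dec.fc2.W"], self.params["dec.fc2.b"])
        return out[0], attention

    def _transformer(self, residue_emb, atom_emb):
        # inline so the output head can carry a LoRa delta
        from .interaction import _multihead_attention
        from .nn import layer_norm

        p = self.params
        heads = self.config.heads
        self_out, _ = _multihead_attention(
            residue_emb @ p["tx.self.Wq"], residue_emb @ p["tx.self.Wk"],
            residue_emb @ p["tx.self.Wv"], heads)
        h = layer_norm(self_out, p["tx.ln1.g"], p["tx.ln1.b"])
        cross_out, cross_weights = _multihead_attention(
            h @ p["tx.cross.Wq"], atom_emb @ p["tx.cross.Wk"],
            atom_emb @ p["tx.cross.Wv"], heads)
        h = layer_norm(cross_out, p["tx.ln2.g"], p["tx.ln2.b"])
        h = linear(linear(h, p["tx.ffn.W1"], p["tx.ffn.b1"]).relu(),
                   p["tx.ffn.W2"], p["tx.ffn.b2"])
        pooled = h.mean(axis=0)
        out = linear(pooled, self._effective("tx.out.W"), p["tx.out.b"])
        weights = np.stack([w.T for w in cross_weights])
        return out, AttentionMap(weights, module_tag="transformer")

    def predict(self, protein_graph: ProteinGraph, ligand_graph: LigandGraph
                ) -> float:
        """Point prediction: probability for classification, value for
        regression."""
        raw, _ = self.forward(protein_graph, ligand_graph)
        if self.config.task == "classification":
            return float(1.0 / (1.0 + np.exp(-raw.data)))
        return float(raw.data)

    # ------------------------------------------------------------ utilities
    def parameter_manifest(self) -> dict[str, list[int]]:
        from .nn import manifest
        return manifest(self.params)

    def n_parameters(self, only: set[str] | None = None) -> int:
        names = only if only is not None else set(self.params)
        return sum(self.params[n].data.size for n in names)

    def clone(self) -> "CPIModel":
        clone = CPIModel(self.config,
                         {k: param(v.data.copy(), k) for k, v in self.params.items()})
        clone.trainable = set(self.trainable)
        clone.lora = dict(self.lora)
        return clone

    def save(self, path: str | Path) -> None:
        meta = {"config": asdict(self.config),
                "trainable": sorted(self.trainable),
                "lora": {k: list(v) for k, v in self.lora.items()}}
        save_params(path, self.params, meta)

    @classmethod
    def load(cls, path: str | Path) -> "CPIModel":
        params, meta = load_params(path)
        if "config" not in meta:
            raise ValueError(f"checkpoint {path} lacks a config manifest")
        model = cls(ModelConfig(**meta["config"]), params)
        if meta.get("trainable"):
            model.trainable = set(meta["trainable"])
        model.lora = {k: (v[0], v[1], float(v[2]), int(v[3]))
                      for k, v in meta.get("lora", {}).items()}
        return model
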