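"""Graph encoders for proteins and ligands.

Protein encoder: sinusoidal positional encoding (added after projecting the
26-dim residue features to the model width, in residue sequence order) plus
three graph-convolution layers Q^(l+1) = relu(A_hat Q^(l) W^(l)), where
A_hat is the row-normalised adjacency with self-loops. Two fully connected
layers map the mean node embedding to a global protein representation.

Ligand encoder: three message-passing layers. Each layer sums the linearly
transformed features of a node's neighbours, applies a further linear +
rectifier transform, then feeds the result and the previous hidden state to
a gated recurrent unit cell.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .featurize import LigandGraph, ProteinGraph
from .nn import glorot, gru_cell, init_gru_cell, linear, param

__all__ = [
    "positional_encoding", "init_protein_encoder", "encode_protein",
    "init_ligand_encoder", "encode_ligand",
]


def positional_encoding(n_positions: int, d_model: int = 128) -> np.ndarray:
    """Sinusoidal positional-encoding matrix (n_positions x d_model).

    entry(pos, 2i)   = sin(pos / 10000^(2i/d_model))
    entry(pos, 2i+1) = cos(pos / 10000^(2i/d_model))
    """
    if d_model % 2 != 0:
        raise ValueError(f"d_model must be even, got {d_model}")
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    pos = np.arange(n_positions)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angle = pos / np.power(10000.0, 2.0 * i / d_model)
    pe = np.empty((n_positions, d_model))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


# ---------------------------------------------------------------------------
# Protein encoder
# ---------------------------------------------------------------------------

def init_protein_encoder(rng: np.random.Generator, d_in: int = 26,
                         widths: tuple[int, ...] = (128, 128, 128),
                         global_dim: int | None = None,
                         prefix: str = "prot") -> dict[str, Tensor]:
    """Parameters for the protein GCN; widths[0] is also the PE width.

    ``global_dim`` adds the two fully connected layers that consolidate the
    node embeddings into a global representation; omit it when only
    residue-level embeddings are consumed downstream.
    """
    d_model = widths[0]
    p = {
        f"{prefix}.proj.W": param(glorot(rng, d_in, d_model), f"{prefix}.proj.W"),
        f"{prefix}.proj.b": param(np.zeros(d_model), f"{prefix}.proj.b"),
    }
    d_prev = d_model
    for layer, width in enumerate(widths):
        name = f"{prefix}.gcn{layer}.W"
        p[name] = param(glorot(rng, d_prev, width), name)
        d_prev = width
    if global_dim is not None:
        p[f"{prefix}.fc1.W"] = param(glorot(rng, d_prev, global_dim), f"{prefix}.fc1.W")
        p[f"{prefix}.fc1.b"] = param(np.zeros(global_dim), f"{prefix}.fc1.b")
        p[f"{prefix}.fc2.W"] = param(glorot(rng, global_dim, global_dim), f"{prefix}.fc2.W")
        p[f"{prefix}.fc2.b"] = param(np.zeros(global_dim), f"{prefix}.fc2.b")
    return p


def _normalized_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Row-normalised A + I: self-loops preserve each node's own signal and
    degree normalisation keeps propagation bounded."""
    a_hat = adjacency + np.eye(adjacency.shape[0])
    return a_hat / a_hat.sum(axis=1, keepdims=True)


def encode_protein(graph: ProteinGraph, params: dict[str, Tensor],
                   prefix: str = "prot",
                   add_positional_encoding: bool = True
                   ) -> tuple[Tensor, Tensor | None]:
    """Residue-level embeddings (N x width) and, if the encoder was built
    with a global head, the global protein representation."""
    n, d_in = graph.node_features.shape
    if params[f"{prefix}.proj.W"].shape[0] != d_in:
        raise ValueError(
            f"feature width {d_in} does not match encoder input width "
            f"{params[f'{prefix}.proj.W'].shape[0]}")
    d_model = params[f"{prefix}.proj.W"].shape[1]
    h = linear(Tensor(graph.node_features), params[f"{prefix}.proj.W"],
               params[f"{prefix}.proj.b"])
    if add_positional_encoding:
        h = h + Tensor(positional_encoding(n, d_model))
    a_hat = Tensor(_normalized_adjacency(graph.adjacency))
    layer = 0
    while f"{prefix}.gcn{layer}.W" in params:
        h = (a_hat @ h @ params[f"{prefix}.gcn{layer}.W"]).relu()
        layer += 1
    global_emb = None
    if f"{prefix}.fc1.W" in params:
        pooled = h.mean(axis=0)
        hidden = linear(pooled, params[f"{prefix}.fc1.W"], params[f"{prefix}.fc1.b"]).relu()
        global_emb = linear(hidden, params[f"{prefix}.fc2.W"], params[f"{prefix}.fc2.b"])
    return h, global_emb


# ---------------------------------------------------------------------------
# Ligand encoder
# ---------------------------------------------------------------------------

def init_ligand_encoder(rng: np.random.Generator, d_in: int = 74,
                        widths: tuple[int, ...] = (128, 128, 128),
                        prefix: str = "lig") -> dict[str, Tensor]:
    d_model = widths[0]
    p = {
        f"{prefix}.embed.W": param(glorot(rng, d_in, d_model), f"{prefix}.embed.W"),
        f"{prefix}.embed.b": param(np.zeros(d_model), f"{prefix}.embed.b"),
    }
    d_prev = d_model
    for layer, width in enumerate(widths):
        base = f"{prefix}.layer{layer}"
        p[f"{base}.msg.W"] = param(glorot(rng, d_prev, width), f"{base}.msg.W")
        p[f"{base}.msg.b"] = param(np.zeros(width), f"{base}.msg.b")
        p[f"{base}.trans.W"] = param(glorot(rng, width, width), f"{base}.trans.W")
        p[f"{base}.trans.b"] = param(np.zeros(width), f"{base}.trans.b")
        p.update(init_gru_cell(rng, width, width, f"{base}.gru"))
        d_prev = width
    return p


def encode_ligand(graph: LigandGraph, params: dict[str, Tensor],
                  prefix: str = "lig") -> Tensor:
    """Atom-level embeddings (N_atoms x width) via GCN-GRU message passing.

    Per layer: m_j = sum over neighbours i of (W v_i + b); the messages are
    passed through a linear + rectifier transform and a GRU cell combines
    them with the previous hidden state.
    """
    n, d_in = graph.node_features.shape
    if params[f"{prefix}.embed.W"].shape[0] != d_in:
        raise ValueError(
            f"feature width {d_in} does not match encoder input width "
            f"{params[f'{prefix}.embed.W'].shape[0]}")
    adjacency = Tensor(graph.adjacency)
    v = linear(Tensor(graph.node_features), params[f"{prefix}.embed.W"],
               params[f"{prefix}.embed.b"])
    layer = 0
    while f"{prefix}.layer{layer}.msg.W" in params:
        base = f"{prefix}.layer{layer}"
        # m_j = sum_{i in N(j)} (W v_i + b): isolated atoms receive zero.
        transformed = linear(v, params[f"{base}.msg.W"], params[f"{base}.msg.b"])
        messages = adjacency @ transformed
        x = linear(messages, params[f"{base}.trans.W"], params[f"{base}.trans.b"]).relu()
        v = gru_cell(x, v, params, f"{base}.gru")
        layer += 1
    return v
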