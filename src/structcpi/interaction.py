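"""Protein-ligand interaction modules.

Two alternatives fuse atom-level ligand embeddings and residue-level
protein embeddings into a joint vector plus an atom x residue attention
map:

* **BCN** (bilinear co-attention): per head, the interaction intensity
  between ligand atom i and protein residue j is
  ``I[i, j] = q . (relu(Wv^T v_i) * relu(Wq^T q_j))``; the joint
  representation gates the k-th latent coordinate through I
  (``f'_k = hv_k^T I hq_k``) and is compacted by non-overlapping sum
  pooling with stride s. Intensities are raw (unnormalised) — they are
  only min-max normalised downstream, for interpretability.

* **Transformer**: protein self-attention, layer norm, cross-attention
  with protein queries over ligand keys/values, layer norm, a 2-layer
  feed-forward network, global average pooling over residues and a final
  linear head. Cross-attention weights (softmax-normalised over atoms)
  are returned as the attention map.

``bcn_oracle`` and ``attention_oracle`` are deliberately naive
double-loop references used to validate the vectorised forward passes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autograd import Tensor, concat, softmax
from .nn import glorot, layer_norm, linear, param

__all__ = [
    "AttentionMap", "init_bcn", "bcn_forward", "bcn_oracle",
    "init_transformer", "transformer_forward", "attention_oracle",
]


@dataclass
class AttentionMap:
    """Atom x residue attention weights, one slab per head.

    ``weights[h, i, j]`` couples ligand atom i with protein residue j. For
    the transformer the weights are the cross-attention distribution of
    residue j over atoms (each column sums to 1 per head); for the BCN they
    are raw bilinear intensities.
    """

    weights: np.ndarray               # heads x N_atoms x M_residues
    module_tag: str                   # "bcn" | "transformer"
    atom_ids: list[int] | None = None
    residue_ids: list[int] | None = None

    def to_long_dataframe(self):
        import pandas as pd

        heads, n, m = self.weights.shape
        atom_ids = self.atom_ids or list(range(n))
        residue_ids = self.residue_ids or list(range(m))
        rows = [(h, atom_ids[i], residue_ids[j], self.weights[h, i, j])
                for h in range(heads) for i in range(n) for j in range(m)]
        return pd.DataFrame(rows, columns=["head", "atom_id", "residue_id", "weight"])

    def save(self, path: str | Path) -> None:
        """Compressed named-array file plus a TSV long format alongside."""
        path = Path(path)
        np.savez_compressed(path, weights=self.weights,
                            atom_ids=np.array(self.atom_ids or range(self.weights.shape[1])),
                            residue_ids=np.array(self.residue_ids or range(self.weights.shape[2])))
        self.to_long_dataframe().to_csv(path.with_suffix(".tsv"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# Bilinear co-attention network
# ---------------------------------------------------------------------------

def init_bcn(rng: np.random.Generator, d: int = 128, heads: int = 2,
             latent: int = 768, stride: int = 3,
             prefix: str = "bcn") -> dict[str, Tensor]:
    if heads < 1:
        raise ValueError("heads must be >= 1")
    if latent % stride != 0:
        raise ValueError(f"latent size {latent} not divisible by pooling stride {stride}")
    p = {}
    for h in range(heads):
        base = f"{prefix}.head{h}"
        p[f"{base}.WV"] = param(glorot(rng, d, latent), f"{base}.WV")
        p[f"{base}.WQ"] = param(glorot(rng, d, latent), f"{base}.WQ")
        p[f"{base}.q"] = param(rng.standard_normal(latent) / np.sqrt(latent), f"{base}.q")
    return p


def bcn_forward(ligand_feats: Tensor | np.ndarray, protein_feats: Tensor | np.ndarray,
                params: dict[str, Tensor], heads: int = 2, stride: int = 3,
                prefix: str = "bcn") -> tuple[Tensor, AttentionMap]:
    """Joint representation (length latent/stride) and the per-head raw
    interaction-intensity map."""
    V = Tensor._lift(ligand_feats)    # N x d
    Q = Tensor._lift(protein_feats)   # M x d
    joint_per_head = []
    maps = []
    for h in range(heads):
        base = f"{prefix}.head{h}"
        hv = (V @ params[f"{base}.WV"]).relu()          # N x latent
        hq = (Q @ params[f"{base}.WQ"]).relu()          # M x latent
        intensity = (hv * params[f"{base}.q"]) @ hq.T   # N x M
        # f'_k = hv_{.k}^T I hq_{.k}, vectorised over k
        joint = ((intensity @ hq) * hv).sum(axis=0)     # latent
        joint_per_head.append(joint)
        maps.append(intensity.data.copy())
    combined = joint_per_head[0]
    for j in joint_per_head[1:]:
        combined = combined + j
    combined = combined * (1.0 / heads)                 # heads averaged
    latent = combined.shape[0]
    pooled = combined.reshape(latent // stride, stride).sum(axis=1)
    return pooled, AttentionMap(np.stack(maps), module_tag="bcn")


def bcn_oracle(ligand_feats: np.ndarray, protein_feats: np.ndarray,
               params: dict[str, Tensor], head: int = 0,
               prefix: str = "bcn") -> np.ndarray:
    """Explicit double loop over (atom i, residue j) for one head; the
    reference implementation for testing the vectorised bilinear form."""
    WV = params[f"{prefix}.head{head}.WV"].data
    WQ = params[f"{prefix}.head{head}.WQ"].data
    q = params[f"{prefix}.head{head}.q"].data
    n, m = ligand_feats.shape[0], protein_feats.shape[0]
    intensity = np.zeros((n, m))
    for i in range(n):
        for j in range(m):
            hv = np.maximum(WV.T @ ligand_feats[i], 0.0)
            hq = np.maximum(WQ.T @ protein_feats[j], 0.0)
            intensity[i, j] = q @ (hv * hq)
    return intensity


# ---------------------------------------------------------------------------
# Transformer interaction module
# ---------------------------------------------------------------------------

def init_transformer(rng: np.random.Generator, d: int = 128, heads: int = 2,
                     ffn_hidden: int = 512, prefix: str = "tx") -> dict[str, Tensor]:
    if d % heads != 0:
        raise ValueError(f"model width {d} not divisible by heads {heads}")
    p = {}
    for blk in ("self", "cross"):
        for proj in ("Wq", "Wk", "Wv"):
            name = f"{prefix}.{blk}.{proj}"
            p[name] = param(glorot(rng, d, d), name)
    for ln in ("ln1", "ln2"):
        p[f"{prefix}.{ln}.g"] = param(np.ones(d), f"{prefix}.{ln}.g")
        p[f"{prefix}.{ln}.b"] = param(np.zeros(d), f"{prefix}.{ln}.b")
    p[f"{prefix}.ffn.W1"] = param(glorot(rng, d, ffn_hidden), f"{prefix}.ffn.W1")
    p[f"{prefix}.ffn.b1"] = param(np.zeros(ffn_hidden), f"{prefix}.ffn.b1")
    p[f"{prefix}.ffn.W2"] = param(glorot(rng, ffn_hidden, d), f"{prefix}.ffn.W2")
    p[f"{prefix}.ffn.b2"] = param(np.zeros(d), f"{prefix}.ffn.b2")
    p[f"{prefix}.out.W"] = param(glorot(rng, d, d), f"{prefix}.out.W")
    p[f"{prefix}.out.b"] = param(np.zeros(d), f"{prefix}.out.b")
    return p


def _multihead_attention(queries: Tensor, keys: Tensor, values: Tensor,
                         heads: int, logit_offset: float = 0.0
                         ) -> tuple[Tensor, list[np.ndarray]]:
    """Scaled dot-product attention; returns concatenated head outputs and
    the per-head softmax weight matrices (rows = queries)."""
    d = queries.shape[1]
    d_head = d // heads
    outs, weights = [], []
    for h in range(heads):
        sl = slice(h * d_head, (h + 1) * d_head)
        qh, kh, vh = queries[:, sl], keys[:, sl], values[:, sl]
        logits = (qh @ kh.T) * (1.0 / np.sqrt(d_head)) + logit_offset
        attn = softmax(logits, axis=-1)
        outs.append(attn @ vh)
        weights.append(attn.data.copy())
    return concat(outs, axis=1), weights


def transformer_forward(protein_feats: Tensor | np.ndarray,
                        ligand_feats: Tensor | np.ndarray,
                        params: dict[str, Tensor], heads: int = 2,
                        prefix: str = "tx", logit_offset: float = 0.0
                        ) -> tuple[Tensor, AttentionMap]:
    """Pooled interaction vector (model width) and the cross-attention map.

    ``logit_offset`` is a test hook adding a constant to every attention
    logit; softmax shift invariance makes the output independent of it.
    """
    P = Tensor._lift(protein_feats)   # M x d
    L = Tensor._lift(ligand_feats)    # N x d
    g = lambda k: params[f"{prefix}.{k}"]
    # protein self-attention
    self_out, _ = _multihead_attention(
        P @ g("self.Wq"), P @ g("self.Wk"), P @ g("self.Wv"),
        heads, logit_offset)
    h = layer_norm(self_out, g("ln1.g"), g("ln1.b"))
    # cross-attention: protein queries, ligand keys/values
    cross_out, cross_weights = _multihead_attention(
        h @ g("cross.Wq"), L @ g("cross.Wk"), L @ g("cross.Wv"),
        heads, logit_offset)
    h = layer_norm(cross_out, g("ln2.g"), g("ln2.b"))
    h = linear(linear(h, g("ffn.W1"), g("ffn.b1")).relu(), g("ffn.W2"), g("ffn.b2"))
    pooled = h.mean(axis=0)
    out = linear(pooled, g("out.W"), g("out.b"))
    # store atom x residue: transpose the (residue x atom) softmax rows
    weights = np.stack([w.T for w in cross_weights])
    return out, AttentionMap(weights, module_tag="transformer")


def attention_oracle(queries: np.ndarray, keys: np.ndarray, values: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Single-head scaled dot-product attention by explicit loops."""
    m, d_k = queries.shape
    n = keys.shape[0]
    weights = np.zeros((m, n))
    for i in range(m):
        logits = np.array([queries[i] @ keys[j] / np.sqrt(d_k) for j in range(n)])
        e = np.exp(logits - logits.max())
        weights[i] = e / e.sum()
    out = np.zeros((m, values.shape[1]))
    for i in range(m):
        for j in range(n):
            out[i] += weights[i, j] * values[j]
    return out, weights
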