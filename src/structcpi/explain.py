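"""Attention-based interpretability.

Post-processes an atom x residue attention map into the analyses used for
binding-site inspection: head averaging, min-max normalisation to [0, 1],
a top-p% mask retaining the strongest couplings with their original
values, marginal residue/atom importance scores (means along each axis),
top-n% residue sets, and signed variant-minus-wild-type difference maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .interaction import AttentionMap

__all__ = [
    "head_average", "minmax_normalize", "top_percent_mask", "marginal_scores",
    "top_residues", "variant_difference_map", "ExplainReport", "explain",
]


def head_average(attention: AttentionMap | np.ndarray) -> np.ndarray:
    """Elementwise mean over heads -> single atom x residue score matrix."""
    weights = attention.weights if isinstance(attention, AttentionMap) else attention
    if weights.ndim != 3 or weights.shape[0] < 1:
        raise ValueError("expected a heads x atoms x residues array")
    return weights.mean(axis=0)


def minmax_normalize(scores: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min); a constant map normalises to all zeros."""
    scores = np.asarray(scores, float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("attention map contains non-finite entries")
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        return np.zeros_like(scores)
    return (scores - lo) / (hi - lo)


def top_percent_mask(scores: np.ndarray, percent: float = 30.0) -> np.ndarray:
    """Keep the floor(percent * count / 100) largest entries with their
    original values; zero the rest. Ties break by row-major order."""
    if not 0 < percent <= 100:
        raise ValueError("percent must be in (0, 100]")
    scores = np.asarray(scores, float)
    keep = math.floor(percent * scores.size / 100.0)
    flat = scores.ravel(order="C")          # row-major flattening for ties
    masked = np.zeros(flat.size)
    if keep:
        # stable sort on (-value, position): equal values keep first occurrence
        order = np.lexsort((np.arange(flat.size), -flat))
        idx = order[:keep]
        masked[idx] = flat[idx]
    return masked.reshape(scores.shape)


def marginal_scores(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(residue_scores, atom_scores): column means and row means of the
    atom x residue map."""
    scores = np.asarray(scores, float)
    if scores.size == 0:
        raise ValueError("empty attention map")
    return scores.mean(axis=0), scores.mean(axis=1)


def top_residues(residue_scores: np.ndarray, percent: float,
                 residue_ids: list[int] | None = None) -> set[int]:
    """Ids of the ceil(percent * M / 100) highest-scoring residues; ties
    break deterministically by residue index."""
    if not 0 < percent <= 100:
        raise ValueError("percent must be in (0, 100]")
    residue_scores = np.asarray(residue_scores, float)
    m = residue_scores.size
    ids = residue_ids if residue_ids is not None else list(range(m))
    keep = math.ceil(percent * m / 100.0)
    order = np.lexsort((np.arange(m), -residue_scores))
    return {ids[i] for i in order[:keep]}


def variant_difference_map(variant_scores: dict[int, float] | np.ndarray,
                           wildtype_scores: dict[int, float] | np.ndarray
                           ) -> dict[int, float] | np.ndarray:
    """Signed per-residue difference (variant - wild type); positive means
    higher attention in the variant. Accepts aligned arrays or dicts keyed
    by reference residue numbering."""
    if isinstance(variant_scores, dict) or isinstance(wildtype_scores, dict):
        unmatched = set(variant_scores) ^ set(wildtype_scores)
        if unmatched:
            raise ValueError(f"residue indices do not align; unmatched "
                             f"positions: {sorted(unmatched)}")
        return {k: variant_scores[k] - wildtype_scores[k] for k in variant_scores}
    variant_scores = np.asarray(variant_scores, float)
    wildtype_scores = np.asarray(wildtype_scores, float)
    if variant_scores.shape != wildtype_scores.shape:
        raise ValueError(f"residue score shapes differ: "
                         f"{variant_scores.shape} vs {wildtype_scores.shape}")
    return variant_scores - wildtype_scores


@dataclass
class ExplainReport:
    normalized_map: np.ndarray
    masked_map: np.ndarray
    residue_scores: np.ndarray
    atom_scores: np.ndarray
    top_residue_sets: dict[float, set[int]]
    residue_ids: list[int] = field(default_factory=list)
    atom_ids: list[int] = field(default_factory=list)

    def residue_table(self) -> pd.DataFrame:
        m = self.residue_scores.size
        ids = self.residue_ids or list(range(m))
        rank = np.empty(m, int)
        rank[np.lexsort((np.arange(m), -self.residue_scores))] = np.arange(1, m + 1)
        return pd.DataFrame({
            "residue_id": ids,
            "score": self.residue_scores,
            "rank": rank,
            "top5pct": [i in self.top_residue_sets.get(5.0, set()) for i in ids],
            "top30pct": [i in self.top_residue_sets.get(30.0, set()) for i in ids],
        })

    def save(self, out_dir: str | Path, stem: str = "explain") -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.residue_table().to_csv(out_dir / f"{stem}_residues.tsv",
                                    sep="\t", index=False)
        np.savez_compressed(out_dir / f"{stem}_maps.npz",
                            normalized=self.normalized_map,
                            masked=self.masked_map,
                            residue_scores=self.residue_scores,
                            atom_scores=self.atom_scores)


def explain(attention: AttentionMap, mask_percent: float = 30.0,
            top_percents: tuple[float, ...] = (5.0, 30.0)) -> ExplainReport:
    """Full pipeline: head average -> min-max normalise -> top-p% mask ->
    marginal scores -> top-n% residue sets."""
    averaged = head_average(attention)
    normalized = minmax_normalize(averaged)
    masked = top_percent_mask(normalized, mask_percent)
    residue_scores, atom_scores = marginal_scores(masked)
    ids = attention.residue_ids or list(range(normalized.shape[1]))
    tops = {float(p): top_residues(residue_scores, p, ids) for p in top_percents}
    return ExplainReport(normalized_map=normalized, masked_map=masked,
                         residue_scores=residue_scores, atom_scores=atom_scores,
                         top_residue_sets=tops, residue_ids=list(ids),
                         atom_ids=list(attention.atom_ids or
                                       range(normalized.shape[0])))
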