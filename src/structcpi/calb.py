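"""Target-task label construction and distal-mutation negative augmentation.

Built for conversion assays of enzyme variants (the motivating system is
Candida antarctica lipase B, catalytic triad Ser105-Asp187-His224): each
record is a variant, a substrate SMILES and a conversion percentage.
Two labelling rules produce binary targets:

* threshold labels — positive iff conversion >= cutoff (15/30/40 %);
* relative labels — positive iff the variant converts comparably to
  (within a tolerance delta) or better than the wild type on the same
  substrate.

Negative augmentation plants random single-point mutations at residues
whose minimum C-alpha distance to the catalytic triad exceeds a cutoff
(20 Angstrom): such distal mutations are expected to leave activity
unchanged relative to the redundant wild-type background, so the records
are labelled 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .featurize import CANONICAL_AA, ProteinStructure

__all__ = [
    "ConversionRecord", "AugmentationConfig", "parse_mutation",
    "threshold_labels", "relative_labels", "eligible_distal_residues",
    "augment_negatives", "read_conversion_table", "write_labeled_dataset",
]

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass
class ConversionRecord:
    variant_id: str
    mutations: list[tuple[str, int, str]]   # (wild-type aa, position, mutant aa)
    substrate_smiles: str
    conversion: float                        # percent, in [0, 100]
    provenance: str = "observed"             # "observed" | "augmented"

    @property
    def is_wildtype(self) -> bool:
        return not self.mutations


@dataclass
class AugmentationConfig:
    triad_positions: tuple[int, ...] = (105, 187, 224)   # Ser105, Asp187, His224
    min_distance: float = 20.0                            # Angstrom
    mutations_per_position: int = 8
    seed: int = 0
    substrate_pool: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.mutations_per_position < 1:
            raise ValueError("mutations_per_position must be >= 1")
        if self.mutations_per_position > 19:
            raise ValueError("at most 19 alternative residues exist per position")
        if self.min_distance <= 0:
            raise ValueError("min_distance must be positive")


def parse_mutation(token: str) -> tuple[str, int, str]:
    """Parse a 'W104C'-style token into (wild-type aa, position, mutant aa)."""
    m = _MUTATION_RE.match(token.strip())
    if not m:
        raise ValueError(f"malformed mutation token {token!r}")
    return m.group(1), int(m.group(2)), m.group(3)


# ---------------------------------------------------------------------------
# Label rules
# ---------------------------------------------------------------------------

def threshold_labels(records: list[ConversionRecord], cutoff: float) -> list[int]:
    """Binary labels: 1 iff conversion >= cutoff (in percent)."""
    labels = []
    for rec in records:
        if not 0.0 <= rec.conversion <= 100.0:
            raise ValueError(f"record {rec.variant_id}: conversion "
                             f"{rec.conversion} outside [0, 100]")
        labels.append(1 if rec.conversion >= cutoff else 0)
    return labels


def relative_labels(records: list[ConversionRecord],
                    tolerance: float = 0.0) -> list[int]:
    """1 iff the variant converts >= wild-type conversion - tolerance for
    the same substrate; wild-type records are labelled 1."""
    wt: dict[str, float] = {}
    for rec in records:
        if rec.is_wildtype:
            wt[rec.substrate_smiles] = rec.conversion
    labels = []
    for rec in records:
        if rec.substrate_smiles not in wt:
            raise ValueError(f"no wild-type reference conversion for "
                             f"substrate {rec.substrate_smiles!r}")
        if rec.is_wildtype:
            labels.append(1)
        else:
            labels.append(1 if rec.conversion >= wt[rec.substrate_smiles] - tolerance
                          else 0)
    return labels


# ---------------------------------------------------------------------------
# Distal-residue negative augmentation
# ---------------------------------------------------------------------------

def eligible_distal_residues(structure: ProteinStructure,
                             config: AugmentationConfig) -> list[int]:
    """Positions whose minimum C-alpha distance to any triad C-alpha exceeds
    ``min_distance``; the triad itself is excluded."""
    index = {seq_index: xyz for seq_index, _, xyz in structure.residues}
    missing = [p for p in config.triad_positions if p not in index]
    if missing:
        raise ValueError(f"{structure.id}: catalytic-triad residues "
                         f"{missing} absent from structure")
    triad_xyz = np.stack([index[p] for p in config.triad_positions])
    eligible = []
    for seq_index, _, xyz in structure.residues:
        if seq_index in config.triad_positions:
            continue
        dmin = np.min(np.linalg.norm(triad_xyz - xyz, axis=1))
        if dmin > config.min_distance:
            eligible.append(seq_index)
    return eligible


def augment_negatives(structure: ProteinStructure,
                      records: list[ConversionRecord],
                      config: AugmentationConfig) -> list[ConversionRecord]:
    """Seeded random single-point mutations at distal positions, labelled
    as negatives.

    For each eligible position, ``mutations_per_position`` distinct
    non-wild-type amino acids are drawn; substrates are assigned round-robin
    (seeded starting order) from the observed substrate pool. Count =
    k x |eligible positions|.
    """
    eligible = eligible_distal_residues(structure, config)
    if not eligible:
        return []
    pool = config.substrate_pool or sorted({r.substrate_smiles for r in records})
    if not pool:
        raise ValueError("no substrates available to pair with augmented variants")
    aa_by_pos = {r[0]: r[1] for r in structure.residues}
    rng = np.random.default_rng(config.seed)
    pool = [pool[i] for i in rng.permutation(len(pool))]
    negatives: list[ConversionRecord] = []
    counter = 0
    for pos in eligible:
        wt_aa = aa_by_pos[pos]
        alternatives = [a for a in CANONICAL_AA if a != wt_aa]
        picks = rng.choice(len(alternatives), size=config.mutations_per_position,
                           replace=False)
        for pick in picks:
            mut_aa = alternatives[pick]
            substrate = pool[counter % len(pool)]
            counter += 1
            negatives.append(ConversionRecord(
                variant_id=f"aug_{wt_aa}{pos}{mut_aa}",
                mutations=[(wt_aa, pos, mut_aa)],
                substrate_smiles=substrate,
                conversion=0.0,
                provenance="augmented"))
    return negatives


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_conversion_table(path: str | Path) -> list[ConversionRecord]:
    """TSV with columns variant_id, mutations (semicolon list, e.g.
    'W104C;A281E'; empty = wild type), smiles, conversion_pct."""
    df = pd.read_csv(path, sep="\t")
    required = {"variant_id", "mutations", "smiles", "conversion_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: required columns absent: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        raw = "" if pd.isna(row["mutations"]) else str(row["mutations"]).strip()
        mutations = [parse_mutation(tok) for tok in raw.split(";") if tok.strip()]
        records.append(ConversionRecord(
            variant_id=str(row["variant_id"]), mutations=mutations,
            substrate_smiles=str(row["smiles"]),
            conversion=float(row["conversion_pct"])))
    return records


def write_labeled_dataset(path: str | Path, records: list[ConversionRecord],
                          labels: list[int], label_rule: str) -> None:
    rows = []
    for rec, label in zip(records, labels):
        rows.append({
            "variant_id": rec.variant_id,
            "mutations": ";".join(f"{w}{p}{m}" for w, p, m in rec.mutations),
            "smiles": rec.substrate_smiles,
            "conversion_pct": rec.conversion,
            "label": label,
            "label_rule": label_rule,
            "provenance": rec.provenance,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
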