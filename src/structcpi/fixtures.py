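"""Synthetic fixtures: self-contained proteins, ligands and interaction
datasets with planted statistical structure.

``make_helix_protein`` places C-alpha atoms on an ideal helix whose
geometry (radius 2.3 A, rise 1.5 A per residue, 100 degrees per residue)
reproduces the canonical ~3.8 A consecutive C-alpha spacing, so contact
maps have closed-form expectations. ``make_cpi_dataset`` plants an
interpretable signal: the regression label couples a ligand's aromatic
atom count to the presence of an aromatic-rich sequence motif in the
protein, mimicking an aromatic-stacking contact that an attention-based
model can localise. ``make_augmentation_fixture`` builds a structure with
exact counts of residues inside/beyond a distance shell around a
catalytic triad, so the negative-augmentation arithmetic is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .featurize import CANONICAL_AA, InteractionSample, ProteinStructure

__all__ = [
    "FixtureSpec", "DRUGLIKE_SMILES", "make_helix_protein",
    "make_augmentation_fixture", "make_cpi_dataset", "write_pdb",
    "write_interaction_tsv",
]

# A bundled pool of drug-like and fragment-like molecules (valid SMILES,
# a spread of aromatic atom counts from 0 to 13).
DRUGLIKE_SMILES: list[str] = [
    "C", "CC", "CCO", "CC(C)O", "CCCCCC", "CC(=O)O", "CC(=O)C", "CCN(CC)CC",
    "C1CCCCC1", "C1CCOC1", "c1ccccc1", "Cc1ccccc1", "Oc1ccccc1",
    "Nc1ccccc1", "Clc1ccccc1", "c1ccncc1", "c1ccc2ccccc2c1",
    "c1ccc2[nH]ccc2c1", "CC(=O)Oc1ccccc1C(=O)O",        # aspirin
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",                        # ibuprofen
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",                        # caffeine
    "c1ccc(cc1)C(=O)O", "c1ccc(cc1)S(=O)(=O)N", "COc1ccccc1",
    "CCOC(=O)c1ccccc1", "c1ccc(-c2ccccc2)cc1",           # biphenyl
    "c1ccc2c(c1)ccc1ccccc12",                            # anthracene-like
    "OCC1OC(O)C(O)C(O)C1O",                              # glucose
    "NC(Cc1ccccc1)C(=O)O",                               # phenylalanine
    "NC(Cc1c[nH]c2ccccc12)C(=O)O",                       # tryptophan
]

HELIX_RADIUS = 2.3       # Angstrom
HELIX_RISE = 1.5         # Angstrom per residue
HELIX_TURN_DEG = 100.0   # degrees per residue


@dataclass
class FixtureSpec:
    n_residues: int = 30
    n_proteins: int = 12
    n_samples: int = 300
    motif: str = "HWH"            # planted aromatic-rich motif
    effect_size: float = 2.0      # beta: label units per aromatic atom
    noise_sd: float = 0.5
    seed: int = 0
    planted_fraction: float = 0.5  # fraction of proteins carrying the motif

    def __post_init__(self):
        if min(self.n_residues, self.n_proteins, self.n_samples) < 1:
            raise ValueError("fixture sizes must be positive")
        if self.n_residues < len(self.motif):
            raise ValueError("protein shorter than the planted motif")


def _helix_coords(n: int) -> np.ndarray:
    k = np.arange(n)
    theta = np.deg2rad(HELIX_TURN_DEG) * k
    return np.column_stack([HELIX_RADIUS * np.cos(theta),
                            HELIX_RADIUS * np.sin(theta),
                            HELIX_RISE * k])


def make_helix_protein(n: int, seed: int, structure_id: str | None = None,
                       motif: str | None = None,
                       motif_position: int | None = None) -> ProteinStructure:
    """Ideal-helix C-alpha trace with a seeded random sequence; optionally
    overwrite a window with ``motif`` at a (seeded) position."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    seq = [CANONICAL_AA[i] for i in rng.integers(0, 20, size=n)]
    if motif:
        if motif_position is None:
            motif_position = int(rng.integers(0, n - len(motif) + 1))
        seq[motif_position:motif_position + len(motif)] = list(motif)
    coords = _helix_coords(n)
    residues = [(i + 1, seq[i], coords[i]) for i in range(n)]
    return ProteinStructure(id=structure_id or f"helix{n}_s{seed}",
                            chain="A", residues=residues)


def make_augmentation_fixture(n_near: int, n_far: int, seed: int = 0
                              ) -> tuple[ProteinStructure, tuple[int, int, int]]:
    """Structure with a 3-residue catalytic triad at the origin, exactly
    ``n_near`` other residues with min C-alpha distance to the triad
    <= 20 A and ``n_far`` residues beyond 20 A.

    Returns (structure, triad seq positions).
    """
    if n_near < 0 or n_far < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    coords = [np.array([0.0, 0.0, 0.0]), np.array([3.0, 0.0, 0.0]),
              np.array([0.0, 3.0, 0.0])]
    aas = ["S", "D", "H"]  # serine-aspartate-histidine triad
    # near shell: radius 10 from the origin (well inside 20 A of the triad)
    for i in range(n_near):
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        coords.append(10.0 * direction)
        aas.append(CANONICAL_AA[rng.integers(0, 20)])
    # far shell: radius 30 and growing (beyond 20 A of every triad atom)
    for i in range(n_far):
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        coords.append((30.0 + 0.05 * i) * direction)
        aas.append(CANONICAL_AA[rng.integers(0, 20)])
    residues = [(i + 1, aas[i], coords[i]) for i in range(len(coords))]
    structure = ProteinStructure(id=f"augfix_{n_near}_{n_far}_s{seed}",
                                 chain="A", residues=residues)
    return structure, (1, 2, 3)


def _aromatic_atom_count(smiles: str) -> int:
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    return sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())


def make_cpi_dataset(spec: FixtureSpec
                     ) -> tuple[list[InteractionSample],
                                dict[str, ProteinStructure], dict]:
    """Interaction dataset with a planted protein-motif x ligand-aromaticity
    signal.

    label = beta * (ligand aromatic atom count) * 1[motif in sequence]
            + Normal(0, sigma)

    Classification labels (returned in ``info``) threshold the continuous
    label at its median. Fully seeded and deterministic.
    """
    rng = np.random.default_rng(spec.seed)
    structures: dict[str, ProteinStructure] = {}
    motif_present: dict[str, bool] = {}
    n_planted = int(round(spec.planted_fraction * spec.n_proteins))
    for i in range(spec.n_proteins):
        planted = i < n_planted
        pid = f"prot{i:03d}"
        struct = make_helix_protein(
            spec.n_residues, seed=int(rng.integers(2**31)), structure_id=pid,
            motif=spec.motif if planted else None)
        # a decoy without the motif could still contain it by chance; resample
        while not planted and spec.motif in struct.sequence:
            struct = make_helix_protein(spec.n_residues,
                                        seed=int(rng.integers(2**31)),
                                        structure_id=pid)
        structures[pid] = struct
        motif_present[pid] = spec.motif in struct.sequence
    aromatic = {s: _aromatic_atom_count(s) for s in DRUGLIKE_SMILES}
    samples: list[InteractionSample] = []
    for _ in range(spec.n_samples):
        pid = f"prot{rng.integers(0, spec.n_proteins):03d}"
        smiles = DRUGLIKE_SMILES[rng.integers(0, len(DRUGLIKE_SMILES))]
        label = (spec.effect_size * aromatic[smiles] * motif_present[pid]
                 + rng.normal(0.0, spec.noise_sd))
        samples.append(InteractionSample(pid, smiles, float(label)))
    labels = np.array([s.label for s in samples])
    median = float(np.median(labels))
    info = {
        "motif_present": motif_present,
        "median_label": median,
        "class_labels": [1 if s.label > median else 0 for s in samples],
        "aromatic_counts": aromatic,
    }
    return samples, structures, info


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Minimal PDB writer: one CA ATOM record per residue, chain A."""
    one_to_three = {
        "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
        "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
        "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
        "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
        "X": "UNK",
    }
    lines = []
    for serial, (seq_index, aa, xyz) in enumerate(structure.residues, start=1):
        lines.append(
            f"ATOM  {serial:5d}  CA  {one_to_three[aa]} {structure.chain}"
            f"{seq_index:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"  1.00  0.00           C")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_interaction_tsv(samples: list[InteractionSample],
                          path: str | Path) -> None:
    import pandas as pd

    rows = [{"protein_id": s.protein_ref, "smiles": s.smiles,
             "label": s.label, "split": s.split_tag or ""} for s in samples]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_fixture_directory(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write PDB files, the SMILES pool and the interaction TSV."""
    out_dir = Path(out_dir)
    (out_dir / "pdb").mkdir(parents=True, exist_ok=True)
    samples, structures, info = make_cpi_dataset(spec)
    for pid, struct in structures.items():
        write_pdb(struct, out_dir / "pdb" / f"{pid}.pdb")
    (out_dir / "smiles.txt").write_text("\n".join(DRUGLIKE_SMILES) + "\n")
    write_interaction_tsv(samples, out_dir / "interactions.tsv")
    return {"n_samples": len(samples), "n_proteins": len(structures),
            "median_label": info["median_label"]}
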