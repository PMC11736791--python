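"""Protein and ligand graph featurization.

Proteins become contact-map graphs: one node per residue, an edge wherever
two C-alpha atoms lie within a distance cutoff (8 Angstrom by default).
Node features concatenate a 21-slot one-hot (20 canonical residues plus
unknown) with five z-scored physicochemical properties: molecular weight,
pKa of the alpha-carboxyl group, pKb of the alpha-amino group, pKx of the
ionizable side chain, and the isoelectric point pI.

Ligands parsed from SMILES become molecular graphs over heavy atoms with
the canonical 74-dimensional atom feature vector (atom type, degree,
implicit hydrogens, formal charge, radical electrons, hybridization, total
hydrogens, aromaticity).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Amino-acid property table: MW (g/mol), pKa (alpha-COOH), pKb (alpha-NH3+),
# pKx (ionizable side chain; 0.0 marks "none"), pI.
# Values from the standard free-amino-acid table reproduced in Lehninger,
# Principles of Biochemistry (and the CRC Handbook of Chemistry and Physics).
# ---------------------------------------------------------------------------
AA_PROPERTIES: dict[str, tuple[float, float, float, float, float]] = {
    #        MW     pKa   pKb    pKx    pI
    "A": (89.09, 2.34, 9.69, 0.00, 6.00),
    "R": (174.20, 2.17, 9.04, 12.48, 10.76),
    "N": (132.12, 2.02, 8.80, 0.00, 5.41),
    "D": (133.10, 1.88, 9.60, 3.65, 2.77),
    "C": (121.16, 1.96, 10.28, 8.18, 5.07),
    "E": (147.13, 2.19, 9.67, 4.25, 3.22),
    "Q": (146.15, 2.17, 9.13, 0.00, 5.65),
    "G": (75.07, 2.34, 9.60, 0.00, 5.97),
    "H": (155.16, 1.82, 9.17, 6.00, 7.59),
    "I": (131.17, 2.36, 9.60, 0.00, 6.02),
    "L": (131.17, 2.36, 9.60, 0.00, 5.98),
    "K": (146.19, 2.18, 8.95, 10.53, 9.74),
    "M": (149.21, 2.28, 9.21, 0.00, 5.74),
    "F": (165.19, 1.83, 9.13, 0.00, 5.48),
    "P": (115.13, 1.99, 10.60, 0.00, 6.30),
    "S": (105.09, 2.21, 9.15, 0.00, 5.68),
    "T": (119.12, 2.09, 9.10, 0.00, 5.60),
    "W": (204.23, 2.83, 9.39, 0.00, 5.89),
    "Y": (181.19, 2.20, 9.11, 10.07, 5.66),
    "V": (117.15, 2.32, 9.62, 0.00, 5.96),
}

CANONICAL_AA = "ARNDCQEGHILKMFPSTWYV"
N_RESIDUE_FEATURES = 26  # 21 one-hot + 5 physicochemical

_prop_matrix = np.array([AA_PROPERTIES[a] for a in CANONICAL_AA])
_PROP_MEAN = _prop_matrix.mean(axis=0)
_PROP_STD = _prop_matrix.std(axis=0)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ProteinStructure:
    """A single protein chain: ordered residues with C-alpha coordinates."""

    id: str
    chain: str
    # (seq_index, one-letter aa, C-alpha xyz in Angstrom)
    residues: list[tuple[int, str, np.ndarray]]
    atoms: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self):
        idx = [r[0] for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"{self.id}: seq_index must be strictly increasing")
        for _, aa, xyz in self.residues:
            if aa not in CANONICAL_AA and aa != "X":
                raise ValueError(f"{self.id}: unknown residue code {aa!r}")
            if not np.all(np.isfinite(xyz)):
                raise ValueError(f"{self.id}: non-finite C-alpha coordinates")

    @property
    def sequence(self) -> str:
        return "".join(r[1] for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.array([r[2] for r in self.residues], dtype=float)


@dataclass
class ProteinGraph:
    node_features: np.ndarray   # N x 26
    adjacency: np.ndarray       # N x N, binary, symmetric, zero diagonal
    residue_ids: list[int]      # node index -> PDB seq_index


@dataclass
class LigandGraph:
    node_features: np.ndarray   # N_atoms x 74
    adjacency: np.ndarray       # N_atoms x N_atoms, binary, from covalent bonds
    atom_ids: list[int]         # canonical atom ordering from the SMILES parse


@dataclass
class InteractionSample:
    protein_ref: str
    smiles: str
    label: float
    split_tag: str | None = None


# ---------------------------------------------------------------------------
# Residue features
# ---------------------------------------------------------------------------

def residue_features(aa: str) -> np.ndarray:
    """26-dim feature vector for a one-letter residue code.

    Slots 0-20 one-hot (canonical order ``ARNDCQEGHILKMFPSTWYV`` + unknown);
    slots 21-25 hold MW, pKa, pKb, pKx, pI z-scored over the 20 canonical
    residues. 'X' maps to the unknown slot with physicochemical values at
    the canonical mean (0 after z-scoring).
    """
    vec = np.zeros(N_RESIDUE_FEATURES)
    if aa in AA_PROPERTIES:
        vec[CANONICAL_AA.index(aa)] = 1.0
        vec[21:] = (np.array(AA_PROPERTIES[aa]) - _PROP_MEAN) / _PROP_STD
    elif aa == "X":
        vec[20] = 1.0
    else:
        raise ValueError(f"unknown residue code {aa!r}: expected one of "
                         f"{CANONICAL_AA} or 'X'")
    return vec


# ---------------------------------------------------------------------------
# Protein contact-map graphs
# ---------------------------------------------------------------------------

def build_protein_graph(structure: ProteinStructure,
                        cutoff_angstrom: float = 8.0) -> ProteinGraph:
    """Contact-map graph: edge (i, j) iff ||Ca_i - Ca_j|| < cutoff, i != j."""
    if not structure.residues:
        raise ValueError(f"{structure.id}: structure has no residues")
    coords = structure.ca_coords()
    feats = np.stack([residue_features(r[1]) for r in structure.residues])
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    adjacency = (dist < cutoff_angstrom).astype(float)
    np.fill_diagonal(adjacency, 0.0)
    return ProteinGraph(node_features=feats, adjacency=adjacency,
                        residue_ids=[r[0] for r in structure.residues])


# ---------------------------------------------------------------------------
# Ligand molecular graphs (74-dim canonical atom features)
# ---------------------------------------------------------------------------

_ATOM_TYPES = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb",
]  # 43 symbols; an element outside the list maps to the final slot

N_ATOM_FEATURES = 74


def _one_hot(value, choices, strict_last_fallback=True):
    vec = [0.0] * len(choices)
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        if strict_last_fallback:
            vec[-1] = 1.0
    return vec


def atom_features(atom) -> np.ndarray:
    """Canonical 74-dim atom descriptor for an RDKit atom."""
    from rdkit import Chem

    hyb = {
        Chem.HybridizationType.SP: 0, Chem.HybridizationType.SP2: 1,
        Chem.HybridizationType.SP3: 2, Chem.HybridizationType.SP3D: 3,
        Chem.HybridizationType.SP3D2: 4,
    }
    hyb_vec = [0.0] * 5
    if atom.GetHybridization() in hyb:
        hyb_vec[hyb[atom.GetHybridization()]] = 1.0
    feats = (
        _one_hot(atom.GetSymbol(), _ATOM_TYPES)
        + _one_hot(atom.GetDegree(), list(range(11)))
        + _one_hot(atom.GetNumImplicitHs(), list(range(7)))
        + [float(atom.GetFormalCharge())]
        + [float(atom.GetNumRadicalElectrons())]
        + hyb_vec
        + _one_hot(atom.GetTotalNumHs(), list(range(5)))
        + [1.0 if atom.GetIsAromatic() else 0.0]
    )
    return np.array(feats)


def build_ligand_graph(smiles: str) -> LigandGraph:
    """Molecular graph over heavy atoms from a SMILES string."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    n = mol.GetNumAtoms()
    feats = np.stack([atom_features(mol.GetAtomWithIdx(i)) for i in range(n)])
    adjacency = np.zeros((n, n))
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adjacency[i, j] = adjacency[j, i] = 1.0
    return LigandGraph(node_features=feats, adjacency=adjacency,
                       atom_ids=list(range(n)))


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path, chain: str = "A",
             structure_id: str | None = None) -> ProteinStructure:
    """Read one chain of the first model of a PDB file.

    Residues without a C-alpha atom are skipped with a warning; the skip is
    recorded on the returned structure as ``structure.skipped``.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import protein_letters_3to1

    path = Path(path)
    sid = structure_id or path.stem
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PDBParser(QUIET=True).get_structure(sid, str(path))[0]
    if chain not in model:
        raise ValueError(f"{path}: chain {chain!r} not present")
    residues, atoms, skipped = [], {}, []
    for res in model[chain]:
        if res.id[0] != " ":   # skip waters / heteroatoms
            continue
        seq_index = res.id[1]
        aa = protein_letters_3to1.get(res.get_resname().upper(), "X")
        if "CA" not in res:
            logger.warning("%s: residue %s%d lacks a C-alpha atom; skipped",
                           sid, aa, seq_index)
            skipped.append(seq_index)
            continue
        residues.append((seq_index, aa, np.array(res["CA"].get_coord(), dtype=float)))
        atoms[seq_index] = {a.get_name(): np.array(a.get_coord(), dtype=float)
                            for a in res}
    struct = ProteinStructure(id=sid, chain=chain, residues=residues, atoms=atoms)
    struct.skipped = skipped  # skip report
    return struct


# ---------------------------------------------------------------------------
# Interaction tables
# ---------------------------------------------------------------------------

def read_interaction_table(path: str | Path,
                           protein_col: str = "protein_id",
                           smiles_col: str = "smiles",
                           label_col: str = "label",
                           split_col: str = "split") -> tuple[list[InteractionSample], int]:
    """Read a delimited interaction table; returns (samples, n_dropped).

    Rows with a missing protein id, SMILES, or unparsable label are dropped
    and counted.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    for col in (protein_col, smiles_col, label_col):
        if col not in df.columns:
            raise ValueError(f"{path}: required column {col!r} absent "
                             f"(found {list(df.columns)})")
    samples, dropped = [], 0
    has_split = split_col in df.columns
    for _, row in df.iterrows():
        pid, smi = row[protein_col], row[smiles_col]
        try:
            label = float(row[label_col])
        except (TypeError, ValueError):
            label = np.nan
        if (pd.isna(pid) or pd.isna(smi) or str(smi).strip() == ""
                or not np.isfinite(label)):
            dropped += 1
            continue
        tag = None
        if has_split and not pd.isna(row[split_col]):
            tag = str(row[split_col])
        samples.append(InteractionSample(str(pid), str(smi), label, tag))
    return samples, dropped


# ---------------------------------------------------------------------------
# Graph serialization
# ---------------------------------------------------------------------------

def save_graph_archive(path: str | Path, proteins: dict[str, ProteinGraph],
                       ligands: dict[str, LigandGraph]) -> None:
    """Serialize graphs to a compressed archive of named arrays per sample."""
    arrays = {}
    for key, g in proteins.items():
        arrays[f"protein/{key}/features"] = g.node_features
        arrays[f"protein/{key}/adjacency"] = g.adjacency
        arrays[f"protein/{key}/residue_ids"] = np.array(g.residue_ids)
    for key, g in ligands.items():
        arrays[f"ligand/{key}/features"] = g.node_features
        arrays[f"ligand/{key}/adjacency"] = g.adjacency
        arrays[f"ligand/{key}/atom_ids"] = np.array(g.atom_ids)
    np.savez_compressed(path, **arrays)


def load_graph_archive(path: str | Path) -> tuple[dict[str, ProteinGraph],
                                                  dict[str, LigandGraph]]:
    proteins: dict[str, ProteinGraph] = {}
    ligands: dict[str, LigandGraph] = {}
    with np.load(path) as npz:
        keys = {tuple(k.rsplit("/", 1)[0].split("/", 1)) for k in npz.files}
        for kind, name in keys:
            base = f"{kind}/{name}"
            if kind == "protein":
                proteins[name] = ProteinGraph(
                    npz[f"{base}/features"], npz[f"{base}/adjacency"],
                    [int(i) for i in npz[f"{base}/residue_ids"]])
            else:
                ligands[name] = LigandGraph(
                    npz[f"{base}/features"], npz[f"{base}/adjacency"],
                    [int(i) for i in npz[f"{base}/atom_ids"]])
    return proteins, ligands
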