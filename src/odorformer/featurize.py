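"""Atom featurization and batching.

Every atom is encoded as a fixed 71-dimensional binary vector made of
one-hot blocks (element identity, neighbor counts, aromaticity, ring
membership, hybridization, chirality, formal charge, valences). Molecules
become :class:`MolGraph` objects carrying the feature matrix together with
the binary adjacency matrix and the conformer-derived Euclidean distance
matrix; :func:`build_batch` pads a list of graphs into dense arrays with an
atom mask for the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

__all__ = ["MolGraph", "Batch", "atom_features", "mol_features",
           "build_batch", "save_graphs", "load_graphs", "FEATURE_DIM"]

_IDENTITY = ["C", "O", "S", "N", "Cl", "Na", "P", "F", "Mg", "I", "Br", "Zn",
             "Fe", "As", "Ca", "B", "Si", "K", "Co", "Cr", "H", "Al"]
_HYBRID = [Chem.HybridizationType.S, Chem.HybridizationType.SP,
           Chem.HybridizationType.SP2, Chem.HybridizationType.SP3,
           Chem.HybridizationType.SP3D, Chem.HybridizationType.SP3D2,
           Chem.HybridizationType.UNSPECIFIED]
_CHIRALITY = [Chem.ChiralType.CHI_TETRAHEDRAL_CW,
              Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
              Chem.ChiralType.CHI_UNSPECIFIED]
_CHARGES = [0, -1, 1, -2, 2, 3, 4]

#: block widths: identity 23, heavy nbrs 6, H nbrs 6, aromatic 1, ring 1,
#: hybridization 8, chirality 4, charge 8, explicit valence 9, implicit 5
FEATURE_DIM = 23 + 6 + 6 + 1 + 1 + 8 + 4 + 8 + 9 + 5


def _one_hot(value, choices, n_bins):
    """One-hot with a final catch-all bin; n_bins = len(choices) + 1."""
    vec = np.zeros(n_bins)
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


def atom_features(mol: Chem.Mol, atom_idx: int) -> np.ndarray:
    """Binary feature vector for one atom of a sanitized molecule.

    Concatenates, in order: element identity (23 bins, last = others),
    number of heavy neighbors (6 bins: 0-4, other), number of hydrogen
    neighbors (6), is-aromatic (1 bit), is-in-ring (1 bit), hybridization
    (8 bins), chirality (4 bins: CW, CCW, unspecified, other), formal charge
    (8 bins), explicit valence (9 bins: 0-7, other) and implicit valence
    (5 bins: 0-3, other). Exactly one bin is active per one-hot block.
    """
    atom = mol.GetAtomWithIdx(atom_idx)
    heavy = sum(1 for n in atom.GetNeighbors() if n.GetAtomicNum() > 1)
    blocks = [
        _one_hot(atom.GetSymbol(), _IDENTITY, 23),
        _one_hot(heavy, [0, 1, 2, 3, 4], 6),
        _one_hot(atom.GetTotalNumHs(), [0, 1, 2, 3, 4], 6),
        np.array([1.0 if atom.GetIsAromatic() else 0.0]),
        np.array([1.0 if atom.IsInRing() else 0.0]),
        _one_hot(atom.GetHybridization(), _HYBRID, 8),
        _one_hot(atom.GetChiralTag(), _CHIRALITY, 4),
        _one_hot(atom.GetFormalCharge(), _CHARGES, 8),
        _one_hot(atom.GetExplicitValence(), list(range(8)), 9),
        _one_hot(atom.GetImplicitValence(), list(range(4)), 5),
    ]
    return np.concatenate(blocks)


def mol_features(mol: Chem.Mol) -> np.ndarray:
    """Feature matrix [n_atoms x FEATURE_DIM] for all modeled atoms."""
    return np.stack([atom_features(mol, i) for i in range(mol.GetNumAtoms())])


@dataclass
class MolGraph:
    """One molecule's model inputs.

    adjacency is binary/symmetric with zero diagonal (1 = covalent bond);
    distance holds pairwise Euclidean distances in Angstrom from one
    embedded conformer (zero diagonal, symmetric).
    """
    id: str
    features: np.ndarray
    adjacency: np.ndarray
    distance: np.ndarray

    @property
    def n_atoms(self) -> int:
        return self.features.shape[0]


@dataclass
class Batch:
    """Zero-padded dense arrays for a list of graphs.

    atom_mask[b, i] == 1 marks a real atom; padded rows/columns are zero
    and are excluded from every softmax downstream.
    """
    features: np.ndarray   # [B, N_max, d_f]
    adjacency: np.ndarray  # [B, N_max, N_max]
    distance: np.ndarray   # [B, N_max, N_max]
    atom_mask: np.ndarray  # [B, N_max]
    labels: np.ndarray | None = None  # [B, n_targets]
    ids: list = field(default_factory=list)

    @property
    def n_molecules(self) -> int:
        return self.features.shape[0]


def build_batch(graphs: list[MolGraph], labels: np.ndarray | None = None) -> Batch:
    """Pad graphs to the largest atom count in the list."""
    if not graphs:
        raise ValueError("cannot batch an empty list of graphs")
    d_f = graphs[0].features.shape[1]
    if any(g.features.shape[1] != d_f for g in graphs):
        raise ValueError("all graphs in a batch must share the feature dimension")
    n_max = max(g.n_atoms for g in graphs)
    b = len(graphs)
    feats = np.zeros((b, n_max, d_f))
    adj = np.zeros((b, n_max, n_max))
    dist = np.zeros((b, n_max, n_max))
    mask = np.zeros((b, n_max))
    for i, g in enumerate(graphs):
        n = g.n_atoms
        feats[i, :n] = g.features
        adj[i, :n, :n] = g.adjacency
        dist[i, :n, :n] = g.distance
        mask[i, :n] = 1.0
    if labels is not None:
        labels = np.asarray(labels, dtype=float)
        if labels.ndim == 1:
            labels = labels[:, None]
    return Batch(feats, adj, dist, mask, labels, [g.id for g in graphs])


def save_graphs(path: str, graphs: list[MolGraph]) -> None:
    """Serialize graphs to a compressed .npz archive keyed by molecule id."""
    arrays = {}
    for g in graphs:
        arrays[f"{g.id}/features"] = g.features
        arrays[f"{g.id}/adjacency"] = g.adjacency
        arrays[f"{g.id}/distance"] = g.distance
    np.savez_compressed(path, **arrays)


def load_graphs(path: str) -> list[MolGraph]:
    data = np.load(path)
    ids = sorted({k.rsplit("/", 1)[0] for k in data.files})
    return [MolGraph(i, data[f"{i}/features"], data[f"{i}/adjacency"],
                     data[f"{i}/distance"]) for i in ids]
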