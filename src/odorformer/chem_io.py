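"""Molecule table I/O, geometry, filtering and SMARTS-based labeling.

Reads SMILES tables (CSV/TSV or SDF), embeds one 3D conformer per molecule
to obtain the interatomic distance matrix, applies the dataset filtering
rules (drop molecules whose conformer cannot be embedded and molecules with
more than ``max_atoms`` heavy atoms, default 60), and computes binary
substructure-presence labels by SMARTS matching. Combination targets carry
several SMARTS and are positive only when every pattern matches.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem
from rdkit.Chem import AllChem

from .featurize import MolGraph, mol_features

__all__ = ["Status", "MolRecord", "TargetSpec", "read_molecule_table",
           "read_sdf", "compute_geometry", "filter_molecules",
           "label_substructures", "merge_label_groups", "DEFAULT_TARGETS",
           "load_targets", "write_filtered_table", "write_labels"]

DEFAULT_MAX_ATOMS = 60


class Status(str, enum.Enum):
    OK = "ok"
    REMOVED_TOO_LARGE = "removed_too_large"
    REMOVED_NO_GEOMETRY = "removed_no_geometry"
    REMOVED_PARSE_ERROR = "removed_parse_error"


@dataclass
class MolRecord:
    id: str
    smiles: str
    n_atoms: int = 0
    labels: dict = field(default_factory=dict)
    status: Status = Status.OK
    mol: Chem.Mol | None = None
    graph: MolGraph | None = None


@dataclass
class TargetSpec:
    """A prediction target: a SMARTS conjunction or a named label column.

    A combination target (two or more SMARTS) is positive iff every pattern
    matches the molecule at least once.
    """
    name: str
    kind: str = "smarts"            # "smarts" | "label_column"
    patterns: list = field(default_factory=list)
    min_positives: int = 0

    def __post_init__(self):
        if self.kind not in ("smarts", "label_column"):
            raise ValueError(f"unknown target kind: {self.kind!r}")
        if self.kind == "smarts":
            if not self.patterns:
                raise ValueError(f"target {self.name!r}: no SMARTS patterns")
            self._queries = []
            for p in self.patterns:
                q = Chem.MolFromSmarts(p)
                if q is None:
                    raise ValueError(
                        f"target {self.name!r}: unparseable SMARTS {p!r}")
                self._queries.append(q)

    def matches(self, mol: Chem.Mol) -> int:
        """1 iff every SMARTS pattern has at least one match."""
        return int(all(mol.HasSubstructMatch(q) for q in self._queries))

    def match_atoms(self, mol: Chem.Mol) -> set:
        """Union of atom indices over all matches of all patterns."""
        atoms: set = set()
        for q in self._queries:
            for match in mol.GetSubstructMatches(q):
                atoms.update(match)
        return atoms


# A default panel of 24 substructure targets (12 single SMARTS + 12
# conjunctions) spanning common functional groups; editable via YAML config.
DEFAULT_TARGETS = [
    TargetSpec("ester_or_acid", patterns=["C(=O)O"]),
    TargetSpec("peroxide", patterns=["OO"]),
    TargetSpec("aromatic_ring", patterns=["c1ccccc1"]),
    TargetSpec("tert_butyl", patterns=["CC(C)(C)C"]),
    TargetSpec("isopropyl", patterns=["CC(C)C"]),
    TargetSpec("carbonyl", patterns=["C=O"]),
    TargetSpec("hydroxyl", patterns=["[OX2H]"]),
    TargetSpec("amine", patterns=["[NX3]"]),
    TargetSpec("thiol_or_sulfide", patterns=["[SX2]"]),
    TargetSpec("ether", patterns=["[OX2]([#6])[#6]"]),
    TargetSpec("alkene", patterns=["C=C"]),
    TargetSpec("halogen", patterns=["[F,Cl,Br,I]"]),
    TargetSpec("isopropyl_and_aryl_ch", patterns=["CC(C)C", "cCc"]),
    TargetSpec("ester_and_alkene", patterns=["C(=O)O", "C=C"]),
    TargetSpec("carbonyl_and_aromatic", patterns=["C=O", "c1ccccc1"]),
    TargetSpec("hydroxyl_and_aromatic", patterns=["[OX2H]", "c1ccccc1"]),
    TargetSpec("amine_and_carbonyl", patterns=["[NX3]", "C=O"]),
    TargetSpec("ether_and_alkene", patterns=["[OX2]([#6])[#6]", "C=C"]),
    TargetSpec("peroxide_and_carbonyl", patterns=["OO", "C=O"]),
    TargetSpec("sulfur_and_aromatic", patterns=["[SX2]", "c1ccccc1"]),
    TargetSpec("tert_butyl_and_hydroxyl", patterns=["CC(C)(C)C", "[OX2H]"]),
    TargetSpec("halogen_and_aromatic", patterns=["[F,Cl,Br,I]", "c1ccccc1"]),
    TargetSpec("ester_alkene_aromatic",
               patterns=["C(=O)O", "C=C", "c1ccccc1"]),
    TargetSpec("amine_hydroxyl_carbonyl",
               patterns=["[NX3]", "[OX2H]", "C=O"]),
]


def load_targets(path: str) -> list[TargetSpec]:
    """Load a YAML/JSON list of {name, kind, patterns} target entries."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    return [TargetSpec(e["name"], e.get("kind", "smarts"),
                       e.get("patterns", []), e.get("min_positives", 0))
            for e in entries]


def read_molecule_table(path: str, label_columns: list[str] | None = None,
                        smiles_column: str = "smiles",
                        sep: str | None = None) -> list[MolRecord]:
    """Read a CSV/TSV of molecules; one MolRecord per row, order preserved.

    Unparseable SMILES yield status ``removed_parse_error``. Label columns,
    when given, must hold 0/1 values.
    """
    if sep is None:
        sep = "\t" if path.endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    if smiles_column not in df.columns:
        raise KeyError(f"missing SMILES column {smiles_column!r} in {path}")
    label_columns = label_columns or []
    for col in label_columns:
        if col not in df.columns:
            raise KeyError(f"missing label column {col!r} in {path}")
    records = []
    id_col = "id" if "id" in df.columns else None
    for i, row in df.iterrows():
        rid = str(row[id_col]) if id_col else f"mol{i}"
        smiles = str(row[smiles_column])
        labels = {}
        for col in label_columns:
            v = row[col]
            if v not in (0, 1, 0.0, 1.0):
                raise ValueError(
                    f"non-binary label {v!r} for {col!r} at row {i}")
            labels[col] = int(v)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            records.append(MolRecord(rid, smiles, 0, labels,
                                     Status.REMOVED_PARSE_ERROR))
        else:
            records.append(MolRecord(rid, smiles, mol.GetNumAtoms(), labels,
                                     Status.OK, mol))
    return records


def read_sdf(path: str) -> list[MolRecord]:
    """Read an SDF; molecule titles become record ids."""
    records = []
    for i, mol in enumerate(Chem.SDMolSupplier(path)):
        if mol is None:
            records.append(MolRecord(f"sdf{i}", "", 0, {},
                                     Status.REMOVED_PARSE_ERROR))
            continue
        rid = mol.GetProp("_Name") or f"sdf{i}"
        records.append(MolRecord(rid, Chem.MolToSmiles(mol),
                                 mol.GetNumAtoms(), {}, Status.OK, mol))
    return records


def compute_geometry(record: MolRecord, embed_seed: int = 1) -> MolGraph | None:
    """Build the molecule's graph: features, adjacency, distance matrix.

    One conformer is embedded (ETKDG, explicit hydrogens added for the
    embedding then stripped); distances are pairwise Euclidean in Angstrom
    over the heavy atoms. Returns None when the embedding fails — geometry
    failure is data, not an exception; the caller marks the record removed.
    """
    if record.mol is None:
        return None
    mol = Chem.Mol(record.mol)
    n = mol.GetNumAtoms()
    if n < 1:
        return None
    adjacency = Chem.GetAdjacencyMatrix(mol).astype(float)
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(embed_seed)
    if AllChem.EmbedMolecule(molh, params) != 0:
        return None
    coords = molh.GetConformer().GetPositions()[:n]  # heavy atoms come first
    diff = coords[:, None, :] - coords[None, :, :]
    distance = np.sqrt((diff ** 2).sum(-1))
    graph = MolGraph(record.id, mol_features(mol), adjacency, distance)
    record.graph = graph
    return graph


def filter_molecules(records: list[MolRecord],
                     max_atoms: int = DEFAULT_MAX_ATOMS,
                     embed_seed: int = 1,
                     compute: bool = True):
    """Partition records into (kept, removed) under the dataset rules.

    Kept records have status ok, an embedded geometry, and at most
    ``max_atoms`` heavy atoms (the bound is inclusive). Every input record
    lands in exactly one of the two lists.
    """
    kept, removed = [], []
    for rec in records:
        if rec.status != Status.OK:
            removed.append(rec)
            continue
        if rec.n_atoms > max_atoms:
            rec.status = Status.REMOVED_TOO_LARGE
            removed.append(rec)
            continue
        if compute and rec.graph is None:
            if compute_geometry(rec, embed_seed) is None:
                rec.status = Status.REMOVED_NO_GEOMETRY
                removed.append(rec)
                continue
        kept.append(rec)
    return kept, removed


def label_substructures(record: MolRecord,
                        targets: list[TargetSpec]) -> dict:
    """Label a parsed molecule against SMARTS targets (conjunction = AND)."""
    if record.mol is None:
        raise ValueError(f"record {record.id} has no parsed molecule")
    labels = {t.name: t.matches(record.mol) for t in targets}
    record.labels.update(labels)
    return labels


def merge_label_groups(labels: list[dict], groups: dict) -> list[dict]:
    """Fold child labels into parent labels (parent ∨ any child).

    ``groups`` maps a parent label name to its child label names. The parent
    becomes 1 wherever it or any child is 1; children are untouched. The
    operation is idempotent and never clears a positive parent.
    """
    known = set().union(*[set(m) for m in labels]) if labels else set()
    for parent, children in groups.items():
        for c in children:
            if c not in known:
                raise KeyError(f"unknown child label {c!r} for {parent!r}")
    out = []
    for m in labels:
        m = dict(m)
        for parent, children in groups.items():
            if m.get(parent, 0) or any(m.get(c, 0) for c in children):
                m[parent] = 1
        out.append(m)
    return out


def write_filtered_table(path: str, kept: list[MolRecord],
                         removed: list[MolRecord]) -> None:
    rows = [{"id": r.id, "smiles": r.smiles, "n_atoms": r.n_atoms,
             "status": r.status.value} for r in kept + removed]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_labels(path: str, records: list[MolRecord]) -> None:
    rows = [{"id": r.id, **r.labels} for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)
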