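"""Seeded synthetic molecule and label generators.

Stands in for the two data sources the model targets: a library of small
organic molecules with controllable substructure prevalence (screening-
database-like diversity: chains, rings, esters, peroxides, amines, bulky
alkyls) and sparse multilabel annotations produced by substructure→label
rules with optional label-flip noise (odorant-annotation-like data).

Molecules are assembled by fragment grafting: chemically valid fragments are
joined by single bonds at atoms with free valence, so every emitted SMILES
parses and passes valence checks without a fixup pass. Per-target prevalence
is held by quota steering — each target SMARTS is force-included with a
probability that tracks its remaining quota, and candidates that would
overshoot any quota are rejected (bounded at 50x oversampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

__all__ = ["GeneratorConfig", "LabelRule", "generate_molecules",
           "generate_labels", "DEFAULT_FRAGMENTS"]

DEFAULT_FRAGMENTS = [
    "C", "CC", "CCC", "CCCC", "CCCCCC", "CCCCCCCC",   # alkyl chains
    "c1ccccc1",                                        # benzene
    "C(=O)O",                                          # ester / acid
    "OO",                                              # peroxide
    "S",                                               # thiol/sulfide
    "N",                                               # amine
    "COC",                                             # ether
    "CC(C)C",                                          # isopropyl
    "CC(C)(C)C",                                       # tert-butyl
    "C=C", "C=O",                                      # alkene, carbonyl
    "O",                                               # hydroxyl
    "C1CCCCCCCCCC1",                                   # 11-membered ring
]


@dataclass
class GeneratorConfig:
    n_molecules: int = 1000
    atom_budget: tuple = (4, 20)
    fragments: list = field(default_factory=lambda: list(DEFAULT_FRAGMENTS))
    target_prevalence: dict = field(default_factory=dict)  # SMARTS -> fraction
    seed: int = 0
    max_attempts_factor: int = 50

    def __post_init__(self):
        lo, hi = self.atom_budget
        if lo < 1 or hi < lo:
            raise ValueError("invalid atom budget")
        for smarts, p in self.target_prevalence.items():
            if not 0 < p < 1:
                raise ValueError(f"prevalence for {smarts!r} must be in (0,1)")
            if Chem.MolFromSmarts(smarts) is None:
                raise ValueError(f"unparseable target SMARTS {smarts!r}")


@dataclass
class LabelRule:
    """label := AND of SMARTS patterns, then flipped with probability eps."""
    name: str
    patterns: list
    eps: float = 0.0

    def __post_init__(self):
        if not 0 <= self.eps < 0.5:
            raise ValueError("flip noise eps must lie in [0, 0.5)")
        self._queries = []
        for p in self.patterns:
            q = Chem.MolFromSmarts(p)
            if q is None:
                raise ValueError(f"unparseable SMARTS {p!r}")
            self._queries.append(q)

    def base_label(self, mol: Chem.Mol) -> int:
        return int(all(mol.HasSubstructMatch(q) for q in self._queries))


def _free_valence_atoms(mol: Chem.Mol) -> list:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() > 0]


def _graft(mol_a: Chem.Mol, mol_b: Chem.Mol,
           rng: np.random.Generator) -> Chem.Mol | None:
    """Join two fragments by a single bond at random free-valence atoms."""
    sites_a = _free_valence_atoms(mol_a)
    sites_b = _free_valence_atoms(mol_b)
    if not sites_a or not sites_b:
        return None
    ia = int(rng.choice(sites_a))
    ib = int(rng.choice(sites_b))
    combo = Chem.RWMol(Chem.CombineMols(mol_a, mol_b))
    combo.AddBond(ia, mol_a.GetNumAtoms() + ib, Chem.BondType.SINGLE)
    mol = combo.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def _assemble(forced: list, fragments: list, size_target: int, max_size: int,
              rng: np.random.Generator) -> Chem.Mol | None:
    """Build one molecule from forced motif fragments plus random fragments."""
    pool = forced if forced else [fragments[int(rng.integers(len(fragments)))]]
    mol = Chem.MolFromSmiles(pool[0])
    for frag_smiles in pool[1:]:
        frag = Chem.MolFromSmiles(frag_smiles)
        if mol.GetNumAtoms() + frag.GetNumAtoms() > max_size:
            return None  # forced motifs do not fit the budget
        joined = _graft(mol, frag, rng)
        if joined is None:
            return None
        mol = joined
    for _ in range(30):
        if mol.GetNumAtoms() >= size_target:
            break
        frag = Chem.MolFromSmiles(
            fragments[int(rng.integers(len(fragments)))])
        if mol.GetNumAtoms() + frag.GetNumAtoms() > max_size:
            continue
        joined = _graft(mol, frag, rng)
        if joined is not None:
            mol = joined
    return mol


def generate_molecules(config: GeneratorConfig) -> list[str]:
    """Generate valid SMILES with per-target prevalence held to quota.

    For each SMARTS in ``target_prevalence`` the realized positive fraction
    equals round(p * n) / n exactly (well within ±0.05 for n >= 1000).
    Fully reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_molecules
    lo, hi = config.atom_budget
    targets = list(config.target_prevalence)
    queries = {s: Chem.MolFromSmarts(s) for s in targets}
    # a target SMARTS that is itself valid SMILES can be force-included as a
    # fragment; otherwise steering falls back to rejection sampling alone
    motif_frag = {s: (s if Chem.MolFromSmiles(s) is not None else None)
                  for s in targets}
    quotas = {s: int(round(config.target_prevalence[s] * n)) for s in targets}
    pos = {s: 0 for s in targets}
    accepted: list[str] = []
    attempts = 0
    max_attempts = config.max_attempts_factor * n
    while len(accepted) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "prevalence targets infeasible for this fragment vocabulary: "
                f"exceeded {max_attempts} attempts with {len(accepted)}/{n} "
                "molecules accepted")
        remaining = n - len(accepted)
        forced = [motif_frag[s] for s in targets
                  if motif_frag[s] is not None
                  and rng.random() < (quotas[s] - pos[s]) / remaining]
        size_target = int(rng.integers(lo, hi + 1))
        mol = _assemble(forced, config.fragments, size_target, hi, rng)
        if mol is None or not lo <= mol.GetNumAtoms() <= hi:
            continue
        labels = {s: int(mol.HasSubstructMatch(queries[s])) for s in targets}
        ok = True
        for s in targets:
            if labels[s] and pos[s] >= quotas[s]:
                ok = False
            if not labels[s] and (len(accepted) - pos[s]) >= n - quotas[s]:
                ok = False
        if not ok:
            continue
        accepted.append(Chem.MolToSmiles(mol))
        for s in targets:
            pos[s] += labels[s]
    return accepted


def generate_labels(smiles: list[str], rules: list[LabelRule],
                    seed: int = 0) -> pd.DataFrame:
    """Noisy multilabel annotations: rule match, then independent eps-flips.

    Returns a DataFrame with columns id, smiles and one 0/1 column per rule,
    directly writable to a CSV readable by ``read_molecule_table``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES from generator: {smi!r}")
        row = {"id": f"mol{i}", "smiles": smi}
        for rule in rules:
            y = rule.base_label(mol)
            if rule.eps > 0 and rng.random() < rule.eps:
                y = 1 - y
            row[rule.name] = y
        rows.append(row)
    return pd.DataFrame(rows)
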