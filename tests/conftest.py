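import numpy as np
import pytest
from rdkit import Chem

import odorformer as of


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_records(smiles_list):
    """Parsed MolRecords from SMILES (no geometry yet)."""
    records = []
    for i, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        rec = of.MolRecord(f"m{i}", smi)
        if mol is None:
            rec.status = of.Status.REMOVED_PARSE_ERROR
        else:
            rec.mol = mol
            rec.n_atoms = mol.GetNumAtoms()
        records.append(rec)
    return records


def random_graph(rng, n_atoms, d_f=of.FEATURE_DIM):
    """A random MolGraph-shaped instance (not necessarily a real molecule)."""
    feats = rng.random((n_atoms, d_f))
    adj = np.zeros((n_atoms, n_atoms))
    for i in range(n_atoms):
        for j in range(i + 1, n_atoms):
            if rng.random() < 0.4:
                adj[i, j] = adj[j, i] = 1.0
    coords = rng.normal(size=(n_atoms, 3)) * 2.0
    diff = coords[:, None] - coords[None, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    return of.MolGraph(f"g{n_atoms}", feats, adj, dist)


@pytest.fixture
def small_graphs(rng):
    return [random_graph(rng, n) for n in (3, 5, 4)]


@pytest.fixture(scope="session")
def toy_fit():
    """A small fitted model on an easily separable task, shared across tests.

    Task: does the molecule contain oxygen (a linear function of one feature
    bin) — 400 generated molecules, tiny architecture.
    """
    gen = of.GeneratorConfig(n_molecules=400, atom_budget=(4, 12),
                             target_prevalence={"[#8]": 0.4}, seed=7)
    smiles = of.generate_molecules(gen)
    targets = [of.TargetSpec("has_oxygen", patterns=["[#8]"])]
    cfg = of.RunConfig(
        model=of.ModelConfig(n_heads=2, head_dim=8, n_encoder_layers=1,
                             n_decoder_layers=1, seed=0),
        loss=of.LossConfig(contrastive_weight=0.0),
        learning_rate=3e-3, max_epochs=12, patience=12, seed=0)
    model = of.MolecularTransformer.from_smiles(smiles, targets, config=cfg)
    results = model.fit()
    return model, results
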