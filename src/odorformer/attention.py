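"""Attention summation, localization statistics, and ensemble atom annotation.

Decoder attention rows each sum to 1 over the molecule's atoms, so summing
over all decoder layers and heads gives per-atom totals whose mass is
n_heads x n_decoder_layers. For a target substructure occupying atom set T:

* attn_sum        = Σ_{a∈T} attn(a)                       (raw mass on T)
* normalized      = attn_sum / (n_h · n_dc)   ∈ [0, 1]    (localization)
* variance        = (1/|T|) Σ_{a∈T} (attn(a) - attn_sum / (|T|·n_h·n_dc))²

The variance is implemented exactly in that printed form, where the inner
mean is rescaled by n_h·n_dc but attn(a) is not; a corrected variant
(variance of attn(a)/(n_h·n_dc)) is available behind a flag.

Because a single trained model annotates only some of a substructure's
atoms, and which ones varies with initialization, atoms are annotated by an
ensemble vote: train M models, count per atom how many models rank it in the
molecule's top-k attention values, and keep atoms whose counter is strictly
greater than a threshold n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem.Draw import rdMolDraw2D

from .nn import AttentionRecord

__all__ = ["AtomCounter", "sum_attention", "localization_stats",
           "ensemble_topk_counts", "select_annotated_atoms", "select_tp_tn",
           "render_attention"]


@dataclass
class AtomCounter:
    """Per-(molecule, target) atom vote counts from M models' top-k atoms."""
    counts: dict          # (mol_id, target) -> int array [n_atoms]
    n_models: int
    k: int


def sum_attention(record: AttentionRecord) -> np.ndarray:
    """Per-atom attention totals summed over decoder layers and heads.

    The totals over all atoms sum to n_heads x n_decoder_layers.
    """
    w = np.asarray(record.weights, dtype=float)
    if w.size == 0:
        raise ValueError("empty attention record (simplified-decoder variant "
                         "produces no decoder attention)")
    return w.sum(axis=(0, 1))


def localization_stats(record: AttentionRecord, target_atoms,
                       corrected_variance: bool = False):
    """(attn_sum, normalized, variance) for the atoms of a target substructure.

    target_atoms: nonempty set of atom indices belonging to the target.
    normalized lies in [0, 1] and equals |T|/N under uniform attention.
    """
    atoms = sorted(set(target_atoms))
    if not atoms:
        raise ValueError("target atom set is empty")
    totals = sum_attention(record)
    if max(atoms) >= totals.shape[0]:
        raise IndexError("target atom index out of range")
    n_dc, n_h, _ = record.weights.shape
    mass = float(n_h * n_dc)
    attn_sum = float(totals[atoms].sum())
    normalized = attn_sum / mass
    t = len(atoms)
    if corrected_variance:
        scaled = totals[atoms] / mass
        variance = float(np.mean((scaled - scaled.mean()) ** 2))
    else:
        inner = attn_sum / (t * mass)
        variance = float(np.mean((totals[atoms] - inner) ** 2))
    return attn_sum, normalized, variance


def ensemble_topk_counts(records_per_model: list, k: int = 5) -> AtomCounter:
    """Vote counts over M models' per-molecule top-k attention atoms.

    records_per_model: list over models; each element is a list of
    AttentionRecords (same molecule ids and targets across models). Ties in
    the top-k ranking are broken toward the lowest atom index; molecules
    with at most k atoms increment every atom.
    """
    if not records_per_model:
        raise ValueError("no models given")
    keysets = [{(r.mol_id, r.target) for r in recs}
               for recs in records_per_model]
    if any(ks != keysets[0] for ks in keysets[1:]):
        raise ValueError("models cover different (molecule, target) sets")
    counts: dict = {}
    for recs in records_per_model:
        for rec in recs:
            totals = sum_attention(rec)
            n = totals.shape[0]
            key = (rec.mol_id, rec.target)
            if key not in counts:
                counts[key] = np.zeros(n, dtype=int)
            if n <= k:
                top = np.arange(n)
            else:
                # stable sort on (-value, index): lowest index wins ties
                top = np.lexsort((np.arange(n), -totals))[:k]
            counts[key][top] += 1
    return AtomCounter(counts, n_models=len(records_per_model), k=k)


def select_annotated_atoms(counter: AtomCounter, n: int = 50) -> dict:
    """Atoms whose counter is strictly greater than n, per (molecule, target)."""
    import warnings
    if n >= counter.n_models:
        warnings.warn(f"threshold n={n} >= number of models "
                      f"{counter.n_models}: no atom can be selected")
    return {key: set(np.where(c > n)[0]) for key, c in counter.counts.items()}


def select_tp_tn(predictions: np.ndarray, labels: np.ndarray,
                 tp_quorum: int = 90, tn_quorum: int = 85,
                 sample_ids: list | None = None):
    """Quorum-consistent true positives / true negatives per target.

    predictions: binarized [M, n_samples, n_targets] over M models. A
    positive sample enters the TP set of a target when at least tp_quorum of
    the M models predict it positive; a negative sample enters the TN set at
    tn_quorum negative votes. The default quorums (90, 85) are stated for
    M = 100 and scale as ceil(quorum/100 * M) for other M.
    """
    preds = np.asarray(predictions)
    y = np.asarray(labels)
    if preds.ndim != 3 or preds.shape[1:] != y.shape:
        raise ValueError("predictions must be [M, n_samples, n_targets] "
                         "matching labels")
    m = preds.shape[0]
    if tp_quorum > 100 or tn_quorum > 100:
        raise ValueError("quorums are counts out of 100")
    tp_q = int(np.ceil(tp_quorum / 100 * m)) if m != 100 else tp_quorum
    tn_q = int(np.ceil(tn_quorum / 100 * m)) if m != 100 else tn_quorum
    if tp_q > m or tn_q > m:
        raise ValueError("quorum exceeds the number of models")
    ids = sample_ids or list(range(y.shape[0]))
    pos_votes = preds.sum(axis=0)              # [n_samples, n_targets]
    neg_votes = m - pos_votes
    tp_sets, tn_sets = {}, {}
    for t in range(y.shape[1]):
        tp_sets[t] = [ids[i] for i in range(y.shape[0])
                      if y[i, t] == 1 and pos_votes[i, t] >= tp_q]
        tn_sets[t] = [ids[i] for i in range(y.shape[0])
                      if y[i, t] == 0 and neg_votes[i, t] >= tn_q]
    return tp_sets, tn_sets


def render_attention(mol: Chem.Mol, values, out_path: str,
                     size: tuple = (400, 400)) -> None:
    """2D depiction with a blue circle per atom shaded by attention value.

    The shade is linear in value / max(value) (white → blue); output format
    follows the file extension (.svg or .png). Deterministic for fixed input.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.shape[0] != mol.GetNumAtoms():
        raise ValueError("need one nonnegative value per atom")
    if np.any(values < 0):
        raise ValueError("attention values must be nonnegative")
    vmax = values.max()
    rel = values / vmax if vmax > 0 else values
    mol = Chem.Mol(mol)
    Chem.rdDepictor.Compute2DCoords(mol)
    colors = {i: (1.0 - 0.8 * r, 1.0 - 0.5 * r, 1.0)
              for i, r in enumerate(rel)}
    highlight = list(range(mol.GetNumAtoms()))
    if out_path.endswith(".png"):
        drawer = rdMolDraw2D.MolDraw2DCairo(*size)
    else:
        drawer = rdMolDraw2D.MolDraw2DSVG(*size)
    rdMolDraw2D.PrepareAndDrawMolecule(
        drawer, mol, highlightAtoms=highlight, highlightAtomColors=colors,
        highlightBonds=[])
    drawer.FinishDrawing()
    mode = "wb" if out_path.endswith(".png") else "w"
    data = drawer.GetDrawingText()
    with open(out_path, mode) as fh:
        fh.write(data)
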