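"""Model/Results interface over the attention transformer.

`MolecularTransformer` is constructed from molecule data plus target
specifications (SMARTS substructures or label columns) and a `RunConfig`;
`fit()` trains the network and returns a `TransformerResults` holding the
learned parameters, the training history, test-set metrics, and the
attention-based interpretation utilities.
"""

from __future__ import annotations

import io
from dataclasses import replace

import numpy as np
import pandas as pd

from . import chem_io
from .chem_io import MolRecord, TargetSpec, Status, filter_molecules, \
    label_substructures
from .featurize import MolGraph
from .nn import AttentionRecord, ModelConfig, save_checkpoint, load_checkpoint
from .training import RunConfig, MetricsReport, split_dataset, train_model, \
    evaluate, records_to_dataset, model_predict

__all__ = ["MolecularTransformer", "TransformerResults"]


class MolecularTransformer:
    """Interpretable attention model over molecules.

    Parameters
    ----------
    records : list of MolRecord
        Parsed molecules; geometry is computed (and failing molecules
        dropped) at construction if not already present.
    targets : list of TargetSpec
        Prediction targets. SMARTS targets are labeled here by substructure
        matching; label-column targets must already be present in each
        record's ``labels``.
    config : RunConfig, optional
        Architecture, loss and optimization settings.
    """

    def __init__(self, records: list[MolRecord], targets: list[TargetSpec],
                 config: RunConfig | None = None, max_atoms: int = 60,
                 embed_seed: int = 1):
        self.config = config or RunConfig()
        self.targets = targets
        self.target_names = [t.name for t in targets]
        kept, removed = filter_molecules(records, max_atoms=max_atoms,
                                         embed_seed=embed_seed)
        for rec in kept:
            smarts_targets = [t for t in targets if t.kind == "smarts"]
            if smarts_targets:
                label_substructures(rec, smarts_targets)
            missing = [t.name for t in targets if t.name not in rec.labels]
            if missing:
                raise KeyError(f"record {rec.id} lacks labels {missing}")
        self.records = kept
        self.removed = removed
        train, test = split_dataset(kept, self.config.split_ratio,
                                    self.config.seed)
        self.train_records, self.test_records = train, test
        self._embed_seed = embed_seed
        self._max_atoms = max_atoms

    # -- constructors --------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, targets: list[TargetSpec],
                       smiles_column: str = "smiles", **kwargs):
        """Build from a table with a SMILES column (+ 0/1 label columns)."""
        from rdkit import Chem
        label_cols = [t.name for t in targets if t.kind == "label_column"]
        records = []
        id_col = "id" if "id" in df.columns else None
        for i, row in df.reset_index(drop=True).iterrows():
            rid = str(row[id_col]) if id_col else f"mol{i}"
            smiles = str(row[smiles_column])
            mol = Chem.MolFromSmiles(smiles)
            labels = {c: int(row[c]) for c in label_cols}
            if mol is None:
                records.append(MolRecord(rid, smiles, 0, labels,
                                         Status.REMOVED_PARSE_ERROR))
            else:
                records.append(MolRecord(rid, smiles, mol.GetNumAtoms(),
                                         labels, Status.OK, mol))
        return cls(records, targets, **kwargs)

    @classmethod
    def from_smiles(cls, smiles: list[str], targets: list[TargetSpec],
                    **kwargs):
        df = pd.DataFrame({"id": [f"mol{i}" for i in range(len(smiles))],
                           "smiles": smiles})
        return cls.from_dataframe(df, targets, **kwargs)

    # -- fitting ---------------------------------------------------------------
    def fit(self, verbose: bool = False) -> "TransformerResults":
        """Train on the training split; evaluate on the held-out test split."""
        graphs, labels = records_to_dataset(self.train_records,
                                            self.target_names)
        params, history = train_model(graphs, labels, self.config, verbose)
        mcfg = replace(self.config.model, n_targets=len(self.target_names))
        report = None
        if self.test_records:
            tg, tl = records_to_dataset(self.test_records, self.target_names)
            report = evaluate(params, mcfg, tg, tl, self.target_names,
                              self.config.threshold)
        return TransformerResults(self, params, mcfg, history, report)


class TransformerResults:
    """Fitted model: parameters, history, metrics, prediction and attention."""

    def __init__(self, model: MolecularTransformer | None, params: dict,
                 model_config: ModelConfig, history: pd.DataFrame | None,
                 report: MetricsReport | None):
        self.model = model
        self.params = params
        self.model_config = model_config
        self.history = history
        self.report = report
        self.target_names = (model.target_names if model is not None else
                             [f"target{t}" for t in
                              range(model_config.n_targets)])

    # -- prediction ------------------------------------------------------------
    def _to_graphs(self, data) -> list[MolGraph]:
        if isinstance(data, list) and data and isinstance(data[0], MolGraph):
            return data
        if isinstance(data, list) and data and isinstance(data[0], MolRecord):
            kept, _ = filter_molecules(data)
            return [r.graph for r in kept]
        raise TypeError("expected a list of MolGraph or MolRecord")

    def predict(self, data, threshold: float | None = None) -> pd.DataFrame:
        """Per-target probabilities (and calls, if a threshold is given)."""
        graphs = self._to_graphs(data)
        probs = model_predict(graphs, self.params, self.model_config)
        out = pd.DataFrame(probs, columns=self.target_names)
        out.insert(0, "id", [g.id for g in graphs])
        if threshold is not None:
            for name in self.target_names:
                out[f"{name}_call"] = (out[name] >= threshold).astype(int)
        return out

    def evaluate(self, data, labels, threshold: float = 0.5) -> MetricsReport:
        graphs = self._to_graphs(data)
        return evaluate(self.params, self.model_config, graphs,
                        np.asarray(labels), self.target_names, threshold)

    def attention(self, data) -> list[AttentionRecord]:
        """Decoder attention records (one per molecule per target)."""
        graphs = self._to_graphs(data)
        _, attns = model_predict(graphs, self.params, self.model_config,
                                 collect_attention=True)
        records = []
        for gph, a in zip(graphs, attns):
            for t in range(self.model_config.n_targets):
                records.append(AttentionRecord(gph.id, t, a[t]))
        return records

    # -- reporting ---------------------------------------------------------------
    def summary(self) -> str:
        buf = io.StringIO()
        cfg = self.model_config
        print("Molecular attention transformer results", file=buf)
        print("=" * 55, file=buf)
        print(f"variant: {cfg.variant}   d_model: {cfg.d_model} "
              f"({cfg.n_heads} heads x {cfg.head_dim})", file=buf)
        print(f"encoder layers: {cfg.n_encoder_layers}   "
              f"decoder layers: {cfg.n_decoder_layers}   "
              f"targets: {cfg.n_targets}", file=buf)
        if self.model is not None:
            print(f"train/test: {len(self.model.train_records)}/"
                  f"{len(self.model.test_records)} molecules "
                  f"({len(self.model.removed)} removed by filtering)",
                  file=buf)
        if self.history is not None and len(self.history):
            last = self.history.iloc[-1]
            best = self.history["val_macro_f1"].max()
            print(f"epochs run: {len(self.history)}   "
                  f"final loss: {last['total']:.4f}   "
                  f"best val macro F1: {best:.4f}", file=buf)
        if self.report is not None:
            print("-" * 55, file=buf)
            print(f"{'target':<28}{'F1':>8}{'prec':>8}{'recall':>8}",
                  file=buf)
            for t in self.report.target_names:
                print(f"{t:<28}{self.report.f1[t]:>8.3f}"
                      f"{self.report.precision[t]:>8.3f}"
                      f"{self.report.recall[t]:>8.3f}", file=buf)
            print(f"macro F1: {self.report.macro_f1:.3f}   "
                  f"micro F1: {self.report.micro_f1:.3f}", file=buf)
        return buf.getvalue()

    def save(self, path: str) -> None:
        save_checkpoint(path, self.params, self.model_config)

    @classmethod
    def load(cls, path: str) -> "TransformerResults":
        params, config = load_checkpoint(path)
        return cls(None, params, config, None, None)
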