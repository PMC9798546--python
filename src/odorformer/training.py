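"""Dataset splitting, the training loop, F1 evaluation and model comparison.

Training uses Adam (default learning rate 7e-5), dropout 0.1, a 5:1
train/test split, and early stopping on the macro F1 of a held-out
validation fraction of the training set. Two fitted models are compared
with an approximate randomization test on a paired test set: per sample,
the two models' prediction rows are swapped with probability 1/2 and the
absolute difference of the metric is recomputed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._autograd import Adam, Tensor
from .featurize import MolGraph, build_batch
from .losses import LossConfig, compute_class_weights, total_loss, \
    weighted_bce
from .nn import ModelConfig, init_params, predict

__all__ = ["RunConfig", "MetricsReport", "split_dataset", "train_model",
           "evaluate", "approx_randomization_test", "model_predict",
           "records_to_dataset"]


@dataclass
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    learning_rate: float = 7e-5
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    split_ratio: tuple = (5, 1)
    validation_fraction: float = 0.1
    threshold: float = 0.5
    seed: int = 0


@dataclass
class MetricsReport:
    target_names: list
    f1: dict
    precision: dict
    recall: dict
    counts: dict          # per target: dict(tp=, fp=, fn=, tn=)
    macro_f1: float
    micro_f1: float
    n_samples: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.target_names:
            c = self.counts[t]
            rows.append({"target": t, "f1": self.f1[t],
                         "precision": self.precision[t],
                         "recall": self.recall[t], **c})
        return pd.DataFrame(rows)


def split_dataset(records: list, ratio: tuple = (5, 1), seed: int = 0):
    """Seeded uniform split into (train, test) at the given ratio.

    Train size is ceil(N * ratio_train / (ratio_train + ratio_test)); the
    split is disjoint and covers the input. Works on any sequence.
    """
    r_train, r_test = ratio
    if r_train <= 0 or r_test <= 0:
        raise ValueError("split ratio parts must be positive")
    n = len(records)
    idx = np.random.default_rng(seed).permutation(n)
    n_train = int(np.ceil(n * r_train / (r_train + r_test)))
    train = [records[i] for i in idx[:n_train]]
    test = [records[i] for i in idx[n_train:]]
    return train, test


def records_to_dataset(records: list, target_names: list):
    """Extract (graphs, labels [n, T]) from filtered MolRecords."""
    graphs, rows = [], []
    for rec in records:
        if rec.graph is None:
            raise ValueError(f"record {rec.id} has no computed geometry")
        graphs.append(rec.graph)
        rows.append([rec.labels[t] for t in target_names])
    return graphs, np.asarray(rows, dtype=float)


def model_predict(graphs: list[MolGraph], params: dict, config: ModelConfig,
                  batch_size: int = 128, collect_attention: bool = False):
    """Probabilities [n, n_targets] (and per-molecule attention arrays)."""
    probs, attns = [], []
    for i in range(0, len(graphs), batch_size):
        chunk = graphs[i:i + batch_size]
        batch = build_batch(chunk)
        p, attn, _ = predict(batch, config, params)
        probs.append(p.data)
        if collect_attention and attn is not None:
            for j, gph in enumerate(chunk):
                attns.append(attn[j, :, :, :, :gph.n_atoms])
    out = np.concatenate(probs, axis=0)
    return (out, attns) if collect_attention else out


def _macro_f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = ((y_pred == 1) & (y_true == 1)).sum(axis=0)
    fp = ((y_pred == 1) & (y_true == 0)).sum(axis=0)
    fn = ((y_pred == 0) & (y_true == 1)).sum(axis=0)
    den = 2 * tp + fp + fn
    f1 = np.where(den > 0, 2 * tp / np.where(den > 0, den, 1), 0.0)
    return float(f1.mean())


def train_model(graphs: list[MolGraph], labels: np.ndarray, config: RunConfig,
                verbose: bool = False):
    """Fit the model; returns (best params, per-epoch log DataFrame).

    A validation fraction of the training data is held out for early
    stopping on macro F1; the best-validation checkpoint is returned. The
    log has columns epoch, bce, contrastive, total, val_macro_f1.
    """
    labels = np.asarray(labels, dtype=float)
    if labels.ndim == 1:
        labels = labels[:, None]
    n, n_targets = labels.shape
    mcfg = copy.deepcopy(config.model)
    mcfg.n_targets = n_targets
    rng = np.random.default_rng(config.seed)

    n_val = max(1, int(round(config.validation_fraction * n)))
    perm = rng.permutation(n)
    val_idx, fit_idx = perm[:n_val], perm[n_val:]
    fit_graphs = [graphs[i] for i in fit_idx]
    fit_labels = labels[fit_idx]
    val_graphs = [graphs[i] for i in val_idx]
    val_labels = labels[val_idx]

    lcfg = copy.deepcopy(config.loss)
    if lcfg.class_weights is None:
        lcfg.class_weights = compute_class_weights(fit_labels)

    params = init_params(mcfg)
    opt = Adam(params, lr=config.learning_rate)
    best_f1, best_params, since_best = -1.0, None, 0
    log_rows = []
    n_fit = len(fit_graphs)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n_fit)
        ep_bce = ep_con = ep_total = 0.0
        n_batches = 0
        for start in range(0, n_fit, config.batch_size):
            bidx = order[start:start + config.batch_size]
            batch = build_batch([fit_graphs[i] for i in bidx],
                                fit_labels[bidx])
            probs, _, cls = predict(batch, mcfg, params, rng, training=True)
            bce = weighted_bce(probs, batch.labels, lcfg.class_weights)
            loss = total_loss(probs, cls, batch.labels, lcfg)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_bce += float(bce.data)
            ep_total += float(loss.data)
            ep_con += float(loss.data - bce.data)
            n_batches += 1
        val_probs = model_predict(val_graphs, params, mcfg)
        val_pred = (val_probs >= config.threshold).astype(int)
        val_f1 = _macro_f1(val_labels, val_pred)
        log_rows.append({"epoch": epoch, "bce": ep_bce / n_batches,
                         "contrastive": ep_con / n_batches,
                         "total": ep_total / n_batches,
                         "val_macro_f1": val_f1})
        if verbose:
            print(f"epoch {epoch}: loss {ep_total / n_batches:.4f} "
                  f"val macro F1 {val_f1:.4f}")
        if val_f1 > best_f1:
            best_f1 = val_f1
            best_params = {k: Tensor(p.data.copy(), requires_grad=True)
                           for k, p in params.items()}
            since_best = 0
        else:
            since_best += 1
            if since_best > config.patience:
                break
    return best_params, pd.DataFrame(log_rows)


def evaluate(params: dict, config: ModelConfig, graphs: list[MolGraph],
             labels: np.ndarray, target_names: list | None = None,
             threshold: float = 0.5) -> MetricsReport:
    """Per-target F1/precision/recall plus macro and micro aggregates.

    F1 = 2TP / (2TP + FP + FN), taken as 0 when the denominator is 0;
    macro F1 is the unweighted mean over targets (targets with neither a
    positive label nor a positive prediction are reported as NaN and
    excluded), micro F1 pools the confusion counts over targets.
    """
    labels = np.asarray(labels, dtype=float)
    if labels.ndim == 1:
        labels = labels[:, None]
    probs = model_predict(graphs, params, config)
    preds = (probs >= threshold).astype(int)
    n_targets = labels.shape[1]
    names = target_names or [f"target{t}" for t in range(n_targets)]
    f1_d, prec_d, rec_d, counts = {}, {}, {}, {}
    tp_all = fp_all = fn_all = 0
    macro_terms = []
    for t, name in enumerate(names):
        yt, pt = labels[:, t], preds[:, t]
        tp = int(((pt == 1) & (yt == 1)).sum())
        fp = int(((pt == 1) & (yt == 0)).sum())
        fn = int(((pt == 0) & (yt == 1)).sum())
        tn = int(((pt == 0) & (yt == 0)).sum())
        counts[name] = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
        prec_d[name] = tp / (tp + fp) if tp + fp else 0.0
        rec_d[name] = tp / (tp + fn) if tp + fn else 0.0
        if 2 * tp + fp + fn == 0:
            f1_d[name] = float("nan")
        else:
            f1_d[name] = 2 * tp / (2 * tp + fp + fn)
            macro_terms.append(f1_d[name])
        tp_all, fp_all, fn_all = tp_all + tp, fp_all + fp, fn_all + fn
    macro = float(np.mean(macro_terms)) if macro_terms else float("nan")
    micro_den = 2 * tp_all + fp_all + fn_all
    micro = 2 * tp_all / micro_den if micro_den > 0 else 0.0
    return MetricsReport(names, f1_d, prec_d, rec_d, counts, macro,
                         float(micro), labels.shape[0])


def approx_randomization_test(pred_a: np.ndarray, pred_b: np.ndarray,
                              labels: np.ndarray, metric=_macro_f1,
                              n_iter: int = 9999, seed: int = 0) -> float:
    """Paired approximate randomization test on binarized predictions.

    The statistic is |metric(A) - metric(B)|; each iteration swaps the two
    models' prediction rows per sample with probability 1/2. The reported
    p-value uses the add-one estimator (1 + #{>= observed}) / (1 + n_iter),
    so p ∈ (0, 1].
    """
    a = np.asarray(pred_a)
    b = np.asarray(pred_b)
    y = np.asarray(labels)
    if a.ndim == 1:
        a, b, y = a[:, None], b[:, None], y[:, None]
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("prediction and label matrices must share a shape")
    observed = abs(metric(y, a) - metric(y, b))
    rng = np.random.default_rng(seed)
    count = 0
    n = a.shape[0]
    for _ in range(n_iter):
        swap = rng.random(n) < 0.5
        a2 = np.where(swap[:, None], b, a)
        b2 = np.where(swap[:, None], a, b)
        stat = abs(metric(y, a2) - metric(y, b2))
        if stat >= observed - 1e-12:
            count += 1
    return (1 + count) / (1 + n_iter)
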