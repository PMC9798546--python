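"""Training objectives: class-weighted BCE and the supervised contrastive loss.

The classification loss is binary cross-entropy where, per target, every
negative sample weighs 1 and every positive sample weighs
(number of all samples - number of positive samples) / number of positive
samples, counteracting label imbalance.

The supervised contrastive term pulls the (unit-normalized) per-target cls
feature vectors of same-label samples together within a batch::

    L = Σ_i (-1/|P(i)|) Σ_{p∈P(i)} log exp(z_i·z_p/τ) / Σ_{a∈A(i)} exp(z_i·z_a/τ)

with P(i) the other samples sharing sample i's label, A(i) the batch minus i,
and τ a temperature. In the multilabel setting the loss is applied per
target on that target's binary label and averaged over targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor

__all__ = ["LossConfig", "compute_class_weights", "weighted_bce",
           "contrastive_loss", "total_loss", "PROB_EPS"]

PROB_EPS = 1e-7  # probabilities are clamped to [PROB_EPS, 1 - PROB_EPS]


@dataclass
class LossConfig:
    tau: float = 0.7
    contrastive_weight: float = 1.0
    class_weights: np.ndarray | None = None

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.contrastive_weight < 0:
            raise ValueError("contrastive_weight must be nonnegative")


def compute_class_weights(labels: np.ndarray,
                          target_names: list[str] | None = None) -> np.ndarray:
    """Per-target positive-sample weight (N - P) / P.

    labels: binary [n_samples, n_targets]. A target with zero positives is a
    configuration error (such targets should have been dropped upstream).
    """
    labels = np.asarray(labels, dtype=float)
    if labels.ndim == 1:
        labels = labels[:, None]
    n = labels.shape[0]
    pos = labels.sum(axis=0)
    if np.any(pos == 0):
        bad = np.where(pos == 0)[0]
        names = ([target_names[i] for i in bad] if target_names
                 else list(bad))
        raise ValueError(f"targets with zero positive samples: {names}")
    return (n - pos) / pos


def weighted_bce(probabilities, labels, class_weights=None):
    """Mean over samples and targets of -[w_t y log p + (1-y) log(1-p)].

    Accepts Tensors (differentiable) or arrays; probabilities are clamped at
    PROB_EPS for log stability.
    """
    p = probabilities if isinstance(probabilities, Tensor) \
        else Tensor(np.asarray(probabilities, dtype=float))
    y = np.asarray(labels, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    w = np.ones(y.shape[1]) if class_weights is None \
        else np.asarray(class_weights, dtype=float)
    p = p.clip(PROB_EPS, 1.0 - PROB_EPS)
    term = Tensor(-w[None, :] * y) * p.log() + Tensor(-(1.0 - y)) * (1.0 - p).log()
    return term.mean()


def contrastive_loss(z, labels, tau: float = 0.7):
    """Supervised contrastive loss over one batch for one binary target.

    z: [B, d] feature vectors (defensively L2-normalized); labels: [B]
    binary. Samples with no same-label partner in the batch contribute 0;
    batches of fewer than 2 samples return 0.
    """
    zt = z if isinstance(z, Tensor) else Tensor(np.asarray(z, dtype=float))
    y = np.asarray(labels, dtype=float).reshape(-1)
    b = zt.shape[0]
    if b < 2:
        return Tensor(0.0)
    norm = (zt.pow(2).sum(axis=-1, keepdims=True) + 1e-12).pow(0.5)
    zn = zt / norm
    sims = zn @ zn.swap_last() * (1.0 / tau)          # [B, B]
    same = (y[:, None] == y[None, :]).astype(float)
    off_diag = 1.0 - np.eye(b)
    pos_mask = same * off_diag                         # P(i)
    n_pos = pos_mask.sum(axis=1)                       # |P(i)|

    # log denominator over A(i) = batch \ {i}
    neg_inf_diag = np.where(np.eye(b, dtype=bool), -np.inf, 0.0)
    shifted = sims + Tensor(neg_inf_diag)
    m = np.max(shifted.data, axis=1, keepdims=True)
    log_den = ((shifted - Tensor(m)).exp() * Tensor(off_diag)) \
        .sum(axis=1, keepdims=True).log() + Tensor(m)
    log_ratio = sims - log_den                         # [B, B]
    inv = np.where(n_pos > 0, 1.0 / np.where(n_pos > 0, n_pos, 1.0), 0.0)
    loss = (log_ratio * Tensor(pos_mask) * Tensor(-inv[:, None])).sum()
    return loss


def total_loss(probabilities, cls_features, labels, config: LossConfig):
    """weighted BCE + contrastive_weight x mean-over-targets contrastive loss.

    cls_features: [B, n_targets, d] per-target decoder outputs (or None,
    e.g. the simplified-decoder variant, which disables the contrastive
    term). The contrastive term uses each target's own binary labels.
    """
    y = np.asarray(labels, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    bce = weighted_bce(probabilities, y, config.class_weights)
    if config.contrastive_weight == 0 or cls_features is None:
        return bce
    n_targets = y.shape[1]
    contrib = None
    for t in range(n_targets):
        zt = cls_features if isinstance(cls_features, Tensor) \
            else Tensor(np.asarray(cls_features, dtype=float))
        b, _, d = zt.shape
        z_t = zt.transpose(1, 0, 2).reshape(n_targets, b, d)
        # slice target t without indexing support: multiply by a selector
        sel = np.zeros((n_targets, 1, 1))
        sel[t, 0, 0] = 1.0
        z_sel = (z_t * Tensor(sel)).sum(axis=0)
        c = contrastive_loss(z_sel, y[:, t], config.tau)
        contrib = c if contrib is None else contrib + c
    return bce + contrib * (config.contrastive_weight / n_targets)
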