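"""The dual-branch masked-attention encoder and per-target decoder module.

The encoder replaces positional embeddings with molecular structure: each
head computes two standard scaled-dot-product attention maps, one masked
elementwise (after the softmax, without renormalization) by the bond
adjacency matrix A and one by g(D) = exp(-D) applied to the conformer
distance matrix, so message passing between two atoms happens only when they
are bonded or spatially close::

    Attention = (softmax(Q_adj K_adj^T / sqrt(d_k)) ⊙ A) V_adj
              + (softmax(Q_dist K_dist^T / sqrt(d_k)) ⊙ g(D)) V_dist

Variants: ``adj_only`` / ``dist_only`` keep a single branch; ``mat_attn`` is
the additive mixture (λ1·softmax(QK^T/√d_k) + λ2·g(D) + λ3·A)·V of the
Molecular Attention Transformer.

The decoder-like module is a Transformer decoder without self-attention:
one learnable query vector per target (an affine image of the constant 1)
cross-attends onto the encoder's atom attributes; its attention rows are the
model's per-atom attribution and sum to 1 over real atoms. A
``simplified_decoder`` variant replaces the module with sum pooling.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np

from ._autograd import Tensor, masked_softmax, layer_norm, concat
from .featurize import Batch, FEATURE_DIM

__all__ = ["ModelConfig", "AttentionRecord", "g", "init_params",
           "encoder_attention", "encoder_attention_maps", "encoder_forward",
           "decoder_module", "predict", "save_checkpoint", "load_checkpoint",
           "VARIANTS"]

VARIANTS = ("proposed", "mat_attn", "adj_only", "dist_only",
            "simplified_decoder")


@dataclass
class ModelConfig:
    """Architecture hyperparameters; model width d_model = n_heads * head_dim."""
    n_heads: int = 4
    head_dim: int = 15
    n_encoder_layers: int = 2
    n_decoder_layers: int = 1
    variant: str = "proposed"
    lambda1: float = 0.33
    lambda2: float = 0.33
    lambda3: float = 0.33
    dropout: float = 0.1
    n_targets: int = 1
    share_decoder_weights: bool = True
    seed: int = 0

    @property
    def d_model(self) -> int:
        return self.n_heads * self.head_dim

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class AttentionRecord:
    """Decoder attention over atoms for one molecule and one target.

    weights has shape [n_decoder_layers, n_heads, n_atoms]; every
    [layer, head] row sums to 1 over the molecule's real atoms.
    """
    mol_id: str
    target: int
    weights: np.ndarray


def g(d):
    """Distance kernel g(d) = exp(-d), strictly decreasing with g(0) = 1."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    return np.exp(-d)


# ---------------------------------------------------------------------------
# parameters

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=(fan_in, fan_out)),
                  requires_grad=True)


def _zeros(*shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def _ones(*shape) -> Tensor:
    return Tensor(np.ones(shape), requires_grad=True)


def _attn_branch(params, prefix, rng, d):
    for w in ("Wq", "Wk", "Wv"):
        params[f"{prefix}/{w}"] = _glorot(rng, d, d)


def _sublayer_common(params, prefix, rng, d):
    params[f"{prefix}/Wo"] = _glorot(rng, d, d)
    params[f"{prefix}/bo"] = _zeros(d)
    params[f"{prefix}/ln1/g"] = _ones(d)
    params[f"{prefix}/ln1/b"] = _zeros(d)
    params[f"{prefix}/ff/W1"] = _glorot(rng, d, d)
    params[f"{prefix}/ff/b1"] = _zeros(d)
    params[f"{prefix}/ff/W2"] = _glorot(rng, d, d)
    params[f"{prefix}/ff/b2"] = _zeros(d)
    params[f"{prefix}/ln2/g"] = _ones(d)
    params[f"{prefix}/ln2/b"] = _zeros(d)


def init_params(config: ModelConfig, d_f: int = FEATURE_DIM) -> dict:
    """Seeded Glorot-uniform initialization of all learnable tensors."""
    rng = np.random.default_rng(config.seed)
    d = config.d_model
    params: dict = {"embed/W": _glorot(rng, d_f, d), "embed/b": _zeros(d)}
    for layer in range(config.n_encoder_layers):
        p = f"enc{layer}"
        if config.variant in ("proposed", "simplified_decoder"):
            _attn_branch(params, f"{p}/adj", rng, d)
            _attn_branch(params, f"{p}/dist", rng, d)
        else:
            _attn_branch(params, f"{p}/attn", rng, d)
        _sublayer_common(params, p, rng, d)
    if config.variant != "simplified_decoder":
        params["cls_embed"] = Tensor(
            rng.uniform(-1, 1, size=(config.n_targets, d)) * np.sqrt(3.0 / d),
            requires_grad=True)
        for layer in range(config.n_decoder_layers):
            prefixes = ([f"dec{layer}"] if config.share_decoder_weights else
                        [f"dec{layer}/t{t}" for t in range(config.n_targets)])
            for p in prefixes:
                _attn_branch(params, f"{p}/x", rng, d)
                _sublayer_common(params, p, rng, d)
    params["out/W"] = _glorot(rng, config.n_targets, d)
    params["out/b"] = _zeros(config.n_targets)
    return params


# ---------------------------------------------------------------------------
# forward passes

class _Dropout:
    """Inverted dropout; inactive unless training with rate > 0."""

    def __init__(self, rate: float, rng: np.random.Generator | None,
                 training: bool):
        self.rate = rate
        self.rng = rng
        self.active = training and rate > 0 and rng is not None

    def __call__(self, x: Tensor) -> Tensor:
        if not self.active:
            return x
        keep = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * Tensor(keep)


def _split_heads(x: Tensor, n_heads: int, head_dim: int) -> Tensor:
    b, n, _ = x.shape
    return x.reshape(b, n, n_heads, head_dim).transpose(0, 2, 1, 3)


def _merge_heads(x: Tensor) -> Tensor:
    b, h, n, dk = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, n, h * dk)


def _branch_qkv(x: Tensor, params: dict, prefix: str, n_heads: int,
                head_dim: int):
    q = _split_heads(x @ params[f"{prefix}/Wq"], n_heads, head_dim)
    k = _split_heads(x @ params[f"{prefix}/Wk"], n_heads, head_dim)
    v = _split_heads(x @ params[f"{prefix}/Wv"], n_heads, head_dim)
    return q, k, v


def _attention_sublayer(x: Tensor, adj: np.ndarray, gdist: np.ndarray,
                        key_mask: np.ndarray, params: dict, prefix: str,
                        config: ModelConfig) -> Tensor:
    """One encoder attention sublayer (pre-residual), heads merged and mixed."""
    h, dk = config.n_heads, config.head_dim
    scale = 1.0 / np.sqrt(dk)
    adj4, gd4 = adj[:, None], gdist[:, None]  # broadcast over heads
    variant = config.variant

    if variant in ("proposed", "simplified_decoder"):
        qa, ka, va = _branch_qkv(x, params, f"{prefix}/adj", h, dk)
        qd, kd, vd = _branch_qkv(x, params, f"{prefix}/dist", h, dk)
        wa = masked_softmax(qa @ ka.swap_last() * scale, key_mask) * Tensor(adj4)
        wd = masked_softmax(qd @ kd.swap_last() * scale, key_mask) * Tensor(gd4)
        out = wa @ va + wd @ vd
    else:
        q, k, v = _branch_qkv(x, params, f"{prefix}/attn", h, dk)
        soft = masked_softmax(q @ k.swap_last() * scale, key_mask)
        if variant == "adj_only":
            w = soft * Tensor(adj4)
        elif variant == "dist_only":
            w = soft * Tensor(gd4)
        else:  # mat_attn
            w = (soft * config.lambda1 + Tensor(gd4) * config.lambda2
                 + Tensor(adj4) * config.lambda3)
        out = w @ v
    return _merge_heads(out) @ params[f"{prefix}/Wo"] + params[f"{prefix}/bo"]


def _ffn(x: Tensor, params: dict, prefix: str) -> Tensor:
    hidden = (x @ params[f"{prefix}/ff/W1"] + params[f"{prefix}/ff/b1"]).relu()
    return hidden @ params[f"{prefix}/ff/W2"] + params[f"{prefix}/ff/b2"]


def _masked_gdist(batch: Batch) -> np.ndarray:
    """g(D) with padded pairs zeroed (the diagonal keeps g(0) = 1)."""
    pair = batch.atom_mask[:, :, None] * batch.atom_mask[:, None, :]
    return g(batch.distance) * pair


def encoder_forward(batch: Batch, config: ModelConfig, params: dict,
                    rng: np.random.Generator | None = None,
                    training: bool = False) -> Tensor:
    """Embed atom features and run the encoder stack.

    Returns atom attributes [B, N_max, d_model]. Each sublayer ends with
    dropout and is wrapped in a residual connection followed by layer
    normalization (post-norm, as in the original Transformer); the pointwise
    feedforward uses ReLU, the Q/K/V projections carry no activation.
    """
    drop = _Dropout(config.dropout, rng, training)
    key_mask = batch.atom_mask[:, None, None, :]  # [B,1,1,N]
    gdist = _masked_gdist(batch)
    x = Tensor(batch.features) @ params["embed/W"] + params["embed/b"]
    for layer in range(config.n_encoder_layers):
        p = f"enc{layer}"
        a = _attention_sublayer(x, batch.adjacency, gdist, key_mask,
                                params, p, config)
        x = layer_norm(x + drop(a), params[f"{p}/ln1/g"], params[f"{p}/ln1/b"])
        f = _ffn(x, params, p)
        x = layer_norm(x + drop(f), params[f"{p}/ln2/g"], params[f"{p}/ln2/b"])
    return x


def _decoder_stack(atom_attr: Tensor, atom_mask: np.ndarray, params: dict,
                   config: ModelConfig, drop: _Dropout, target: int | None):
    """Cross-attention decoder for all targets (shared weights) or one target.

    Returns (cls [B, T, d_model], attention list per layer of numpy
    [B, n_heads, T, N]).
    """
    h, dk = config.n_heads, config.head_dim
    b = atom_attr.shape[0]
    scale = 1.0 / np.sqrt(dk)
    key_mask = atom_mask[:, None, None, :]
    if target is None:
        cls = params["cls_embed"]                      # [T, d]
    else:
        t0 = target
        cls = Tensor._make(params["cls_embed"].data[t0:t0 + 1],
                           (params["cls_embed"],),
                           _slice_backward(params["cls_embed"].data.shape, t0))
    n_t = cls.shape[0]
    q_in = cls.reshape(1, n_t, config.d_model) * Tensor(np.ones((b, 1, 1)))
    attn_layers = []
    for layer in range(config.n_decoder_layers):
        p = (f"dec{layer}" if target is None or config.share_decoder_weights
             else f"dec{layer}/t{target}")
        if target is not None and config.share_decoder_weights:
            p = f"dec{layer}"
        q = _split_heads(q_in @ params[f"{p}/x/Wq"], h, dk)
        k = _split_heads(atom_attr @ params[f"{p}/x/Wk"], h, dk)
        v = _split_heads(atom_attr @ params[f"{p}/x/Wv"], h, dk)
        weights = masked_softmax(q @ k.swap_last() * scale, key_mask)
        attn_layers.append(weights.data.copy())       # [B, h, T, N]
        a = _merge_heads(weights @ v) @ params[f"{p}/Wo"] + params[f"{p}/bo"]
        q_in = layer_norm(q_in + drop(a),
                          params[f"{p}/ln1/g"], params[f"{p}/ln1/b"])
        f = _ffn(q_in, params, p)
        q_in = layer_norm(q_in + drop(f),
                          params[f"{p}/ln2/g"], params[f"{p}/ln2/b"])
    return q_in, attn_layers


def _slice_backward(full_shape, index):
    def backward(gr):
        out = np.zeros(full_shape)
        out[index:index + 1] = gr
        return (out,)
    return backward


def decoder_module(atom_attributes, atom_mask, target_index: int,
                   params: dict, config: ModelConfig):
    """Run the decoder-like module for one target on one molecule or batch.

    Returns (attribute_cls [d_model] or [B, d_model], attention as numpy
    [n_decoder_layers, n_heads, n_atoms] (or with a leading batch axis)).
    """
    if not 0 <= target_index < config.n_targets:
        raise IndexError(f"target index {target_index} out of range")
    data = atom_attributes.data if isinstance(atom_attributes, Tensor) \
        else np.asarray(atom_attributes, dtype=float)
    single = data.ndim == 2
    if single:
        data = data[None]
        atom_mask = np.asarray(atom_mask, dtype=float)[None]
    x = atom_attributes if isinstance(atom_attributes, Tensor) else Tensor(data)
    if isinstance(atom_attributes, Tensor) and single:
        x = x.reshape(1, *data.shape[1:])
    drop = _Dropout(0.0, None, False)
    cls, attn = _decoder_stack(x, np.asarray(atom_mask, dtype=float),
                               params, config, drop, target_index)
    stack = np.stack([a[:, :, 0, :] for a in attn], axis=1)  # [B, L, h, N]
    cls_out = cls.reshape(data.shape[0], config.d_model)
    if single:
        return cls_out.reshape(config.d_model), stack[0]
    return cls_out, stack


def predict(batch: Batch, config: ModelConfig, params: dict,
            rng: np.random.Generator | None = None, training: bool = False):
    """Full forward pass.

    Returns (probabilities Tensor [B, n_targets], attention numpy array
    [B, n_targets, n_decoder_layers, n_heads, N_max] or None for the
    simplified-decoder variant, cls_features Tensor [B, n_targets, d_model]
    or None). Probabilities are sigmoid outputs, strictly in (0, 1).
    """
    drop = _Dropout(config.dropout, rng, training)
    atom_attr = encoder_forward(batch, config, params, rng, training)
    w_out, b_out = params["out/W"], params["out/b"]

    if config.variant == "simplified_decoder":
        pooled = (atom_attr * Tensor(batch.atom_mask[:, :, None])).sum(axis=1)
        # per-target affine heads on the pooled molecule vector
        logits = pooled @ w_out.swap_last() + b_out
        return logits.sigmoid(), None, None

    if config.share_decoder_weights:
        cls, attn_layers = _decoder_stack(atom_attr, batch.atom_mask, params,
                                          config, drop, None)
    else:
        per_t = [_decoder_stack(atom_attr, batch.atom_mask, params, config,
                                drop, t) for t in range(config.n_targets)]
        cls = concat([c for c, _ in per_t], axis=1)
        attn_layers = [np.concatenate([a[li] for _, a in per_t], axis=2)
                       for li in range(config.n_decoder_layers)]
    # [B, T, L, h, N]
    attention = np.stack(attn_layers, axis=1).transpose(0, 3, 1, 2, 4)
    logits = (cls * w_out.reshape(1, config.n_targets, config.d_model)
              ).sum(axis=-1) + b_out
    return logits.sigmoid(), attention, cls


def encoder_attention(X, A, D, layer_params: dict, n_heads: int,
                      variant: str = "proposed", lambdas=(0.33, 0.33, 0.33)):
    """Single-molecule encoder attention sublayer on plain arrays.

    ``layer_params`` maps, per branch ('adj'/'dist' for the proposed variant,
    'attn' otherwise), the keys Wq/Wk/Wv to [d_model, d_model] arrays, plus
    'Wo' and 'bo' for the head-mixing projection. Returns [n, d_model].
    """
    X = np.asarray(X, dtype=float)
    n, d_model = X.shape
    head_dim = d_model // n_heads
    cfg = ModelConfig(n_heads=n_heads, head_dim=head_dim, variant=variant,
                      lambda1=lambdas[0], lambda2=lambdas[1],
                      lambda3=lambdas[2], dropout=0.0)
    params = {}
    for key, val in layer_params.items():
        params[f"enc0/{key}"] = (val if isinstance(val, Tensor)
                                 else Tensor(np.asarray(val, dtype=float)))
    if "enc0/bo" not in params:
        params["enc0/bo"] = Tensor(np.zeros(d_model))
    key_mask = np.ones((1, 1, 1, n))
    gdist = g(np.asarray(D, dtype=float))[None]
    out = _attention_sublayer(Tensor(X[None]), np.asarray(A, float)[None],
                              gdist, key_mask, params, "enc0", cfg)
    return out.data[0]


def encoder_attention_maps(X, A, D, layer_params: dict, n_heads: int,
                           variant: str = "proposed",
                           lambdas=(0.33, 0.33, 0.33)):
    """Final (post-mask) encoder attention weight matrices, per head.

    Returns a dict of [n_heads, n, n] weight arrays: keys 'adj' and 'dist'
    for the proposed variant, 'attn' otherwise. Entry [h, i, j] is the
    weight with which atom j's value row contributes to atom i in head h —
    exactly 0 for non-bonded pairs in the adjacency branch.
    """
    X = np.asarray(X, dtype=float)
    n, d_model = X.shape
    dk = d_model // n_heads
    gd = g(np.asarray(D, dtype=float))
    adj = np.asarray(A, dtype=float)

    def head_weights(prefix):
        q = (X @ np.asarray(layer_params[f"{prefix}/Wq"])).reshape(n, n_heads, dk)
        k = (X @ np.asarray(layer_params[f"{prefix}/Wk"])).reshape(n, n_heads, dk)
        logits = np.einsum("ihd,jhd->hij", q, k) / np.sqrt(dk)
        e = np.exp(logits - logits.max(axis=-1, keepdims=True))
        return e / e.sum(axis=-1, keepdims=True)

    if variant == "proposed":
        return {"adj": head_weights("adj") * adj[None],
                "dist": head_weights("dist") * gd[None]}
    soft = head_weights("attn")
    if variant == "adj_only":
        return {"attn": soft * adj[None]}
    if variant == "dist_only":
        return {"attn": soft * gd[None]}
    l1, l2, l3 = lambdas
    return {"attn": l1 * soft + l2 * gd[None] + l3 * adj[None]}


# ---------------------------------------------------------------------------
# checkpoints

def _schema_hash() -> str:
    return hashlib.sha256(f"atom-features-v1:{FEATURE_DIM}".encode()).hexdigest()


def save_checkpoint(path: str, params: dict, config: ModelConfig) -> None:
    arrays = {k: p.data for k, p in params.items()}
    arrays["__config__"] = np.frombuffer(
        json.dumps(asdict(config)).encode(), dtype=np.uint8)
    arrays["__schema__"] = np.frombuffer(_schema_hash().encode(),
                                         dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str):
    data = np.load(path)
    schema = bytes(data["__schema__"]).decode()
    if schema != _schema_hash():
        raise ValueError("checkpoint feature schema does not match this build")
    config = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
    params = {k: Tensor(data[k], requires_grad=True) for k in data.files
              if not k.startswith("__")}
    return params, config
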