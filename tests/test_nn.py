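"""Attention-variant oracles and structural properties of the model core."""

import numpy as np
import pytest

import odorformer as of
from odorformer.featurize import build_batch
from odorformer.nn import (ModelConfig, decoder_module, encoder_attention,
                           encoder_forward, g, init_params, predict)

from conftest import random_graph


# ---------------------------------------------------------------------------
# brute-force pairwise oracle: explicit double loop over atoms, per head

def oracle_attention(X, A, D, weights, n_heads, variant, lambdas):
    """Per-atom accumulation of softmax weights and masked value rows."""
    X = np.asarray(X, float)
    n, d_model = X.shape
    dk = d_model // n_heads
    gD = np.exp(-np.asarray(D, float))
    heads_out = np.zeros((n, d_model))

    def proj(W, h):
        return X @ W[:, h * dk:(h + 1) * dk]

    for h in range(n_heads):
        out_h = np.zeros((n, dk))
        branches = (("adj", A), ("dist", gD)) if variant == "proposed" else \
                   (("attn", None),)
        for bname, mask in branches:
            q = proj(weights[f"{bname}/Wq"], h)
            k = proj(weights[f"{bname}/Wk"], h)
            v = proj(weights[f"{bname}/Wv"], h)
            for i in range(n):
                logits = np.array([q[i] @ k[j] / np.sqrt(dk)
                                   for j in range(n)])
                soft = np.exp(logits - logits.max())
                soft = soft / soft.sum()
                for j in range(n):
                    if variant == "proposed":
                        w_ij = soft[j] * mask[i, j]
                    elif variant == "adj_only":
                        w_ij = soft[j] * A[i, j]
                    elif variant == "dist_only":
                        w_ij = soft[j] * gD[i, j]
                    else:  # mat_attn
                        l1, l2, l3 = lambdas
                        w_ij = l1 * soft[j] + l2 * gD[i, j] + l3 * A[i, j]
                    out_h[i] += w_ij * v[j]
        heads_out[:, h * dk:(h + 1) * dk] = out_h
    return heads_out @ weights["Wo"] + weights["bo"]


def random_layer_weights(rng, d_model, variant):
    branches = ("adj", "dist") if variant == "proposed" else ("attn",)
    w = {"Wo": rng.normal(size=(d_model, d_model)), "bo": rng.normal(size=d_model)}
    for b in branches:
        for name in ("Wq", "Wk", "Wv"):
            w[f"{b}/{name}"] = rng.normal(size=(d_model, d_model))
    return w


@pytest.mark.parametrize("variant", ["proposed", "mat_attn", "adj_only",
                                     "dist_only"])
def test_attention_variants_match_bruteforce_oracle(rng, variant):
    """All four attention forms agree with an explicit pairwise double loop."""
    n_heads, dk = 2, 3
    d_model = n_heads * dk
    lambdas = (0.5, 0.3, 0.2)
    for _ in range(50):
        n = int(rng.integers(1, 6))
        gph = random_graph(rng, n, d_f=d_model)
        w = random_layer_weights(rng, d_model, variant)
        expected = oracle_attention(gph.features, gph.adjacency, gph.distance,
                                    w, n_heads, variant, lambdas)
        got = encoder_attention(gph.features, gph.adjacency, gph.distance,
                                w, n_heads, variant, lambdas)
        assert np.max(np.abs(got - expected)) < 1e-6


def test_g_kernel_values():
    assert g(0.0) == pytest.approx(1.0)
    assert g(np.log(2)) == pytest.approx(0.5)
    assert g(1.5) == pytest.approx(np.exp(-1.5))
    assert np.all(np.diff(g(np.linspace(0, 5, 50))) < 0)
    with pytest.raises(ValueError):
        g(-0.1)


def test_single_atom_adj_branch_contributes_nothing(rng):
    """With one atom, zero-diagonal A annihilates the adj branch; the output
    is the dist branch's value row (softmax of a singleton is 1, g(0)=1)."""
    d_model = 6
    X = rng.normal(size=(1, d_model))
    w = random_layer_weights(rng, d_model, "proposed")
    out = encoder_attention(X, np.zeros((1, 1)), np.zeros((1, 1)), w, 2,
                            "proposed")
    v_dist = X @ w["dist/Wv"]
    assert np.allclose(out, v_dist @ w["Wo"] + w["bo"], atol=1e-10)


def test_bondless_molecule_reduces_to_dist_branch(rng):
    d_model = 6
    n = 4
    gph = random_graph(rng, n, d_f=d_model)
    A0 = np.zeros((n, n))
    w = random_layer_weights(rng, d_model, "proposed")
    out = encoder_attention(gph.features, A0, gph.distance, w, 2, "proposed")
    w_dist = dict(w)
    for name in ("Wq", "Wk", "Wv"):
        w_dist[f"attn/{name}"] = w[f"dist/{name}"]
    dist_only = encoder_attention(gph.features, A0, gph.distance, w_dist, 2,
                                  "dist_only")
    assert np.allclose(out, dist_only, atol=1e-10)


def test_mat_attn_reductions(rng):
    """λ1=1 recovers plain softmax attention; λ3=1 with A=I gives V."""
    d_model, n = 6, 4
    gph = random_graph(rng, n, d_f=d_model)
    w = random_layer_weights(rng, d_model, "mat_attn")
    w["Wo"] = np.eye(d_model)
    w["bo"] = np.zeros(d_model)
    # λ1=1, λ2=λ3=0: standard attention
    got = encoder_attention(gph.features, gph.adjacency, gph.distance, w, 2,
                            "mat_attn", (1.0, 0.0, 0.0))
    dk = d_model // 2
    expected = np.zeros((n, d_model))
    for h in range(2):
        q = gph.features @ w["attn/Wq"][:, h * dk:(h + 1) * dk]
        k = gph.features @ w["attn/Wk"][:, h * dk:(h + 1) * dk]
        v = gph.features @ w["attn/Wv"][:, h * dk:(h + 1) * dk]
        logits = q @ k.T / np.sqrt(dk)
        soft = np.exp(logits - logits.max(1, keepdims=True))
        soft /= soft.sum(1, keepdims=True)
        expected[:, h * dk:(h + 1) * dk] = soft @ v
    assert np.allclose(got, expected, atol=1e-10)
    # λ3=1 with A=I: output is V itself
    got = encoder_attention(gph.features, np.eye(n), gph.distance, w, 2,
                            "mat_attn", (0.0, 0.0, 1.0))
    assert np.allclose(got, gph.features @ w["attn/Wv"], atol=1e-10)


def test_adj_only_locality(rng):
    """One adj_only layer blocks all message passing from non-neighbors.

    The post-softmax adjacency mask zeroes the attention weight of every
    non-bonded pair exactly, so an atom's output is unchanged when the value
    rows of its non-neighbors are arbitrarily replaced (the masking happens
    after the softmax, so non-neighbor keys still shape the normalization —
    the blocked quantity is the message itself).
    """
    from odorformer.nn import encoder_attention_maps
    n_heads, dk = 2, 4
    d_model = n_heads * dk
    for _ in range(50):
        n = int(rng.integers(3, 8))
        gph = random_graph(rng, n, d_f=d_model)
        w = random_layer_weights(rng, d_model, "adj_only")
        maps = encoder_attention_maps(gph.features, gph.adjacency,
                                      gph.distance, w, n_heads, "adj_only")
        off = gph.adjacency == 0
        assert np.all(maps["attn"][:, off] == 0.0)
        # replacing non-neighbor value rows leaves each atom's output intact:
        # recompute contributions with garbage values at masked positions
        v = (gph.features @ w["attn/Wv"]).reshape(n, n_heads, dk)
        v_garbage = v + rng.normal(size=v.shape) * 100.0
        for i in range(n):
            mask_row = gph.adjacency[i] > 0
            v_mixed = np.where(mask_row[:, None, None], v, v_garbage)
            out_a = np.einsum("hj,jhd->hd", maps["attn"][:, i], v)
            out_b = np.einsum("hj,jhd->hd", maps["attn"][:, i], v_mixed)
            assert np.array_equal(out_a, out_b)


def test_dist_only_monotone_decay(rng):
    """Moving an atom farther never increases its contribution weight."""
    n, dk = 4, 3
    q = rng.normal(size=dk)
    k = rng.normal(size=(n, dk))
    logits = k @ q / np.sqrt(dk)
    soft = np.exp(logits - logits.max())
    soft /= soft.sum()
    j = 2
    prev = np.inf
    for d in np.linspace(0.5, 6.0, 25):
        w_j = soft[j] * np.exp(-d)
        assert w_j <= prev + 1e-15
        prev = w_j


def test_encoder_permutation_equivariance(rng):
    cfg = ModelConfig(n_heads=2, head_dim=5, n_encoder_layers=2,
                      dropout=0.0, n_targets=1, seed=3)
    params = init_params(cfg)
    gph = random_graph(rng, 6)
    out = encoder_forward(build_batch([gph]), cfg, params).data[0]
    perm = rng.permutation(6)
    gph_p = of.MolGraph("p", gph.features[perm],
                        gph.adjacency[np.ix_(perm, perm)],
                        gph.distance[np.ix_(perm, perm)])
    out_p = encoder_forward(build_batch([gph_p]), cfg, params).data[0]
    assert np.allclose(out_p, out[perm], atol=1e-8)


def test_probability_permutation_invariance(rng):
    cfg = ModelConfig(n_heads=2, head_dim=5, n_encoder_layers=1,
                      n_decoder_layers=2, dropout=0.0, n_targets=3, seed=4)
    params = init_params(cfg)
    gph = random_graph(rng, 5)
    p1, _, _ = predict(build_batch([gph]), cfg, params)
    perm = rng.permutation(5)
    gph_p = of.MolGraph("p", gph.features[perm],
                        gph.adjacency[np.ix_(perm, perm)],
                        gph.distance[np.ix_(perm, perm)])
    p2, _, _ = predict(build_batch([gph_p]), cfg, params)
    assert np.allclose(p1.data, p2.data, atol=1e-8)


def test_forward_determinism(rng):
    cfg = ModelConfig(n_heads=2, head_dim=4, n_encoder_layers=2,
                      n_decoder_layers=1, dropout=0.1, n_targets=2, seed=6)
    params = init_params(cfg)
    batch = build_batch([random_graph(rng, 4)])
    p1, _, _ = predict(batch, cfg, params)          # eval mode: no dropout
    p2, _, _ = predict(batch, cfg, params)
    assert np.array_equal(p1.data, p2.data)


class TestDecoderModule:
    def setup_method(self):
        self.cfg = ModelConfig(n_heads=3, head_dim=4, n_encoder_layers=1,
                               n_decoder_layers=2, dropout=0.0, n_targets=2,
                               seed=8)
        self.params = init_params(self.cfg)

    def test_single_atom_gets_all_attention(self, rng):
        attrs = rng.normal(size=(1, self.cfg.d_model))
        _, attn = decoder_module(attrs, np.ones(1), 0, self.params, self.cfg)
        assert attn.shape == (2, 3, 1)
        assert np.allclose(attn, 1.0)

    def test_attention_rows_sum_to_one(self, rng):
        attrs = rng.normal(size=(5, self.cfg.d_model))
        _, attn = decoder_module(attrs, np.ones(5), 1, self.params, self.cfg)
        assert np.allclose(attn.sum(axis=-1), 1.0, atol=1e-6)

    def test_identical_keys_give_uniform_attention(self, rng):
        row = rng.normal(size=self.cfg.d_model)
        attrs = np.tile(row, (3, 1))
        _, attn = decoder_module(attrs, np.ones(3), 0, self.params, self.cfg)
        assert np.allclose(attn, 1.0 / 3.0, atol=1e-10)

    def test_target_index_out_of_range(self, rng):
        attrs = rng.normal(size=(3, self.cfg.d_model))
        with pytest.raises(IndexError):
            decoder_module(attrs, np.ones(3), 5, self.params, self.cfg)


def test_simplified_decoder_has_no_attention(rng):
    cfg = ModelConfig(n_heads=2, head_dim=4, n_encoder_layers=1,
                      variant="simplified_decoder", dropout=0.0, n_targets=2,
                      seed=9)
    params = init_params(cfg)
    probs, attn, cls = predict(build_batch([random_graph(rng, 4)]), cfg, params)
    assert attn is None and cls is None
    assert probs.data.shape == (1, 2)
    assert np.all((probs.data > 0) & (probs.data < 1))


def test_duplicate_molecules_get_identical_rows(rng):
    cfg = ModelConfig(n_heads=2, head_dim=4, n_encoder_layers=1,
                      n_decoder_layers=1, dropout=0.0, n_targets=2, seed=10)
    params = init_params(cfg)
    gph = random_graph(rng, 4)
    probs, _, _ = predict(build_batch([gph, gph]), cfg, params)
    assert np.allclose(probs.data[0], probs.data[1], atol=1e-12)


def test_separate_decoder_weights_match_shared_shape(rng):
    cfg = ModelConfig(n_heads=2, head_dim=4, n_encoder_layers=1,
                      n_decoder_layers=1, dropout=0.0, n_targets=3,
                      share_decoder_weights=False, seed=11)
    params = init_params(cfg)
    probs, attn, cls = predict(build_batch([random_graph(rng, 4)]), cfg, params)
    assert probs.data.shape == (1, 3)
    assert attn.shape == (1, 3, 1, 2, 4)
    assert np.allclose(attn.sum(axis=-1), 1.0, atol=1e-6)


def test_checkpoint_roundtrip(tmp_path, rng):
    cfg = ModelConfig(n_heads=2, head_dim=4, n_encoder_layers=1,
                      n_decoder_layers=1, n_targets=2, seed=12)
    params = of.init_params(cfg)
    path = str(tmp_path / "ckpt.npz")
    from odorformer.nn import save_checkpoint, load_checkpoint
    save_checkpoint(path, params, cfg)
    params2, cfg2 = load_checkpoint(path)
    assert cfg2 == cfg
    batch = build_batch([random_graph(rng, 3)])
    p1, _, _ = predict(batch, cfg, params)
    p2, _, _ = predict(batch, cfg2, params2)
    assert np.array_equal(p1.data, p2.data)
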