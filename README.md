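# odorformer

An interpretable molecular Transformer for predicting binary molecular
properties — substructure presence and odor descriptors (ODs) — from SMILES,
with per-atom attribution of every prediction through decoder attention.

## Who this is for

Structure–odor relationships are notoriously subtle: near-identical molecules
can smell completely different. Data-driven models can predict odor
descriptors, but most feature-free models (graph networks, sequence
transformers) are hard to interpret. This package is for cheminformaticians
who want a *feature-free* predictor whose outputs can be traced back to
atoms: which part of the molecule made the model call a compound "fruity" or
flag an ester.

## The model

Molecules are encoded as atom-feature matrices (71 binary features per heavy
atom: element identity, neighbor counts, aromaticity, ring membership,
hybridization, chirality, charge, valences), a bond adjacency matrix *A*,
and a conformer-derived Euclidean distance matrix *D* (Å). Instead of
positional embeddings, each encoder head computes two masked attention maps:

```
Attention = (softmax(Q_adj K_adjᵀ / √d_k) ⊙ A) V_adj
          + (softmax(Q_dist K_distᵀ / √d_k) ⊙ g(D)) V_dist,   g(d) = exp(−d)
```

so message passing between two atoms happens only when they are covalently
bonded or spatially close. The masking is applied **after** the softmax,
without renormalization. Three published ablations are built in:
`mat_attn` ((λ₁·softmax + λ₂·g(D) + λ₃·A)·V), `adj_only`, and `dist_only`,
plus a `simplified_decoder` variant (sum pooling instead of the decoder).

Each prediction target owns a learnable query vector (*embedded cls*, an
affine image of the constant 1) that cross-attends onto the encoder's atom
attributes in a decoder-like module (a Transformer decoder without
self-attention). Its attention rows sum to 1 over atoms and are the model's
per-atom attribution. A single affine + sigmoid head yields the probability.

Training combines class-weighted binary cross-entropy (positive weight
(N−P)/P per target) with a supervised contrastive loss

```
L = Σᵢ (−1/|P(i)|) Σ_{p∈P(i)} log [ exp(zᵢ·z_p/τ) / Σ_{a∈A(i)} exp(zᵢ·z_a/τ) ]
```

applied per target to the unit-normalized cls features (τ = 0.7 by default).

Attention is quantified per molecule by the share of total decoder attention
mass (summed over heads and decoder layers) that falls on a target
substructure's atoms, and atoms are annotated by an ensemble vote: train M
models, count per atom how often it ranks in the molecule's top-k attention
values, and keep atoms whose counter exceeds a threshold n (defaults
k = 5, n = 50, M = 100; true-positive/true-negative samples are chosen by
90/100 and 85/100 model quorums).

Because the network is small, the package ships its own reverse-mode
autodiff engine on NumPy (`odorformer._autograd`) — no GPU framework needed;
gradients are pinned against finite differences in the test suite.

## Worked example

```python
import odorformer as of

# 1. generate a synthetic screening library with known substructure labels
gen = of.GeneratorConfig(n_molecules=2000, atom_budget=(4, 20),
                         target_prevalence={"C(=O)O": 0.3, "OO": 0.3},
                         seed=1)
smiles = of.generate_molecules(gen)

# 2. define targets and fit
targets = [of.TargetSpec("ester", patterns=["C(=O)O"]),
           of.TargetSpec("peroxide", patterns=["OO"])]
cfg = of.RunConfig(model=of.ModelConfig(n_heads=4, head_dim=15,
                                        n_encoder_layers=2,
                                        n_decoder_layers=1, seed=1),
                   max_epochs=30, seed=1)
model = of.MolecularTransformer.from_smiles(smiles, targets, config=cfg)
results = model.fit()
print(results.summary())
```

prints (exact output for this configuration and seed):

```
Molecular attention transformer results
=======================================================
variant: proposed   d_model: 60 (4 heads x 15)
encoder layers: 2   decoder layers: 1   targets: 2
train/test: 1667/333 molecules (0 removed by filtering)
epochs run: 26   final loss: 92.4987   best val macro F1: 0.9953
-------------------------------------------------------
target                            F1    prec  recall
ester                          0.985   0.971   1.000
peroxide                       0.995   1.000   0.991
macro F1: 0.990   micro F1: 0.990
```

i.e. the model detects both substructures near-perfectly on held-out
molecules; `results.attention(graphs)` then yields the per-atom decoder
attention used for annotation, and
`of.render_attention(mol, values, "out.svg")` draws it.

A command-line interface wraps the same pipeline:
`odorformer synth|train|eval|compare|attend|render --help`.

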