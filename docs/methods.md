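# Methods

## Model

The encoder is a stack of Transformer layers in which positional information
is replaced by molecular structure. Atoms are the tokens; the input to the
first layer is a linear embedding of 71 binary atom features (element
identity with a catch-all bin, heavy- and hydrogen-neighbor counts,
aromaticity, ring membership, hybridization, chirality, formal charge,
explicit and implicit valence; binary properties are single bits rather than
2-bin one-hots, which only changes the feature dimension). Each attention
head carries two independent Q/K/V projections and computes

    (softmax(Q_adj K_adjᵀ/√d_k) ⊙ A) V_adj + (softmax(Q_dist K_distᵀ/√d_k) ⊙ g(D)) V_dist

where A is the bond adjacency matrix (zero diagonal), D the pairwise
Euclidean distance matrix of one embedded conformer, and g(d) = exp(−d).
Three ablation variants replace this sublayer: a single-branch form masked
by A only or by g(D) only, and the additive mixture
(λ₁·softmax(QKᵀ/√d_k) + λ₂·g(D) + λ₃·A)·V with scalar hyperparameters λᵢ.

Two behaviorally significant readings of the equations are fixed here:

* **Post-softmax masking, no renormalization.** The softmax runs over all
  real atoms (padding excluded by an additive −∞ mask); the elementwise
  product with A or g(D) happens after it. Masked rows therefore generally
  sum to less than 1 in the encoder. A consequence worth stating plainly:
  an atom's encoder output is *not* strictly invariant to its non-neighbors
  (their keys shape the softmax denominator), but non-neighbors contribute
  exactly zero value mass — the blocked quantity is the message itself. The
  tests assert precisely that form of locality.
* **No self-loops in A.** In the adjacency branch an atom cannot attend to
  itself; self-information flows through the residual connections and
  through the distance branch, where g(0) = 1 keeps the diagonal.

Sublayers follow the original Transformer: each attention or pointwise
feedforward sublayer (two layers, hidden width = d_model, ReLU; Q/K/V
projections carry no activation) ends with dropout (rate 0.1) and is wrapped
in a residual connection followed by layer normalization. Post-norm was
chosen since the reference architecture for "similar to the original
Transformer" is the original post-norm design.

The decoder-like module is a Transformer decoder without self-attention.
Each target owns a learnable query (an affine image of the constant scalar
1, i.e. one learnable d_model vector per target) that cross-attends onto the
encoder's atom attributes; attention rows are softmax-normalized over real
atoms only and sum to 1. Decoder layer weights are shared across targets by
default — with ~100 targets, fully separate modules are rarely affordable
and nothing requires them — with a config switch (`share_decoder_weights =
False`) for fully separate per-target modules. A single affine + sigmoid
head maps each target's cls vector to a probability. The
`simplified_decoder` variant replaces the module with masked sum pooling
over atoms and per-target output heads; it produces no attention record.

## Losses

Classification uses binary cross-entropy with per-target positive-sample
weight (N − P)/P (negatives weigh 1), averaged over samples and targets;
probabilities are clamped at 1e−7 for log stability. The supervised
contrastive term is applied per target on the L2-normalized per-target cls
vectors within a batch, with P(i) the other samples sharing that target's
binary label and A(i) the batch minus sample i; samples without a same-label
partner contribute 0 (unavoidable in small batches), and batches smaller
than 2 return 0. The total objective is BCE + w · mean over targets of the
contrastive term, with w = 1 and τ = 0.7 by default; both the weighting and
the multilabel per-target reading are design choices documented as such —
a single-label formulation does not dictate them.

## Attention statistics and annotation

Per molecule and target, decoder attention is summed over all layers and
heads, giving per-atom totals with total mass n_h · n_dc. For a target atom
set T the package reports the raw mass on T, the normalized share
(∈ [0, 1]; equals |T|/N under uniform attention), and a variance of the
target atoms' attention values. The variance formula is implemented exactly
as specified even though its inner mean is rescaled by n_h · n_dc while the
attention values are not — the two scales mix, so it is not the ordinary
variance and is generally nonzero even for uniform attention over T; a
corrected variant (ordinary variance of attn/(n_h·n_dc)) is available
behind `corrected_variance=True`, default off, because the printed form is
the specified one.

Ensemble annotation trains M models with identical hyperparameters and
different initializations, counts per atom how often it ranks in its
molecule's top-k summed-attention values (ties broken toward the lowest atom
index, for reproducibility; molecules with ≤ k atoms count every atom), and
selects atoms whose counter is strictly greater than n. Defaults k = 5,
n = 50 at M = 100; the TP/TN sample quorums (90 and 85 of 100) scale as
ceil(quorum/100 · M) for other M so the procedure stays usable at desk
scale. Per-model "predicted positive" uses threshold 0.5 (a decision; no
other value is dictated).

## Training

Adam at learning rate 7e−5, batch size 32, up to 100 epochs with early
stopping (patience 10) on the macro F1 of a held-out 10% validation fraction
of the training split; the best-validation checkpoint is returned. The
train/test split is uniform and seeded at ratio 5:1 (train size
⌈5N/6⌉). Class weights are computed on the fitting portion. Optimizer,
batch size, epoch budget and stopping rule are conventional defaults, all
configurable. Evaluation reports per-target F1 = 2TP/(2TP+FP+FN) (0 when
the denominator is 0), unweighted macro F1, and micro F1 from pooled
counts. Two models are compared with a paired approximate randomization
test: per test sample the two prediction rows are swapped with probability
1/2, the absolute macro-F1 difference is recomputed, and the add-one
estimator p = (1 + #{stat ≥ observed})/(1 + n_iter) keeps p in (0, 1].

## Numerical engine

The network runs on a small reverse-mode autodiff engine written on NumPy
(`odorformer._autograd`): broadcasting arithmetic, batched matmul, a masked
softmax (probability exactly 0 at masked keys, stable against all-masked
rows), layer-norm building blocks, and Adam. Float64 throughout. Gradients
of every operation and of the full model loss are pinned against central
finite differences in the test suite. Weight initialization is seeded
Glorot-uniform; dropout draws from the training RNG, so fixed seeds give
bit-identical training logs.

## Geometry

One conformer per molecule, embedded with ETKDG after adding explicit
hydrogens (the toolkit's documented default practice); distances are taken
over heavy atoms only, in Å, with a config-level embedding seed and no
geometry optimization beyond the embedding defaults. Molecules whose
embedding fails are removed as data (not errors), as are molecules with
more than 60 heavy atoms — the atom cap counts modeled (heavy) atoms, since
hydrogens are implicit and enter only through the hydrogen-neighbor feature.

## Synthetic data

The generator assembles molecules by fragment grafting: chemically valid
fragments (alkyl chains, benzene, ester, peroxide, thiol, amine, ether,
isopropyl/tert-butyl, alkene, carbonyl, hydroxyl, an 11-membered ring) are
joined by single bonds at atoms with free valence, so every emitted SMILES
parses and passes valence checks by construction. Per-target prevalence is
held by quota steering: each target SMARTS that is itself valid SMILES is
force-included as a fragment with probability tracking its remaining quota,
and candidates that would overshoot any target's positive or negative quota
are rejected (bounded at 50× oversampling, then a configuration error).
Realized prevalence is exact at round(p·n)/n. Label rules produce
multilabel annotations as SMARTS conjunctions with independent flip noise
ε ∈ [0, 0.5).

What the generator emulates — and does not. It mimics a screening library's
size range, element palette and functional-group diversity, and an
annotation table's sparse noisy labels. It does not reproduce real
databases' property distributions, scaffold statistics, stereochemistry
richness, or the label correlations of human odor annotation. Passing the
scaled-down study therefore shows that the architecture, losses, training
loop and attention analysis work end-to-end and that attention localizes on
label-generating substructures — it does not certify F1 levels on real
odorant data.

## Scaled-down study sizes

The shipped end-to-end study uses 12,000 generated molecules of 4–20 heavy
atoms with four single-SMARTS targets at 0.30 prevalence, a 2-encoder-layer
/ 4-head × 15 / 1-decoder-layer model, and a 5:1 split — sizes chosen so a
full run (generation, conformers, training, evaluation) completes in
minutes on one CPU core while leaving the learning problem non-trivial.
With one decoder layer the mean attention share on target atoms over
true-positive test molecules exceeds the |T|/N size baseline by ≥ 1.5× on
all four targets (the test asserts at least 3 of 4).

## Known limitations

* The NumPy engine is single-core and unsuitable for 100k-molecule runs at
  the reference architecture (12 heads × 15, 6 encoder layers); the
  architecture scales, the wall-clock does not.
* Distance matrices come from a single unoptimized conformer; conformer
  flexibility is ignored.
* The 24-substructure default panel is a plausible editable stand-in, not a
  reconstruction of any particular published panel (only a few of those
  substructures are publicly enumerated).
* The contrastive/BCE combination weight is a package default, not an
  established value.
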