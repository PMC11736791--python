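# Methods

## Overview

`structcpi` predicts compound–protein interactions (CPI) — continuous
activities such as log2 turnover numbers, or binary labels such as
conversion-above-threshold — from a protein 3-D structure and a ligand
SMILES string. The model couples two graph encoders through an explicit
atom × residue interaction module, which doubles as the interpretability
signal: the learned attention intensities are post-processed into
residue-importance profiles for enzyme-engineering analysis.

## Model

### Protein contact-map encoder

A protein chain becomes a graph with one node per residue and an edge
wherever the Cα–Cα distance is strictly below a cutoff (default 8 Å).
Node features are a 21-slot one-hot (20 canonical residues + unknown)
concatenated with five physicochemical properties — molecular weight,
pKa (α-COOH), pKb (α-NH3+), pKx (ionizable side chain, 0 when absent),
and pI — taken from the standard free-amino-acid table (Lehninger,
*Principles of Biochemistry*; also in the CRC Handbook) and z-scored over
the 20 canonical residues so they are commensurate with the one-hot block.

The encoder projects the 26-dim features to the model width, adds a
sinusoidal positional encoding in residue sequence order
(PE(pos, 2i) = sin(pos / 10000^(2i/d)), cosine in the odd columns) to
restore sequence information that graph convolution alone discards, and
applies three graph-convolution layers

    Q^(l+1) = relu(Â Q^(l) W^(l)),   Â = row-normalized (A + I).

The bare adjacency of the propagation rule is augmented with self-loops
(so a node keeps its own signal) and row-normalized (so propagation is
bounded regardless of degree). Two fully connected layers over the mean
node embedding produce an optional global representation; the interaction
modules consume the residue-level embeddings, so the full CPI model omits
the global head from its parameter manifest rather than carry parameters
that receive no gradient.

### Ligand GCN-GRU encoder

Ligands parsed from SMILES become heavy-atom graphs (hydrogens implicit)
with the canonical 74-dim atom descriptor: atom type (43), degree (11),
implicit hydrogens (7), formal charge, radical electrons, hybridization
(5), total hydrogens (5), aromaticity. Each of three layers computes
messages m_j = Σ_{i∈N(j)} (W v_i + b), passes them through a linear +
rectifier transform, and updates each atom's hidden state with a gated
recurrent unit cell — the recurrence lets successive layers refine rather
than overwrite atom states.

### Interaction modules

**Bilinear co-attention (BCN).** Per head, atom i and residue j couple
through

    I[i, j] = q · (relu(W_Vᵀ v_i) ⊙ relu(W_Qᵀ q_j)),

a bilinear form in a shared latent space (default 768). The joint
representation gates the k-th latent coordinate through the intensity
map, f′_k = h_V,·kᵀ I h_Q,·k, heads are averaged, and non-overlapping sum
pooling with stride s (default 3) compacts f′ to length latent/s (256 at
defaults). Intensities are returned raw — no softmax inside the forward
pass; normalization is purely an interpretability post-process.

**Transformer.** One block: protein self-attention (scaled by √d_k),
post-attention layer norm, cross-attention with protein queries over
ligand keys/values, layer norm, a 128→512→128 feed-forward network with
a rectifier, global average pooling over residues, and a linear output
head. The cross-attention softmax weights are the attention map; each
residue's distribution over atoms sums to one per head.

Both modules feed a fully connected decoder (default hidden width 512)
producing one output: the prediction for regression, a logit for
classification (trained with binary cross-entropy).

### Numerical core

No deep-learning framework is used: the package carries a small
reverse-mode automatic-differentiation engine over NumPy float64 arrays
(`structcpi.autograd`), with gradients validated against central finite
differences in the test suite. Weights use Glorot-uniform initialization;
optimization is Adam. Everything is deterministic given the master seed —
there is no dropout, and evaluation-mode forward passes are pure
functions of the parameters.

## Training protocol

Defaults mirror the reference configuration: batch 64, learning rate
5e-5, at most 100 epochs, early stopping with patience 5 on the monitored
validation quantity (loss, R², or AUC), encoder widths [128, 128, 128],
2 attention heads. Cross-validation is Monte-Carlo: five independent
seeded 70/15/15 train/validation/test splits, the per-split model chosen
by best validation R², metrics averaged with their spread. Small
classification sets use bootstrapped evaluation instead: each of 100
iterations resamples the training pool with replacement (a same-size
resample covers 1 − (1 − 1/n)ⁿ ≈ 63.2% of the pool in expectation),
validates on the out-of-bag remainder, keeps the best epoch by validation
AUC, and metrics are averaged across iterations; single-class out-of-bag
pools are skipped and counted. One master seed fans out to named
sub-seeds (splits, initialization, batch order, resampling, augmentation).

## Transfer learning

Three strategies adapt a source checkpoint to a small target set:

- **free** — all parameters trainable;
- **block** — only the decoder head and the final interaction layer
  (the BCN attention vectors q, or the transformer output layer) train;
  everything else is frozen and verified bit-identical after tuning;
- **lora** — base weights frozen; zero-initialized low-rank pairs
  (B: out×r, A: r×in, delta (α/r)·B·A, defaults r = 4, α = 1) attach
  after the attention mechanism: on the transformer's output layer, and
  as one adapter on each of the BCN's ligand-input and protein-input
  paths (exactly two pairs, shared across heads). Zero-initialized B
  makes the adapted model reproduce the base exactly before training.
  The decoder head also trains by default, since it is the target task's
  head; `train_head=False` restricts training to the adapters.

## Label construction and negative augmentation

For conversion-assay datasets (the motivating enzyme is *Candida
antarctica* lipase B, catalytic triad Ser105–Asp187–His224), binary
labels come from either a threshold rule (positive iff conversion ≥
15/30/40%) or a relative rule (positive iff the variant converts within
a tolerance δ of, or better than, the wild type on the same substrate;
δ defaults to 0 and quantifies "comparable within experimental error").

Negative augmentation plants k (default 8) distinct random single-point
mutations at every residue whose minimum Cα distance to the triad Cαs
exceeds 20 Å — distal mutations are unlikely to perturb the active site,
so these records are labelled 0. Substrates are assigned round-robin
from the observed pool in a seeded order. On a structure with 151
eligible distal residues and k = 8 this yields exactly 1208 negatives.
The distance convention (Cα–Cα minimum to the triad) is a package choice;
an any-atom convention would change the eligible count on real
structures. Augmented variants reuse the wild-type contact graph with
mutated node features; no structures are modeled for them.

## Interpretability

Attention maps are post-processed as: elementwise mean over heads →
min-max normalization to [0, 1] (a constant map becomes all zeros) →
top-p% mask keeping the floor(p·count/100) largest entries at their
original values (ties broken row-major) → marginal residue/atom scores
as column/row means → top-n% residue sets (ceil(n·M/100), ties broken by
residue index). Variant-minus-wild-type difference maps are signed
per-residue differences of these scores computed on identical inputs
except the mutated node features.

## Synthetic data generator

Fixtures are fully self-contained. Proteins are ideal helices (radius
2.3 Å, rise 1.5 Å, 100°/residue), giving the canonical ~3.83 Å
consecutive Cα spacing and hence closed-form contact-map expectations
(contacts out to i±4 at the 8 Å cutoff, none at i±7). Ligands come from
a bundled pool of 30 valid drug-like SMILES spanning 0–13 aromatic
atoms. The planted interaction signal is

    label = β · (aromatic atom count) · 1[motif ⊂ protein sequence] + N(0, σ²),

with an aromatic-rich motif ("HWH") written into half the proteins —
an interpretable aromatic-contact surrogate. Defaults for the recovery
study are n = 300 samples, β = 2, σ = 0.5. Classification labels
threshold the continuous label at its median.

What the generator does *not* emulate: realistic turnover-number
distributions, structural diversity beyond a single helical fold,
mutant-specific conformational change, binding-pocket geometry, or
experimental assay noise structure. Passing the recovery tests shows the
architecture, optimization and pipeline can extract a planted
protein-conditioned ligand signal at favourable signal-to-noise; it does
not certify predictive performance on curated kinetic databases.

## Problem sizes and tolerances

Tests and the acceptance script run desk-scale configurations chosen by
the package: recovery/null studies use encoder width 32, BCN latent 96
(stride 3), decoder 64, learning rate 2e-3, ≤ 25 epochs with patience 5 —
the dataset conditions (300 samples, β = 2, σ = 0.5, 70/15/15 split)
are kept as stated above. Oracle equivalences are checked at 1e-6
relative (BCN) and 1e-5 absolute (attention); metric implementations at
1e-10 against direct formulas; gradient checks at 1e-5 against central
differences. Degenerate conventions: constant maps normalize to zero;
single-class validation pools make AUC undefined (reported missing, or
the bootstrap iteration is skipped); R² is undefined for zero-variance
truth and rejected with a message.

## Known limitations

- Runtime: the NumPy autodiff engine processes one graph pair at a time;
  it is designed for correctness and desk-scale experiments, not for
  training on databases with tens of thousands of pairs.
- Single-chain PDB input; no mmCIF; residues lacking a Cα are skipped
  (logged and recorded), not imputed.
- One transformer block; no virtual-atom augmentation; no pretrained
  protein language-model embeddings.
- The BCN latent contraction (how the intensity map gates each joint
  coordinate) follows the bilinear-pooling reading f′_k = h_V,·kᵀ I h_Q,·k;
  other contractions are conceivable under the same prose description.
- Whether transformer LoRa should also adapt the attention projections is
  left configurable in principle; the default adapts the output layer only.
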