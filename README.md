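# structcpi

Structure-based compound–protein interaction (CPI) learning for enzyme
engineering: predict continuous activities (e.g. log2 turnover numbers)
or binary functional labels (e.g. conversion above a threshold) from a
protein 3-D structure and a ligand SMILES string, then read the model's
attention back out as residue-level interpretability.

The package is aimed at computational enzymologists who have a large
general interaction dataset and a small function-specific one: pretrain
on the former, transfer to the latter with free, block, or low-rank
(LoRa) fine-tuning, and inspect atom × residue attention maps to locate
the residues driving a prediction.

## Model

- **Protein encoder** — the chain becomes a contact-map graph (edge iff
  Cα–Cα distance < 8 Å). Node features: 21-way residue one-hot + five
  z-scored physicochemical properties (MW, pKa, pKb, pKx, pI). A
  sinusoidal positional encoding PE(pos, 2i) = sin(pos/10000^(2i/d)) is
  added after input projection, then three graph-convolution layers
  Q^(l+1) = relu(Â Q^(l) W^(l)) with Â the row-normalized A + I.
- **Ligand encoder** — heavy-atom molecular graph with the canonical
  74-dim atom features; three message-passing layers, each summing
  transformed neighbour features m_j = Σ_{i∈N(j)}(W v_i + b) and
  updating atom states through a GRU cell.
- **Interaction** — either a bilinear co-attention network (BCN),
  I[i,j] = q·(σ(W_Vᵀ v_i) ⊙ σ(W_Qᵀ q_j)) with bilinear pooling and
  stride-3 sum pooling (latent 768 → joint 256), or a transformer block
  (protein self-attention → cross-attention with ligand keys/values →
  FFN 128→512→128 → mean pool). Both expose atom × residue attention.
- **Decoder** — fully connected head (hidden width 512); MSE loss for
  regression, binary cross-entropy for classification.
- **Transfer** — `free` (all parameters), `block` (decoder + final
  interaction layer only), `lora` (frozen base + zero-initialized
  low-rank pairs B·A with effective delta (α/r)·B·A).

Everything runs on a self-contained NumPy reverse-mode autodiff engine
(no deep-learning framework required); gradients are finite-difference
validated in the test suite. See `docs/methods.md` for the full model
description, conventions, and limitations.

## Worked example

Train the BCN model on a synthetic dataset with a planted signal — the
label couples a ligand's aromatic atom count to the presence of an
aromatic-rich motif in the protein sequence
(label = 2 · aromatic_count · 1[motif present] + N(0, 0.5²)):

```python
import numpy as np
from structcpi import CPIModel, ModelConfig, TrainConfig
from structcpi.fixtures import FixtureSpec, make_cpi_dataset
from structcpi.training import GraphCache, split_indices, train_model, evaluate

spec = FixtureSpec(n_samples=300, effect_size=2.0, noise_sd=0.5, seed=1)
samples, structures, info = make_cpi_dataset(spec)
cache = GraphCache.build(samples, structures)

model = CPIModel.new(ModelConfig(arch="bcn", d_model=32, n_layers=3,
                                 bcn_latent=96, bcn_stride=3,
                                 decoder_hidden=64), seed=2)
rng = np.random.default_rng(1)
tr, va, te = split_indices(len(samples), (0.70, 0.15, 0.15), rng)
config = TrainConfig(batch_size=32, learning_rate=2e-3, max_epochs=25,
                     patience=5, seed=1)
result = train_model(model, [samples[i] for i in tr], cache, config,
                     val_samples=[samples[i] for i in va])
report = evaluate(result.model, [samples[i] for i in te], cache)
print(f"best epoch {result.best_epoch}, test RMSE {report.rmse:.3f}, "
      f"test R^2 {report.r2:.3f}")
```

```
best epoch 11, test RMSE 0.455, test R^2 0.994
```

The model recovers the planted signal almost perfectly: test RMSE 0.455
is close to the irreducible noise floor (σ = 0.5), and R² = 0.994 says
virtually all label variance is explained. Now ask *where* the model
looks, for an aromatic ligand against a motif-carrying protein:

```python
from structcpi.explain import explain

pg = cache.proteins["prot000"]               # carries the motif at 24-26
lg = cache.ligands["c1ccc2ccccc2c1"]         # naphthalene, 10 aromatic atoms
_, attention = result.model.forward(pg, lg)
rep = explain(attention, mask_percent=30)
print("top-5% residues by attention:", sorted(rep.top_residue_sets[5.0]))
```

```
top-5% residues by attention: [25, 26]
```

The top-5% attention residues fall inside the planted motif (sequence
positions 24–26) — the attention map localizes the interaction site that
generated the labels.

The same workflow is available from the shell:

```bash
structcpi simulate --seed 1 --out fixtures/
structcpi train --seed 1 --pdb-dir fixtures/pdb --table fixtures/interactions.tsv --out runs/demo
structcpi explain --seed 1 --checkpoint runs/demo/fold0/best.npz \
    --pdb fixtures/pdb/prot000.pdb --smiles 'c1ccc2ccccc2c1' --out runs/demo
```

plus `featurize`, `finetune` (`--strategy {free,block,lora} --rank R`),
`evaluate`, and `augment` (distal-mutation negative augmentation for
conversion tables: residues beyond 20 Å of the catalytic triad receive
k random single-point mutations labelled negative).

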