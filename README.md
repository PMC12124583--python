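# crossdti

Drug–target interaction (DTI) prediction from raw sequence pairs: a SMILES
string for the small molecule and an amino-acid sequence for the protein,
with a binary label saying whether the two interact. Predicting these labels
in silico is a standard screening step in drug discovery and repurposing;
this package implements a sequence-only deep model for it, together with the
data tooling and a synthetic test bed that make every stage verifiable
offline.

## The model

Four ideas are combined:

1. **Substructure mining.** A byte-pair-encoding-style procedure learns a
   vocabulary of frequent subsequences from the training corpus: starting
   from single characters, the most frequent adjacent token pair is merged
   repeatedly until its frequency falls below a threshold *d* or the
   vocabulary reaches a cap *θ*. Every sequence then decomposes into an
   ordered, non-overlapping list of substructure tokens `M = {A1 … Ak}`
   whose concatenation reconstructs the original sequence `B` exactly.
   Drugs and proteins get separate vocabularies.
2. **Four embedding + CNN streams.** Both the substructure view and the
   untouched original sequence of each molecule are embedded (learned
   content dictionary + learned position dictionary, summed) and refined by
   an independent block of three stacked 1-D convolutions — kernel sizes
   (4, 6, 8) for the drug branches and (4, 8, 12) for the protein branches.
3. **Cross co-attention (CPA).** Per stacked layer, four multi-head
   scaled-dot-product attention units run over the concatenated
   (substructure, original) feature maps: drug self-attention (DA) and
   protein self-attention (PA) fuse the two views of each molecule, then
   protein→drug (PDA) and drug→protein (DPA) cross-attention exchange
   information between the molecules. Each unit ends in a feed-forward
   layer with dropout, a residual connection and layer normalisation. After
   the last layer the attended features are blended half-and-half with the
   pre-attention CNN maps: `Y = 0.5·Y_att + 0.5·Y_cnn`.
4. **Prediction head.** Global max pooling over each molecule's feature
   map, concatenation (drug first), and a fully connected network with
   Leaky-ReLU activations, dropout, and a final sigmoid giving the
   interaction probability. Training minimises binary cross-entropy.

Evaluation reports AUC, AUPR, accuracy, precision and recall, and the
training protocol follows an 80:20 train/test split with 5-fold cross
validation and early stopping on validation AUC. Two ablation variants are
built in: `without_mimm` (substructure streams removed) and `without_cpa`
(attention cascade removed).

The model is implemented on a small numpy reverse-mode autodiff engine
(`crossdti.autograd`) written for exactly the operations the architecture
needs; gradients are verified against finite differences in the test suite.

## Worked example

```python
import numpy as np
from crossdti import fit_vocabulary, encode_sequence, reconstruct

vocab = fit_vocabulary(["ABAB", "ABAB"], min_frequency=2, max_size=10)
print(vocab.tokens)           # ['A', 'B', 'AB', 'ABAB']
print(vocab.merges)           # [('A','B','AB'), ('AB','AB','ABAB')]
enc = encode_sequence("ABABA", vocab)
print(enc.tokens)             # ['ABAB', 'A']
print(reconstruct(enc))       # 'ABABA'
```

The pair `(A, B)` occurs four times (≥ d = 2), so it merges first; the new
token pair `(AB, AB)` then occurs twice and merges next. Encoding replays
those merges in order, and concatenating the emitted tokens always returns
the input string — including characters outside the training alphabet,
which pass through as single unknown-index tokens.

An end-to-end run on synthetic data:

```bash
crossdti simulate --n 2000 --noise 0.0 --seed 1 --out data.csv
crossdti summarize --data data.csv --report summary.json
crossdti train --data data.csv --seed 1 --out run/
```

`simulate` plants a known rule — a pair interacts exactly when a fixed drug
motif and a fixed protein motif are both present — so a correct
implementation can drive held-out AUC to 1.0, and the printed per-fold and
mean metrics in `run/report.json` measure how completely the model recovers
the rule.

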