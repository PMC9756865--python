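# predpair

Learning RNA base pairing from sequence alone — and reading back what
was learned.

`predpair` trains a neural network on the most minimal formulation of
RNA secondary structure: *given a sequence with one marked nucleotide,
where is its base-pairing partner?*  The model gets no pairing rules,
no stacking energies and no structural priors; everything it knows it
learned from sequence–structure examples.  The package is aimed at
people studying representation learning on biological sequences and at
structural bioinformaticians who want certainty-matrix-style pairing
predictions with a full interpretation toolkit.

## The model

A question sample is an (L, 5) matrix: one-hot nucleotides (A, C, G, U)
plus a mark channel holding 2 at the query position and 1 elsewhere.
The network — two parallel Conv1D branches (64 filters, kernel 10),
a 5-channel attention layer over the original input, a bidirectional
LSTM (16 units per direction), dense layers of 16 and 8 units and a
per-position output neuron — emits a softmax distribution over the L
positions: the *certainty* that each position is the partner.  Training
minimises categorical cross-entropy under Adam, two samples per
annotated pair (i→j and j→i).

Stacking the rows of every query gives the L×L certainty matrix **M**
(row-stochastic, asymmetric).  Downstream analyses:

- **Symmetrization** S(i,j) = S(j,i) = min(M(i,j), M(j,i)).
- **Pair calling** by best bidirectional hits: (i,j) is called iff each
  position is the other's argmax.
- **Accuracy/reciprocity diagnostics** (top-k over paired queries;
  reciprocal fraction of correct vs erroneous predictions).
- **Saliency**: vanilla input gradients per query, symmetrized into an
  importance matrix.
- **Learned features**: frequencies of called pair types and stacked
  doublets, correlated with nearest-neighbour stacking energies.
- **Embeddings**: BiLSTM activations averaged into one length-32 vector
  per sequence, with t-SNE clustering.
- **Evaluation**: confusion counts/PR curves/F1 against reference
  structures; decile analysis against per-nucleotide accessibility
  (DMS-seq-like) tables.

A synthetic module generates all input classes — sequences with planted
complementary stretches, structure-constrained random sequences and
accessibility profiles — so everything here runs offline.  File formats:
Stockholm (`#=GC SS_cons`, with consensus projection onto members),
FASTA, CT, dot-bracket (pseudoknot-aware) and plain TSV tables.

## Worked example

```python
from predpair import PredPair, ModelConfig
from predpair.synthetic import gen_stretch_sequences

train = gen_stretch_sequences(n=1000, length=50, stretch_len=7, seed=1)
val   = gen_stretch_sequences(n=100,  length=50, stretch_len=7, seed=2)
test  = gen_stretch_sequences(n=100,  length=50, stretch_len=7, seed=3)

model = PredPair(train, val, ModelConfig(learning_rate=3e-3))
res = model.fit(epochs=15, seed=0, batch_size=64)
print(res.summary())
print("held-out top-1:", round(res.top_k_accuracy(test, k=1), 3))

s = test[3]
M = res.certainty_matrix(s)          # 50x50, rows sum to 1
print("called pairs:", sorted(res.best_pairs(s, min_score=0.5)))
print("true pairs:  ", sorted(s.pairs))
```

Output from this exact script:

```
PredPair Results
==========================================================
conv filters / kernel           64 / 10
attention channels              5
LSTM units per direction        16
dense sizes                     (16, 8)
L2 coefficient (output neuron)  0.1
optimizer                       Adam(lr=0.003)
seed                            0
training sequences              1000
training samples                14000
validation samples              1400
epochs run                      15
best epoch (val loss)           13
final train loss / accuracy     0.0881 / 0.9703
final val loss / accuracy       0.2244 / 0.9321
==========================================================
held-out top-1: 0.925
called pairs: [(7, 27), (8, 26), (9, 25), (10, 24), (11, 23), (12, 22), (13, 21), (17, 39), (43, 49)]
true pairs:   [(7, 27), (8, 26), (9, 25), (10, 24), (11, 23), (12, 22), (13, 21)]
```

92.5 % of queries rank the true partner first after fifteen epochs at
this reduced scale, and the planted 7-pair stem of the example sequence
is called exactly; the two extra calls are confident false positives
between unpaired positions — the characteristic failure mode of a model
trained without thermodynamic priors.  The shipped study (2,000
training sequences, up to 50 epochs) pushes held-out top-1 accuracy
above 0.95 (0.97 after symmetrization).  A command-line
interface covers the same pipeline: `predpair synth|data|train|predict|
eval|interpret --help`.

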