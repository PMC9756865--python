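# Methods

## The prediction problem

RNA secondary structure is held together by base pairs (Watson–Crick
A·U and G·C, plus the G·U wobble).  `predpair` trains a network on the
narrowest possible reading of the folding problem: given a sequence and
*one marked nucleotide*, predict the position of that nucleotide's
pairing partner.  No thermodynamic parameters, no pairing rules and no
structural priors enter the model; whatever it uses, it learned from
sequence–structure examples.  The interest is as much in what the model
learns (pairing rules, stacking preferences, helix structure) as in raw
accuracy.

A question sample is an `(L, 5)` matrix: columns 1–4 one-hot encode the
nucleotide (A, C, G, U; degenerate IUPAC letters encode as all-zero),
and column 5 is the query mark — 2 at the marked position, 1 everywhere
else.  The target is the partner position, treated as a categorical
distribution over the L positions.  Every annotated pair (i, j) yields
two samples (query i → answer j, query j → answer i); unpaired positions
are never queried during training.  Stacking the output rows for all L
queries of one sequence gives the *base-pairing certainty matrix* M:
row-stochastic, generally asymmetric.

## Architecture

Input `(L, 5)` → two parallel 1-D convolutions (64 filters, kernel 10,
'same' padding, ReLU) → channel-wise attention → concatenation of the
5-channel attention context with the input (depth 10) → bidirectional
LSTM, 16 units per direction (depth 32) → per-position dense layers of
16 and 8 units (ReLU) → one dense output neuron per position (L2
penalty 0.1 on kernel and bias) → softmax across positions.  Loss is
categorical cross-entropy; the optimizer is Adam.  The network is fully
length-agnostic: one weight set serves any L.

The attention wiring is the one genuinely open design point.  We give
the layer one score channel per input channel (five): the two
convolution branches are projected, per channel, to a small
query/key vector per position (head dimension 8 by default), the score
for (query position t, key position s) in channel c is the scaled dot
product `q[t,c]·k[s,c]/√d`, softmax-normalised over s, and the weights
are applied to input channel c.  The context therefore has the same
depth as the input, and each "attention neuron" is attached to one
input channel — four nucleotide channels plus the query mark — which is
what makes the per-neuron inspection (`attention_inspection`) readable.

The head dimension matters scientifically: with scalar scores (d = 1,
whether multiplicative or the additive-tanh variant kept as
`ModelConfig(attention_score="additive")`), the score is separable in
(t, s), so every query position ranks the key positions identically
and attention cannot match a query's neighbourhood to its complement;
in our experiments such models plateau around 0.85 held-out top-1 on
the planted-stretch task, with the BiLSTM doing all the partner
finding.  With d = 8 the attention itself can align
reverse-complementary contexts, and the same training budget reaches
the near-perfect regime.

### Numerical and training choices

- Parameters are float32; initialisation is Glorot-uniform (orthogonal
  per-gate blocks for the recurrent kernels, forget-gate bias 1).  All
  initialisation and batch order derive from one integer seed; repeated
  runs are bit-identical.
- "L2 regularization … with the learning rate of 0.1" on the output
  neuron is read as an L2 *coefficient* of 0.1 on that layer's kernel
  and bias (a learning rate is an optimizer property; the 0.1 attaches
  to the regulariser).
- The default Adam step size is 1e-3; the planted-stretch study uses
  3e-3, which converges several times faster at that data scale with no
  loss in final accuracy.  When the monitored validation loss stalls
  for 3 epochs the step size is halved (floor 1e-4).
- Early stopping monitors validation loss (patience 5 by default, best
  weights restored); `fit(target_accuracy=...)` additionally stops once
  validation top-1 reaches a requested level.
- Samples of one sequence always share a batch.  Sequences of equal
  length may be pooled into one batch (cap 128 by default): per-sample
  losses and gradients are unaffected; only the batch-mean scaling seen
  by Adam changes, and it keeps the numpy backend efficient.
- Softmax rows sum to 1 within 1e-5 in float32; certainty-matrix
  consumers treat that as the row-stochasticity tolerance.
- Argmax ties (measure-zero for trained models, common in synthetic
  test matrices) break toward the lowest index everywhere.

The network, backpropagation and Adam are implemented in numpy inside
`predpair.nn`; every layer's analytic gradients are checked against
central finite differences in the test suite (float64, with ReLU
pre-activations shifted off their kinks, where finite differences are
invalid).

## Postprocessing

Row i of M is the distribution over partners for query i, so M(i,j) and
M(j,i) answer different questions and are dependent; their product
would be wrong, and the symmetric score takes the elementwise minimum
S(i,j) = S(j,i) = min(M(i,j), M(j,i)), with no rescaling.  Pair calling
uses best bidirectional hits on the raw M (diagonal excluded): (i, j)
is called iff each is the other's argmax.  BBH on S is available by
flag; on raw M it matches the way predictions are described upstream of
the accessibility comparison.  Top-k accuracy counts every paired
position as a query (both directions).  Reciprocity of a prediction
i→j means argmax of row j is i; it is tallied separately for correct
and erroneous predictions, and an empty error set reports NaN rather
than 0.

## Interpretation

*Saliency* is the vanilla gradient of the cross-entropy loss for the
output class with respect to the input, reduced per position by the
maximum absolute value over the 5 channels (`sum` and `l2` reductions
available; the choice of reduction is not critical and `max_abs` is
standard saliency-map practice).  The loss class is the true partner
where a reference structure is supplied, else the model's own argmax.
Full saliency matrices stack the reduced rows over all queries and are
min-symmetrized like certainty matrices.

*Embeddings* average the BiLSTM activations of a sequence's question
batch along the sequence and then over the batch, giving one vector of
length 32 (2 × 16 units).  t-SNE uses perplexity 30, learning rate 200
and 1,000 iterations; when fewer points than the perplexity supports
are given, the perplexity is reduced with a warning.

*Learned-feature statistics* compare called pairs (BBH by default) with
nearest-neighbour stacking energies.  The packaged table
(`predpair/data/stacking_energies.tsv`) carries ΔG°37 for all 21
distinct stacked doublets of canonical/wobble pairs: Watson–Crick
values from the Xia et al. (1998)/Turner 2004 set, wobble values from
the Turner/Mathews wobble set.  Doublets are canonicalised under strand
symmetry (reading the helix from the other strand names the same
stack).  Two tandem-wobble stacks are genuinely destabilising
(positive ΔG°37); the table keeps the published signs.

## Synthetic data

The generators define the study conditions under which the package is
exercised without downloads; they are first-class, tested code.

**Planted stretches** (`gen_stretch_sequences`): uniform-random
sequences (default length 50) with one Watson–Crick
reverse-complementary stretch (default 7 nt) planted at two
non-overlapping locations (≥3 nt apart), annotated as 7 pairs.  Draws
containing an accidental complementary run longer than `stretch_len−2`
elsewhere — or extending the planted stem — are rejected and redrawn, so
the planted answer is unambiguous and the near-perfect-accuracy regime
is well posed.  These defaults are the conditions of the learnability
study (2,000 train / 200 validation / 400 test, ≤50 epochs), sizes at
which a single CPU trains in minutes.

**Structure-constrained sequences** (`gen_structured_sequences`):
given a template pair set, unpaired positions draw from a nucleotide
frequency table; each stacked helix run draws its first pair from the
pair-type table and each subsequent pair from the doublet table
conditioned on the previous pair (falling back to the pair table where
the conditional mass is empty).  This uses all three frequency tables
in one well-defined generative process, and every emitted sequence is
canonical/wobble-compatible with its template by construction.  Tables
default to uniform; `estimate_frequency_tables` derives them from any
annotated corpus.  `gen_random_templates` supplies nested (optionally
pseudoknotted) random helix layouts — by default 12 templates of
length 140 with 40–55 % of positions paired — standing in for
database-derived structures.

**Accessibility profiles** (`gen_accessibility_profiles`): paired
positions draw accessibility around 0.2, unpaired around 1.0 (Gaussian
noise σ = 0.25, clipped at zero), coverage uniform on [20, 120].  This
emulates the *shape* of chemical-probing data — paired nucleotides less
accessible, with overlap — not its full error structure (no
sequence-context bias, no coverage-dependent variance, no
normalisation artefacts).  Passing decile tests on these profiles shows
the analysis machinery is correct, not that the model would reproduce
any particular experimental effect size.

What the synthetic data do not emulate: family structure and homology
(all sequences are independent), natural base composition, multi-helix
global structures in the training task, and probing-assay biases.
Results on them bound what the pipeline can do, not what real-data
performance would be.

## Evaluation

Structure scoring thresholds S: predicted pairs are those at or above
the threshold; Tp/Fp/Fn against the reference pair set (unordered pairs
counted once) give precision and recall; the PR curve uses 200
thresholds evenly spaced on [0, max(S)] (score scale, not quantiles),
dropping points with no predictions; F1 is per sequence, 0 when Tp = 0.

Accessibility comparison: genes are filtered to plus-strand CDS records
of length divisible by 3 with mean coverage strictly above 15 reads per
nucleotide (a per-position coverage variant is available by flag).
Within each gene, scored positions — A/C only by default, matching what
the probing chemistry sees; `--all-bases` available — are stable-sorted
from least to most accessible (position as tie-break) and cut by rank
into ten equal-count bins; predicted-paired positions are counted per
bin and summed over genes.  Histograms are compared by expanding them
back into decile-index samples and applying a two-sided Mann–Whitney
test; the within-histogram trend is summarised by the Spearman
correlation of counts against decile index.

Externally produced matrices (e.g. partition-function pair
probabilities) enter through `import_external_matrix` (sparse 1-based
`i j p` triples or dense TSV); running external predictors is out of
scope.

## Problem sizes used in the shipped analyses

The learnability study trains on 2,000 sequences (28,000 samples) and
evaluates on 400 held-out sequences; rank tests for reciprocity and
saliency use 250 and 200 held-out sequences; the decile analysis uses
100 sequences; the structure-constrained generator is exercised at full
scale (12 × 100 sequences of length 140).  These sizes give
stable statistics on a single CPU in minutes.  Full-database training
(hundreds of thousands of samples from curated alignments) is supported
through the same `PredPair.from_stockholm` path but is not part of the
shipped analyses.

## Known limitations

- The model answers one query at a time; it is not an end-to-end
  structure predictor, and no global structure assembly (MFE-style or
  otherwise) is built on top of S.
- The attention realisation is one defensible reading of an
  underspecified design; both it and the gradient-saliency target class
  (true vs predicted partner) are configurable rather than settled.
- The numpy backend is CPU-bound and single-threaded in practice;
  full-database training is possible but slow (hours, not minutes).
- Synthetic-data caveats above: passing tests on generated data
  validates the machinery, not real-data effect sizes.
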