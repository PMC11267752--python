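# Methods

## Task and model

The package treats relation extraction as sentence classification: an
example is a tokenized sentence with a dependency parse, a subject and an
object entity mention, and a label from a fixed inventory of relation
types plus a catch-all *None*. A possibly multi-token mention is reduced
to a single *anchor* token — by default its first token, the one
convention the entity-pair literature states explicitly; syntactic-head
anchoring can be configured instead. The same anchor is used both for
embedding lookup and as a dependency-path endpoint.

The shortest dependency path (SDP) between the two anchors is computed on
the undirected view of the head graph. In a tree the simple path between
two nodes is unique, so "shortest" is a characterization, not a search
problem; the implementation splices the two root paths at their lowest
common ancestor, which is linear in tree depth, and the test suite checks
it against exhaustive simple-path enumeration on random trees.
Dependency-relation labels are stored for round-tripping but never
consulted: only the tree topology determines the path. The path's
*interior* — endpoints excluded — is what downstream averaging consumes;
including the endpoints would double-count them, since every 3L-dim
representation already carries the anchor embeddings in its outer thirds.
When the anchors are tree-adjacent the interior is empty and the middle
third of the SDP representation is the zero vector, the one convention
that injects no spurious token information into an undefined average.

Four instance representations are built from any encoder exposing token
embeddings `H`, a sentence vector, and final-layer attentions:
sentence-level (`cls`, dim L), entity-pair (`ent`, 2L), entity pair with
localized-context pooling (`atlop`, 3L), and entity pair around the mean
interior-token embedding (`sdp`, 3L). Localized-context pooling uses the
anchor token's attention row for each entity (per head), multiplies the
two rows elementwise, sums over heads, and normalizes the result into the
weights of a convex combination of embedding rows. If the two entities
attend to disjoint token sets the product has zero mass and the
normalization is undefined; the implementation falls back to uniform
weights and warns, which keeps the output a convex combination of rows
rather than an arbitrary vector.

Classification is a single linear layer with softmax. The soft-label loss
is the standard noise-aware cross-entropy `−Σ_c y_c log p_c`; it is
implemented with the minus sign (so that it is a loss, minimized at
`p = y` by the Gibbs inequality) and probabilities are clipped at 1e-12
before the logarithm.

## Semi-supervised loop

Soft labels for unlabeled examples come from their top-k (default 5)
labeled nearest neighbors by cosine similarity: similarities are summed
per class (absent classes aggregate 0, zero-norm vectors contribute
similarity 0, negative similarities are kept signed) and the aggregates
are softmaxed. Each iteration imputes the m (default 5) unlabeled
examples with the highest mean similarity to their own top-k labeled
neighbors — the count is inherited from the method's top-5 rule; the
ranking criterion is this package's choice, since only the count is
specified upstream. Neighbors always come from the original hard-labeled
pool, never from previously imputed examples, so imputation noise cannot
compound across iterations. Imputed examples keep their full soft
distribution for training; the hard argmax is used only for the bias
audit and an ablation toggle (`SSLConfig.hard_labels`).

Convergence needs no gold validation data: 10% of the unlabeled pool
(`val_fraction`) is drawn once as a monitoring set — never imputed, never
trained on — and the loop stops when the fraction of monitored
predictions that change between consecutive snapshots drops below
`conv_threshold` (default 0.05), or at `max_iters` (default 10), or when
the candidate pool is exhausted. The model is warm-started between
iterations by default (configurable to retrain from scratch).

A note on training length, because it is load-bearing. The default
refresh is 5 epochs (`TrainConfig.stub_default`, learning rate 0.1 for a
from-scratch linear head; plain `TrainConfig` keeps the 3e-5/5-epoch
fine-tuning profile for trainable-encoder use). The soft targets produced
by softmaxing class aggregates carry uniform residual mass over classes
with no retrieved neighbor — a class with zero evidence still receives
`e^0` in the denominator — so the targets are systematically smoothed.
Used as a finite-step training signal, a soft example's gradient points
at its dominant class; but optimizing the linear head to that objective's
*optimum* forces the head to reproduce the residual mass exactly, which
measurably biases the decision boundary (the over-represented imputed
class gets suppressed near its margin). The short refresh is therefore
integral to the method, not an economy measure.

The self-training baseline pseudo-labels unlabeled examples whose top
predicted probability exceeds 0.90, keeps the 100 most confident, and
hard-labels them with the argmax.

## Evaluation

Micro precision, recall and F1 use the None-exclusion convention:
`TP = #(pred = gold ≠ None)`, precision divides by all non-None
predictions, recall by all non-None gold labels. Correctly predicted None
pairs appear in no numerator or denominator — adding one to an evaluation
set provably changes nothing — while a None mistaken for a relation
lowers precision and a relation mistaken for None lowers recall. All 0/0
ratios are 0. Repeated runs are summarized as mean ± population standard
deviation.

## Synthetic corpus and stub encoder

The generator emulates the structural premise of path-based relation
extraction: the relation's lexical trigger lies on the dependency path
between the entities. Sentences are built from templates with explicit
head assignment (no parser is involved): a chemical subject and a
gene/protein object (1–2 tokens each, anchored at the first token), a
root verb between them — the class trigger for substantive relations, one
of four neutral verbs for None — optionally followed by a preposition so
interior lengths vary between one and two tokens, plus distractor
modifiers attached only off the path. By construction every substantive
example's path interior contains exactly its class trigger and never
another class's; None examples carry no trigger on the path.

The stub encoder is a pure function of (tokens, config). Each token's
vector is Gaussian noise keyed by its surface *and* the sorted bag of
sentence surfaces — the same word repeats within a sentence but varies
across sentences, like a contextual encoder, and the bag-keying keeps the
map order-independent so that permuting tokens permutes embedding rows.
Trigger surfaces additionally receive an offset of magnitude δ along a
fixed seed-derived unit direction per class. Both δ and the noise scale σ
are vector magnitudes (the per-coordinate noise is scaled by 1/√L), so
δ/σ is the realized signal-to-noise ratio, independent of the embedding
width. Attention is a per-head softmax of seeded bilinear scores of the
embeddings. Stub defaults are L = 16 and 2 heads — small enough for
fast tests, wide enough for a nontrivial per-head dimension — and
sentences longer than `max_len` raise an error rather than being silently
clipped.

The default fixture is 4 relation types plus None sampled uniformly, 500
sentences (labeled budget 50, test 100, the rest unlabeled), δ/σ = 4
(δ = 2, σ = 0.5), mirroring a low-resource benchmark at desk scale. At
this calibration nearest-neighbor imputation recovers the planted labels
essentially perfectly and the imputed class distribution matches the
planted one (total-variation distance ≈ 0); the supervised baseline on 50
labels is already strong, so the semi-supervised gain over it is small —
the fixture demonstrates *correct recovery*, not a large augmentation
effect. Lowering δ makes recovery accuracy fall monotonically toward
chance, which the suite checks at three separation levels.

What the fixture does not emulate: real biomedical vocabulary statistics,
entity surfaces that correlate with the relation (here they are pure
noise, which is why the entity-only `ent` scheme is near chance on this
corpus while it is competitive on real benchmarks), parser errors
(templates emit gold trees), triggers off the path, and multi-sentence or
cross-sentence relations. Passing tests therefore certify the algorithmic
contracts — path extraction, pooling arithmetic, loss behavior, the
imputation/convergence machinery, the metric convention — not performance
on real corpora, which additionally depends on a fine-tuned transformer
encoder and a real parser.

## In-context retrieval

Demonstration selection supports a fixed stratified set (every relation
type present, drawn once per seed), per-instance random draws, and
per-instance kNN retrieval by cosine similarity over the SDP
representation (descending, ties broken by example id). The prompt
template is deliberately minimal and machine-parseable — instruction
line, one `sentence => label` line per demonstration with inline entity
markup, and an open test line — since no canonical template exists
upstream; prompts are emitted to files and no language model is called.

## Numerical and degenerate-input conventions

- Cosine similarity with any zero-norm vector is 0.
- Soft labels with all-zero aggregates are uniform (softmax of zeros).
- Overlapping entity spans are accepted; coinciding anchors are flagged
  (`REExample.degenerate`), and the degenerate path is the single shared
  token with empty interior.
- CoNLL-U heads are validated into a connected, acyclic, single-root tree
  at read time; violations raise a parse error naming the sentence.
- All randomness flows from explicit integer seeds; corpus files, model
  checkpoints and reports are byte-reproducible per seed.
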