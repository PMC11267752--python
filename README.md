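# sdpre — dependency-path representations for biomedical relation extraction

`sdpre` is a desk-scale toolkit for sentence-level relation extraction (RE)
between a marked subject and object entity — e.g. deciding whether a
CHEMICAL *inhibits*, *activates*, *binds* or *phosphorylates* a GENE, or
stands in no relation (*None*). Its organizing idea is the **shortest
dependency path (SDP)**: in the undirected view of a sentence's dependency
parse there is exactly one simple path between the two entity tokens, and
its interior tokens tend to carry the lexical trigger of the relation.

Given an encoder that exposes token embeddings `H = [h_1, …, h_n]`, a
sentence vector `h_cls` and final-layer attentions, the package builds four
fixed-length instance representations:

| scheme  | vector                                  | dim |
|---------|-----------------------------------------|-----|
| `cls`   | `h_cls`                                 | L   |
| `ent`   | `h_s ⊕ h_o`                             | 2L  |
| `atlop` | `h_s ⊕ c(s,o) ⊕ h_o`                    | 3L  |
| `sdp`   | `h_s ⊕ mean(h_i : i ∈ SDP interior) ⊕ h_o` | 3L  |

where `h_s`, `h_o` are the entity anchor (first-token) embeddings and
`c(s,o)` is localized-context pooling: per attention head, the elementwise
product of the two entities' attention rows, summed over heads, normalized
to a distribution and used to average `H`. A single linear layer with
softmax, `p(r|x) = softmax(V_x Wᵀ)`, classifies the representation.

On top of this sit three workflows:

* **Semi-supervised soft-label training.** With only a handful of labels,
  unlabeled sentences are labeled by their top-k labeled nearest neighbors
  (cosine similarity in representation space): similarities are aggregated
  per class and softmaxed into a *soft label*, trained with the noise-aware
  cross-entropy `−Σ_c y_c log p_c`. Each iteration imputes the m most
  confidently placed candidates; convergence is declared when predictions
  on a held-back monitoring slice of the unlabeled pool change by less
  than 5% between iterations — no gold validation data needed. A
  confidence-thresholded self-training baseline is included.
* **In-context example retrieval.** kNN retrieval over the SDP
  representation selects demonstration examples per test instance and
  renders prompts (fixed / random / nearest-neighbor modes); no LLM is
  called.
* **Evaluation.** Micro precision/recall/F1 with the None-exclusion
  convention: correctly predicted None instances are dropped from every
  numerator and denominator, while incorrect predictions involving None
  still count.

Everything is testable offline: a synthetic corpus generator emits
dependency-parsed sentences whose relation trigger is planted *on* the
path between the entities (distractors only off-path), and a deterministic
stub encoder gives trigger tokens a class-signal offset of magnitude δ
over token noise σ, so the planted signal is linearly separable by
construction and every knob (separation, budget, class mix) is a dial.

## Worked example

```
$ sdpre synth --seed 0 --out corpus
labeled=50 unlabeled=350 test=100 classes=5

$ sdpre train --corpus corpus --scheme sdp --seed 0 --out run-sdp
scheme=sdp P=0.872 R=1.000 F1=0.932

$ sdpre train --corpus corpus --scheme cls --seed 0 --out run-cls
scheme=cls P=0.691 R=0.817 F1=0.749

$ sdpre ssl --corpus corpus --scheme sdp --seed 0 --out run-ssl
run                P       R      F1
supervised     0.872   1.000   0.932
ssl            0.919   0.963   0.940
stop: prediction variation 0.029 < 0.05; imputed=5; TV=0.000
```

The corpus has 4 relation types plus None, 500 sentences, and a labeled
budget of 50. Training the linear head on the path representation reaches
micro-F1 0.932 on the held-out test split, versus 0.749 for the
sentence-level `cls` representation at the same budget — the planted
trigger sits on the dependency path, and only the path-aware scheme reads
it directly. The semi-supervised run imputes 5 unlabeled examples before
its monitored predictions stabilize (2.9% variation < the 5% threshold),
every imputed argmax matches the planted truth (TV distance 0 between
imputed and true class distributions), and test F1 edges up to 0.940.

```
$ sdpre icl --corpus corpus --mode sdp_nn --k 5 --seed 0 --out prompts
wrote 100 prompts (sdp_nn) to prompts
```

Each prompt holds the instruction, the five nearest labeled neighbors of
the test instance in SDP-representation space (rendered as
``sentence => label`` with inline entity markup), and the open test line.

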