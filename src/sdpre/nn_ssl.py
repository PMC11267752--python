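"""Nearest-neighbor soft-label semi-supervised training, plus self-training.

With only a handful of labeled sentences, a predictor's own pseudo-labels
are too biased to trust.  Instead, unlabeled examples are labeled *softly*
by their proximity to labeled neighbors in representation space:

1. find the top-k labeled nearest neighbors of the unlabeled example by
   cosine similarity;
2. aggregate the similarities per relation class (absent classes get 0);
3. softmax the aggregates into a probability vector — the soft label.

Each iteration imputes the ``m`` most confidently placed unlabeled examples
(highest mean similarity to their own top-k labeled neighbors), adds them
to an augmented set trained with noise-aware cross-entropy, and retrains.
Neighbors always come from the original hard-labeled pool, never from
previously imputed examples, so imputation noise cannot compound.
Convergence needs no gold validation data: a held-back slice of the
unlabeled pool is monitored and the loop stops when the fraction of
monitored predictions that change between iterations drops below a
threshold (default 5%), or at the iteration cap, or when the pool runs out.

A confidence-thresholded self-training baseline is included for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import REModel, TrainConfig, predict, train
from .corpus_io import REExample, RelationSchema
from .metrics import class_distribution
from .representations import build_representation
from .sdp import sdp_for_example


@dataclass(frozen=True)
class SSLConfig:
    """Semi-supervised loop settings.

    ``k_neighbors`` labeled neighbors feed each soft label and
    ``m_impute`` unlabeled examples are imputed per iteration (both 5 by
    default, matching the top-5 retrieval/imputation rule).  The loop
    converges when monitored prediction variation falls below
    ``conv_threshold`` (default 5%); ``val_fraction`` of the unlabeled
    pool is reserved for that monitoring and never imputed or trained on.
    """

    k_neighbors: int = 5
    m_impute: int = 5
    max_iters: int = 10
    conv_threshold: float = 0.05
    val_fraction: float = 0.1
    seed: int = 0
    warm_start: bool = True
    soft_weight: float = 1.0
    hard_labels: bool = False  # ablation: train on the argmax instead of the soft label

    def __post_init__(self) -> None:
        if not (0.0 < self.conv_threshold <= 1.0):
            raise ValueError("conv_threshold must be in (0, 1]")
        if self.k_neighbors < 1 or self.m_impute < 1:
            raise ValueError("k_neighbors and m_impute must be >= 1")


@dataclass
class SSLState:
    """Audit trail of one semi-supervised run."""

    iteration: int = 0
    augmented: list[tuple[str, np.ndarray]] = field(default_factory=list)
    snapshots: list[np.ndarray] = field(default_factory=list)
    converged: bool = False
    reason: str = ""
    log: list[dict] = field(default_factory=list)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity, defined as 0 when either vector has zero norm."""
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(u @ v / (nu * nv))


def _cosine_matrix(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarities, zero-norm rows mapped to similarity 0."""
    nu = np.linalg.norm(U, axis=1, keepdims=True)
    nv = np.linalg.norm(V, axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        S = (U @ V.T) / (nu * nv.T)
    return np.nan_to_num(S, nan=0.0)


def compute_soft_label(
    u_vec: np.ndarray,
    labeled_vecs: np.ndarray,
    labeled_classes: np.ndarray,
    n_classes: int,
    k: int = 5,
) -> np.ndarray:
    """Soft label of one unlabeled vector from its labeled neighbors.

    Similarities of the top-k neighbors are summed per class; classes with
    no neighbor aggregate 0; the soft label is the softmax of the
    aggregates (all-zero aggregates yield the uniform distribution).
    """
    if len(labeled_vecs) == 0:
        raise ValueError("need at least one labeled representation")
    sims = _cosine_matrix(u_vec[None, :], labeled_vecs)[0]
    k = min(k, len(sims))
    top = np.argsort(-sims, kind="stable")[:k]
    agg = np.zeros(n_classes)
    for i in top:
        agg[labeled_classes[i]] += sims[i]
    z = agg - agg.max()
    e = np.exp(z)
    return e / e.sum()


def select_candidates(
    unlabeled: list[tuple[str, np.ndarray]],
    labeled_vecs: np.ndarray,
    m: int,
    k: int = 5,
) -> list[str]:
    """Ids of the ``m`` unlabeled examples most confidently placeable.

    Confidence is the mean cosine similarity to the example's own top-k
    labeled neighbors; returned in descending order, ties broken by id.
    Returns the whole pool when it holds fewer than ``m`` examples.
    """
    if not unlabeled:
        return []
    U = np.stack([v for _, v in unlabeled])
    S = _cosine_matrix(U, labeled_vecs)
    kk = min(k, S.shape[1])
    topk = -np.sort(-S, axis=1)[:, :kk]
    scores = topk.mean(axis=1)
    order = sorted(range(len(unlabeled)), key=lambda i: (-scores[i], unlabeled[i][0]))
    return [unlabeled[i][0] for i in order[:m]]


def check_convergence(prev_preds: np.ndarray, cur_preds: np.ndarray, threshold: float) -> bool:
    """True when the fraction of changed predictions is below the threshold."""
    prev_preds = np.asarray(prev_preds)
    cur_preds = np.asarray(cur_preds)
    if prev_preds.shape != cur_preds.shape:
        raise ValueError("prediction snapshots differ in length")
    if prev_preds.size == 0:
        raise ValueError("empty monitoring set")
    return float(np.mean(prev_preds != cur_preds)) < threshold


def embed_examples(examples: list[REExample], encoder, scheme: str) -> np.ndarray:
    """Representation matrix for a list of examples under one scheme."""
    vecs = []
    for ex in examples:
        enc = encoder.encode(ex.tree.surfaces)
        sdp = sdp_for_example(ex) if scheme == "sdp" else None
        vecs.append(build_representation(scheme, enc, ex, sdp).vector)
    return np.stack(vecs)


def run_ssl(
    labeled: list[REExample],
    unlabeled: list[REExample],
    schema: RelationSchema,
    scheme: str,
    encoder,
    ssl_config: SSLConfig | None = None,
    train_config: TrainConfig | None = None,
) -> tuple[REModel, SSLState]:
    """Iterative nearest-neighbor soft-label augmentation.

    Per cycle: train/refresh the classifier on the hard pool plus the
    current soft-augmented set, select the ``m`` best candidates from the
    remaining unlabeled pool, soft-label them against the *original*
    labeled pool, and fold them in.  Stops on monitored-prediction
    convergence, the iteration cap, or pool exhaustion.
    """
    cfg = ssl_config or SSLConfig()
    tcfg = train_config or TrainConfig.stub_default(seed=cfg.seed)
    if not labeled:
        raise ValueError("labeled pool is empty")

    X_lab = embed_examples(labeled, encoder, scheme)
    y_lab = np.array([schema.index(ex.label) for ex in labeled])
    X_unl = embed_examples(unlabeled, encoder, scheme)
    by_id = {ex.id: i for i, ex in enumerate(unlabeled)}

    rng = np.random.default_rng(cfg.seed)
    n_val = max(1, int(round(cfg.val_fraction * len(unlabeled))))
    val_idx = rng.choice(len(unlabeled), size=n_val, replace=False)
    val_set = set(int(i) for i in val_idx)
    X_val = X_unl[sorted(val_set)]
    pool = [(unlabeled[i].id, X_unl[i]) for i in range(len(unlabeled)) if i not in val_set]

    state = SSLState()
    K = len(schema)
    model = REModel.initialize(schema, scheme, X_lab.shape[1], seed=cfg.seed)
    model = train(model, X_lab, y_lab, tcfg)
    state.snapshots.append(predict(model, X_val))

    while state.iteration < cfg.max_iters:
        if not pool:
            state.reason = "pool exhausted"
            break
        state.iteration += 1
        chosen = select_candidates(pool, X_lab, cfg.m_impute, cfg.k_neighbors)
        chosen_set = set(chosen)
        for ex_id in chosen:
            soft = compute_soft_label(X_unl[by_id[ex_id]], X_lab, y_lab, K, cfg.k_neighbors)
            state.augmented.append((ex_id, soft))
        pool = [(i, v) for i, v in pool if i not in chosen_set]

        X_soft = np.stack([X_unl[by_id[i]] for i, _ in state.augmented])
        Y_soft = np.stack([s for _, s in state.augmented])
        if cfg.hard_labels:
            Y_soft = np.eye(K)[Y_soft.argmax(axis=1)]
        if not cfg.warm_start:
            model = REModel.initialize(schema, scheme, X_lab.shape[1], seed=cfg.seed)
        model = train(model, X_lab, y_lab, tcfg, X_soft, Y_soft, soft_weight=cfg.soft_weight)

        cur = predict(model, X_val)
        variation = float(np.mean(state.snapshots[-1] != cur))
        state.snapshots.append(cur)
        state.log.append({
            "iteration": state.iteration,
            "imputed_ids": chosen,
            "soft_labels": [state.augmented[-len(chosen) + j][1].tolist() for j in range(len(chosen))],
            "variation": variation,
            "augmented_size": len(state.augmented),
        })
        if check_convergence(state.snapshots[-2], cur, cfg.conv_threshold):
            state.converged = True
            state.reason = f"prediction variation {variation:.3f} < {cfg.conv_threshold}"
            break
    else:
        state.reason = "max iterations reached"
    return model, state


def self_training_iteration(
    model: REModel,
    unlabeled: list[tuple[str, np.ndarray]],
    tau: float = 0.90,
    cap: int = 100,
) -> list[tuple[str, int, float]]:
    """Confidence-thresholded pseudo-labeling baseline.

    Returns ``(id, argmax class, confidence)`` for unlabeled examples whose
    top predicted probability exceeds ``tau``, sorted by confidence
    descending (ties by id) and truncated to the ``cap`` most confident.
    """
    if not unlabeled:
        return []
    from .classifier import _softmax, predict_logits

    X = np.stack([v for _, v in unlabeled])
    probs = _softmax(predict_logits(model, X))
    conf = probs.max(axis=1)
    arg = probs.argmax(axis=1)
    picked = [(unlabeled[i][0], int(arg[i]), float(conf[i]))
              for i in range(len(unlabeled)) if conf[i] > tau]
    picked.sort(key=lambda t: (-t[2], t[0]))
    return picked[:cap]


def imputation_bias_report(
    imputed_labels: list[str], gold_labels: list[str]
) -> dict:
    """Compare imputed and gold class distributions on the augmented set.

    Returns both count vectors and the total-variation distance between
    their normalizations (half the L1 distance; 0 = identical, 1 =
    disjoint supports).
    """
    if not imputed_labels or len(imputed_labels) != len(gold_labels):
        raise ValueError("need equal-length, non-empty label lists")
    imp = class_distribution(imputed_labels)
    gold = class_distribution(gold_labels)
    classes = sorted(set(imp) | set(gold))
    p = np.array([imp.get(c, 0) for c in classes], dtype=float)
    q = np.array([gold.get(c, 0) for c in classes], dtype=float)
    tv = 0.5 * np.abs(p / p.sum() - q / q.sum()).sum()
    return {"imputed_counts": imp, "gold_counts": gold, "tv_distance": float(tv)}
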