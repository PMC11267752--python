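"""Synthetic relation-extraction corpora with planted dependency-path signal.

The generator emulates the structural assumption behind path-based relation
extraction: the tokens on the shortest dependency path between two entities
carry the relation's lexical trigger.  Each sentence is built from a
template with an explicit head assignment (no parser involved):

* a chemical subject mention and a gene/protein object mention, both
  possibly multi-token, anchored at their first token;
* a root verb between them — the class's trigger lemma for substantive
  relations, a neutral verb for the None class — optionally followed by a
  preposition so path lengths vary;
* distractor modifiers (adjectives/adverbs) attached to the entity anchors
  or sentence edges, i.e. always *off* the subject–verb–object path.

By construction the path interior of every substantive example contains
exactly its class trigger and never another class's, so a representation
that averages path-interior tokens is strictly more informative here than
a sentence-level one.  Pairing the corpus with the stub encoder (whose
trigger surfaces carry a class-signal offset of magnitude ``delta`` over
noise ``sigma``) yields linearly separable classes whose separation is a
single dial.

Defaults mirror a low-resource benchmark at desk scale: 4 relation types
plus None, 500 sentences, a labeled budget of 50 and signal-to-noise
``delta/sigma = 4``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

import json

import numpy as np

from .corpus_io import (
    UNLABELED,
    DependencyTree,
    EntityMention,
    REExample,
    RelationSchema,
    Token,
    write_conllu,
    write_examples,
)
from .encoding import EncoderConfig

DEFAULT_TRIGGERS = {
    "INHIBITION": "inhibits",
    "ACTIVATION": "activates",
    "BINDING": "binds",
    "PHOSPHORYLATION": "phosphorylates",
}

NEUTRAL_VERBS = ("accompanies", "precedes", "follows", "parallels")

DISTRACTORS = (
    "novel", "potent", "recombinant", "human", "selective", "putative",
    "stable", "soluble", "endogenous", "purified", "mutant", "native",
    "markedly", "strongly", "weakly", "reportedly",
)

PREPOSITIONS = ("of", "with", "via")


@dataclass(frozen=True)
class SynthConfig:
    """Corpus-generation settings.

    ``triggers`` maps each relation type to its distinct trigger lemma;
    ``class_probs`` is the sampling distribution over relation types plus
    None (uniform by default).  ``delta`` and ``sigma`` parameterize the
    stub encoder's class-signal magnitude and token-noise scale.
    """

    n_examples: int = 500
    labeled_budget: int = 50
    test_size: int = 100
    triggers: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TRIGGERS))
    distractors: tuple[str, ...] = DISTRACTORS
    neutral_verbs: tuple[str, ...] = NEUTRAL_VERBS
    length_range: tuple[int, int] = (7, 14)
    class_probs: tuple[float, ...] | None = None
    none_share: float | None = None
    delta: float = 2.0
    sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.labeled_budget + self.test_size > self.n_examples:
            raise ValueError("labeled_budget + test_size exceeds n_examples")
        if len(set(self.triggers.values())) != len(self.triggers):
            raise ValueError("every relation needs a distinct trigger lemma")
        if set(self.triggers.values()) & (set(self.distractors) | set(self.neutral_verbs)):
            raise ValueError("trigger lemmas must not appear among distractors or neutral verbs")
        if self.delta < 0 or self.sigma < 0:
            raise ValueError("delta and sigma must be non-negative")
        lo, hi = self.length_range
        if lo < 7:
            raise ValueError("templates need at least 7 tokens")

    @property
    def schema(self) -> RelationSchema:
        return RelationSchema(tuple(self.triggers) + ("None",), none_type="None")

    def probs(self) -> np.ndarray:
        K1 = len(self.triggers) + 1
        if self.class_probs is not None:
            p = np.asarray(self.class_probs, dtype=float)
            if len(p) != K1:
                raise ValueError(f"class_probs needs {K1} entries")
            return p / p.sum()
        if self.none_share is not None:
            rel = (1.0 - self.none_share) / (K1 - 1)
            return np.array([rel] * (K1 - 1) + [self.none_share])
        return np.full(K1, 1.0 / K1)


@dataclass
class SynthCorpus:
    """Generated splits plus the hidden truth for the unmarked ones."""

    labeled: list[REExample]
    unlabeled: list[REExample]
    test: list[REExample]
    truth: dict[str, str]  # gold labels for unlabeled + test ids
    schema: RelationSchema
    config: SynthConfig


def _make_sentence(
    rng: np.random.Generator, cfg: SynthConfig, label: str, ex_id: str
) -> REExample:
    """One templated sentence with its head-assigned dependency tree."""
    if label == "None":
        verb = cfg.neutral_verbs[rng.integers(len(cfg.neutral_verbs))]
    else:
        verb = cfg.triggers[label]
    use_prep = bool(rng.integers(2))
    subj_len = int(rng.integers(1, 3))
    obj_len = int(rng.integers(1, 3))
    core = subj_len + 1 + int(use_prep) + obj_len
    lo, hi = cfg.length_range
    target = int(rng.integers(max(lo, core), hi + 1))
    n_fill = max(0, target - core)
    n_pre = int(rng.integers(0, n_fill + 1))
    n_post = n_fill - n_pre

    surfaces: list[str] = []
    surfaces += [str(cfg.distractors[rng.integers(len(cfg.distractors))]) for _ in range(n_pre)]
    s_start = len(surfaces)
    surfaces += [f"chem{rng.integers(200)}" for _ in range(subj_len)]
    v_pos = len(surfaces)
    surfaces.append(verb)
    p_pos = None
    if use_prep:
        p_pos = len(surfaces)
        surfaces.append(str(PREPOSITIONS[rng.integers(len(PREPOSITIONS))]))
    o_start = len(surfaces)
    surfaces += [f"gene{rng.integers(200)}" for _ in range(obj_len)]
    surfaces += [str(cfg.distractors[rng.integers(len(cfg.distractors))]) for _ in range(n_post)]

    heads = [0] * len(surfaces)
    deprels = ["dep"] * len(surfaces)
    for i in range(n_pre):  # pre-fillers modify the subject anchor
        heads[i], deprels[i] = s_start, "amod"
    heads[s_start], deprels[s_start] = v_pos, "nsubj"
    for i in range(s_start + 1, v_pos):
        heads[i], deprels[i] = s_start, "flat"
    heads[v_pos], deprels[v_pos] = -1, "root"
    if p_pos is not None:
        heads[p_pos], deprels[p_pos] = v_pos, "case"
        heads[o_start], deprels[o_start] = p_pos, "obl"
    else:
        heads[o_start], deprels[o_start] = v_pos, "obj"
    for i in range(o_start + 1, o_start + obj_len):
        heads[i], deprels[i] = o_start, "flat"
    for i in range(o_start + obj_len, len(surfaces)):  # post-fillers modify object anchor
        heads[i], deprels[i] = o_start, "amod"

    tree = DependencyTree(tuple(
        Token(index=i, surface=s, head=h, deprel=d)
        for i, (s, h, d) in enumerate(zip(surfaces, heads, deprels))
    ))
    return REExample(
        id=ex_id,
        tree=tree,
        subject=EntityMention(start=s_start, end=s_start + subj_len, etype="CHEMICAL"),
        object=EntityMention(start=o_start, end=o_start + obj_len, etype="GENE"),
        label=label,
    )


def generate_corpus(config: SynthConfig | None = None) -> SynthCorpus:
    """Generate labeled / unlabeled / test splits, deterministic per seed.

    Unlabeled examples carry :data:`UNLABELED`; their planted labels (and
    the test labels) are kept in ``truth`` keyed by example id.
    """
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    schema = cfg.schema
    probs = cfg.probs()

    examples = []
    for i in range(cfg.n_examples):
        label = schema.types[int(rng.choice(len(schema), p=probs))]
        examples.append(_make_sentence(rng, cfg, label, ex_id=f"synth-{i:05d}"))

    order = rng.permutation(cfg.n_examples)
    lab_idx = order[: cfg.labeled_budget]
    test_idx = order[cfg.labeled_budget : cfg.labeled_budget + cfg.test_size]
    unl_idx = order[cfg.labeled_budget + cfg.test_size :]

    labeled = [examples[i] for i in lab_idx]
    test = [examples[i] for i in test_idx]
    truth = {examples[i].id: examples[i].label for i in np.concatenate([unl_idx, test_idx])}
    from dataclasses import replace
    unlabeled = [replace(examples[i], label=UNLABELED) for i in unl_idx]
    return SynthCorpus(labeled=labeled, unlabeled=unlabeled, test=test,
                       truth=truth, schema=schema, config=cfg)


def make_stub_signal(config: SynthConfig) -> EncoderConfig:
    """Stub-encoder settings matching the corpus's planted triggers.

    Each trigger surface maps to its relation's schema index so the
    encoder adds ``delta`` along that class's direction; all other tokens
    get noise of scale ``sigma`` only.
    """
    schema = config.schema
    return EncoderConfig(
        seed=config.seed,
        sigma=config.sigma,
        delta=config.delta,
        trigger_classes={trig: schema.index(rel) for rel, trig in config.triggers.items()},
    )


def write_corpus(corpus: SynthCorpus, out_dir: str | Path) -> dict[str, Path]:
    """Write splits as JSON Lines + CoNLL-U, with a truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, split in (("labeled", corpus.labeled), ("unlabeled", corpus.unlabeled),
                        ("test", corpus.test)):
        p = out / f"{name}.jsonl"
        with p.open("w") as fh:
            write_examples(split, fh)
        paths[name] = p
        c = out / f"{name}.conllu"
        with c.open("w") as fh:
            write_conllu([ex.tree for ex in split], fh)
        paths[f"{name}_conllu"] = c
    truth_path = out / "truth.jsonl"
    with truth_path.open("w") as fh:
        for ex_id in sorted(corpus.truth):
            fh.write(json.dumps({"id": ex_id, "label": corpus.truth[ex_id]}) + "\n")
    paths["truth"] = truth_path
    schema_path = out / "schema.json"
    schema_path.write_text(json.dumps(
        {"types": list(corpus.schema.types), "none_type": corpus.schema.none_type}))
    paths["schema"] = schema_path
    return paths
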