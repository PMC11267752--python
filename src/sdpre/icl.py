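"""In-context example selection and prompt assembly (no LLM calls).

Demonstration examples for a prompting experiment can be chosen three
ways: a fixed stratified set shared by every test instance, a fresh random
draw per instance, or per-instance k-nearest-neighbor retrieval in
representation space (cosine similarity over the dependency-path
representation is the intended metric).  Stratified sampling guarantees
every relation type present in the pool appears among the demonstrations.

The prompt template is deliberately minimal and machine-parseable: an
instruction line, one demonstration per line rendered as
``sentence => label`` with inline entity markup, and a final test line
ending in ``=>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import REExample

ARROW = "=>"

DEFAULT_INSTRUCTION = (
    "Classify the relation between the marked CHEMICAL and GENE entities. "
    "Answer with one relation type."
)


def render_sentence(ex: REExample) -> str:
    """Sentence text with inline entity markup.

    Subject tokens are wrapped ``[S:TYPE ... ]`` and object tokens
    ``[O:TYPE ... ]`` so the entity pair survives rendering.
    """
    parts: list[str] = []
    for t in ex.tree.tokens:
        s = t.surface
        if t.index == ex.subject.start:
            s = f"[S:{ex.subject.etype} {s}"
        if t.index == ex.object.start:
            s = f"[O:{ex.object.etype} {s}"
        if t.index == ex.subject.end - 1:
            s = f"{s} ]"
        if t.index == ex.object.end - 1:
            s = f"{s} ]"
        parts.append(s)
    return " ".join(parts)


@dataclass(frozen=True)
class PromptSpec:
    """Everything needed to render one prompt."""

    instruction: str
    demonstrations: tuple[tuple[str, str], ...]  # (rendered sentence, label)
    test_rendering: str
    mode: str = "fixed"  # fixed | random | sdp_nn


def retrieve_neighbors(
    test_vec: np.ndarray,
    pool: list[tuple[np.ndarray, REExample]],
    k: int,
) -> list[REExample]:
    """Top-k pool examples by cosine similarity to the test vector.

    Descending similarity, ties broken by example id; the whole pool when
    ``k`` exceeds its size.  Zero-norm vectors score similarity 0.
    """
    from .nn_ssl import cosine_similarity

    if not pool:
        raise ValueError("retrieval pool is empty")
    scored = [(cosine_similarity(test_vec, v), ex) for v, ex in pool]
    scored.sort(key=lambda t: (-t[0], t[1].id))
    return [ex for _, ex in scored[:k]]


def stratified_sample(
    pool: list[REExample], per_class: int, seed: int
) -> list[REExample]:
    """``per_class`` examples per relation type present in the pool.

    Deterministic per seed; a class with fewer than ``per_class`` examples
    contributes all of them.  Output is ordered by class name, then draw.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[REExample]] = {}
    for ex in pool:
        by_class.setdefault(ex.label, []).append(ex)
    out: list[REExample] = []
    for label in sorted(by_class):
        members = sorted(by_class[label], key=lambda e: e.id)
        take = min(per_class, len(members))
        idx = rng.choice(len(members), size=take, replace=False)
        out.extend(members[i] for i in sorted(idx))
    return out


def build_prompt(spec: PromptSpec) -> str:
    """Render one prompt: instruction, demonstrations, open test line."""
    lines = [spec.instruction]
    for sentence, label in spec.demonstrations:
        lines.append(f"{sentence} {ARROW} {label}")
    lines.append(f"{spec.test_rendering} {ARROW}")
    return "\n".join(lines) + "\n"


def parse_prompt(text: str) -> tuple[str, list[tuple[str, str]], str]:
    """Inverse of :func:`build_prompt`: (instruction, demos, test sentence)."""
    lines = text.rstrip("\n").split("\n")
    instruction = lines[0]
    demos = []
    for line in lines[1:-1]:
        sentence, _, label = line.rpartition(f" {ARROW} ")
        demos.append((sentence, label))
    test = lines[-1]
    if not test.endswith(ARROW):
        raise ValueError("prompt does not end with an open test line")
    return instruction, demos, test[: -len(ARROW)].rstrip()


def make_prompts(
    test_items: list[tuple[np.ndarray, REExample]],
    pool: list[tuple[np.ndarray, REExample]],
    mode: str,
    k: int,
    seed: int = 0,
    instruction: str = DEFAULT_INSTRUCTION,
) -> list[tuple[str, PromptSpec]]:
    """One prompt spec per test instance under the chosen selection mode.

    ``fixed`` draws one stratified demonstration set shared by all
    instances; ``random`` redraws per instance; ``sdp_nn`` retrieves the
    k nearest pool neighbors of each test representation.
    """
    if mode not in ("fixed", "random", "sdp_nn"):
        raise ValueError(f"unknown selection mode {mode!r}")
    pool_examples = [ex for _, ex in pool]
    out = []
    if mode == "fixed":
        fixed = stratified_sample(pool_examples, per_class=max(1, k // _n_classes(pool_examples)), seed=seed)
        fixed_demos = tuple((render_sentence(e), e.label) for e in fixed)
    for i, (vec, test_ex) in enumerate(test_items):
        if mode == "fixed":
            demos = fixed_demos
        elif mode == "random":
            rng = np.random.default_rng((seed, i))
            idx = rng.choice(len(pool_examples), size=min(k, len(pool_examples)), replace=False)
            demos = tuple((render_sentence(pool_examples[j]), pool_examples[j].label) for j in sorted(idx))
        else:
            neigh = retrieve_neighbors(vec, pool, k)
            demos = tuple((render_sentence(e), e.label) for e in neigh)
        spec = PromptSpec(instruction=instruction, demonstrations=demos,
                          test_rendering=render_sentence(test_ex), mode=mode)
        out.append((test_ex.id, spec))
    return out


def _n_classes(examples: list[REExample]) -> int:
    return max(1, len({ex.label for ex in examples}))
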