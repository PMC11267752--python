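"""Data model and I/O for relation-extraction examples and dependency parses.

A relation-extraction (RE) example is one sentence with a dependency parse,
a marked subject and object entity mention, and an optional relation label
drawn from a fixed schema (a set of relation types plus ``None``).

Two on-disk formats are supported:

* standard 10-column CoNLL-U for dependency parses, and
* a JSON Lines dialect for full RE examples — one object per line with keys
  ``id``, ``tokens`` (list of ``{surface, head, deprel}``; ``head`` is a
  0-based token index, ``-1`` for the root), ``subject`` / ``object``
  (``{start, end, type, anchor?}``, half-open 0-based spans) and optional
  ``label``.

Indices are 0-based half-open everywhere inside the package; CoNLL-U's
1-based convention is converted at the boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator

#: Sentinel head value marking the root token (internal and JSONL dialect).
ROOT = -1

#: Label value for examples whose relation is unknown (the unlabeled pool).
UNLABELED = "__UNLABELED__"


class MalformedParseError(ValueError):
    """Head pointers do not form a single-rooted tree."""


class ValidationError(ValueError):
    """An RE example violates the data-model invariants."""


@dataclass(frozen=True)
class Token:
    """One sentence token: surface form, syntactic head and relation label.

    ``head`` is the 0-based index of the syntactic head, or :data:`ROOT`.
    ``deprel`` is stored for round-tripping but never used in path
    computation — only the tree topology matters for the shortest
    dependency path.
    """

    index: int
    surface: str
    head: int
    deprel: str = "dep"


@dataclass(frozen=True)
class DependencyTree:
    """A rooted dependency tree over a sentence's tokens."""

    tokens: tuple[Token, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        validate_tree(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def root(self) -> int:
        """Index of the token whose head is :data:`ROOT`."""
        return next(t.index for t in self.tokens if t.head == ROOT)

    @property
    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]

    def heads(self) -> list[int]:
        return [t.head for t in self.tokens]


def validate_tree(tokens: Iterable[Token], name: str = "<sentence>") -> None:
    """Check connectivity, acyclicity and single-rootedness by traversal.

    Raises :class:`MalformedParseError` naming the offending sentence.
    """
    toks = list(tokens)
    n = len(toks)
    if n == 0:
        raise MalformedParseError(f"{name}: empty sentence")
    for i, t in enumerate(toks):
        if t.index != i:
            raise MalformedParseError(f"{name}: token index {t.index} at position {i}")
        if t.head != ROOT and not (0 <= t.head < n):
            raise MalformedParseError(f"{name}: head {t.head} out of range")
    roots = [t.index for t in toks if t.head == ROOT]
    if len(roots) != 1:
        raise MalformedParseError(f"{name}: expected exactly one root, found {len(roots)}")
    # Walk up from every token; a cycle never reaches the root.
    for t in toks:
        seen = set()
        cur = t.index
        while cur != ROOT:
            if cur in seen:
                raise MalformedParseError(f"{name}: cycle through token {cur}")
            seen.add(cur)
            cur = toks[cur].head


@dataclass(frozen=True)
class EntityMention:
    """A possibly multi-token entity: half-open span, type and anchor token.

    The anchor is the single token used for embedding lookup and as the
    dependency-path endpoint; it defaults to the first token of the span.
    """

    start: int
    end: int
    etype: str
    anchor: int = -1

    def __post_init__(self) -> None:
        if self.anchor == -1:
            object.__setattr__(self, "anchor", self.start)
        if not (0 <= self.start < self.end):
            raise ValidationError(f"bad span [{self.start}, {self.end})")
        if not (self.start <= self.anchor < self.end):
            raise ValidationError(f"anchor {self.anchor} outside span [{self.start}, {self.end})")


@dataclass(frozen=True)
class REExample:
    """One relation-extraction instance."""

    id: str
    tree: DependencyTree
    subject: EntityMention
    object: EntityMention
    label: str = UNLABELED

    def __post_init__(self) -> None:
        n = len(self.tree)
        for which, m in (("subject", self.subject), ("object", self.object)):
            if m.end > n:
                raise ValidationError(f"example {self.id}: {which} span end {m.end} > sentence length {n}")

    @property
    def degenerate(self) -> bool:
        """True when the two anchors coincide (overlapping mentions)."""
        return self.subject.anchor == self.object.anchor


@dataclass(frozen=True)
class RelationSchema:
    """Ordered relation-type inventory; one entry may be the None class."""

    types: tuple[str, ...]
    none_type: str | None = "None"

    def __post_init__(self) -> None:
        object.__setattr__(self, "types", tuple(self.types))
        if len(set(self.types)) != len(self.types):
            raise ValidationError("relation type names must be unique")
        if self.none_type is not None and self.none_type not in self.types:
            raise ValidationError(f"none_type {self.none_type!r} not among types")

    def __len__(self) -> int:
        return len(self.types)

    def index(self, label: str) -> int:
        try:
            return self.types.index(label)
        except ValueError:
            raise ValidationError(f"unknown relation type {label!r}") from None


# ---------------------------------------------------------------------------
# CoNLL-U

def read_conllu(source: IO[str] | str) -> list[DependencyTree]:
    """Parse CoNLL-U text into dependency trees.

    Multiword-token lines (``1-2``) and empty-node lines (``1.1``) are
    skipped.  CoNLL-U 1-based heads are converted to 0-based, with head 0
    mapped to :data:`ROOT`.
    """
    if isinstance(source, str):
        lines: Iterator[str] = iter(source.splitlines())
    else:
        lines = iter(source.read().splitlines())

    trees: list[DependencyTree] = []
    current: list[Token] = []
    sent_id = "<sentence 1>"

    def flush() -> None:
        nonlocal current
        if current:
            validate_tree(current, name=sent_id)
            trees.append(DependencyTree(tuple(current)))
            current = []

    for line in lines:
        line = line.rstrip("\n")
        if line.startswith("#"):
            if line.startswith("# sent_id"):
                sent_id = line.split("=", 1)[-1].strip()
            continue
        if not line.strip():
            flush()
            sent_id = f"<sentence {len(trees) + 1}>"
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise MalformedParseError(f"{sent_id}: expected ≥8 tab-separated columns, got {len(cols)}")
        tok_id = cols[0]
        if "-" in tok_id or "." in tok_id:
            continue  # multiword token / empty node
        try:
            idx = int(tok_id) - 1
            head = int(cols[6])
        except ValueError as exc:
            raise MalformedParseError(f"{sent_id}: non-integer id/head in line {line!r}") from exc
        current.append(Token(index=idx, surface=cols[1], head=ROOT if head == 0 else head - 1, deprel=cols[7]))
    flush()
    return trees


def write_conllu(trees: Iterable[DependencyTree], dest: IO[str]) -> None:
    """Serialize trees as 10-column CoNLL-U (unused columns ``_``)."""
    for i, tree in enumerate(trees, 1):
        dest.write(f"# sent_id = {i}\n")
        for t in tree.tokens:
            head = 0 if t.head == ROOT else t.head + 1
            dest.write(f"{t.index + 1}\t{t.surface}\t_\t_\t_\t_\t{head}\t{t.deprel}\t_\t_\n")
        dest.write("\n")


# ---------------------------------------------------------------------------
# RE examples (JSON Lines dialect)

def _mention_from_json(obj: dict, which: str, ex_id: str) -> EntityMention:
    try:
        return EntityMention(
            start=obj["start"], end=obj["end"], etype=obj["type"],
            anchor=obj.get("anchor", -1),
        )
    except (KeyError, ValidationError) as exc:
        raise ValidationError(f"example {ex_id}: bad {which} mention: {exc}") from exc


def read_examples(source: IO[str] | str, schema: RelationSchema) -> list[REExample]:
    """Read RE examples from the JSON Lines dialect, validating each one.

    A missing ``label`` key yields :data:`UNLABELED`; a label outside the
    schema raises :class:`ValidationError` naming the example.
    """
    text = source if isinstance(source, str) else source.read()
    examples: list[REExample] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip():
            continue
        obj = json.loads(line)
        ex_id = str(obj.get("id", f"line{lineno}"))
        tokens = tuple(
            Token(index=i, surface=t["surface"], head=t["head"], deprel=t.get("deprel", "dep"))
            for i, t in enumerate(obj["tokens"])
        )
        try:
            tree = DependencyTree(tokens)
        except MalformedParseError as exc:
            raise ValidationError(f"example {ex_id}: {exc}") from exc
        label = obj.get("label", UNLABELED)
        if label != UNLABELED and label not in schema.types:
            raise ValidationError(f"example {ex_id}: unknown relation type {label!r}")
        try:
            ex = REExample(
                id=ex_id, tree=tree,
                subject=_mention_from_json(obj["subject"], "subject", ex_id),
                object=_mention_from_json(obj["object"], "object", ex_id),
                label=label,
            )
        except ValidationError:
            raise
        examples.append(ex)
    return examples


def example_to_json(ex: REExample) -> dict:
    obj = {
        "id": ex.id,
        "tokens": [{"surface": t.surface, "head": t.head, "deprel": t.deprel} for t in ex.tree.tokens],
        "subject": {"start": ex.subject.start, "end": ex.subject.end,
                    "type": ex.subject.etype, "anchor": ex.subject.anchor},
        "object": {"start": ex.object.start, "end": ex.object.end,
                   "type": ex.object.etype, "anchor": ex.object.anchor},
    }
    if ex.label != UNLABELED:
        obj["label"] = ex.label
    return obj


def write_examples(examples: Iterable[REExample], dest: IO[str]) -> None:
    for ex in examples:
        dest.write(json.dumps(example_to_json(ex), sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Entity blinding

def blind_entities(example: REExample, placeholder: str = "@{etype}$") -> REExample:
    """Replace entity-token surfaces with a typed placeholder.

    Every token inside either mention span gets the placeholder built from
    the mention's entity type (e.g. ``@CHEMICAL$``); the tree structure,
    spans and anchors are untouched.  Idempotent: blinding an already
    blinded example is a no-op.
    """
    surf = {i: placeholder.format(etype=example.subject.etype)
            for i in range(example.subject.start, example.subject.end)}
    # Object wins on overlap; overlap implies a shared token, rare and flagged
    # upstream via `degenerate`.
    surf.update({i: placeholder.format(etype=example.object.etype)
                 for i in range(example.object.start, example.object.end)})
    tokens = tuple(
        replace(t, surface=surf.get(t.index, t.surface)) for t in example.tree.tokens
    )
    return replace(example, tree=DependencyTree(tokens))
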