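"""Shortest-dependency-path extraction.

The shortest dependency path (SDP) between two tokens is the unique simple
path connecting them in the undirected view of the dependency tree.  Edge
direction and dependency-relation labels are ignored: what matters is which
tokens lie between the two entity anchors, since those interior tokens
("SDP tokens") tend to carry the lexical trigger of the relation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .corpus_io import ROOT, DependencyTree, MalformedParseError, REExample


@dataclass(frozen=True)
class SDPResult:
    """Path between two anchors: endpoints inclusive, plus its interior.

    ``interior`` is ``path`` minus its two endpoints — the tokens whose
    embeddings are averaged into the middle third of the SDP representation.
    """

    path: tuple[int, ...]
    interior: tuple[int, ...]


def extract_sdp(tree: DependencyTree, a: int, b: int) -> SDPResult:
    """Return the unique simple path from token ``a`` to token ``b``.

    Uses the root-path meet: walk each anchor up to the root, find the
    lowest common ancestor, and splice the two half-paths.  Equivalent to
    BFS on the undirected head graph but linear in tree depth.
    """
    n = len(tree)
    for name, idx in (("a", a), ("b", b)):
        if not (0 <= idx < n):
            raise IndexError(f"anchor {name}={idx} out of bounds for sentence of length {n}")
    if a == b:
        return SDPResult(path=(a,), interior=())

    heads = tree.heads()

    def root_path(i: int) -> list[int]:
        out = [i]
        while heads[i] != ROOT:
            i = heads[i]
            out.append(i)
            if len(out) > n:
                raise MalformedParseError("head chain longer than sentence")
        return out

    up_a = root_path(a)
    up_b = root_path(b)
    on_b = {tok: d for d, tok in enumerate(up_b)}
    for d_a, tok in enumerate(up_a):
        if tok in on_b:
            lca_a, lca_b = d_a, on_b[tok]
            break
    else:  # pragma: no cover - impossible for a validated tree
        raise MalformedParseError("anchors lie in disconnected components")

    path = tuple(up_a[: lca_a + 1] + up_b[:lca_b][::-1])
    return SDPResult(path=path, interior=path[1:-1])


def sdp_for_example(example: REExample) -> SDPResult:
    """SDP between the subject and object anchors of an example."""
    return extract_sdp(example.tree, example.subject.anchor, example.object.anchor)
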