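"""Fixed-length instance representations for relation classification.

Four schemes turn an encoded sentence plus an entity pair into one vector:

* ``CLS`` (dim L): the sentence vector alone.
* ``ENT`` (dim 2L): concatenated anchor-token embeddings ``h_s ⊕ h_o``.
* ``ATLOP`` (dim 3L): ``h_s ⊕ c(s,o) ⊕ h_o`` where the localized context
  ``c(s,o)`` is an attention-derived weighted average of all token
  embeddings — per head, the subject's and object's attention rows are
  multiplied elementwise; the head-summed product is normalized to a
  distribution ``a`` and ``c = Hᵀa``.
* ``SDP`` (dim 3L): ``h_s ⊕ mean(H[interior]) ⊕ h_o`` over the interior
  tokens of the shortest dependency path between the anchors.

Multi-token entities contribute only their anchor (first) token; when the
dependency path has no interior tokens the SDP middle third is the zero
vector, which injects no spurious token information into the classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .corpus_io import EntityMention, REExample
from .encoding import EncoderOutput
from .sdp import SDPResult

SCHEMES = ("cls", "ent", "atlop", "sdp")

#: Multiplier of the encoder width L per scheme.
SCHEME_DIM_FACTOR = {"cls": 1, "ent": 2, "atlop": 3, "sdp": 3}


@dataclass(frozen=True)
class Representation:
    vector: np.ndarray
    scheme: str

    @property
    def dim(self) -> int:
        return self.vector.shape[0]


def cls_rep(enc: EncoderOutput) -> Representation:
    """Sentence-level representation: the CLS vector unchanged."""
    return Representation(vector=enc.h_cls.copy(), scheme="cls")


def ent_rep(enc: EncoderOutput, subject: EntityMention, obj: EntityMention) -> Representation:
    """Concatenation of the two anchor-token embeddings."""
    return Representation(
        vector=np.concatenate([enc.H[subject.anchor], enc.H[obj.anchor]]),
        scheme="ent",
    )


def local_context(enc: EncoderOutput, subject: EntityMention, obj: EntityMention) -> np.ndarray:
    """Localized context vector: tokens both entities attend to, averaged.

    Per head, the elementwise product of the two anchors' attention rows is
    taken; products are summed over heads and normalized to a distribution
    used to weight the embedding rows.  A zero-mass product (the two
    entities attend to disjoint tokens) falls back to uniform weights with
    a warning — the normalization is otherwise undefined.
    """
    q = (enc.A[:, subject.anchor, :] * enc.A[:, obj.anchor, :]).sum(axis=0)
    total = q.sum()
    if total <= 0.0:
        warnings.warn("zero-mass entity-attention product; using uniform context weights")
        a = np.full(enc.n_words, 1.0 / enc.n_words)
    else:
        a = q / total
    return enc.H.T @ a


def atlop_rep(enc: EncoderOutput, subject: EntityMention, obj: EntityMention) -> Representation:
    """Anchor embeddings concatenated around the localized context vector."""
    return Representation(
        vector=np.concatenate(
            [enc.H[subject.anchor], local_context(enc, subject, obj), enc.H[obj.anchor]]
        ),
        scheme="atlop",
    )


def sdp_rep(
    enc: EncoderOutput, sdp: SDPResult, subject: EntityMention, obj: EntityMention
) -> Representation:
    """Anchor embeddings concatenated around the mean interior-token embedding."""
    if sdp.interior:
        middle = enc.H[list(sdp.interior)].mean(axis=0)
    else:
        middle = np.zeros(enc.L)
    return Representation(
        vector=np.concatenate([enc.H[subject.anchor], middle, enc.H[obj.anchor]]),
        scheme="sdp",
    )


def build_representation(
    scheme: str,
    enc: EncoderOutput,
    example: REExample,
    sdp: SDPResult | None = None,
) -> Representation:
    """Dispatch to one of the four schemes.

    ``sdp`` is required by (and only used by) the SDP scheme.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if scheme == "cls":
        return cls_rep(enc)
    if scheme == "ent":
        return ent_rep(enc, example.subject, example.object)
    if scheme == "atlop":
        return atlop_rep(enc, example.subject, example.object)
    if sdp is None:
        raise ValueError("the SDP scheme requires a precomputed dependency path")
    return sdp_rep(enc, sdp, example.subject, example.object)
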